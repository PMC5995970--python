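"""Contig/HSP filtering, interval-union coverage and the sweep."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpsweep.evaluation import (
    CoverageResult,
    HspFilterConfig,
    best_hsp_per_query,
    filter_contigs_by_length,
    filter_hsps,
    grid_points,
    k_sweep,
    merge_intervals,
    reference_coverage,
    remove_redundant_contigs,
    run_configuration,
)
from cpsweep.io_formats import Contig, Hsp, revcomp
from cpsweep.simdata import SimParams, simulate_dataset


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _hsp(query="q", score=100.0, align_len=200, s_start=1, s_end=None,
         identity=95.0, evalue=1e-40, subject="ref"):
    if s_end is None:
        s_end = s_start + align_len - 1
    return Hsp(query, subject, identity, align_len, 1, align_len,
               s_start, s_end, score, evalue)


def _mask_coverage(hsps, ref_len):
    """Independent per-position boolean-mask oracle."""
    mask = np.zeros(ref_len, dtype=bool)
    for h in hsps:
        lo, hi = h.subject_interval()
        mask[lo:hi] = True
    return int(mask.sum())


class TestContigFilters:
    def test_length_boundary(self):
        contigs = [Contig(f"c{n}", "A" * n) for n in (149, 150, 151)]
        assert [len(c) for c in filter_contigs_by_length(contigs)] == [150, 151]

    def test_empty_and_all_pass(self):
        assert filter_contigs_by_length([]) == []
        contigs = [Contig("a", "A" * 200)]
        assert filter_contigs_by_length(contigs) == contigs

    def test_contained_substring_removed(self):
        rng = np.random.default_rng(0)
        big = _random_seq(rng, 600)
        contigs = [Contig("big", big), Contig("sub", big[100:300])]
        kept = remove_redundant_contigs(contigs)
        assert [c.contig_id for c in kept] == ["big"]

    def test_revcomp_substring_removed(self):
        rng = np.random.default_rng(1)
        big = _random_seq(rng, 600)
        contigs = [Contig("big", big), Contig("rc", revcomp(big[200:450]))]
        kept = remove_redundant_contigs(contigs)
        assert [c.contig_id for c in kept] == ["big"]

    def test_near_identical_containment_removed_via_aligner(self):
        rng = np.random.default_rng(2)
        big = _random_seq(rng, 600)
        sub = list(big[100:400])
        sub[50] = "ACGT"[("ACGT".index(sub[50]) + 1) % 4]  # one mismatch
        contigs = [Contig("big", big), Contig("near", "".join(sub))]
        kept = remove_redundant_contigs(contigs)
        assert [c.contig_id for c in kept] == ["big"]

    def test_disjoint_contigs_kept(self):
        rng = np.random.default_rng(3)
        contigs = [Contig("a", _random_seq(rng, 300)), Contig("b", _random_seq(rng, 250))]
        assert len(remove_redundant_contigs(contigs)) == 2


class TestBestHsp:
    def test_max_score_kept(self):
        hsps = [_hsp(score=370), _hsp(score=200)]
        assert best_hsp_per_query(hsps) == [hsps[0]]

    def test_empty(self):
        assert best_hsp_per_query([]) == []

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            hsps = []
            for q in ("q1", "q2", "q3"):
                for _ in range(3):
                    hsps.append(
                        _hsp(
                            query=q,
                            score=float(rng.integers(10, 500)),
                            align_len=int(rng.integers(50, 400)),
                            s_start=int(rng.integers(1, 1000)),
                        )
                    )
            got = {h.query_id: h for h in best_hsp_per_query(hsps)}
            for q in ("q1", "q2", "q3"):
                group = [h for h in hsps if h.query_id == q]
                expected = min(
                    group,
                    key=lambda h: (
                        -h.score, -h.align_len, min(h.s_start, h.s_end), h.subject_id,
                    ),
                )
                assert got[q] == expected


class TestFilterHsps:
    def test_identity_strictly_greater(self):
        cfg = HspFilterConfig(min_identity=85.0)
        assert filter_hsps([_hsp(identity=84.9, align_len=200)], cfg) == []
        assert filter_hsps([_hsp(identity=85.0, align_len=200)], cfg) == []
        assert len(filter_hsps([_hsp(identity=85.1, align_len=200)], cfg)) == 1

    def test_length_strictly_greater(self):
        cfg = HspFilterConfig(min_hsp_len=150)
        assert filter_hsps([_hsp(align_len=150)], cfg) == []
        assert len(filter_hsps([_hsp(align_len=151)], cfg)) == 1

    def test_evalue_only_when_configured(self):
        weak = _hsp(evalue=1e-10)
        assert len(filter_hsps([weak], HspFilterConfig())) == 1
        assert filter_hsps([weak], HspFilterConfig.construction_profile()) == []

    def test_construction_profile_values(self):
        cfg = HspFilterConfig.construction_profile()
        assert (cfg.min_identity, cfg.min_hsp_len, cfg.max_evalue) == (80.0, 150, 1e-30)


class TestCoverage:
    def test_overlapping_intervals_union(self):
        hsps = [_hsp(align_len=100, s_start=1, s_end=100),
                _hsp(query="q2", align_len=100, s_start=51, s_end=150)]
        cov = reference_coverage(hsps, 1000)
        assert cov.covered_bp == 150 == _mask_coverage(hsps, 1000)
        assert cov.proportion == pytest.approx(0.15)
        assert cov.raw_hsp_bp == 200  # raw sum double-counts the overlap

    def test_no_hsps(self):
        cov = reference_coverage([], 500)
        assert (cov.covered_bp, cov.proportion) == (0, 0.0)

    def test_full_span(self):
        cov = reference_coverage([_hsp(align_len=400, s_start=1, s_end=400)], 400)
        assert cov.proportion == 1.0

    def test_out_of_range_names_query(self):
        with pytest.raises(ValueError, match="'q'"):
            reference_coverage([_hsp(align_len=100, s_start=950, s_end=1049)], 1000)

    def test_minus_strand_counts_identically(self):
        plus = [_hsp(align_len=100, s_start=11, s_end=110)]
        minus = [_hsp(align_len=100, s_start=110, s_end=11)]
        assert (
            reference_coverage(plus, 500).covered_bp
            == reference_coverage(minus, 500).covered_bp
        )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(1, 280), st.integers(1, 120)),
        min_size=0,
        max_size=25,
    )
)
def test_union_equals_mask_oracle(raw):
    """Interval-union coverage equals the per-position boolean mask."""
    ref_len = 400
    hsps = []
    for i, (start, length) in enumerate(raw):
        end = min(start + length - 1, ref_len)
        hsps.append(_hsp(query=f"q{i}", align_len=end - start + 1,
                         s_start=start, s_end=end))
    cov = reference_coverage(hsps, ref_len)
    assert cov.covered_bp == _mask_coverage(hsps, ref_len)
    assert cov.covered_bp <= min(cov.raw_hsp_bp, ref_len)


def test_coverage_monotone_in_filter_thresholds():
    """Tightening identity or length cutoffs never increases coverage."""
    rng = np.random.default_rng(6)
    hsps = [
        _hsp(
            query=f"q{i}",
            identity=float(rng.uniform(70, 100)),
            align_len=int(rng.integers(100, 400)),
            s_start=int(rng.integers(1, 3000)),
        )
        for i in range(60)
    ]
    ref_len = 4000
    last = None
    for ident in (70, 75, 80, 85, 90, 95):
        cov = reference_coverage(
            filter_hsps(hsps, HspFilterConfig(min_identity=ident, min_hsp_len=1)),
            ref_len,
        )
        if last is not None:
            assert cov.covered_bp <= last
        last = cov.covered_bp
    last = None
    for cutoff in (100, 150, 200, 250, 300):
        cov = reference_coverage(
            filter_hsps(hsps, HspFilterConfig(min_identity=0, min_hsp_len=cutoff)),
            ref_len,
        )
        if last is not None:
            assert cov.covered_bp <= last
        last = cov.covered_bp


def test_merge_intervals_basic():
    assert merge_intervals([(5, 10), (0, 6), (20, 30), (10, 12)]) == [(0, 12), (20, 30)]
    assert merge_intervals([]) == []


class TestSweep:
    def test_default_grid_size(self):
        assert len(grid_points()) == 126

    def test_custom_grid_size(self):
        assert len(grid_points((17,), (21, 25), (150, 200))) == 3 * 2

    def test_sweep_best_matches_independent_reruns(self):
        """The sweep's fast path equals running every grid point on its own."""
        ds = simulate_dataset(
            SimParams(genome_len=6000, seed=3, insert_mean=400, insert_sd=30, depth=25)
        )
        mrls, k_range, cutoffs = (17, 25), (31, 37), (150, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = k_sweep(ds.reads, ds.reference, mrls, k_range, cutoffs)
            assert len(table.rows) == len(grid_points(mrls, k_range, cutoffs))
            for row in table.rows:
                solo = run_configuration(
                    ds.reads,
                    ds.reference,
                    row.min_read_len,
                    row.k,
                    HspFilterConfig(min_hsp_len=row.hsp_len_cutoff),
                )
                assert solo.covered_bp == row.covered_bp
                assert solo.n_contigs == row.n_contigs
        assert table.best.proportion == max(r.proportion for r in table.rows)
        top = [r for r in table.rows if r.proportion == table.best.proportion]
        assert table.best.k == min(r.k for r in top)  # ties -> smaller k

    def test_sweep_tsv_layout(self, tmp_path):
        row = CoverageResult(17, 31, 150, 100, 1000, 0.1, 2, 1, 120)
        from cpsweep.evaluation import SweepTable

        table = SweepTable([row], row)
        path = tmp_path / "sweep.tsv"
        table.write_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[:3] == ["min_read_len", "k", "hsp_len_cutoff"]
        assert "proportion" in header
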