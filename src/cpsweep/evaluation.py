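"""Configuration sweep and reference-coverage scoring.

The pipeline's selection statistic: assemble reads at each odd k, filter
contigs and HSPs, and measure what fraction of the reference genome the
retained best-per-query HSPs cover.  The sweep runs the full
(minimum read length x k x HSP-length cutoff) grid and selects the
configuration with maximal coverage proportion.

Coverage is computed from the *union* of HSP subject intervals, which
guarantees a proportion <= 1; the raw sum of HSP lengths (which can
double-count overlapping intervals) is reported alongside for comparison
with summation-based bookkeeping.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .assembler import (
    AssemblyConfig,
    _assemble_from_graph,
    _count_from_pairs,
    _seq_pairs,
    k_sweep_values,
)
from .homology import AlignParams, build_seed_index, find_hsps, hsps_for_contig_set
from .io_formats import Contig, Hsp, QualRead, revcomp
from .qc import QcConfig, qc_reads


@dataclass
class HspFilterConfig:
    """Thresholds applied to best-per-query HSPs before coverage.

    Both inequalities are strict: identity must exceed ``min_identity`` and
    alignment length must exceed ``min_hsp_len``.  ``max_evalue`` is off by
    default; the construction-stage profile (identity 80, e-value 1e-30)
    enables it.  HSPs lacking an e-value pass an enabled e-value filter
    (the field is optional in externally supplied tables).
    """

    min_identity: float = 85.0
    min_hsp_len: int = 150
    max_evalue: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_hsp_len < 1:
            raise ValueError("min_hsp_len must be >= 1")

    @classmethod
    def construction_profile(cls) -> "HspFilterConfig":
        """Looser identity (80) plus an e-value ceiling of 1e-30, the
        combination used when assembling the final sequence rather than
        ranking k values."""
        return cls(min_identity=80.0, min_hsp_len=150, max_evalue=1e-30)


@dataclass
class CoverageCore:
    """Union coverage of a reference by a set of HSP subject intervals."""

    covered_bp: int
    ref_len: int
    proportion: float
    raw_hsp_bp: int
    intervals: tuple[tuple[int, int], ...]


@dataclass
class CoverageResult:
    """Coverage outcome for one (min_read_len, k, hsp_len_cutoff) point."""

    min_read_len: int
    k: int
    hsp_len_cutoff: int
    covered_bp: int
    ref_len: int
    proportion: float
    n_contigs: int
    n_hsps_kept: int
    raw_hsp_bp: int = 0
    intervals: tuple[tuple[int, int], ...] = field(default=(), repr=False)


@dataclass
class SweepTable:
    """All grid rows plus the best row (max proportion, ties to smaller k)."""

    rows: list[CoverageResult]
    best: CoverageResult

    _TSV_COLUMNS = [
        "min_read_len",
        "k",
        "hsp_len_cutoff",
        "n_contigs",
        "n_hsps_kept",
        "covered_bp",
        "ref_len",
        "proportion",
        "raw_hsp_bp",
    ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in self._TSV_COLUMNS] for r in self.rows],
            columns=self._TSV_COLUMNS,
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        df = self.to_dataframe()
        df["proportion"] = df["proportion"].map(lambda x: f"{x:.6f}")
        df.to_csv(path, sep="\t", index=False)


def filter_contigs_by_length(
    contigs: Iterable[Contig], min_len: int = 150
) -> list[Contig]:
    """Remove contigs *shorter than* ``min_len`` (length == min_len is kept)."""
    return [c for c in contigs if len(c) >= min_len]


def remove_redundant_contigs(
    contigs: Sequence[Contig],
    containment_identity: float = 95.0,
    containment_fraction: float = 0.98,
    align_params: AlignParams | None = None,
) -> list[Contig]:
    """Containment-based redundancy removal.

    A contig is dropped when it aligns, on either strand, over at least
    ``containment_fraction`` of its own length at >= ``containment_identity``
    percent identity to a longer (or equal-length, earlier-sorted) kept
    contig.  Candidates are processed longest first, ties broken by id, so
    the outcome is deterministic.  This stands in for an overlap-layout
    merge step: unitigs from one graph never contain each other, so it
    matters mainly for externally supplied contig sets.
    """
    params = align_params or AlignParams()
    ordered = sorted(contigs, key=lambda c: (-len(c), c.contig_id))
    kept: list[Contig] = []
    for cand in ordered:
        contained = False
        rc = revcomp(cand.seq)
        for keeper in kept:
            if cand.seq in keeper.seq or rc in keeper.seq:
                contained = True
                break
            if len(cand) >= params.seed_len:
                for hsp in find_hsps(cand, keeper.seq, params):
                    qlo, qhi = hsp.query_interval()
                    if (
                        qhi - qlo >= containment_fraction * len(cand)
                        and hsp.pct_identity >= containment_identity
                    ):
                        contained = True
                        break
            if contained:
                break
        if not contained:
            kept.append(cand)
    return kept


def best_hsp_per_query(hsps: Iterable[Hsp]) -> list[Hsp]:
    """Keep exactly one HSP per query: maximal score, ties broken by longer
    alignment, then smaller subject start, then subject id."""
    best: dict[str, Hsp] = {}
    order: list[str] = []
    for h in hsps:
        key = (-h.score, -h.align_len, min(h.s_start, h.s_end), h.subject_id)
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            order.append(h.query_id)
        else:
            cur_key = (-cur.score, -cur.align_len, min(cur.s_start, cur.s_end), cur.subject_id)
            if key < cur_key:
                best[h.query_id] = h
    return [best[q] for q in order]


def filter_hsps(hsps: Iterable[Hsp], config: HspFilterConfig | None = None) -> list[Hsp]:
    """Strict-threshold HSP filter: identity > min, length > min, and
    (when configured) e-value < max."""
    config = config or HspFilterConfig()
    out = []
    for h in hsps:
        if h.pct_identity <= config.min_identity:
            continue
        if h.align_len <= config.min_hsp_len:
            continue
        if (
            config.max_evalue is not None
            and h.evalue is not None
            and h.evalue >= config.max_evalue
        ):
            continue
        out.append(h)
    return out


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and disjoint."""
    ivs = sorted(iv for iv in intervals if iv[1] > iv[0])
    merged: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            if hi > merged[-1][1]:
                merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


def reference_coverage(hsps: Sequence[Hsp], ref_len: int) -> CoverageCore:
    """Union coverage of the reference by HSP subject intervals.

    Each interval is normalised to 0-based half-open regardless of strand;
    ``covered_bp`` is the union length and ``raw_hsp_bp`` the (possibly
    double-counting) sum of HSP alignment lengths.
    """
    if ref_len < 1:
        raise ValueError("ref_len must be >= 1")
    ivs = []
    for h in hsps:
        lo, hi = h.subject_interval()
        if hi > ref_len:
            raise ValueError(
                f"HSP for query {h.query_id!r} spans subject positions "
                f"{h.s_start}..{h.s_end}, beyond reference length {ref_len}"
            )
        ivs.append((lo, hi))
    merged = merge_intervals(ivs)
    covered = sum(hi - lo for lo, hi in merged)
    return CoverageCore(
        covered_bp=covered,
        ref_len=ref_len,
        proportion=covered / ref_len,
        raw_hsp_bp=sum(h.align_len for h in hsps),
        intervals=tuple(merged),
    )


def _configuration_core(
    pairs: Sequence[tuple[bytes, bytes]],
    reference: str,
    min_read_len: int,
    k: int,
    hsp_filter: HspFilterConfig,
    assembly_config: AssemblyConfig,
    align_params: AlignParams,
    seed_index: dict[bytes, list[int]],
) -> tuple[CoverageResult, list[Contig], list[Hsp]]:
    graph = _count_from_pairs(pairs, k)
    if graph.counts:
        contigs = _assemble_from_graph(graph, assembly_config)
    else:
        warnings.warn(f"k={k}: every read is shorter than k; coverage is 0")
        contigs = []
    contigs = filter_contigs_by_length(contigs)
    contigs = remove_redundant_contigs(contigs, align_params=align_params)
    hsps = hsps_for_contig_set(contigs, reference, align_params, index=seed_index)
    best = best_hsp_per_query(hsps)
    kept = filter_hsps(best, hsp_filter)
    cov = reference_coverage(kept, len(reference))
    result = CoverageResult(
        min_read_len=min_read_len,
        k=k,
        hsp_len_cutoff=hsp_filter.min_hsp_len,
        covered_bp=cov.covered_bp,
        ref_len=cov.ref_len,
        proportion=cov.proportion,
        n_contigs=len(contigs),
        n_hsps_kept=len(kept),
        raw_hsp_bp=cov.raw_hsp_bp,
        intervals=cov.intervals,
    )
    return result, contigs, kept


def run_configuration(
    reads: Iterable[QualRead],
    reference: str,
    min_read_len: int,
    k: int,
    hsp_filter: HspFilterConfig | None = None,
    qc_config: QcConfig | None = None,
    assembly_config: AssemblyConfig | None = None,
    align_params: AlignParams | None = None,
    return_artifacts: bool = False,
):
    """Run the full per-configuration pipeline: QC, assembly, length filter,
    redundancy removal, homology search, best-HSP reduction, HSP filter,
    coverage.  Deterministic for fixed inputs.

    With ``return_artifacts=True`` returns ``(CoverageResult, contigs,
    kept_hsps)`` for downstream gap filling.
    """
    hsp_filter = hsp_filter or HspFilterConfig()
    align_params = align_params or AlignParams()
    qc_cfg = replace(qc_config or QcConfig(), min_read_len=min_read_len)
    asm_cfg = replace(assembly_config or AssemblyConfig(), k=k)
    trimmed, _ = qc_reads(reads, qc_cfg)
    pairs = _seq_pairs(trimmed)
    index = build_seed_index(reference, align_params.seed_len)
    result, contigs, kept = _configuration_core(
        pairs, reference, min_read_len, k, hsp_filter, asm_cfg, align_params, index
    )
    if return_artifacts:
        return result, contigs, kept
    return result


def grid_points(
    min_read_lens: Sequence[int] = (17, 21, 25),
    k_range: tuple[int, int] = (17, 99),
    hsp_cutoffs: Sequence[int] = (150,),
) -> list[tuple[int, int, int]]:
    """Enumerate the sweep grid; the default reproduces the 3 x 42 = 126
    configurations of the standard protocol."""
    ks = k_sweep_values(*k_range)
    return [
        (mrl, k, cut) for mrl in min_read_lens for k in ks for cut in hsp_cutoffs
    ]


def k_sweep(
    reads: Iterable[QualRead],
    reference: str,
    min_read_lens: Sequence[int] = (17, 21, 25),
    k_range: tuple[int, int] = (17, 99),
    hsp_cutoffs: Sequence[int] = (150,),
    hsp_filter: HspFilterConfig | None = None,
    qc_config: QcConfig | None = None,
    assembly_config: AssemblyConfig | None = None,
    align_params: AlignParams | None = None,
) -> SweepTable:
    """Evaluate every (min_read_len, k, hsp_len_cutoff) grid point.

    Assembly and alignment run once per (min_read_len, k); HSP-length
    cutoffs only re-filter the same best-per-query HSP list.  ``best`` is
    the row with maximal proportion; ties go to the smaller k, then the
    smaller minimum read length, then the smaller cutoff.
    """
    reads = list(reads)
    base_filter = hsp_filter or HspFilterConfig()
    align_params = align_params or AlignParams()
    ks = k_sweep_values(*k_range)
    index = build_seed_index(reference, align_params.seed_len)
    rows: list[CoverageResult] = []
    for mrl in min_read_lens:
        qc_cfg = replace(qc_config or QcConfig(), min_read_len=mrl)
        trimmed, _ = qc_reads(reads, qc_cfg)
        pairs = _seq_pairs(trimmed)
        for k in ks:
            asm_cfg = replace(assembly_config or AssemblyConfig(), k=k)
            graph = _count_from_pairs(pairs, k)
            contigs = _assemble_from_graph(graph, asm_cfg) if graph.counts else []
            contigs = filter_contigs_by_length(contigs)
            contigs = remove_redundant_contigs(contigs, align_params=align_params)
            hsps = hsps_for_contig_set(contigs, reference, align_params, index=index)
            best = best_hsp_per_query(hsps)
            for cutoff in hsp_cutoffs:
                filt = replace(base_filter, min_hsp_len=cutoff)
                kept = filter_hsps(best, filt)
                cov = reference_coverage(kept, len(reference))
                rows.append(
                    CoverageResult(
                        min_read_len=mrl,
                        k=k,
                        hsp_len_cutoff=cutoff,
                        covered_bp=cov.covered_bp,
                        ref_len=cov.ref_len,
                        proportion=cov.proportion,
                        n_contigs=len(contigs),
                        n_hsps_kept=len(kept),
                        raw_hsp_bp=cov.raw_hsp_bp,
                        intervals=cov.intervals,
                    )
                )
    best_row = max(
        rows,
        key=lambda r: (r.proportion, -r.k, -r.min_read_len, -r.hsp_len_cutoff),
    )
    return SweepTable(rows=rows, best=best_row)
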