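"""Seed-and-extend local alignment of contigs against a reference genome.

This is a small BLASTN-like procedure: exact ``seed_len``-mer matches on
both strands are extended first without gaps under an x-drop rule, then the
two ends are polished with a banded, affine-gap x-drop extension.  Its job
is interchangeable HSP production for the coverage statistic — it is not a
score-identical BLAST emulation, and externally produced BLAST tabular files
(:func:`cpsweep.io_formats.read_blast_tab`) are the full-fidelity input path.

E-values use the Karlin-Altschul formula ``E = K * m * n * exp(-lambda*S)``
with the ungapped constants for the +1/-2 scoring scheme; they are
approximate and serve only the optional e-value filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import Contig, Hsp, revcomp

NEG = -(10**9)

# traceback states
_M, _IX, _IY = 0, 1, 2


@dataclass
class AlignParams:
    """Scoring and heuristics for the internal aligner.

    ``x_drop`` bounds how far an extension may run past its best score
    before stopping; ``band`` is the half-width of the gapped extension band
    (the maximum net indel offset considered).
    """

    seed_len: int = 19
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 20
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    band: int = 8

    def __post_init__(self) -> None:
        if self.seed_len < 11:
            raise ValueError("seed_len must be >= 11")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.x_drop <= 0 or self.band < 1:
            raise ValueError("x_drop must be > 0 and band >= 1")


def build_seed_index(reference: str, seed_len: int) -> dict[bytes, list[int]]:
    """Map every ``seed_len``-mer of the reference to its start positions."""
    ref = reference.encode()
    index: dict[bytes, list[int]] = {}
    for i in range(len(ref) - seed_len + 1):
        index.setdefault(ref[i : i + seed_len], []).append(i)
    return index


def _ungapped_extend(
    q: bytes, s: bytes, qlo: int, qhi: int, slo: int, shi: int, p: AlignParams
) -> tuple[int, int, int, int, int, int]:
    """X-drop ungapped extension of an exact seed match.

    Returns ``(ext_left, ext_right, score_left, score_right, m_left,
    m_right)`` — extension lengths beyond the seed, their score gains at the
    trimmed optimum, and match counts within the retained extensions.
    """
    # rightwards
    best = cur = 0
    bi = bm = m = 0
    i = 0
    lim = min(len(q) - qhi, len(s) - shi)
    while i < lim:
        if q[qhi + i] == s[shi + i]:
            cur += p.match
            m += 1
        else:
            cur += p.mismatch
        i += 1
        if cur > best:
            best, bi, bm = cur, i, m
        elif best - cur > p.x_drop:
            break
    ext_r, score_r, m_r = bi, best, bm
    # leftwards
    best = cur = 0
    bi = bm = m = 0
    i = 0
    lim = min(qlo, slo)
    while i < lim:
        if q[qlo - 1 - i] == s[slo - 1 - i]:
            cur += p.match
            m += 1
        else:
            cur += p.mismatch
        i += 1
        if cur > best:
            best, bi, bm = cur, i, m
        elif best - cur > p.x_drop:
            break
    return bi, ext_r, best, score_r, bm, m_r


def _banded_extend(
    q: bytes, s: bytes, p: AlignParams
) -> tuple[int, int, int, int, int, int, int]:
    """Banded affine-gap x-drop extension from position 0 of both strings.

    Returns ``(q_used, s_used, score, matches, columns, gap_cols,
    gap_opens)`` for the best-scoring endpoint.  Alignments are anchored at
    (0, 0); the caller passes reversed slices for leftward extension.
    """
    B = p.band
    W = 2 * B + 1
    nq, ns = len(q), len(s)
    if nq == 0 or ns == 0:
        return 0, 0, 0, 0, 0, 0, 0

    # rows[i] = (M, Ix, Iy) lists over band offset index (d + B), d = j - i
    M0 = [NEG] * W
    Ix0 = [NEG] * W
    Iy0 = [NEG] * W
    M0[B] = 0
    for d in range(1, B + 1):
        if d <= ns:
            Iy0[B + d] = p.gap_open + (d - 1) * p.gap_extend
    rows = [(M0, Ix0, Iy0)]
    best = (0, 0, B, _M)  # score, i, band index, state

    i = 0
    while i < nq:
        i += 1
        Mp, Ixp, Iyp = rows[-1]
        Mc = [NEG] * W
        Ixc = [NEG] * W
        Iyc = [NEG] * W
        row_best = NEG
        qi = q[i - 1]
        for bi_ in range(W):
            d = bi_ - B
            j = i + d
            if j < 0 or j > ns:
                continue
            if j >= 1:
                prev = max(Mp[bi_], Ixp[bi_], Iyp[bi_])
                if prev > NEG // 2:
                    Mc[bi_] = prev + (p.match if qi == s[j - 1] else p.mismatch)
            if bi_ + 1 < W:
                o = Mp[bi_ + 1] + p.gap_open
                e = Ixp[bi_ + 1] + p.gap_extend
                v = o if o >= e else e
                if v > NEG // 2:
                    Ixc[bi_] = v
            if bi_ >= 1 and j >= 1:
                o = Mc[bi_ - 1] + p.gap_open
                e = Iyc[bi_ - 1] + p.gap_extend
                v = o if o >= e else e
                if v > NEG // 2:
                    Iyc[bi_] = v
            cell = max(Mc[bi_], Ixc[bi_], Iyc[bi_])
            if cell > row_best:
                row_best = cell
            if Mc[bi_] > best[0]:
                best = (Mc[bi_], i, bi_, _M)
        rows.append((Mc, Ixc, Iyc))
        if row_best <= NEG // 2 or row_best < best[0] - p.x_drop:
            break

    score, bi_i, bi_b, state = best
    if score <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback for match / column / gap accounting
    matches = cols = gap_cols = gap_opens = 0
    i, b, st = bi_i, bi_b, state
    while not (i == 0 and b == B and st == _M):
        Mr, Ixr, Iyr = rows[i]
        d = b - B
        j = i + d
        if st == _M:
            cols += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
            Mp, Ixp, Iyp = rows[i - 1]
            target = Mr[b] - (p.match if q[i - 1] == s[j - 1] else p.mismatch)
            if Mp[b] == target:
                st = _M
            elif Ixp[b] == target:
                st = _IX
            else:
                st = _IY
            i -= 1
        elif st == _IX:  # gap in subject, consumes q[i-1]
            cols += 1
            gap_cols += 1
            Mp, Ixp, Iyp = rows[i - 1]
            if Mp[b + 1] + p.gap_open == Ixr[b]:
                st = _M
                gap_opens += 1
            else:
                st = _IX
            i -= 1
            b += 1
        else:  # _IY: gap in query, consumes s[j-1]
            cols += 1
            gap_cols += 1
            if Mr[b - 1] + p.gap_open == Iyr[b]:
                st = _M
                gap_opens += 1
            else:
                st = _IY
            b -= 1
    return bi_i, bi_i + (bi_b - B), score, matches, cols, gap_cols, gap_opens


def _extend_seed(
    q: bytes, s: bytes, qpos: int, spos: int, p: AlignParams
) -> tuple[int, int, int, int, int, int, int, int]:
    """Full two-stage extension of one seed.

    Returns ``(qs, qe, ss, se, score, matches, cols, gap_cols, gap_opens)``
    with 0-based half-open coordinates on ``q`` and ``s``.
    """
    L = p.seed_len
    ext_l, ext_r, sc_l, sc_r, m_l, m_r = _ungapped_extend(
        q, s, qpos, qpos + L, spos, spos + L, p
    )
    q0, q1 = qpos - ext_l, qpos + L + ext_r
    s0, s1 = spos - ext_l, spos + L + ext_r
    gq_r, gs_r, gsc_r, gm_r, gc_r, gg_r, go_r = _banded_extend(q[q1:], s[s1:], p)
    gq_l, gs_l, gsc_l, gm_l, gc_l, gg_l, go_l = _banded_extend(
        q[:q0][::-1], s[:s0][::-1], p
    )
    qs, qe = q0 - gq_l, q1 + gq_r
    ss, se = s0 - gs_l, s1 + gs_r
    score = L * p.match + sc_l + sc_r + gsc_l + gsc_r
    matches = L + m_l + m_r + gm_l + gm_r
    cols = L + ext_l + ext_r + gc_l + gc_r
    return qs, qe, ss, se, score, matches, cols, gg_l + gg_r, go_l + go_r


def _evalue(score: float, m: int, n: int, p: AlignParams) -> float:
    return p.karlin_k * m * n * math.exp(-p.karlin_lambda * score)


def _dedupe(hsps: list[Hsp]) -> list[Hsp]:
    """Drop HSPs whose query and subject extents both lie inside a
    higher-scoring HSP on the same strand."""
    hsps = sorted(hsps, key=lambda h: (-h.score, -h.align_len, h.q_start))
    kept: list[Hsp] = []
    for h in hsps:
        qlo, qhi = h.query_interval()
        slo, shi = h.subject_interval()
        contained = False
        for g in kept:
            if g.strand != h.strand:
                continue
            gql, gqh = g.query_interval()
            gsl, gsh = g.subject_interval()
            if gql <= qlo and qhi <= gqh and gsl <= slo and shi <= gsh:
                contained = True
                break
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.query_interval()[0], h.subject_interval()[0]))
    return kept


def find_hsps(
    query: Contig | str,
    reference: str,
    params: AlignParams | None = None,
    index: dict[bytes, list[int]] | None = None,
    query_id: str = "query",
) -> list[Hsp]:
    """All HSPs between one query and the reference, both strands.

    Coordinates follow the BLAST tabular convention: 1-based inclusive,
    query ascending, subject descending (``s_start > s_end``) on the minus
    strand.  Pass a prebuilt ``index`` (from :func:`build_seed_index`) when
    aligning many queries against the same reference.
    """
    p = params or AlignParams()
    if not reference:
        raise ValueError("reference must be non-empty")
    if isinstance(query, Contig):
        seq, qid = query.seq, query.contig_id
    else:
        seq, qid = query, query_id
    n = len(seq)
    if n < p.seed_len:
        return []
    if index is None:
        index = build_seed_index(reference, p.seed_len)
    sb = reference.encode()
    nref = len(reference)

    hsps: list[Hsp] = []
    for strand, q_str in ((1, seq), (-1, revcomp(seq))):
        qb = q_str.encode()
        covered: dict[int, int] = {}
        for qpos in range(n - p.seed_len + 1):
            hits = index.get(qb[qpos : qpos + p.seed_len])
            if not hits:
                continue
            for spos in hits:
                diag = spos - qpos
                if covered.get(diag, -1) >= qpos:
                    continue
                qs, qe, ss, se, score, matches, cols, gapcols, gapopen = _extend_seed(
                    qb, sb, qpos, spos, p
                )
                for d in {diag, se - qe, ss - qs}:
                    if covered.get(d, -1) < qe - 1:
                        covered[d] = qe - 1
                if strand == 1:
                    q_start, q_end = qs + 1, qe
                    s_start, s_end = ss + 1, se
                else:
                    q_start, q_end = n - qe + 1, n - qs
                    s_start, s_end = se, ss + 1
                hsps.append(
                    Hsp(
                        query_id=qid,
                        subject_id="reference",
                        pct_identity=round(100.0 * matches / cols, 2),
                        align_len=cols,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_start,
                        s_end=s_end,
                        score=score,
                        evalue=_evalue(score, n, nref, p),
                        mismatch=cols - matches - gapcols,
                        gapopen=gapopen,
                    )
                )
    return _dedupe(hsps)


def hsps_for_contig_set(
    contigs: Sequence[Contig],
    reference: str,
    params: AlignParams | None = None,
    index: dict[bytes, list[int]] | None = None,
) -> list[Hsp]:
    """Concatenated HSP lists for a whole contig set (index built once)."""
    p = params or AlignParams()
    if index is None:
        index = build_seed_index(reference, p.seed_len)
    out: list[Hsp] = []
    for contig in contigs:
        out.extend(find_hsps(contig, reference, p, index=index))
    return out
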