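"""A minimal de Bruijn-graph contig assembler.

The assembler exists so the whole k sweep is runnable and testable at desk
scale without any third-party binary: it counts canonical k-mers, prunes
low-count (error) k-mers, and emits every maximal non-branching path of the
remaining graph as a contig.  It deliberately does *not* pop bubbles, clip
tips beyond count pruning, or scaffold with pair information — real
production assemblers do all of that, and the pipeline accepts their contigs
through a FASTA bypass (:func:`cpsweep.io_formats.read_contigs_fasta`).

Only odd k are accepted: an even-length k-mer can equal its own reverse
complement, which makes canonical counting ambiguous and biases coverage
statistics; odd k rules such palindromes out entirely.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Contig, QualRead, revcomp_bytes


class KmerParityError(ValueError):
    """An even k was requested where only odd k are meaningful."""


def _check_odd(k: int) -> None:
    if k % 2 == 0:
        raise KmerParityError(
            f"k={k} is even: even-length k-mers can be their own reverse "
            "complement, so only odd k-mer lengths are used"
        )
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")


@dataclass
class AssemblyConfig:
    """Parameters for one assembly run.

    ``avg_insert_size``, ``pair_cutoff`` and ``min_read_contig_align`` are
    recorded for provenance and reused as defaults by read-back mapping and
    gap filling; pair information is not used during graph construction
    (scaffolding is out of scope), so mates are treated as independent reads.
    """

    k: int = 81
    min_kmer_count: int = 2
    avg_insert_size: int = 500
    pair_cutoff: int = 3
    min_read_contig_align: int = 32

    def __post_init__(self) -> None:
        _check_odd(self.k)
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass
class KmerGraph:
    """Canonical k-mer counts plus bookkeeping for skipped short reads."""

    k: int
    counts: dict[bytes, int]
    n_reads_skipped: int = 0

    @property
    def nodes(self) -> set[bytes]:
        """All (k-1)-mers incident to a counted k-mer (both orientations)."""
        out: set[bytes] = set()
        for km in self.counts:
            for e in (km, revcomp_bytes(km)):
                out.add(e[:-1])
                out.add(e[1:])
        return out


def k_sweep_values(k_min: int, k_max: int) -> list[int]:
    """All odd integers in ``[k_min, k_max]``, ascending.

    Requesting a single explicit even k (``k_min == k_max`` even) is an
    error; an even endpoint of a genuine range is simply rounded inward.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_min == k_max and k_min % 2 == 0:
        _check_odd(k_min)
    start = k_min if k_min % 2 == 1 else k_min + 1
    return list(range(start, k_max + 1, 2))


def _seq_pairs(reads: Iterable[QualRead | str]) -> list[tuple[bytes, bytes]]:
    """Encode reads as (forward, reverse-complement) byte pairs."""
    pairs = []
    for read in reads:
        seq = read if isinstance(read, str) else read.bases
        fwd = seq.encode()
        pairs.append((fwd, revcomp_bytes(fwd)))
    return pairs


def _count_from_pairs(pairs: Sequence[tuple[bytes, bytes]], k: int) -> KmerGraph:
    counts: dict[bytes, int] = {}
    get = counts.get
    skipped = 0
    for fwd, rev in pairs:
        n = len(fwd)
        if n < k:
            skipped += 1
            continue
        for i in range(n - k + 1):
            a = fwd[i : i + k]
            b = rev[n - k - i : n - i]
            if b < a:
                a = b
            counts[a] = get(a, 0) + 1
    return KmerGraph(k=k, counts=counts, n_reads_skipped=skipped)


def count_kmers(reads: Iterable[QualRead | str], k: int) -> KmerGraph:
    """Count canonical k-mers (lexicographic min of k-mer and revcomp).

    Every length-k substring of every read contributes one count; reads
    shorter than k contribute nothing and are tallied in
    ``n_reads_skipped``.
    """
    _check_odd(k)
    return _count_from_pairs(_seq_pairs(reads), k)


def _assemble_from_graph(graph: KmerGraph, config: AssemblyConfig) -> list[Contig]:
    k = graph.k
    surviving = [km for km, c in graph.counts.items() if c >= config.min_kmer_count]
    if not surviving:
        warnings.warn(
            f"k={k}: no k-mer reached min_kmer_count={config.min_kmer_count}; "
            "no contigs produced",
            stacklevel=3,
        )
        return []

    # Directed graph over both orientations; nodes are (k-1)-mers.
    edges: set[bytes] = set()
    for km in surviving:
        edges.add(km)
        edges.add(revcomp_bytes(km))
    out_edges: dict[bytes, list[bytes]] = defaultdict(list)
    indeg: dict[bytes, int] = defaultdict(int)
    for e in edges:
        out_edges[e[:-1]].append(e)
        indeg[e[1:]] += 1
    for lst in out_edges.values():
        lst.sort()

    def interior(node: bytes) -> bool:
        return len(out_edges.get(node, ())) == 1 and indeg.get(node, 0) == 1

    visited: set[bytes] = set()
    raw: list[bytes] = []

    def walk(first: bytes) -> bytes:
        seq = bytearray(first)
        visited.add(first)
        node = first[1:]
        while interior(node):
            nxt = out_edges[node][0]
            if nxt in visited:
                break  # closed a cycle
            visited.add(nxt)
            seq.append(nxt[-1])
            node = nxt[1:]
        return bytes(seq)

    # Paths anchored at branching/terminal nodes, smallest start node first.
    for node in sorted(out_edges):
        if not interior(node):
            for e in out_edges[node]:
                if e not in visited:
                    raw.append(walk(e))
    # Remaining edges lie on isolated simple cycles.
    for e in sorted(edges):
        if e not in visited:
            raw.append(walk(e))

    # Each contig appears once per orientation.  A contig and its reverse
    # complement share the same canonical edge set (for cycles the two
    # traversals start at different rotations, so comparing sequences is not
    # enough); dedupe on the edge set and keep the canonical orientation.
    by_edges: dict[frozenset[bytes], bytes] = {}
    for seq in raw:
        key = frozenset(
            min(seq[i : i + k], revcomp_bytes(seq[i : i + k]))
            for i in range(len(seq) - k + 1)
        )
        form = min(seq, revcomp_bytes(seq))
        prev = by_edges.get(key)
        if prev is None or form < prev:
            by_edges[key] = form
    ordered = sorted(by_edges.values(), key=lambda s: (-len(s), s))
    return [
        Contig(f"contig_{i + 1}_k{k}_len{len(seq)}", seq.decode(), k, "internal")
        for i, seq in enumerate(ordered)
    ]


def assemble_contigs(
    reads: Iterable[QualRead | str], config: AssemblyConfig
) -> list[Contig]:
    """Assemble reads into unitigs (maximal non-branching paths).

    K-mers seen fewer than ``min_kmer_count`` times are pruned first.  The
    output is deterministic: paths are enumerated from the lexicographically
    smallest start node, each contig is reported in its canonical
    orientation, and contigs are sorted longest-first (ties by sequence).
    Every contig has length >= k.
    """
    pairs = _seq_pairs(reads)
    if not pairs:
        raise ValueError("no reads supplied to assemble_contigs")
    _check_odd(config.k)
    graph = _count_from_pairs(pairs, config.k)
    if not graph.counts:
        warnings.warn(
            f"k={config.k} exceeds every read length ({graph.n_reads_skipped} "
            "reads skipped); no contigs produced",
            stacklevel=2,
        )
        return []
    return _assemble_from_graph(graph, config)
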