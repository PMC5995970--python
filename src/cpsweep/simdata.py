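"""Synthetic chloroplast-like datasets: genome, diverged reference, reads.

The generator emulates the shape of a plastome study without any download:

* a circular quadripartite genome LSC-IRa-SSC-IRb in which IRb is the exact
  reverse complement of IRa (the inverted repeat), each IR holding
  ``ir_fraction`` of the genome;
* a reference genome derived from the truth by independent per-site
  substitution at rate ``divergence`` (0.15 by default, matching a
  congeneric reference that is ~85% identical); indels and rearrangements
  are deliberately not modelled so identity bookkeeping stays exact;
* paired 100 bp reads with normally distributed insert sizes, mate 1 from
  the fragment's 5' end and mate 2 as the reverse complement of its 3' end,
  and a linear 5'->3' error-rate ramp whose per-base error probability also
  determines the Phred score written to FASTQ.

Everything is deterministic under a fixed ``seed``: the three stages draw
from independent child streams of one seed sequence, so each stage is also
individually reproducible.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import QualRead, revcomp, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


@dataclass
class SimParams:
    """Generating parameters for one synthetic dataset.

    ``genome_len`` defaults to 20 kb — a scaled-down plastome that keeps the
    full 126-point sweep fast; 150 kb reproduces a realistically sized one.
    ``ssc_fraction`` sets the small single-copy share (real plastomes sit
    near 12-15%); the LSC takes the remainder.
    """

    genome_len: int = 20_000
    ir_fraction: float = 0.15
    ssc_fraction: float = 0.14
    divergence: float = 0.15
    read_len: int = 100
    insert_mean: int = 500
    insert_sd: int = 50
    depth: float = 30.0
    error_rate_start: float = 0.001
    error_rate_end: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.ir_fraction < 0 or self.ssc_fraction < 0:
            raise ValueError("fractions must be >= 0")
        if 2 * self.ir_fraction + self.ssc_fraction >= 1:
            raise ValueError("2*ir_fraction + ssc_fraction must be < 1")
        for rate in (self.error_rate_start, self.error_rate_end):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must be probabilities")


@dataclass
class DivergenceResult:
    """A diverged reference plus the realised substitution bookkeeping."""

    reference: str
    n_substitutions: int
    realized_identity: float


@dataclass
class SimulatedDataset:
    truth_genome: str
    reference: str
    pairs: list[tuple[QualRead, QualRead]]
    params: SimParams
    realized_identity: float

    @property
    def reads(self) -> list[QualRead]:
        """All reads, mates interleaved."""
        return [m for pair in self.pairs for m in pair]


def _child_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def quadripartite_layout(params: SimParams) -> dict[str, tuple[int, int]]:
    """0-based half-open intervals of LSC, IRa, SSC, IRb on the genome."""
    L = params.genome_len
    ir = round(params.ir_fraction * L)
    ssc = round(params.ssc_fraction * L)
    lsc = L - 2 * ir - ssc
    a = lsc
    b = a + ir
    c = b + ssc
    return {"LSC": (0, a), "IRa": (a, b), "SSC": (b, c), "IRb": (c, L)}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_genome(params: SimParams, rng: np.random.Generator | None = None) -> str:
    """A random quadripartite circular genome LSC-IRa-SSC-IRb.

    IRb is the exact reverse complement of IRa; with ``ir_fraction`` 0 the
    genome is a plain repeat-free random sequence.
    """
    if rng is None:
        rng = _child_rngs(params.seed)[0]
    layout = quadripartite_layout(params)
    ir_len = layout["IRa"][1] - layout["IRa"][0]
    lsc = _random_dna(rng, layout["LSC"][1] - layout["LSC"][0])
    ira = _random_dna(rng, ir_len)
    ssc = _random_dna(rng, layout["SSC"][1] - layout["SSC"][0])
    if ir_len == 0:
        return lsc + ssc
    return lsc + ira + ssc + revcomp(ira)


def diverge_reference(
    truth_genome: str,
    divergence: float,
    seed: int | np.random.Generator = 0,
) -> DivergenceResult:
    """Substitute each site independently with probability ``divergence``,
    uniformly over the three alternative bases."""
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(truth_genome.encode(), dtype=np.uint8).copy()
    idx = np.array([_BASE_INDEX[b] for b in arr], dtype=np.int8)
    hit = rng.random(len(arr)) < divergence
    n_sub = int(hit.sum())
    offsets = rng.integers(1, 4, size=n_sub)
    idx[hit] = (idx[hit] + offsets) % 4
    ref = _BASES[idx].tobytes().decode()
    return DivergenceResult(
        reference=ref,
        n_substitutions=n_sub,
        realized_identity=1.0 - n_sub / len(arr) if len(arr) else 1.0,
    )


def _quality_ramp(params: SimParams) -> tuple[np.ndarray, list[int]]:
    """Per-position error probabilities and the Phred scores they imply."""
    n = params.read_len
    if n == 1:
        probs = np.array([params.error_rate_start], dtype=float)
    else:
        probs = np.linspace(params.error_rate_start, params.error_rate_end, n)
    quals = [
        93 if p <= 0 else int(min(93, round(-10.0 * math.log10(p)))) for p in probs
    ]
    return probs, quals


def simulate_reads(
    truth_genome: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> list[tuple[QualRead, QualRead]]:
    """Paired reads from the circular truth genome.

    Fragment starts are uniform on the circle; insert lengths are normal
    (mean, sd) resampled into ``[2*read_len, genome_len]``.  The number of
    pairs is fixed by ``round(depth * genome_len / (2 * read_len))``.
    """
    if rng is None:
        rng = _child_rngs(params.seed)[2]
    L = len(truth_genome)
    if L < 2 * params.read_len or L < params.insert_mean:
        raise ValueError(
            f"genome length {L} is shorter than the insert size "
            f"({params.insert_mean}); cannot draw fragments"
        )
    n_pairs = round(params.depth * L / (2 * params.read_len))
    doubled = truth_genome + truth_genome
    starts = rng.integers(0, L, size=n_pairs)
    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs))
    lo = 2 * params.read_len
    bad = (inserts < lo) | (inserts > L)
    while bad.any():
        inserts[bad] = np.rint(
            rng.normal(params.insert_mean, params.insert_sd, size=int(bad.sum()))
        )
        bad = (inserts < lo) | (inserts > L)
    inserts = inserts.astype(int)

    probs, quals = _quality_ramp(params)
    any_error = probs.sum() > 0
    pairs: list[tuple[QualRead, QualRead]] = []
    rl = params.read_len
    for i in range(n_pairs):
        start = int(starts[i])
        frag = doubled[start : start + inserts[i]]
        m1 = frag[:rl]
        m2 = revcomp(frag[-rl:])
        if any_error:
            m1 = _apply_errors(m1, probs, rng)
            m2 = _apply_errors(m2, probs, rng)
        rid = f"sim{i:06d}"
        pairs.append(
            (
                QualRead(rid, m1, list(quals), mate=1),
                QualRead(rid, m2, list(quals), mate=2),
            )
        )
    return pairs


def _apply_errors(seq: str, probs: np.ndarray, rng: np.random.Generator) -> str:
    hit = rng.random(len(seq)) < probs
    if not hit.any():
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.array([_BASE_INDEX[b] for b in arr], dtype=np.int8)
    offsets = rng.integers(1, 4, size=int(hit.sum()))
    idx[hit] = (idx[hit] + offsets) % 4
    return _BASES[idx].tobytes().decode()


def simulate_dataset(params: SimParams | None = None) -> SimulatedDataset:
    """Generate truth genome, diverged reference and paired reads in one go."""
    params = params or SimParams()
    rng_g, rng_d, rng_r = _child_rngs(params.seed)
    truth = simulate_genome(params, rng_g)
    div = diverge_reference(truth, params.divergence, rng_d)
    pairs = simulate_reads(truth, params, rng_r)
    return SimulatedDataset(
        truth_genome=truth,
        reference=div.reference,
        pairs=pairs,
        params=params,
        realized_identity=div.realized_identity,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | os.PathLike) -> None:
    """Write truth.fa, reference.fa, reads_1.fq, reads_2.fq and params.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([("truth_genome", dataset.truth_genome)], out / "truth.fa")
    write_fasta([("reference", dataset.reference)], out / "reference.fa")
    write_fastq((p[0] for p in dataset.pairs), out / "reads_1.fq")
    write_fastq((p[1] for p in dataset.pairs), out / "reads_2.fq")
    meta = asdict(dataset.params)
    meta["realized_identity"] = dataset.realized_identity
    meta["n_pairs"] = len(dataset.pairs)
    with open(out / "params.json", "w") as fh:
        json.dump(meta, fh, indent=2)
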