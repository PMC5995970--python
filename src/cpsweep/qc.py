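"""Read quality control: hard truncation at the first low-quality base.

The quality-control policy is deliberately blunt: a base whose Phred score
falls below the threshold (default 13, i.e. error probability 0.05) marks the
start of an unreliable 3' segment, and the read is truncated from that base
to its end.  Removing a single interior base would shift the remaining
sequence out of register with the genome, so the whole tail goes.  Reads
that end up shorter than a minimum length (17, 21 or 25 by the default
policy) are then discarded outright.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import QualRead, read_fastq, write_fastq


@dataclass
class QcConfig:
    """Truncation threshold and minimum retained read length."""

    min_phred: int = 13
    min_read_len: int = 17

    def __post_init__(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")


@dataclass
class QcReport:
    """Per-stage read/base accounting for one QC run."""

    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    def add(self, other: "QcReport") -> None:
        self.reads_in += other.reads_in
        self.reads_out += other.reads_out
        self.bases_in += other.bases_in
        self.bases_out += other.bases_out

    def write_tsv(self, path: str | os.PathLike, stage: str = "qc") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["stage", "reads_in", "reads_out", "bases_in", "bases_out"])
            w.writerow([stage, self.reads_in, self.reads_out, self.bases_in, self.bases_out])


def phred_to_error_prob(q: float) -> float:
    """Error probability implied by a Phred score: ``10 ** (-q / 10)``.

    Phred 13 corresponds to an error probability of 0.05 (to two decimals),
    which is the rationale behind the default truncation threshold.
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def phred_truncate(read: QualRead, min_phred: int = 13) -> QualRead:
    """Longest prefix of ``read`` in which every Phred score >= ``min_phred``.

    The first offending base and everything 3' of it are removed; qualities
    are cut in lockstep and identifier/mate are preserved.  May return an
    empty read (removed later by the length filter, never emitted).
    """
    for i, q in enumerate(read.quals):
        if q < min_phred:
            return read.prefix(i)
    return read


def length_filter(
    reads: Iterable[QualRead], min_read_len: int
) -> tuple[list[QualRead], tuple[int, int]]:
    """Keep reads with length >= ``min_read_len`` ("less than" is deleted).

    Returns ``(kept_reads, (n_kept, n_discarded))`` with input order preserved.
    """
    kept: list[QualRead] = []
    discarded = 0
    for read in reads:
        if len(read) >= min_read_len:
            kept.append(read)
        else:
            discarded += 1
    return kept, (len(kept), discarded)


def qc_reads(
    reads: Iterable[QualRead], config: QcConfig | None = None
) -> tuple[list[QualRead], QcReport]:
    """Truncate then length-filter an in-memory read collection."""
    config = config or QcConfig()
    report = QcReport()
    kept: list[QualRead] = []
    for read in reads:
        report.reads_in += 1
        report.bases_in += len(read)
        trimmed = phred_truncate(read, config.min_phred)
        if len(trimmed) >= config.min_read_len:
            kept.append(trimmed)
            report.reads_out += 1
            report.bases_out += len(trimmed)
    return kept, report


def run_qc(
    fastq_in: Sequence[str | os.PathLike],
    out_dir: str | os.PathLike,
    config: QcConfig | None = None,
) -> QcReport:
    """Apply truncation + length filtering to one or two FASTQ files.

    Mates are filtered independently: when one mate of a pair is discarded
    the surviving mate is kept (written to its own output file) rather than
    dropped, which retains the maximum amount of usable sequence.  Output
    files are named ``<stem>.trimmed.fq`` under ``out_dir``, plus a
    ``qc_report.tsv``.
    """
    config = config or QcConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total = QcReport()
    for i, path in enumerate(fastq_in):
        path = Path(path)
        mate = i + 1 if len(fastq_in) == 2 else 0
        kept, report = qc_reads(read_fastq(path, mate=mate), config)
        stem = path.name
        for suffix in (".fastq", ".fq", ".gz"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        write_fastq(kept, out_dir / f"{stem}.trimmed.fq")
        total.add(report)
    total.write_tsv(out_dir / "qc_report.tsv")
    return total
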