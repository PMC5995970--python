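"""Readers and writers for the file formats the pipeline touches.

Supported formats: FASTQ (Phred+33 only), FASTA, and the 12-column
tab-separated BLAST tabular dialect (``-outfmt 6``).  Sequences are DNA over
the alphabet {A, C, G, T, N}; FASTA input is normalised to uppercase on read
and anything outside the alphabet is rejected, which keeps the k-mer code
free of alphabet checks.

Coordinate conventions
----------------------
HSPs carry BLAST coordinates: 1-based, inclusive, with minus-strand subject
hits encoded as ``s_start > s_end``.  All internal interval arithmetic uses
0-based half-open intervals; :meth:`Hsp.subject_interval` performs the
normalisation exactly once.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_BYTES = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT_BYTES)[::-1]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: mate codes: 0 = unpaired, 1 = first mate, 2 = second mate
UNPAIRED = 0


@dataclass
class QualRead:
    """One sequencing read with per-base Phred scores (Phred+33 scale)."""

    read_id: str
    bases: str
    quals: list[int]
    mate: int = UNPAIRED

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred scores must be in [0, 93]")
        if self.mate not in (0, 1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "QualRead":
        """The first ``n`` bases as a new read (id and mate preserved)."""
        return QualRead(self.read_id, self.bases[:n], self.quals[:n], self.mate)


@dataclass
class Contig:
    """An assembled sequence, tagged with the k that produced it.

    ``k_used`` is ``None`` for contigs imported from an external assembler.
    """

    contig_id: str
    seq: str
    k_used: int | None = None
    source: str = "internal"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        if self.k_used is not None:
            if self.k_used % 2 == 0 or not (17 <= self.k_used <= 99):
                raise ValueError(
                    f"contig {self.contig_id!r}: k_used must be odd in [17, 99]"
                )
        if self.source not in ("internal", "external"):
            raise ValueError("source must be 'internal' or 'external'")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Hsp:
    """One local-alignment high-scoring pair, BLAST tabular field set.

    ``score`` holds the bit score when parsed from a BLAST table and the raw
    alignment score when produced by the internal aligner; both are used only
    for ranking within one HSP list, never mixed.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    evalue: float | None = None
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if min(self.s_start, self.s_end) < 1 or min(self.q_start, self.q_end) < 1:
            raise ValueError("HSP coordinates are 1-based; got coordinate < 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def strand(self) -> int:
        """+1 for plus-strand subject hits, -1 for minus."""
        return 1 if self.s_end >= self.s_start else -1

    def subject_interval(self) -> tuple[int, int]:
        """Subject extent as a 0-based half-open interval, strand-agnostic."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    def query_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike, mate: int = UNPAIRED) -> Iterator[QualRead]:
    """Stream Phred+33 FASTQ records as :class:`QualRead` objects.

    ``mate`` tags every read from this file (paired data ships as two files,
    conventionally mates 1 and 2; see :func:`read_paired_fastq`).
    """
    path = Path(path)
    try:
        for record in SeqIO.parse(str(path), "fastq"):
            yield QualRead(
                record.id,
                str(record.seq).upper(),
                list(record.letter_annotations["phred_quality"]),
                mate,
            )
    except ValueError as err:
        raise FormatError(f"{path}: malformed FASTQ record: {err}") from err


def read_paired_fastq(
    path1: str | os.PathLike, path2: str | os.PathLike
) -> Iterator[tuple[QualRead, QualRead]]:
    """Zip two mate files into read pairs; unequal record counts are an error."""
    it1, it2 = read_fastq(path1, mate=1), read_fastq(path2, mate=2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError(f"{path1} and {path2} hold different record counts")
        yield r1, r2  # type: ignore[misc]


def write_fastq(reads: Iterable[QualRead], path: str | os.PathLike) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    def _records():
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = read.quals
            yield rec

    return SeqIO.write(_records(), str(path), "fastq")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, uppercase sequence), ...]``.

    Rejects duplicate identifiers, empty sequences and non-ACGTN symbols.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {record.id!r} has an empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} contains non-ACGTN symbols "
                f"{sorted(bad)}"
            )
        seen[record.id] = seen.get(record.id, 0) + 1
        out.append((record.id, seq))
    dups = sorted(name for name, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"{path}: duplicate identifiers {dups}")
    return out


def write_fasta(
    records: Iterable[tuple[str, str] | Contig],
    path: str | os.PathLike,
    width: int = 70,
) -> int:
    """Write ``(id, seq)`` pairs or :class:`Contig` objects as FASTA."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Contig):
                name, seq = rec.contig_id, rec.seq
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def read_contigs_fasta(path: str | os.PathLike, source: str = "external") -> list[Contig]:
    """Load an external contig FASTA (``k_used`` unknown)."""
    return [Contig(name, seq, None, source) for name, seq in read_fasta(path)]


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(path: str | os.PathLike) -> list[Hsp]:
    """Parse a 12-column BLAST tabular file into :class:`Hsp` objects.

    Minus-strand rows keep ``s_start > s_end`` exactly as printed.
    """
    path = Path(path)
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns "
                    f"({' '.join(_BLAST_COLUMNS)}), got {len(fields)}"
                )
            try:
                hsps.append(
                    Hsp(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        align_len=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        score=float(fields[11]),
                    )
                )
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from err
    return hsps


def _fmt_num(x: float) -> str:
    """Print a number the way BLAST tables do: integers bare, floats compact."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:g}"


def write_blast_tab(hsps: Iterable[Hsp], path: str | os.PathLike) -> int:
    """Serialise HSPs in the 12-column tabular dialect read back by
    :func:`read_blast_tab` (round trip preserves every field)."""
    n = 0
    with open(path, "w") as fh:
        for h in hsps:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:g}",
                        str(h.align_len),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        "{:g}".format(h.evalue if h.evalue is not None else 0.0),
                        _fmt_num(h.score),
                    ]
                )
                + "\n"
            )
            n += 1
    return n
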