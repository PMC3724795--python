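"""Readers and writers for the formats the pipeline touches.

Coordinates are 0-based half-open (BED native) everywhere.  A *tag* is a
mapped short read reduced to the genomic coordinate of its first sequenced
base (the DNase I cut position), its strand and its length.  For a ``+``
strand BED record the 5' end is ``start``; for a ``-`` strand record it is
``end - 1``, the last base of the interval, because BED stores the leftmost
coordinate regardless of strand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

# base -> integer code used throughout (A,C,G,T = 0..3, N = 4)
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = np.array(list("ACGTN"))

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A,C,G,T=0..3, N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(CODE_BASES[codes])


class GenomeSequence:
    """An ordered collection of contigs over the alphabet {A,C,G,T,N}.

    Parameters
    ----------
    contigs
        Mapping from contig name to base string.  Input is uppercased;
        any character outside {A,C,G,T,N} is rejected.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)!r}"
                )
            self.contigs[name] = seq
        self._encoded: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        try:
            return self.contigs[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def encoded(self, name: str) -> np.ndarray:
        """Integer-coded contig sequence, cached."""
        if name not in self._encoded:
            self._encoded[name] = encode_sequence(self[name])
        return self._encoded[name]

    def reverse_complement(self) -> "GenomeSequence":
        """New genome with every contig reverse-complemented (used in tests
        of strand symmetry)."""
        comp = str.maketrans("ACGTN", "TGCAN")
        return GenomeSequence(
            {n: s.translate(comp)[::-1] for n, s in self.contigs.items()}
        )


@dataclass(frozen=True)
class Tag:
    """A mapped sequence tag reduced to its cut coordinate.

    ``five_prime`` is the 0-based genomic coordinate of the first sequenced
    base, i.e. the DNase I cut position.
    """

    contig: str
    five_prime: int
    strand: str
    length: int = 36

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length < 1:
            raise ValueError("tag length must be >= 1")


@dataclass(frozen=True, order=True)
class Interval:
    """A strand-less genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A sorted collection of intervals (DHS calls, gold peaks, open regions).

    Intervals are kept sorted by (contig, start); they are not merged on
    construction — use :func:`dnasebias.evaluation.union_intervals` for a
    disjoint cover.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = sorted(intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals)"

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_contig(self) -> dict[str, np.ndarray]:
        """Per-contig (n, 2) arrays of [start, end), sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.contig, []).append((iv.start, iv.end))
        return {
            c: np.array(pairs, dtype=np.int64).reshape(-1, 2)
            for c, pairs in out.items()
        }


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Soft-masked (lowercase) bases are uppercased; contig order follows the
    file.  An empty file or a file whose first record has no header raises
    :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: expected '>' header on line 1")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tags (BED6 / BAM)


def read_tags(path: str | Path, dialect: str = "bed6") -> list[Tag]:
    """Read mapped tags from a BED6 file or a BAM file.

    BED6 convention: for strand ``+`` the 5' end is ``start``; for ``-`` it
    is ``end - 1``.  Zero-length records and records with a strand outside
    {+,-} are skipped and counted in the log.  For BAM, only primary mapped
    alignments are converted.
    """
    if dialect == "bed6":
        return _read_tags_bed6(Path(path))
    if dialect == "bam":
        return _read_tags_bam(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tags_bed6(path: Path) -> list[Tag]:
    tags: list[Tag] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if end <= start or strand not in ("+", "-"):
                skipped += 1
                continue
            five_prime = start if strand == "+" else end - 1
            tags.append(Tag(chrom, five_prime, strand, end - start))
    if skipped:
        logger.info("read_tags: skipped %d malformed/zero-length records", skipped)
    return tags


def _read_tags_bam(path: Path) -> list[Tag]:
    import pysam

    tags: list[Tag] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            start, end = aln.reference_start, aln.reference_end
            if end is None or end <= start:
                skipped += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            five_prime = start if strand == "+" else end - 1
            tags.append(Tag(aln.reference_name, five_prime, strand, end - start))
    if skipped:
        logger.info("read_tags(bam): skipped %d non-primary/unmapped records", skipped)
    return tags


def write_tags(tags: Iterable[Tag], path: str | Path) -> None:
    """Write tags as BED6 (name '.', score 0), inverse of BED6 read_tags."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            if t.strand == "+":
                start = t.five_prime
            else:
                start = t.five_prime - t.length + 1
            fh.write(f"{t.contig}\t{start}\t{start + t.length}\tt{i}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Intervals (BED3 / narrowPeak)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read BED3/BED6/narrowPeak intervals; columns beyond 3 are ignored."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED requires >= 3 columns, got {len(fields)}"
                )
            intervals.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet(intervals)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write as BED3, sorted by (contig, start); round-trips byte-identically
    through :func:`read_intervals`."""
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# PWM serialization (self-describing JSON)


def write_pwm(pwm, path: str | Path) -> None:
    """Serialize a PWM to JSON, recording alphabet order, window offsets,
    expected frequencies, pseudocount and the full-precision weight matrix."""
    payload = {
        "alphabet": "ACGT",
        "window": {
            "start_offset": pwm.window.start_offset,
            "end_offset": pwm.window.end_offset,
        },
        "expected_freqs": pwm.expected_freqs.tolist(),
        "pseudocount": pwm.pseudocount,
        "weights": pwm.weights.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_pwm(path: str | Path):
    """Inverse of :func:`write_pwm`; full stored precision."""
    from .bias_model import PWM, Window

    with open(path) as fh:
        payload = json.load(fh)
    for key in ("window", "expected_freqs", "pseudocount", "weights"):
        if key not in payload:
            raise FormatError(f"{path}: PWM file missing {key!r} record")
    window = Window(payload["window"]["start_offset"], payload["window"]["end_offset"])
    weights = np.asarray(payload["weights"], dtype=float)
    if weights.shape != (4, window.width):
        raise FormatError(
            f"{path}: weight matrix shape {weights.shape} does not match "
            f"window width {window.width}"
        )
    return PWM(
        weights=weights,
        expected_freqs=np.asarray(payload["expected_freqs"], dtype=float),
        pseudocount=float(payload["pseudocount"]),
        window=window,
    )
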