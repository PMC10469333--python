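"""Core coordinate/sequence types and readers/writers.

Conventions used throughout the package:

* internal coordinates are 0-based, half-open (BED-style);
* SNP positions are 1-based in files and converted at the I/O boundary;
* sequences are upper-case over the alphabet ``{A, C, G, T, N}``;
* one-hot channel order is A, C, G, T and an ``N`` base encodes as an
  all-zero row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed; message names the line."""


class BedParseError(ValueError):
    """Raised when a BED line violates interval invariants."""


@dataclass
class Genome:
    """In-memory genome: mapping of chromosome name to sequence string.

    Sequences are upper-case and restricted to ``{A, C, G, T, N}``.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence of the half-open interval [start, end)."""
        if not (0 <= start < end <= self.length(chrom)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {self.length(chrom)})"
            )
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open genomic interval with optional strand/annotations."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None
    score: float | None = None
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Point-in-interval test at a 0-based position (half-open)."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class SNPRecord:
    """Single-nucleotide variant. ``pos`` is 1-based; ``pos0`` 0-based."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"SNP {self.id}: ref equals alt ({self.ref})")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"SNP {self.id}: only single-nucleotide alleles")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"SNP {self.id}: alleles must be A/C/G/T")
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences upper-cased)."""
    path = Path(path)
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    sequences[current] = "".join(chunks)
                current = line[1:].split()[0] if line[1:].split() else None
                if not current:
                    raise FastaParseError(f"{path}: empty record name at line {lineno}")
                if current in sequences:
                    raise FastaParseError(
                        f"{path}: duplicate record {current!r} at line {lineno}"
                    )
                chunks = []
            else:
                if current is None:
                    raise FastaParseError(
                        f"{path}: sequence before header at line {lineno}"
                    )
                seq = line.strip().upper()
                bad = set(seq) - set(ALPHABET)
                if bad:
                    raise FastaParseError(
                        f"{path}: invalid characters {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
    if current is not None:
        sequences[current] = "".join(chunks)
    if not sequences:
        raise FastaParseError(f"{path}: no FASTA records found")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file. Columns beyond 6 are kept in ``extra``."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            extra = tuple(fields[6:])
            intervals.append(
                GenomicInterval(chrom, start, end, strand, name, score, extra)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_later = iv.score is not None or iv.strand is not None or iv.extra
            if iv.name is not None or has_later:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None or iv.extra:
                fields.append("." if iv.score is None else repr(iv.score))
            if iv.strand is not None or iv.extra:
                fields.append(iv.strand if iv.strand is not None else ".")
            fields.extend(iv.extra)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(
    path: str | Path,
    genome: Genome | None = None,
    return_stats: bool = False,
):
    """Read a VCF-like tab-separated SNP table (CHROM POS ID REF ALT).

    Rows with multi-nucleotide alleles are skipped with a warning; rows whose
    reference allele does not match ``genome`` are excluded and counted.
    """
    path = Path(path)
    records: list[SNPRecord] = []
    n_ref_mismatch = 0
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr"):  # header row
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            chrom, pos_s, snp_id, ref, alt = fields[:5]
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                n_skipped += 1
                logger.warning("%s:%d: non-SNV alleles %s>%s skipped", path, lineno, ref, alt)
                continue
            pos = int(pos_s)
            rec = SNPRecord(snp_id, chrom, pos, ref, alt)
            if genome is not None:
                if chrom not in genome or not (1 <= pos <= genome.length(chrom)):
                    n_ref_mismatch += 1
                    continue
                if genome[chrom][rec.pos0] != ref:
                    n_ref_mismatch += 1
                    continue
            records.append(rec)
    if n_ref_mismatch:
        logger.info("%s: excluded %d SNPs with reference mismatch", path, n_ref_mismatch)
    if return_stats:
        return records, {"ref_mismatch": n_ref_mismatch, "non_snv": n_skipped}
    return records


def write_snp_table(records: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\n")


# ---------------------------------------------------------------------------
# Sequence encoding and windows
# ---------------------------------------------------------------------------

def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode a DNA sequence as an L x 4 float32 matrix (A,C,G,T).

    ``N`` encodes as an all-zero row; any other character is an error.
    """
    seq = sequence.upper()
    idx = np.empty(len(seq), dtype=np.int64)
    for i, base in enumerate(seq):
        code = _BASE_INDEX.get(base)
        if code is None:
            raise ValueError(f"invalid base {base!r} at position {i}")
        idx[i] = code
    eye = np.zeros((5, 4), dtype=np.float32)
    eye[:4] = np.eye(4, dtype=np.float32)
    return eye[idx]


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero rows decode to N)."""
    bases = np.array(list("ACGT"))
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(bases[int(np.argmax(row))])
    return "".join(out)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def extract_window(genome: Genome, chrom: str, center: int, length: int) -> str:
    """Extract a window of ``length`` bases centered on ``center``.

    Centering is left-biased for even lengths: start = center - length // 2.
    Raises if the window runs off the chromosome (callers must filter).
    """
    start = center - length // 2
    end = start + length
    if start < 0 or end > genome.length(chrom):
        raise ValueError(
            f"window [{start}, {end}) for center {center} off chromosome "
            f"{chrom} (length {genome.length(chrom)})"
        )
    return genome.sequences[chrom][start:end]


# ---------------------------------------------------------------------------
# Interval utilities shared by several modules
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal nonempty intersection intervals between two merged sets."""
    a_m = merge_intervals(a) if a else []
    b_m = merge_intervals(b) if b else []
    out: list[GenomicInterval] = []
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_m:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in a_m:
        for other in b_by_chrom.get(iv.chrom, []):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    out.sort(key=lambda v: (v.chrom, v.start))
    return out


def coverage_mask(
    intervals: Iterable[GenomicInterval], chrom: str, length: int
) -> np.ndarray:
    """Boolean per-base coverage array for one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[max(0, iv.start) : min(length, iv.end)] = True
    return mask
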