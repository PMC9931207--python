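"""Genomic interval primitives, BED/FASTA I/O and enhancer construction.

Coordinates are 0-based half-open everywhere (BED native). Enhancers are
fixed 1-kb windows centred on a H3K27ac peak, with windows overlapping any
promoter (±1 kb around every supplied TSS, alternative TSSs included)
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Enhancer",
    "GeneAnnotation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "make_enhancers",
    "open_genome",
    "extract_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_STRANDS = frozenset({"+", "-", "."})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor of the midpoint: deterministic tie-break for even widths
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Enhancer:
    """A fixed-width candidate enhancer derived from a peak.

    ``signal`` is the integrated H3K27ac intensity of the source peak;
    ``clamped`` marks windows truncated at a chromosome edge (dropped by
    default downstream because they break the fixed 1-kb contract).
    """

    interval: GenomicInterval
    signal: float = 0.0
    source_peak: GenomicInterval | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("enhancer signal must be nonnegative")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into intervals (0-based half-open, as on disk)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSV gene table with columns gene_id, chrom, tss, strand."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected gene_id, chrom, tss[, strand]"
                )
            strand = fields[3] if len(fields) >= 4 else "+"
            genes.append(GeneAnnotation(fields[0], fields[1], int(fields[2]), strand))
    return genes


def make_enhancers(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    half_width: int = 500,
    promoter_pad: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
    signals: Sequence[float] | None = None,
) -> list[Enhancer]:
    """Centre a fixed window on each peak and drop promoter-overlapping ones.

    Each peak is replaced by the ``2 * half_width`` window centred on its
    midpoint (floor for even widths). Windows overlapping
    ``[tss - promoter_pad, tss + promoter_pad]`` of any gene are removed.
    Windows running off a chromosome edge (when ``chrom_sizes`` is given)
    are clamped and flagged.
    """
    if signals is not None and len(signals) != len(peaks):
        raise ValueError("signals must align with peaks")

    promoters: list[GenomicInterval] = [
        GenomicInterval(g.chrom, max(0, g.tss - promoter_pad), g.tss + promoter_pad + 1)
        for g in genes
    ]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)

    out: list[Enhancer] = []
    for i, peak in enumerate(peaks):
        c = peak.center
        start, end = c - half_width, c + half_width
        clamped = False
        if start < 0:
            start, clamped = 0, True
        if chrom_sizes is not None:
            size = chrom_sizes.get(peak.chrom)
            if size is None:
                raise KeyError(f"unknown chromosome {peak.chrom!r}")
            if end > size:
                end, clamped = size, True
        window = GenomicInterval(peak.chrom, start, end, peak.strand)
        if any(window.overlaps(p) for p in by_chrom.get(peak.chrom, ())):
            continue
        out.append(
            Enhancer(
                interval=window,
                signal=float(signals[i]) if signals is not None else 0.0,
                source_peak=peak,
                clamped=clamped,
            )
        )
    return out


def open_genome(path: str | Path):
    """Open an indexed FASTA for random access (pyfaidx handle)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def extract_sequence(genome, interval: GenomicInterval) -> str:
    """Extract the uppercase sequence of ``interval`` from ``genome``.

    ``genome`` may be a plain mapping of chromosome name to sequence string
    or a ``pyfaidx.Fasta`` handle. Minus-strand intervals return the reverse
    complement.
    """
    try:
        record = genome[interval.chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {interval.chrom!r}") from None
    chrom_seq = str(record[:]) if not isinstance(record, str) else record
    if interval.end > len(chrom_seq):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end].upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
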