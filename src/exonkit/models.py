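"""Core genomic domain types: intervals, transcripts and gene models.

All coordinates are 0-based, half-open (BED convention). GTF/GFF3 input is
converted at the I/O boundary (:mod:`exonkit.annotation_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval", strict: bool = False) -> bool:
        """Whether ``other`` lies within this interval.

        With ``strict=True`` both of ``other``'s boundaries must be strictly
        internal (no shared endpoint).
        """
        if self.chrom != other.chrom:
            return False
        if strict:
            return self.start < other.start and other.end < self.end
        return self.start <= other.start and other.end <= self.end

    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Transcript:
    """One isoform: an ordered, non-overlapping exon chain on one strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons on mixed strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @cached_property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def total_exon_length(self) -> int:
        return sum(e.length for e in self.exons)

    def attributes_dict(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcript isoforms (all on one chromosome and strand)."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 transcript")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id}: transcripts on multiple chromosomes")
        if len(strands) > 1:
            raise ValueError(f"gene {self.gene_id}: transcripts on mixed strands")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @cached_property
    def exon_units(self) -> tuple[GenomicInterval, ...]:
        """Distinct exon coordinate tuples across all transcripts, sorted."""
        seen = {e for t in self.transcripts for e in t.exons}
        return tuple(sorted(seen, key=lambda e: (e.start, e.end)))

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"gene {self.gene_id}: no transcript {transcript_id!r}")

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)
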