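"""Exon inclusion levels (PSI) from splice-junction read counts.

The inclusion level of an alternative exon is the fraction of the gene's
transcripts that include it, estimated from reads supporting the two
inclusion junctions versus the skip junction. Estimates >= the cutoff
(default 0.5) are called "major", below it "minor"; an empty denominator
yields a missing estimate ("undetermined").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .exon_classify import AE_CASSETTE, ExonCall, select_reference_isoform
from .models import GeneModel, GenomicInterval

JunctionKey = tuple[str, int, int, str]  # chrom, intron start, intron end, strand

MAJOR = "major"
MINOR = "minor"
UNDETERMINED = "undetermined"

INCLUSION_RULES = ("mean", "min", "sum")


@dataclass(frozen=True)
class JunctionCounts:
    """Read support for the three junctions of one cassette-exon event."""

    inclusion_upstream: int
    inclusion_downstream: int
    exclusion: int
    retention: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("inclusion_upstream", "inclusion_downstream", "exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class InclusionEstimate:
    psi: Optional[float]
    n_effective: float
    isoform_class: str

    def __post_init__(self) -> None:
        if (self.psi is None) != (self.isoform_class == UNDETERMINED):
            raise ValueError("psi is missing iff the isoform class is undetermined")


def read_junctions(
    path: Union[str, Path], dialect: str = "simple"
) -> dict[JunctionKey, int]:
    """Read a junction-count TSV into ``{(chrom, start, end, strand): count}``.

    Columns: chrom, intron start, intron end, strand, read count. The
    ``simple`` dialect is 0-based half-open; ``sj_tab`` is 1-based inclusive
    and converted on read. Duplicate keys are summed.
    """
    if dialect not in ("simple", "sj_tab"):
        raise ValueError(f"unknown junction dialect {dialect!r}")
    table: dict[JunctionKey, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"line {lineno}: expected >= 5 tab-separated fields"
                )
            chrom, start_s, end_s, strand, count_s = fields[:5]
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: bad strand symbol {strand!r}")
            start, end, count = int(start_s), int(end_s), int(count_s)
            if count < 0:
                raise ValueError(f"line {lineno}: negative count {count}")
            if dialect == "sj_tab":
                start -= 1  # 1-based inclusive -> 0-based half-open
            key = (chrom, start, end, strand)
            table[key] = table.get(key, 0) + count
    return table


def compute_psi(
    counts: JunctionCounts,
    inclusion_rule: str = "mean",
    major_cutoff: float = 0.5,
) -> InclusionEstimate:
    """PSI = inclusion / (inclusion + exclusion).

    The two inclusion junctions are combined by ``inclusion_rule`` (mean by
    default, so inclusion and exclusion are on the same per-event scale).
    """
    if inclusion_rule not in INCLUSION_RULES:
        raise ValueError(f"unknown inclusion rule {inclusion_rule!r}")
    up, down = counts.inclusion_upstream, counts.inclusion_downstream
    if inclusion_rule == "mean":
        inclusion = (up + down) / 2
    elif inclusion_rule == "min":
        inclusion = min(up, down)
    else:
        inclusion = up + down
    denominator = inclusion + counts.exclusion
    if denominator == 0:
        return InclusionEstimate(None, 0.0, UNDETERMINED)
    psi = inclusion / denominator
    cls = MAJOR if psi >= major_cutoff else MINOR
    return InclusionEstimate(psi, denominator, cls)


def cassette_junction_keys(
    gene: GeneModel, exon: GenomicInterval
) -> Optional[tuple[JunctionKey, JunctionKey, JunctionKey]]:
    """(upstream, downstream, skip) junction keys for a cassette exon.

    Junctions are derived from the reference isoform's exon chain: the gaps
    to the nearest reference exons on either side, and their fusion for the
    skip junction. None when the exon has no reference exon on both sides.
    """
    ref = gene.transcript(select_reference_isoform(gene))
    prev_ends = [e.end for e in ref.exons if e.end <= exon.start]
    next_starts = [e.start for e in ref.exons if e.start >= exon.end]
    if not prev_ends or not next_starts:
        return None
    left, right = max(prev_ends), min(next_starts)
    chrom, strand = gene.chrom, gene.strand
    up = (chrom, left, exon.start, strand)
    down = (chrom, exon.end, right, strand)
    skip = (chrom, left, right, strand)
    if strand == "-":
        up, down = down, up
    return up, down, skip


def psi_for_gene(
    gene: GeneModel,
    exon_calls: Sequence[ExonCall],
    junctions: dict[JunctionKey, int],
    labels: Sequence[str] = (AE_CASSETTE,),
    inclusion_rule: str = "mean",
    major_cutoff: float = 0.5,
) -> dict[GenomicInterval, InclusionEstimate]:
    """Inclusion estimate per exon whose label is in ``labels``.

    Exons with no matching junction key at all get a missing estimate.
    """
    out: dict[GenomicInterval, InclusionEstimate] = {}
    for call in exon_calls:
        if call.label not in labels:
            continue
        keys = cassette_junction_keys(gene, call.interval)
        if keys is None:
            out[call.interval] = InclusionEstimate(None, 0.0, UNDETERMINED)
            continue
        up_key, down_key, skip_key = keys
        if not any(k in junctions for k in keys):
            out[call.interval] = InclusionEstimate(None, 0.0, UNDETERMINED)
            continue
        counts = JunctionCounts(
            inclusion_upstream=junctions.get(up_key, 0),
            inclusion_downstream=junctions.get(down_key, 0),
            exclusion=junctions.get(skip_key, 0),
        )
        out[call.interval] = compute_psi(counts, inclusion_rule, major_cutoff)
    return out
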