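"""Exon classification and alternative-splicing event detection.

Two complementary schemes are implemented:

* *intact* — each distinct exon coordinate tuple of a gene is one unit and
  receives a single label (constitutive, cassette, alt-3'/5' SS, both-ends
  variable, or intron-retention merged);
* *regions* — the union of exonic bases is segmented into maximal runs that
  are covered by every isoform (constitutive regions, CR) or only a proper
  subset (alternative regions, AR).

Event detection compares an alternative isoform against the reference
isoform (maximum exon count, then longest, then smallest id) and reports
exon skipping, alternative 3'/5' splice sites, intron retention and exonic
introns from interval relations alone.

Conventions: A3SS is variation at the acceptor-side exon boundary (exon
start in transcription direction) and A5SS at the donor side; boundaries at
the transcription start/end of an isoform are not splice sites and, by
default, do not make an exon alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import GeneModel, GenomicInterval, Transcript

# intact-scheme labels
CE = "CE"
AE_CASSETTE = "AE_CASSETTE"
AE_ALT3SS = "AE_ALT3SS"
AE_ALT5SS = "AE_ALT5SS"
AE_ALT_BOTH = "AE_ALT_BOTH"
AE_IR_MERGED = "AE_IR_MERGED"
EXON_LABELS = (CE, AE_CASSETTE, AE_ALT3SS, AE_ALT5SS, AE_ALT_BOTH, AE_IR_MERGED)

# region-scheme labels
CR = "CR"
AR = "AR"

# event types
ES = "ES"
A3SS = "A3SS"
A5SS = "A5SS"
IR = "IR"
EXONIC_INTRON = "EXONIC_INTRON"
EVENT_TYPES = (ES, A3SS, A5SS, IR, EXONIC_INTRON)

ACCEPTOR_END = "acceptor_end"
DONOR_END = "donor_end"


@dataclass(frozen=True)
class ExonCall:
    """Classification of one distinct exon coordinate unit."""

    interval: GenomicInterval
    gene_id: str
    exon_index: int
    label: str
    containing_transcripts: tuple[str, ...]
    variable_ends: frozenset[str] = frozenset()
    attributes: tuple[tuple[str, str], ...] = ()

    def supporting_transcripts(self) -> tuple[str, ...]:
        return self.containing_transcripts

    def feature_index(self) -> int:
        return self.exon_index

    def attributes_field(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes)


@dataclass(frozen=True)
class RegionCall:
    """One maximal constitutive (CR) or alternative (AR) exonic region."""

    interval: GenomicInterval
    gene_id: str
    label: str
    coverage: int
    region_index: int = 0
    attributes: tuple[tuple[str, str], ...] = ()

    def supporting_transcripts(self) -> tuple[str, ...]:
        return ()

    def feature_index(self) -> int:
        return self.region_index

    def attributes_field(self) -> str:
        parts = [f"coverage={self.coverage}"]
        parts.extend(f"{k}={v}" for k, v in self.attributes)
        return ";".join(parts)


@dataclass(frozen=True)
class SpliceEvent:
    """A single alternative-splicing event between two isoforms."""

    event_type: str
    gene_id: str
    isoform_a: str
    isoform_b: str
    coordinates: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


def select_reference_isoform(gene: GeneModel) -> str:
    """Pick the reference isoform id.

    Maximizes exon count, then summed exon length; ties broken by the
    lexicographically smallest transcript id, so the result is
    deterministic.
    """
    best = min(
        gene.transcripts,
        key=lambda t: (-t.exon_count, -t.total_exon_length, t.transcript_id),
    )
    return best.transcript_id


def _donor_acceptor(intron: GenomicInterval) -> tuple[int, int]:
    """(donor, acceptor) genomic coordinates of an intron, strand-aware."""
    if intron.strand == "+":
        return intron.start, intron.end
    return intron.end, intron.start


def detect_events(ref: Transcript, alt: Transcript) -> list[SpliceEvent]:
    """Detect splice events of ``alt`` relative to ``ref``.

    Rules (interval relations only):

    * ES — an exon of ``ref`` lies strictly within one intron of ``alt``;
    * A3SS / A5SS — an intron of ``alt`` (containing no complete ref exon)
      shares its donor (resp. acceptor) boundary with a ref intron but
      differs at the other boundary;
    * IR — an exon of ``alt`` exactly spans >= 2 consecutive exons of
      ``ref`` plus the intervening intron(s);
    * EXONIC_INTRON — an intron of ``alt`` lies strictly inside a single
      exon of ``ref``.
    """
    if ref.gene_id != alt.gene_id:
        raise ValueError("transcripts belong to different genes")
    if ref.chrom != alt.chrom or ref.strand != alt.strand:
        raise ValueError("transcripts on different chromosomes or strands")
    chrom, strand = ref.chrom, ref.strand
    events: list[SpliceEvent] = []

    ref_intron_set = {i.coords() for i in ref.introns}
    ref_exon_set = {e.coords() for e in ref.exons}

    # intron retention: alt exon tiles a chain of >=2 consecutive ref exons
    for exon in alt.exons:
        if exon.coords() in ref_exon_set:
            continue
        chain = [
            k
            for k, e in enumerate(ref.exons)
            if exon.start <= e.start and e.end <= exon.end
        ]
        if len(chain) >= 2 and chain == list(range(chain[0], chain[-1] + 1)):
            first, last = ref.exons[chain[0]], ref.exons[chain[-1]]
            if first.start == exon.start and last.end == exon.end:
                for k in range(chain[0], chain[-1]):
                    retained = GenomicInterval(
                        chrom, ref.exons[k].end, ref.exons[k + 1].start, strand
                    )
                    events.append(
                        SpliceEvent(
                            IR,
                            ref.gene_id,
                            ref.transcript_id,
                            alt.transcript_id,
                            (retained,),
                        )
                    )

    for intron in alt.introns:
        if intron.coords() in ref_intron_set:
            continue
        skipped = [e for e in ref.exons if intron.contains(e, strict=True)]
        if skipped:
            for exon in skipped:
                events.append(
                    SpliceEvent(
                        ES,
                        ref.gene_id,
                        ref.transcript_id,
                        alt.transcript_id,
                        (exon,),
                    )
                )
            continue
        donor_a, acceptor_a = _donor_acceptor(intron)
        matched = False
        for ref_intron in ref.introns:
            donor_r, acceptor_r = _donor_acceptor(ref_intron)
            if donor_a == donor_r and acceptor_a != acceptor_r:
                lo, hi = sorted((acceptor_a, acceptor_r))
                events.append(
                    SpliceEvent(
                        A3SS,
                        ref.gene_id,
                        ref.transcript_id,
                        alt.transcript_id,
                        (GenomicInterval(chrom, lo, hi, strand),),
                    )
                )
                matched = True
            elif acceptor_a == acceptor_r and donor_a != donor_r:
                lo, hi = sorted((donor_a, donor_r))
                events.append(
                    SpliceEvent(
                        A5SS,
                        ref.gene_id,
                        ref.transcript_id,
                        alt.transcript_id,
                        (GenomicInterval(chrom, lo, hi, strand),),
                    )
                )
                matched = True
        if not matched:
            for exon in ref.exons:
                if exon.contains(intron, strict=True):
                    events.append(
                        SpliceEvent(
                            EXONIC_INTRON,
                            ref.gene_id,
                            ref.transcript_id,
                            alt.transcript_id,
                            (intron,),
                        )
                    )
                    break
    return events


def detect_gene_events(gene: GeneModel, all_pairs: bool = False) -> list[SpliceEvent]:
    """Events of every isoform against the reference isoform.

    With ``all_pairs=True``, every ordered pair (a, b), a != b, is compared
    instead.
    """
    events: list[SpliceEvent] = []
    if all_pairs:
        for ref in gene.transcripts:
            for alt in gene.transcripts:
                if ref.transcript_id != alt.transcript_id:
                    events.extend(detect_events(ref, alt))
        return events
    ref = gene.transcript(select_reference_isoform(gene))
    for alt in gene.transcripts:
        if alt.transcript_id != ref.transcript_id:
            events.extend(detect_events(ref, alt))
    return events


def _merged_chain(
    unit: GenomicInterval, transcript: Transcript
) -> list[GenomicInterval] | None:
    """Exons of ``transcript`` exactly tiled by ``unit`` (>= 2), else None."""
    chain = [
        e
        for e in transcript.exons
        if unit.start <= e.start and e.end <= unit.end
    ]
    if (
        len(chain) >= 2
        and chain[0].start == unit.start
        and chain[-1].end == unit.end
    ):
        return chain
    return None


def _is_splice_boundary(
    exon: GenomicInterval, pos: int, transcript: Transcript
) -> bool:
    """True when ``pos`` (an endpoint of ``exon``) abuts an intron of the
    transcript, i.e. is a genuine splice site rather than the transcript's
    terminus."""
    if pos == exon.start:
        return exon != transcript.exons[0]
    return exon != transcript.exons[-1]


def classify_exons_intact(
    gene: GeneModel, include_end_variation: bool = False
) -> list[ExonCall]:
    """Classify every distinct exon coordinate unit of a gene.

    Label precedence when multiple kinds of evidence apply:
    AE_IR_MERGED > AE_CASSETTE > AE_ALT_BOTH > AE_ALT3SS / AE_ALT5SS > CE.
    With ``include_end_variation=False`` (default), variation confined to
    transcript termini (TSS/TES) is not alternative splicing.
    """
    units = gene.exon_units
    strand = gene.strand
    containing: dict[GenomicInterval, list[Transcript]] = {u: [] for u in units}
    for t in gene.transcripts:
        for e in t.exons:
            containing[e].append(t)

    # IR-merged units first: they are excluded as alt-SS partners.
    ir_merged: set[GenomicInterval] = set()
    for u in units:
        for t in gene.transcripts:
            if u in t.exons:
                continue
            if _merged_chain(u, t) is not None:
                ir_merged.add(u)
                break

    calls: list[ExonCall] = []
    for idx, u in enumerate(units):
        hosts = containing[u]
        tx_ids = tuple(sorted(t.transcript_id for t in hosts))

        if u in ir_merged:
            calls.append(
                ExonCall(u, gene.gene_id, idx, AE_IR_MERGED, tx_ids)
            )
            continue

        cassette = any(
            any(i.contains(u) for i in t.introns)
            for t in gene.transcripts
            if u not in t.exons
        )
        if cassette:
            calls.append(
                ExonCall(u, gene.gene_id, idx, AE_CASSETTE, tx_ids)
            )
            continue

        variable: set[str] = set()
        for t2 in gene.transcripts:
            for v in t2.exons:
                if v == u or not v.overlaps(u) or v in ir_merged:
                    continue
                for u_pos, v_pos in ((u.start, v.start), (u.end, v.end)):
                    if u_pos == v_pos:
                        continue
                    if not include_end_variation:
                        u_is_splice = any(
                            _is_splice_boundary(u, u_pos, h) for h in hosts
                        )
                        v_is_splice = _is_splice_boundary(v, v_pos, t2)
                        if not (u_is_splice or v_is_splice):
                            continue
                    if (u_pos == u.start) == (strand == "+"):
                        variable.add(ACCEPTOR_END)
                    else:
                        variable.add(DONOR_END)
        if variable == {ACCEPTOR_END, DONOR_END}:
            label = AE_ALT_BOTH
        elif variable == {ACCEPTOR_END}:
            label = AE_ALT3SS
        elif variable == {DONOR_END}:
            label = AE_ALT5SS
        else:
            label = CE
        calls.append(
            ExonCall(u, gene.gene_id, idx, label, tx_ids, frozenset(variable))
        )
    return calls


def segment_exon_regions(gene: GeneModel) -> list[RegionCall]:
    """Segment the exonic union into maximal CR/AR regions.

    A base is CR when every transcript of the gene covers it, AR when a
    proper non-empty subset does. Output regions are sorted, disjoint, and
    cover exactly the union of all exon intervals.
    """
    n = len(gene.transcripts)
    points = sorted(
        {p for t in gene.transcripts for e in t.exons for p in (e.start, e.end)}
    )
    raw: list[tuple[int, int, int]] = []  # (start, end, coverage)
    for a, b in zip(points, points[1:]):
        cov = sum(
            1
            for t in gene.transcripts
            if any(e.start <= a and b <= e.end for e in t.exons)
        )
        if cov > 0:
            raw.append((a, b, cov))
    # merge contiguous runs sharing a label
    merged: list[tuple[int, int, str]] = []
    for a, b, cov in raw:
        label = CR if cov == n else AR
        if merged and merged[-1][1] == a and merged[-1][2] == label:
            merged[-1] = (merged[-1][0], b, label)
        else:
            merged.append((a, b, label))
    calls = []
    for idx, (a, b, label) in enumerate(merged):
        iv = GenomicInterval(gene.chrom, a, b, gene.strand)
        coverage = sum(
            1
            for t in gene.transcripts
            if any(e.start <= a and b <= e.end for e in t.exons)
        )
        calls.append(RegionCall(iv, gene.gene_id, label, coverage, idx))
    return calls


def annotate(genes, scheme: str = "intact"):
    """Classify a collection of genes under one scheme.

    Returns a flat record list suitable for
    :func:`exonkit.annotation_io.write_bed_like`.
    """
    if scheme == "intact":
        records: list = []
        for gene in genes:
            records.extend(classify_exons_intact(gene))
        return records
    if scheme == "regions":
        records = []
        for gene in genes:
            records.extend(segment_exon_regions(gene))
        return records
    raise ValueError(f"unknown scheme {scheme!r}; expected 'intact' or 'regions'")
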