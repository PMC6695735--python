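"""Synthetic test-data generation.

Provides the canonical four-exon worked example (one isoform per event
type), a seeded simulator for random multi-isoform genes with planted
events and controllable splice-site strength, and a junction-count
simulator with known inclusion levels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .exon_classify import (
    A3SS,
    A5SS,
    AE_ALT3SS,
    AE_ALT5SS,
    AE_CASSETTE,
    AE_IR_MERGED,
    CE,
    ES,
    EXONIC_INTRON,
    IR,
)
from .inclusion_level import JunctionKey, cassette_junction_keys
from .models import GeneModel, GenomicInterval, Transcript
from .sequence_features import (
    ACCEPTOR_CONSENSUS,
    ACCEPTOR_EXONIC,
    ACCEPTOR_INTRONIC,
    DONOR_CONSENSUS,
    DONOR_EXONIC,
    DONOR_INTRONIC,
    reverse_complement,
)

ALPHABET = "ACGT"

WORKED_CHROM = "chrT"
WORKED_GENOME_LENGTH = 1300
# no GT or AG dinucleotide anywhere in the repeated filler, so canonical
# splice dinucleotides occur only where planted
_FILLER = "CCATCCTTAC"


@dataclass(frozen=True)
class PlantedEvent:
    event_type: str
    alt_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted alongside a simulated gene."""

    events: tuple[PlantedEvent, ...]
    exon_labels: dict[GenomicInterval, str]
    psi: dict[GenomicInterval, float]


def _plant(seq: list[str], start: int, motif: str, strength: float, rng) -> None:
    for i, base in enumerate(motif):
        if 0 <= start + i < len(seq):
            seq[start + i] = base if rng.random() < strength else rng.choice(ALPHABET)


def _plant_site(
    seq: list[str], boundary: int, strand: str, side: str, strength: float, rng
) -> None:
    """Plant a consensus splice-site window around a junction coordinate."""
    if side == "donor":
        motif = DONOR_CONSENSUS if strand == "+" else reverse_complement(DONOR_CONSENSUS)
        start = boundary - DONOR_EXONIC if strand == "+" else boundary - DONOR_INTRONIC
    else:
        motif = (
            ACCEPTOR_CONSENSUS if strand == "+" else reverse_complement(ACCEPTOR_CONSENSUS)
        )
        start = (
            boundary - ACCEPTOR_INTRONIC
            if strand == "+"
            else boundary - ACCEPTOR_EXONIC
        )
    _plant(seq, start, motif, strength, rng)


def _splice_boundaries(
    transcripts: list[Transcript],
) -> tuple[set[int], set[int]]:
    """(donor boundaries, acceptor boundaries) used by any isoform."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for tx in transcripts:
        strand = tx.strand
        for k, exon in enumerate(tx.exons):
            if k < len(tx.exons) - 1:
                (donors if strand == "+" else acceptors).add(exon.end)
            if k > 0:
                (acceptors if strand == "+" else donors).add(exon.start)
    return donors, acceptors


def make_worked_example() -> tuple[GeneModel, dict[str, str]]:
    """The canonical four-exon gene with one isoform per event type.

    Deterministic: i0 contains all four exons; i1 skips exon 3; i2 uses an
    alternative acceptor for exon 2 (start 430); i3 an alternative donor for
    exon 1 (end 170); i4 retains intron 2 (merged exon [400, 790)). Every
    used intron begins with GT and ends with AG.
    """
    c, s = WORKED_CHROM, "+"
    e1 = GenomicInterval(c, 100, 200, s)
    e2 = GenomicInterval(c, 400, 500, s)
    e3 = GenomicInterval(c, 700, 790, s)
    e4 = GenomicInterval(c, 1000, 1100, s)
    e1_short = GenomicInterval(c, 100, 170, s)
    e2_short = GenomicInterval(c, 430, 500, s)
    e_merged = GenomicInterval(c, 400, 790, s)
    gid = "GENE1"
    gene = GeneModel(
        gene_id=gid,
        transcripts=(
            Transcript("i0", gid, (e1, e2, e3, e4)),
            Transcript("i1", gid, (e1, e2, e4)),
            Transcript("i2", gid, (e1, e2_short, e3, e4)),
            Transcript("i3", gid, (e1_short, e2, e3, e4)),
            Transcript("i4", gid, (e1, e_merged, e4)),
        ),
    )
    seq = list((_FILLER * (WORKED_GENOME_LENGTH // len(_FILLER) + 1))[:WORKED_GENOME_LENGTH])

    class _Fixed:
        # strength-1.0 planting needs no randomness
        def random(self) -> float:
            return 0.0

        def choice(self, xs):  # pragma: no cover - never reached at strength 1
            return xs[0]

    rng = _Fixed()
    donors, acceptors = _splice_boundaries(list(gene.transcripts))
    for a in sorted(acceptors):
        _plant_site(seq, a, s, "acceptor", 1.0, rng)
    for d in sorted(donors):
        _plant_site(seq, d, s, "donor", 1.0, rng)
    return gene, {c: "".join(seq)}


@dataclass(frozen=True)
class SimSpec:
    """Parameters for one simulated gene."""

    n_exons: int = 6
    exon_length_range: tuple[int, int] = (60, 150)
    intron_length_range: tuple[int, int] = (120, 400)
    events: tuple[str, ...] = (ES,)
    shift_range: tuple[int, int] = (9, 30)
    donor_strength: float = 1.0
    acceptor_strength: float = 1.0
    psi: float = 0.5
    depth: int = 0
    seed: int = 0
    strand: str = "+"
    chrom: str = "chrSim"
    gene_id: str = "SIMGENE"
    margin: int = 60

    def __post_init__(self) -> None:
        if self.n_exons < 3:
            raise ValueError("need >= 3 exons to host internal events")
        for lo, hi in (self.exon_length_range, self.intron_length_range, self.shift_range):
            if not (0 < lo <= hi):
                raise ValueError("length/shift ranges must be positive and ordered")
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError("psi must lie in [0, 1]")
        for x in (self.donor_strength, self.acceptor_strength):
            if not (0.0 <= x <= 1.0):
                raise ValueError("site strengths must lie in [0, 1]")
        unknown = set(self.events) - {ES, A3SS, A5SS, IR, EXONIC_INTRON}
        if unknown:
            raise ValueError(f"unknown planted event types {sorted(unknown)}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def _feasible(spec: SimSpec) -> None:
    max_shift = spec.shift_range[1]
    if max_shift >= spec.exon_length_range[0]:
        raise ValueError(
            "infeasible spec: maximum shift must be smaller than the shortest exon"
        )
    if max_shift >= spec.intron_length_range[0]:
        raise ValueError(
            "infeasible spec: maximum shift must be smaller than the shortest intron"
        )
    # EXONIC_INTRON removes an internal slice: exon must fit slice + 2 flanks
    if EXONIC_INTRON in spec.events and spec.exon_length_range[0] < max_shift + 2 * 10:
        raise ValueError(
            "infeasible spec: exons too short to host an exonic intron"
        )
    # each event needs its own internal exon (IR consumes two)
    needed = sum(2 if e == IR else 1 for e in spec.events)
    if needed > spec.n_exons - 2:
        raise ValueError(
            f"infeasible spec: {len(spec.events)} events need {needed} internal "
            f"exons but only {spec.n_exons - 2} are available"
        )


def simulate_gene(spec: SimSpec) -> tuple[GeneModel, dict[str, str], TruthRecord]:
    """Simulate one multi-isoform gene with planted events.

    Deterministic given ``spec.seed``. The truth record lists every planted
    event (against the full-length isoform ``i0``) and each exon unit's
    intended classification label.
    """
    _feasible(spec)
    rng = random.Random(spec.seed)
    c, strand = spec.chrom, spec.strand

    # i0: the full-length exon chain
    pos = spec.margin
    i0_exons: list[GenomicInterval] = []
    for k in range(spec.n_exons):
        length = rng.randint(*spec.exon_length_range)
        i0_exons.append(GenomicInterval(c, pos, pos + length, strand))
        pos += length
        if k < spec.n_exons - 1:
            pos += rng.randint(*spec.intron_length_range)
    gene_end = pos

    # assign each event a distinct internal exon (IR reserves two)
    available = list(range(1, spec.n_exons - 1))
    rng.shuffle(available)
    labels: dict[GenomicInterval, str] = {e: CE for e in i0_exons}
    psi: dict[GenomicInterval, float] = {}
    events: list[PlantedEvent] = []
    transcripts: list[Transcript] = [Transcript("i0", spec.gene_id, tuple(i0_exons))]

    def take(n_slots: int) -> Optional[int]:
        for i, k in enumerate(available):
            if n_slots == 1:
                return available.pop(i)
            # IR needs exons k and k+1, both internal and both unclaimed
            if k + 1 in available and k + 1 <= spec.n_exons - 2:
                available.pop(i)
                available.remove(k + 1)
                return k
        return None

    alt_counter = 0
    for event_type in spec.events:
        k = take(2 if event_type == IR else 1)
        if k is None:
            raise ValueError("infeasible spec: could not place all events disjointly")
        alt_counter += 1
        alt_id = f"i{alt_counter}"
        target = i0_exons[k]
        alt_exons = list(i0_exons)
        if event_type == ES:
            del alt_exons[k]
            labels[target] = AE_CASSETTE
            psi[target] = spec.psi
            coords = target
        elif event_type in (A3SS, A5SS):
            shift = rng.randint(*spec.shift_range)
            # acceptor side = transcription-upstream boundary
            move_start = (event_type == A3SS) == (strand == "+")
            if move_start:
                new = GenomicInterval(c, target.start + shift, target.end, strand)
                coords = GenomicInterval(c, target.start, target.start + shift, strand)
            else:
                new = GenomicInterval(c, target.start, target.end - shift, strand)
                coords = GenomicInterval(c, target.end - shift, target.end, strand)
            alt_exons[k] = new
            label = AE_ALT3SS if event_type == A3SS else AE_ALT5SS
            labels[target] = label
            labels[new] = label
        elif event_type == IR:
            nxt = i0_exons[k + 1]
            merged = GenomicInterval(c, target.start, nxt.end, strand)
            alt_exons[k : k + 2] = [merged]
            labels[merged] = AE_IR_MERGED
            coords = GenomicInterval(c, target.end, nxt.start, strand)
        else:  # EXONIC_INTRON
            width = rng.randint(*spec.shift_range)
            lo = target.start + 10
            hi = target.end - 10 - width
            cut = rng.randint(lo, hi)
            left = GenomicInterval(c, target.start, cut, strand)
            right = GenomicInterval(c, cut + width, target.end, strand)
            alt_exons[k : k + 1] = [left, right]
            labels[target] = AE_IR_MERGED  # statically identical to retention
            labels[left] = CE
            labels[right] = CE
            coords = GenomicInterval(c, cut, cut + width, strand)
        transcripts.append(Transcript(alt_id, spec.gene_id, tuple(alt_exons)))
        events.append(PlantedEvent(event_type, alt_id, coords))

    gene = GeneModel(gene_id=spec.gene_id, transcripts=tuple(transcripts))

    # genome: random background, then consensus windows at every used splice
    # site. Acceptors are planted before donors so that at strength 1.0 every
    # used donor window is exactly the consensus even where windows collide.
    seq = [rng.choice(ALPHABET) for _ in range(gene_end + spec.margin)]
    donors, acceptors = _splice_boundaries(transcripts)
    for a in sorted(acceptors):
        _plant_site(seq, a, strand, "acceptor", spec.acceptor_strength, rng)
    for d in sorted(donors):
        _plant_site(seq, d, strand, "donor", spec.donor_strength, rng)

    truth = TruthRecord(
        events=tuple(events),
        exon_labels={e: labels[e] for e in gene.exon_units},
        psi=psi,
    )
    return gene, {c: "".join(seq)}, truth


def simulate_junction_counts(
    gene: GeneModel,
    psi: Mapping[GenomicInterval, float],
    depth: int,
    seed: int = 0,
) -> dict[JunctionKey, int]:
    """Simulate junction read counts with known inclusion levels.

    Every reference-isoform junction receives ``depth`` reads; for each
    alternative exon in ``psi``, inclusion events ~ Binomial(depth, psi)
    support both of its inclusion junctions (a spliced-in molecule spans
    each of them) and the remaining events support the skip junction, so
    the junction-averaging estimator recovers psi without bias.
    """
    rng = np.random.default_rng(seed)
    try:
        ref = gene.transcript("i0")
    except KeyError:
        from .exon_classify import select_reference_isoform

        ref = gene.transcript(select_reference_isoform(gene))
    counts: dict[JunctionKey, int] = {}
    for intron in ref.introns:
        counts[(gene.chrom, intron.start, intron.end, gene.strand)] = depth
    for exon in sorted(psi, key=lambda e: (e.start, e.end)):
        keys = cassette_junction_keys(gene, exon)
        if keys is None:
            continue
        up_key, down_key, skip_key = keys
        inclusion = int(rng.binomial(depth, psi[exon])) if depth else 0
        counts[up_key] = inclusion
        counts[down_key] = inclusion
        counts[skip_key] = depth - inclusion
    return counts


def write_junctions(counts: Mapping[JunctionKey, int], path) -> None:
    """Write a junction table in the 0-based 'simple' TSV dialect."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tcount\n")
        for (chrom, start, end, strand), count in sorted(counts.items()):
            fh.write(f"{chrom}\t{start}\t{end}\t{strand}\t{count}\n")
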