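from __future__ import annotations

import random

import pytest

from exonkit.models import GeneModel, GenomicInterval, Transcript
from exonkit.synthetic_data import SimSpec, make_worked_example, simulate_gene

EVENT_TYPES = ("ES", "A3SS", "A5SS", "IR", "EXONIC_INTRON")


@pytest.fixture(scope="session")
def worked():
    """(GeneModel, genome) of the canonical four-exon worked example."""
    return make_worked_example()


@pytest.fixture
def worked_gene(worked):
    return worked[0]


@pytest.fixture
def worked_genome(worked):
    return worked[1]


def random_sim(seed: int, with_truth: bool = False):
    """A random simulated gene with a random disjoint event mix."""
    rng = random.Random(seed)
    n_events = rng.randint(1, 3)
    events = tuple(rng.choice(EVENT_TYPES) for _ in range(n_events))
    n_internal = sum(2 if e == "IR" else 1 for e in events)
    spec = SimSpec(
        n_exons=max(4, n_internal + 2 + rng.randint(0, 2)),
        events=events,
        seed=seed,
        strand=rng.choice("+-"),
        psi=rng.uniform(0.05, 0.95),
    )
    gene, genome, truth = simulate_gene(spec)
    if with_truth:
        return gene, genome, truth
    return gene


def random_isoform(base: Transcript, rng: random.Random, tid: str) -> Transcript:
    """A random perturbation of ``base``: possibly compound events."""
    exons = list(base.exons)
    n_ops = rng.randint(1, 2)
    for _ in range(n_ops):
        internal = list(range(1, len(exons) - 1))
        if not internal:
            break
        op = rng.choice(["skip", "shift_start", "shift_end", "merge", "split"])
        k = rng.choice(internal)
        e = exons[k]
        if op == "skip":
            del exons[k]
        elif op == "shift_start" and e.length > 12:
            exons[k] = GenomicInterval(
                e.chrom, e.start + rng.randint(3, min(12, e.length - 3)), e.end, e.strand
            )
        elif op == "shift_end" and e.length > 12:
            exons[k] = GenomicInterval(
                e.chrom, e.start, e.end - rng.randint(3, min(12, e.length - 3)), e.strand
            )
        elif op == "merge" and k + 1 < len(exons):
            exons[k : k + 2] = [
                GenomicInterval(e.chrom, e.start, exons[k + 1].end, e.strand)
            ]
        elif op == "split" and e.length > 30:
            cut = e.start + rng.randint(8, e.length - 20)
            width = rng.randint(5, 10)
            exons[k : k + 1] = [
                GenomicInterval(e.chrom, e.start, cut, e.strand),
                GenomicInterval(e.chrom, cut + width, e.end, e.strand),
            ]
    return Transcript(tid, base.gene_id, tuple(exons))


def random_gene_freeform(seed: int) -> GeneModel:
    """A random gene built by perturbing a base chain, independent of the
    simulator's non-overlap guarantees."""
    rng = random.Random(seed)
    chrom, strand = "chrF", rng.choice("+-")
    n_exons = rng.randint(4, 8)
    pos, exons = 80, []
    for _ in range(n_exons):
        length = rng.randint(40, 120)
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + rng.randint(60, 200)
    base = Transcript("t0", "G", tuple(exons))
    txs = [base]
    for i in range(rng.randint(1, 5)):
        txs.append(random_isoform(base, rng, f"t{i + 1}"))
    return GeneModel("G", tuple(txs))


def mirror_gene(gene: GeneModel, genome_len: int) -> GeneModel:
    """Reverse-complement mirror of a locus: coordinates flipped, strand
    swapped."""
    flip = {"+": "-", "-": "+"}

    def mirror_iv(iv):
        return GenomicInterval(
            iv.chrom, genome_len - iv.end, genome_len - iv.start, flip[iv.strand]
        )

    txs = tuple(
        Transcript(
            t.transcript_id,
            t.gene_id,
            tuple(mirror_iv(e) for e in t.exons),
            t.attributes,
        )
        for t in gene.transcripts
    )
    return GeneModel(gene.gene_id, txs)
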