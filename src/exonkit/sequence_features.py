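"""Diagnostic sequence features of exons and their splice sites.

Covers: splice-site window extraction (9-nt donor, 23-nt acceptor), PWM
training and log-odds scoring of splice-site strength, branch-point
(YTNAY) and polypyrimidine-tract detection, splicing-regulatory-element
k-mer scanning, and exon-intron architecture (lengths, ratios, GC,
reading-frame symmetry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq

from .exon_classify import classify_exons_intact, select_reference_isoform
from .models import GeneModel, GenomicInterval, Transcript

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
PYRIMIDINES = frozenset("CT")

# splice-site window geometry: the donor motif spans the exon/intron
# boundary with 3 exonic (-3..-1) and 6 intronic (+1..+6) nucleotides;
# the acceptor window covers the last 20 intronic plus 3 exonic bases.
DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_WINDOW = DONOR_EXONIC + DONOR_INTRONIC  # 9 nt
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
ACCEPTOR_WINDOW = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23 nt

CANONICAL_DONOR_DINUCLEOTIDES = frozenset({"GT", "GC"})
ACCEPTOR_DINUCLEOTIDE = "AG"

DONOR_CONSENSUS = "CAGGTAAGT"
ACCEPTOR_CONSENSUS = "T" * 17 + "CAG" + "GTT"

SYMMETRY_DIVISOR = 3


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gc_fraction(seq: str) -> Optional[float]:
    """GC fraction of ``seq``; None for empty input or any N."""
    if not seq or "N" in seq:
        return None
    return sum(1 for b in seq if b in "GC") / len(seq)


def is_symmetric(length: int, divisor: int = SYMMETRY_DIVISOR) -> bool:
    """Whether an exon (region) length preserves reading frame."""
    return length % divisor == 0


# ---------------------------------------------------------------------------
# splice-site windows


def site_window(
    genome: Mapping[str, str], chrom: str, boundary: int, strand: str, side: str
) -> str:
    """Strand-oriented splice-site window around an exon/intron ``boundary``.

    ``boundary`` is the genomic coordinate of the junction (the exon's
    half-open end for a plus-strand donor). ``side`` is ``"donor"`` or
    ``"acceptor"`` in transcription direction.
    """
    seq = genome[chrom]
    if side == "donor":
        if strand == "+":
            lo, hi = boundary - DONOR_EXONIC, boundary + DONOR_INTRONIC
        else:
            lo, hi = boundary - DONOR_INTRONIC, boundary + DONOR_EXONIC
    elif side == "acceptor":
        if strand == "+":
            lo, hi = boundary - ACCEPTOR_INTRONIC, boundary + ACCEPTOR_EXONIC
        else:
            lo, hi = boundary - ACCEPTOR_EXONIC, boundary + ACCEPTOR_INTRONIC
    else:
        raise ValueError(f"unknown side {side!r}")
    if lo < 0 or hi > len(seq):
        raise ValueError(
            f"window [{lo}, {hi}) extends beyond contig {chrom!r} (length {len(seq)})"
        )
    window = seq[lo:hi]
    return window if strand == "+" else reverse_complement(window)


def extract_site_window(
    genome: Mapping[str, str],
    transcript: Transcript,
    exon_index: int,
    side: str,
) -> str:
    """Window at an internal boundary of ``transcript.exons[exon_index]``.

    ``exon_index`` counts exons in genomic order; ``side`` is interpreted in
    transcription direction. Terminal boundaries raise (no splice site
    there).
    """
    exon = transcript.exons[exon_index]
    strand = transcript.strand
    # the donor is the transcription-downstream junction of the exon
    if side == "donor":
        boundary = exon.end if strand == "+" else exon.start
        terminal = (
            exon_index == len(transcript.exons) - 1
            if strand == "+"
            else exon_index == 0
        )
    elif side == "acceptor":
        boundary = exon.start if strand == "+" else exon.end
        terminal = (
            exon_index == 0
            if strand == "+"
            else exon_index == len(transcript.exons) - 1
        )
    else:
        raise ValueError(f"unknown side {side!r}")
    if terminal:
        raise ValueError(
            f"exon {exon_index} of {transcript.transcript_id}: "
            f"no splice site at its {side} side (transcript terminus)"
        )
    return site_window(genome, transcript.chrom, boundary, strand, side)


# ---------------------------------------------------------------------------
# position weight matrix


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide frequencies for log-odds site scoring."""

    site_kind: str  # "donor" or "acceptor"
    frequencies: np.ndarray  # shape (L, 4), rows sum to 1
    pseudocount: float
    background: np.ndarray  # shape (4,)

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.frequencies, axis=1))

    def max_score(self) -> float:
        per_pos = np.log2(self.frequencies / self.background[None, :])
        return float(per_pos.max(axis=1).sum())

    def save(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#site_kind={self.site_kind}\tpseudocount={self.pseudocount}\n")
            fh.write("#pos\t" + "\t".join(ALPHABET) + "\tbackground\n")
            for i in range(self.length):
                row = "\t".join(f"{x:.10g}" for x in self.frequencies[i])
                fh.write(f"{i}\t{row}\t.\n")
            fh.write(
                "bg\t" + "\t".join(f"{x:.10g}" for x in self.background) + "\t.\n"
            )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PWM":
        site_kind, pseudocount = "donor", 1.0
        rows, background = [], None
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#site_kind="):
                    head = dict(
                        kv.split("=", 1) for kv in line.lstrip("#").split("\t")
                    )
                    site_kind = head["site_kind"]
                    pseudocount = float(head["pseudocount"])
                elif line.startswith("#") or not line:
                    continue
                else:
                    fields = line.split("\t")
                    if fields[0] == "bg":
                        background = np.array([float(x) for x in fields[1:5]])
                    else:
                        rows.append([float(x) for x in fields[1:5]])
        if background is None:
            background = np.full(4, 0.25)
        return cls(site_kind, np.array(rows), pseudocount, background)


def train_pwm(
    windows: Sequence[str],
    site_kind: str,
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
) -> PWM:
    """Estimate a PWM from aligned splice-site windows.

    Frequencies are ``(count + a) / (n + 4a)`` with pseudocount ``a``;
    background defaults to uniform 0.25.
    """
    if not windows:
        raise ValueError("cannot train a PWM on zero windows")
    length = len(windows[0])
    expected = DONOR_WINDOW if site_kind == "donor" else ACCEPTOR_WINDOW
    if length != expected:
        raise ValueError(
            f"{site_kind} windows must be {expected} nt, got {length}"
        )
    counts = np.zeros((length, 4))
    for w in windows:
        if len(w) != length:
            raise ValueError(
                f"window length mismatch: expected {length}, got {len(w)} ({w!r})"
            )
        for i, b in enumerate(w):
            if b == "N":
                continue
            try:
                counts[i, _BASE_INDEX[b]] += 1
            except KeyError:
                raise ValueError(f"invalid nucleotide {b!r} in window {w!r}") from None
    n = len(windows)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    q = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if not math.isclose(q.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background distribution must sum to 1")
    return PWM(site_kind, freqs, pseudocount, q)


def score_site(pwm: PWM, window: str) -> Optional[float]:
    """Log-odds splice-strength score in bits; None if the window has an N."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} does not match PWM length {pwm.length}"
        )
    if "N" in window:
        return None
    total = 0.0
    for i, b in enumerate(window):
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid nucleotide {b!r} in window {window!r}")
        j = _BASE_INDEX[b]
        total += math.log2(pwm.frequencies[i, j] / pwm.background[j])
    return total


# ---------------------------------------------------------------------------
# branch point and polypyrimidine tract


@dataclass(frozen=True)
class BranchPointConfig:
    consensus: str = "YTNAY"
    min_distance: int = 14
    typical_max: int = 50
    hard_max: int = 350

    def __post_init__(self) -> None:
        if not (self.min_distance < self.typical_max <= self.hard_max):
            raise ValueError("need min_distance < typical_max <= hard_max")


@dataclass(frozen=True)
class BranchPointHit:
    distance: int  # motif start, nt upstream of the intron's 3' end
    motif: str
    start: int  # index within the intron sequence


_IUPAC = {"Y": "CT", "N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T", "U": "T"}


def _matches_degenerate(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern)
    )


def find_branch_point(
    intron_seq: str, config: BranchPointConfig = BranchPointConfig()
) -> Optional[BranchPointHit]:
    """Closest-to-3'SS branch-point candidate, or None.

    Scans 5-mer start positions whose distance upstream of the intron's 3'
    end lies in [min_distance, hard_max] and returns the first (most
    proximal) match of the YTNAY consensus.
    """
    pattern = config.consensus.replace("U", "T")
    L = len(intron_seq)
    for distance in range(config.min_distance, config.hard_max + 1):
        start = L - distance
        if start < 0:
            break
        candidate = intron_seq[start : start + len(pattern)]
        if _matches_degenerate(candidate, pattern):
            return BranchPointHit(distance=distance, motif=candidate, start=start)
    return None


@dataclass(frozen=True)
class PPTConfig:
    nominal_length: int = 20
    gap_to_ag: int = 2
    min_pyrimidine_fraction: float = 0.7
    min_length: int = 10
    search_span: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pyrimidine_fraction <= 1.0):
            raise ValueError("min_pyrimidine_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PPTHit:
    start: int  # index within the intron sequence
    length: int
    pyrimidine_fraction: float


def find_ppt(
    intron_seq: str, config: PPTConfig = PPTConfig()
) -> Optional[PPTHit]:
    """Longest pyrimidine-rich run near the intron's 3' end, or None.

    The search covers the last ``search_span`` nucleotides of the intron,
    excluding the terminal AG dinucleotide and the ``gap_to_ag`` gap before
    it. Candidate runs need length >= min_length and pyrimidine fraction >=
    min_pyrimidine_fraction; ties on length go to the run closest to the 3'
    splice site.
    """
    L = len(intron_seq)
    if L < config.min_length:
        return None
    region_end = L - 2 - config.gap_to_ag
    region_start = max(0, L - config.search_span)
    if region_end - region_start < config.min_length:
        return None
    region = intron_seq[region_start:region_end]
    prefix = [0]
    for b in region:
        prefix.append(prefix[-1] + (1 if b in PYRIMIDINES else 0))
    best: Optional[PPTHit] = None
    m = len(region)
    for i in range(m):
        for j in range(i + config.min_length, m + 1):
            length = j - i
            frac = (prefix[j] - prefix[i]) / length
            if frac < config.min_pyrimidine_fraction:
                continue
            if (
                best is None
                or length > best.length
                or (length == best.length and region_start + j > best.start + best.length)
            ):
                best = PPTHit(region_start + i, length, frac)
    return best


# ---------------------------------------------------------------------------
# splicing regulatory elements


# the six SRE cluster motifs enriched near alternative cassette exons,
# stored as DNA (U -> T)
DEFAULT_CASSETTE_CLUSTERS = ("TCTCT", "TGCATG", "TGCT", "TGTGT", "TTTT", "AGGG")


@dataclass(frozen=True)
class SREMotifSet:
    """Named k-mer lists per SRE class, plus the cassette-cluster set."""

    ese: tuple[str, ...] = ()
    ess: tuple[str, ...] = ()
    ise: tuple[str, ...] = ()
    iss: tuple[str, ...] = ()
    cassette_clusters: tuple[str, ...] = DEFAULT_CASSETTE_CLUSTERS

    def __post_init__(self) -> None:
        for name in ("ese", "ess", "ise", "iss", "cassette_clusters"):
            motifs = tuple(m.upper().replace("U", "T") for m in getattr(self, name))
            object.__setattr__(self, name, motifs)
            for m in motifs:
                if not m or set(m) - set(ALPHABET):
                    raise ValueError(f"invalid SRE motif {m!r}")

    def all_motifs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for group in (self.ese, self.ess, self.ise, self.iss, self.cassette_clusters):
            for m in group:
                seen[m] = None
        return tuple(seen)


@dataclass(frozen=True)
class SREScan:
    motif: str
    count: int
    positions: tuple[int, ...]
    density_per_100nt: float


def scan_sre(
    seq: str,
    motifs: Union[SREMotifSet, Iterable[str]] = SREMotifSet(),
    region: Optional[tuple[int, int]] = None,
) -> dict[str, SREScan]:
    """Exact-match motif counts over ``seq`` (overlaps allowed).

    ``seq`` must be strand-oriented (reverse-complement minus-strand input
    first). ``region`` optionally restricts the scan to ``seq[start:end]``;
    reported positions stay in ``seq`` coordinates.
    """
    if isinstance(motifs, SREMotifSet):
        motif_list = motifs.all_motifs()
    else:
        motif_list = tuple(m.upper().replace("U", "T") for m in motifs)
    offset = 0
    if region is not None:
        offset = region[0]
        seq = seq[region[0] : region[1]]
    n = len(seq)
    out: dict[str, SREScan] = {}
    for motif in motif_list:
        positions = []
        start = seq.find(motif)
        while start != -1:
            positions.append(start + offset)
            start = seq.find(motif, start + 1)  # overlapping matches count
        density = 100.0 * len(positions) / n if n else 0.0
        out[motif] = SREScan(motif, len(positions), tuple(positions), density)
    return out


# ---------------------------------------------------------------------------
# exon-intron architecture


@dataclass(frozen=True)
class ArchitectureFeatures:
    """Length, ratio, GC and symmetry features of one exon unit.

    Intron lengths follow the reference isoform's intron chain; terminal
    exons carry None for the absent flank. GC fields are None without a
    genome (or when the window contains N or runs off the contig).
    """

    exon_length: int
    upstream_intron_length: Optional[int]
    downstream_intron_length: Optional[int]
    intron_to_exon_ratio: Optional[float]
    exon_gc: Optional[float]
    upstream_boundary_gc: Optional[float]
    downstream_boundary_gc: Optional[float]
    symmetric: bool


def _boundary_gc(
    seq: str, boundary: int, window: int
) -> Optional[float]:
    lo, hi = boundary - window, boundary + window
    if lo < 0 or hi > len(seq):
        return None
    return gc_fraction(seq[lo:hi])


def architecture(
    gene: GeneModel,
    genome: Optional[Mapping[str, str]] = None,
    boundary_gc_window: int = 25,
) -> dict[GenomicInterval, ArchitectureFeatures]:
    """Architecture features for every distinct exon unit of ``gene``.

    Flanking intron lengths are gaps to the nearest reference-isoform exon
    on either side; upstream/downstream are in transcription direction.
    """
    ref = gene.transcript(select_reference_isoform(gene))
    seq = genome.get(gene.chrom) if genome is not None else None
    out: dict[GenomicInterval, ArchitectureFeatures] = {}
    for unit in gene.exon_units:
        prev_ends = [e.end for e in ref.exons if e.end <= unit.start]
        next_starts = [e.start for e in ref.exons if e.start >= unit.end]
        left = unit.start - max(prev_ends) if prev_ends else None
        right = min(next_starts) - unit.end if next_starts else None
        left = left if left else None  # zero-length gap is no intron
        right = right if right else None
        if gene.strand == "+":
            up_len, down_len = left, right
        else:
            up_len, down_len = right, left
        flanks = [x for x in (up_len, down_len) if x is not None]
        ratio = (sum(flanks) / len(flanks)) / unit.length if flanks else None
        exon_gc = up_gc = down_gc = None
        if seq is not None:
            exon_gc = gc_fraction(seq[unit.start : unit.end])
            left_gc = _boundary_gc(seq, unit.start, boundary_gc_window)
            right_gc = _boundary_gc(seq, unit.end, boundary_gc_window)
            if gene.strand == "+":
                up_gc, down_gc = left_gc, right_gc
            else:
                up_gc, down_gc = right_gc, left_gc
        out[unit] = ArchitectureFeatures(
            exon_length=unit.length,
            upstream_intron_length=up_len,
            downstream_intron_length=down_len,
            intron_to_exon_ratio=ratio,
            exon_gc=exon_gc,
            upstream_boundary_gc=up_gc,
            downstream_boundary_gc=down_gc,
            symmetric=is_symmetric(unit.length),
        )
    return out


# ---------------------------------------------------------------------------
# per-exon feature table (CLI backend)


def collect_site_windows(
    genes: Iterable[GeneModel], genome: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """All internal donor and acceptor windows across the gene models."""
    donors, acceptors = [], []
    for gene in genes:
        for tx in gene.transcripts:
            for k in range(len(tx.exons)):
                for side, bucket in (("donor", donors), ("acceptor", acceptors)):
                    try:
                        bucket.append(extract_site_window(genome, tx, k, side))
                    except ValueError:
                        continue
    return donors, acceptors


def feature_table(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    motifs: SREMotifSet = SREMotifSet(),
    pseudocount: float = 1.0,
    bp_config: BranchPointConfig = BranchPointConfig(),
    ppt_config: PPTConfig = PPTConfig(),
    boundary_gc_window: int = 25,
):
    """One feature row per exon-coordinate unit, as a pandas DataFrame."""
    import pandas as pd

    donors, acceptors = collect_site_windows(genes, genome)
    donor_pwm = train_pwm(donors, "donor", pseudocount) if donors else None
    acceptor_pwm = train_pwm(acceptors, "acceptor", pseudocount) if acceptors else None

    rows = []
    for gene in genes:
        ref = gene.transcript(select_reference_isoform(gene))
        calls = {c.interval: c for c in classify_exons_intact(gene)}
        arch = architecture(gene, genome, boundary_gc_window)
        seq = genome[gene.chrom]
        for unit in gene.exon_units:
            call = calls[unit]
            feats = arch[unit]
            strand = gene.strand
            donor_boundary = unit.end if strand == "+" else unit.start
            acceptor_boundary = unit.start if strand == "+" else unit.end
            donor_score = acceptor_score = None
            bp = ppt = None
            has_down = feats.downstream_intron_length is not None
            has_up = feats.upstream_intron_length is not None
            if has_down and donor_pwm is not None:
                try:
                    w = site_window(genome, gene.chrom, donor_boundary, strand, "donor")
                    donor_score = score_site(donor_pwm, w)
                except ValueError:
                    pass
            if has_up and acceptor_pwm is not None:
                try:
                    w = site_window(
                        genome, gene.chrom, acceptor_boundary, strand, "acceptor"
                    )
                    acceptor_score = score_site(acceptor_pwm, w)
                except ValueError:
                    pass
            if has_up:
                # upstream intron (transcription direction) sequence, 5'->3'
                if strand == "+":
                    intron_seq = seq[unit.start - feats.upstream_intron_length : unit.start]
                else:
                    intron_seq = reverse_complement(
                        seq[unit.end : unit.end + feats.upstream_intron_length]
                    )
                bp = find_branch_point(intron_seq, bp_config)
                ppt = find_ppt(intron_seq, ppt_config)
            exon_seq = seq[unit.start : unit.end]
            if strand == "-":
                exon_seq = reverse_complement(exon_seq)
            sre = scan_sre(exon_seq, motifs)
            row = {
                "gene_id": gene.gene_id,
                "chrom": unit.chrom,
                "start": unit.start,
                "end": unit.end,
                "strand": strand,
                "label": call.label,
                "donor_score": donor_score,
                "acceptor_score": acceptor_score,
                "bp_distance": bp.distance if bp else None,
                "bp_motif": bp.motif if bp else None,
                "ppt_length": ppt.length if ppt else None,
                "ppt_pyrimidine_fraction": ppt.pyrimidine_fraction if ppt else None,
                "exon_length": feats.exon_length,
                "upstream_intron_length": feats.upstream_intron_length,
                "downstream_intron_length": feats.downstream_intron_length,
                "intron_to_exon_ratio": feats.intron_to_exon_ratio,
                "exon_gc": feats.exon_gc,
                "upstream_boundary_gc": feats.upstream_boundary_gc,
                "downstream_boundary_gc": feats.downstream_boundary_gc,
                "symmetric": feats.symmetric,
            }
            for motif, scan in sre.items():
                row[f"sre_{motif}_per_100nt"] = scan.density_per_100nt
            rows.append(row)
    return pd.DataFrame(rows)
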