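"""Independent brute-force oracles used to cross-check the package.

These deliberately use different mechanics (per-base sets, exhaustive
enumeration, regex) from the implementations they verify.
"""

from __future__ import annotations

import math
import re

from exonkit.models import GeneModel, GenomicInterval, Transcript


def bases(iv) -> set[int]:
    return set(range(iv.start, iv.end))


# ---------------------------------------------------------------------------
# region segmentation: literal per-base counting


def oracle_segment(gene: GeneModel) -> list[tuple[int, int, str]]:
    n = len(gene.transcripts)
    cov: dict[int, int] = {}
    for t in gene.transcripts:
        for e in t.exons:
            for b in range(e.start, e.end):
                cov[b] = cov.get(b, 0) + 1
    labels = {b: ("CR" if c == n else "AR") for b, c in cov.items()}
    out = []
    for b in sorted(labels):
        lab = labels[b]
        if out and out[-1][1] == b and out[-1][2] == lab:
            out[-1] = (out[-1][0], b + 1, lab)
        else:
            out.append((b, b + 1, lab))
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# event detection: exhaustive relation enumeration over base sets


def _tx_introns(t: Transcript) -> list[GenomicInterval]:
    return list(t.introns)


def oracle_detect_events(ref: Transcript, alt: Transcript) -> set[tuple]:
    """Returns {(event_type, start, end), ...} of alt relative to ref."""
    events: set[tuple] = set()
    ref_intron_coords = {(i.start, i.end) for i in _tx_introns(ref)}
    ref_exon_coords = {(e.start, e.end) for e in ref.exons}
    plus = ref.strand == "+"

    # IR: an alt exon whose base set equals the union of a run of >=2
    # consecutive ref exons plus the gaps between them
    for exon in alt.exons:
        if (exon.start, exon.end) in ref_exon_coords:
            continue
        for i in range(len(ref.exons)):
            for j in range(i + 1, len(ref.exons)):
                if (
                    ref.exons[i].start == exon.start
                    and ref.exons[j].end == exon.end
                ):
                    # exact tiling: all intermediate exons inside
                    if all(
                        exon.start <= ref.exons[k].start
                        and ref.exons[k].end <= exon.end
                        for k in range(i, j + 1)
                    ):
                        for k in range(i, j):
                            events.add(
                                ("IR", ref.exons[k].end, ref.exons[k + 1].start)
                            )

    for intron in _tx_introns(alt):
        if (intron.start, intron.end) in ref_intron_coords:
            continue
        ibase = bases(intron)
        contained = [
            e
            for e in ref.exons
            if bases(e) < ibase and e.start != intron.start and e.end != intron.end
        ]
        if contained:
            for e in contained:
                events.add(("ES", e.start, e.end))
            continue
        handled = False
        for r in _tx_introns(ref):
            donor_alt = intron.start if plus else intron.end
            donor_ref = r.start if plus else r.end
            acc_alt = intron.end if plus else intron.start
            acc_ref = r.end if plus else r.start
            if donor_alt == donor_ref and acc_alt != acc_ref:
                events.add(("A3SS", min(acc_alt, acc_ref), max(acc_alt, acc_ref)))
                handled = True
            elif acc_alt == acc_ref and donor_alt != donor_ref:
                events.add(("A5SS", min(donor_alt, donor_ref), max(donor_alt, donor_ref)))
                handled = True
        if not handled:
            for e in ref.exons:
                if ibase < bases(e) and intron.start != e.start and intron.end != e.end:
                    events.add(("EXONIC_INTRON", intron.start, intron.end))
                    break
    return events


# ---------------------------------------------------------------------------
# intact exon classification: per-unit testing against every transcript


def oracle_classify(gene: GeneModel, include_end_variation: bool = False) -> dict:
    """{(start, end): label} for every distinct exon unit."""
    units = sorted({(e.start, e.end) for t in gene.transcripts for e in t.exons})
    plus = gene.strand == "+"

    def merged_in(u, t) -> bool:
        inside = [e for e in t.exons if u[0] <= e.start and e.end <= u[1]]
        return (
            len(inside) >= 2
            and inside[0].start == u[0]
            and inside[-1].end == u[1]
        )

    merged_units = {
        u for u in units if any(merged_in(u, t) for t in gene.transcripts)
    }

    def terminal_side(u, t, pos) -> bool:
        """pos (an endpoint of exon u within transcript t) is t's terminus."""
        sorted_exons = sorted(t.exons, key=lambda e: e.start)
        if pos == u[0]:
            return (sorted_exons[0].start, sorted_exons[0].end) == u
        return (sorted_exons[-1].start, sorted_exons[-1].end) == u

    labels = {}
    for u in units:
        if u in merged_units:
            labels[u] = "AE_IR_MERGED"
            continue
        hosts = [
            t
            for t in gene.transcripts
            if any((e.start, e.end) == u for e in t.exons)
        ]
        ubase = bases(GenomicInterval(gene.chrom, u[0], u[1], gene.strand))
        if any(
            ubase <= bases(i)
            for t in gene.transcripts
            if not any((e.start, e.end) == u for e in t.exons)
            for i in t.introns
        ):
            labels[u] = "AE_CASSETTE"
            continue
        varied = set()
        for t2 in gene.transcripts:
            for v in t2.exons:
                vc = (v.start, v.end)
                if vc == u or vc in merged_units:
                    continue
                if not (u[0] < v.end and v.start < u[1]):
                    continue
                for side in (0, 1):
                    if u[side] == vc[side]:
                        continue
                    if not include_end_variation:
                        u_splice = any(
                            not terminal_side(u, h, u[side]) for h in hosts
                        )
                        v_splice = not terminal_side(vc, t2, vc[side])
                        if not (u_splice or v_splice):
                            continue
                    is_start = side == 0
                    if is_start == plus:
                        varied.add("acceptor")
                    else:
                        varied.add("donor")
        if varied == {"acceptor", "donor"}:
            labels[u] = "AE_ALT_BOTH"
        elif varied == {"acceptor"}:
            labels[u] = "AE_ALT3SS"
        elif varied == {"donor"}:
            labels[u] = "AE_ALT5SS"
        else:
            labels[u] = "CE"
    return labels


# ---------------------------------------------------------------------------
# sequence features


def oracle_score(freqs, background, window: str) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(
        math.log2(freqs[i][idx[b]] / background[idx[b]])
        for i, b in enumerate(window)
    )


_BP_RE = re.compile(r"[CT]T[ACGT]A[CT]")


def oracle_branch_point(intron: str, min_distance=14, hard_max=350):
    """Regex scan; returns distance of the most proximal in-range match."""
    best = None
    for s in range(len(intron) - 4):
        if _BP_RE.fullmatch(intron[s : s + 5]):
            d = len(intron) - s
            if min_distance <= d <= hard_max and (best is None or d < best):
                best = d
    return best


def oracle_ppt(intron: str, threshold=0.7, min_length=10, span=50, gap=2):
    L = len(intron)
    region_start = max(0, L - span)
    region_end = L - 2 - gap
    best = None  # (length, end, start, frac)
    for i in range(region_start, region_end):
        for j in range(i + min_length, region_end + 1):
            sub = intron[i:j]
            frac = sum(1 for b in sub if b in "CT") / len(sub)
            if frac >= threshold:
                key = (j - i, j)
                if best is None or key > (best[0], best[1]):
                    best = (j - i, j, i, frac)
    if best is None:
        return None
    return (best[2], best[0], best[3])


def oracle_sre_count(seq: str, motif: str) -> int:
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)
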