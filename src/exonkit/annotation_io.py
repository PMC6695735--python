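"""Reading/writing the standard formats.

GTF and GFF3 annotations are read into :class:`~exonkit.models.GeneModel`
objects with coordinates normalized to 0-based half-open. FASTA genomes are
read into a plain ``{chrom: sequence}`` dict. Classification results are
written as a BED-like 8-column TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .models import GeneModel, GenomicInterval, Transcript

VALID_ALPHABET = frozenset("ACGTN")

_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


class AnnotationError(ValueError):
    """Malformed annotation input."""


def _parse_attributes(field: str, dialect: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    field = field.strip()
    if field in ("", "."):
        return attrs
    if dialect == "gtf":
        for chunk in field.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            m = _GTF_ATTR_RE.match(chunk)
            if m:
                attrs[m.group(1)] = m.group(2)
            elif "=" in chunk:  # tolerate GFF3-style pairs in GTF input
                k, _, v = chunk.partition("=")
                attrs[k.strip()] = v.strip()
            else:
                raise AnnotationError(
                    f"line {lineno}: cannot parse attribute chunk {chunk!r}"
                )
    else:  # gff3
        for chunk in field.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" in chunk:
                k, _, v = chunk.partition("=")
                attrs[k.strip()] = v.strip()
            else:
                m = _GTF_ATTR_RE.match(chunk)
                if m:
                    attrs[m.group(1)] = m.group(2)
                else:
                    raise AnnotationError(
                        f"line {lineno}: cannot parse attribute chunk {chunk!r}"
                    )
    return attrs


def read_gene_models(path: Union[str, Path], dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from a GTF or GFF3 file.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes (GFF3 ``Parent``/``ID`` conventions are
    accepted as fallbacks). Coordinates are converted from 1-based inclusive
    to internal 0-based half-open.

    Raises
    ------
    AnnotationError
        On malformed lines (with the offending line number), exons lacking a
        transcript id, or transcripts mixing strands/chromosomes.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    # (gene_id, transcript_id) -> list of exon intervals / attribute dict
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    tx_attrs: dict[tuple[str, str], dict[str, str]] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature.lower() != "exon":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end1 < start1:
                raise AnnotationError(
                    f"line {lineno}: end ({end1}) < start ({start1})"
                )
            if strand not in ("+", "-"):
                raise AnnotationError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_field, dialect, lineno)
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            gid = attrs.get("gene_id") or attrs.get("gene")
            if not tid:
                raise AnnotationError(f"line {lineno}: exon lacks transcript_id")
            if not gid:
                gid = tid
            key = (gid, tid)
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            if key not in exons:
                exons[key] = []
                tx_attrs[key] = {}
                order.append(key)
            prior = exons[key]
            if prior and (prior[0].chrom != chrom or prior[0].strand != strand):
                raise AnnotationError(
                    f"line {lineno}: transcript {tid!r} mixes chromosomes or strands"
                )
            prior.append(interval)
            for k, v in attrs.items():
                tx_attrs[key].setdefault(k, v)

    genes: dict[str, list[Transcript]] = {}
    gene_order: list[str] = []
    for gid, tid in order:
        extra = {
            k: v
            for k, v in tx_attrs[(gid, tid)].items()
            if k not in ("gene_id", "transcript_id")
        }
        try:
            tx = Transcript(
                transcript_id=tid,
                gene_id=gid,
                exons=tuple(exons[(gid, tid)]),
                attributes=tuple(sorted(extra.items())),
            )
        except ValueError as exc:
            raise AnnotationError(str(exc)) from None
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(tx)
    out = []
    for gid in gene_order:
        try:
            out.append(GeneModel(gene_id=gid, transcripts=tuple(genes[gid])))
        except ValueError as exc:
            raise AnnotationError(str(exc)) from None
    return out


def write_gene_models(
    genes: Iterable[GeneModel], path: Union[str, Path], dialect: str = "gtf"
) -> None:
    """Write gene models as GTF (exon features only; coordinates re-based to 1)."""
    if dialect != "gtf":
        raise ValueError("only GTF output is supported")
    path = Path(path)
    with path.open("w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                extras = tx.attributes_dict()
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    )
                    for k, v in sorted(extras.items()):
                        attrs += f' {k} "{v}";'
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "exonkit",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_genome(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    Sequences are restricted to the {A, C, G, T, N} alphabet; duplicate
    record names are rejected.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise AnnotationError(f"duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise AnnotationError(
                f"sequence {record.id!r}: non-nucleotide character {sorted(bad)[0]!r}"
            )
        genome[record.id] = seq
    return genome


def write_genome(genome: dict[str, str], path: Union[str, Path], width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


BED_HEADER = (
    "#chrom\tstart\tend\tname\tlabel\tstrand\ttranscripts\tattributes"
)


def write_bed_like(records: Sequence, path: Union[str, Path]) -> None:
    """Write ExonCall/RegionCall records as a BED-like 8-column TSV.

    Columns: chrom, start (0-based), end (half-open), name
    (``gene_id:feature_index``), label, strand, supporting transcript ids
    (comma-joined, sorted), original attributes (semicolon-joined
    ``key=value``, or ``.``). Records are ordered by
    (chrom, start, end, label).
    """
    rows = []
    for rec in records:
        iv = rec.interval
        tx_ids = ",".join(sorted(rec.supporting_transcripts()))
        attrs = rec.attributes_field()
        rows.append(
            (
                iv.chrom,
                iv.start,
                iv.end,
                f"{rec.gene_id}:{rec.feature_index()}",
                rec.label,
                iv.strand,
                tx_ids or ".",
                attrs or ".",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    with Path(path).open("w") as fh:
        fh.write(BED_HEADER + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
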