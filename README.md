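# exonkit

Toolkit for annotating the exons of multi-isoform eukaryotic genes as
constitutively or alternatively spliced, detecting alternative-splicing
events, computing diagnostic sequence features, and quantifying exon
inclusion levels from splice-junction read counts.

## What it does

* **Event detection** — compares each isoform against the reference isoform
  (maximum exon count, then longest, then smallest id) and reports exon
  skipping (ES), alternative 3′/5′ splice sites (A3SS/A5SS), intron
  retention (IR) and exonic introns, from interval relations alone.
* **Exon classification, two schemes** —
  *intact*: every distinct exon coordinate unit gets one label from
  {CE, AE_CASSETTE, AE_ALT3SS, AE_ALT5SS, AE_ALT_BOTH, AE_IR_MERGED};
  *regions*: the exonic union is segmented into maximal constitutive (CR)
  and alternative (AR) regions by per-base isoform coverage.
* **Sequence features** — PWM log-odds splice-site strength (9-nt donor
  window spanning −3..−1 exonic / +1..+6 intronic; 23-nt acceptor window),
  branch-point search (YTNAY consensus, 14–350 nt upstream of the 3′ SS),
  polypyrimidine-tract detection, SRE k-mer scanning (including the six
  cassette-exon cluster motifs UCUCU, UGCAUG, UGCU, UGUGU, UUUU, AGGG),
  exon/intron lengths and ratios, GC content, boundary GC, and
  reading-frame symmetry (length divisible by 3).
* **Inclusion levels (PSI)** — per cassette exon, the two inclusion
  junctions are averaged and divided by inclusion + exclusion support;
  estimates are classed major (≥ 0.5) or minor.
* **Simulator** — a deterministic four-exon worked example (one isoform per
  event type) plus a seeded generator for random genes with planted events,
  tunable splice-site strength, and junction counts with known PSI.

Inputs are GTF/GFF3 gene models (coordinates normalized internally to
0-based half-open), optional FASTA genomes, and junction-count TSVs.
Outputs are BED-like 8-column TSVs and plain feature tables.

## CLI

```sh
exonkit annotate --annotation genes.gtf --scheme intact  --out exons.bed
exonkit annotate --annotation genes.gtf --scheme regions --out regions.bed
exonkit segment  --annotation genes.gtf --out regions.bed   # alias
exonkit events   --annotation genes.gtf --out events.tsv
exonkit features --annotation genes.gtf --genome genome.fa --out features.tsv
exonkit psi      --annotation genes.gtf --junctions junctions.tsv --out psi.tsv
exonkit simulate --out-dir sim/ --seed 1 --events ES,IR --depth 100
exonkit config-dump            # effective configuration as JSON
```

All thresholds (PWM pseudocount, branch-point/PPT bounds, boundary-GC
window, PSI denominator rule, major/minor cutoff) live in one YAML config
schema (`--config config.yaml`); CLI flags override config values, which
override built-ins. Every subcommand is deterministic given inputs, config
and seed.

## Layout

```
src/exonkit/
  models.py             intervals, transcripts, gene models
  annotation_io.py      GTF/GFF3 + FASTA readers, BED-like writer
  exon_classify.py      both classification schemes + event detection
  sequence_features.py  PWM, branch point, PPT, SREs, architecture
  inclusion_level.py    junction tables and PSI estimation
  synthetic_data.py     worked example + simulators
  config.py, cli.py     configuration schema and command line
tests/                  unit, property and acceptance suites
                        (oracles.py holds independent brute-force checkers)
scripts/acceptance.py   acceptance report
```
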