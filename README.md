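# g4kit

Evidence-tiered G-quadruplex (G4) analysis toolkit. g4kit predicts G4
candidate sites from genome sequence with a run-length G/C scoring scheme,
partitions G4 evidence into three tiers (ChIP-detected only, ChIP-detected
and predicted, predicted only), quantifies their genomic distribution
(feature-class fractions, bp-per-kb densities, TSS-distance profiles),
relates them to gene expression, epigenomic tracks, CpG methylation and
TF binding, fits/applies an 8-feature elastic-net logistic model of
high/low expression, and runs a 6-mer enrichment analysis on G4 flanking
sequences ("feet") with binomial significance, Bonferroni correction and
greedy motif clustering. A seeded simulator generates every input format
the pipeline consumes, with ground-truth bookkeeping for testing.

All coordinates are BED-convention 0-based half-open.

## Test

```sh
python -m pytest -q tests/
```

The suite is self-contained: every fixture is generated at test time by
`g4kit.synthio`.

## CLI

```sh
g4kit simulate --seed 1 --out sim/                 # synthetic input bundle
g4kit predict  --fasta sim/genome.fa --window 25 --threshold 1.5 --out pred.bed
g4kit classify --predictions pred.bed --peaks sim/peaks.bed --out-prefix g4
g4kit annotate --groups-prefix g4 --genes sim/genes.tsv --fasta sim/genome.fa \
               --out-prefix anno
g4kit run-all  --config run.yaml --out out/        # full pipeline + manifest
```

`run-all` takes a YAML config with an `inputs:` section (fasta, peaks,
genes, expression, methylation, tracks, tf_sets) and a `params:` section
(window, threshold, quantile, seed, ...). Stages whose inputs are missing
are skipped with a logged notice; a `manifest.json` records every output
file with its SHA-256 checksum so reruns can be verified byte-for-byte.

Other subcommands: `assoc` (gene-level G4 labels, expression summaries,
hypergeometric enrichment of a gene list), `tracks` (track overlap ratios
and the TF Jaccard matrix), `methyl` (CpG state summary and telomere
profile), `model fit|apply` (the 8-feature expression model; `--printed`
applies the packaged published equation), `feet` (6-mer enrichment and
MEME-format motif export).

## Package layout

| module | contents |
| --- | --- |
| `g4kit.intervals` | interval data model, merge/intersect/Jaccard/subtract, BED + FASTA I/O |
| `g4kit.hunter` | run-length base scoring and windowed G4 prediction |
| `g4kit.evidence` | G4-I/II/III classification and group summaries |
| `g4kit.annotate` | gene models, genome-tiling feature map, densities, TSS profile |
| `g4kit.assoc` | gene G4 labels, antisense flags, expression tests, hypergeometric enrichment |
| `g4kit.tracks` | track overlap ratios, TF Jaccard matrix, CpG methylation analysis |
| `g4kit.model` | 8-feature elastic-net logistic model + the packaged published equation |
| `g4kit.feet` | foot extraction, 6-mer presence/enrichment, motif clustering |
| `g4kit.synthio` | seeded synthetic-data generator with truth reporting |
| `g4kit.cli` | click CLI and `run-all` orchestration |
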