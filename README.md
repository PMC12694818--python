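# mitoshift

Analysis toolkit for germline mitochondrial-DNA heteroplasmy transmission:
heteroplasmy-shift statistics, a simulation-based Kimura-drift neutral null,
mother–offspring selection inference, follicle-stage and copy-number dynamics
summaries, droplet-digital-PCR quantification, conversion-rate off-target
calling, and synthetic data generators that emulate the underlying
experiments so every analysis stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `mitoshift.core` | heteroplasmy shift transforms (`shift_ratio`, `log_shift`), ddPCR Poisson quantification, ≥1 % conversion-rate off-target caller |
| `mitoshift.kimura` | Kimura drift distribution (boundary masses + series density), seeded sampling, drift-parameter estimation, `neutral_null_test` |
| `mitoshift.transmission` | transmission regression, normality-gated mean-shift test, follicle-stage summaries, age/litter associations, tissue CV, copy-number dynamics |
| `mitoshift.simulate` | pedigree (bottleneck + selection), follicle copy-number time course, ddPCR partitioning, base-editing pileup generators |
| `mitoshift.io` / `mitoshift.cli` | TSV schemas and validation, JSON reports, `mitoshift` command-line interface |
| `mitoshift.datasheet` | import of the study's numerical XLSX workbook via an explicit YAML sheet/column mapping |

Heteroplasmy is always a fraction in `[0, 1]` internally; percent-scale
inputs are converted exactly once at the I/O boundary (`--percent` flag —
never guessed).

## Command line

```sh
mitoshift simulate-pedigree --seed 7 --out run/           # writes pairs.tsv
mitoshift transmit run/pairs.tsv --out run/               # regression + mean shift
mitoshift kimura-null run/pairs.tsv --seed 7 --out run/   # neutral-null comparison
mitoshift simulate-follicle --seed 7 --out run/           # oocyte time course
mitoshift dynamics run/oocytes.tsv --out run/             # per-day copy summaries
mitoshift tissue-cv tissues.tsv --out run/
mitoshift simulate-sites --edit 1:0.05 --out run/
mitoshift offtarget run/sites.tsv --out run/
mitoshift simulate-ddpcr --out run/ && mitoshift ddpcr run/ddpcr.tsv --out run/
```

Each command validates its input against the schema (exit 1 with a row/column
error listing on violation), runs the analysis, and atomically writes a JSON
report plus companion TSV tables. Identical inputs, flags and `--seed`
reproduce byte-identical outputs.

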