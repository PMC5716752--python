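# coexscreen

Seed-gene co-expression screening with multi-cohort recurrence consensus.

Given normalized log2-scale expression cohorts, `coexscreen` correlates
every gene with a single *seed gene* within each cohort, splits the
significant genes (two-sided p < alpha from the t-transform of r) into
positive and negative lists, applies a per-condition-group recurrence
cutoff ("significant in at least k of the group's m cohorts"), and
intersects the recurrent lists across groups, reporting consensus gene
sets, Venn region counts, hypergeometric fold enrichment against
user-supplied GMT gene sets, and seed-high/low stratified two-group
tests.  A synthetic multi-cohort generator with planted, latent-factor
driven positive/negative modules makes the whole pipeline testable
offline, and recovery of the planted truth is scored with
precision/recall/F1.

## CLI

All stages are exposed through one entry point:

```sh
# generate a synthetic 4-group screen (TSV cohorts + truth.json + manifest)
coexscreen simulate --seed 1 --outdir sim --groups g1:3,g2:3,g3:3,g4:3 \
    --genes 2000 --samples 100 --beta 0.8 --pi 1.0

# one cohort: correlation table + positive/negative significant lists
coexscreen correlate sim/g1_c1.tsv --seed-gene SEED --alpha 0.05 --outdir corr

# full screen from a YAML/JSON config (see below)
coexscreen screen --config config.yaml --outdir out
coexscreen run-all --config config.yaml          # + enrichment/stratification

# seed-median dichotomization + per-gene t-tests
coexscreen stratify sim/g1_c1.tsv --seed-gene SEED --genes POS0001,NEG0001 --out strat.tsv

# fold enrichment of a gene list against a GMT collection
coexscreen enrich out/consensus.positive.tsv --gmt sets.gmt \
    --background background.tsv --out enrichment.tsv

# score recovered consensus lists against the planted truth
coexscreen recover --truth sim/truth.json --consensus-dir out
```

A run config lists the cohort manifest and thresholds; every printed
default (alpha 0.05, per-group cutoffs) is configurable:

```yaml
cohorts:
  - {path: sim/g1_c1.tsv, cohort_id: g1_c1, group_id: g1}
  # ...
seed_gene: SEED
method: pearson          # or spearman
alpha: 0.05
group_cutoffs: {g1: 2, g2: 2, g3: 2, g4: 2}
consensus_level: 4       # 0 = all groups
outdir: out
```

Screen outputs: per-cohort correlation TSVs and sign lists, per-group
recurrent lists with cohort counts, `consensus.<sign>.tsv`,
`venn.<sign>.tsv` (2-4 groups), `summary.json` (byte-identical across
re-runs of the same config) and `run.log`.

## Expression input format

Tab-separated text, features in rows, header row = sample ids, first
column = feature id, `NA` for missing values.  Values are assumed
log2-scale; a warning is logged when the maximum exceeds 30.  Probe
level data can be collapsed to gene symbols with a 2-column probe map
(`max_mean` keeps the probe with the highest mean; `named_probe` pins
designated probes).

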