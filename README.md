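# latgc — latitude-stratified gastric-cancer multi-omics analysis

`latgc` re-implements, as a tested and reusable pipeline, a latitude-stratified
analysis of gastric-cancer cohorts: patients are split into low- (0–45°) and
high-latitude (46–90°) groups and compared at the clinical, genomic,
transcriptomic, metabolic, and immune level, ending in an immune-related
prognostic model (IRPM). It is aimed at computational-biology researchers who
want each analysis step as a typed, unit-tested library function rather than a
one-off script, and who need synthetic cohorts with known ground truth to
validate the statistics before touching real data.

## What it computes

- **ssGSEA activity scores.** For sample *j* and gene set *S*, genes are
  ranked by expression and the enrichment score is the integrated difference
  between the weighted in-set and unweighted out-of-set empirical CDFs,

  ES(S, j) = Σᵢ [ P_in(i) − P_out(i) ],  P_in(i) = Σ_{k≤i, g_k∈S} r_k^α / Σ_{g∈S} r_g^α,

  with tie-averaged ranks r, exponent α = 0.25, and optional matrix-wide
  (max − min) normalization. Scores depend on expression only through
  within-sample ranks. Used for DNA-repair/metabolic pathway activity,
  28-immune-cell infiltration, and ESTIMATE-style stromal/immune/composite
  scores (composite = stromal + immune).
- **Mutation profiling.** Tumour mutation burden (nonsynonymous mutations per
  Mb, default 38 Mb capture), top mutated genes, pairwise co-occurrence /
  mutual exclusivity (Fisher exact on mutated/wild-type 2×2 tables), and
  per-sample subclone counts: a 1-D Gaussian mixture over variant allele
  frequencies (VAF = alt/(ref+alt)), component count chosen by BIC, component
  variances floored at the binomial sampling variance v(1−v)/depth.
- **Survival statistics.** Kaplan–Meier product-limit curves, log-rank tests,
  and univariate Cox proportional-hazards regression (Efron ties), via
  lifelines behind a typed interface.
- **Driver regulation networks.** Per driver gene and scored feature, a
  rank-sum test of mutated vs wild-type samples; signed edges at p < 0.05,
  assembled per latitude group.
- **IRPM.** (1) Rank immune cells by univariate Cox significance, keep the
  top 5; (2) screen the top 5% of genes by |mean Spearman correlation| with
  the selected cells' infiltration scores, partitioned by sign into positive
  and negative marker sets; (3) score each sample with the Welch *t*
  statistic contrasting positive- vs negative-set expression, and stratify at
  the training cohort's median score (high risk ⇔ score strictly above the
  cutoff). The published 35-positive / 12-negative marker-gene signature is
  packaged (`load_table1_signature()`).
- **Synthetic cohorts.** `generate_cohort(config, seed)` draws a two-group
  cohort in which latent per-cell immune infiltration drives marker-gene
  expression (linear link on the log2 scale), survival hazard
  (hazard = baseline × Π multiplierᶜ^infiltrationᶜ), group-specific mutation
  frequencies, and per-sample subclonal VAF mixtures — with the full ground
  truth retained for recovery tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (200 samples, 2000 genes, 5 immune cells, seed 7) and write their
tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_activity_scores.py
python analysis/04_mutation_profile.py
python analysis/05_differential_expression.py
python analysis/06_regulation_networks.py
python analysis/07_irpm.py
```

Selected output (verbatim):

```
zero-fraction filter: 2000 -> 1943 genes (57 removed at >70% zeros)
immune cells: 5/5 differ between latitudes (rank-sum p<0.05), 5 higher in high latitude
TMB: median high=0.237, low=0.158 mut/Mb (rank-sum p=6.26e-12)
prognostic immune cells (by Cox p, low-latitude training):
  immune_cell_01: HR=25.63 [6.90, 95.20], p=1.27e-06
signature: 75 positive / 22 negative genes
cutoff (low-latitude median score): -1.370
risk stratification log-rank p: low-latitude 1.23e-13, whole cohort 1.44e-19
```

Reading: genes that were zero in more than 70% of samples are dropped and the
rest imputed; all five simulated immune cells infiltrate more strongly at
high latitude (by construction, matching the modelled cohort); the
high-latitude group carries a higher mutation burden; the IRPM recovers the
risk-bearing immune cells (hazard ratios > 1), builds a signed marker-gene
signature, and the resulting score splits survival sharply at the
training-median cutoff.

The same run is available as one command (`latgc run --outdir OUT --seed 7`),
which also writes a manifest with the config snapshot, per-stage output
hashes, and the declared methodological substitutions. `latgc simulate`,
`latgc ssgsea`, `latgc tmb`, and `latgc irpm build|score|validate` expose the
individual stages.

## Layout

- `src/latgc/` — the library: `io_formats`, `synthetic_cohort`, `preprocess`,
  `ssgsea_scoring`, `mutation_profile`, `diff_expression`, `survival_stats`,
  `regulation_network`, `irpm_model`, `benchmarks`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property, and acceptance suites.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
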