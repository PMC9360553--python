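# Methods

## The analysis model

The pipeline compares two latitude-defined groups of gastric-cancer samples.
Samples at 0–45° are low-latitude and 46–90° high-latitude; a sample at
exactly 45° is low, following the printed group ranges rather than a strict
"< 45" rule. Group assignment is data-driven from the clinical latitude
column; samples without a latitude are excluded with a log entry.

Expression preprocessing follows the usual FPKM clean-up: genes whose value
is 0 in strictly more than 70% of samples are removed; the remaining zeros
are treated as *missing* (scheduled for imputation), deliberately distinct
from observed zeros, and imputed by K-nearest-neighbour regression over genes
(Euclidean distance over mutually observed samples, k = 10, tie sets at the
k-th distance averaged in full so the result is deterministic; a gene with no
observed candidate neighbour falls back to its gene mean). Values are then
log2(x+1) transformed. The filter→impute pipeline is idempotent: a matrix
already processed passes through unchanged.

## ssGSEA

For each sample, genes are ranked by expression with tie-averaged ranks
(1 = lowest). Walking the genes in descending order, the enrichment score of
set S accumulates the difference between the weighted in-set ECDF (weights
|rank|^α, α = 0.25) and the unweighted out-of-set ECDF. α and the matrix-wide
(max − min) normalization follow the standard ssGSEA convention; both are
configurable because the analysis they support does not pin them down. Sets
overlapping the matrix in fewer than 2 genes are dropped with a warning;
constant-expression samples cannot be ranked and are an error. The
implementation is checked against an independent brute-force running-sum
oracle on all 3-gene subsets of a 6-gene matrix and against the unweighted
ECDF form at α = 0; rank invariance is asserted under random strictly
monotone transforms.

ESTIMATE-style composites take stromal and immune gene sets as inputs (GMT),
score both unnormalized, and define the composite as their sum — a proxy for
non-tumour content. The published stromal/immune signatures are not
redistributed; the synthetic cohort ships its own.

Group comparisons of score matrices use the two-sided Wilcoxon rank-sum test:
exact enumeration when both groups have ≤ 10 samples and no ties, the
tie-corrected normal approximation otherwise; a feature with all values tied
gets p = 1 and no direction. BH q-values are reported alongside raw p.

## Mutation profiling

TMB is the nonsynonymous mutation count divided by the interrogated territory
in Mb. The synonymous vocabulary is {Silent, Synonymous_Variant} and the
capture size defaults to 38 Mb (the common whole-exome convention); both are
configurable because MAF dialects and capture designs differ. Unknown variant
classes are retained as nonsynonymous with a warning.

Pairwise co-occurrence/exclusivity tests use Fisher's exact test on the
(both, only-A, only-B, neither) table; OR > 1 with p < 0.05 labels the pair
co-occurring, OR < 1 exclusive, mirroring the usual oncoplot convention of
labelling on raw p (BH q is reported for users). Note that swapping the gene
pair transposes the table and therefore preserves the odds ratio.

Subclone counts come from a 1-D Gaussian mixture over the sample's VAFs
(≥ 10 variants with allele counts required, otherwise the sample is flagged
not evaluable). Mixtures with k = 1..5 components are fitted by EM with 10
restarts (tolerance 1e-4, ≤ 500 iterations — a tighter tolerance only makes
the near-degenerate surplus components exhaust the iteration cap without
changing the selected k), and k is chosen by minimum BIC. Because read
sampling makes VAFs granular (a depth-100 VAF takes ~100 distinct values), a
mixture component can collapse onto duplicated values with arbitrarily large
likelihood gain; component variances are therefore floored at the median
binomial sampling variance v(1−v)/depth, which is the known measurement noise
of a VAF at that depth. Clusters assigned fewer than 3 variants are merged
into their nearest-mean neighbour. The reported count includes the clonal
(highest-VAF) cluster, which is flagged separately, since whether published
subclone counts exclude the clonal cluster is generally ambiguous.

Driver genes are selected by mutation frequency — mutated in at least
max(5% of samples, 5 samples) — as a deliberate, configurable substitute for
selection-based (dN/dS) driver calling, which needs reference-genome context
outside this package's scope. The substitution is recorded in every run
manifest.

## Differential expression

Counts are TMM-normalized (reference sample by closest upper quartile, 30%
M-trim, 5% A-trim, precision-weighted mean M, factors rescaled to geometric
mean 1), converted to log2 CPM, and compared per gene with the rank-sum test
plus BH adjustment; calls require |log2FC| ≥ 1 and q ≤ 0.05 (configurable —
the thresholds are a declared default, not an external given). This is a
dependency-light substitute for a negative-binomial GLM fit and is flagged in
the run manifest. Overlap decomposition partitions each direction's calls
into shared / group-specific / neither over a common gene universe.

## Survival statistics

Kaplan–Meier, log-rank, and univariate Cox regression wrap lifelines. Cox
fits use the Efron tie correction and Wald inference; perfect separation is
flagged rather than silently reported. On tie-free data the two-group
log-rank chi-square equals the Cox score test at β = 0, which the tests
assert to 1e-6 against a directly computed partial-likelihood score
statistic. Whether Cox covariates enter continuously or median-dichotomized
is left to the caller (default continuous; a `median_split` helper covers the
common dichotomization).

## Regulation networks

For each driver gene with at least 3 mutated and 3 wild-type samples in a
latitude group, each feature's scores are compared mutated vs wild-type with
the rank-sum test. An edge is emitted at p < 0.05, positive when the mutated
group's median is higher. Edges found in both latitude groups with the same
sign get context "both". Raw p decides edges (matching the rule the analysis
mirrors); BH q within each group's family is reported. Under independence the
edge rate per test is ≈ the 0.05 threshold, which the acceptance suite checks
at n = 200 over 50 seeds.

## IRPM

Step 1 ranks immune cells by univariate Cox p on their infiltration scores
and keeps the top 5; a warning is raised if a selected cell is protective
(HR < 1), since the modelled signature assumes risk cells. Step 2 correlates
every gene with each selected cell's score (Spearman — robust to mixed
expression scales), summarizes per gene as the arithmetic mean across cells,
ranks by absolute summary, keeps the top 5%, and partitions by sign. Step 3
scores a sample with the Welch two-sample t statistic (positive-set minus
negative-set expression); Welch because the two sides have unequal sizes and
no variance-equality argument exists. Degenerate profiles: both sides
constant and equal → 0; constant and unequal → signed infinity flag.
Correlation measure, aggregation, and the |corr|-then-sign selection are
package conventions, stated here because the three-step recipe does not
determine them; all are configurable. Ties at the risk cutoff are assigned
low risk because high risk requires a score *strictly* above the cutoff.
Reproducing the published numeric cutoff (−3.82) requires the original
external cohort and is out of scope; the cutoff is always recomputed as the
training cohort's median score.

## Synthetic cohort

The generator draws, from a single seeded RNG stream:

- latent infiltration z per sample and immune cell, Normal(μ_group, 1), with
  the high-latitude mean shifted by 0.8 (high latitude more infiltrated);
- marker-gene log2 expression = gene baseline (Normal(3,1)) + 1.0·z + noise
  (σ = 0.5); a configurable block of genes is negatively linked to the mean
  risk-cell infiltration, giving signed ground-truth marker lists;
- FPKM = 2^(log2 expression) with no length correction (downstream methods
  are rank-based, so only ordering structure matters), counts
  negative-binomial (gamma–Poisson, dispersion 0.1) around a scaled FPKM
  mean; a block of non-marker genes receives sample-wise dropout with
  per-gene zero probabilities in [0.2, 0.9] so the filter/imputation path is
  exercised;
- survival exponential with hazard = baseline (1/1000 per day) ×
  Π multiplierᶜ^{zᶜ}; censoring times exponential with hazard proportional to
  the event hazard, which makes the per-sample censoring probability exactly
  the configured rate (default 0.3);
- mutations Bernoulli per gene with group-specific probabilities (low-group
  rates Uniform(0.02, 0.25), high-group 1.5×, capped), each record's VAF drawn
  from the sample's subclone mixture (1–3 clusters, clonal centre in
  [0.40, 0.50], subclonal in [0.05, 0.30], ≥ 0.10 apart) with binomial read
  sampling at depth 100; ~20% of records are Silent;
- clinical factors (stage, grade, gender) with mildly group-dependent rates
  so the Fisher contingency path has signal.

Defaults: 100+100 samples, 2000 genes, 5 immune cells × 20 markers, all cells
risk factors (multiplier 2 per unit infiltration). The IRPM recovery
experiments (`benchmarks.IRPM_STUDY_CONFIG`) use 300 samples, 1200 genes, 8
cells of which exactly 5 are risk factors, 40 positively and 15 negatively
linked genes.

What the generator does **not** emulate: trinucleotide mutational-signature
structure, copy number (so VAF clusters map to subclones without CCF
correction), batch effects, realistic gene–gene correlation beyond the shared
infiltration factors, tumour purity, and tumour-vs-normal contrasts (there
are no normal samples; the DE driver demonstrates the machinery on the
latitude contrast and on half-cohort replication splits). Passing recovery
tests therefore show that the statistics behave correctly under the model's
assumptions — not that those assumptions hold in any real cohort.

## Benchmarks and problem sizes

The evaluation suite (`latgc.benchmarks`, exercised by `tests/test_acceptance.py`
and `scripts/acceptance.py`) uses: Cox slope recovery at n = 500 (true slope
0.7), type-I calibration over 200 null fits at n = 100, subclone recovery over
50 seeds per scenario (50 variants, depth 100; centres 0.45/0.10 and a single
0.50 cluster), IRPM end-to-end recovery over 50 fresh 300-sample cohorts, and
the network null over 50 seeds × 24 tests at n = 200. These sizes give
stable rates (binomial SE ≤ ~0.04 on any reported proportion) while keeping
the whole suite around two minutes on one CPU.

## Known limitations

- The rank-sum DE substitute has less power than dispersion-shrinkage NB
  models at small n and ignores count overdispersion structure beyond ranks.
- Frequency-based driver selection conflates mutability with selection; at
  the synthetic mutation rates it selects many genes by design.
- ssGSEA normalization couples scores across the whole matrix; scores are
  comparable within a run, not across runs with different set collections.
- Subclone counting treats VAF clusters as subclones; without copy-number or
  purity correction the mapping is approximate, and samples with < 10
  count-bearing variants are not evaluable (a real exome typically clears
  this bar; sparse synthetic samples may not).
- Cox fits with very strong effects on small groups can show wide Wald CIs
  (the hazard-ratio point estimates in the worked example are n = 100
  training fits).
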