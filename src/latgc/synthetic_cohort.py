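"""Synthetic gastric-cancer cohort with the latent structure the analysis assumes.

The generator emulates the data model the pipeline consumes:

* two latitude groups (low: 0-45 deg, high: 46-90 deg);
* per-sample latent immune-infiltration levels, one per immune cell, that
  shift the log-scale mean expression of that cell's marker genes (linear
  link, Gaussian noise on the log2 scale);
* an FPKM-like matrix (2**log-mean, no length correction — downstream scoring
  is rank-based so only ordering structure matters) and a counts matrix drawn
  negative-binomial around the FPKM-derived mean;
* exponential survival with hazard = baseline * prod_c multiplier_c**z_c and
  independent censoring at a configured rate;
* group-specific per-gene mutation probabilities, with per-record variant
  allele frequencies drawn from a per-sample subclonal mixture and binomial
  read sampling at a declared depth.

Ground truth (infiltration, hazard multipliers, mutation probabilities, VAF
cluster centers, signed infiltration-linked gene lists) is retained for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CohortClinical,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

__all__ = ["CohortConfig", "CohortTruth", "SyntheticCohort", "generate_cohort", "truth_report", "write_cohort"]


@dataclass
class CohortConfig:
    """Generator settings. Defaults describe the standard study conditions:
    a 200-sample two-group cohort over 2000 genes with 5 immune cells."""

    n_low: int = 100
    n_high: int = 100
    n_genes: int = 2000
    n_immune_cells: int = 5
    markers_per_cell: int = 20
    #: genes constructed to track mean risk-cell infiltration negatively
    n_negative_link_genes: int = 15
    #: log2-FPKM shift per unit latent infiltration for marker genes
    infiltration_effect: float = 1.0
    #: mean latent infiltration in the high-latitude group (low group: 0)
    high_group_infiltration_shift: float = 0.8
    #: Gaussian noise s.d. on the log2-FPKM scale
    noise_sd: float = 0.5
    #: per-cell hazard multiplier per unit infiltration; None -> all risk
    #: cells at 2.0 (cells are risk factors, matching the modelled cohort)
    hazard_multipliers: tuple[float, ...] | None = None
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.3
    #: number of genes carrying somatic mutations
    n_mutation_genes: int = 60
    #: scales group-specific mutation probabilities (high latitude higher TMB)
    mutation_rate_low: tuple[float, float] = (0.02, 0.25)
    mutation_rate_high_factor: float = 1.5
    #: probability of 1, 2, ... subclones per sample
    subclone_count_probs: tuple[float, ...] = (0.4, 0.4, 0.2)
    sequencing_depth: int = 100
    synonymous_fraction: float = 0.2
    #: extra non-marker genes given sample-wise dropout (zeros) in FPKM
    n_zero_inflated_genes: int = 200
    zero_prob_range: tuple[float, float] = (0.2, 0.9)
    #: negative-binomial dispersion (var = mu + dispersion * mu**2)
    nb_dispersion: float = 0.1
    counts_scale: float = 30.0
    #: auxiliary random gene sets written as a pathway collection
    n_pathway_sets: int = 10
    pathway_set_size: int = 30

    def validate(self) -> None:
        if min(self.n_low, self.n_high, self.n_genes, self.n_immune_cells, self.markers_per_cell) <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        lo, hi = self.mutation_rate_low
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mutation_rate_low must be an increasing pair in [0,1]")
        if not np.isclose(sum(self.subclone_count_probs), 1.0):
            raise ValueError("subclone_count_probs must sum to 1")
        needed = self.n_immune_cells * self.markers_per_cell + self.n_negative_link_genes
        if needed + self.n_mutation_genes > self.n_genes:
            raise ValueError("n_genes too small for requested marker/mutation gene counts")

    def resolved_multipliers(self) -> np.ndarray:
        if self.hazard_multipliers is None:
            return np.full(self.n_immune_cells, 2.0)
        m = np.asarray(self.hazard_multipliers, dtype=float)
        if len(m) != self.n_immune_cells:
            raise ValueError("hazard_multipliers length must equal n_immune_cells")
        if (m <= 0).any():
            raise ValueError("hazard multipliers must be positive")
        return m


@dataclass
class CohortTruth:
    """Ground truth retained from generation, for recovery tests."""

    latitude_group: pd.Series  # sample -> {low, high}
    infiltration: pd.DataFrame  # samples x immune cells, latent levels
    hazard_multipliers: pd.Series  # cell -> multiplier
    mutation_probs: pd.DataFrame  # gene x {low, high}
    subclone_counts: pd.Series  # sample -> k
    vaf_centers: dict[str, np.ndarray]  # sample -> cluster centers in (0,1]
    positive_link_genes: list[str]
    negative_link_genes: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.infiltration.to_numpy()).all():
            raise ValueError("infiltration levels must be finite")
        if (self.hazard_multipliers <= 0).any():
            raise ValueError("hazard multipliers must be > 0")
        if (self.subclone_counts < 1).any():
            raise ValueError("subclone counts must be >= 1")
        for sample, centers in self.vaf_centers.items():
            if ((centers <= 0) | (centers > 1)).any():
                raise ValueError(f"VAF centers out of (0,1] for {sample}")


@dataclass
class SyntheticCohort:
    expression_counts: ExpressionMatrix
    expression_fpkm: ExpressionMatrix
    mutations: MutationTable
    clinical: CohortClinical
    genesets: GeneSetCollection
    truth: CohortTruth | None

    def __post_init__(self) -> None:
        ids = set(self.expression_fpkm.sample_ids)
        if set(self.expression_counts.sample_ids) != ids or set(self.clinical.sample_ids) != ids:
            raise ValueError("components disagree on sample ids")


def _draw_vaf_centers(rng: np.random.Generator, k: int) -> np.ndarray:
    """One clonal cluster near 0.5 plus k-1 subclonal clusters, separated."""
    centers = [rng.uniform(0.40, 0.50)]
    while len(centers) < k:
        c = rng.uniform(0.05, 0.30)
        if all(abs(c - other) >= 0.10 for other in centers):
            centers.append(c)
    return np.sort(np.asarray(centers))[::-1]


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Deterministically generate a cohort under ``config`` from one RNG stream."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n = config.n_low + config.n_high
    samples = [f"S{i:04d}" for i in range(n)]
    group = pd.Series(["low"] * config.n_low + ["high"] * config.n_high, index=samples, name="group")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    cells = [f"immune_cell_{c:02d}" for c in range(config.n_immune_cells)]
    multipliers = config.resolved_multipliers()

    # gene role assignment: first blocks are markers, then negative-link genes
    risk_cells = multipliers > 1
    if not risk_cells.any():
        risk_cells = np.ones_like(risk_cells, dtype=bool)
    marker_sets: dict[str, set[str]] = {}
    pos_link: list[str] = []  # genes constructed to track risk-cell infiltration
    idx = 0
    for c, cell in enumerate(cells):
        block = genes[idx : idx + config.markers_per_cell]
        marker_sets[cell] = set(block)
        if risk_cells[c]:
            pos_link.extend(block)
        idx += config.markers_per_cell
    neg_link = genes[idx : idx + config.n_negative_link_genes]
    idx += config.n_negative_link_genes
    mutation_genes = genes[idx : idx + config.n_mutation_genes]

    # latent infiltration: higher on average at high latitude
    shift = np.where(group.to_numpy() == "high", config.high_group_infiltration_shift, 0.0)
    infiltration = rng.normal(loc=shift[:, None], scale=1.0, size=(n, config.n_immune_cells))
    infil_df = pd.DataFrame(infiltration, index=samples, columns=cells)

    # expression: baseline log2-FPKM per gene, infiltration-linked shifts
    base = rng.normal(loc=3.0, scale=1.0, size=config.n_genes)
    log2_mean = np.tile(base[:, None], (1, n))
    for c, cell in enumerate(cells):
        rows = [genes.index(g) for g in sorted(marker_sets[cell])]
        log2_mean[rows, :] += config.infiltration_effect * infiltration[:, c][None, :]
    if neg_link:
        mean_risk_infil = infiltration[:, risk_cells].mean(axis=1)
        rows = [genes.index(g) for g in neg_link]
        log2_mean[rows, :] -= config.infiltration_effect * mean_risk_infil[None, :]
    log2_expr = log2_mean + rng.normal(scale=config.noise_sd, size=log2_mean.shape)
    fpkm = np.power(2.0, log2_expr)

    # sample-wise dropout on a block of non-marker genes (exercises the
    # zero-fraction filter and KNN imputation downstream)
    n_zi = min(config.n_zero_inflated_genes, config.n_genes - idx)
    if n_zi > 0:
        zi_rows = np.arange(idx, idx + n_zi)
        zero_probs = rng.uniform(*config.zero_prob_range, size=n_zi)
        dropout = rng.random(size=(n_zi, n)) < zero_probs[:, None]
        fpkm[zi_rows, :] = np.where(dropout, 0.0, fpkm[zi_rows, :])

    mu = config.counts_scale * fpkm
    # NB via gamma-Poisson; dispersion 0 degenerates to Poisson
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, 1.0, size=mu.shape) / shape * mu
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    fpkm_mat = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples), "fpkm")
    counts_mat = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), "counts")

    # survival: exponential event times; hazard tied to infiltration
    log_hazard = np.log(config.baseline_hazard) + infiltration @ np.log(multipliers)
    hazard = np.exp(log_hazard)
    event_t = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        # censoring hazard proportional to the event hazard gives an exact
        # per-sample censoring probability equal to the configured rate
        c = config.censoring_rate
        censor_t = rng.exponential(1.0 / (hazard * c / (1.0 - c)))
    else:
        censor_t = np.full(n, np.inf)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)

    latitude = np.where(group.to_numpy() == "low", rng.uniform(5, 45, size=n), rng.uniform(46, 70, size=n))
    stage_p = np.where(group.to_numpy() == "low", 0.7, 0.55)
    grade_p = np.where(group.to_numpy() == "low", 0.45, 0.7)
    clinical = CohortClinical(
        pd.DataFrame(
            {
                "os_time": np.round(os_time, 2),
                "os_event": os_event,
                "latitude": np.round(latitude, 2),
                "group": group.to_numpy(),
                "stage": np.where(rng.random(n) < stage_p, "III-IV", "I-II"),
                "grade": np.where(rng.random(n) < grade_p, "G3", "G1-2"),
                "gender": np.where(rng.random(n) < 0.6, "male", "female"),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    # mutations: group-specific per-gene Bernoulli, subclonal VAF mixture
    lo, hi = config.mutation_rate_low
    p_low = rng.uniform(lo, hi, size=config.n_mutation_genes)
    p_high = np.clip(p_low * config.mutation_rate_high_factor, 0, 0.95)
    mut_probs = pd.DataFrame({"low": p_low, "high": p_high}, index=mutation_genes)

    k_choices = np.arange(1, len(config.subclone_count_probs) + 1)
    subclone_counts = pd.Series(
        rng.choice(k_choices, size=n, p=config.subclone_count_probs), index=samples
    )
    vaf_centers = {s: _draw_vaf_centers(rng, int(k)) for s, k in subclone_counts.items()}

    rows = []
    for si, s in enumerate(samples):
        p = p_high if group.iloc[si] == "high" else p_low
        mutated = rng.random(config.n_mutation_genes) < p
        centers = vaf_centers[s]
        weights = np.full(len(centers), 1.0 / len(centers))
        for gi in np.flatnonzero(mutated):
            center = centers[rng.choice(len(centers), p=weights)]
            alt = rng.binomial(config.sequencing_depth, center)
            alt = max(int(alt), 1)  # a called variant has >= 1 alt read
            vc = "Silent" if rng.random() < config.synonymous_fraction else "Missense_Mutation"
            rows.append(
                {
                    "sample_id": s,
                    "gene": mutation_genes[gi],
                    "variant_classification": vc,
                    "chrom": str(rng.integers(1, 23)),
                    "position": int(rng.integers(1, 10_000_000)),
                    "ref_count": config.sequencing_depth - alt,
                    "alt_count": alt,
                }
            )
    mutations = MutationTable(
        pd.DataFrame(rows, columns=["sample_id", "gene", "variant_classification", "chrom", "position", "ref_count", "alt_count"])
    )

    sets: dict[str, set[str]] = {cell: set(marker_sets[cell]) for cell in cells}
    free_genes = genes[idx + n_zi :] or genes
    for p in range(config.n_pathway_sets):
        size = min(config.pathway_set_size, len(free_genes))
        members = rng.choice(free_genes, size=size, replace=False)
        sets[f"pathway_{p:02d}"] = set(members.tolist())
    # composite-score inputs: the immune signature pools the marker genes,
    # the stromal signature is an unlinked gene block
    sets["immune_signature"] = set(pos_link)
    stromal_size = min(config.pathway_set_size, len(free_genes))
    sets["stromal_signature"] = set(rng.choice(free_genes, size=stromal_size, replace=False).tolist())
    genesets = GeneSetCollection(sets)

    truth = CohortTruth(
        latitude_group=group,
        infiltration=infil_df,
        hazard_multipliers=pd.Series(multipliers, index=cells),
        mutation_probs=mut_probs,
        subclone_counts=subclone_counts,
        vaf_centers=vaf_centers,
        positive_link_genes=pos_link,
        negative_link_genes=list(neg_link),
    )
    return SyntheticCohort(counts_mat, fpkm_mat, mutations, clinical, genesets, truth)


def truth_report(cohort: SyntheticCohort) -> CohortTruth:
    """Return the stored ground truth; error if the cohort carries none."""
    if cohort.truth is None:
        raise ValueError("cohort has no stored ground truth")
    return cohort.truth


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write all cohort components to TSV/GMT under ``outdir``; returns paths."""
    from pathlib import Path

    from .io_formats import write_clinical, write_expression_matrix, write_gmt, write_maf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "expression_counts.tsv",
        "fpkm": outdir / "expression_fpkm.tsv",
        "mutations": outdir / "mutations.maf.tsv",
        "clinical": outdir / "clinical.tsv",
        "genesets": outdir / "genesets.gmt",
    }
    write_expression_matrix(cohort.expression_counts, paths["counts"])
    write_expression_matrix(cohort.expression_fpkm, paths["fpkm"])
    write_maf(cohort.mutations, paths["mutations"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(cohort.genesets, paths["genesets"])
    return {k: str(v) for k, v in paths.items()}
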