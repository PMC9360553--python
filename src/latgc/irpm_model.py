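"""The immune-related prognostic model (IRPM).

Construction proceeds in three steps:

1. rank immune cells by univariate Cox significance of their infiltration
   scores and keep the most significant few (default 5) — in the cohort this
   models, those cells are all risk factors (hazard ratio > 1);
2. correlate every gene's expression with the selected cells' infiltration
   scores (Spearman), summarize per gene as the mean correlation across the
   cells, rank by |mean correlation| and keep the top fraction (default 5%),
   partitioned by correlation sign into positive and negative marker sets;
3. score each sample with the Welch two-sample t statistic contrasting its
   expression of the positive-set genes against the negative-set genes
   (positive minus negative): a high score means the immune-positive markers
   are relatively overexpressed.

Samples are stratified at a cutoff (the training cohort's median score when
constructed) into high-risk (score > cutoff) and low-risk groups, and the
split is validated by Kaplan-Meier curves and a log-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortClinical, ExpressionMatrix, GeneSetCollection
from .ssgsea_scoring import ScoreMatrix
from .survival_stats import CoxResult, cox_univariate, km_estimate, logrank_test, KmCurve

__all__ = [
    "IrpmSignature",
    "IrpmScores",
    "rank_prognostic_cells",
    "select_marker_genes",
    "irpm_score",
    "score_matrix",
    "stratify_and_validate",
    "signature_from_collection",
]

log = logging.getLogger(__name__)


@dataclass
class IrpmSignature:
    """Signed marker-gene signature: positive and negative gene sets."""

    positive_genes: frozenset[str]
    negative_genes: frozenset[str]
    source: str = "constructed"  # constructed | table1
    selected_cells: list[str] = field(default_factory=list)
    gene_correlations: pd.Series | None = None

    def __post_init__(self) -> None:
        self.positive_genes = frozenset(self.positive_genes)
        self.negative_genes = frozenset(self.negative_genes)
        if not self.positive_genes or not self.negative_genes:
            raise ValueError("both signature sides must be non-empty")
        if self.positive_genes & self.negative_genes:
            raise ValueError("positive and negative sets must be disjoint")

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            {"IRPM_positive": set(self.positive_genes), "IRPM_negative": set(self.negative_genes)},
            {
                "IRPM_positive": {g: 1 for g in self.positive_genes},
                "IRPM_negative": {g: -1 for g in self.negative_genes},
            },
        )


@dataclass
class IrpmScores:
    """Per-sample IRPM score with cutoff-based risk stratification."""

    scores: pd.Series
    cutoff: float
    risk: pd.Series  # high | low; high iff score > cutoff

    def __post_init__(self) -> None:
        mismatch = (self.risk == "high") != (self.scores > self.cutoff)
        if mismatch.any():
            raise ValueError("risk labels inconsistent with cutoff rule")


def signature_from_collection(collection: GeneSetCollection, source: str = "table1") -> IrpmSignature:
    """Build a signature from a signed two-set collection (e.g. the packaged
    marker-gene fixture)."""
    return IrpmSignature(
        positive_genes=frozenset(collection["IRPM_positive"]),
        negative_genes=frozenset(collection["IRPM_negative"]),
        source=source,
    )


def rank_prognostic_cells(
    immune_scores: ScoreMatrix,
    clinical: CohortClinical,
    n_cells: int = 5,
) -> tuple[list[str], dict[str, CoxResult]]:
    """Univariate Cox fit per immune cell; returns the ``n_cells`` most
    significant cells (ordered by p) with their fits. Warns when a selected
    cell is protective (HR < 1), since the modelled signature assumes risk
    cells."""
    common = [s for s in immune_scores.sample_ids if s in clinical.table.index]
    if not common:
        raise ValueError("no samples shared between scores and clinical table")
    surv = clinical.table.loc[common]
    if surv["os_event"].sum() == 0:
        raise ValueError("no events in cohort; Cox undefined")
    fits: dict[str, CoxResult] = {}
    for cell in immune_scores.feature_ids:
        x = immune_scores.data.loc[cell, common].to_numpy(dtype=float)
        try:
            fits[cell] = cox_univariate(x, surv["os_time"], surv["os_event"])
        except ValueError as err:
            log.warning("Cox fit failed for %s: %s", cell, err)
    if not fits:
        raise ValueError("all Cox fits failed")
    ordered = sorted(fits, key=lambda c: fits[c].p)
    selected = ordered[: min(n_cells, len(ordered))]
    protective = [c for c in selected if fits[c].hazard_ratio < 1]
    if protective:
        warnings.warn(f"selected cells with HR < 1 (protective): {protective}", stacklevel=2)
    return selected, {c: fits[c] for c in selected}


def select_marker_genes(
    expr: ExpressionMatrix,
    cell_scores: ScoreMatrix,
    top_fraction: float = 0.05,
    method: str = "spearman",
) -> IrpmSignature:
    """Screen the genes most correlated with the selected cells' infiltration.

    Per gene: correlation with each cell's score vector, summarized as the
    arithmetic mean across cells; genes ranked by |mean correlation|; the top
    ``top_fraction`` retained and partitioned by sign. Constant genes have
    undefined correlation and are excluded (logged).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    common = [s for s in expr.sample_ids if s in cell_scores.sample_ids]
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    x = expr.data[common].to_numpy(dtype=float)
    cells = cell_scores.data[common].to_numpy(dtype=float)

    const = np.ptp(x, axis=1) == 0
    if const.any():
        log.info("select_marker_genes: excluding %d constant genes", int(const.sum()))
    genes = np.asarray(expr.gene_ids)[~const]
    x = x[~const]

    if method == "spearman":
        xr = stats.rankdata(x, axis=1)
        cr = stats.rankdata(cells, axis=1)
    elif method == "pearson":
        xr, cr = x, cells
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    xs = (xr - xr.mean(axis=1, keepdims=True)) / xr.std(axis=1, keepdims=True)
    cs = (cr - cr.mean(axis=1, keepdims=True)) / cr.std(axis=1, keepdims=True)
    corr = xs @ cs.T / xs.shape[1]  # genes x cells
    mean_corr = pd.Series(corr.mean(axis=1), index=genes)

    n_top = max(int(round(top_fraction * len(mean_corr))), 2)
    top = mean_corr.reindex(mean_corr.abs().sort_values(ascending=False).index).head(n_top)
    positive = frozenset(top.index[top > 0])
    negative = frozenset(top.index[top < 0])
    if not positive or not negative:
        raise ValueError("top-correlated genes are all one sign; cannot form a two-sided signature")
    return IrpmSignature(
        positive_genes=positive,
        negative_genes=negative,
        source="constructed",
        selected_cells=list(cell_scores.feature_ids),
        gene_correlations=mean_corr,
    )


def irpm_score(expr_sample: pd.Series, sig: IrpmSignature) -> float:
    """Welch two-sample t statistic contrasting the sample's expression of the
    positive-set genes against the negative-set genes (positive minus
    negative). Higher score = positive genes relatively overexpressed."""
    pos = [g for g in sig.positive_genes if g in expr_sample.index]
    neg = [g for g in sig.negative_genes if g in expr_sample.index]
    if len(pos) < 2 or len(neg) < 2:
        missing_pos = sorted(sig.positive_genes - set(pos))
        missing_neg = sorted(sig.negative_genes - set(neg))
        raise ValueError(
            f"signature genes missing from profile (need >= 2 per side): "
            f"positive missing {missing_pos[:5]}, negative missing {missing_neg[:5]}"
        )
    a = expr_sample[pos].to_numpy(dtype=float)
    b = expr_sample[neg].to_numpy(dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0
        return float(np.sign(a.mean() - b.mean()) * np.inf)
    return float(stats.ttest_ind(a, b, equal_var=False).statistic)


def score_matrix(expr: ExpressionMatrix, sig: IrpmSignature) -> pd.Series:
    """IRPM score of every sample in an expression matrix."""
    return pd.Series(
        {s: irpm_score(expr.data[s], sig) for s in expr.sample_ids},
        name="irpm_score",
    )


def stratify_and_validate(
    scores: pd.Series,
    clinical: CohortClinical,
    cutoff: float | None = None,
) -> tuple[IrpmScores, dict[str, KmCurve], float]:
    """Dichotomize IRPM scores at ``cutoff`` (median of the supplied scores
    when omitted; ties at the cutoff are low risk since risk requires a
    strictly greater score) and test the survival split by log-rank.

    Returns the stratification, per-risk-group KM curves, and the log-rank p.
    """
    common = [s for s in scores.index if s in clinical.table.index]
    if not common:
        raise ValueError("scores and clinical table share no samples")
    s = scores[common].astype(float)
    if cutoff is None:
        cutoff = float(np.median(s))
    risk = pd.Series(np.where(s > cutoff, "high", "low"), index=s.index, name="risk")
    if risk.nunique() < 2:
        raise ValueError("all samples fall on one side of the cutoff")
    surv = clinical.table.loc[common]
    curves = {
        level: km_estimate(surv.loc[risk == level, "os_time"], surv.loc[risk == level, "os_event"])
        for level in ("high", "low")
    }
    _, p = logrank_test(surv["os_time"], surv["os_event"], risk.to_numpy())
    return IrpmScores(s, float(cutoff), risk), curves, float(p)
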