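"""Single-sample gene set enrichment (ssGSEA) scoring and group comparisons.

For each sample, genes are ranked by expression and the enrichment score of a
gene set is the integrated difference between the weighted in-set empirical
cumulative distribution (weights |rank|^alpha over the expression ranks) and
the unweighted out-of-set ECDF, accumulated down the ranked list:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{j <= i, g_j in S} r_j^alpha / sum_{g in S} r_g^alpha
    P_out(i) = #{j <= i, g_j not in S} / (N - |S|)

where r_g is the (tie-averaged) within-sample rank, N at the top. Scores
depend on expression only through within-sample ranks, so any strictly
monotone per-sample transform leaves them unchanged. With normalize=True the
whole score matrix is divided by its (max - min), the usual ssGSEA convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = ["ScoreMatrix", "GroupComparison", "ssgsea_scores", "estimate_scores", "compare_groups"]

log = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Feature-by-sample activity/infiltration scores."""

    data: pd.DataFrame  # features x samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GroupComparison:
    """Per-feature two-group rank-sum comparison with BH adjustment."""

    table: pd.DataFrame  # columns: median_<g1>, median_<g2>, stat, p, q, direction


def ssgsea_scores(
    mat: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    min_overlap: int = 2,
) -> ScoreMatrix:
    """ssGSEA enrichment score of every gene set in every sample.

    Sets overlapping the matrix in fewer than ``min_overlap`` genes are
    dropped with a warning; a sample with constant expression has no ranking
    and is an error.
    """
    if mat.layout not in ("log2", "fpkm"):
        raise ValueError(f"ssGSEA expects log2 or fpkm layout, got {mat.layout}")
    expr = mat.values
    if np.isnan(expr).any():
        raise ValueError("expression contains missing values; impute first")
    n_genes, n_samples = expr.shape
    const = np.ptp(expr, axis=0) == 0
    if const.any():
        bad = [mat.sample_ids[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant-expression samples cannot be ranked: {bad[:5]}")

    gene_index = {g: i for i, g in enumerate(mat.gene_ids)}
    kept: list[tuple[str, np.ndarray]] = []
    for name in sets.names():
        rows = np.array(sorted(gene_index[g] for g in sets[name] if g in gene_index), dtype=int)
        if rows.size < min_overlap:
            log.warning("ssgsea_scores: dropping set %r (overlap %d < %d)", name, rows.size, min_overlap)
            continue
        if rows.size == n_genes:
            raise ValueError(f"set {name!r} covers every gene; out-of-set ECDF undefined")
        kept.append((name, rows))
    if not kept:
        raise ValueError("no gene set overlaps the matrix sufficiently")

    # tie-averaged within-sample ranks (1 = lowest expression, N = highest)
    ranks = stats.rankdata(expr, axis=0)
    order = np.argsort(-expr, axis=0, kind="stable")  # descending positions

    scores = np.empty((len(kept), n_samples))
    for j in range(n_samples):
        ordered_genes = order[:, j]
        w = np.abs(ranks[ordered_genes, j]) ** alpha
        for si, (_, rows) in enumerate(kept):
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[rows] = True
            in_ordered = in_set[ordered_genes]
            w_in = np.where(in_ordered, w, 0.0)
            denom_in = w_in.sum()
            cum_in = np.cumsum(w_in) / denom_in
            cum_out = np.cumsum(~in_ordered) / (n_genes - rows.size)
            scores[si, j] = float(np.sum(cum_in - cum_out))

    df = pd.DataFrame(scores, index=[name for name, _ in kept], columns=mat.sample_ids)
    if normalize:
        span = float(df.to_numpy().max() - df.to_numpy().min())
        if span > 0:
            df = df / span
    return ScoreMatrix(df, normalized=normalize)


def estimate_scores(
    mat: ExpressionMatrix,
    stromal_set: set[str] | frozenset[str],
    immune_set: set[str] | frozenset[str],
    alpha: float = 0.25,
) -> ScoreMatrix:
    """Stromal, immune, and combined (estimate = stromal + immune) scores.

    The composite proxies the non-tumour content of a sample: a higher value
    means a larger stromal/immune component in the microenvironment.
    """
    sets = GeneSetCollection({"stromal": set(stromal_set), "immune": set(immune_set)})
    base = ssgsea_scores(mat, sets, alpha=alpha, normalize=False)
    df = base.data.reindex(["stromal", "immune"])
    if df.isna().any().any():
        raise ValueError("stromal/immune sets do not overlap the matrix")
    est = df.loc["stromal"] + df.loc["immune"]
    out = pd.concat([df, est.to_frame("estimate").T])
    return ScoreMatrix(out, normalized=False)


def _ranksum_two_sided(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum. Exact enumeration when both groups are
    small and tie-free; normal approximation (tie-corrected, with continuity
    correction) otherwise. Degenerate all-tied input gives (0, 1)."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    scores: ScoreMatrix,
    groups: pd.Series,
    group_a: str = "high",
    group_b: str = "low",
    p_threshold: float = 0.05,
) -> GroupComparison:
    """Per-feature two-sided rank-sum comparison between two sample groups,
    with BH q-values and a median-based direction call at ``p_threshold``."""
    groups = groups.reindex(scores.sample_ids).dropna()
    a_ids = groups.index[groups == group_a]
    b_ids = groups.index[groups == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for feature in scores.feature_ids:
        x = scores.data.loc[feature, a_ids].to_numpy(dtype=float)
        y = scores.data.loc[feature, b_ids].to_numpy(dtype=float)
        stat, p = _ranksum_two_sided(x, y)
        med_a, med_b = float(np.median(x)), float(np.median(y))
        if p < p_threshold and med_a > med_b:
            direction = f"higher_in_{group_a}"
        elif p < p_threshold and med_a < med_b:
            direction = f"higher_in_{group_b}"
        else:
            direction = "none"
        rows.append({
            "feature": feature,
            f"median_{group_a}": med_a,
            f"median_{group_b}": med_b,
            "stat": stat,
            "p": p,
            "direction": direction,
        })
    table = pd.DataFrame(rows).set_index("feature")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return GroupComparison(table)
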