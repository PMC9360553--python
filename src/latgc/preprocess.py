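"""Expression filtering/imputation/transformation, latitude grouping, and
clinical contingency tests.

The expression pipeline mirrors the standard FPKM cleanup: genes with zeros
in more than 70% of samples are dropped, the remaining zeros are treated as
missing and imputed by K-nearest neighbours over genes, and values are
log2(x+1) transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

from .io_formats import CohortClinical, ExpressionMatrix

__all__ = [
    "FisherResult",
    "filter_low_expression",
    "knn_impute",
    "log2_transform",
    "assign_latitude_group",
    "clinical_contingency_test",
    "fisher_2x2",
]

log = logging.getLogger(__name__)


@dataclass
class FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Odds ratio convention: for table [[a, b], [c, d]], OR = (a*d)/(b*c);
    ``or_defined`` is False when a margin is zero (0/0 form), in which case
    ``odds_ratio`` is NaN but the p-value is still computed.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    or_defined: bool = True

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be 2x2 non-negative integers")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of [0,1]")


def filter_low_expression(mat: ExpressionMatrix, zero_fraction: float = 0.7) -> ExpressionMatrix:
    """Remove genes whose zero-value fraction strictly exceeds ``zero_fraction``
    and convert the remaining zeros to NaN (missing, pending imputation)."""
    if mat.layout != "fpkm":
        raise ValueError(f"expected fpkm layout, got {mat.layout}")
    values = mat.data
    frac_zero = (values == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction
    if not keep.any():
        raise ValueError("all genes removed by zero-fraction filter")
    kept = values.loc[keep].replace(0.0, np.nan)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_low_expression: removed %d genes (> %.0f%% zeros)", n_removed, 100 * zero_fraction)
    return ExpressionMatrix(kept, "fpkm")


def knn_impute(mat: ExpressionMatrix, k: int = 10, max_missing_fraction: float = 0.8) -> ExpressionMatrix:
    """Impute missing entries by the mean of the k nearest genes.

    Distances are Euclidean over mutually observed samples (NaN-aware,
    rescaled to the full sample count); for each missing entry only genes
    observed in that sample are candidate neighbours. Ties at the k-th
    distance are resolved by averaging the whole tie set, so the result is
    deterministic. A gene with no observed candidate neighbour falls back to
    its own gene mean (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = mat.data.to_numpy(dtype=float).copy()
    missing = np.isnan(data)
    if not missing.any():
        return ExpressionMatrix(mat.data.copy(), mat.layout)
    frac = missing.mean(axis=1)
    over = frac > max_missing_fraction
    if over.any():
        bad = mat.data.index[over].tolist()
        raise ValueError(f"genes exceed missing-fraction cap {max_missing_fraction}: {bad[:5]}")

    dist = nan_euclidean_distances(data, data)
    np.fill_diagonal(dist, np.inf)
    filled = data.copy()
    gene_means = np.nanmean(data, axis=1)
    for gi in np.flatnonzero(missing.any(axis=1)):
        for sj in np.flatnonzero(missing[gi]):
            candidates = np.flatnonzero(~missing[:, sj] & np.isfinite(dist[gi]))
            if candidates.size == 0:
                filled[gi, sj] = gene_means[gi]
                log.warning("knn_impute: no neighbours for gene %s sample %s; gene-mean fallback",
                            mat.data.index[gi], mat.data.columns[sj])
                continue
            d = dist[gi, candidates]
            kth = np.sort(d)[min(k, d.size) - 1]
            neighbours = candidates[d <= kth + 1e-12]
            filled[gi, sj] = data[neighbours, sj].mean()
    out = pd.DataFrame(filled, index=mat.data.index, columns=mat.data.columns)
    return ExpressionMatrix(out, mat.layout)


def log2_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """v -> log2(v + pseudocount); requires v >= 0 and v + pseudocount > 0."""
    values = mat.data.to_numpy(dtype=float)
    observed = values[np.isfinite(values)]
    if (observed < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    if (observed + pseudocount <= 0).any():
        raise ValueError("pseudocount too small: zero or negative argument to log2")
    out = pd.DataFrame(np.log2(values + pseudocount), index=mat.data.index, columns=mat.data.columns)
    return ExpressionMatrix(out, "log2")


def assign_latitude_group(clinical: CohortClinical, boundary_deg: float = 45.0) -> pd.Series:
    """Map each sample to 'low' (latitude <= boundary) or 'high' (> boundary).

    Samples without a latitude are excluded (logged). The boundary sample at
    exactly 45 deg is low-latitude, matching the 0-45 / 46-90 convention.
    """
    if "latitude" not in clinical.table.columns:
        raise ValueError("clinical table lacks a latitude column")
    lat = pd.to_numeric(clinical.table["latitude"], errors="coerce")
    missing = lat.isna()
    if missing.any():
        log.warning("assign_latitude_group: excluding %d samples without latitude", int(missing.sum()))
    groups = pd.Series(np.where(lat <= boundary_deg, "low", "high"), index=clinical.table.index, name="group")
    return groups[~missing]


def fisher_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test (hypergeometric enumeration: sum of tables
    with probability <= the observed one) plus the cross-product odds ratio."""
    t = np.asarray(table, dtype=int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b = t[0]
    c, d = t[1]
    row_margins = t.sum(axis=1)
    col_margins = t.sum(axis=0)
    if (row_margins == 0).any() or (col_margins == 0).any():
        return FisherResult(t, np.nan, float(p), or_defined=False)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        return FisherResult(t, float(odds), float(p), or_defined=np.isfinite(odds) or np.isinf(odds))
    return FisherResult(t, float(a * d) / float(b * c), float(p))


def clinical_contingency_test(
    clinical: CohortClinical,
    factor: str,
    groups: pd.Series,
    positive_level: str | None = None,
) -> dict[str, FisherResult]:
    """Fisher exact test of each level-vs-rest dichotomy of ``factor`` against
    the two latitude groups. Rows: factor level yes/no; columns: low/high."""
    if factor not in clinical.table.columns:
        raise ValueError(f"unknown clinical factor {factor!r}")
    aligned = clinical.table.loc[groups.index, factor]
    keep = aligned.notna()
    aligned, grp = aligned[keep], groups[keep]
    levels = [positive_level] if positive_level is not None else sorted(aligned.unique())
    results: dict[str, FisherResult] = {}
    for level in levels:
        is_level = aligned == level
        a = int(((grp == "low") & is_level).sum())
        b = int(((grp == "high") & is_level).sum())
        c = int(((grp == "low") & ~is_level).sum())
        d = int(((grp == "high") & ~is_level).sum())
        results[str(level)] = fisher_2x2([[a, b], [c, d]])
    return results
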