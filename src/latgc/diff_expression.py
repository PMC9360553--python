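"""Tumour-vs-normal differential expression on count matrices.

Counts are normalised by trimmed-mean-of-M-values (TMM) effective library
sizes, converted to log2 counts-per-million, and compared per gene by a
two-sided Wilcoxon rank-sum test with Benjamini-Hochberg adjustment. The
log2 fold change is the difference of group means on the log2-CPM scale.
This is a deliberately dependency-light count pipeline; the substitution is
recorded in every run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix
from .ssgsea_scoring import _ranksum_two_sided

__all__ = ["DeTable", "tmm_normalize", "log_cpm", "differential_expression", "de_overlap"]


@dataclass
class DeTable:
    """Per-gene DE results: log2FC, rank-sum stat, p, BH q, and call."""

    table: pd.DataFrame  # index gene; columns log2_fc, stat, p, q, call
    lfc_min: float
    q_max: float

    def called(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["call"] == direction])


def tmm_normalize(
    counts: ExpressionMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (multiply library sizes).

    The reference sample is the one whose upper-quartile (of library-size
    scaled counts) is closest to the mean upper-quartile. M (log ratio) and
    A (log abundance) values are computed over genes expressed in both the
    sample and the reference; the most extreme 30% of M and 5% of A are
    trimmed and the factor is 2**(precision-weighted mean M), using the
    asymptotic binomial variance weights. Factors are rescaled so their
    geometric mean is 1.
    """
    if counts.layout != "counts":
        raise ValueError("tmm_normalize expects a counts matrix")
    y = counts.values
    if np.isnan(y).any():
        raise ValueError("counts contain missing values")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"all-zero samples: {bad}")
    if y.shape[1] < 2:
        raise ValueError("need >= 2 samples")

    scaled = y / lib
    uq = np.array([np.quantile(scaled[:, j][scaled[:, j] > 0], 0.75) if (scaled[:, j] > 0).any() else 0.0
                   for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        if ok.sum() < 2:
            continue
        yj, yr = y[ok, j], y[ok, ref]
        pj, pr = yj / lib[j], yr / lib[ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        if np.ptp(m) == 0:
            factors[j] = 2.0 ** m[0]
            continue
        m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        w = (lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr)
        w = np.where(w > 0, 1.0 / w, 0.0)[keep]
        mk = m[keep]
        factors[j] = 2.0 ** (np.sum(w * mk) / np.sum(w)) if w.sum() > 0 else 2.0 ** mk.mean()

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(counts: ExpressionMatrix, factors: pd.Series | None = None, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    if factors is None:
        factors = tmm_normalize(counts)
    y = counts.values
    eff_lib = y.sum(axis=0) * factors.reindex(counts.sample_ids).to_numpy()
    cpm = (y + prior) / (eff_lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.gene_ids, columns=counts.sample_ids)


def differential_expression(
    counts: ExpressionMatrix,
    group_tumor,
    group_normal,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> DeTable:
    """Rank-sum DE between tumour and normal samples of a counts matrix."""
    tumor = [str(s) for s in group_tumor]
    normal = [str(s) for s in group_normal]
    if set(tumor) & set(normal):
        raise ValueError("tumour and normal groups overlap")
    missing = (set(tumor) | set(normal)) - set(counts.sample_ids)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)[:5]}")
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError("each group needs >= 3 samples")

    sub = ExpressionMatrix(counts.data[tumor + normal], "counts")
    lcpm = log_cpm(sub)
    xt = lcpm[tumor].to_numpy()
    xn = lcpm[normal].to_numpy()
    log2_fc = xt.mean(axis=1) - xn.mean(axis=1)
    stats_p = [_ranksum_two_sided(xt[i], xn[i]) for i in range(lcpm.shape[0])]
    stat = np.array([s for s, _ in stats_p])
    p = np.array([pv for _, pv in stats_p])
    q = multipletests(p, method="fdr_bh")[1]
    call = np.where((q <= q_max) & (log2_fc >= lfc_min), "up",
                    np.where((q <= q_max) & (log2_fc <= -lfc_min), "down", "none"))
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "stat": stat, "p": p, "q": q, "call": call},
        index=pd.Index(lcpm.index, name="gene"),
    )
    return DeTable(table, lfc_min, q_max)


def de_overlap(de_high: DeTable, de_low: DeTable) -> dict[str, dict[str, set[str]]]:
    """Shared/specific decomposition of up and down calls of two DE tables.

    Returns, per direction, the four-way partition {shared, high_specific,
    low_specific, neither} over the common gene universe.
    """
    if set(de_high.table.index) != set(de_low.table.index):
        raise ValueError("DE tables have different gene universes")
    universe = set(de_high.table.index)
    out: dict[str, dict[str, set[str]]] = {}
    for direction in ("up", "down"):
        h = de_high.called(direction)
        l = de_low.called(direction)
        out[direction] = {
            "shared": h & l,
            "high_specific": h - l,
            "low_specific": l - h,
            "neither": universe - (h | l),
        }
    return out
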