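"""Driver-gene regulation networks over activity-score matrices.

For each driver gene and each scored feature (metabolic pathway or immune
cell), samples are split into mutated vs wild-type and the feature's activity
scores are compared by a two-sided Wilcoxon rank-sum test. An edge is emitted
when p < 0.05; it is *positive regulation* when the mutated group's median
score is higher, *negative* otherwise. Edges are computed separately per
latitude group and assembled, with context "both" when a (driver, feature,
sign) pair appears in both groups. Raw p decides edges (as in the figure
convention it mirrors); BH q over each group's test family is reported too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationTable
from .mutation_profile import _mutated_matrix
from .ssgsea_scoring import ScoreMatrix, _ranksum_two_sided

__all__ = ["RegulationEdge", "build_regulation_network"]

log = logging.getLogger(__name__)


@dataclass
class RegulationEdge:
    driver: str
    feature: str
    context: str  # high | low | both
    sign: str  # positive | negative
    p_value: float
    q_value: float
    n_mutated: int
    n_wildtype: int


def _edges_for_group(
    drivers,
    flag: pd.DataFrame,
    scores: ScoreMatrix,
    sample_ids,
    context: str,
    p_threshold: float,
    min_group: int,
) -> list[RegulationEdge]:
    rows = []
    for driver in drivers:
        if driver not in flag.columns:
            log.info("driver %s has no mutations in %s group; skipped", driver, context)
            continue
        mutated = [s for s in sample_ids if flag.loc[s, driver]]
        wildtype = [s for s in sample_ids if not flag.loc[s, driver]]
        if len(mutated) < min_group or len(wildtype) < min_group:
            log.info("driver %s: group sizes %d/%d below min_group=%d in %s; skipped",
                     driver, len(mutated), len(wildtype), min_group, context)
            continue
        for feature in scores.feature_ids:
            x = scores.data.loc[feature, mutated].to_numpy(dtype=float)
            y = scores.data.loc[feature, wildtype].to_numpy(dtype=float)
            _, p = _ranksum_two_sided(x, y)
            rows.append((driver, feature, p, float(np.median(x)), float(np.median(y)), len(mutated), len(wildtype)))
    if not rows:
        return []
    pvals = np.array([r[2] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    edges = []
    for (driver, feature, p, med_m, med_w, nm, nw), q in zip(rows, qvals):
        if p < p_threshold and med_m != med_w:
            sign = "positive" if med_m > med_w else "negative"
            edges.append(RegulationEdge(driver, feature, context, sign, float(p), float(q), nm, nw))
    return edges


def build_regulation_network(
    drivers,
    mut: MutationTable,
    scores: ScoreMatrix,
    groups: pd.Series,
    p_threshold: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Assemble the driver-gene regulation edge list across latitude groups.

    ``groups`` maps sample_id -> {'high','low'}; only samples present in both
    the score matrix and the grouping participate. Returns a DataFrame with
    columns driver, feature, context, sign, p, q, n_mutated, n_wildtype.
    """
    drivers = list(drivers)
    samples = [s for s in scores.sample_ids if s in groups.index]
    if not samples:
        raise ValueError("no scored samples carry a group label")
    flag = _mutated_matrix(mut, genes=None, sample_ids=samples)
    for d in drivers:
        if d not in flag.columns:
            flag[d] = False

    all_edges: list[RegulationEdge] = []
    for context in ("high", "low"):
        ids = [s for s in samples if groups.loc[s] == context]
        if len(ids) < 2 * min_group:
            continue
        all_edges.extend(_edges_for_group(drivers, flag, scores, ids, context, p_threshold, min_group))

    seen: dict[tuple[str, str, str], RegulationEdge] = {}
    merged: list[RegulationEdge] = []
    for edge in all_edges:
        key = (edge.driver, edge.feature, edge.sign)
        if key in seen:
            prev = seen[key]
            prev.context = "both"
            prev.p_value = max(prev.p_value, edge.p_value)
            prev.q_value = max(prev.q_value, edge.q_value)
        else:
            seen[key] = edge
            merged.append(edge)
    return pd.DataFrame(
        [
            {
                "driver": e.driver,
                "feature": e.feature,
                "context": e.context,
                "sign": e.sign,
                "p": e.p_value,
                "q": e.q_value,
                "n_mutated": e.n_mutated,
                "n_wildtype": e.n_wildtype,
            }
            for e in merged
        ],
        columns=["driver", "feature", "context", "sign", "p", "q", "n_mutated", "n_wildtype"],
    )
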