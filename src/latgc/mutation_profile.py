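"""Mutation profiling: TMB, top mutated genes, pairwise co-occurrence /
mutual exclusivity, VAF-based subclone counting, and frequency-based driver
selection.

TMB is the nonsynonymous somatic mutation count per megabase of interrogated
territory (default 38 Mb, the common whole-exome capture convention).
Subclones are approximated by components of a 1-D Gaussian mixture over
variant allele frequencies, with the component count chosen by BIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .io_formats import SYNONYMOUS_CLASSES, MutationTable
from .preprocess import fisher_2x2

__all__ = [
    "TmbResult",
    "InteractionResult",
    "SubcloneResult",
    "remove_synonymous",
    "compute_tmb",
    "top_mutated_genes",
    "somatic_interactions",
    "infer_subclones",
    "select_driver_genes",
]

log = logging.getLogger(__name__)


@dataclass
class TmbResult:
    """Per-sample nonsynonymous count and mutations/Mb."""

    table: pd.DataFrame  # index sample_id, columns: n_mutations, tmb
    capture_size_mb: float


@dataclass
class InteractionResult:
    """Pairwise mutation co-occurrence/exclusivity over a gene panel."""

    table: pd.DataFrame  # gene_a, gene_b, both, only_a, only_b, neither, odds_ratio, p, q, label
    n_samples: int


@dataclass
class SubcloneResult:
    """Mixture-model subclone call for one sample."""

    sample_id: str
    vafs: np.ndarray
    n_subclones: int | None
    cluster_means: np.ndarray
    cluster_weights: np.ndarray
    bic_trace: dict[int, float] = field(default_factory=dict)
    evaluable: bool = True
    #: index into cluster_means of the highest-VAF (putatively clonal) cluster
    clonal_cluster: int | None = None


def remove_synonymous(mut: MutationTable, vocabulary: frozenset[str] = SYNONYMOUS_CLASSES) -> MutationTable:
    """Drop records whose variant class is synonymous; unknown classes are
    retained with a warning (dialects differ in their class vocabularies)."""
    from .io_formats import KNOWN_VARIANT_CLASSES

    classes = mut.records["variant_classification"]
    unknown = sorted(set(classes) - KNOWN_VARIANT_CLASSES)
    if unknown:
        warnings.warn(f"unknown variant classes retained as nonsynonymous: {unknown}", stacklevel=2)
    kept = mut.records.loc[~classes.isin(vocabulary)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all records removed as synonymous", stacklevel=2)
    return MutationTable(kept)


def compute_tmb(mut: MutationTable, capture_size_mb: float = 38.0, sample_ids=None) -> TmbResult:
    """Mutations per megabase per sample. ``sample_ids`` (optional) fixes the
    cohort so samples without records get TMB 0."""
    if capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be positive")
    counts = mut.records.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex(sample_ids, fill_value=0)
    table = pd.DataFrame({"n_mutations": counts.astype(int)})
    table["tmb"] = table["n_mutations"] / capture_size_mb
    table.index.name = "sample_id"
    return TmbResult(table, capture_size_mb)


def _mutated_matrix(mut: MutationTable, genes=None, sample_ids=None) -> pd.DataFrame:
    """Boolean samples x genes mutated-indicator matrix."""
    flag = mut.records.assign(mutated=True).pivot_table(
        index="sample_id", columns="gene", values="mutated", aggfunc="any", fill_value=False
    )
    if sample_ids is not None:
        flag = flag.reindex(sample_ids, fill_value=False)
    if genes is not None:
        flag = flag.reindex(columns=list(genes), fill_value=False)
    return flag.astype(bool)


def top_mutated_genes(mut: MutationTable, n: int = 25, sample_ids=None) -> pd.DataFrame:
    """Genes ordered by number of distinct mutated samples (ties broken
    alphabetically), with mutated-sample fractions."""
    flag = _mutated_matrix(mut, sample_ids=sample_ids)
    n_total = flag.shape[0]
    counts = flag.sum(axis=0).astype(int)
    table = (
        pd.DataFrame({"gene": counts.index, "n_mutated": counts.to_numpy()})
        .sort_values(["n_mutated", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    table["fraction"] = table["n_mutated"] / max(n_total, 1)
    return table.head(min(n, len(table)))


def somatic_interactions(
    mut: MutationTable,
    genes,
    sample_ids=None,
    p_threshold: float = 0.05,
) -> InteractionResult:
    """Pairwise Fisher exact tests of mutated/not indicators.

    OR > 1 with p < threshold labels the pair co-occurring; OR < 1 labels it
    exclusive. Raw p decides the label (mirroring the usual oncoplot
    convention); BH q is additionally reported.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    flag = _mutated_matrix(mut, genes=genes, sample_ids=sample_ids)
    n_samples = flag.shape[0]
    rows = []
    for ga, gb in combinations(genes, 2):
        a = flag[ga].to_numpy()
        b = flag[gb].to_numpy()
        both = int((a & b).sum())
        only_a = int((a & ~b).sum())
        only_b = int((~a & b).sum())
        neither = n_samples - both - only_a - only_b
        res = fisher_2x2([[both, only_a], [only_b, neither]])
        rows.append({
            "gene_a": ga,
            "gene_b": gb,
            "both": both,
            "only_a": only_a,
            "only_b": only_b,
            "neither": neither,
            "odds_ratio": res.odds_ratio,
            "p": res.p_value,
        })
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]

    def _label(row):
        orr = row["odds_ratio"]
        if row["p"] >= p_threshold or np.isnan(orr):
            return "none"
        if orr > 1:
            return "co-occurring"
        if orr < 1:
            return "exclusive"
        return "none"

    table["label"] = table.apply(_label, axis=1)
    return InteractionResult(table, n_samples)


def infer_subclones(
    mut: MutationTable,
    sample_id: str,
    k_max: int = 5,
    min_cluster_size: int = 3,
    min_vaf_count: int = 10,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> SubcloneResult:
    """Count subclones in one sample from its VAF distribution.

    Fits 1-D Gaussian mixtures for k = 1..k_max (EM with ``n_init`` random
    restarts), picks k by minimum BIC, then merges any cluster assigned fewer
    than ``min_cluster_size`` variants into its nearest-mean neighbour. The
    highest-mean surviving cluster is flagged as the putatively clonal one;
    the reported count includes it.

    Component variances are floored at the median binomial sampling variance
    v(1-v)/depth of the observed VAFs: read sampling makes VAF values
    granular, and without the floor a spurious component can collapse onto
    duplicated values with arbitrarily large likelihood gain.
    """
    rec = mut.records
    sel = rec.loc[(rec["sample_id"] == sample_id) & rec["ref_count"].notna() & rec["alt_count"].notna()]
    depths = (sel["ref_count"] + sel["alt_count"]).to_numpy(dtype=float)
    vafs = (sel["alt_count"].to_numpy(dtype=float) / depths) if len(depths) else np.array([])
    if len(vafs) < min_vaf_count:
        return SubcloneResult(sample_id, vafs, None, np.array([]), np.array([]), {}, evaluable=False)
    x = vafs.reshape(-1, 1)
    reg_covar = max(1e-6, float(np.median(vafs * (1 - vafs) / depths)))
    k_cap = min(k_max, len(np.unique(vafs)))
    bic_trace: dict[int, float] = {}
    best_k, best_bic, best_model = 1, np.inf, None
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k,
            n_init=n_init,
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
            reg_covar=reg_covar,
        )
        with warnings.catch_warnings():
            # duplicate VAF values (binomial granularity) make surplus
            # components near-degenerate; the BIC choice is unaffected
            warnings.simplefilter("ignore")
            gm.fit(x)
        bic = float(gm.bic(x))
        bic_trace[k] = bic
        if bic < best_bic:
            best_k, best_bic, best_model = k, bic, gm
    labels = best_model.predict(x)
    means = best_model.means_.ravel().copy()
    sizes = np.bincount(labels, minlength=best_k)

    # merge under-populated clusters into their nearest neighbour by mean
    keep = list(range(best_k))
    assignment = labels.copy()
    changed = True
    while changed and len(keep) > 1:
        changed = False
        sizes = np.array([(assignment == c).sum() for c in keep])
        small = [c for c, s in zip(keep, sizes) if s < min_cluster_size]
        if small:
            c = small[0]
            others = [o for o in keep if o != c]
            nearest = min(others, key=lambda o: abs(means[o] - means[c]))
            assignment[assignment == c] = nearest
            keep.remove(c)
            changed = True
    final_means = []
    final_weights = []
    for c in keep:
        mask = assignment == c
        if mask.any():
            final_means.append(float(np.clip(vafs[mask].mean(), 1e-6, 1 - 1e-6)))
            final_weights.append(mask.mean())
    order = np.argsort(final_means)[::-1]
    final_means = np.asarray(final_means)[order]
    final_weights = np.asarray(final_weights)[order]
    return SubcloneResult(
        sample_id,
        vafs,
        int(len(final_means)),
        final_means,
        final_weights,
        bic_trace,
        evaluable=True,
        clonal_cluster=0,
    )


def select_driver_genes(
    mut: MutationTable,
    min_fraction: float = 0.05,
    min_samples: int = 5,
    sample_ids=None,
) -> list[str]:
    """Frequency-based driver selection: genes mutated in at least
    max(min_fraction * n, min_samples) samples, ordered by frequency
    (ties alphabetical)."""
    flag = _mutated_matrix(mut, sample_ids=sample_ids)
    if flag.empty:
        return []
    n = flag.shape[0]
    threshold = max(min_fraction * n, min_samples)
    counts = flag.sum(axis=0)
    selected = counts[counts >= threshold]
    ordered = selected.to_frame("n").reset_index().sort_values(["n", "gene"], ascending=[False, True], kind="stable")
    return ordered["gene"].tolist()
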