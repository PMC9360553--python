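"""Construct and validate the immune-related prognostic model (IRPM).

Training follows the three-step recipe on the low-latitude samples: rank
immune cells by univariate Cox significance and keep the top 5; screen the
top 5% of genes by |mean Spearman correlation| with those cells' infiltration
scores, partitioned by sign; score every sample with the Welch t statistic
contrasting positive- vs negative-set expression. The low-latitude median
score is the risk cutoff; risk groups are compared by Kaplan-Meier/log-rank
in the training group and in the whole cohort.

Writes the signature (signed GMT), per-sample scores/risk, a summary JSON,
and a KM figure under results/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from latgc.io_formats import CohortClinical, ExpressionMatrix, read_clinical, read_expression_matrix, write_gmt
from latgc.irpm_model import rank_prognostic_cells, score_matrix, select_marker_genes, stratify_and_validate
from latgc.ssgsea_scoring import ScoreMatrix

OUT = Path(__file__).resolve().parent.parent / "results"


def _km_plot(curves, p, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(np.concatenate([[0], curve.times]), np.concatenate([[1.0], curve.survival]),
                where="post", label=f"{label} risk")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {p:.2e}", frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def main() -> None:
    log2_mat = read_expression_matrix(OUT / "expression_log2.tsv", "log2")
    clinical = read_clinical(OUT / "cohort" / "clinical.tsv")
    immune = ScoreMatrix(pd.read_csv(OUT / "immune_scores.tsv", sep="\t", index_col=0))
    groups = pd.read_csv(OUT / "latitude_groups.tsv", sep="\t", index_col=0)["group"]

    low_ids = groups.index[groups == "low"].tolist()
    train_clin = CohortClinical(clinical.table.loc[low_ids])
    train_scores = ScoreMatrix(immune.data[low_ids])
    cells, fits = rank_prognostic_cells(train_scores, train_clin, n_cells=5)
    print("prognostic immune cells (by Cox p, low-latitude training):")
    for c in cells:
        f = fits[c]
        print(f"  {c}: HR={f.hazard_ratio:.2f} [{f.ci_low:.2f}, {f.ci_high:.2f}], p={f.p:.2e}")

    train_expr = ExpressionMatrix(log2_mat.data[low_ids], "log2")
    sig = select_marker_genes(train_expr, ScoreMatrix(train_scores.data.loc[cells]), top_fraction=0.05)
    write_gmt(sig.to_collection(), OUT / "irpm_signature.gmt")
    print(f"signature: {len(sig.positive_genes)} positive / {len(sig.negative_genes)} negative genes")

    cutoff = float(np.median(score_matrix(train_expr, sig)))
    all_scores = score_matrix(log2_mat, sig)
    stratified, curves, p_all = stratify_and_validate(all_scores, clinical, cutoff=cutoff)
    pd.DataFrame({"irpm_score": stratified.scores, "risk": stratified.risk}).to_csv(
        OUT / "irpm_scores.tsv", sep="\t", index_label="sample_id")

    _, curves_low, p_low = stratify_and_validate(all_scores[low_ids], train_clin, cutoff=cutoff)
    figdir = OUT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    _km_plot(curves, p_all, figdir / "km_irpm_all.svg")
    _km_plot(curves_low, p_low, figdir / "km_irpm_low_latitude.svg")

    summary = {
        "selected_cells": cells,
        "cell_hazard_ratios": {c: fits[c].hazard_ratio for c in cells},
        "n_positive": len(sig.positive_genes),
        "n_negative": len(sig.negative_genes),
        "cutoff_training_median": cutoff,
        "logrank_p_low_latitude": p_low,
        "logrank_p_all_samples": p_all,
    }
    (OUT / "irpm_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cutoff (low-latitude median score): {cutoff:.3f}")
    print(f"risk stratification log-rank p: low-latitude {p_low:.2e}, whole cohort {p_all:.2e}")


if __name__ == "__main__":
    main()
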