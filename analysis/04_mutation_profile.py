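"""Mutation profiling per latitude group: tumour mutation burden, top mutated
genes, pairwise co-occurrence/exclusivity, per-sample subclone counts from
VAF mixtures, and frequency-based driver selection.

Reads results/cohort/mutations.maf.tsv; writes TMB, top-gene, interaction,
subclone, and driver tables under results/.
"""

import json
from pathlib import Path

import pandas as pd
from scipy import stats

from latgc.io_formats import read_clinical, read_maf
from latgc.mutation_profile import (
    compute_tmb,
    infer_subclones,
    remove_synonymous,
    select_driver_genes,
    somatic_interactions,
    top_mutated_genes,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    mutations = read_maf(OUT / "cohort" / "mutations.maf.tsv")
    clinical = read_clinical(OUT / "cohort" / "clinical.tsv")
    groups = pd.read_csv(OUT / "latitude_groups.tsv", sep="\t", index_col=0)["group"]

    nonsyn = remove_synonymous(mutations)
    print(f"records: {len(mutations)} total, {len(nonsyn)} after removing synonymous")

    tmb = compute_tmb(nonsyn, capture_size_mb=38.0, sample_ids=clinical.sample_ids)
    tmb.table.to_csv(OUT / "tmb.tsv", sep="\t")
    high = tmb.table.loc[groups.index[groups == "high"], "tmb"]
    low = tmb.table.loc[groups.index[groups == "low"], "tmb"]
    p = stats.mannwhitneyu(high, low, alternative="two-sided").pvalue
    print(f"TMB: median high={high.median():.3f}, low={low.median():.3f} mut/Mb (rank-sum p={p:.2e})")

    for ctx in ("high", "low"):
        ids = groups.index[groups == ctx].tolist()
        sub = nonsyn.records[nonsyn.records["sample_id"].isin(ids)]
        top = top_mutated_genes(type(nonsyn)(sub.reset_index(drop=True)), n=25, sample_ids=ids)
        top.to_csv(OUT / f"top_mutated_genes_{ctx}.tsv", sep="\t", index=False)

    top_all = top_mutated_genes(nonsyn, n=15, sample_ids=clinical.sample_ids)
    inter = somatic_interactions(nonsyn, top_all["gene"].tolist(), sample_ids=clinical.sample_ids)
    inter.table.to_csv(OUT / "somatic_interactions.tsv", sep="\t", index=False)
    labelled = inter.table[inter.table["label"] != "none"]
    print(f"interactions among top 15 genes: {len(labelled)}/{len(inter.table)} pairs labelled "
          f"({(labelled['label'] == 'co-occurring').sum()} co-occurring, "
          f"{(labelled['label'] == 'exclusive').sum()} exclusive)")

    rows = []
    for i, s in enumerate(clinical.sample_ids):
        res = infer_subclones(nonsyn, s, seed=SEED + i)
        rows.append({"sample_id": s, "n_subclones": res.n_subclones, "evaluable": res.evaluable})
    sub = pd.DataFrame(rows).set_index("sample_id")
    sub.to_csv(OUT / "subclones.tsv", sep="\t")
    ev = sub[sub["evaluable"]]
    sh = ev.loc[ev.index.isin(groups.index[groups == "high"]), "n_subclones"]
    sl = ev.loc[ev.index.isin(groups.index[groups == "low"]), "n_subclones"]
    p = stats.mannwhitneyu(sh, sl, alternative="two-sided").pvalue if len(sh) and len(sl) else float("nan")
    print(f"subclones ({len(ev)}/{len(sub)} evaluable): mean high={sh.mean():.2f}, low={sl.mean():.2f} "
          f"(rank-sum p={p:.3f})")

    drivers = {
        ctx: select_driver_genes(nonsyn, min_fraction=0.05, min_samples=5,
                                 sample_ids=groups.index[groups == ctx].tolist())
        for ctx in ("high", "low")
    }
    (OUT / "driver_genes.json").write_text(json.dumps(drivers, indent=2))
    print(f"drivers (>=5% of group and >=5 samples): high={len(drivers['high'])}, low={len(drivers['low'])}, "
          f"shared={len(set(drivers['high']) & set(drivers['low']))}")


if __name__ == "__main__":
    main()
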