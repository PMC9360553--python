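"""Differential expression between latitude groups on the counts matrix
(TMM-normalized log-CPM, rank-sum test, BH adjustment), plus a shared/specific
overlap decomposition computed on two half-cohort splits.

Reads results/cohort/; writes DE tables and the overlap summary under results/.
"""

import json
from pathlib import Path

import pandas as pd

from latgc.diff_expression import de_overlap, differential_expression
from latgc.io_formats import read_expression_matrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_expression_matrix(OUT / "cohort" / "expression_counts.tsv", "counts")
    groups = pd.read_csv(OUT / "latitude_groups.tsv", sep="\t", index_col=0)["group"]
    ids_high = groups.index[groups == "high"].tolist()
    ids_low = groups.index[groups == "low"].tolist()

    de = differential_expression(counts, ids_high, ids_low, lfc_min=1.0, q_max=0.05)
    de.table.to_csv(OUT / "de_high_vs_low.tsv", sep="\t")
    n_up, n_down = len(de.called("up")), len(de.called("down"))
    print(f"high vs low latitude: {n_up} genes up, {n_down} down (|log2FC|>=1, BH q<=0.05)")

    # shared/specific decomposition: repeat the contrast on two disjoint
    # half-cohorts; shared calls are the replication-stable core
    half_a = differential_expression(counts, ids_high[::2], ids_low[::2])
    half_b = differential_expression(counts, ids_high[1::2], ids_low[1::2])
    overlap = de_overlap(half_a, half_b)
    summary = {
        direction: {part: len(genes) for part, genes in parts.items()}
        for direction, parts in overlap.items()
    }
    (OUT / "de_overlap_summary.json").write_text(json.dumps(summary, indent=2))
    for direction in ("up", "down"):
        s = summary[direction]
        print(f"{direction}: shared={s['shared']} half-A-specific={s['high_specific']} "
              f"half-B-specific={s['low_specific']}")


if __name__ == "__main__":
    main()
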