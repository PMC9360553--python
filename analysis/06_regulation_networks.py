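"""Driver-gene regulation networks: for each driver, compare pathway and
immune-cell activity scores between mutated and wild-type samples (rank-sum,
per latitude group); signed edges at p < 0.05.

Reads driver lists and score matrices from results/; writes the two edge
lists under results/.
"""

import json
from pathlib import Path

import pandas as pd

from latgc.io_formats import read_maf
from latgc.mutation_profile import remove_synonymous
from latgc.regulation_network import build_regulation_network
from latgc.ssgsea_scoring import ScoreMatrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    nonsyn = remove_synonymous(read_maf(OUT / "cohort" / "mutations.maf.tsv"))
    groups = pd.read_csv(OUT / "latitude_groups.tsv", sep="\t", index_col=0)["group"]
    drivers_by_group = json.loads((OUT / "driver_genes.json").read_text())
    drivers = sorted(set(drivers_by_group["high"]) | set(drivers_by_group["low"]))

    for name, path in (("pathways", "pathway_scores.tsv"), ("immune", "immune_scores.tsv")):
        scores = ScoreMatrix(pd.read_csv(OUT / path, sep="\t", index_col=0))
        edges = build_regulation_network(drivers, nonsyn, scores, groups)
        edges.to_csv(OUT / f"network_{name}.tsv", sep="\t", index=False)
        if edges.empty:
            print(f"{name}: no edges at p < 0.05 from {len(drivers)} drivers")
            continue
        pos = int((edges["sign"] == "positive").sum())
        both = int((edges["context"] == "both").sum())
        print(f"{name}: {len(edges)} edges from {edges['driver'].nunique()} drivers "
              f"({pos} positive, {len(edges) - pos} negative, {both} in both latitudes)")


if __name__ == "__main__":
    main()
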