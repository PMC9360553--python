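"""End-to-end pipeline: one config, one seed, one artifact directory.

Stages run in dependency order (data -> preprocess -> ssgsea -> mutations ->
[de] -> survival -> networks -> irpm). Every run writes a manifest recording
the config snapshot, the seed, per-stage output hashes, and the declared
methodological substitutions (frequency-based driver selection; TMM +
rank-sum + BH differential expression). Runs are deterministic given
(config, seed): re-running into the same directory reproduces every stage
hash, and the manifest flags when a previous identical-config run was found.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diff_expression import differential_expression
from .io_formats import (
    read_clinical,
    read_expression_matrix,
    read_gmt,
    read_maf,
    write_gmt,
)
from .irpm_model import (
    rank_prognostic_cells,
    score_matrix,
    select_marker_genes,
    stratify_and_validate,
)
from .mutation_profile import (
    compute_tmb,
    infer_subclones,
    remove_synonymous,
    select_driver_genes,
    somatic_interactions,
    top_mutated_genes,
)
from .preprocess import assign_latitude_group, clinical_contingency_test, filter_low_expression, knn_impute, log2_transform
from .regulation_network import build_regulation_network
from .ssgsea_scoring import ScoreMatrix, compare_groups, estimate_scores, ssgsea_scores
from .survival_stats import logrank_test
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger(__name__)

SUBSTITUTIONS = [
    "driver selection: mutation-frequency rule in place of dN/dS-based driver calling",
    "differential expression: TMM-normalized log-CPM + rank-sum + BH in place of a negative-binomial GLM package",
]

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "synthetic": True,
    "cohort": {},  # CohortConfig overrides
    "paths": {},  # fpkm, counts, maf, clinical, genesets (used when synthetic false)
    "params": {
        "zero_fraction": 0.7,
        "knn_k": 10,
        "pseudocount": 1.0,
        "latitude_boundary": 45.0,
        "ssgsea_alpha": 0.25,
        "capture_size_mb": 38.0,
        "top_mutated_n": 25,
        "driver_min_fraction": 0.05,
        "driver_min_samples": 5,
        "irpm_n_cells": 5,
        "irpm_top_fraction": 0.05,
        "de_lfc_min": 1.0,
        "de_q_max": 0.05,
    },
    "stages": {"de": True, "subclones": True},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if key in ("params", "stages", "cohort", "paths") and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not cfg.get("synthetic"):
        paths = cfg.get("paths") or {}
        needed = {"fpkm", "counts", "maf", "clinical", "genesets"}
        missing = needed - set(k for k, v in paths.items() if v)
        if missing:
            raise ValueError(f"non-synthetic run requires input paths: {sorted(missing)}")
    p = cfg["params"]
    if not 0 <= p["zero_fraction"] < 1:
        raise ValueError("zero_fraction must be in [0,1)")
    if p["knn_k"] < 1:
        raise ValueError("knn_k must be >= 1")
    CohortConfig(**cfg.get("cohort", {})).validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written to
    ``outdir/manifest.json``)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge_config(dict(config))
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config["seed"])
    params = config["params"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    previous = None
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": _hash_obj(config),
        "substitutions": SUBSTITUTIONS,
        "stages": {},
    }
    manifest["reused_previous_run"] = bool(previous is not None and previous.get("config_hash") == manifest["config_hash"])

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {"outputs": {f.name: _sha256(f) for f in files}}

    # --- data ---------------------------------------------------------------
    if config.get("synthetic", True):
        cohort = generate_cohort(CohortConfig(**config.get("cohort", {})), seed=seed)
        write_cohort(cohort, outdir / "cohort")
        fpkm, counts = cohort.expression_fpkm, cohort.expression_counts
        mutations, clinical, genesets = cohort.mutations, cohort.clinical, cohort.genesets
    else:
        paths = config["paths"]
        fpkm = read_expression_matrix(paths["fpkm"], "fpkm")
        counts = read_expression_matrix(paths["counts"], "counts")
        mutations = read_maf(paths["maf"])
        clinical = read_clinical(paths["clinical"])
        genesets = read_gmt(paths["genesets"])
    record("data", sorted((outdir / "cohort").glob("*")) if config.get("synthetic", True) else [])

    # --- preprocess ----------------------------------------------------------
    filtered = filter_low_expression(fpkm, params["zero_fraction"])
    imputed = knn_impute(filtered, k=params["knn_k"])
    log2_mat = log2_transform(imputed, pseudocount=params["pseudocount"])
    groups = assign_latitude_group(clinical, params["latitude_boundary"])
    contingency = {}
    for factor in ("stage", "grade", "gender"):
        if factor in clinical.table.columns:
            for level, res in clinical_contingency_test(clinical, factor, groups).items():
                contingency[f"{factor}={level}"] = {
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                    "or_defined": res.or_defined,
                }
    pd.DataFrame(contingency).T.to_csv(outdir / "clinical_contingency.tsv", sep="\t")
    log2_mat.data.to_csv(outdir / "expression_log2.tsv", sep="\t", index_label="gene_id")
    groups.to_csv(outdir / "latitude_groups.tsv", sep="\t")
    record("preprocess", [outdir / "clinical_contingency.tsv", outdir / "expression_log2.tsv", outdir / "latitude_groups.tsv"])

    # --- ssGSEA scoring -------------------------------------------------------
    cell_names = [n for n in genesets.names() if n.startswith("immune_cell")]
    pathway_names = [n for n in genesets.names() if n.startswith("pathway")]
    immune_scores = ssgsea_scores(log2_mat, genesets.subset(cell_names), alpha=params["ssgsea_alpha"])
    pathway_scores = (
        ssgsea_scores(log2_mat, genesets.subset(pathway_names), alpha=params["ssgsea_alpha"])
        if pathway_names
        else None
    )
    immune_scores.data.to_csv(outdir / "immune_scores.tsv", sep="\t", index_label="cell")
    files = [outdir / "immune_scores.tsv"]
    if pathway_scores is not None:
        pathway_scores.data.to_csv(outdir / "pathway_scores.tsv", sep="\t", index_label="pathway")
        compare_groups(pathway_scores, groups).table.to_csv(outdir / "pathway_group_comparison.tsv", sep="\t")
        files += [outdir / "pathway_scores.tsv", outdir / "pathway_group_comparison.tsv"]
    compare_groups(immune_scores, groups).table.to_csv(outdir / "immune_group_comparison.tsv", sep="\t")
    files.append(outdir / "immune_group_comparison.tsv")
    if "stromal_signature" in genesets and "immune_signature" in genesets:
        est = estimate_scores(log2_mat, genesets["stromal_signature"], genesets["immune_signature"])
        est.data.to_csv(outdir / "estimate_scores.tsv", sep="\t", index_label="score")
        files.append(outdir / "estimate_scores.tsv")
    record("ssgsea", files)

    # --- mutation profile ------------------------------------------------------
    nonsyn = remove_synonymous(mutations)
    tmb = compute_tmb(nonsyn, params["capture_size_mb"], sample_ids=clinical.sample_ids)
    tmb.table.to_csv(outdir / "tmb.tsv", sep="\t")
    top = top_mutated_genes(nonsyn, n=params["top_mutated_n"], sample_ids=clinical.sample_ids)
    top.to_csv(outdir / "top_mutated_genes.tsv", sep="\t", index=False)
    interactions = somatic_interactions(nonsyn, top["gene"].tolist()[: min(len(top), 15)], sample_ids=clinical.sample_ids)
    interactions.table.to_csv(outdir / "somatic_interactions.tsv", sep="\t", index=False)
    files = [outdir / "tmb.tsv", outdir / "top_mutated_genes.tsv", outdir / "somatic_interactions.tsv"]
    if config["stages"].get("subclones", True):
        sub_rows = []
        for i, s in enumerate(clinical.sample_ids):
            res = infer_subclones(nonsyn, s, seed=seed + i)
            sub_rows.append({"sample_id": s, "n_subclones": res.n_subclones, "evaluable": res.evaluable,
                             "clonal_vaf": res.cluster_means[0] if res.evaluable and len(res.cluster_means) else np.nan})
        pd.DataFrame(sub_rows).to_csv(outdir / "subclones.tsv", sep="\t", index=False)
        files.append(outdir / "subclones.tsv")
    drivers = {
        ctx: select_driver_genes(
            nonsyn, params["driver_min_fraction"], params["driver_min_samples"],
            sample_ids=groups.index[groups == ctx].tolist(),
        )
        for ctx in ("high", "low")
    }
    (outdir / "driver_genes.json").write_text(json.dumps(drivers, indent=2))
    files.append(outdir / "driver_genes.json")
    record("mutations", files)

    # --- differential expression (optional stage) -------------------------------
    if config["stages"].get("de", True):
        ids_high = groups.index[groups == "high"].tolist()
        ids_low = groups.index[groups == "low"].tolist()
        de = differential_expression(counts, ids_high, ids_low, params["de_lfc_min"], params["de_q_max"])
        de.table.to_csv(outdir / "de_high_vs_low.tsv", sep="\t")
        record("de", [outdir / "de_high_vs_low.tsv"])
    else:
        manifest["stages"]["de"] = {"skipped": True}

    # --- survival ----------------------------------------------------------------
    surv = clinical.table.loc[groups.index]
    chi2, p = logrank_test(surv["os_time"], surv["os_event"], groups.to_numpy())
    surv_summary = {"logrank_chi2_latitude": chi2, "logrank_p_latitude": p}
    (outdir / "survival_latitude.json").write_text(json.dumps(surv_summary, indent=2))
    record("survival", [outdir / "survival_latitude.json"])

    # --- regulation networks --------------------------------------------------------
    driver_union = sorted(set(drivers["high"]) | set(drivers["low"]))
    net_files = []
    if driver_union and pathway_scores is not None:
        net = build_regulation_network(driver_union, nonsyn, pathway_scores, groups)
        net.to_csv(outdir / "network_pathways.tsv", sep="\t", index=False)
        net_files.append(outdir / "network_pathways.tsv")
    if driver_union:
        net = build_regulation_network(driver_union, nonsyn, immune_scores, groups)
        net.to_csv(outdir / "network_immune.tsv", sep="\t", index=False)
        net_files.append(outdir / "network_immune.tsv")
    record("networks", net_files)

    # --- IRPM ------------------------------------------------------------------------
    low_ids = groups.index[groups == "low"].tolist()
    train_clinical = type(clinical)(clinical.table.loc[low_ids])
    low_scores = ScoreMatrix(immune_scores.data[low_ids], immune_scores.normalized)
    cells, fits = rank_prognostic_cells(low_scores, train_clinical, n_cells=params["irpm_n_cells"])
    sig = select_marker_genes(
        _subset_samples(log2_mat, low_ids),
        ScoreMatrix(low_scores.data.loc[cells], low_scores.normalized),
        top_fraction=params["irpm_top_fraction"],
    )
    write_gmt(sig.to_collection(), outdir / "irpm_signature.gmt")
    train_scores = score_matrix(_subset_samples(log2_mat, low_ids), sig)
    cutoff = float(np.median(train_scores))
    all_scores = score_matrix(log2_mat, sig)
    stratified, _, logrank_p = stratify_and_validate(all_scores, clinical, cutoff=cutoff)
    out = pd.DataFrame({"irpm_score": stratified.scores, "risk": stratified.risk})
    out.to_csv(outdir / "irpm_scores.tsv", sep="\t", index_label="sample_id")
    irpm_summary = {
        "selected_cells": cells,
        "cell_hazard_ratios": {c: fits[c].hazard_ratio for c in cells},
        "n_positive": len(sig.positive_genes),
        "n_negative": len(sig.negative_genes),
        "cutoff": cutoff,
        "logrank_p": logrank_p,
    }
    (outdir / "irpm_summary.json").write_text(json.dumps(irpm_summary, indent=2))
    record("irpm", [outdir / "irpm_signature.gmt", outdir / "irpm_scores.tsv", outdir / "irpm_summary.json"])

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _subset_samples(mat, sample_ids):
    """Column-subset of an expression matrix, preserving layout."""
    from .io_formats import ExpressionMatrix

    return ExpressionMatrix(mat.data[list(sample_ids)], mat.layout)
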