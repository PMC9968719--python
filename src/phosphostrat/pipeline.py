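"""End-to-end orchestration: simulate -> QC -> stratify -> differential ->
KSEA -> DSS -> correlate, driven by a single configuration mapping.

The configuration is a plain nested dict (usually loaded from YAML); every
stage parameter has a default, so ``run_pipeline({}, out_dir)`` performs a
complete run on the default synthetic cohort.  Outputs are TSV/JSON files in
``out_dir`` plus a report dict; reruns with the same configuration are
identical because all randomness flows from the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import association, differential, drugresponse, ksea, qc, signature, simulate
from .errors import PhosphostratError
from .omics import write_matrix, write_metadata

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulation": {},
    "normalize": "median_center",
    "qc": {"enabled": True},
    "signature": {"k": None, "margin": None, "n_trees": 1000, "min_obs": 3,
                  "positive_karyotype": "KMT2Ar"},
    "differential": {"p_max": 0.05, "lfc_min": 0.7, "min_obs": 3},
    "ksea": {"min_substrates": 3},
    "dss": {"t": 10.0, "variant": "DSS2", "min_n": 3},
    "association": {"alpha": 0.05, "adjust": "none", "min_pairs": 5},
}


def resolve_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Merge a user configuration over the defaults (one level deep)."""
    resolved: dict[str, Any] = {}
    config = dict(config or {})
    for key, default in DEFAULTS.items():
        if isinstance(default, dict):
            merged = dict(default)
            merged.update(config.get(key) or {})
            resolved[key] = merged
        else:
            resolved[key] = config.get(key, default)
    unknown = set(config) - set(DEFAULTS)
    if unknown:
        raise PhosphostratError(f"unknown configuration section(s): {sorted(unknown)}")
    return resolved


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: Mapping[str, Any] | None, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in dependency order; see the module docstring.

    Returns the report dict (also written to ``report.json``).  Any stage
    failure is re-raised annotated with the stage name.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PhosphostratError as exc:
                raise PhosphostratError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- simulate -----------------------------------------------------------
    sim_cfg = simulate.SimulationConfig(**{**cfg["simulation"], "seed": seed})
    cohort = stage("simulate")(lambda: simulate.simulate_cohort(sim_cfg))
    screen = stage("simulate")(lambda: simulate.simulate_screen(sim_cfg, cohort.metadata))
    write_matrix(cohort.phospho, out / "phospho.tsv")
    write_metadata(cohort.metadata, out / "metadata.tsv")
    report["stages"]["simulate"] = {
        "n_samples": cohort.phospho.n_samples, "n_features": cohort.phospho.n_features,
        "n_drugs": sim_cfg.n_drugs,
    }

    # --- qc + normalize -----------------------------------------------------
    meta = cohort.metadata
    matrix = cohort.phospho
    if cfg["qc"]["enabled"]:
        qr = stage("qc")(lambda: qc.apply_qc(meta))
        meta = meta.loc[qr.retained]
        matrix = matrix.subset(samples=qr.retained)
        report["stages"]["qc"] = {"retained": len(qr.retained), "excluded": qr.counts}
    if cfg["normalize"] != "none":
        matrix = stage("normalize")(lambda: qc.normalize(matrix, cfg["normalize"]))

    # --- stratify -----------------------------------------------------------
    sig_cfg = cfg["signature"]
    strat = stage("signature")(lambda: signature.stratify_cohort(
        matrix, meta, positive_karyotype=sig_cfg["positive_karyotype"], seed=seed,
        k=sig_cfg["k"], margin=sig_cfg["margin"], n_trees=sig_cfg["n_trees"],
        min_obs=sig_cfg["min_obs"],
    ))
    strat.assignments.rename_axis("sample_id").to_csv(out / "assignments.tsv", sep="\t")
    pd.DataFrame({"feature_id": strat.signature.feature_ids,
                  "p": strat.signature.selection_p.to_numpy()}).to_csv(
        out / "signature.tsv", sep="\t", index=False)
    strat.importances.to_csv(out / "importances.tsv", sep="\t")
    report["stages"]["signature"] = {
        "k": strat.signature.k,
        "oob_accuracy": strat.classifier.oob_accuracy,
        "n_mllga": int((strat.assignments["label"] == signature.POSITIVE_LABEL).sum()),
    }
    truth = meta["group"].replace({"MLLGB": "No-MLL", "Normal": "No-MLL"})
    if set(truth.unique()) == {"MLLGA", "No-MLL"}:
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth.to_numpy(),
                                  strat.assignments.loc[truth.index, "label"].to_numpy())
        report["stages"]["signature"]["ari_vs_truth"] = float(ari)

    # --- differential (derived MLLGA vs rest) -------------------------------
    labels = strat.assignments["label"]
    group_a = [s for s in meta["sample_id"] if labels[s] == signature.POSITIVE_LABEL]
    group_b = [s for s in meta["sample_id"] if labels[s] != signature.POSITIVE_LABEL]
    diff_cfg = cfg["differential"]
    results = stage("differential")(lambda: differential.ttest_two_group(
        matrix, group_a, group_b, min_obs=diff_cfg["min_obs"]))
    differential.write_results(results, out / "differential.tsv")
    rule = differential.CountRule(p_max=diff_cfg["p_max"], lfc_min=diff_cfg["lfc_min"])
    report["stages"]["differential"] = {
        "groups": {"MLLGA": len(group_a), "rest": len(group_b)},
        **differential.count_significant(results, rule),
    }

    # --- ksea ---------------------------------------------------------------
    kin = stage("ksea")(lambda: ksea.ksea_contrast(
        results[results["tested"]], cohort.kinase_sets,
        min_substrates=cfg["ksea"]["min_substrates"]))
    kin.to_csv(out / "ksea_contrast.tsv", sep="\t", na_rep="")
    report["stages"]["ksea"] = {"n_kinases_tested": int(kin["z"].notna().sum())}

    # --- drug response ------------------------------------------------------
    dss_cfg = cfg["dss"]
    dss_table = stage("dss")(lambda: drugresponse.compute_dss(
        screen, t=dss_cfg["t"], variant=dss_cfg["variant"]))
    dss_table.to_csv(out / "dss.tsv", sep="\t", index=False)
    comparison = stage("dss")(lambda: drugresponse.compare_groups(
        dss_table, group_a, group_b, min_n=dss_cfg["min_n"]))
    comparison.to_csv(out / "dss_comparison.tsv", sep="\t", na_rep="")
    n_sig = int((comparison["fdr"] < 0.05).sum())
    report["stages"]["dss"] = {"n_drugs_significant_fdr05": n_sig}

    # --- association (DSS vs signature phosphopeptides) ---------------------
    assoc_cfg = cfg["association"]
    wide = drugresponse.dss_wide(dss_table)
    sig_matrix = matrix.subset(features=strat.signature.feature_ids)
    corr = stage("association")(lambda: association.correlate_matrix(
        wide, sig_matrix, alpha=assoc_cfg["alpha"], adjust=assoc_cfg["adjust"],
        min_pairs=assoc_cfg["min_pairs"]))
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False, na_rep="")
    report["stages"]["association"] = {
        "n_cells": int(len(corr)), "n_significant": int(corr["significant"].sum()),
    }

    with open(out / "resolved_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
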