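"""End-to-end orchestration: simulate -> QC -> per-set OPLS-DA -> replicated
selection -> enrichment -> network -> GWAS/GRS -> prediction models.

``run_pipeline`` executes the full analysis on either a synthetic study
(generated from the config) or user-supplied TSV inputs, writing every stage
artifact as plain TSV/JSON/GraphML plus a run manifest with the config
snapshot, per-stage seeds and SHA-256 checksums of every output.  Re-running
with the same config and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable, GenotypePanel
from .simulate import SimulationConfig, generate_study
from .design import baseline_table, standardized_mean_difference
from .preprocess import qc_filter, rsd_report, log_pareto
from .chemometrics import fit_pca, fit_oplsda, cross_validated_q2, permutation_test
from .selection import replicated_selection, superclass_enrichment, fold_change
from .network import build_network
from .genetics import snp_qc, gwas_logistic, select_grs_weights, compute_grs, \
    split_by_grs
from .prediction import fit_predict_logistic

log = logging.getLogger("metabrisk")

DEFAULT_CONFIG: dict = {
    "simulate": {},               # SimulationConfig overrides
    "qc": {"min_detect": 0.8, "rsd_threshold": 15.0},
    "oplsda": {"n_orth": 1, "folds": 7, "n_perm": 100,
               "perm_statistic": "r2y"},
    "selection": {"vip_threshold": 1.0, "network_top": 23},
    "network": {"shrinkage": "auto", "q_threshold": 0.05,
                "centrality_cutoff": 0.5},
    "genetics": {"grs_p_threshold": 5e-5},
    "prediction": {"n_panel": 5},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section: {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            cfg[section].update(values)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path | None = None,
                 out_dir: str | Path = "metabrisk_run", seed: int = 0,
                 ) -> dict:
    """Run the complete analysis and return the manifest dictionary.

    ``config`` is a config dict (see :data:`DEFAULT_CONFIG`), a path to a
    YAML/JSON file of section overrides, or None for defaults.  All
    randomness derives from ``seed`` through per-stage substreams.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for section, values in config.items():
            if section not in cfg:
                raise ValueError(f"unknown config section: {section!r}")
            cfg[section].update(values)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ["simulate", "permutation", "bootstrap"], root.spawn(3))}
    artifacts: list[Path] = []

    # ---------------------------------------------------------------- stage 1
    log.info("stage simulate: generating synthetic two-set study")
    sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": stage_seeds["simulate"]})
    set1, set2, panel, truth = generate_study(sim_cfg)
    for prefix, table in (("set1", set1), ("set2", set2)):
        artifacts += table.write(out, prefix).values()
    artifacts += panel.write(out, "panel").values()
    truth.write(out / "truth.json")
    artifacts.append(out / "truth.json")

    # ---------------------------------------------------------------- stage 2
    log.info("stage match/baseline: baseline characteristic tables")
    for prefix, table in (("set1", set1), ("set2", set2)):
        meta = table.samples.copy()
        base = baseline_table(meta, "group", continuous=["age"])
        base["age_smd"] = standardized_mean_difference(
            meta.loc[meta["group"] == "case", "age"],
            meta.loc[meta["group"] == "control", "age"])
        path = out / f"{prefix}_baseline.tsv"
        base.to_csv(path, sep="\t", index=False)
        artifacts.append(path)

    # ---------------------------------------------------------------- stage 3
    log.info("stage preprocess: QC filter + log/Pareto scaling")
    qc_cfg = cfg["qc"]
    f1 = qc_filter(set1, min_detect=qc_cfg["min_detect"])
    f2 = qc_filter(set2, min_detect=qc_cfg["min_detect"])
    shared = [f for f in f1.abundance.columns if f in set(f2.abundance.columns)]
    f1, f2 = f1.subset_features(shared), f2.subset_features(shared)
    rsd = rsd_report(set1.qc_replicates, threshold=qc_cfg["rsd_threshold"])
    rsd.to_frame().to_csv(out / "qc_rsd.tsv", sep="\t", index_label="feature_id")
    artifacts.append(out / "qc_rsd.tsv")
    X1, X2 = log_pareto(f1), log_pareto(f2)

    # ---------------------------------------------------------------- stage 4
    log.info("stage oplsda: per-set discriminant models")
    op_cfg = cfg["oplsda"]
    perm_rng = np.random.default_rng(stage_seeds["permutation"])
    models = {}
    model_summary = {}
    for name, (Xs, tab) in {"set1": (X1, f1), "set2": (X2, f2)}.items():
        y = tab.groups
        pca = fit_pca(Xs.to_numpy(), k=3)
        model = fit_oplsda(Xs.to_numpy(), y.to_numpy(), n_orth=op_cfg["n_orth"])
        q2 = cross_validated_q2(Xs.to_numpy(), y.to_numpy(),
                                folds=op_cfg["folds"], n_orth=op_cfg["n_orth"])
        perm = permutation_test(Xs.to_numpy(), y.to_numpy(),
                                n_perm=op_cfg["n_perm"],
                                statistic=op_cfg["perm_statistic"],
                                n_orth=op_cfg["n_orth"], folds=op_cfg["folds"],
                                seed=perm_rng)
        models[name] = model
        model_summary[name] = {
            "pca_explained_3pc": float(pca.explained_fraction.sum()),
            "r2x": model.r2x, "r2y": model.r2y, "q2": q2,
            "n_orth": model.n_orth,
            "permutation": {"statistic": perm.statistic, "label": perm.label,
                            "p_value": perm.p_value},
        }
        vips = pd.Series(model.vip, index=Xs.columns, name="vip")
        vips.to_csv(out / f"{name}_vip.tsv", sep="\t", index_label="feature_id")
        artifacts.append(out / f"{name}_vip.tsv")
    (out / "oplsda_summary.json").write_text(json.dumps(model_summary, indent=1))
    artifacts.append(out / "oplsda_summary.json")

    # ---------------------------------------------------------------- stage 5
    log.info("stage select: replicated VIP selection + enrichment")
    sel_cfg = cfg["selection"]
    vips1 = pd.Series(models["set1"].vip, index=X1.columns)
    vips2 = pd.Series(models["set2"].vip, index=X2.columns)
    sel = replicated_selection(
        vips1, vips2, threshold=sel_cfg["vip_threshold"],
        fold_change1=fold_change(f1.abundance, f1.groups),
        fold_change2=fold_change(f2.abundance, f2.groups))
    sel.to_csv(out / "selection.tsv", sep="\t", index_label="feature_id")
    artifacts.append(out / "selection.tsv")

    identified = f1.features.index[f1.features["identified"].astype(bool)]
    selected_identified = [f for f in sel.index[sel["selected"]]
                           if f in set(identified)]
    enrich = superclass_enrichment(selected_identified,
                                   f1.features["super_class"], identified)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    artifacts.append(out / "enrichment.tsv")

    # ---------------------------------------------------------------- stage 6
    log.info("stage network: Gaussian graphical model on selected metabolites")
    net_cfg = cfg["network"]
    min_vip = sel.loc[selected_identified, ["vip_set1", "vip_set2"]].min(axis=1)
    net_nodes = list(min_vip.sort_values(ascending=False)
                     .head(sel_cfg["network_top"]).index)
    combined_ab = pd.concat([f1.abundance[net_nodes], f2.abundance[net_nodes]])
    combined_groups = pd.concat([f1.groups, f2.groups])
    combined_scaled = log_pareto(combined_ab)
    net = build_network(combined_ab, combined_scaled, combined_groups,
                        shrinkage=net_cfg["shrinkage"],
                        q_threshold=net_cfg["q_threshold"],
                        centrality_cutoff=net_cfg["centrality_cutoff"])
    net.edge_list().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    net.node_table().to_csv(out / "network_nodes.tsv", sep="\t",
                            index_label="feature_id")
    net.write_graphml(out / "network.graphml")
    artifacts += [out / "network_edges.tsv", out / "network_nodes.tsv",
                  out / "network.graphml"]

    # ---------------------------------------------------------------- stage 7
    log.info("stage grs: SNP QC, GWAS and genetic risk score")
    gen_cfg = cfg["genetics"]
    clean = snp_qc(panel)
    gwas = gwas_logistic(clean)
    gwas.to_csv(out / "gwas.tsv", sep="\t")
    weights = select_grs_weights(gwas, clean,
                                 p_threshold=gen_cfg["grs_p_threshold"])
    weights.to_csv(out / "grs_weights.tsv", sep="\t")
    study_ids = [s for s in clean.genotypes.index
                 if clean.samples.loc[s, "cohort"] in ("set1", "set2")]
    grs_summary: dict = {"n_risk_snps": int(len(weights))}
    grs = None
    if len(weights) > 0:
        grs = compute_grs(clean.subset_samples(study_ids), weights)
        grs.rename("grs").to_csv(out / "grs.tsv", sep="\t",
                                 index_label="sample_id")
        artifacts.append(out / "grs.tsv")
        case_ids = [s for s in study_ids
                    if clean.samples.loc[s, "group"] == "case"]
        grs_groups = split_by_grs(grs.loc[case_ids])
        grs_summary.update({
            "grs_mean_low": float(grs.loc[grs_groups.index[grs_groups == "low"]].mean()),
            "grs_mean_high": float(grs.loc[grs_groups.index[grs_groups == "high"]].mean()),
        })
    artifacts += [out / "gwas.tsv", out / "grs_weights.tsv"]

    # ---------------------------------------------------------------- stage 8
    log.info("stage predict: ROC models on significant network metabolites")
    pred_cfg = cfg["prediction"]
    sig_nodes = [n for n in net_nodes
                 if bool(net.node_stats.loc[n, "significant"])]
    ranked = [n for n in min_vip.sort_values(ascending=False).index
              if n in sig_nodes]
    panel_feats = ranked[: pred_cfg["n_panel"]]
    pred_summary: dict = {"panel": panel_feats,
                          "n_significant_nodes": len(sig_nodes),
                          "n_network_nodes": len(net_nodes)}
    if len(panel_feats) >= 2:
        feats_log = np.log(combined_ab[panel_feats])
        res_panel = fit_predict_logistic(feats_log, combined_groups,
                                         seed=stage_seeds["bootstrap"])
        res_panel.roc_points.to_csv(out / "roc_panel.tsv", sep="\t", index=False)
        artifacts.append(out / "roc_panel.tsv")
        pred_summary["metabolites"] = res_panel.summary()
        res_red = fit_predict_logistic(feats_log.iloc[:, 1:], combined_groups,
                                       seed=stage_seeds["bootstrap"])
        pred_summary["metabolites_reduced"] = res_red.summary()
        if grs is not None:
            with_grs = feats_log.join(grs.rename("GRS"), how="inner")
            res_grs = fit_predict_logistic(with_grs,
                                           combined_groups.loc[with_grs.index],
                                           seed=stage_seeds["bootstrap"])
            res_grs.roc_points.to_csv(out / "roc_panel_grs.tsv", sep="\t",
                                      index=False)
            artifacts.append(out / "roc_panel_grs.tsv")
            pred_summary["metabolites_plus_grs"] = res_grs.summary()
    (out / "prediction_summary.json").write_text(
        json.dumps(pred_summary, indent=1))
    artifacts.append(out / "prediction_summary.json")

    # ---------------------------------------------------------------- manifest
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": {**cfg, "simulate": sim_cfg.to_dict()},
        "models": model_summary,
        "grs": grs_summary,
        "prediction": pred_summary,
        "checksums": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
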