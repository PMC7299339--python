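"""End-to-end orchestration of the network-inference pipeline from one YAML
configuration: expression filtering -> normalization -> differential
expression -> all-pairs correlation with permutation null -> stratified
distribution test -> (optional) miRNA x gene-set association matrix ->
network assembly -> topology summary with power-law fit and subnetworks ->
optional cohort and ΔΔCt stages.

Every intermediate table is written to the output directory, randomness is
driven by per-stage seeds split deterministically from the master seed, and
identical (config, seed) reproduce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_enrichment, correlation, diffexpr, gsea_engine
from . import io_formats, network_builder, synthetic_data
from .exceptions import ConfigurationError, ContractError

__all__ = ["load_config", "run_pipeline"]

logger = logging.getLogger("sproutnet")

_STAGES = ("synthetic", "de", "correlation", "gsea", "network", "cohort", "ddct")


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("run configuration must be a YAML mapping")
    return cfg


def _stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _load_inputs(cfg: dict, seed: int, out: Path):
    """Return (mir_counts, gene_counts, predictions, collection, truth_or_None)."""
    synth = cfg.get("synthetic")
    inputs = cfg.get("inputs")
    if (synth is None) == (inputs is None):
        raise ConfigurationError(
            "exactly one of 'synthetic:' or 'inputs:' must be configured")
    if synth is not None:
        params = dict(synth)
        params.setdefault("seed", _stage_seed(seed, "synthetic"))
        config = synthetic_data.SyntheticConfig(**params)
        mir_m, gene_m, preds, collection, truth = \
            synthetic_data.generate_experiment(config)
        io_formats.write_counts(mir_m, out / "mirna_counts.tsv")
        io_formats.write_counts(gene_m, out / "gene_counts.tsv")
        io_formats.write_predictions(preds, out / "predictions.tsv")
        io_formats.write_gmt(collection, out / "gene_sets.gmt")
        return mir_m, gene_m, preds, collection, truth
    cond = inputs.get("conditions")
    if not cond:
        raise ConfigurationError("inputs: requires a 'conditions' mapping")
    mir_m = io_formats.read_counts(inputs["mirna_counts"], cond, "mirna")
    gene_m = io_formats.read_counts(inputs["gene_counts"], cond, "gene")
    pred_cfg = cfg.get("predictions", {})
    preds = io_formats.read_predictions(
        inputs["predictions"],
        conserved_min_pct=pred_cfg.get("conserved_min_pct", 50.0),
        nonconserved_min_pct=pred_cfg.get("nonconserved_min_pct", 90.0))
    collection = io_formats.read_gmt(inputs["gene_sets"]) \
        if "gene_sets" in inputs else None
    return mir_m, gene_m, preds, collection, None


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the full pipeline; returns the summary dict written to
    ``summary.json`` in ``out_dir``."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(seed if seed is not None else cfg.get("seed", 0))

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"seed": master_seed}
    try:
        return _run(cfg, out, master_seed, summary)
    except (ConfigurationError, ContractError) as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path, master_seed: int, summary: dict) -> dict:
    logger.info("loading inputs")
    mir_raw, gene_raw, preds, collection, truth = _load_inputs(cfg, master_seed, out)

    # --- expression filter, normalization, DE --------------------------------
    de_cfg = cfg.get("de", {})
    min_raw = de_cfg.get("min_raw", 5.0)
    mir_f = diffexpr.filter_expressed(mir_raw, min_raw=min_raw)
    gene_f = diffexpr.filter_expressed(gene_raw, min_raw=min_raw)
    summary["n_mirna_expressed"] = len(mir_f.feature_ids)
    summary["n_gene_expressed"] = len(gene_f.feature_ids)
    logger.info("expressed: %d miRNAs, %d genes",
                len(mir_f.feature_ids), len(gene_f.feature_ids))

    mir_n = diffexpr.normalize_counts(mir_f)
    gene_n = diffexpr.normalize_counts(gene_f)
    lfc_thr = de_cfg.get("lfc_threshold", 0.5)
    fdr_cut = de_cfg.get("fdr_cutoff", 0.05)
    if "external_gene_table" in de_cfg:
        de_gene = diffexpr.ingest_de_table(de_cfg["external_gene_table"],
                                           lfc_thr, fdr_cut)
    else:
        de_gene = diffexpr.differential_expression(gene_n, lfc_thr, fdr_cut)
    if "external_mirna_table" in de_cfg:
        de_mir = diffexpr.ingest_de_table(de_cfg["external_mirna_table"],
                                          lfc_thr, fdr_cut)
    else:
        de_mir = diffexpr.differential_expression(mir_n, lfc_thr, fdr_cut)
    diffexpr.write_de_table(de_mir, out / "de_mirna.tsv")
    diffexpr.write_de_table(de_gene, out / "de_gene.tsv")
    summary["n_mirna_de"] = int((de_mir["direction"] != "ns").sum())
    summary["n_gene_de"] = int((de_gene["direction"] != "ns").sum())

    # --- correlation ----------------------------------------------------------
    corr_cfg = cfg.get("correlation", {})
    mir_log = mir_n.to_log2()
    gene_log = gene_n.to_log2()
    ct = correlation.pairwise_correlation(mir_log, gene_log)
    n_perm = corr_cfg.get("n_perm", 1000)
    null = correlation.permutation_null(
        mir_log, gene_log, n_perm=n_perm,
        seed=corr_cfg.get("seed", _stage_seed(master_seed, "correlation")))
    ct = correlation.attach_empirical_p(ct, null)
    ct.drop(columns=["undefined"]).to_csv(out / "correlations.tsv",
                                          sep="\t", index=False)
    summary["correlation"] = {
        "n_pairs": int(len(ct)),
        "n_samples": ct.attrs["n_samples"],
        "null_mean_r": null.mean,
        "null_n_pooled": null.n_pooled,
        "n_permutations": null.n_permutations,
    }
    strata = {}
    for stratum in ("conserved", "nonconserved"):
        if (preds["conservation"] == stratum).any():
            rec = correlation.stratified_distribution_test(ct, preds, stratum)
            strata[stratum] = {k: rec[k] for k in
                               ("n_stratum", "d", "p_two_sided",
                                "d_negative_shift", "p_negative_shift",
                                "mean_r_all", "mean_r_stratum")}
    summary["stratified_test"] = strata
    with open(out / "null_summary.json", "w") as fh:
        json.dump(_round_floats({
            "n_permutations": null.n_permutations,
            "n_pooled": null.n_pooled,
            "mean_r": null.mean,
            "sd_r": float(null.samples.std()),
        }), fh, indent=2, sort_keys=True)

    # --- association matrix ---------------------------------------------------
    gsea_cfg = cfg.get("gsea", {})
    if collection is not None and gsea_cfg.get("association_matrix", True):
        am = gsea_engine.mirna_association_matrix(
            mir_log, gene_log, collection,
            n_perm=gsea_cfg.get("n_perm", 1000),
            seed=gsea_cfg.get("seed", _stage_seed(master_seed, "gsea")),
            fdr_threshold=gsea_cfg.get("fdr_threshold", 0.05),
            n_clusters=gsea_cfg.get("n_clusters", 5))
        am.nes.to_csv(out / "association_nes.tsv", sep="\t")
        am.fdr_q.to_csv(out / "association_fdr.tsv", sep="\t")
        summary["association_matrix"] = {
            "shape": list(am.nes.shape),
            "n_significant_cells": int((am.fdr_q < am.fdr_threshold).sum().sum()),
            "core_enrichment_sizes": {str(c): len(g)
                                      for c, g in am.core_enrichment.items()},
        }

    # --- network --------------------------------------------------------------
    net_cfg = cfg.get("network", {})
    net = network_builder.build_network(
        de_mir, de_gene, ct, preds,
        p_threshold=net_cfg.get("p_threshold", 0.05),
        conservation_mode=net_cfg.get("conservation_mode", "conserved_only"),
        p_column=net_cfg.get("p_column", "p_analytic"),
        require_de=net_cfg.get("require_de", True))
    io_formats.write_network(net, out / "network.graphml", "graphml")
    io_formats.write_network(net, out / "network_edges.tsv", "edge_tsv")
    net_summary = network_builder.network_summary(
        net, n_hubs=net_cfg.get("n_hubs", 10))
    net_summary.pop("components")
    summary["network"] = net_summary

    out_degrees = sorted(net_summary["mirna_out_degrees"].values())
    if len(out_degrees) >= 10 and len(set(out_degrees)) > 1:
        fit = network_builder.fit_power_law(
            out_degrees,
            n_bootstrap=net_cfg.get("powerlaw_bootstrap", 200),
            seed=_stage_seed(master_seed, "powerlaw"))
        summary["power_law"] = {
            "alpha": fit.alpha, "xmin": fit.xmin, "ks_d": fit.ks_d,
            "p_gof": fit.p_gof, "n_tail": fit.n_tail,
            "plausible": (fit.p_gof is not None and fit.p_gof > 0.1),
        }

    if truth is not None:
        edges = set()
        for u, v in net.edges():
            if net.nodes[u].get("type") == "mirna":
                edges.add((u, v))
            else:
                edges.add((v, u))
        planted = truth.planted_edges
        tp = len(edges & planted)
        summary["recovery"] = {
            "n_planted": len(planted),
            "n_recovered_edges": len(edges),
            "true_positives": tp,
            "precision": tp / len(edges) if edges else float("nan"),
            "recall": tp / len(planted) if planted else float("nan"),
        }

    # --- optional cohort stage ------------------------------------------------
    cohort_cfg = cfg.get("cohort")
    if cohort_cfg is not None:
        summary["cohort"] = _run_cohort_stage(cohort_cfg, truth, master_seed, out)

    # --- optional ΔΔCt stage --------------------------------------------------
    ddct_cfg = cfg.get("ddct")
    if ddct_cfg is not None:
        summary["ddct"] = _run_ddct_stage(ddct_cfg, master_seed, out)

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "seed": master_seed,
        "stage_seeds": {s: _stage_seed(master_seed, s) for s in _STAGES},
        "config": _round_floats(cfg),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %d edges", summary["network"]["n_edges"])
    return summary


def _run_cohort_stage(cohort_cfg: dict, truth, master_seed: int, out: Path) -> dict:
    synth = cohort_cfg.get("synthetic", {})
    module = None
    if truth is not None and truth.module_sets.get("planted_up_module"):
        module = truth.module_sets["planted_up_module"]
    module = synth.get("module_genes", module)
    if module is None:
        raise ConfigurationError("cohort stage needs module genes")
    signature = synth.get("signature_genes",
                          [f"EC{i+1:03d}" for i in range(35)])
    cohort, signature, labels, ctruth = synthetic_data.generate_cohort(
        n_samples=synth.get("n_samples", 100),
        signature_genes=signature,
        module_genes=module,
        beta=synth.get("beta", 0.5),
        noise_sd=synth.get("noise_sd", 1.0),
        responder_effect=synth.get("responder_effect", 0.8),
        seed=synth.get("seed", _stage_seed(master_seed, "cohort")))
    scores = cohort_enrichment.endothelial_score(cohort, signature)
    scores.to_csv(out / "endothelial_scores.tsv", sep="\t")
    r, p = cohort_enrichment.module_score_correlation(cohort, module, scores)
    return {
        "n_samples": cohort.n_samples,
        "module_score_r": r,
        "module_score_p": p,
        "latent_score_r": float(np.corrcoef(
            scores.reindex(ctruth.latent_score.index),
            ctruth.latent_score)[0, 1]),
    }


def _run_ddct_stage(ddct_cfg: dict, master_seed: int, out: Path) -> dict:
    synth = ddct_cfg.get("synthetic", {})
    n_mirna = synth.get("n_mirna", 40)
    shifted = synth.get("shifted_ids",
                        [f"miR-{i+1:03d}" for i in range(5)])
    table, cond, truth = synthetic_data.generate_ct_card(
        n_mirna=n_mirna, shifted_ids=shifted,
        shift_ddct=synth.get("shift_ddct", 3.0),
        noise_sd=synth.get("noise_sd", 0.3),
        seed=synth.get("seed", _stage_seed(master_seed, "ddct")))
    result = cohort_enrichment.ddct_analysis(
        table, cond, reference_assays=truth.reference_assays,
        threshold=ddct_cfg.get("threshold", 2.0))
    result.to_csv(out / "ddct.tsv", sep="\t", index_label="assay")
    recovered = set(result.index[result["passes_threshold"]])
    return {
        "n_assays": int(len(result)),
        "n_altered": int(result["passes_threshold"].sum()),
        "recovery": len(recovered & set(truth.shifted_assays)) / max(len(truth.shifted_assays), 1),
    }
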