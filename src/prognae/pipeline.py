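"""End-to-end orchestration: preprocess -> integrate -> select latent ->
cluster -> classify -> transfer -> differential expression -> enrichment.

A run is driven by a config mapping (usually YAML) that either names
input files or contains a ``simulate`` block.  One global seed fans out
to per-stage seeds by stable hashing of the stage name, so any stage can
be re-run in isolation; a JSON manifest records every parameter, derived
seed, and artifact SHA-256, which makes a run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autoencoder as ae
from . import classify, downstream, io, preprocess, subtype
from .errors import ValidationError
from .synthetic import (SimulationConfig, make_gene_models, segments_from_cna_matrix,
                        simulate_cohorts)
from .types import OmicsMatrix, SurvivalTable

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "integrate", "cluster", "classify",
          "transfer", "de")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "autoencoder": {"profile": "adequate"},
    "k_range": [2, 6],
    "kmeans_restarts": 50,
    "classify": {
        "expression_algorithms": ["svm", "naive_bayes", "logistic", "xgboost"],
        "cna_algorithms": ["svm", "naive_bayes", "logistic", "xgboost"],
        "folds": 10,
        "repeats": 10,
        "start_size": 100,
    },
    "de_fdr": 0.05,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = _merge(DEFAULT_CONFIG, user)
    has_inputs = "inputs" in cfg or "simulate" in cfg
    if not has_inputs:
        raise ValidationError("config must contain an 'inputs' or 'simulate' block")
    if "inputs" in cfg:
        required = ["expression", "seg", "genes_bed", "clinical"]
        missing = [k for k in required if k not in cfg["inputs"]]
        if missing:
            raise ValidationError(f"config inputs block missing: {missing}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _ae_config(cfg: dict, seed: int) -> ae.AutoencoderConfig:
    block = dict(cfg.get("autoencoder", {}))
    profile = block.pop("profile", "adequate")
    maker = ae.adequate_profile if profile == "adequate" else ae.default_profile
    block.setdefault("seed", seed)
    if "hidden_sizes" in block:
        block["hidden_sizes"] = tuple(block["hidden_sizes"])
    return maker(**block)


def run_pipeline(config, outdir) -> dict:
    """Execute the full flow and return the run manifest (also written to
    ``outdir/manifest.json``).  Any stage failure aborts with the stage
    name in the exception message."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": _jsonable(cfg), "stages": {}, "artifacts": {}}

    stage = "inputs"
    try:
        if "simulate" in cfg:
            stage = "simulate"
            sim_seed = stage_seed(seed, "simulate")
            sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": sim_seed})
            study = simulate_cohorts(sim_cfg)
            manifest["stages"]["simulate"] = {
                "seed": sim_seed, "config": _jsonable(dataclasses.asdict(sim_cfg))}
            expr, train_cna = study.train_expr, study.train_cna
            internal_cna, external_expr = study.internal_cna, study.external_expr
            clinical = study.clinical
            genes = make_gene_models(train_cna.feature_ids)
            _write_cohorts(outdir / "inputs", study, genes)
        else:
            inputs = cfg["inputs"]
            expr = io.read_expression_matrix(inputs["expression"])
            genes = io.read_gene_bed(inputs["genes_bed"])
            segs = io.read_seg(inputs["seg"], scale=inputs.get("seg_scale", "log2ratio"))
            clinical = io.read_clinical(inputs["clinical"])
            train_cna = preprocess.cna_gene_matrix(segs, genes, expr.sample_ids)
            internal_cna = external_expr = None
            study = None

        stage = "preprocess"
        alpha = float(cfg["alpha"])
        expr_z = preprocess.zscore_by_gene(expr)
        expr_screened, expr_report = preprocess.cox_screen_features(expr_z, clinical, alpha)
        cna_screened, cna_report = preprocess.cox_screen_features(train_cna, clinical, alpha)
        stacked = preprocess.stack_omics(expr_screened, cna_screened)
        manifest["stages"]["preprocess"] = {
            "n_expression_screened": expr_screened.n_features,
            "n_cna_screened": cna_screened.n_features,
            "n_stacked": stacked.n_features,
        }
        io.write_expression_matrix(stacked, outdir / "stacked.tsv")
        expr_report.to_csv(outdir / "screen_expression.tsv", sep="\t")
        cna_report.to_csv(outdir / "screen_cna.tsv", sep="\t")

        stage = "integrate"
        ae_seed = stage_seed(seed, "integrate")
        ae_cfg = _ae_config(cfg, ae_seed)
        model = ae.train(stacked, ae_cfg)
        latent = ae.encode(model, stacked)
        latent = ae.select_prognostic_latent(latent, clinical, alpha)
        manifest["stages"]["integrate"] = {
            "seed": ae_seed,
            "final_epoch_loss": model.training_log[-1],
            "n_latent_selected": int(latent.selected.sum()),
        }
        pd.DataFrame(latent.values, index=latent.sample_ids,
                     columns=latent.feature_names).to_csv(
            outdir / "latent.tsv", sep="\t", index_label="sample_id")

        stage = "cluster"
        cl_seed = stage_seed(seed, "cluster")
        k_lo, k_hi = cfg["k_range"]
        chosen_k, k_table = subtype.select_k(
            latent, clinical, range(int(k_lo), int(k_hi) + 1),
            seed=cl_seed, n_restarts=int(cfg["kmeans_restarts"]))
        assign = subtype.kmeans_cluster(latent, chosen_k, seed=cl_seed,
                                        n_restarts=int(cfg["kmeans_restarts"]))
        if chosen_k == 2:
            assign = subtype.orient_labels(assign, clinical)
        k_table.to_csv(outdir / "k_selection.tsv", sep="\t")
        io.write_labels(assign.sample_ids, assign.labels, outdir / "labels.tsv")
        manifest["stages"]["cluster"] = {
            "seed": cl_seed, "chosen_k": int(chosen_k),
            "logrank_p_efs": subtype.subtype_logrank(assign, clinical, "efs").p_value
            if chosen_k == 2 else None,
        }

        stage = "classify"
        cls_seed = stage_seed(seed, "classify")
        ccfg = cfg["classify"]
        models = {}
        # each layer is z-scored for supervised modelling so transfer is
        # robust to platform/scale differences between cohorts
        cna_z = preprocess.zscore_by_gene(train_cna)
        layers = {"expression": (expr_z, ccfg["expression_algorithms"]),
                  "cna": (cna_z, ccfg["cna_algorithms"])}
        for kind, (matrix, algorithms) in layers.items():
            candidates = [
                classify.fit_candidate(matrix, assign, algo,
                                       folds=int(ccfg["folds"]),
                                       repeats=int(ccfg["repeats"]),
                                       seed=cls_seed,
                                       start_size=int(ccfg["start_size"]))
                for algo in algorithms]
            best = classify.select_best_model(candidates)
            models[kind] = best
            best.save(outdir / f"model_{kind}.joblib")
            manifest["stages"].setdefault("classify", {})[kind] = {
                "seed": cls_seed, "algorithm": best.algorithm,
                "n_features": len(best.selected_features),
                "cv_mean_accuracy": best.cv_mean_accuracy,
                "cv_mean_auc": best.cv_mean_auc,
                "training_auc": best.training_auc,
            }

        stage = "transfer"
        transfers = {}
        if internal_cna is not None:
            transfers["internal_cna"] = (
                models["cna"], preprocess.zscore_by_gene(internal_cna))
        if external_expr is not None:
            transfers["external_expr"] = (
                models["expression"], preprocess.zscore_by_gene(external_expr))
        de_tables = {}
        for name, (model_t, cohort) in transfers.items():
            pred, logrank, cindex = classify.transfer_labels(model_t, cohort, clinical)
            io.write_labels(pred.sample_ids, pred.labels, outdir / f"labels_{name}.tsv")
            manifest["stages"].setdefault("transfer", {})[name] = {
                "n_g1": int((pred.labels == "G1").sum()),
                "n_g2": int((pred.labels == "G2").sum()),
                "logrank_p_efs": logrank.get("efs").p_value if "efs" in logrank else None,
                "c_index_efs": cindex.get("efs").c_index if "efs" in cindex else None,
            }
            if name == "external_expr":
                de_tables["external"] = (cohort, pred)

        stage = "de"
        de_train = downstream.ttest_de(expr_z, assign, fdr_cut=float(cfg["de_fdr"]))
        de_train.to_csv(outdir / "de_train.tsv", sep="\t")
        manifest["stages"]["de"] = {
            "n_significant_train": int(de_train["significant"].sum())}
        if "external" in de_tables:
            cohort, pred = de_tables["external"]
            if len(set(pred.labels)) == 2:
                de_valid = downstream.ttest_de(cohort, pred, fdr_cut=float(cfg["de_fdr"]))
                de_valid.to_csv(outdir / "de_external.tsv", sep="\t")
                up, down = downstream.intersect_de(de_train, de_valid,
                                                   fdr_cut=float(cfg["de_fdr"]))
                (outdir / "de_up.txt").write_text("\n".join(sorted(up)) + "\n")
                (outdir / "de_down.txt").write_text("\n".join(sorted(down)) + "\n")
                manifest["stages"]["de"].update(
                    {"n_up_consistent": len(up), "n_down_consistent": len(down)})
                gmt_path = cfg.get("gmt")
                if gmt_path:
                    collection = io.read_gmt(gmt_path)
                    universe = set(de_train.index)
                    hits = (up | down) or None
                    if hits:
                        enr = downstream.ora_collection(collection, hits, universe)
                        enr.to_csv(outdir / "enrichment.tsv", sep="\t")
                        manifest["stages"]["de"]["n_enriched_fdr05"] = int(
                            (enr["fdr"] < 0.05).sum())
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def analyze_study(study, seed: int = 0, alpha: float = 0.05,
                  ae_profile: str = "adequate",
                  k_range=range(2, 7), kmeans_restarts: int = 50,
                  cv_repeats: int = 2, start_size: int = 50) -> dict:
    """Run the discovery-and-transfer flow on an in-memory
    :class:`~prognae.synthetic.SimulatedStudy` and score it against the
    planted truth.

    This is the programmatic counterpart of :func:`run_pipeline` used for
    replicate experiments: no files are written, and because the planted
    labels are known it also reports adjusted Rand index and per-cohort
    transfer accuracy.  The transfer models are the expression SVM and
    the copy-number gradient-boosted trees.
    """
    from sklearn.metrics import adjusted_rand_score

    clinical = study.clinical
    expr_z = preprocess.zscore_by_gene(study.train_expr)
    expr_scr, _ = preprocess.cox_screen_features(expr_z, clinical, alpha)
    cna_scr, _ = preprocess.cox_screen_features(study.train_cna, clinical, alpha)
    stacked = preprocess.stack_omics(expr_scr, cna_scr)

    maker = ae.adequate_profile if ae_profile == "adequate" else ae.default_profile
    model = ae.train(stacked, maker(seed=stage_seed(seed, "integrate")))
    latent = ae.select_prognostic_latent(ae.encode(model, stacked), clinical, alpha)

    cl_seed = stage_seed(seed, "cluster")
    chosen_k, k_table = subtype.select_k(latent, clinical, k_range,
                                         seed=cl_seed, n_restarts=kmeans_restarts)
    assign = subtype.kmeans_cluster(latent, 2, seed=cl_seed,
                                    n_restarts=kmeans_restarts)
    assign = subtype.orient_labels(assign, clinical)
    truth_train = study.labels_for(assign.sample_ids)
    result = {
        "chosen_k": int(chosen_k),
        "k_table": k_table,
        "n_latent_selected": int(latent.selected.sum()),
        "ari": float(adjusted_rand_score(truth_train, assign.labels)),
        "train_accuracy": float((assign.labels == truth_train).mean()),
        "logrank_p_efs": subtype.subtype_logrank(assign, clinical, "efs").p_value,
        "logrank_p_os": subtype.subtype_logrank(assign, clinical, "os").p_value,
    }
    risk = assign.binary().astype(float)
    for endpoint in ("efs", "os"):
        time, event = clinical.endpoint(endpoint, assign.sample_ids)
        from .survival import concordance_index
        result[f"c_index_{endpoint}"] = concordance_index(risk, time, event).c_index

    cls_seed = stage_seed(seed, "classify")
    expr_model = classify.fit_candidate(expr_z, assign, "svm", repeats=cv_repeats,
                                        seed=cls_seed, start_size=start_size)
    cna_model = classify.fit_candidate(preprocess.zscore_by_gene(study.train_cna),
                                       assign, "xgboost", repeats=cv_repeats,
                                       seed=cls_seed)
    transfers = {
        "external_expr": (expr_model, preprocess.zscore_by_gene(study.external_expr)),
        "internal_cna": (cna_model, preprocess.zscore_by_gene(study.internal_cna)),
    }
    for name, (mdl, cohort) in transfers.items():
        pred, logrank, _ = classify.transfer_labels(mdl, cohort, clinical)
        truth = study.labels_for(pred.sample_ids)
        result[name] = {
            "accuracy": float((pred.labels == truth).mean()),
            "logrank_p_efs": logrank["efs"].p_value if "efs" in logrank else 1.0,
        }
    return result


def _write_cohorts(indir: Path, study, genes) -> None:
    """Write simulated cohorts in the exact formats the readers consume."""
    indir.mkdir(parents=True, exist_ok=True)
    io.write_expression_matrix(study.train_expr, indir / "train_expression.tsv")
    io.write_expression_matrix(study.external_expr, indir / "external_expression.tsv")
    io.write_seg(segments_from_cna_matrix(study.train_cna, genes),
                 indir / "train_cna.seg")
    io.write_seg(segments_from_cna_matrix(study.internal_cna, genes),
                 indir / "internal_cna.seg")
    io.write_gene_bed(genes, indir / "genes.bed")
    io.write_clinical(study.clinical, indir / "clinical.tsv")
    io.write_labels(list(study.true_labels), list(study.true_labels.values()),
                    indir / "true_labels.tsv")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
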