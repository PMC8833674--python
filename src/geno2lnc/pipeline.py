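"""End-to-end pipeline: simulate -> prep -> preselect -> genoqc -> eqtl ->
associate, with per-stage manifests, input-hash caching and a funnel-count
summary."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from geno2lnc import expression_prep, genotype_qc, impute_associate, preselect, synthdata
from geno2lnc import eqtl_validation
from geno2lnc._vcf import read_vcf, write_vcf
from geno2lnc.datatypes import (
    CountMatrix,
    DataError,
    EqtlModel,
    ExpressionMatrix,
    SampleCovariates,
)

log = logging.getLogger("geno2lnc")

DEFAULTS: dict = {
    "seed": 0,
    "sim": {},
    "prep": {"pseudocount": 1.0, "depth_frac": 0.05, "k_pcs": 10},
    "preselect": {
        "n_perm": 5000,
        "fdr_max": 0.05,
        "split_frac": 0.8,
        "cv_folds": 5,
        "grid_size": 10,
    },
    "genoqc": {
        "maf_min": 0.01,
        "snp_callrate_min": 0.95,
        "sample_callrate_min": 0.95,
        "ibd_threshold": 0.1,
        "ld_r2_max": 0.1,
        "ld_window": 50,
        "ld_step": 5,
        "depth_frac": 0.05,
        "n_pcs": 10,
    },
    "eqtl": {"alpha": 0.05, "huber_c": 1.345, "effect_allele": "major"},
    "associate": {"huber_c": 1.2, "n_pcs": 10},
}


def load_config_defaults() -> dict:
    return json.loads(json.dumps(DEFAULTS))


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_current(stage_dir: Path, inputs: list[Path], params: dict) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    with open(manifest) as fh:
        m = json.load(fh)
    if m.get("params") != json.loads(json.dumps(params)):
        return False
    if m.get("input_hashes") != {str(p): _hash_file(p) for p in inputs}:
        return False
    return all((stage_dir / f).exists() for f in m.get("outputs", []))


def _write_manifest(
    stage_dir: Path, stage: str, inputs: list[Path], params: dict,
    outputs: list[str], funnel: dict,
) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "input_hashes": {str(p): _hash_file(p) for p in inputs},
        "outputs": outputs,
        "output_hashes": {f: _hash_file(stage_dir / f) for f in outputs},
        "funnel": funnel,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "sim"
    stage_dir.mkdir(parents=True, exist_ok=True)
    params = {"seed": cfg["seed"], **cfg["sim"]}
    if _stage_current(stage_dir, [], params):
        log.info("sim: cached")
        return stage_dir
    sim = synthdata.SimConfig(seed=cfg["seed"], **cfg["sim"]).validate()

    counts, truth = synthdata.gen_tissue_counts(sim)
    rng = np.random.default_rng(sim.seed + 101)
    tissue_cov = synthdata.gen_covariates(
        len(counts.sample_ids), rng, sample_ids=list(counts.sample_ids)
    )

    geno_eqtl = synthdata.gen_genotypes(sim, stream="geno-eqtl", prefix="E")
    synthdata.assign_eqtls(sim, truth, geno_eqtl)
    eqtl_cov = synthdata.gen_covariates(
        len(geno_eqtl.sample_ids), rng, sample_ids=list(geno_eqtl.sample_ids)
    )
    serum = synthdata.gen_serum_matrix(
        geno_eqtl, truth, eqtl_cov, sim, list(counts.transcript_ids)
    )
    candidates = synthdata.gen_candidate_table(truth, geno_eqtl, seed=sim.seed)

    n_assoc = sim.n_cases + sim.n_controls
    geno_assoc = synthdata.gen_genotypes(
        sim, n_individuals=n_assoc, stream="geno-assoc", prefix="A"
    )
    assoc_cov = synthdata.gen_covariates(
        n_assoc, rng, sample_ids=list(geno_assoc.sample_ids)
    )
    first_trend = truth.trend_transcript_ids[0]
    status = synthdata.gen_case_control(
        geno_assoc, truth.prediction_model(first_trend), assoc_cov, sim
    )

    counts_out = counts.values.copy()
    counts_out.insert(0, "length", counts.lengths)
    _tsv(counts_out, stage_dir / "counts.tsv", index_label="transcript_id")
    _tsv(
        counts.stage_labels.astype(str).to_frame("stage"),
        stage_dir / "stages.tsv",
        index_label="sample_id",
    )
    _tsv(tissue_cov.table, stage_dir / "tissue_covariates.tsv", index_label="sample_id")
    write_vcf(geno_eqtl, stage_dir / "eqtl.vcf")
    _tsv(serum, stage_dir / "serum.tsv", index_label="transcript_id")
    _tsv(eqtl_cov.table, stage_dir / "eqtl_covariates.tsv", index_label="sample_id")
    _tsv(candidates, stage_dir / "candidates.tsv", index=False)
    write_vcf(geno_assoc, stage_dir / "assoc.vcf")
    _tsv(assoc_cov.table, stage_dir / "assoc_covariates.tsv", index_label="sample_id")
    _tsv(status.to_frame("status"), stage_dir / "status.tsv", index_label="sample_id")
    truth.to_json(stage_dir / "truth.json")

    outputs = [
        "counts.tsv", "stages.tsv", "tissue_covariates.tsv", "eqtl.vcf",
        "serum.tsv", "eqtl_covariates.tsv", "candidates.tsv", "assoc.vcf",
        "assoc_covariates.tsv", "status.tsv", "truth.json",
    ]
    funnel = {
        "n_transcripts": int(sim.n_transcripts),
        "n_tissue_samples": int(sum(sim.n_per_stage)),
        "n_eqtl_individuals": int(sim.n_individuals_eqtl),
        "n_association_individuals": int(n_assoc),
        "n_planted_trends": int(sim.n_trend),
    }
    _write_manifest(stage_dir, "sim", [], params, outputs, funnel)
    return stage_dir


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.pop("length")
    stages = pd.read_csv(
        Path(path).with_name("stages.tsv"), sep="\t", index_col=0
    )["stage"]
    return CountMatrix(df, lengths, stages)


def stage_prep(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "prep"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    inputs = [sim_dir / "counts.tsv", sim_dir / "stages.tsv"]
    params = cfg["prep"]
    if _stage_current(stage_dir, inputs, params):
        log.info("prep: cached")
        return stage_dir
    counts = read_counts_tsv(inputs[0])
    expr = expression_prep.counts_to_log2tpm(counts, pseudocount=params["pseudocount"])
    n_detected = len(expr.transcript_ids)
    expr, excluded = expression_prep.mad_filter(expr)
    expr = expression_prep.quantile_normalize(expr, groups=expr.stage_labels)
    expr = expression_prep.quantile_normalize(expr, groups=None)
    kept, scores, depth = expression_prep.pca_depth_exclude(
        expr, frac=params["depth_frac"],
        k_pcs=min(params["k_pcs"], len(expr.sample_ids) - 1),
    )
    dropped = [s for s in expr.sample_ids if s not in set(kept)]
    expr = ExpressionMatrix(
        expr.values[kept], expr.stage_labels[kept], expr.normalization_state
    )
    _tsv(expr.values, stage_dir / "normalized.tsv", index_label="transcript_id")
    _tsv(
        expr.stage_labels.astype(str).to_frame("stage"),
        stage_dir / "kept_stages.tsv",
        index_label="sample_id",
    )
    report = pd.DataFrame(
        {
            "id": list(excluded) + dropped,
            "kind": ["transcript_mad0"] * len(excluded) + ["sample_low_depth"] * len(dropped),
        }
    )
    _tsv(report, stage_dir / "exclusions.tsv", index=False)
    _tsv(depth.to_frame(), stage_dir / "depth.tsv", index_label="sample_id")
    funnel = {
        "n_transcripts_detected": n_detected,
        "n_transcripts_mad_zero": int(len(excluded)),
        "n_transcripts_kept": int(len(expr.transcript_ids)),
        "n_samples_in": int(len(counts.sample_ids)),
        "n_samples_kept": int(len(kept)),
    }
    outputs = ["normalized.tsv", "kept_stages.tsv", "exclusions.tsv", "depth.tsv"]
    _write_manifest(stage_dir, "prep", inputs, params, outputs, funnel)
    return stage_dir


def _read_expr(path, stages_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    stages = None
    if stages_path is not None and Path(stages_path).exists():
        stages = pd.read_csv(stages_path, sep="\t", index_col=0)["stage"]
    return ExpressionMatrix(df, stages, "global-QN")


def stage_preselect(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "preselect"
    stage_dir.mkdir(parents=True, exist_ok=True)
    prep_dir, sim_dir = outdir / "prep", outdir / "sim"
    inputs = [
        prep_dir / "normalized.tsv", prep_dir / "kept_stages.tsv",
        sim_dir / "serum.tsv", sim_dir / "candidates.tsv",
    ]
    params = {"seed": cfg["seed"], **cfg["preselect"]}
    if _stage_current(stage_dir, inputs, params):
        log.info("preselect: cached")
        return stage_dir
    expr = _read_expr(inputs[0], inputs[1])
    serum = ExpressionMatrix(pd.read_csv(inputs[2], sep="\t", index_col=0))
    candidates = pd.read_csv(inputs[3], sep="\t")

    trend = preselect.jt_permutation_test(
        expr, n_perm=params["n_perm"], seed=cfg["seed"]
    )
    trend_df = preselect.trend_results_frame(trend)
    imp = preselect.train_stage_classifier(
        expr,
        split_frac=params["split_frac"],
        cv_folds=params["cv_folds"],
        grid_size=params["grid_size"],
        seed=cfg["seed"],
    )
    cand = preselect.select_candidates(
        trend_df, imp, serum, candidates, fdr_max=params["fdr_max"]
    )
    _tsv(trend_df, stage_dir / "trend.tsv")
    _tsv(imp.importances.to_frame(), stage_dir / "importance.tsv", index_label="transcript_id")
    _tsv(cand.criteria, stage_dir / "candidate_report.tsv", index_label="transcript_id")
    with open(stage_dir / "classifier_metrics.json", "w") as fh:
        json.dump(
            {
                "auc_weighted_ovr": imp.auc,
                "mean_per_class_error": imp.mean_per_class_error,
                "cv_folds": imp.cv_folds,
                "best_params": imp.best_params,
            },
            fh,
            indent=2,
        )
    crit = cand.criteria
    funnel = {
        "n_tested": int(len(trend_df)),
        "n_jt_fdr_significant": int((trend_df["fdr"] < params["fdr_max"]).sum()),
        "n_importance_above_median": int(
            (crit["crit_i_trend_and_importance"]).sum()
        ),
        "n_serum_mad_nonzero": int(crit["crit_iii_serum_mad"].sum()),
        "n_in_candidate_table": int(crit["crit_iv_in_candidate_table"].sum()),
        "n_selected": int(len(cand.selected)),
    }
    outputs = ["trend.tsv", "importance.tsv", "candidate_report.tsv", "classifier_metrics.json"]
    _write_manifest(stage_dir, "preselect", inputs, params, outputs, funnel)
    return stage_dir


def stage_genoqc(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "genoqc"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    inputs = [sim_dir / "eqtl.vcf"]
    params = cfg["genoqc"]
    if _stage_current(stage_dir, inputs, params):
        log.info("genoqc: cached")
        return stage_dir
    geno = read_vcf(inputs[0])
    n_samples_in, n_snps_in = len(geno.sample_ids), len(geno.snp_ids)
    geno, report = genotype_qc.snp_sample_filter(
        geno,
        maf_min=params["maf_min"],
        snp_callrate_min=params["snp_callrate_min"],
        sample_callrate_min=params["sample_callrate_min"],
    )
    kin = genotype_qc.ibd_kinship(geno)
    kept_samples = genotype_qc.relatedness_prune(
        kin, geno, threshold=params["ibd_threshold"]
    )
    n_related_removed = len(geno.sample_ids) - len(kept_samples)
    geno = geno.subset(samples=kept_samples)
    kept_snps = genotype_qc.ld_prune(
        geno, r2_max=params["ld_r2_max"],
        window=params["ld_window"], step=params["ld_step"],
    )
    geno = geno.subset(snps=kept_snps)
    pcs = genotype_qc.genetic_pca(geno, k=min(params["n_pcs"], len(geno.sample_ids) - 1))
    final_samples = genotype_qc.depth_exclude_genetic(pcs, frac=params["depth_frac"])

    _tsv(pcs.scores.loc[final_samples], stage_dir / "pcs.tsv", index_label="sample_id")
    _tsv(kin.coefficients, stage_dir / "kinship.tsv", index_label="sample_id")
    pd.Series(final_samples).to_csv(
        stage_dir / "kept_samples.txt", index=False, header=False
    )
    pd.Series(kept_snps).to_csv(stage_dir / "kept_snps.txt", index=False, header=False)
    funnel = {
        "n_samples_in": n_samples_in,
        "n_snps_in": n_snps_in,
        "n_snps_after_filter": report.n_snps_kept,
        "n_samples_low_callrate": len(report.samples_removed_callrate),
        "n_samples_related_removed": int(n_related_removed),
        "n_snps_after_ld_prune": int(len(kept_snps)),
        "n_samples_final": int(len(final_samples)),
    }
    outputs = ["pcs.tsv", "kinship.tsv", "kept_samples.txt", "kept_snps.txt"]
    _write_manifest(stage_dir, "genoqc", inputs, params, outputs, funnel)
    return stage_dir


def stage_eqtl(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "eqtl"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir, pre_dir, qc_dir = outdir / "sim", outdir / "preselect", outdir / "genoqc"
    inputs = [
        sim_dir / "eqtl.vcf", sim_dir / "serum.tsv", sim_dir / "eqtl_covariates.tsv",
        sim_dir / "candidates.tsv", pre_dir / "candidate_report.tsv",
        qc_dir / "kept_samples.txt", qc_dir / "pcs.tsv",
    ]
    params = cfg["eqtl"]
    if _stage_current(stage_dir, inputs, params):
        log.info("eqtl: cached")
        return stage_dir
    geno = read_vcf(sim_dir / "eqtl.vcf")
    kept_samples = pd.read_csv(
        qc_dir / "kept_samples.txt", header=None
    )[0].astype(str).tolist()
    geno = geno.subset(samples=kept_samples)
    serum = ExpressionMatrix(
        pd.read_csv(sim_dir / "serum.tsv", sep="\t", index_col=0)[kept_samples]
    )
    pcs = pd.read_csv(qc_dir / "pcs.tsv", sep="\t", index_col=0)
    covars = SampleCovariates(
        pd.read_csv(sim_dir / "eqtl_covariates.tsv", sep="\t", index_col=0),
        pcs,
    )
    report = pd.read_csv(pre_dir / "candidate_report.tsv", sep="\t", index_col=0)
    selected = report.index[report["selected"]].tolist()
    candidates = pd.read_csv(sim_dir / "candidates.tsv", sep="\t")
    candidates = candidates[candidates["transcript_id"].isin(selected)]

    result = eqtl_validation.validate_candidates(
        serum, geno, covars, candidates,
        alpha=params["alpha"], huber_c=params["huber_c"],
        effect_allele=params["effect_allele"],
    )
    models, model_meta = {}, {}
    for transcript, hits in result.validated.items():
        if not hits:
            continue
        model, fit, ref_fit, _ = eqtl_validation.select_prediction_model(
            serum, transcript, hits, geno, covars, huber_c=params["huber_c"]
        )
        models[transcript] = model
        model_meta[transcript] = {
            "raic": fit.raic,
            "r2_adj_full": fit.r2_adj,
            "r2_adj_reference": ref_fit.r2_adj,
            "n_predictors": len(model.terms),
        }
    _tsv(result.fits, stage_dir / "fits.tsv", index=False)
    with open(stage_dir / "models.json", "w") as fh:
        json.dump(
            {
                "models": {t: m.to_dict() for t, m in models.items()},
                "meta": model_meta,
                "validated_counts": {
                    t: len(h) for t, h in result.validated.items()
                },
                "untestable": [list(map(str, u)) for u in result.untestable],
            },
            fh,
            indent=2,
        )
    funnel = {
        "n_candidate_pairs": int(len(candidates)),
        "n_untestable": int(len(result.untestable)),
        "validated_per_transcript": {
            t: len(h) for t, h in result.validated.items()
        },
        "n_transcripts_with_model": int(len(models)),
    }
    outputs = ["fits.tsv", "models.json"]
    _write_manifest(stage_dir, "eqtl", inputs, params, outputs, funnel)
    return stage_dir


def stage_associate(outdir: Path, cfg: dict) -> Path:
    stage_dir = outdir / "associate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim_dir, eqtl_dir = outdir / "sim", outdir / "eqtl"
    inputs = [
        sim_dir / "assoc.vcf", sim_dir / "assoc_covariates.tsv",
        sim_dir / "status.tsv", eqtl_dir / "models.json",
    ]
    params = cfg["associate"]
    if _stage_current(stage_dir, inputs, params):
        log.info("associate: cached")
        return stage_dir
    geno = read_vcf(sim_dir / "assoc.vcf")
    with open(eqtl_dir / "models.json") as fh:
        models_doc = json.load(fh)
    models = {
        t: EqtlModel.from_dict(d) for t, d in models_doc["models"].items()
    }
    status = pd.read_csv(sim_dir / "status.tsv", sep="\t", index_col=0)["status"]
    pcs = genotype_qc.genetic_pca(
        geno, k=min(params["n_pcs"], len(geno.sample_ids) - 1)
    )
    covars = SampleCovariates(
        pd.read_csv(sim_dir / "assoc_covariates.tsv", sep="\t", index_col=0),
        pcs.scores,
    )
    results, predictions = [], {}
    for transcript, model in models.items():
        pred = impute_associate.predict_expression(geno, model)
        predictions[transcript] = pred
        try:
            res = impute_associate.associate(
                pred, status, covars, huber_c=params["huber_c"],
                n_pcs=params["n_pcs"], transcript_id=transcript,
            )
        except DataError as exc:
            log.warning("associate %s skipped: %s", transcript, exc)
            continue
        results.append(res)

    table3 = impute_associate.association_table(results, predictions)
    _tsv(table3, stage_dir / "association.tsv", index=False)

    # Table-1-shaped report from the preselection dataset
    prep_dir = outdir / "prep"
    expr = _read_expr(prep_dir / "normalized.tsv", prep_dir / "kept_stages.tsv")
    tissue_cov = SampleCovariates(
        pd.read_csv(sim_dir / "tissue_covariates.tsv", sep="\t", index_col=0)
    )
    trend_df = pd.read_csv(outdir / "preselect" / "trend.tsv", sep="\t", index_col=0)
    report_ids = sorted(models.keys())
    if report_ids:
        table1 = impute_associate.stagewise_expression_table(
            expr, tissue_cov, report_ids, trend_fdr=trend_df["fdr"]
        )
        _tsv(table1, stage_dir / "stage_expression_report.tsv", index=False)

    serum = ExpressionMatrix(pd.read_csv(sim_dir / "serum.tsv", sep="\t", index_col=0))
    candidates = pd.read_csv(sim_dir / "candidates.tsv", sep="\t")
    cand_counts = candidates.groupby("transcript_id").size().to_dict()
    meta = models_doc["meta"]
    table2 = impute_associate.eqtl_summary_table(
        serum,
        {t: int(cand_counts.get(t, 0)) for t in models_doc["validated_counts"]},
        models_doc["validated_counts"],
        {t: m["n_predictors"] for t, m in meta.items()},
        {t: m["r2_adj_full"] for t, m in meta.items()},
    )
    _tsv(table2, stage_dir / "eqtl_summary_report.tsv", index=False)

    funnel = {
        "n_models": int(len(models)),
        "n_associations": int(len(results)),
        "odds_ratios": {r.transcript_id: r.odds_ratio for r in results},
    }
    outputs = ["association.tsv", "eqtl_summary_report.tsv"] + (
        ["stage_expression_report.tsv"] if report_ids else []
    )
    _write_manifest(stage_dir, "associate", inputs, params, outputs, funnel)
    return stage_dir


_STAGES = {
    "sim": stage_simulate,
    "prep": stage_prep,
    "preselect": stage_preselect,
    "genoqc": stage_genoqc,
    "eqtl": stage_eqtl,
    "associate": stage_associate,
}


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run all stages in order; returns the merged manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged: dict = {"seed": cfg["seed"], "stages": {}}
    for name, fn in _STAGES.items():
        log.info("running stage %s", name)
        stage_dir = fn(outdir, cfg)
        with open(stage_dir / "manifest.json") as fh:
            merged["stages"][name] = json.load(fh)
    merged["funnel"] = {
        name: m["funnel"] for name, m in merged["stages"].items()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(merged, fh, indent=2, sort_keys=True)
    return merged
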