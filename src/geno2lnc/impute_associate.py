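"""Genotype-based expression imputation and robust case-control association.

Predicted log2 serum expression is the intercept-free sum of fitted SNP
effects times the penetrance-encoded genotype.  The association model is

    status ~ predicted log2 expression + age + gender + first 10 genetic PCs

fitted by robust quasi-likelihood logistic regression (Huber tuning
constant 1.2 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from geno2lnc._robust import huber_rlm, robust_logistic
from geno2lnc.datatypes import (
    AssociationResult,
    DataError,
    EqtlModel,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleCovariates,
)
from geno2lnc.eqtl_validation import encode_penetrance

_Z95 = 1.959963984540054


def predict_expression(geno: GenotypeMatrix, model: EqtlModel) -> pd.Series:
    """Predicted log2 expression per individual: sum of beta_i * A_i.

    No intercept or covariate terms enter the prediction; individuals
    missing any model SNP get a missing prediction.
    """
    if not model.terms:
        raise DataError("empty prediction model")
    missing_snps = [t.snp_id for t in model.terms if t.snp_id not in set(geno.snp_ids)]
    if missing_snps:
        raise DataError(f"model SNPs absent from genotype data: {missing_snps}")
    total = np.zeros(len(geno.sample_ids))
    for term in model.terms:
        dos = geno.dosages[term.snp_id]
        oriented = dos if term.effect_is_alt else 2.0 - dos
        enc = encode_penetrance(oriented.to_numpy(), term.model)
        total = total + enc @ np.asarray(term.betas, dtype=float)
    return pd.Series(total, index=geno.sample_ids, name=model.transcript_id)


def distinct_levels(model: EqtlModel) -> int:
    """Number of distinct predicted values over all genotype combinations."""
    values = np.array([0.0])
    for term in model.terms:
        dosage_levels = np.array([0.0, 1.0, 2.0])
        enc = encode_penetrance(dosage_levels, term.model)
        contrib = np.unique(enc @ np.asarray(term.betas, dtype=float))
        values = np.unique(np.add.outer(values, contrib).ravel())
    return len(values)


def associate(
    pred: pd.Series,
    status: pd.Series,
    covars: SampleCovariates,
    huber_c: float = 1.2,
    n_pcs: int = 10,
    transcript_id: str | None = None,
) -> AssociationResult:
    """Robust logistic association of disease status with predicted expression.

    OR is per log2 expression unit; the 95% CI is Wald on the log-odds scale.
    Individuals with a missing prediction are excluded.
    """
    samples = status.index.intersection(pred.index)
    pred = pred.reindex(samples)
    status_v = status.reindex(samples).astype(float)
    ok = pred.notna() & status_v.notna()
    samples = samples[ok]
    pred, status_v = pred[ok], status_v[ok]
    if pred.nunique() < 2:
        raise DataError("predicted expression is constant; nothing to test")
    covar = covars.design(samples, n_pcs=n_pcs)
    X = covar.copy()
    X.insert(0, "predicted_log2_expression", pred.to_numpy())
    X.insert(0, "intercept", 1.0)
    params, bse, pvals, _, converged = robust_logistic(
        status_v.to_numpy(), X, huber_c=huber_c
    )
    if not converged:
        raise DataError("robust logistic regression did not converge")
    b = float(params["predicted_log2_expression"])
    se = float(bse["predicted_log2_expression"])
    return AssociationResult(
        transcript_id=transcript_id or str(pred.name),
        odds_ratio=float(np.exp(b)),
        ci_lower=float(np.exp(b - _Z95 * se)),
        ci_upper=float(np.exp(b + _Z95 * se)),
        p_value=float(pvals["predicted_log2_expression"]),
        huber_c=huber_c,
        n_cases=int((status_v == 1).sum()),
        n_controls=int((status_v == 0).sum()),
        covariates=list(X.columns[2:]),
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _stage_difference_fit(
    values: pd.Series, stages: pd.Series, huber_c: float = 1.345
) -> dict:
    """Robust regression of expression on stage indicators (GS baseline)."""
    stages = stages.reindex(values.index)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "dys": (stages == "Dys").astype(float),
            "gbc": (stages == "GBC").astype(float),
        },
        index=values.index,
    )
    out: dict = {}
    try:
        fit = huber_rlm(values.to_numpy(dtype=float), X, huber_c=huber_c)
        ci = fit.conf_int()
        for key, term in (("dys_vs_gs", "dys"), ("gbc_vs_gs", "gbc")):
            out[f"{key}_estimate"] = float(fit.params[term])
            out[f"{key}_ci_lower"] = float(ci.loc[term, "lower"])
            out[f"{key}_ci_upper"] = float(ci.loc[term, "upper"])
    except DataError:
        for key in ("dys_vs_gs", "gbc_vs_gs"):
            out[f"{key}_estimate"] = np.nan
            out[f"{key}_ci_lower"] = np.nan
            out[f"{key}_ci_upper"] = np.nan
    return out


def stagewise_expression_table(
    expr: ExpressionMatrix,
    covars: SampleCovariates,
    transcripts: list[str],
    trend_fdr: pd.Series | None = None,
    age_cut: float = 60.0,
) -> pd.DataFrame:
    """Per-stratum stage-wise medians and robust expression differences.

    Strata: All, Women, Men, Age<cut, Age>=cut.  For each transcript the
    table reports the GS median (5th; 95th percentiles) and robust-
    regression differences Dys vs GS and GBC vs GS with 95% CIs.
    """
    cov = covars.table.reindex(expr.sample_ids)
    strata = {
        "All": pd.Series(True, index=expr.sample_ids),
        "Women": cov["gender"] == 0,
        "Men": cov["gender"] == 1,
        f"Age<{age_cut:g}": cov["age"] < age_cut,
        f"Age>={age_cut:g}": cov["age"] >= age_cut,
    }
    rows = []
    for stratum, mask in strata.items():
        samples = expr.sample_ids[mask.to_numpy(dtype=bool)]
        stages = expr.stage_labels.reindex(samples)
        for t in transcripts:
            vals = expr.values.loc[t, samples]
            gs = vals[(stages == "GS").to_numpy()]
            row = {
                "stratum": stratum,
                "transcript_id": t,
                "n_gs": int((stages == "GS").sum()),
                "n_dys": int((stages == "Dys").sum()),
                "n_gbc": int((stages == "GBC").sum()),
                "fdr": float(trend_fdr[t]) if trend_fdr is not None and t in trend_fdr else np.nan,
                "gs_median": float(gs.median()) if len(gs) else np.nan,
                "gs_p5": float(gs.quantile(0.05)) if len(gs) else np.nan,
                "gs_p95": float(gs.quantile(0.95)) if len(gs) else np.nan,
            }
            row.update(_stage_difference_fit(vals, stages))
            rows.append(row)
    return pd.DataFrame(rows)


def eqtl_summary_table(
    serum_expr: ExpressionMatrix,
    candidate_counts: dict[str, int],
    validated_counts: dict[str, int],
    predictor_counts: dict[str, int],
    r2_adj: dict[str, float],
) -> pd.DataFrame:
    """Candidate / validated / predictor SNP counts and best-model adjusted r^2.

    Transcripts without validated SNPs get dashes, mirroring the report
    layout for failed validations.
    """
    rows = []
    for t, n_cand in candidate_counts.items():
        if t in serum_expr.transcript_ids:
            vals = serum_expr.values.loc[t]
            med, p5, p95 = (
                float(vals.median()),
                float(vals.quantile(0.05)),
                float(vals.quantile(0.95)),
            )
        else:
            med = p5 = p95 = np.nan
        n_val = validated_counts.get(t, 0)
        rows.append(
            {
                "transcript_id": t,
                "serum_median": med,
                "serum_p5": p5,
                "serum_p95": p95,
                "n_candidate_eqtls": n_cand,
                "n_validated_eqtls": n_val if n_val else "-",
                "n_predictor_eqtls": predictor_counts.get(t, 0) or "-",
                "r2_adj_best_model": (
                    round(r2_adj[t], 4) if t in r2_adj and n_val else "-"
                ),
            }
        )
    return pd.DataFrame(rows)


def association_table(
    results: list[AssociationResult], predictions: dict[str, pd.Series]
) -> pd.DataFrame:
    """Median predicted expression, OR, CI and p per transcript."""
    rows = []
    for res in results:
        pred = predictions.get(res.transcript_id)
        rows.append(
            {
                "transcript_id": res.transcript_id,
                "median_predicted_log2_expression": (
                    float(pred.median()) if pred is not None else np.nan
                ),
                "odds_ratio": res.odds_ratio,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p_value": res.p_value,
                "n_cases": res.n_cases,
                "n_controls": res.n_controls,
            }
        )
    return pd.DataFrame(rows)
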