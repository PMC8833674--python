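"""Cis-eQTL validation by robust linear regression under four penetrance
encodings, and RAIC-based selection of the multi-SNP prediction model.

Every fit follows the same structure:

    log2 expression ~ SNP term(s) + age + gender + first 10 genetic PCs
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from geno2lnc._robust import huber_rlm, raic, raic_at_scale, wald_joint_test
from geno2lnc.datatypes import (
    ConfigError,
    DataError,
    EqtlModel,
    EqtlTerm,
    ExpressionMatrix,
    GenotypeMatrix,
    PENETRANCE_MODELS,
    RobustFit,
    SampleCovariates,
)

__all__ = [
    "encode_penetrance",
    "effect_dosages",
    "huber_rlm",
    "raic",
    "validate_candidates",
    "select_prediction_model",
    "ValidationResult",
]


def encode_penetrance(dosages, model: str) -> np.ndarray:
    """Encode effect-allele dosages as penetrance design columns.

    additive -> dosage; dominant -> 1[dosage >= 1]; recessive ->
    1[dosage == 2]; three_genotype -> indicator columns for dosage 1 and
    dosage 2 (dosage 0 is the baseline).  Missing dosages propagate as NaN
    so callers can drop those rows from the fit.
    """
    if model not in PENETRANCE_MODELS:
        raise ConfigError(f"unknown penetrance model {model!r}")
    d = np.asarray(dosages, dtype=float)
    bad = ~(np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0)))
    if bad.any():
        raise DataError("dosages must be 0, 1, 2 or missing")
    nan = np.isnan(d)
    if model == "additive":
        out = d[:, None].copy()
    elif model == "dominant":
        out = (d >= 1).astype(float)[:, None]
    elif model == "recessive":
        out = (d == 2).astype(float)[:, None]
    else:  # three_genotype
        out = np.column_stack([(d == 1).astype(float), (d == 2).astype(float)])
    out[nan] = np.nan
    return out


def effect_dosages(
    geno: GenotypeMatrix, snp_id: str, effect_allele: str = "major"
) -> tuple[pd.Series, bool]:
    """Dosages oriented to the chosen effect allele.

    ``effect_allele`` is ``"major"`` (default: the more frequent allele in
    this dataset), ``"minor"``, or ``"alt"``.  Returns the oriented dosage
    vector and whether the effect allele is the ALT allele, so the same
    orientation can be replayed on other genotype sets.
    """
    dos = geno.dosages[snp_id]
    alt_freq = float(dos.mean(skipna=True)) / 2.0
    if effect_allele == "alt":
        effect_is_alt = True
    elif effect_allele == "major":
        effect_is_alt = alt_freq >= 0.5
    elif effect_allele == "minor":
        effect_is_alt = alt_freq < 0.5
    else:
        raise ConfigError(f"effect_allele must be major/minor/alt, got {effect_allele!r}")
    return (dos if effect_is_alt else 2.0 - dos), effect_is_alt


def _design_frame(
    enc: np.ndarray, snp_cols: list[str], covar: pd.DataFrame
) -> pd.DataFrame:
    X = pd.DataFrame(enc, index=covar.index, columns=snp_cols)
    X = pd.concat([X, covar], axis=1)
    X.insert(0, "intercept", 1.0)
    return X


@dataclass
class ValidationResult:
    fits: pd.DataFrame  # one row per (transcript, snp, model)
    validated: dict = field(default_factory=dict)
    # transcript -> list of dicts {snp_id, model, p_value, effect_is_alt}
    untestable: list = field(default_factory=list)


def _fit_snp_model(
    y: pd.Series,
    oriented: pd.Series,
    model: str,
    covar: pd.DataFrame,
    huber_c: float,
) -> tuple[RobustFit, float] | None:
    enc = encode_penetrance(oriented.to_numpy(), model)
    cols = [f"snp_{model}_{i}" for i in range(enc.shape[1])]
    X = _design_frame(enc, cols, covar)
    keep = ~X.isna().any(axis=1) & ~y.isna()
    Xc, yc = X.loc[keep], y.loc[keep]
    # degenerate encodings (e.g. recessive with no homozygotes) are untestable
    if any(Xc[c].nunique() < 2 for c in cols):
        return None
    try:
        fit = huber_rlm(yc.to_numpy(), Xc, huber_c=huber_c, description=model)
    except DataError:
        return None
    if len(cols) == 1:
        p_snp = float(fit.pvalues[cols[0]])
    else:
        p_snp = wald_joint_test(fit, cols)
    return fit, p_snp


def validate_candidates(
    serum_expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covars: SampleCovariates,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    huber_c: float = 1.345,
    effect_allele: str = "major",
    r2_prune: float = 0.1,
    n_pcs: int = 10,
) -> ValidationResult:
    """Fit every candidate (transcript, SNP) pair under all four penetrance
    models; a SNP is validated when its term reaches p < ``alpha`` under at
    least one model.  Validated SNPs in mutual LD (r^2 > ``r2_prune``) are
    reduced keeping the smaller per-SNP p-value.
    """
    samples = [s for s in serum_expr.sample_ids if s in set(geno.sample_ids)]
    if not samples:
        raise DataError("no overlapping samples between expression and genotypes")
    covar = covars.design(samples, n_pcs=n_pcs)
    rows = []
    result = ValidationResult(fits=pd.DataFrame())
    per_snp_best: dict[str, list] = {}
    for transcript, snp in candidates[["transcript_id", "snp_id"]].itertuples(index=False):
        if transcript not in serum_expr.transcript_ids:
            result.untestable.append((transcript, snp, "transcript absent"))
            continue
        if snp not in set(geno.snp_ids):
            result.untestable.append((transcript, snp, "SNP absent"))
            continue
        y = serum_expr.values.loc[transcript, samples]
        oriented, effect_is_alt = effect_dosages(geno, snp, effect_allele)
        oriented = oriented.reindex(samples)
        best = None
        for model in PENETRANCE_MODELS:
            out = _fit_snp_model(y, oriented, model, covar, huber_c)
            if out is None:
                continue
            fit, p_snp = out
            beta = float(fit.params.filter(like="snp_").iloc[0])
            rows.append(
                {
                    "transcript_id": transcript,
                    "snp_id": snp,
                    "model": model,
                    "beta": beta,
                    "se": float(fit.bse.filter(like="snp_").iloc[0]),
                    "p_value": p_snp,
                    "raic": fit.raic,
                    "n": fit.n,
                }
            )
            if best is None or p_snp < best["p_value"]:
                best = {
                    "snp_id": snp,
                    "model": model,
                    "p_value": p_snp,
                    "effect_is_alt": effect_is_alt,
                }
        if best is not None and best["p_value"] < alpha:
            per_snp_best.setdefault(transcript, []).append(best)

    result.fits = pd.DataFrame(rows)

    # reduce LD-redundant validated SNPs per transcript (best p first)
    for transcript, hits in per_snp_best.items():
        hits = sorted(hits, key=lambda h: (h["p_value"], h["snp_id"]))
        kept: list[dict] = []
        for h in hits:
            dos_h = geno.dosages[h["snp_id"]].to_numpy(dtype=float)
            redundant = False
            for k in kept:
                dos_k = geno.dosages[k["snp_id"]].to_numpy(dtype=float)
                ok = ~np.isnan(dos_h) & ~np.isnan(dos_k)
                if ok.sum() > 2 and np.std(dos_h[ok]) > 0 and np.std(dos_k[ok]) > 0:
                    r2 = float(np.corrcoef(dos_h[ok], dos_k[ok])[0, 1]) ** 2
                    if r2 > r2_prune:
                        redundant = True
                        break
            if not redundant:
                kept.append(h)
        result.validated[transcript] = kept
    return result


def select_prediction_model(
    serum_expr: ExpressionMatrix,
    transcript_id: str,
    validated: list[dict],
    geno: GenotypeMatrix,
    covars: SampleCovariates,
    huber_c: float = 1.345,
    n_pcs: int = 10,
    max_snps: int = 20,
    allow_large: bool = False,
) -> tuple[EqtlModel, RobustFit, RobustFit, pd.DataFrame]:
    """Exhaustive RAIC search over non-empty subsets of validated SNPs.

    Each SNP enters with its winning penetrance encoding.  Returns the
    selected :class:`EqtlModel`, the winning fit, the covariates-only
    reference fit and a table of all subset fits.
    """
    if not validated:
        raise DataError(
            f"no validated SNPs for {transcript_id}; "
            "run validate_candidates first or relax alpha"
        )
    if len(validated) > max_snps and not allow_large:
        raise ConfigError(
            f"{len(validated)} validated SNPs would need "
            f"2^{len(validated)} subset fits; pass allow_large=True to proceed"
        )
    samples = [s for s in serum_expr.sample_ids if s in set(geno.sample_ids)]
    covar = covars.design(samples, n_pcs=n_pcs)
    y_all = serum_expr.values.loc[transcript_id, samples]

    ref_X = covar.copy()
    ref_X.insert(0, "intercept", 1.0)
    keep = ~ref_X.isna().any(axis=1) & ~y_all.isna()
    reference_fit = huber_rlm(
        y_all.loc[keep].to_numpy(), ref_X.loc[keep], huber_c=huber_c,
        description="reference (covariates only)",
    )

    encodings = {}
    for h in validated:
        # replay the orientation stored at validation time
        dos = geno.dosages[h["snp_id"]]
        oriented = dos if h["effect_is_alt"] else 2.0 - dos
        encodings[h["snp_id"]] = encode_penetrance(
            oriented.reindex(samples).to_numpy(), h["model"]
        )

    snp_ids = [h["snp_id"] for h in validated]
    by_snp = {h["snp_id"]: h for h in validated}

    def _subset_fit(subset):
        cols, names = [], []
        for s in subset:
            enc = encodings[s]
            cols.append(enc)
            names.extend([s] if enc.shape[1] == 1 else [f"{s}_het", f"{s}_hom"])
        X = _design_frame(np.column_stack(cols), names, covar)
        keep = ~X.isna().any(axis=1) & ~y_all.isna()
        yk, Xk = y_all.loc[keep].to_numpy(), X.loc[keep]
        return yk, Xk, huber_rlm(yk, Xk, huber_c=huber_c, description="+".join(subset))

    # common residual scale from the largest model so subset RAICs are
    # comparable (each fit's own MAD scale standardizes fit quality away)
    try:
        _, _, full_fit = _subset_fit(tuple(snp_ids))
        common_scale = full_fit.scale
    except DataError:
        common_scale = reference_fit.scale

    records = []
    best = None
    for size in range(1, len(snp_ids) + 1):
        for subset in combinations(snp_ids, size):
            try:
                yk, Xk, fit = _subset_fit(subset)
            except DataError:
                continue
            score = raic_at_scale(yk, Xk, fit, common_scale)
            records.append(
                {"subset": "+".join(subset), "raic": score,
                 "raic_own_scale": fit.raic, "r2_adj": fit.r2_adj,
                 "converged": fit.converged}
            )
            if fit.converged and (best is None or score < best[2]):
                best = (subset, fit, score)
    if best is None:
        raise DataError(f"no subset model converged for {transcript_id}")
    subset, fit, _ = best
    terms = []
    for s in subset:
        h = by_snp[s]
        if h["model"] == "three_genotype":
            betas = [float(fit.params[f"{s}_het"]), float(fit.params[f"{s}_hom"])]
        else:
            betas = [float(fit.params[s])]
        terms.append(
            EqtlTerm(snp_id=s, model=h["model"], betas=betas,
                     effect_is_alt=bool(h["effect_is_alt"]))
        )
    model = EqtlModel(
        transcript_id=transcript_id,
        terms=terms,
        provenance=f"raic={fit.raic:.3f}",
    )
    return model, fit, reference_fit, pd.DataFrame(records)
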