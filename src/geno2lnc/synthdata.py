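"""Synthetic-data generators with the statistical structure the analysis
assumes, plus a ground-truth record enabling recovery tests.

All generators are pure functions of (config, seed): the same configuration
always yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import zlib

import numpy as np
import pandas as pd
from scipy import optimize, special

from geno2lnc.datatypes import (
    ConfigError,
    CountMatrix,
    EqtlModel,
    EqtlTerm,
    GenotypeMatrix,
    SampleCovariates,
    STAGES,
)
from geno2lnc.eqtl_validation import encode_penetrance
from geno2lnc.impute_associate import predict_expression


@dataclass
class SimConfig:
    """Parameters for every synthetic dataset.

    Tissue counts are negative-binomial with a common dispersion and
    log-normal library sizes; genotypes follow a Balding-Nichols-style
    subpopulation model; serum expression is SNP effects + age/gender +
    Gaussian noise scaled to a target variance fraction; case-control
    status comes from a logistic model on the imputed expression.
    """

    seed: int = 0
    # tissue stage counts (preselection dataset)
    n_per_stage: tuple[int, int, int] = (31, 35, 32)
    n_transcripts: int = 200
    n_trend: int = 10
    trend_effect: float = 1.0
    nb_dispersion: float = 0.3
    length_range: tuple[int, int] = (200, 3000)
    lib_size: float = 1e6
    lib_size_log_sd: float = 0.3
    # eQTL validation dataset
    n_individuals_eqtl: int = 110
    n_snps: int = 2000  # MoM IBD needs thousands of SNPs for a tight null
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_true_eqtls_per_transcript: int = 2
    eqtl_beta: float = 0.5
    target_r2: float = 0.26
    serum_baseline: float = 4.0
    age_beta: float = 0.005
    gender_beta: float = 0.1
    frac_serum_flat: float = 0.2  # transcripts with zero serum MAD
    # association dataset
    n_cases: int = 540
    n_controls: int = 2397
    true_or_per_log2: float = 1.25
    cc_age_logor: float = 0.01
    cc_gender_logor: float = 0.3
    # population structure
    n_subpops: int = 1
    fst_like_divergence: float = 0.0

    def validate(self) -> "SimConfig":
        counts = [
            self.n_transcripts, self.n_snps, self.n_individuals_eqtl,
            self.n_cases, self.n_controls, self.n_subpops,
            *self.n_per_stage,
        ]
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be > 0")
        if self.n_trend > self.n_transcripts:
            raise ConfigError("n_trend cannot exceed n_transcripts")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 < self.target_r2 < 1:
            raise ConfigError("target_r2 must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.true_or_per_log2 <= 0:
            raise ConfigError("true_or_per_log2 must be positive")
        if self.fst_like_divergence < 0:
            raise ConfigError("fst_like_divergence must be >= 0")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    trend_transcript_ids: list[str] = field(default_factory=list)
    trend_directions: dict = field(default_factory=dict)  # id -> +1 / -1
    eqtl_map: dict = field(default_factory=dict)
    # transcript -> list of (snp_id, encoding, beta)
    true_or: float = 1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "trend_transcript_ids": self.trend_transcript_ids,
                    "trend_directions": self.trend_directions,
                    "eqtl_map": self.eqtl_map,
                    "true_or": self.true_or,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trend_transcript_ids=d["trend_transcript_ids"],
            trend_directions=d["trend_directions"],
            eqtl_map={k: [tuple(e) for e in v] for k, v in d["eqtl_map"].items()},
            true_or=d["true_or"],
        )

    def prediction_model(self, transcript_id: str) -> EqtlModel:
        """True eQTL effects as a prediction model (effect allele = ALT)."""
        terms = [
            EqtlTerm(snp_id=s, model=m, betas=[b], effect_is_alt=True)
            for s, m, b in self.eqtl_map[transcript_id]
        ]
        return EqtlModel(transcript_id=transcript_id, terms=terms, provenance="truth")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # crc32 keeps the stream label -> seed mapping stable across processes
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# Tissue counts
# ---------------------------------------------------------------------------

def gen_tissue_counts(cfg: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial staged counts with planted monotone log2 trends.

    Planted transcripts shift their stage-wise mean log2 abundance by
    +/- ``trend_effect`` per stage step (both directions represented);
    all remaining transcripts are stage-independent.
    """
    cfg.validate()
    rng = _rng(cfg, "tissue")
    t, stages = cfg.n_transcripts, cfg.n_per_stage
    tids = [f"LNC{i:05d}" for i in range(t)]
    sids = [f"T{i:04d}" for i in range(sum(stages))]
    stage_labels = pd.Series(
        np.repeat(list(STAGES), stages), index=sids
    )
    lengths = pd.Series(
        rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=t),
        index=tids,
    )
    base_log2 = rng.uniform(2.0, 10.0, size=t)
    trend_ids = list(rng.choice(t, size=cfg.n_trend, replace=False))
    directions = np.ones(cfg.n_trend)
    directions[1::2] = -1.0  # both directions represented

    stage_codes = np.repeat(np.arange(3), stages)
    log2_mean = np.tile(base_log2[:, None], (1, len(sids)))
    for k, ti in enumerate(trend_ids):
        log2_mean[ti] += directions[k] * cfg.trend_effect * stage_codes

    weights = (2.0**log2_mean) * lengths.to_numpy()[:, None]
    frac = weights / weights.sum(axis=0, keepdims=True)
    lib = cfg.lib_size * np.exp(
        rng.normal(0.0, cfg.lib_size_log_sd, size=len(sids))
    )
    mean = frac * lib[None, :]
    if cfg.nb_dispersion > 0:
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mean)
    values = pd.DataFrame(counts, index=tids, columns=sids)
    truth = SyntheticTruth(
        trend_transcript_ids=[tids[i] for i in trend_ids],
        trend_directions={
            tids[i]: int(directions[k]) for k, i in enumerate(trend_ids)
        },
        true_or=cfg.true_or_per_log2,
    )
    return CountMatrix(values, lengths, stage_labels), truth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def gen_genotypes(
    cfg: SimConfig,
    n_individuals: int | None = None,
    stream: str = "geno",
    prefix: str = "S",
) -> GenotypeMatrix:
    """Biallelic SNP genotypes under Hardy-Weinberg within subpopulations.

    Ancestral MAFs are drawn from ``maf_range``; with ``n_subpops > 1`` and
    positive ``fst_like_divergence`` F, subpopulation allele frequencies are
    Beta(p(1-F)/F, (1-p)(1-F)/F) perturbations (Balding-Nichols), which
    gives genetic PCA real structure.
    """
    cfg.validate()
    rng = _rng(cfg, stream)
    n = n_individuals if n_individuals is not None else cfg.n_individuals_eqtl
    m = cfg.n_snps
    sids = [f"{prefix}{i:05d}" for i in range(n)]
    snp_ids = [f"rs{i + 1:06d}" for i in range(m)]
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    subpop = rng.integers(0, cfg.n_subpops, size=n)
    f = cfg.fst_like_divergence
    if cfg.n_subpops > 1 and f > 0:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))
    dosages = rng.binomial(2, p_sub[subpop, :]).astype(float)

    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    info = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 5000,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        },
        index=snp_ids,
    )
    geno = GenotypeMatrix(
        pd.DataFrame(dosages, index=sids, columns=snp_ids), info
    )
    geno.subpop_labels = pd.Series(subpop, index=sids)  # extra attribute
    return geno


def gen_covariates(
    n: int,
    rng: np.random.Generator,
    sample_ids=None,
    n_pcs: int = 0,
) -> SampleCovariates:
    """Age/gender covariates; optional standard-normal stand-in PC scores."""
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "age": np.round(rng.normal(55.0, 10.0, size=n), 1),
            "gender": rng.integers(0, 2, size=n).astype(float),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    pcs = None
    if n_pcs > 0:
        pcs = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(n, n_pcs)),
            index=table.index,
            columns=[f"PC{i + 1}" for i in range(n_pcs)],
        )
    return SampleCovariates(table, pcs)


# ---------------------------------------------------------------------------
# Serum expression
# ---------------------------------------------------------------------------

_TRUTH_ENCODINGS = ("additive", "dominant")


def assign_eqtls(cfg: SimConfig, truth: SyntheticTruth, geno: GenotypeMatrix) -> None:
    """Plant ``n_true_eqtls_per_transcript`` eQTLs for every trend transcript.

    Encodings cycle additive -> dominant; effect signs alternate so both
    directions occur.  SNPs are drawn without replacement across transcripts.
    """
    rng = _rng(cfg, "eqtl-assign")
    needed = len(truth.trend_transcript_ids) * cfg.n_true_eqtls_per_transcript
    if needed > len(geno.snp_ids):
        raise ConfigError("not enough SNPs to plant the requested eQTLs")
    chosen = rng.choice(len(geno.snp_ids), size=needed, replace=False)
    snp_iter = iter(geno.snp_ids[chosen])
    for t in truth.trend_transcript_ids:
        entries = []
        for j in range(cfg.n_true_eqtls_per_transcript):
            enc = _TRUTH_ENCODINGS[j % len(_TRUTH_ENCODINGS)]
            # alternate sign and scale so predicted levels never collapse
            beta = cfg.eqtl_beta * (1.0 if j % 2 == 0 else -0.8)
            entries.append((str(next(snp_iter)), enc, float(beta)))
        truth.eqtl_map[t] = entries


def gen_serum_expression(
    geno: GenotypeMatrix,
    truth: SyntheticTruth,
    covars: SampleCovariates,
    cfg: SimConfig,
    stream: str = "serum",
) -> pd.DataFrame:
    """Serum log2 expression for every transcript with planted eQTLs.

    expression = sum beta * encoding(genotype) + age/gender effects +
    Gaussian noise whose variance is set so the SNP terms explain
    ``target_r2`` of the total variance (in expectation).
    """
    cfg.validate()
    rng = _rng(cfg, stream)
    if not truth.eqtl_map:
        raise ConfigError("truth has no planted eQTLs; call assign_eqtls first")
    cov = covars.table.reindex(geno.sample_ids)
    age_c = cov["age"].to_numpy() - cov["age"].mean()
    gender = cov["gender"].to_numpy()
    covar_signal = cfg.age_beta * age_c + cfg.gender_beta * gender
    var_covar = float(np.var(covar_signal))
    rows = {}
    for t, entries in truth.eqtl_map.items():
        signal = np.zeros(len(geno.sample_ids))
        for snp, enc_name, beta in entries:
            if snp not in set(geno.snp_ids):
                raise ConfigError(f"planted eQTL SNP {snp} missing from genotypes")
            enc = encode_penetrance(geno.dosages[snp].to_numpy(), enc_name)
            signal = signal + beta * enc[:, 0]
        var_snp = float(np.var(signal))
        if var_snp <= 0:
            raise ConfigError(
                f"target_r2={cfg.target_r2} unreachable for {t}: SNP terms "
                "have zero variance (all betas zero or monomorphic SNPs)"
            )
        var_noise = var_snp * (1.0 - cfg.target_r2) / cfg.target_r2 - var_covar
        if var_noise <= 0:
            raise ConfigError(
                "covariate effects too strong for the requested target_r2"
            )
        rows[t] = (
            cfg.serum_baseline
            + signal
            + covar_signal
            + rng.normal(0.0, np.sqrt(var_noise), size=len(signal))
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=geno.sample_ids)


def gen_serum_matrix(
    geno: GenotypeMatrix,
    truth: SyntheticTruth,
    covars: SampleCovariates,
    cfg: SimConfig,
    transcript_ids: list[str],
) -> pd.DataFrame:
    """Full serum matrix: eQTL-driven rows plus noise and flat rows.

    A ``frac_serum_flat`` share of the non-eQTL transcripts is constant
    (zero MAD) to exercise the serum-variability preselection criterion.
    """
    rng = _rng(cfg, "serum-extra")
    driven = gen_serum_expression(geno, truth, covars, cfg)
    others = [t for t in transcript_ids if t not in truth.eqtl_map]
    n_flat = int(round(cfg.frac_serum_flat * len(others)))
    flat = set(rng.choice(len(others), size=n_flat, replace=False))
    rows = {}
    for i, t in enumerate(others):
        if i in flat:
            rows[t] = np.full(len(geno.sample_ids), cfg.serum_baseline)
        else:
            rows[t] = cfg.serum_baseline + rng.normal(
                0.0, 1.0, size=len(geno.sample_ids)
            )
    extra = pd.DataFrame.from_dict(rows, orient="index", columns=geno.sample_ids)
    full = pd.concat([driven, extra])
    return full.reindex([t for t in transcript_ids if t in full.index])


# ---------------------------------------------------------------------------
# Case-control status
# ---------------------------------------------------------------------------

def gen_case_control(
    geno: GenotypeMatrix,
    eqtl_model: EqtlModel,
    covars: SampleCovariates,
    cfg: SimConfig,
    stream: str = "status",
) -> pd.Series:
    """Bernoulli case/control status from a logistic model on imputed
    expression, with the intercept calibrated so the expected number of
    cases equals ``n_cases``."""
    cfg.validate()
    rng = _rng(cfg, stream)
    pred = predict_expression(geno, eqtl_model)
    cov = covars.table.reindex(geno.sample_ids)
    lin = (
        np.log(cfg.true_or_per_log2) * pred.to_numpy()
        + cfg.cc_age_logor * (cov["age"].to_numpy() - 55.0)
        + cfg.cc_gender_logor * cov["gender"].to_numpy()
    )
    n = len(lin)
    target = cfg.n_cases / (cfg.n_cases + cfg.n_controls) * n

    def excess(alpha: float) -> float:
        return float(special.expit(alpha + lin).sum()) - target

    alpha = optimize.brentq(excess, -50.0, 50.0)
    status = rng.binomial(1, special.expit(alpha + lin))
    return pd.Series(status, index=geno.sample_ids, name="status")


# ---------------------------------------------------------------------------
# Candidate cis-eQTL table
# ---------------------------------------------------------------------------

def gen_candidate_table(
    truth: SyntheticTruth,
    geno: GenotypeMatrix,
    n_decoys: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """All true eQTL pairs plus ``n_decoys`` null SNP pairs per transcript."""
    rng = np.random.default_rng(seed)
    true_snps = {
        s for entries in truth.eqtl_map.values() for s, _, _ in entries
    }
    pool = [s for s in geno.snp_ids if s not in true_snps]
    if n_decoys > 0 and n_decoys * len(truth.eqtl_map) > len(pool):
        raise ConfigError("not enough decoy SNPs available")
    rows = []
    for t, entries in truth.eqtl_map.items():
        for s, _, _ in entries:
            rows.append((t, s))
        if n_decoys > 0:
            chosen = rng.choice(len(pool), size=n_decoys, replace=False)
            for c in chosen:
                rows.append((t, pool[c]))
    table = pd.DataFrame(rows, columns=["transcript_id", "snp_id"])
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
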