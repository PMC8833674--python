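"""Core data containers shared across pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Ordered disease-progression stages used as the trend factor.
STAGES = ("GS", "Dys", "GBC")

PENETRANCE_MODELS = ("additive", "three_genotype", "dominant", "recessive")


class ConfigError(ValueError):
    """Invalid configuration or generator parameters."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def stage_categorical(labels: Sequence[str]) -> pd.Categorical:
    """Return ``labels`` as an ordered categorical GS < Dys < GBC."""
    cat = pd.Categorical(labels, categories=list(STAGES), ordered=True)
    if cat.isna().any():
        bad = sorted(set(labels) - set(STAGES))
        raise DataError(f"unknown stage labels: {bad}")
    return cat


@dataclass
class CountMatrix:
    """Raw read counts, transcripts x samples, with transcript lengths (bp)."""

    values: pd.DataFrame  # transcripts x samples, non-negative integers
    lengths: pd.Series  # bp per transcript
    stage_labels: pd.Series  # per sample, ordered GS < Dys < GBC

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise DataError("negative counts")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise DataError("every transcript needs a positive length")
        self.stage_labels = pd.Series(
            stage_categorical(self.stage_labels.reindex(self.values.columns)),
            index=self.values.columns,
        )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


#: Forward-only normalization states of an expression matrix.
NORMALIZATION_STATES = ("raw-log2", "group-QN", "global-QN")


@dataclass
class ExpressionMatrix:
    """Log2 expression values, transcripts x samples."""

    values: pd.DataFrame
    stage_labels: pd.Series | None = None
    normalization_state: str = "raw-log2"

    def __post_init__(self) -> None:
        if self.normalization_state not in NORMALIZATION_STATES:
            raise DataError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        if self.stage_labels is not None:
            self.stage_labels = pd.Series(
                stage_categorical(self.stage_labels.reindex(self.values.columns)),
                index=self.values.columns,
            )

    def mad(self) -> pd.Series:
        """Per-transcript unscaled median absolute deviation."""
        x = self.values.to_numpy(dtype=float)
        med = np.median(x, axis=1, keepdims=True)
        return pd.Series(np.median(np.abs(x - med), axis=1), index=self.values.index)

    def advance_state(self, new_state: str) -> str:
        """Check the forward-only state transition and return ``new_state``."""
        order = {s: i for i, s in enumerate(NORMALIZATION_STATES)}
        if order[new_state] < order[self.normalization_state]:
            raise DataError(
                f"cannot move normalization state backwards: "
                f"{self.normalization_state} -> {new_state}"
            )
        return new_state

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GenotypeMatrix:
    """Effect(ALT)-allele dosages {0,1,2, NaN=missing}, samples x SNPs."""

    dosages: pd.DataFrame  # samples x SNPs, float with NaN for missing
    snp_info: pd.DataFrame  # index snp_id; columns chrom, pos, ref, alt

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        self.snp_info = self.snp_info.reindex(self.dosages.columns)
        if self.snp_info["pos"].isna().any():
            raise DataError("snp_info missing entries for some SNPs")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def alt_freq(self) -> pd.Series:
        """ALT allele frequency per SNP over non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.alt_freq()
        return pd.Series(np.minimum(p, 1.0 - p), index=p.index)

    def snp_call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def sample_call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=1)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        d = self.dosages
        if samples is not None:
            d = d.loc[list(samples)]
        if snps is not None:
            d = d[list(snps)]
        return GenotypeMatrix(d, self.snp_info.loc[d.columns])


@dataclass
class SampleCovariates:
    """Per-sample covariates entering every regression: age, gender, PCs."""

    table: pd.DataFrame  # index sample_id; columns age, gender
    pc_scores: pd.DataFrame | None = None  # index sample_id; PC1..PCk

    def design(self, sample_ids: Sequence[str], n_pcs: int = 10) -> pd.DataFrame:
        """Covariate design block (no intercept) aligned to ``sample_ids``."""
        cols = self.table.reindex(sample_ids)[["age", "gender"]].astype(float)
        if cols.isna().any().any():
            missing = cols.index[cols.isna().any(axis=1)].tolist()
            raise DataError(f"incomplete covariates for samples {missing[:5]}")
        if self.pc_scores is not None and n_pcs > 0:
            pcs = self.pc_scores.reindex(sample_ids).iloc[:, :n_pcs].astype(float)
            if pcs.isna().any().any():
                missing = pcs.index[pcs.isna().any(axis=1)].tolist()
                raise DataError(f"missing PC scores for samples {missing[:5]}")
            cols = pd.concat([cols, pcs], axis=1)
        return cols


@dataclass
class RobustFit:
    """Result of one Huber-IRLS linear regression."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    scale: float
    huber_c: float
    raic: float
    r2: float
    r2_adj: float
    n: int
    converged: bool
    cov: pd.DataFrame
    description: str = ""

    def conf_int(self, z: float = 1.959963984540054) -> pd.DataFrame:
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})


@dataclass
class EqtlTerm:
    """One SNP term of a prediction model: encoding plus fitted effect(s).

    ``betas`` has one entry for additive/dominant/recessive and two
    (heterozygote, homozygote) for the three-genotype encoding.
    ``effect_is_alt`` records the allele orientation chosen at validation
    time so the same encoding is reproducible in other genotype sets.
    """

    snp_id: str
    model: str
    betas: list[float]
    effect_is_alt: bool = True

    def __post_init__(self) -> None:
        if self.model not in PENETRANCE_MODELS:
            raise ConfigError(f"unknown penetrance model {self.model!r}")
        want = 2 if self.model == "three_genotype" else 1
        if len(self.betas) != want:
            raise ConfigError(
                f"{self.model} encoding takes {want} beta(s), got {len(self.betas)}"
            )

    @property
    def n_levels(self) -> int:
        return 2 if self.model in ("dominant", "recessive") else 3


@dataclass
class EqtlModel:
    """Validated SNP set with chosen encodings used for expression prediction."""

    transcript_id: str
    terms: list[EqtlTerm]
    provenance: str = ""

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "terms": [
                {
                    "snp_id": t.snp_id,
                    "model": t.model,
                    "betas": list(map(float, t.betas)),
                    "effect_is_alt": bool(t.effect_is_alt),
                }
                for t in self.terms
            ],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EqtlModel":
        return cls(
            transcript_id=d["transcript_id"],
            terms=[EqtlTerm(**t) for t in d["terms"]],
            provenance=d.get("provenance", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EqtlModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AssociationResult:
    """Robust logistic association of disease status with predicted expression."""

    transcript_id: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    huber_c: float
    n_cases: int
    n_controls: int
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.odds_ratio <= self.ci_upper):
            raise DataError("confidence interval does not bracket the odds ratio")
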