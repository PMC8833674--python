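"""Genotype quality control: SNP/sample filters, method-of-moments IBD
kinship, relatedness and LD pruning, eigenstrat-normalized genetic PCA and
depth-based sample exclusion."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from geno2lnc._depth import lowest_depth_exclusion, mahalanobis_depth
from geno2lnc.datatypes import DataError, GenotypeMatrix


@dataclass
class QcReport:
    n_snps_in: int = 0
    n_snps_kept: int = 0
    n_samples_in: int = 0
    n_samples_kept: int = 0
    snps_removed_maf: list = field(default_factory=list)
    snps_removed_callrate: list = field(default_factory=list)
    samples_removed_callrate: list = field(default_factory=list)


def snp_sample_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_callrate_min: float = 0.95,
    sample_callrate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs by MAF/call rate, then samples by call rate (in that order)."""
    report = QcReport(
        n_snps_in=len(geno.snp_ids), n_samples_in=len(geno.sample_ids)
    )
    maf = geno.maf()
    snp_cr = geno.snp_call_rate()
    low_maf = maf < maf_min
    low_cr = snp_cr < snp_callrate_min
    report.snps_removed_maf = geno.snp_ids[low_maf].tolist()
    report.snps_removed_callrate = geno.snp_ids[~low_maf & low_cr].tolist()
    kept_snps = geno.snp_ids[~(low_maf | low_cr)]
    filtered = geno.subset(snps=kept_snps)

    sample_cr = filtered.sample_call_rate()
    bad_samples = sample_cr < sample_callrate_min
    report.samples_removed_callrate = filtered.sample_ids[bad_samples].tolist()
    filtered = filtered.subset(samples=filtered.sample_ids[~bad_samples])

    report.n_snps_kept = len(filtered.snp_ids)
    report.n_samples_kept = len(filtered.sample_ids)
    if report.n_snps_kept == 0 or report.n_samples_kept == 0:
        raise DataError("no SNPs or samples survive the QC filters")
    return filtered, report


@dataclass
class KinshipEstimate:
    """Pairwise IBD coefficients (PI-HAT-like): P(IBD=2) + P(IBD=1)/2."""

    coefficients: pd.DataFrame  # symmetric samples x samples
    unreliable_pairs: list = field(default_factory=list)

    def pairs_above(self, threshold: float) -> list[tuple[str, str]]:
        ids = self.coefficients.index
        out = []
        for i, j in combinations(range(len(ids)), 2):
            if self.coefficients.iat[i, j] > threshold:
                out.append((ids[i], ids[j]))
        return out


def ibd_kinship(geno: GenotypeMatrix, min_joint_snps: int = 50) -> KinshipEstimate:
    """PLINK-style method-of-moments IBD from IBS counts.

    Per SNP with allele frequency p (q = 1 - p), the IBS-class probabilities
    conditional on the IBD state are
        P(IBS0 | IBD0) = 2 p^2 q^2
        P(IBS1 | IBD0) = 4 p^3 q + 4 p q^3
        P(IBS2 | IBD0) = p^4 + q^4 + 4 p^2 q^2
        P(IBS1 | IBD1) = 2 p q          P(IBS2 | IBD1) = 1 - 2 p q
        P(IBS2 | IBD2) = 1.
    The observed IBS counts are equated to their expectations in the order
    P(IBD=0), P(IBD=1), P(IBD=2); the coefficient is P2 + P1/2 in [0, 1].
    """
    m = len(geno.snp_ids)
    if m < 100:
        warnings.warn(f"ibd_kinship on {m} SNPs; >= 100 recommended", stacklevel=2)
    dos = geno.dosages.to_numpy(dtype=float)
    valid = ~np.isnan(dos)
    p = np.nanmean(dos, axis=0) / 2.0
    q = 1.0 - p
    c0_ibd0 = 2.0 * p**2 * q**2
    c1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    c2_ibd0 = 1.0 - c0_ibd0 - c1_ibd0
    c1_ibd1 = 2.0 * p * q
    c2_ibd1 = 1.0 - c1_ibd1

    ind = {v: ((dos == v) & valid).astype(float) for v in (0.0, 1.0, 2.0)}
    vmask = valid.astype(float)

    n_joint = vmask @ vmask.T
    n_ibs2 = sum(ind[v] @ ind[v].T for v in (0.0, 1.0, 2.0))
    n_ibs0 = ind[0.0] @ ind[2.0].T + ind[2.0] @ ind[0.0].T
    n_ibs1 = n_joint - n_ibs2 - n_ibs0

    def pair_expect(coef: np.ndarray) -> np.ndarray:
        w = vmask * coef[None, :]
        return w @ vmask.T

    e0_0 = pair_expect(c0_ibd0)
    e1_0 = pair_expect(c1_ibd0)
    e2_0 = pair_expect(c2_ibd0)
    e1_1 = pair_expect(c1_ibd1)
    e2_1 = pair_expect(c2_ibd1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = n_ibs0 / e0_0
        p1 = (n_ibs1 - p0 * e1_0) / e1_1
        p2 = (n_ibs2 - p0 * e2_0 - p1 * e2_1) / n_joint
    coef = np.clip(p2 + 0.5 * p1, 0.0, 1.0)
    np.fill_diagonal(coef, 1.0)

    ids = geno.sample_ids
    unreliable = [
        (ids[i], ids[j])
        for i, j in combinations(range(len(ids)), 2)
        if n_joint[i, j] < min_joint_snps
    ]
    return KinshipEstimate(
        coefficients=pd.DataFrame(coef, index=ids, columns=ids),
        unreliable_pairs=unreliable,
    )


def relatedness_prune(
    kin: KinshipEstimate, geno: GenotypeMatrix, threshold: float = 0.1
) -> pd.Index:
    """Greedy removal of related samples.

    While any kept pair exceeds ``threshold``, drop the member with the
    lower call rate (ties: the lexicographically smaller id is dropped).
    """
    call_rate = geno.sample_call_rate()
    kept = set(map(str, geno.sample_ids))
    while True:
        worst = None
        for a, b in kin.pairs_above(threshold):
            if a in kept and b in kept:
                coef = kin.coefficients.loc[a, b]
                if worst is None or coef > worst[0]:
                    worst = (coef, a, b)
        if worst is None:
            break
        _, a, b = worst
        ca, cb = call_rate[a], call_rate[b]
        if ca < cb:
            kept.discard(a)
        elif cb < ca:
            kept.discard(b)
        else:
            kept.discard(min(a, b))
    return pd.Index([s for s in geno.sample_ids if s in kept])


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared genotype correlation; missing values mean-imputed per SNP."""
    x = dos.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_at = np.isnan(x)
    x[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    corr = (x.T @ x) / len(x) / np.outer(sd, sd)
    return corr**2


def ld_prune(
    geno: GenotypeMatrix,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 5,
) -> pd.Index:
    """Sliding-window greedy LD pruning.

    Within each window, while any kept pair has r^2 above ``r2_max``, the
    lower-MAF SNP of the worst pair is dropped (ties: later position
    dropped).  The surviving set has no within-window pair above the
    threshold.
    """
    maf = geno.maf()
    info = geno.snp_info
    dropped: set[str] = set()
    for chrom in pd.unique(info["chrom"]):
        snps = info.index[info["chrom"] == chrom]
        snps = snps[np.argsort(info.loc[snps, "pos"].to_numpy(), kind="stable")]
        m = len(snps)
        start = 0
        while start < m:
            win = [s for s in snps[start : start + window] if s not in dropped]
            while len(win) > 1:
                dos = geno.dosages[win].to_numpy(dtype=float)
                r2 = _pairwise_r2(dos)
                np.fill_diagonal(r2, 0.0)
                r2 = np.nan_to_num(r2)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                a, b = win[i], win[j]
                if maf[a] < maf[b]:
                    loser = a
                elif maf[b] < maf[a]:
                    loser = b
                else:
                    loser = a if info.loc[a, "pos"] > info.loc[b, "pos"] else b
                dropped.add(loser)
                win.remove(loser)
            if start + window >= m:
                break
            start += step
    return pd.Index([s for s in geno.snp_ids if s not in dropped])


@dataclass
class GeneticPCs:
    scores: pd.DataFrame  # samples x PCs, centered
    eigenvalues: np.ndarray
    depth: pd.Series | None = None


def genetic_pca(geno: GenotypeMatrix, k: int = 10) -> GeneticPCs:
    """Genetic PCA with eigenstrat normalization.

    Each SNP column is centered by 2*p_hat and scaled by sqrt(2*p_hat*(1 -
    p_hat)); missing genotypes become 0 after centering (mean imputation).
    Scores are the top-k left singular vectors scaled by singular values;
    the sign convention makes the largest-magnitude score positive.
    """
    n = len(geno.sample_ids)
    if k >= n:
        raise DataError(f"k={k} PCs require more than {n} samples")
    dos = geno.dosages.to_numpy(dtype=float)
    p_hat = np.nanmean(dos, axis=0) / 2.0
    usable = (p_hat > 0) & (p_hat < 1)
    dos = dos[:, usable]
    p_hat = p_hat[usable]
    norm = (dos - 2.0 * p_hat[None, :]) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))[None, :]
    norm = np.nan_to_num(norm, nan=0.0)
    norm = norm - norm.mean(axis=0)  # exact column centering after imputation
    u, s, _ = np.linalg.svd(norm, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1.0
    eigenvalues = (s[:k] ** 2) / max(norm.shape[1], 1)
    return GeneticPCs(
        scores=pd.DataFrame(
            scores, index=geno.sample_ids, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eigenvalues,
    )


def depth_exclude_genetic(pcs: GeneticPCs, frac: float = 0.05) -> pd.Index:
    """Drop the ``frac`` lowest-Mahalanobis-depth samples in genetic PC space."""
    depth = mahalanobis_depth(pcs.scores.to_numpy())
    pcs.depth = pd.Series(depth, index=pcs.scores.index, name="depth")
    keep = lowest_depth_exclusion(depth, frac)
    return pcs.scores.index[keep]
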