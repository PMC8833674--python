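"""Expression preprocessing: log2-TPM, MAD filtering, quantile normalization
and depth-based exclusion of outlying samples."""

from __future__ import annotations

import numpy as np
import pandas as pd

from geno2lnc._depth import lowest_depth_exclusion, mahalanobis_depth
from geno2lnc.datatypes import (
    CountMatrix,
    DataError,
    ExpressionMatrix,
)


def counts_to_log2tpm(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Transform read counts to log2(TPM + pseudocount).

    TPM for transcript t in sample s is the length-normalized count rate
    rescaled so every sample column sums to 1e6 before the log.
    """
    raw = counts.values.to_numpy(dtype=float)
    length_kb = counts.lengths.to_numpy(dtype=float) / 1000.0
    rate = raw / length_kb[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        bad = counts.sample_ids[zero].tolist()
        raise DataError(f"sample(s) with all-zero counts: {bad}")
    tpm = rate / colsum[None, :] * 1e6
    values = pd.DataFrame(
        np.log2(tpm + pseudocount), index=counts.transcript_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(values, counts.stage_labels, "raw-log2")


def mad_filter(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Index]:
    """Drop transcripts with zero (unscaled) median absolute deviation.

    Returns the filtered matrix and the excluded transcript ids.
    """
    mad = expr.mad()
    keep = mad > 0
    excluded = expr.transcript_ids[~keep]
    filtered = ExpressionMatrix(
        expr.values.loc[keep], expr.stage_labels, expr.normalization_state
    )
    return filtered, excluded


def _qn_block(block: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``block`` in place of a copy.

    Every column's sorted values are replaced by the across-column mean of
    order statistics; ties within a column receive the mean of the reference
    values at their tied ranks.
    """
    t, n = block.shape
    order = np.argsort(block, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(block, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(block)
    for j in range(n):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [t]])
        for a, b in zip(starts, stops):
            if b - a > 1:
                assigned[a:b] = reference[a:b].mean()
        out[order[:, j], j] = assigned
    return out


def quantile_normalize(
    expr: ExpressionMatrix, groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Quantile-normalize sample columns, optionally within label groups.

    ``groups=None`` normalizes all samples as one block (the global pass);
    otherwise each group of samples is normalized separately.  Applying the
    grouped pass followed by the global pass reproduces the two-pass scheme.
    """
    values = expr.values.to_numpy(dtype=float).copy()
    if groups is None:
        blocks = {"all": np.arange(values.shape[1])}
        new_state = expr.advance_state("global-QN")
    else:
        groups = pd.Series(groups).reindex(expr.sample_ids)
        blocks = {
            g: np.flatnonzero((groups == g).to_numpy())
            for g in groups.dropna().unique()
        }
        new_state = expr.advance_state("group-QN")
    for name, idx in blocks.items():
        if len(idx) < 2:
            raise DataError(f"quantile normalization block {name!r} has < 2 samples")
        values[:, idx] = _qn_block(values[:, idx])
    out = pd.DataFrame(values, index=expr.transcript_ids, columns=expr.sample_ids)
    return ExpressionMatrix(out, expr.stage_labels, new_state)


def pca_depth_exclude(
    expr: ExpressionMatrix, frac: float = 0.05, k_pcs: int | None = None
) -> tuple[pd.Index, pd.DataFrame, pd.Series]:
    """Exclude the ``frac`` lowest-Mahalanobis-depth samples in PC space.

    PCA is run on sample expression profiles (samples as observations);
    the depth 1/(1 + d^2) is computed on the first ``k_pcs`` PC scores and
    ``round_half_up(frac * n)`` samples with the lowest depth are dropped.

    Returns (kept sample ids, PC scores, depth per sample).
    """
    x = expr.values.to_numpy(dtype=float).T  # samples x transcripts
    n = x.shape[0]
    if k_pcs is None:
        k_pcs = min(10, n - 1)
    if n < k_pcs + 1:
        raise DataError(f"need at least {k_pcs + 1} samples for {k_pcs} PCs")
    centered = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k_pcs] * s[:k_pcs]
    if np.any(s[:k_pcs] <= s[0] * 1e-12):
        raise DataError("singular PC covariance; use fewer PCs")
    depth = mahalanobis_depth(scores)
    keep = lowest_depth_exclusion(depth, frac)
    kept_ids = expr.sample_ids[keep]
    scores_df = pd.DataFrame(
        scores,
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k_pcs)],
    )
    return kept_ids, scores_df, pd.Series(depth, index=expr.sample_ids, name="depth")
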