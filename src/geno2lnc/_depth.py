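"""Mahalanobis depth and depth-based sample exclusion (shared helper)."""

from __future__ import annotations

import math

import numpy as np

from geno2lnc.datatypes import DataError


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def mahalanobis_depth(scores: np.ndarray) -> np.ndarray:
    """Depth 1 / (1 + d^2) with d the Mahalanobis distance of each row.

    Mean and covariance are estimated from ``scores`` itself.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n, k = scores.shape
    if n <= k:
        raise DataError(
            f"covariance of {k} dimensions from {n} points is singular; "
            "use fewer PCs"
        )
    centered = scores - scores.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    try:
        sol = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DataError("singular PC covariance; use fewer PCs") from exc
    d2 = np.einsum("ij,ji->i", centered, sol)
    return 1.0 / (1.0 + d2)


def lowest_depth_exclusion(depth: np.ndarray, frac: float) -> np.ndarray:
    """Boolean keep-mask after excluding round_half_up(frac*n) lowest-depth rows.

    Ties broken by position (earlier rows kept preferentially).
    """
    if not 0.0 <= frac < 1.0:
        raise DataError("exclusion fraction must be in [0, 1)")
    n = len(depth)
    n_excl = round_half_up(frac * n)
    keep = np.ones(n, dtype=bool)
    if n_excl == 0:
        return keep
    order = np.argsort(depth, kind="stable")  # lowest depth first
    keep[order[:n_excl]] = False
    return keep
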