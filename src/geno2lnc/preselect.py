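"""Trend-based transcript preselection.

Permutation Jonckheere-Terpstra tests across the ordered stages, BH false
discovery rates, a boosted-tree three-class importance screen, and the
four-way candidate funnel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold

from geno2lnc.datatypes import DataError, ExpressionMatrix, stage_categorical


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------

def jt_statistic(values, stage_labels) -> float:
    """Jonckheere-Terpstra statistic over ordered groups.

    JT = sum over ordered group pairs (g < h) of the number of cross pairs
    with x_g < x_h, counting ties as 1/2.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(stage_categorical(list(stage_labels)).codes)
    present = np.unique(codes)
    if len(present) < 2:
        raise DataError("Jonckheere-Terpstra needs at least two non-empty groups")
    total = 0.0
    for gi in range(len(present)):
        for hi in range(gi + 1, len(present)):
            xg = values[codes == present[gi]]
            xh = values[codes == present[hi]]
            less = (xg[:, None] < xh[None, :]).sum()
            ties = (xg[:, None] == xh[None, :]).sum()
            total += less + 0.5 * ties
    return float(total)


def jt_null_mean(stage_labels) -> float:
    """Null expectation E[JT] = (N^2 - sum n_g^2) / 4."""
    codes = np.asarray(stage_categorical(list(stage_labels)).codes)
    n = len(codes)
    sizes = np.bincount(codes)
    return (n * n - float((sizes.astype(float) ** 2).sum())) / 4.0


def _jt_all_rows(values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """JT statistic for every row of ``values`` at once.

    Uses the pairwise-comparison tensor C[t,i,j] = 1(x_ti < x_tj) + 0.5 ties,
    so a permutation of the labels only changes the (i, j) mask.
    """
    comp = _comparison_tensor(values)
    mask = (codes[:, None] < codes[None, :]).astype(float).ravel()
    return comp @ mask


def _comparison_tensor(values: np.ndarray) -> np.ndarray:
    t, n = values.shape
    less = (values[:, :, None] < values[:, None, :]).astype(float)
    ties = (values[:, :, None] == values[:, None, :]).astype(float)
    np.einsum("tii->ti", ties)[:] = 0.0  # self pairs never count
    return (less + 0.5 * ties).reshape(t, n * n)


@dataclass
class TrendTestResult:
    transcript_id: str
    jt_statistic: float
    jt_expected: float
    p_value: float
    fdr: float
    direction: str  # "increasing" | "decreasing"


def jt_permutation_test(
    expr: ExpressionMatrix | pd.DataFrame,
    stage_labels: pd.Series | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    perm_block: int = 500,
) -> list[TrendTestResult]:
    """Two-sided permutation J-T test for every transcript.

    The two-sided p-value is (1 + #{perm : |JT_perm - E| >= |JT_obs - E|})
    / (n_perm + 1); one shared stream of label permutations is used for all
    transcripts.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    if isinstance(expr, ExpressionMatrix):
        values = expr.values
        stage_labels = expr.stage_labels
    else:
        values = expr
    codes = np.asarray(stage_categorical(list(stage_labels)).codes)
    if len(np.unique(codes)) < 2:
        raise DataError("need at least two non-empty stages")
    x = values.to_numpy(dtype=float)
    t, n = x.shape
    comp = _comparison_tensor(x)
    obs = comp @ (codes[:, None] < codes[None, :]).astype(float).ravel()
    expected = jt_null_mean(stage_labels)
    obs_dev = np.abs(obs - expected)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(t, dtype=np.int64)
    done = 0
    while done < n_perm:
        block = min(perm_block, n_perm - done)
        masks = np.empty((n * n, block))
        for b in range(block):
            perm = rng.permutation(codes)
            masks[:, b] = (perm[:, None] < perm[None, :]).ravel()
        jt_perm = comp @ masks  # t x block
        exceed += (np.abs(jt_perm - expected) >= obs_dev[:, None] - 1e-9).sum(axis=1)
        done += block
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    fdrs = bh_fdr(pvals)
    results = []
    for i, tid in enumerate(values.index):
        direction = "increasing" if obs[i] >= expected else "decreasing"
        results.append(
            TrendTestResult(
                transcript_id=str(tid),
                jt_statistic=float(obs[i]),
                jt_expected=float(expected),
                p_value=float(pvals[i]),
                fdr=float(fdrs[i]),
                direction=direction,
            )
        )
    return results


def trend_results_frame(results: list[TrendTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "jt_statistic": [r.jt_statistic for r in results],
            "jt_expected": [r.jt_expected for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("transcript_id")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Boosted-tree stage classifier
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Relative feature importances (max scaled to 1) and model metrics."""

    importances: pd.Series  # transcript_id -> relative importance in [0, 1]
    auc: float  # test-set weighted one-vs-rest AUC
    mean_per_class_error: float
    cv_folds: int
    seed: int
    best_params: dict


_DEFAULT_GRID = {
    "n_estimators": [50, 100, 200],
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.3],
    "subsample": [0.7, 1.0],
}


def _mean_per_class_error(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    errs = []
    for c in classes:
        mask = y_true == c
        if mask.sum() == 0:
            continue
        errs.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(errs))


def _upsample_balanced(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Upsample each class (with replacement) to the majority-class count."""
    classes, counts = np.unique(y[idx], return_counts=True)
    target = counts.max()
    chosen = []
    for c in classes:
        members = idx[y[idx] == c]
        chosen.append(members)
        extra = target - len(members)
        if extra > 0:
            chosen.append(rng.choice(members, size=extra, replace=True))
    out = np.concatenate(chosen)
    rng.shuffle(out)
    return out


def train_stage_classifier(
    expr: ExpressionMatrix,
    stage_labels: pd.Series | None = None,
    split_frac: float = 0.8,
    cv_folds: int = 5,
    grid_size: int = 10,
    seed: int = 0,
    param_grid: dict | None = None,
) -> ImportanceTable:
    """Three-class gradient-boosting screen over transcripts.

    Protocol: stratified train/test split, training classes balanced by
    upsampling with replacement to the majority count, random grid search
    tuned by k-fold CV on mean per-class error, best model refit on the
    balanced training set, test metrics (weighted one-vs-rest AUC, mean
    per-class error) and per-feature relative importance scaled to max 1.
    """
    if stage_labels is None:
        stage_labels = expr.stage_labels
    x = expr.values.to_numpy(dtype=float).T  # samples x transcripts
    y = np.asarray(stage_categorical(list(stage_labels.reindex(expr.sample_ids))).codes)
    classes = np.unique(y)
    if len(classes) < 3:
        raise DataError("stage classifier needs all three classes present")
    rng = np.random.default_rng(seed)

    # stratified split
    train_idx, test_idx = [], []
    for c in classes:
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        n_train = max(1, int(round(split_frac * len(members))))
        n_train = min(n_train, len(members) - 1)
        train_idx.append(members[:n_train])
        test_idx.append(members[n_train:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    if len(np.unique(y[train_idx])) < 3:
        raise DataError("a class is absent from the training split")

    balanced = _upsample_balanced(train_idx, y, rng)
    xb, yb = x[balanced], y[balanced]

    grid = param_grid or _DEFAULT_GRID
    sampler = ParameterSampler(grid, n_iter=grid_size, random_state=int(rng.integers(2**31)))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    best_score, best_params = np.inf, None
    for params in sampler:
        fold_errs = []
        for tr, va in skf.split(xb, yb):
            model = GradientBoostingClassifier(random_state=seed, **params)
            model.fit(xb[tr], yb[tr])
            fold_errs.append(_mean_per_class_error(yb[va], model.predict(xb[va]), classes))
        score = float(np.mean(fold_errs))
        if score < best_score:
            best_score, best_params = score, params

    best = GradientBoostingClassifier(random_state=seed, **best_params)
    best.fit(xb, yb)

    proba = best.predict_proba(x[test_idx])
    auc = float(
        roc_auc_score(y[test_idx], proba, multi_class="ovr", average="weighted")
    )
    mpce = _mean_per_class_error(y[test_idx], best.predict(x[test_idx]), classes)

    raw = best.feature_importances_
    if raw.max() > 0:
        rel = raw / raw.max()
    else:  # pragma: no cover - degenerate model
        rel = raw
    importances = pd.Series(rel, index=expr.transcript_ids, name="relative_importance")
    importances = importances.sort_values(ascending=False)
    return ImportanceTable(
        importances=importances,
        auc=auc,
        mean_per_class_error=mpce,
        cv_folds=cv_folds,
        seed=seed,
        best_params=dict(best_params),
    )


# ---------------------------------------------------------------------------
# Candidate funnel
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    selected: pd.Index
    criteria: pd.DataFrame  # pass/fail per criterion, indexed by transcript id


def select_candidates(
    trend: list[TrendTestResult] | pd.DataFrame,
    importance: ImportanceTable,
    serum_expr: ExpressionMatrix,
    candidate_table: pd.DataFrame,
    annotation: pd.Series | None = None,
    fdr_max: float = 0.05,
) -> CandidateSet:
    """Apply the four preselection criteria.

    (i) trend FDR < ``fdr_max`` and relative importance above the median of
    nonzero model importances, (ii) annotated and not duplicated, (iii)
    nonzero MAD in the serum expression matrix, (iv) present in the
    candidate cis-eQTL table.
    """
    if not isinstance(trend, pd.DataFrame):
        trend = trend_results_frame(trend)
    ids = trend.index
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DataError(f"duplicated transcript ids in trend results: {dups[:5]}")

    nonzero = importance.importances[importance.importances > 0]
    imp_cut = float(nonzero.median()) if len(nonzero) else np.inf
    imp = importance.importances.reindex(ids).fillna(0.0)

    crit_i = (trend["fdr"] < fdr_max) & (imp > imp_cut)

    if annotation is None:
        annotation = pd.Series(True, index=ids)
    annotated = annotation.reindex(ids).fillna(False).astype(bool)
    crit_ii = annotated  # duplication already rejected above

    serum_mad = serum_expr.mad().reindex(ids)
    crit_iii = (serum_mad > 0).fillna(False)

    in_table = ids.isin(pd.Index(candidate_table["transcript_id"].unique()))
    crit_iv = pd.Series(in_table, index=ids)

    criteria = pd.DataFrame(
        {
            "crit_i_trend_and_importance": crit_i,
            "crit_ii_annotated_unique": crit_ii,
            "crit_iii_serum_mad": crit_iii,
            "crit_iv_in_candidate_table": crit_iv,
        }
    )
    criteria["selected"] = criteria.all(axis=1)
    selected = criteria.index[criteria["selected"]]
    return CandidateSet(selected=selected, criteria=criteria)
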