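"""L1-regularized logistic regression with cross-validated AUC model selection.

The classifier minimizes, at each penalty value on a descending grid,

    (1/n) sum_i log(1 + exp(-y_i (x_i . w + b)))  +  lambda * ||w||_1

with the intercept unpenalized.  The path is solved by accelerated proximal
gradient descent (FISTA) with warm starts down the grid; the soft-threshold
proximal step yields exact zeros, so at lambda >= lambda_max =
max_j |X^T (y - ybar)| / n the fit is exactly the null model.

Model selection follows the cross-validated-AUC convention: stratified
k-fold splits fixed by seed; per lambda the AUC of the held-out predictions
pooled over folds; per-fold AUCs provide the standard error for the 1-SE
rule.  Both the AUC-maximizing lambda and the largest lambda within one
standard error of the maximum are reported; argmax ties break toward the
larger (sparser) lambda.

Features are standardized (z-scored) separately within each dataset before
model construction, and a fitted model stores those parameters so external
cohorts are standardized dataset-locally at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("nucmorph")

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# standardization

def standardize(
    table: pd.DataFrame,
    dataset_ids: pd.Series | None = None,
    scope: str = "per-dataset",
) -> tuple[pd.DataFrame, dict]:
    """Z-score feature columns, by default separately within each dataset.

    Zero-variance columns map to zeros and are flagged in the returned
    parameter dict.  Returns (standardized table, params) where params maps
    dataset id (or "__global__") to per-column means and SDs.
    """
    if scope not in ("per-dataset", "global"):
        raise ValueError(f"unknown standardization scope: {scope}")
    if scope == "global" or dataset_ids is None:
        groups = {"__global__": table.index}
    else:
        ids = pd.Series(dataset_ids, index=table.index)
        groups = {str(k): idx for k, idx in table.groupby(ids).groups.items()}
    out = table.copy().astype(float)
    params: dict = {"scope": scope, "datasets": {}}
    for key, idx in groups.items():
        sub = table.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"dataset {key!r} has fewer than 2 patients")
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        flagged = [c for c in table.columns if sd[c] == 0]
        sd_safe = sd.replace(0.0, 1.0)
        z = (sub - mean) / sd_safe
        z[flagged] = 0.0
        out.loc[idx] = z
        params["datasets"][key] = {
            "mean": mean.to_dict(), "sd": sd.to_dict(), "zero_variance": flagged,
        }
        if flagged:
            logger.warning("standardize: %d zero-variance columns in %s", len(flagged), key)
    return out, params


def apply_standardization(table: pd.DataFrame, params: dict,
                          dataset_ids: pd.Series | None = None) -> pd.DataFrame:
    """Standardize new data with stored parameters (dataset-local scope).

    Datasets not seen at fit time are z-scored with their own statistics,
    mirroring the per-dataset standardization convention.
    """
    if params["scope"] == "global" or dataset_ids is None:
        known = params["datasets"].get("__global__")
        if known is not None:
            mean = pd.Series(known["mean"])[table.columns]
            sd = pd.Series(known["sd"])[table.columns].replace(0.0, 1.0)
            out = (table - mean) / sd
            out[known["zero_variance"]] = 0.0
            return out
        return standardize(table, None, "global")[0]
    ids = pd.Series(dataset_ids, index=table.index)
    out = table.copy().astype(float)
    for key, idx in table.groupby(ids).groups.items():
        known = params["datasets"].get(str(key))
        sub = table.loc[idx]
        if known is not None:
            mean = pd.Series(known["mean"])[table.columns]
            sd = pd.Series(known["sd"])[table.columns].replace(0.0, 1.0)
            z = (sub - mean) / sd
            z[known["zero_variance"]] = 0.0
            out.loc[idx] = z
        else:
            out.loc[idx] = standardize(sub, None, "global")[0]
    return out


# ---------------------------------------------------------------------------
# path solver

@dataclass
class RegularizationPath:
    """Solutions of the L1 path on a strictly decreasing lambda grid."""

    lambdas: np.ndarray          # descending
    intercepts: np.ndarray       # (L,)
    coefs: np.ndarray            # (L, p)
    n_active: np.ndarray         # (L,) nonzero-weight counts

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the null model is optimal (KKT bound)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                     min_ratio: float = 0.01) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def _fista(X: np.ndarray, y01: np.ndarray, lam: float, w0: np.ndarray, b0: float,
           lipschitz: float, tol: float = 1e-7, max_iter: int = 2000) -> tuple[np.ndarray, float]:
    """Accelerated proximal gradient for the penalized mean logistic loss."""
    n = len(y01)
    w, b = w0.copy(), float(b0)
    zw, zb = w.copy(), b
    t = 1.0
    step = 1.0 / lipschitz
    for _ in range(max_iter):
        eta = X @ zw + zb
        p = 1.0 / (1.0 + np.exp(-eta))
        resid = (p - y01) / n
        grad_w = X.T @ resid
        grad_b = resid.sum()
        w_new = zw - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = zb - step * grad_b
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        zw = w_new + (t - 1.0) / t_new * (w_new - w)
        zb = b_new + (t - 1.0) / t_new * (b_new - b)
        delta = max(np.max(np.abs(w_new - w)), abs(b_new - b))
        w, b, t = w_new, b_new, t_new
        if delta <= tol:
            break
    # Newton polish of the unpenalized intercept (its gradient direction is
    # much flatter than the step size suggests, so FISTA leaves it behind)
    eta = X @ w
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(eta + b)))
        g = float(np.mean(p - y01))
        h = float(np.mean(p * (1.0 - p)))
        if h <= 1e-12:
            break
        step_b = g / h
        b -= step_b
        if abs(step_b) <= 1e-12:
            break
    return w, b


def _sub_lipschitz(X_sub: np.ndarray, upper: float) -> float:
    """Lipschitz constant of the subproblem gradient, by power iteration.

    A 1.05 safety factor keeps the estimate an upper bound in practice;
    ``upper`` (the full-matrix constant) caps it.
    """
    n, m = X_sub.shape
    aug = np.hstack([X_sub, np.ones((n, 1))])
    v = np.ones(m + 1) / np.sqrt(m + 1)
    s = upper * 4.0 * n
    for _ in range(8):
        u = aug @ v
        v = aug.T @ u
        s = float(np.linalg.norm(v))
        if s == 0:
            return upper
        v /= s
    return min(1.05 * s / (4.0 * n), upper)


def _solve_active_set(X: np.ndarray, y01: np.ndarray, lam: float,
                      w0: np.ndarray, b0: float, lipschitz: float,
                      tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    """Solve one penalty value by FISTA restricted to an active set.

    The subproblem is solved on the columns currently nonzero (or KKT-
    violating), then the KKT conditions are re-checked on *all* columns and
    violators are added until none remain — so the returned solution
    satisfies the full-problem optimality conditions at the tolerance.
    """
    n, p = X.shape
    w, b = w0.copy(), float(b0)
    resid = 1.0 / (1.0 + np.exp(-(X @ w + b))) - y01
    grad = X.T @ resid / n
    active = (w != 0) | (np.abs(grad) > lam)
    if not active.any():
        active[np.argmax(np.abs(grad))] = True
    for _ in range(50):
        idx = np.flatnonzero(active)
        X_sub = X[:, idx]
        w_sub, b = _fista(X_sub, y01, lam, w[idx], b,
                          _sub_lipschitz(X_sub, lipschitz),
                          tol=tol, max_iter=max_iter)
        w = np.zeros(p)
        w[idx] = w_sub
        resid = 1.0 / (1.0 + np.exp(-(X @ w + b))) - y01
        grad = X.T @ resid / n
        violators = (~active) & (np.abs(grad) > lam * (1.0 + 1e-9) + 10 * tol)
        if not violators.any():
            break
        active |= violators
    return w, b


def l1_logistic_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                     tol: float = 1e-7, max_iter: int = 2000) -> RegularizationPath:
    """Solve the penalized logistic problem at every lambda, warm-started."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must be binary 0/1 with both classes present")
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0):
        raise ValueError("lambda must be nonnegative")
    n, p = X.shape
    ones = np.ones((n, 1))
    lipschitz = float(np.linalg.norm(np.hstack([X, ones]), 2) ** 2) / (4.0 * n)
    ybar = y.mean()
    w = np.zeros(p)
    b = float(np.log(ybar / (1.0 - ybar)))
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    lmax = lambda_max(X, y)
    for k, lam in enumerate(lambdas):
        if lam >= lmax and np.all(w == 0):
            # KKT: null model is exactly optimal; refresh the null intercept
            b = float(np.log(ybar / (1.0 - ybar)))
        else:
            w, b = _solve_active_set(X, y, lam, w, b, lipschitz,
                                     tol=tol, max_iter=max_iter)
        intercepts[k] = b
        coefs[k] = w
    n_active = np.count_nonzero(coefs, axis=1)
    return RegularizationPath(lambdas=lambdas, intercepts=intercepts,
                              coefs=coefs, n_active=n_active)


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocCurve:
    """ROC points from a descending-score sweep, AUC by Mann-Whitney (ties 1/2)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # collapse score ties: keep the last index of each tied block
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation selection

@dataclass
class CvResult:
    """Per-lambda cross-validated AUC with fold assignments and selections."""

    lambdas: np.ndarray
    auc: np.ndarray              # pooled held-out AUC per lambda
    se: np.ndarray               # SE of per-fold AUCs per lambda
    n_active: np.ndarray         # active features of the full-data path
    fold_ids: np.ndarray         # per-patient fold index
    lambda_max_auc: float
    lambda_1se: float
    best_auc: float
    pooled_scores: np.ndarray    # held-out probabilities at lambda_max_auc
    labels: np.ndarray


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold index per sample; stratified by class, shuffled by seed."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        fold_ids = np.empty(len(y), dtype=int)
        ok = True
        for f, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
            fold_ids[test] = f
            if len(np.unique(y[~np.isin(np.arange(len(y)), test)])) < 2:
                ok = False
        if ok:
            return fold_ids
    raise ValueError("could not build stratified folds with both classes per training split")


def cv_select(X: np.ndarray, y: np.ndarray, k: int = 9,
              lambdas: np.ndarray | None = None, seed: int = 0,
              n_lambda: int = 100, min_ratio: float = 0.01) -> CvResult:
    """Stratified k-fold CV over the lambda path; select by pooled AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if lambdas is None:
        lambdas = make_lambda_grid(X, y, n_lambda, min_ratio)
    fold_ids = _stratified_folds(y, k, seed)
    n, L = len(y), len(lambdas)
    held_out = np.empty((n, L))
    fold_aucs = np.full((k, L), np.nan)
    for f in range(k):
        test = fold_ids == f
        path = l1_logistic_path(X[~test], y[~test], lambdas)
        eta = X[test] @ path.coefs.T + path.intercepts  # (n_test, L)
        held_out[test] = 1.0 / (1.0 + np.exp(-eta))
        if len(np.unique(y[test])) == 2:
            for j in range(L):
                fold_aucs[f, j] = roc_auc(held_out[test][:, j], y[test]).auc
    pooled_auc = np.array([roc_auc(held_out[:, j], y).auc for j in range(L)])
    with np.errstate(invalid="ignore"):
        valid = ~np.isnan(fold_aucs)
        n_valid = valid.sum(axis=0)
        se = np.nanstd(fold_aucs, axis=0, ddof=1) / np.sqrt(np.maximum(n_valid, 1))
    best_j = int(np.argmax(pooled_auc))  # argmax returns first = largest lambda on ties
    best_auc = float(pooled_auc[best_j])
    within = pooled_auc >= best_auc - se[best_j]
    one_se_j = int(np.flatnonzero(within)[0])
    full_path = l1_logistic_path(X, y, lambdas)
    return CvResult(
        lambdas=np.asarray(lambdas, dtype=float), auc=pooled_auc, se=se,
        n_active=full_path.n_active, fold_ids=fold_ids,
        lambda_max_auc=float(lambdas[best_j]), lambda_1se=float(lambdas[one_se_j]),
        best_auc=best_auc, pooled_scores=held_out[:, best_j], labels=y,
    )


# ---------------------------------------------------------------------------
# final model

@dataclass
class FittedModel:
    """A fixed sparse logistic model with its standardization parameters."""

    lam: float
    intercept: float
    weights: dict[str, float]            # nonzero weights by feature name
    feature_names: list[str]
    standardization: dict = field(default_factory=dict)
    schema_version: int = MODEL_SCHEMA_VERSION

    @property
    def n_active(self) -> int:
        return sum(1 for v in self.weights.values() if v != 0)


def fit_final(X: pd.DataFrame, y: np.ndarray, lam: float,
              standardization: dict | None = None) -> FittedModel:
    """Refit on all training patients at the selected lambda."""
    Xv = X.to_numpy(dtype=float)
    path = l1_logistic_path(Xv, np.asarray(y, dtype=int), np.array([lam * 1.5, lam]),
                            tol=1e-8, max_iter=50000)
    w, b = path.coefs[-1], float(path.intercepts[-1])
    weights = {name: float(wj) for name, wj in zip(X.columns, w) if wj != 0.0}
    return FittedModel(lam=float(lam), intercept=b, weights=weights,
                       feature_names=list(X.columns),
                       standardization=standardization or {})


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities sigma(b + Xw); columns aligned by name."""
    missing = [n for n in model.feature_names if n not in X.columns]
    if missing:
        raise ValueError(f"feature-name mismatch: {len(missing)} model features absent "
                         f"(first: {missing[:3]})")
    w = np.array([model.weights.get(n, 0.0) for n in model.feature_names])
    eta = X[model.feature_names].to_numpy(dtype=float) @ w + model.intercept
    return 1.0 / (1.0 + np.exp(-eta))


def rank_table(model: FittedModel, X: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-case probability of the benign class (UDH-like), ranked."""
    p_disease = predict(model, X)
    table = pd.DataFrame({
        "patient_id": X.index,
        "label": np.asarray(labels, dtype=int),
        "prob_udh": 1.0 - p_disease,
    }).sort_values("prob_udh", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# ablation

def feature_subsets(feature_names: list[str]) -> dict[str, list[str]]:
    """Named column subsets for the ablation analysis.

    Feature-class subsets (Textural / Morphological / Intensity) and one
    subset per color channel (first-order + texture columns of that
    channel; shape features carry no channel).
    """
    from .color import CHANNEL_SUFFIX
    from .firstorder import FIRSTORDER_STATS
    from .shape import SHAPE_FEATURE_NAMES
    from .texture import GLCM_FEATURE_NAMES, GLRLM_FEATURE_NAMES

    def base(name: str) -> str:
        return name.split("_", 1)[1]  # strip Mean_/SD_ prefix

    shape_set = set(SHAPE_FEATURE_NAMES)
    texture_stats = set(GLCM_FEATURE_NAMES) | set(GLRLM_FEATURE_NAMES)
    intensity_stats = set(FIRSTORDER_STATS)

    def stat_of(base_name: str) -> str:
        return base_name.rsplit("_", 1)[0] if "_" in base_name else base_name

    subsets: dict[str, list[str]] = {
        "Textural Features": [n for n in feature_names if stat_of(base(n)) in texture_stats],
        "Morphological Features": [n for n in feature_names if base(n) in shape_set],
        "Intensity Features": [n for n in feature_names if stat_of(base(n)) in intensity_stats],
    }
    channel_labels = {
        "Red": "Red Channel", "Green": "Green Channel", "Blue": "Blue Channel",
        "HSV": "V (HSV) Channel", "Lab": "L (Lab) Channel", "Luv": "L (Luv) Channel",
        "BR": "BlueRatio Image", "HE": "H (H&E)",
    }
    for suffix, label in channel_labels.items():
        subsets[label] = [n for n in feature_names
                          if base(n) not in shape_set and base(n).endswith(f"_{suffix}")]
    return subsets


def ablate(X: pd.DataFrame, y: np.ndarray,
           subsets: dict[str, list[str]] | None = None,
           k: int = 9, seed: int = 0, n_lambda: int = 100,
           min_ratio: float = 0.01) -> pd.DataFrame:
    """Re-run CV selection on each feature subset; Table-2-shaped output."""
    if subsets is None:
        subsets = feature_subsets(list(X.columns))
    rows = []
    for name, cols in subsets.items():
        if not cols:
            raise ValueError(f"empty feature subset: {name}")
        cv = cv_select(X[cols].to_numpy(dtype=float), y, k=k, seed=seed,
                       n_lambda=n_lambda, min_ratio=min_ratio)
        sel = int(cv.n_active[np.argmax(cv.lambdas == cv.lambda_max_auc)])
        rows.append({"Subset": name, "Total Features": len(cols),
                     "Selected Features": sel, "AUC": cv.best_auc})
        logger.info("ablate: %s -> %d features, AUC %.3f", name, len(cols), cv.best_auc)
    return pd.DataFrame(rows)
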