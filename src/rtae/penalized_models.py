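"""Penalized logistic regression pipeline (model 1).

Feature selection by elastic-net-penalized logistic regression on a
stratified 80/20 split, followed by a ridge-penalized logistic refit on
the selected columns. The penalized objective is the glmnet one,

    f(b0, b) = -(1/n) loglik + lambda * [alpha ||b||_1 + (1-alpha)/2 ||b||_2^2],

with an unpenalized intercept and standardized features. (alpha, lambda)
are tuned by minimum mean 5-fold cross-validated binomial deviance over
an alpha grid on [0.5, 1] and a warm-started log-spaced lambda path from
lambda_max (the smallest lambda with all penalized coefficients zero)
downwards.

The solver is coordinate descent on the 1/4-curvature quadratic
majorization of the logistic loss, which decreases the true objective at
every coordinate update (a property the tests assert).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evaluation


@dataclass
class PenalizedFit:
    alpha: float
    lam: float
    coefficients: np.ndarray  # intercept first
    feature_names: list[str]
    nonzero_names: list[str]
    cv_curve: list[tuple[float, float]] = field(default_factory=list)  # (lambda, mean CV deviance)

    def __post_init__(self) -> None:
        nz = [n for n, c in zip(self.feature_names, self.coefficients[1:]) if c != 0.0]
        if set(nz) != set(self.nonzero_names):
            raise ValueError("nonzero_names inconsistent with coefficients")

    def predict_proba(self, X) -> np.ndarray:
        eta = self.coefficients[0] + np.asarray(X, dtype=float) @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass
class SplitSpec:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


def soft_threshold(z: float, g: float) -> float:
    return np.sign(z) * max(abs(z) - g, 0.0)


def enet_objective(beta: np.ndarray, X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> float:
    """The penalized objective at beta (intercept first, unpenalized)."""
    eta = beta[0] + X @ beta[1:]
    nll = np.mean(np.logaddexp(0.0, (1 - 2 * y) * eta))
    pen = lam * (alpha * np.abs(beta[1:]).sum() + 0.5 * (1 - alpha) * np.sum(beta[1:] ** 2))
    return float(nll + pen)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all penalized coefficients are zero
    (KKT stationarity at beta = 0, intercept at the empirical logit)."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(alpha, 1e-3)))


def _gram(X: np.ndarray) -> np.ndarray:
    """Gram matrix (with intercept column) of the design, divided by n."""
    n = X.shape[0]
    Xa = np.column_stack([np.ones(n), X])
    return Xa.T @ Xa / n


@njit(cache=True)
def _cd_quadratic(beta, beta_out, g, C, diagC, lam_l1, lam_l2, inner_iter, tol):
    """Cyclic CD on the penalized quadratic surrogate around ``beta_out``.

    Minimizes g.(b - b_out) + 1/2 (b - b_out)' C (b - b_out)
    + lam_l1 |b[1:]|_1 + lam_l2/2 |b[1:]|_2^2 in place. Index 0 is the
    unpenalized intercept; zero-curvature coordinates are skipped.
    """
    p1 = beta.shape[0]
    cdelta = np.zeros(p1)
    for _ in range(inner_iter):
        max_d = 0.0
        for j in range(p1):
            dcj = diagC[j]
            if dcj == 0.0:
                continue
            sj = g[j] + cdelta[j] - dcj * (beta[j] - beta_out[j])
            if j == 0:
                new = beta_out[0] - sj / dcj
            else:
                zj = dcj * beta_out[j] - sj
                az = abs(zj) - lam_l1
                new = 0.0 if az <= 0.0 else np.sign(zj) * az / (dcj + lam_l2)
            d = new - beta[j]
            if d != 0.0:
                for k in range(p1):
                    cdelta[k] += C[k, j] * d
                beta[j] = new
                if abs(d) > max_d:
                    max_d = abs(d)
        if max_d < tol:
            break


def enet_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    beta_init: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    callback=None,
    gram: np.ndarray | None = None,
    inner_iter: int = 100,
) -> np.ndarray:
    """Majorized coordinate descent for the elastic-net logistic objective.

    Outer iterations majorize the logistic loss at the current point by
    the global quadratic bound with curvature (1/4) X'X/n (the logistic
    gradient's Lipschitz matrix), and the inner loop solves the penalized
    quadratic surrogate by cyclic coordinate descent on the precomputed
    Gram matrix. By the majorize-minimize argument the true penalized
    objective is non-increasing across outer iterations — ``callback``
    receives its value after each one, and the tests assert monotonicity.
    Zero-variance columns keep a zero coefficient. Returns
    [intercept, beta...]; pass ``gram=_gram(X)`` to amortize the Gram
    across a lambda path or alpha grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p + 1) if beta_init is None else beta_init.copy()
    if beta_init is None:
        beta[0] = np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12))
    C = np.ascontiguousarray((gram if gram is not None else _gram(X)) / 4.0)
    diagC = np.ascontiguousarray(np.diag(C))
    obj = enet_objective(beta, X, y, alpha, lam)
    for _ in range(max_iter):
        eta = beta[0] + X @ beta[1:]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        resid = mu - y
        g = np.empty(p + 1)
        g[0] = resid.mean()
        g[1:] = X.T @ resid / n
        # inner CD on: g . d + (1/2) d'C d + pen(beta_out + d)
        beta_out = beta.copy()
        _cd_quadratic(
            beta, beta_out, g, C, diagC, lam * alpha, lam * (1 - alpha),
            inner_iter, 0.1 * tol,
        )
        new_obj = enet_objective(beta, X, y, alpha, lam)
        if callback is not None:
            callback(new_obj)
        if np.max(np.abs(beta - beta_out)) < tol or obj - new_obj < tol * (abs(obj) + tol):
            obj = new_obj
            break
        obj = new_obj
    return beta


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _lambda_path(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def enet_logistic_path(
    X,
    y,
    feature_names: list[str] | None = None,
    alpha_grid=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    k_cv: int = 5,
    seed: int = 0,
    n_lambda: int = 25,
    lambda_min_ratio: float = 0.01,
) -> PenalizedFit:
    """Elastic-net logistic fit with (alpha, lambda) tuned by CV deviance.

    ``X`` is expected standardized. If the CV-optimal lambda selects no
    features, lambda is stepped down the path until the selection is
    non-empty (with a warning) — the elastic net is used precisely to
    reduce the chance of an empty selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    skf = StratifiedKFold(n_splits=k_cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a CV training fold lost a class; reduce k or reseed")

    fold_grams = [_gram(X[tr]) for tr, _ in folds]
    best = None  # (mean_dev, alpha, lam, path, curve)
    for alpha in alpha_grid:
        lmax = lambda_max(X, y, alpha)
        path = _lambda_path(lmax, n_lambda, lambda_min_ratio)
        dev = np.zeros(n_lambda)
        for (tr, te), gram in zip(folds, fold_grams):
            beta = None
            for i, lam in enumerate(path):
                beta = enet_coordinate_descent(
                    X[tr], y[tr], alpha, lam, beta_init=beta, gram=gram
                )
                prob = 1.0 / (1.0 + np.exp(-(beta[0] + X[te] @ beta[1:])))
                dev[i] += binomial_deviance(y[te], prob) * len(te)
        dev /= n
        i_best = int(np.argmin(dev))
        if best is None or dev[i_best] < best[0]:
            best = (dev[i_best], alpha, i_best, path, list(zip(path.tolist(), dev.tolist())))

    _, alpha, i_best, path, curve = best
    # final fit on all rows, warm-started down the path
    full_gram = _gram(X)
    beta = None
    betas = []
    for lam in path:
        beta = enet_coordinate_descent(X, y, alpha, lam, beta_init=beta, gram=full_gram)
        betas.append(beta.copy())
    i_sel = i_best
    while i_sel < len(path) - 1 and not np.any(betas[i_sel][1:] != 0.0):
        i_sel += 1
    if i_sel != i_best:
        warnings.warn(
            "CV-optimal lambda selected zero features; stepped down the path",
            stacklevel=2,
        )
    beta = betas[i_sel]
    nz = [names[j] for j in range(p) if beta[1 + j] != 0.0]
    return PenalizedFit(
        alpha=float(alpha),
        lam=float(path[i_sel]),
        coefficients=beta,
        feature_names=names,
        nonzero_names=nz,
        cv_curve=curve,
    )


def ridge_refit(
    X_selected,
    y,
    feature_names: list[str] | None = None,
    k_cv: int = 5,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> PenalizedFit:
    """Ridge (alpha = 0) logistic refit with lambda re-tuned by CV."""
    X = np.asarray(X_selected, dtype=float)
    y = np.asarray(y).astype(float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("no selected columns for the ridge refit")
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    if lambda_grid is None:
        lambda_grid = np.geomspace(1e2, 1e-4, 25)
    skf = StratifiedKFold(n_splits=k_cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    dev = np.zeros(len(lambda_grid))
    for tr, te in folds:
        gram = _gram(X[tr])
        beta = None
        for i, lam in enumerate(lambda_grid):
            beta = enet_coordinate_descent(X[tr], y[tr], 0.0, lam, beta_init=beta, gram=gram)
            prob = 1.0 / (1.0 + np.exp(-(beta[0] + X[te] @ beta[1:])))
            dev[i] += binomial_deviance(y[te], prob) * len(te)
    dev /= n
    i_best = int(np.argmin(dev))
    full_gram = _gram(X)
    beta = None
    for lam in lambda_grid[: i_best + 1]:
        beta = enet_coordinate_descent(X, y, 0.0, lam, beta_init=beta, gram=full_gram)
    return PenalizedFit(
        alpha=0.0,
        lam=float(lambda_grid[i_best]),
        coefficients=beta,
        feature_names=names,
        nonzero_names=[n_ for n_, c in zip(names, beta[1:]) if c != 0.0],
        cv_curve=list(zip(lambda_grid.tolist(), dev.tolist())),
    )


def split_80_20(y, seed: int = 0, max_redraws: int = 20) -> SplitSpec:
    """Stratified random split with test size round(0.2 n)."""
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 patients to split 80/20")
    n_test = int(round(0.2 * n))
    rs = seed
    for _ in range(max_redraws):
        tr, te = train_test_split(
            np.arange(n), test_size=n_test, random_state=rs, stratify=y
        )
        if len(np.unique(y[tr])) == 2:
            return SplitSpec(train_idx=np.sort(tr), test_idx=np.sort(te), seed=seed)
        warnings.warn("degenerate split; redrawing", stacklevel=2)
        rs += 1
    raise RuntimeError("could not draw a split with both classes in training")


def model1_pipeline(
    dataset,
    endpoint: str = "or",
    seed: int = 0,
    alpha_grid=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_lambda: int = 25,
    context: dict | None = None,
) -> dict:
    """Full model-1 run: split, e-net selection, ridge refit, scoring.

    Returns {"train": ModelPerformance, "test": ModelPerformance,
    "selection": PenalizedFit, "ridge": PenalizedFit, "split": SplitSpec}.
    The operating threshold is the Youden optimum of the training scores,
    applied unchanged to the test set.
    """
    table = dataset.design_matrix()
    y = dataset.endpoint(endpoint)
    split = split_80_20(y, seed=seed)
    X = table.to_numpy(dtype=float)
    Xtr, Xte = X[split.train_idx], X[split.test_idx]
    ytr, yte = y[split.train_idx], y[split.test_idx]
    # z-score on training statistics
    m, s = Xtr.mean(axis=0), Xtr.std(axis=0)
    s = np.where(s > 0, s, 1.0)
    Xtr = (Xtr - m) / s
    Xte = (Xte - m) / s

    sel = enet_logistic_path(
        Xtr, ytr, feature_names=list(table.columns),
        alpha_grid=alpha_grid, seed=seed, n_lambda=n_lambda,
    )
    cols = [table.columns.get_loc(nm) for nm in sel.nonzero_names]
    ridge = ridge_refit(Xtr[:, cols], ytr, feature_names=sel.nonzero_names, seed=seed)
    scores_tr = ridge.predict_proba(Xtr[:, cols])
    scores_te = ridge.predict_proba(Xte[:, cols])
    thr = evaluation.youden_threshold(scores_tr, ytr)
    ctx = context or {}
    perf_tr = evaluation.performance(
        scores_tr, ytr, threshold=thr, context={**ctx, "set": "train", "endpoint": endpoint}
    )
    perf_te = evaluation.performance(
        scores_te, yte, threshold=thr, context={**ctx, "set": "test", "endpoint": endpoint}
    )
    return {"train": perf_tr, "test": perf_te, "selection": sel, "ridge": ridge, "split": split}
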