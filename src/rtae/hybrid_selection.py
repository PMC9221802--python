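"""Hybrid descriptive-inferential feature selection.

The descriptive stage ranks every candidate feature by the absolute
point-biserial correlation |rpb| with the binary outcome. The inferential
stage then adds the ranked features one at a time to a logistic
regression; each iteration's p-value is compared with the previous one
and the cycle stops the first time it fails to decrease. The retained
prefix is the selected feature set — a deliberately greedy rule whose
point is resistance to overfitting at small n.

By default the iteration p-value is the 1-df likelihood-ratio test of the
current model against the previous (nested) one; the Wald p-value of the
newly added coefficient is available as an alternative rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with separation guard."""

    coefficients: np.ndarray  # intercept first
    converged: bool
    separation: bool
    log_likelihood: float
    p_value: float  # LRT against the intercept-only model
    n_iter: int
    cov: np.ndarray | None = None  # inverse observed information

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.coefficients[0] + np.asarray(X) @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass
class SelectionResult:
    """Outcome of the ranked add-one-feature selection loop."""

    ranked_names: list[str]
    rpb: dict[str, float]
    p_trajectory: list[float]
    stop_index: int
    retained_names: list[str] = field(default_factory=list)
    fits: list[LogisticFit] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ranked_names": self.ranked_names,
            "rpb": self.rpb,
            "p_trajectory": self.p_trajectory,
            "stop_index": self.stop_index,
            "retained_names": self.retained_names,
        }


def point_biserial(x, y) -> float:
    """Point-biserial correlation: the Pearson correlation of a continuous
    feature with a 0/1 outcome. A constant feature returns 0.0 (it carries
    no discriminative information and is ranked last)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    sx = x.std()
    if sx == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * y.std()))


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    return float(-np.sum(np.logaddexp(0.0, (1 - 2 * y) * eta)))


def logistic_fit(
    X,
    y,
    max_iter: int = 100,
    tol: float = 1e-10,
    coef_cap: float = 30.0,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    An intercept is always included (pass an empty-column X for the
    intercept-only model, whose fitted probability is the prevalence).
    Quasi-complete separation is detected when any coefficient exceeds
    ``coef_cap`` in absolute value; the fit is then clamped and flagged
    rather than allowed to diverge. Non-convergence without separation
    raises, carrying the iteration log.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y).astype(float)
    n, p = X.shape if X.size else (len(y), 0)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} features")
    Xd = np.column_stack([np.ones(n), X]) if p else np.ones((n, 1))
    beta = np.zeros(p + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    ll = _log_likelihood(Xd @ beta, y)
    converged = separation = False
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1 - mu)
        grad = Xd.T @ (y - mu)
        H = (Xd * np.maximum(w, 1e-10)[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving to guarantee likelihood ascent
        new_ll, scale = -np.inf, 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll = _log_likelihood(Xd @ cand, y)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        history.append((it, new_ll, float(np.abs(beta).max())))
        if np.abs(beta).max() > coef_cap:
            beta = np.clip(beta, -coef_cap, coef_cap)
            separation = True
            ll = _log_likelihood(Xd @ beta, y)
            break
        if abs(new_ll - ll) < tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged and not separation:
        raise RuntimeError(f"IRLS did not converge; iteration log: {history}")
    ll0 = _log_likelihood(
        np.full(n, np.log(y.mean() / (1 - y.mean()))), y
    )
    if p == 0:
        p_value = 1.0
    else:
        p_value = float(stats.chi2.sf(max(0.0, 2 * (ll - ll0)), df=p))
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1 - mu), 1e-10)
    try:
        cov = np.linalg.inv((Xd * w[:, None]).T @ Xd)
    except np.linalg.LinAlgError:
        cov = None
    return LogisticFit(
        coefficients=beta,
        converged=converged,
        separation=separation,
        log_likelihood=ll,
        p_value=p_value,
        n_iter=it,
        cov=cov,
    )


def rank_by_rpb(table: pd.DataFrame, y) -> tuple[list[str], dict[str, float]]:
    """Feature names sorted by |rpb| descending; ties (and constant
    features, rpb = 0) broken by ascending original column order."""
    rpb = {name: point_biserial(table[name].to_numpy(), y) for name in table.columns}
    order = sorted(
        range(len(table.columns)),
        key=lambda j: (-abs(rpb[table.columns[j]]), j),
    )
    return [table.columns[j] for j in order], rpb


def hybrid_select(
    table: pd.DataFrame,
    y,
    p_rule: str = "lrt",
    standardize: bool = True,
    max_features: int | None = None,
) -> SelectionResult:
    """Rank by |rpb|, then add one feature at a time while the model
    p-value keeps decreasing.

    ``p_rule='lrt'`` (default): 1-df likelihood-ratio test of iteration i's
    model against iteration i-1's. ``'wald'``: Wald p of the newly added
    coefficient. The first-ranked feature is always retained.
    """
    if p_rule not in ("lrt", "wald"):
        raise ValueError("p_rule must be 'lrt' or 'wald'")
    y = np.asarray(y).astype(int)
    if table.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X_all = table.to_numpy(dtype=float)
    sd = X_all.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("no informative features")
    if standardize:
        X_all = (X_all - X_all.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    ranked, rpb = rank_by_rpb(table, y)
    col_of = {name: j for j, name in enumerate(table.columns)}
    limit = min(len(ranked), max_features or len(ranked), len(y) - 2)

    p_traj: list[float] = []
    fits: list[LogisticFit] = []
    prev_fit: LogisticFit | None = None
    stop = 0
    for i in range(1, limit + 1):
        cols = [col_of[name] for name in ranked[:i]]
        fit = logistic_fit(X_all[:, cols], y)
        if p_rule == "lrt":
            prev_ll = prev_fit.log_likelihood if prev_fit else _log_likelihood(
                np.full(len(y), np.log(y.mean() / (1 - y.mean()))), y
            )
            p_i = float(stats.chi2.sf(max(0.0, 2 * (fit.log_likelihood - prev_ll)), df=1))
        else:
            if fit.cov is None:
                warnings.warn("singular information; falling back to p=1")
                p_i = 1.0
            else:
                se = np.sqrt(max(fit.cov[i, i], 0.0))
                z = fit.coefficients[i] / se if se > 0 else 0.0
                p_i = float(2 * stats.norm.sf(abs(z)))
        p_traj.append(p_i)
        if i == 1 or p_i < p_traj[i - 2]:
            stop = i
            fits.append(fit)
            prev_fit = fit
        else:
            break
    return SelectionResult(
        ranked_names=ranked,
        rpb=rpb,
        p_trajectory=p_traj,
        stop_index=stop,
        retained_names=ranked[:stop],
        fits=fits,
    )
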