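"""Biomass estimators on vegetation-index features.

Two models:

* an elastic-net linear regression minimising

      L(beta) = MSE + r * alpha * sum|beta_i| + (1 - r)/2 * alpha * sum beta_i^2

  (mixing parameter r: 0 = ridge, 1 = lasso; the intercept is not
  penalised), fitted by cyclic coordinate descent on standardized
  features — used to separate genotype / production-system responses;

* a one-hidden-layer perceptron (default 7 VI inputs -> 15 tanh units ->
  linear output) trained with Levenberg-Marquardt on a 60/40
  train/test split — used to estimate above-ground biomass across the
  growth stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .vegindex import pearson_r


# --------------------------------------------------------------------------
# elastic net


@dataclass
class ElasticNetModel:
    beta: np.ndarray  # coefficients on the ORIGINAL feature scale
    intercept: float
    alpha: float
    r_mix: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_iter: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.beta + self.intercept


def elasticnet_loss(
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    r_mix: float,
    intercept: float = 0.0,
) -> float:
    """Mixed-penalty loss; the intercept enters the MSE only."""
    beta = np.asarray(beta, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(beta)):
        raise ValueError("NaN or inf in inputs")
    if alpha < 0 or not 0 <= r_mix <= 1:
        raise ValueError("alpha must be >= 0 and r_mix in [0, 1]")
    resid = y - X @ beta - intercept
    mse = float(np.mean(resid**2))
    return mse + r_mix * alpha * float(np.sum(np.abs(beta))) + (1 - r_mix) / 2 * alpha * float(
        np.sum(beta**2)
    )


def _soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def fit_elasticnet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.0,
    r_mix: float = 0.5,
    max_iter: int = 200_000,
    tol: float = 1e-8,
) -> ElasticNetModel:
    """Cyclic coordinate descent on the standardized problem.

    Features are z-scored and the response scaled by its standard
    deviation before descent (so ``alpha`` is interpreted on the
    standardized problem, as in glmnet); coefficients are mapped back to
    the original scale.  Converged when the largest coefficient change
    in a sweep drops below ``tol``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    y_mean = y.mean()
    y_scale = y.std() or 1.0
    ys = (y - y_mean) / y_scale

    if alpha == 0.0:
        # unpenalised limit: coordinate descent crawls on collinear
        # features, but the minimiser is plain least squares
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        beta_orig = beta * y_scale / x_scale
        intercept = float(y_mean - x_mean @ beta_orig)
        return ElasticNetModel(
            beta=beta_orig, intercept=intercept, alpha=alpha, r_mix=r_mix,
            x_mean=x_mean, x_scale=x_scale, n_iter=0,
        )

    beta = np.zeros(p)
    resid = ys - Xs @ beta
    sq = (Xs**2).sum(axis=0)  # = n for non-constant standardized columns
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            cj = 2.0 / n * (Xs[:, j] @ resid + sq[j] * beta[j])
            aj = 2.0 / n * sq[j] + (1 - r_mix) * alpha
            new_bj = _soft_threshold(cj, r_mix * alpha) / aj
            delta = new_bj - beta[j]
            if delta != 0.0:
                resid -= Xs[:, j] * delta
                beta[j] = new_bj
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    else:
        raise RuntimeError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(last max coefficient change {max_delta:.3e})"
        )
    beta_orig = beta * y_scale / x_scale
    intercept = float(y_mean - x_mean @ beta_orig)
    return ElasticNetModel(
        beta=beta_orig, intercept=intercept, alpha=alpha, r_mix=r_mix,
        x_mean=x_mean, x_scale=x_scale, n_iter=it,
    )


def select_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    alphas=(1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    r_mixes=(0.0, 0.25, 0.5, 0.75, 1.0),
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (alpha, r_mix) by k-fold cross-validated test MSE."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    best, best_mse = (alphas[0], r_mixes[0]), np.inf
    for a in alphas:
        for r in r_mixes:
            errs = []
            for f in folds:
                tr = np.setdiff1d(np.arange(n), f)
                model = fit_elasticnet(X[tr], y[tr], alpha=a, r_mix=r)
                errs.append(np.mean((model.predict(X[f]) - y[f]) ** 2))
            mse = float(np.mean(errs))
            if mse < best_mse:
                best, best_mse = (a, r), mse
    return best


# --------------------------------------------------------------------------
# Levenberg-Marquardt MLP


@dataclass
class MlpModel:
    """7 -> hidden (tanh) -> 1 (linear) network with standardization."""

    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    trace: list[float] = field(default_factory=list)  # accepted SSE values

    def _forward_std(self, Xs: np.ndarray) -> np.ndarray:
        h = np.tanh(Xs @ self.W1.T + self.b1)
        return h @ self.w2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.x_mean) / self.x_scale
        return self._forward_std(Xs) * self.y_scale + self.y_mean


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta, hidden, d):
    i = hidden * d
    W1 = theta[:i].reshape(hidden, d)
    b1 = theta[i : i + hidden]
    w2 = theta[i + hidden : i + 2 * hidden]
    b2 = theta[i + 2 * hidden]
    return W1, b1, w2, b2


def _residuals_jacobian(theta, Xs, ys, hidden):
    n, d = Xs.shape
    W1, b1, w2, b2 = _unpack(theta, hidden, d)
    a = Xs @ W1.T + b1  # (n, hidden)
    h = np.tanh(a)
    pred = h @ w2 + b2
    e = ys - pred
    dh = (1 - h**2) * w2  # (n, hidden): d pred / d a
    J = np.empty((n, len(theta)))
    J[:, : hidden * d] = (dh[:, :, None] * Xs[:, None, :]).reshape(n, hidden * d)
    J[:, hidden * d : hidden * d + hidden] = dh
    J[:, hidden * d + hidden : hidden * d + 2 * hidden] = h
    J[:, -1] = 1.0
    return e, J  # residuals and d pred / d theta


def train_mlp_lm(
    Xs: np.ndarray,
    ys: np.ndarray,
    hidden: int = 15,
    seed: int = 0,
    max_iter: int = 200,
    lam0: float = 1e-2,
    lam_max: float = 1e10,
    gtol: float = 1e-10,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 6,
) -> tuple[np.ndarray, list[float]]:
    """Levenberg-Marquardt on standardized data; returns (theta, SSE trace).

    Damped normal equations (J'J + lam I) delta = J'e; lam is divided by
    10 on an accepted step and multiplied by 10 on a rejected one.  The
    SSE trace contains only accepted steps, so it is non-increasing.

    With validation data, training stops after ``patience`` consecutive
    accepted steps without a validation improvement and the
    best-validation parameters are returned (the network has far more
    parameters than a plot-level feature table has rows, so run-to-
    convergence interpolates the training set).
    """
    n, d = Xs.shape
    rng = np.random.default_rng(seed)
    theta = rng.normal(scale=0.5, size=hidden * d + 2 * hidden + 1)
    e, J = _residuals_jacobian(theta, Xs, ys, hidden)
    sse = float(e @ e)
    trace = [sse]
    lam = lam0

    def val_sse(th):
        ev, _ = _residuals_jacobian(th, X_val, y_val, hidden)
        return float(ev @ ev)

    use_val = X_val is not None and len(X_val) > 0
    best_theta, best_val, fails = theta.copy(), val_sse(theta) if use_val else np.inf, 0

    for _ in range(max_iter):
        g = J.T @ e
        if np.max(np.abs(g)) < gtol:
            break
        A = J.T @ J
        accepted = False
        while lam <= lam_max:
            try:
                delta = np.linalg.solve(A + lam * np.eye(len(theta)), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            theta_new = theta + delta
            e_new, J_new = _residuals_jacobian(theta_new, Xs, ys, hidden)
            sse_new = float(e_new @ e_new)
            if sse_new < sse:
                theta, e, J, sse = theta_new, e_new, J_new, sse_new
                trace.append(sse)
                lam = max(lam / 10, 1e-12)
                accepted = True
                break
            lam *= 10
        if not accepted:
            break
        if use_val:
            v = val_sse(theta)
            if v < best_val:
                best_val, best_theta, fails = v, theta.copy(), 0
            else:
                fails += 1
                if fails >= patience:
                    break
    if use_val:
        return best_theta, trace
    return theta, trace


def train_mlp_bfgs(
    Xs: np.ndarray,
    ys: np.ndarray,
    hidden: int = 15,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[np.ndarray, list[float]]:
    """Quasi-Newton (L-BFGS) alternative to LM, for robustness checks.

    Not the reference training algorithm; exposed behind
    ``fit_mlp(..., method="bfgs")``.
    """
    from scipy.optimize import minimize

    n, d = Xs.shape
    rng = np.random.default_rng(seed)
    theta0 = rng.normal(scale=0.5, size=hidden * d + 2 * hidden + 1)
    trace: list[float] = []

    def fun(theta):
        e, J = _residuals_jacobian(theta, Xs, ys, hidden)
        trace.append(float(e @ e))
        return float(e @ e), -2.0 * (J.T @ e)

    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   options=dict(maxiter=max_iter))
    return res.x, trace


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 15,
    seed: int = 0,
    split: float = 0.6,
    max_iter: int = 200,
    method: str = "lm",
) -> tuple[MlpModel, dict]:
    """Train on a random ``split`` fraction, evaluate on the rest.

    ``method="lm"`` (default) is Levenberg-Marquardt with
    validation-based early stopping; ``method="bfgs"`` swaps in the
    quasi-Newton fallback.  A fifth of the training fraction is held out
    as a validation set for early stopping (the best-validation weights
    are kept).  Returns the model and a dict with ``test_pred``,
    ``test_true``, ``test_index``, ``r`` and ``r2``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 samples")
    if hidden < 1:
        raise ValueError("need at least one hidden unit")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError(f"degenerate split: {n_train} train / {n - n_train} test")
    tr, te = perm[:n_train], perm[n_train:]

    x_mean = X[tr].mean(axis=0)
    x_scale = X[tr].std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y[tr].mean())
    y_scale = float(y[tr].std()) or 1.0
    Xs = (X[tr] - x_mean) / x_scale
    ys = (y[tr] - y_mean) / y_scale

    n_val = max(2, int(round(0.2 * len(tr))))
    X_fit, y_fit = Xs[n_val:], ys[n_val:]
    X_val, y_val = Xs[:n_val], ys[:n_val]
    if method == "lm":
        theta, trace = train_mlp_lm(
            X_fit, y_fit, hidden=hidden, seed=seed, max_iter=max_iter,
            X_val=X_val, y_val=y_val,
        )
    elif method == "bfgs":
        theta, trace = train_mlp_bfgs(Xs, ys, hidden=hidden, seed=seed)
    else:
        raise ValueError(f"unknown training method {method!r}")
    W1, b1, w2, b2 = _unpack(theta, hidden, Xs.shape[1])
    model = MlpModel(
        W1=W1, b1=b1, w2=w2, b2=float(b2),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        trace=trace,
    )
    pred = model.predict(X[te])
    r, r2 = evaluate_estimates(pred, y[te])
    return model, dict(test_pred=pred, test_true=y[te], test_index=te, r=r, r2=r2)


def evaluate_estimates(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Linear correlation r and coefficient of determination R^2.

    A constant prediction has undefined correlation (returned as NaN)
    while R^2 remains defined.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or len(pred) < 2:
        raise ValueError("pred and truth must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance truth")
    r2 = 1.0 - float(np.sum((truth - pred) ** 2)) / ss_tot
    try:
        r = pearson_r(pred, truth)
    except ValueError:
        r = np.nan
    return r, r2


def genotype_separation(
    features: "pd.DataFrame",
    feature_cols: list[str],
    target: str = "dry_biomass",
    genotype_col: str = "genotype",
    system_col: str = "system",
    alpha: float = 1e-3,
    r_mix: float = 0.5,
) -> "pd.DataFrame":
    """Per-production-system elastic-net fits and genotype residual separation.

    For each system an elastic net predicts the biomass from the VI
    features; the separation statistic is the difference of genotype-wise
    mean residuals divided by the pooled residual SD.  Values near 0 mean
    the genotypes are indistinguishable after accounting for the VIs.
    """
    import pandas as pd

    rows = []
    for system, grp in features.groupby(system_col):
        genos = sorted(grp[genotype_col].unique())
        if len(genos) != 2:
            raise ValueError(f"system {system!r}: need exactly 2 genotypes, got {genos}")
        for g in genos:
            if (grp[genotype_col] == g).sum() < 3:
                raise ValueError(f"system {system!r}, genotype {g!r}: fewer than 3 samples")
        Xg = grp[feature_cols].to_numpy()
        yg = grp[target].to_numpy(dtype=np.float64)
        model = fit_elasticnet(Xg, yg, alpha=alpha, r_mix=r_mix)
        resid = yg - model.predict(Xg)
        r0 = resid[(grp[genotype_col] == genos[0]).to_numpy()]
        r1 = resid[(grp[genotype_col] == genos[1]).to_numpy()]
        pooled = np.sqrt(
            ((len(r0) - 1) * r0.var(ddof=1) + (len(r1) - 1) * r1.var(ddof=1))
            / (len(r0) + len(r1) - 2)
        )
        stat = 0.0 if pooled == 0 else float((r0.mean() - r1.mean()) / pooled)
        rows.append(
            dict(system=system, genotype_a=genos[0], genotype_b=genos[1],
                 separation=stat, n=len(grp),
                 mean_resid_a=float(r0.mean()), mean_resid_b=float(r1.mean()))
        )
    return pd.DataFrame(rows)
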