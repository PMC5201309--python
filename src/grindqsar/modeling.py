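"""PLS regression with leave-one-out validation and FFD variable selection.

The chemometric workhorse for descriptor matrices with p ≫ n: NIPALS partial
least squares on autoscaled variables, the latent dimension chosen by LOO
q², and a fractional-factorial-design screen that removes variables whose
exclusion improves prediction more than the average dummy variable does.

Definitions used throughout:

    r²    = 1 − SSE / SS_tot              (training)
    q²    = 1 − PRESS / SS_tot            (leave-one-out, full refits)
    SDEP  = sqrt(PRESS / n)               (standard error of prediction)
    RMSE  = sqrt(SSE / n)

SDEP with the n−1 denominator is also exposed for comparison, since usage
in the literature is split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["ModelStats", "PLSModel", "pls_fit", "loo_q2", "ffd_select", "predict",
           "y_scramble"]


@dataclass
class ModelStats:
    r2: float
    q2_loo: float
    rmse: float
    n: int
    sdep: float = float("nan")        # sqrt(PRESS/n)
    sdep_nm1: float = float("nan")    # sqrt(PRESS/(n-1))

    def __post_init__(self):
        if self.r2 > 1 + 1e-12 or self.q2_loo > 1 + 1e-12:
            raise ValueError("r2/q2 cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray    # (p, A)
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    x_scores: np.ndarray     # (n, A)
    coefficients: np.ndarray  # (p,), original (unscaled) variable space
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    stats: ModelStats | None = None
    kept_variables: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    labels: list[str] | None = None
    train_min: np.ndarray | None = None
    train_max: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "kept_variables": self.kept_variables.tolist(),
            "labels": self.labels,
            "stats": None if self.stats is None else vars(self.stats),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _autoscale(X: np.ndarray, y: np.ndarray):
    """Center X and y; scale X to unit variance, dropping zero-variance columns."""
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(x_std > 1e-12)
    if keep.size == 0:
        raise ValueError("all descriptor columns have zero variance")
    if keep.size < X.shape[1]:
        log.debug("dropping %d zero-variance columns", X.shape[1] - keep.size)
    Xs = (X[:, keep] - x_mean[keep]) / x_std[keep]
    y_mean = float(y.mean())
    return Xs, y - y_mean, x_mean, x_std, keep, y_mean


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_components: int,
            tol: float = 1e-12, max_iter: int = 500):
    """NIPALS PLS1. Returns weights W, X-loadings P, y-loadings q (all per
    component) and the regression vector in the scaled space."""
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy().astype(float)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    actual = 0
    for a in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < tol:
            break
        p_load = X.T @ t / tt
        q_a = y @ t / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, p_load, t, q_a
        X -= np.outer(t, p_load)
        y -= q_a * t
        actual += 1
    W, P, T, q = W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]
    if actual == 0:
        raise ValueError("no usable PLS component (X'y vanished)")
    # b = W (P'W)^{-1} q  — regression vector in the scaled space
    b = W @ np.linalg.solve(P.T @ W, q)
    return W, P, T, q, b


def _fit_fixed(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    Xs, yc, x_mean, x_std, keep, y_mean = _autoscale(X, y)
    n_components = min(n_components, Xs.shape[0] - 1, Xs.shape[1])
    W, P, T, q, b_scaled = _nipals(Xs, yc, n_components)
    coef = np.zeros(X.shape[1])
    coef[keep] = b_scaled / x_std[keep]
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=W.shape[1],
        x_weights=W, x_loadings=P, y_loadings=q, x_scores=T,
        coefficients=coef, intercept=intercept,
        x_mean=x_mean, x_scale=x_std, y_mean=y_mean,
        kept_variables=keep,
        train_min=X.min(axis=0), train_max=X.max(axis=0),
    )


def predict(model: PLSModel, X_new: np.ndarray, labels: list[str] | None = None,
            *, warn_extrapolation: bool = True) -> np.ndarray:
    """ŷ for new rows; warns when a row leaves the per-variable training range."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coefficients.size:
        raise ValueError(
            f"descriptor count mismatch: model has {model.coefficients.size}, "
            f"input has {X_new.shape[1]}"
        )
    if labels is not None and model.labels is not None and labels != model.labels:
        raise ValueError("descriptor labels do not match the training labels")
    if warn_extrapolation and model.train_min is not None:
        outside = (X_new < model.train_min) | (X_new > model.train_max)
        bad_rows = np.flatnonzero(outside.any(axis=1))
        for r in bad_rows:
            log.warning(
                "prediction row %d outside the training hull on %d variables "
                "(applicability domain caveat)", r, int(outside[r].sum())
            )
    return X_new @ model.coefficients + model.intercept


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float]:
    """Leave-one-out q² and PRESS at a fixed latent dimension.

    Each fold refits from scratch, including re-centering and re-scaling, so
    the held-out row influences nothing.
    """
    n = len(y)
    if n < 5:
        raise ValueError(f"LOO needs n ≥ 5, got {n}")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("constant response: total sum of squares is zero")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = _fit_fixed(X[mask], y[mask], n_components)
        press += float((predict(sub, X[i:i + 1], warn_extrapolation=False)[0] - y[i]) ** 2)
    return 1.0 - press / ss_tot, press


def pls_fit(X: np.ndarray, y: np.ndarray, max_components: int = 5,
            labels: list[str] | None = None) -> PLSModel:
    """Fit PLS, choosing the latent dimension that maximizes LOO q²."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 5:
        raise ValueError(f"need at least 5 training rows, got {X.shape[0]}")
    if not np.any(X.std(axis=0) > 1e-12):
        raise ValueError("all descriptor columns are constant")

    n = X.shape[0]
    best_a, best_q2, best_press = 1, -np.inf, np.nan
    for a in range(1, max_components + 1):
        try:
            q2, press = loo_q2(X, y, a)
        except ValueError:
            break
        if q2 > best_q2 + 1e-12:
            best_a, best_q2, best_press = a, q2, press

    model = _fit_fixed(X, y, best_a)
    resid = y - predict(model, X, warn_extrapolation=False)
    sse = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    model.stats = ModelStats(
        r2=1.0 - sse / ss_tot,
        q2_loo=best_q2,
        rmse=float(np.sqrt(sse / n)),
        n=n,
        sdep=float(np.sqrt(best_press / n)),
        sdep_nm1=float(np.sqrt(best_press / (n - 1))),
    )
    model.labels = labels
    return model


def ffd_select(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_components: int = 5,
    dummy_fraction: float = 0.2,
    n_runs: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fractional-factorial-design variable selection. Returns kept indices.

    Random two-level inclusion designs (~2·p runs, each keeping half the
    variables) are evaluated by LOO SDEP; a variable's effect is
    mean SDEP(runs excluding it) − mean SDEP(runs including it). Dummy
    variables (a ``dummy_fraction`` of p) set the noise floor: real variables
    whose exclusion effect is more favorable than the mean positive dummy
    effect are removed, in one pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    kept = _ffd_pass(X, y, max_components=max_components,
                     dummy_fraction=dummy_fraction, n_runs=n_runs, seed=seed)
    if kept.size < X.shape[1] and kept.size >= 4:
        # one refinement pass on the reduced variable set
        kept2 = _ffd_pass(X[:, kept], y, max_components=max_components,
                          dummy_fraction=dummy_fraction, n_runs=n_runs,
                          seed=seed + 1)
        kept = kept[kept2]
    return kept


def _ffd_pass(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_components: int,
    dummy_fraction: float,
    n_runs: int | None,
    seed: int,
) -> np.ndarray:
    n, p = X.shape
    if p < 4:
        log.warning("FFD selection skipped: only %d variables", p)
        return np.arange(p)
    rng = np.random.default_rng(seed)
    n_dummy = max(2, int(round(dummy_fraction * p)))
    total = p + n_dummy

    # +1 = included. Two-level resolution-III design from a Hadamard matrix
    # (columns balanced and mutually orthogonal), with a seed-dependent
    # random assignment of columns to variables and random sign flips.
    # Dummies are ignored in the fit (they carry no information by
    # construction) but tracked for the noise floor.
    from scipy.linalg import hadamard

    n_h = 1
    while n_h < total + 1:
        n_h *= 2
    if n_h <= 512:
        H = hadamard(n_h)
        cols = rng.permutation(n_h - 1)[:total] + 1  # skip the constant column
        design = H[:, cols] * rng.choice([-1, 1], size=total)
        n_runs = n_h
    else:  # very wide matrices: fall back to a balanced random design
        n_runs = n_runs or min(2 * total, 512)
        design = rng.choice([-1, 1], size=(n_runs, total))
        for j in range(total):
            col = design[:, j]
            if (col == 1).all() or (col == -1).all():
                design[rng.integers(n_runs), j] *= -1

    sdep = np.empty(n_runs)
    for r in range(n_runs):
        inc = np.flatnonzero(design[r, :p] == 1)
        if inc.size == 0:
            sdep[r] = np.inf
            continue
        try:
            _, press = loo_q2(X[:, inc], y, min(max_components, inc.size))
            sdep[r] = np.sqrt(press / n)
        except ValueError:
            sdep[r] = np.inf

    ok = np.isfinite(sdep)
    effects = np.empty(total)
    for j in range(total):
        inc_mask = ok & (design[:, j] == 1)
        exc_mask = ok & (design[:, j] == -1)
        if not inc_mask.any() or not exc_mask.any():
            effects[j] = 0.0
            continue
        effects[j] = sdep[exc_mask].mean() - sdep[inc_mask].mean()
    # effect > 0: including the variable lowers SDEP (helpful);
    # effect < 0: excluding it lowers SDEP (harmful variable). A variable is
    # kept only when its benefit clears the dummy noise band (dummies carry
    # no information, so their effects delimit pure estimation noise).
    dummy_effects = effects[p:]
    floor = float(np.abs(dummy_effects).mean())
    kept = np.flatnonzero(effects[:p] >= floor)
    if kept.size == 0:
        log.warning("FFD removed everything; falling back to identity selection")
        return np.arange(p)
    log.info("FFD kept %d of %d variables (noise floor %.4f)", kept.size, p, floor)
    return kept


def y_scramble(X: np.ndarray, y: np.ndarray, n_rounds: int = 20,
               max_components: int = 5, seed: int = 0) -> np.ndarray:
    """q² under random permutations of y — a chance-correlation check."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_rounds)
    for r in range(n_rounds):
        yp = rng.permutation(y)
        try:
            out[r], _ = loo_q2(X, yp, max_components)
        except ValueError:
            out[r] = np.nan
    return out
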