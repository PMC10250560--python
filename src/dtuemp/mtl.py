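"""l1-regularised multi-task least squares for joint outcome prediction.

The model predicts several clinical outcomes (here MMSE and TUG) from the
same standardized movement metrics by minimising

    sum_i || X_i w_i - y_i ||^2  +  rho1 ||W||_1  +  rho_l2 ||W||_F^2

over the p x t weight matrix W, where task i has design X_i and outcome
y_i. rho1 controls sparsity, rho_l2 an optional ridge penalty. The solver is
a monotone accelerated proximal-gradient method (MFISTA): soft-thresholding
prox for the l1 term, the ridge term folded into the smooth part, with a
descent safeguard so the objective trace is non-increasing. Outcomes are
centred per task, so intercepts are the task means.

Estimators follow the scikit-learn protocol (`fit`/`predict`, fitted
attributes with trailing underscores) and compose with sklearn model
selection; `cross_validate_cohort` reproduces the evaluation design used for
the MTL-versus-STL comparison: outer 5-fold CV with per-fold z-scaling and
an inner 3-fold grid search over a logarithmic rho1 grid, scored by MAPE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, column_or_1d, validate_data

from .stats import MAPE_CUTOFFS, _label

COVARIATE_COLS = ("age", "sex", "bmi")
OUTCOME_COLS = ("mmse", "tug")
ID_COL = "subject_id"


# ---------------------------------------------------------------------------
# standardization

def zscore_fit(train: np.ndarray, feature_names=None) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs of the training block; zero variance is an error."""
    train = np.asarray(train, dtype=float)
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    zero = np.where(sds == 0)[0]
    if zero.size:
        name = feature_names[zero[0]] if feature_names is not None else f"column {zero[0]}"
        raise ValueError(f"zero-variance feature: {name}")
    return means, sds


def zscore_apply(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) - means) / sds


def zscore_fit_apply(train, apply_to=None, feature_names=None):
    """Standardise with a train-fitted scale; returns (train_z, other_z, means, sds)."""
    means, sds = zscore_fit(train, feature_names)
    train_z = zscore_apply(train, means, sds)
    other_z = None if apply_to is None else zscore_apply(apply_to, means, sds)
    return train_z, other_z, means, sds


# ---------------------------------------------------------------------------
# solver

@dataclass
class MTLFit:
    """Solution of the multi-task objective on centred outcomes."""

    W: np.ndarray  # (p, t)
    intercepts: np.ndarray  # (t,) task means of y
    rho1: float
    rho_l2: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int


def _objective(W, Xs, Ys_c, rho1, rho_l2):
    smooth = sum(
        float(np.sum((X @ W[:, i] - y) ** 2)) for i, (X, y) in enumerate(zip(Xs, Ys_c))
    )
    return smooth + rho_l2 * float(np.sum(W**2)) + rho1 * float(np.sum(np.abs(W)))


def _grad_smooth(W, Xs, Ys_c, rho_l2):
    g = np.empty_like(W)
    for i, (X, y) in enumerate(zip(Xs, Ys_c)):
        g[:, i] = 2.0 * X.T @ (X @ W[:, i] - y)
    return g + 2.0 * rho_l2 * W


def solve_mtl(
    Xs: list[np.ndarray],
    Ys: list[np.ndarray],
    rho1: float,
    rho_l2: float = 0.0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    kkt_tol: float = 1e-6,
) -> MTLFit:
    """Minimise the multi-task objective by monotone FISTA.

    ``Xs[i]`` is the (n_i, p) design of task i and ``Ys[i]`` its outcomes;
    all tasks share the feature dimension p. Terminates when the relative
    objective change over an accepted step falls below ``tol`` and the
    subgradient optimality residual falls below ``kkt_tol`` (the objective
    can plateau before the iterate settles, so the change criterion alone
    is unreliable).
    """
    if rho1 < 0 or rho_l2 < 0:
        raise ValueError("regularisation parameters must be non-negative")
    if len(Xs) != len(Ys) or not Xs:
        raise ValueError("need matching non-empty task lists")
    Xs = [np.asarray(X, dtype=float) for X in Xs]
    Ys = [np.asarray(y, dtype=float).ravel() for y in Ys]
    p = Xs[0].shape[1]
    for i, (X, y) in enumerate(zip(Xs, Ys)):
        if X.shape[0] != len(y):
            raise ValueError(f"task {i}: X has {X.shape[0]} rows but y has {len(y)}")
        if X.shape[1] != p:
            raise ValueError("all tasks must share the feature dimension")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError(f"task {i}: non-finite inputs")

    intercepts = np.array([y.mean() for y in Ys])
    Ys_c = [y - m for y, m in zip(Ys, intercepts)]

    lip = 2.0 * max(np.linalg.norm(X, 2) ** 2 for X in Xs) + 2.0 * rho_l2
    lip = max(lip, 1e-12)
    step = 1.0 / lip
    thresh = rho1 * step

    t = len(Xs)
    x_cur = np.zeros((p, t))
    y_acc = x_cur.copy()
    f_cur = _objective(x_cur, Xs, Ys_c, rho1, rho_l2)
    trace = [f_cur]
    momentum = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = _grad_smooth(y_acc, Xs, Ys_c, rho_l2)
        z = y_acc - step * grad
        z = np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)
        f_z = _objective(z, Xs, Ys_c, rho1, rho_l2)
        if f_z <= f_cur:  # accept the accelerated step
            delta = f_cur - f_z
            momentum_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * momentum**2))
            y_acc = (
                z
                + ((momentum - 1.0) / momentum_new) * (z - x_cur)
            )
            momentum = momentum_new
            x_cur, f_cur = z, f_z
            trace.append(f_cur)
            if delta <= tol * max(1.0, abs(f_cur)):
                if _kkt_residual_raw(x_cur, Xs, Ys_c, rho1, rho_l2) <= kkt_tol:
                    converged = True
                    break
        else:  # monotone safeguard: restart momentum from the best iterate
            trace.append(f_cur)
            if momentum == 1.0:
                # plain proximal step failed to descend: at a fixed point
                converged = _kkt_residual_raw(x_cur, Xs, Ys_c, rho1, rho_l2) <= kkt_tol
                break
            momentum = 1.0
            y_acc = x_cur.copy()
    return MTLFit(
        W=x_cur,
        intercepts=intercepts,
        rho1=rho1,
        rho_l2=rho_l2,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )


def solve_stl(X: np.ndarray, y: np.ndarray, rho1: float, rho_l2: float = 0.0, **kw) -> MTLFit:
    """Single-task Lasso: the multi-task solver restricted to one task."""
    return solve_mtl([X], [y], rho1, rho_l2, **kw)


def critical_rho1(Xs, Ys) -> float:
    """Smallest rho1 at which W = 0 is optimal: max_i,j 2 |X_i^T y_i,centred|."""
    out = 0.0
    for X, y in zip(Xs, Ys):
        y = np.asarray(y, dtype=float).ravel()
        out = max(out, float(np.max(np.abs(2.0 * np.asarray(X).T @ (y - y.mean())))))
    return out


def _kkt_residual_raw(W, Xs, Ys_c, rho1, rho_l2) -> float:
    grad = _grad_smooth(W, Xs, Ys_c, rho_l2)
    active = W != 0
    viol_active = np.abs(grad + rho1 * np.sign(W))[active]
    viol_zero = np.maximum(np.abs(grad) - rho1, 0.0)[~active]
    pieces = [v.max() for v in (viol_active, viol_zero) if v.size]
    return float(max(pieces)) if pieces else 0.0


def kkt_residual(fit: MTLFit, Xs, Ys) -> float:
    """Max violation of the subgradient optimality conditions at fit.W."""
    Ys_c = [np.asarray(y, float).ravel() - m for y, m in zip(Ys, fit.intercepts)]
    return _kkt_residual_raw(
        fit.W, [np.asarray(X, float) for X in Xs], Ys_c, fit.rho1, fit.rho_l2
    )


# ---------------------------------------------------------------------------
# sklearn estimators

class MultiTaskLassoRegressor(RegressorMixin, BaseEstimator):
    """Multi-outcome l1-regularised least squares on a shared design.

    Parameters
    ----------
    rho1 : float
        Sparsity penalty on the weight matrix.
    rho_l2 : float
        Optional ridge penalty.
    standardize : bool
        Z-score features with a train-fitted scale inside ``fit``.
    """

    def __init__(self, rho1=1.0, rho_l2=0.0, standardize=True,
                 max_iter=10_000, tol=1e-8):
        self.rho1 = rho1
        self.rho_l2 = rho_l2
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X, Y = validate_data(
            self, X, Y, multi_output=True, y_numeric=True, ensure_min_samples=2
        )
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if self.standardize:
            self.feature_means_, self.feature_sds_ = zscore_fit(X)
            Xz = zscore_apply(X, self.feature_means_, self.feature_sds_)
        else:
            self.feature_means_ = np.zeros(X.shape[1])
            self.feature_sds_ = np.ones(X.shape[1])
            Xz = X
        n_tasks = Y.shape[1]
        fit = solve_mtl([Xz] * n_tasks, [Y[:, i] for i in range(n_tasks)],
                        self.rho1, self.rho_l2, self.max_iter, self.tol)
        self.coef_ = fit.W
        self.intercept_ = fit.intercepts
        self.objective_trace_ = fit.objective_trace
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = validate_data(self, X, reset=False)
        Xz = zscore_apply(X, self.feature_means_, self.feature_sds_)
        return Xz @ self.coef_ + self.intercept_


class SingleTaskLassoRegressor(MultiTaskLassoRegressor):
    """The single-task benchmark: same solver, one outcome, rho_l2 = 0."""

    def __init__(self, rho1=1.0, standardize=True, max_iter=10_000, tol=1e-8):
        super().__init__(rho1=rho1, rho_l2=0.0, standardize=standardize,
                         max_iter=max_iter, tol=tol)

    def fit(self, X, y):
        if y is not None and np.asarray(y).ndim > 1:
            y = column_or_1d(y, warn=True)
        return super().fit(X, y)

    def predict(self, X):
        return super().predict(X).ravel()


# ---------------------------------------------------------------------------
# scoring and cross-validation

def mape(y, yhat) -> float:
    """Mean absolute percentage error, 100 * mean(|y - yhat| / |y|)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    if np.any(y == 0):
        raise ValueError("MAPE undefined: outcome contains zero")
    return float(100.0 * np.mean(np.abs(y - yhat) / np.abs(y)))


def mape_label(value: float) -> str:
    """high (< 5%), moderate (5-25%), unacceptable (> 25%)."""
    return _label(value, MAPE_CUTOFFS)


@dataclass
class CVReport:
    """Out-of-fold evaluation of one model kind on one cohort."""

    model: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    predictions: pd.DataFrame  # columns: one per task, out-of-fold, original units
    mape_pooled: dict[str, float]
    mape_fold_mean: dict[str, float]
    chosen_rho1: list  # per fold: float (mtl) or dict task->float (stl)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.labels:
            self.labels = {t: mape_label(v) for t, v in self.mape_pooled.items()}


def _rho_grid(rho_max: float, size: int = 7) -> np.ndarray:
    """Logarithmic grid {1e-3 ... 1e1} * rho_max."""
    return rho_max * np.logspace(-3, 1, size)


def feature_columns(cohort: pd.DataFrame) -> list[str]:
    reserved = {ID_COL, *COVARIATE_COLS, *OUTCOME_COLS}
    return [c for c in cohort.columns if c not in reserved]


def cross_validate_cohort(
    cohort: pd.DataFrame,
    model: str = "mtl",
    k: int = 5,
    seed: int = 0,
    inner_folds: int = 3,
    grid_size: int = 7,
    rho_l2: float = 0.0,
    feature_cols: list[str] | None = None,
    outcome_cols: tuple[str, ...] = OUTCOME_COLS,
) -> CVReport:
    """Outer k-fold CV with nested rho1 selection, scored by MAPE.

    Standardisation and the rho1 grid are fitted on training folds only; the
    same outer folds are used for ``model='mtl'`` and ``model='stl'`` at the
    same seed, so the two are directly comparable. MTL selects one rho1
    minimising the mean inner-CV MAPE across tasks; STL selects rho1 per
    task. Pooled MAPE (over all out-of-fold predictions) is the primary
    score; the mean of per-fold MAPEs is reported alongside.
    """
    if model not in ("mtl", "stl"):
        raise ValueError("model must be 'mtl' or 'stl'")
    feature_cols = feature_cols or feature_columns(cohort)
    X = cohort[feature_cols].to_numpy(dtype=float)
    Y = cohort[list(outcome_cols)].to_numpy(dtype=float)
    n = len(cohort)
    if n < k:
        raise ValueError("need at least k subjects")

    outer = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    oof = np.full_like(Y, np.nan, dtype=float)
    chosen: list = []
    fold_mapes: dict[str, list[float]] = {t: [] for t in outcome_cols}

    for fold, (tr, te) in enumerate(outer.split(X)):
        fold_assignment[te] = fold
        inner_seed = seed * 1009 + fold  # deterministic, distinct per fold
        if model == "mtl":
            rho = _select_rho_mtl(X[tr], Y[tr], inner_folds, grid_size, rho_l2,
                                  inner_seed, feature_cols)
            est = MultiTaskLassoRegressor(rho1=rho, rho_l2=rho_l2).fit(X[tr], Y[tr])
            oof[te] = est.predict(X[te])
            chosen.append(rho)
        else:
            rhos = {}
            for j, task in enumerate(outcome_cols):
                rho = _select_rho_stl(X[tr], Y[tr, j], inner_folds, grid_size,
                                      inner_seed, feature_cols)
                est = SingleTaskLassoRegressor(rho1=rho).fit(X[tr], Y[tr, j])
                oof[te, j] = est.predict(X[te])
                rhos[task] = rho
            chosen.append(rhos)
        for j, task in enumerate(outcome_cols):
            fold_mapes[task].append(mape(Y[te, j], oof[te, j]))

    mape_pooled = {t: mape(Y[:, j], oof[:, j]) for j, t in enumerate(outcome_cols)}
    mape_fold_mean = {t: float(np.mean(v)) for t, v in fold_mapes.items()}
    return CVReport(
        model=model,
        k=k,
        seed=seed,
        fold_assignment=fold_assignment,
        predictions=pd.DataFrame(oof, columns=list(outcome_cols), index=cohort.index),
        mape_pooled=mape_pooled,
        mape_fold_mean=mape_fold_mean,
        chosen_rho1=chosen,
    )


def _inner_splits(n, inner_folds, seed):
    return list(KFold(n_splits=inner_folds, shuffle=True, random_state=seed).split(np.arange(n)))


def _select_rho_mtl(X, Y, inner_folds, grid_size, rho_l2, seed, names):
    n_tasks = Y.shape[1]
    grid = _rho_grid(
        critical_rho1([X] * n_tasks, [Y[:, i] for i in range(n_tasks)]), grid_size
    )
    splits = _inner_splits(len(X), inner_folds, seed)
    scores = []
    for rho in grid:
        errs = []
        for tr, te in splits:
            est = MultiTaskLassoRegressor(rho1=rho, rho_l2=rho_l2).fit(X[tr], Y[tr])
            pred = est.predict(X[te])
            errs.append(np.mean([mape(Y[te, j], pred[:, j]) for j in range(n_tasks)]))
        scores.append(np.mean(errs))
    return float(grid[int(np.argmin(scores))])


def _select_rho_stl(X, y, inner_folds, grid_size, seed, names):
    grid = _rho_grid(critical_rho1([X], [y]), grid_size)
    splits = _inner_splits(len(X), inner_folds, seed)
    scores = []
    for rho in grid:
        errs = []
        for tr, te in splits:
            est = SingleTaskLassoRegressor(rho1=rho).fit(X[tr], y[tr])
            errs.append(mape(y[te], est.predict(X[te])))
        scores.append(np.mean(errs))
    return float(grid[int(np.argmin(scores))])
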