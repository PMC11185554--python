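"""Penalized and dimension-reduction regressions with a shared inner tuner.

All methods address the wide regression ``y = X beta + e`` (m genes >> n
lines) on centered data, and all penalized objectives are scaled against
``(1/(2n)) * RSS`` so that the LASSO's critical penalty is
``lambda_max = max_j |x_j' y| / n`` regardless of sample size:

- ridge:              (1/(2n))||y - Xb||^2 + (lam/2)||b||^2
- LASSO:              (1/(2n))||y - Xb||^2 + lam ||b||_1
- sparse group LASSO: (1/(2n))||y - Xb||^2
                        + lam [alpha ||b||_1 + (1-alpha) sum_g sqrt(m_g) ||b_g||_2]
- PCR / PLSR:         least squares on the top-k principal components /
                      partial-least-squares latent scores.

Hyperparameters (lam or k) are chosen by seeded 5-fold cross-validation
inside the training set, with ties broken toward the more regularized
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .core import GroupPartition

__all__ = [
    "LinearFit",
    "TuningGrid",
    "fit_ridge",
    "fit_lasso",
    "fit_pcr",
    "fit_plsr",
    "fit_sparse_group_lasso",
    "tune_by_inner_cv",
    "default_lambda_grid",
    "lasso_kkt_violation",
    "sgl_kkt_violation",
]


@dataclass(frozen=True)
class LinearFit:
    """A fitted linear predictor in gene space."""

    intercept: float
    effects: np.ndarray
    tuning: float | None = None
    cv_trace: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.effects


@dataclass(frozen=True)
class TuningGrid:
    """Ordered hyperparameter candidates for the inner cross-validation."""

    candidates: tuple[float, ...]
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.candidates)
        object.__setattr__(self, "candidates", c)
        if len(c) == 0:
            raise ValueError("candidate list must be non-empty")
        diffs = np.diff(c)
        if len(c) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("candidates must be strictly ordered")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _as_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    return X, y


# ---------------------------------------------------------------------------
# Ridge


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> LinearFit:
    """Closed-form ridge solution; lam = 0 returns the min-norm OLS fit.

    Uses the dual (n x n) system when m > n so the cost never scales with
    m^2.
    """
    X, y = _as_xy(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, m = X.shape
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif m > n:
        K = X @ X.T
        alpha = np.linalg.solve(K + n * lam * np.eye(n), y)
        beta = X.T @ alpha
    else:
        G = X.T @ X
        beta = np.linalg.solve(G + n * lam * np.eye(m), X.T @ y)
    return LinearFit(0.0, beta, tuning=lam)


def _ridge_path_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xval: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Validation predictions for every lam from one SVD of the training X."""
    n = Xtr.shape[0]
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    uty = U.T @ ytr
    XvV = Xval @ Vt.T
    preds = np.empty((len(lams), Xval.shape[0]))
    for i, lam in enumerate(lams):
        if lam == 0.0:
            d = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        else:
            d = s / (s**2 + n * lam)
        preds[i] = XvV @ (d * uty)
    return preds


# ---------------------------------------------------------------------------
# LASSO


def fit_lasso(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8, max_iter: int = 100_000
) -> LinearFit:
    """l1-penalized regression via coordinate descent (scikit-learn backend)."""
    X, y = _as_xy(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return LinearFit(0.0, beta, tuning=0.0)
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=max_iter)
    model.fit(X, y)
    return LinearFit(0.0, np.asarray(model.coef_, dtype=float), tuning=lam)


def lasso_kkt_violation(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float
) -> float:
    """Max violation of the LASSO subgradient conditions (0 at an exact optimum)."""
    X, y = _as_xy(X, y)
    n = X.shape[0]
    g = X.T @ (X @ beta - y) / n
    active = beta != 0
    v_active = np.abs(g[active] + lam * np.sign(beta[active]))
    v_zero = np.maximum(np.abs(g[~active]) - lam, 0.0)
    parts = [v for v in (v_active, v_zero) if v.size]
    return float(max(p.max() for p in parts)) if parts else 0.0


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_values: int = 100, ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced penalties from lambda_max = max|X'y|/n down to ratio*lambda_max."""
    X, y = _as_xy(X, y)
    lam_max = float(np.max(np.abs(X.T @ y)) / X.shape[0])
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_values)


# ---------------------------------------------------------------------------
# PCR / PLSR


def fit_pcr(X: np.ndarray, y: np.ndarray, k: int) -> LinearFit:
    """Regress y on the top-k principal component scores of X."""
    X, y = _as_xy(X, y)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if not (0 <= k <= rank):
        raise ValueError(f"k={k} outside [0, rank={rank}]")
    if k == 0:
        return LinearFit(0.0, np.zeros(X.shape[1]), tuning=0.0)
    gamma = (U[:, :k].T @ y) / s[:k]
    beta = Vt[:k].T @ gamma
    return LinearFit(0.0, beta, tuning=float(k))


def _kernel_pls_scores(K: np.ndarray, y: np.ndarray, k: int):
    """Wide-kernel PLS recursion on the n x n Gram matrix K = X X'.

    Returns orthonormal X-scores T and y-side scores U for k components.
    Works entirely in sample space, so cost is independent of the gene
    count once K is formed.
    """
    n = K.shape[0]
    Kd = K.copy()
    yd = y.copy()
    T = np.empty((n, k))
    Uy = np.empty((n, k))
    for a in range(k):
        u = yd / np.linalg.norm(yd)
        t = Kd @ u
        nt = np.linalg.norm(t)
        if nt <= 1e-12 * max(1.0, np.linalg.norm(Kd)):
            raise ValueError(f"component {a + 1} exceeds the rank of the data")
        t /= nt
        T[:, a] = t
        Uy[:, a] = u
        # deflate both sides by the projector I - t t'
        Kt = Kd @ t
        Kd -= np.outer(t, Kt) + np.outer(Kt, t) - np.outer(t, t) * (t @ Kt)
        yd = yd - t * (t @ yd)
    return T, Uy


def fit_plsr(X: np.ndarray, y: np.ndarray, k: int) -> LinearFit:
    """Univariate partial least squares via the wide-kernel (n x n) recursion."""
    X, y = _as_xy(X, y)
    if k < 1:
        raise ValueError("k must be >= 1")
    K = X @ X.T
    T, Uy = _kernel_pls_scores(K, y, k)
    # regression coefficients mapped back to gene space (Rannar's identity)
    M = T.T @ K @ Uy
    dual = Uy @ np.linalg.solve(M, T.T @ y)
    beta = X.T @ dual
    return LinearFit(0.0, beta, tuning=float(k))


def _pls_max_components(X: np.ndarray) -> int:
    s = np.linalg.svd(X, compute_uv=False)
    return int(np.sum(s > s[0] * 1e-9)) if s.size else 0


# ---------------------------------------------------------------------------
# Sparse group LASSO


def _sgl_prox(z: np.ndarray, step: float, lam: float, alpha: float, gw: float):
    u = np.sign(z) * np.maximum(np.abs(z) - step * lam * alpha, 0.0)
    nu = np.linalg.norm(u)
    thr = step * lam * (1.0 - alpha) * gw
    if nu <= thr:
        return np.zeros_like(u)
    return (1.0 - thr / nu) * u


def fit_sparse_group_lasso(
    X: np.ndarray,
    y: np.ndarray,
    partition: GroupPartition,
    lam: float,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 2000,
    beta0: np.ndarray | None = None,
) -> LinearFit:
    """Two-group sparse group LASSO by blockwise proximal (FISTA) descent.

    The groups are the genes of one GO term versus all remaining genes;
    group weights are sqrt(group size). Convergence is declared when the
    KKT residual drops below ``tol``.
    """
    X, y = _as_xy(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if partition.n_genes != X.shape[1]:
        raise ValueError("partition does not match the number of genes")
    n = X.shape[0]
    groups = [np.asarray(partition.in_group), np.asarray(partition.out_group)]
    groups = [g for g in groups if g.size]
    Xg = [X[:, g] for g in groups]
    L = [max(np.linalg.norm(xg, 2) ** 2 / n, 1e-12) for xg in Xg]
    gw = [np.sqrt(g.size) for g in groups]

    beta = np.zeros(X.shape[1]) if beta0 is None else beta0.copy()
    resid = y - X @ beta
    for _ in range(max_iter):
        for gi, g in enumerate(groups):
            bg = beta[g]
            r_full = resid + Xg[gi] @ bg  # residual excluding this group
            # group-level screening: whole block zero by the group KKT rule
            grad0 = -(Xg[gi].T @ r_full) / n
            u0 = np.sign(-grad0) * np.maximum(np.abs(grad0) - lam * alpha, 0.0)
            if np.linalg.norm(u0) <= lam * (1.0 - alpha) * gw[gi]:
                new = np.zeros_like(bg)
            else:
                new = _fista_block(
                    Xg[gi], r_full, bg, n, L[gi], lam, alpha, gw[gi], tol
                )
            beta[g] = new
            resid = r_full - Xg[gi] @ new
        if sgl_kkt_violation(X, y, beta, partition, lam, alpha) <= tol:
            break
    return LinearFit(0.0, beta, tuning=lam)


def _fista_block(Xg, r, b, n, L, lam, alpha, gw, tol, max_inner=500):
    z = b.copy()
    t_acc = 1.0
    b_prev = b.copy()
    b_cur = b.copy()
    for _ in range(max_inner):
        grad = -(Xg.T @ (r - Xg @ z)) / n
        b_new = _sgl_prox(z - grad / L, 1.0 / L, lam, alpha, gw)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        z = b_new + ((t_acc - 1.0) / t_new) * (b_new - b_cur)
        b_prev, b_cur, t_acc = b_cur, b_new, t_new
        if np.max(np.abs(b_cur - b_prev)) < tol * 1e-2 * max(1.0, np.max(np.abs(b_cur))):
            break
    return b_cur


def sgl_kkt_violation(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    partition: GroupPartition,
    lam: float,
    alpha: float,
) -> float:
    """Max violation of the sparse-group-LASSO optimality conditions."""
    X, y = _as_xy(X, y)
    n = X.shape[0]
    grad = X.T @ (X @ beta - y) / n
    worst = 0.0
    for g in (partition.in_group, partition.out_group):
        if g.size == 0:
            continue
        bg = beta[g]
        gg = grad[g]
        w = lam * (1.0 - alpha) * np.sqrt(g.size)
        if np.all(bg == 0):
            u = np.sign(-gg) * np.maximum(np.abs(gg) - lam * alpha, 0.0)
            worst = max(worst, max(0.0, float(np.linalg.norm(u) - w)))
        else:
            nb = np.linalg.norm(bg)
            active = bg != 0
            v1 = np.abs(gg[active] + lam * alpha * np.sign(bg[active]) + w * bg[active] / nb)
            worst = max(worst, float(v1.max()))
            if np.any(~active):
                v0 = np.maximum(np.abs(gg[~active]) - lam * alpha, 0.0)
                worst = max(worst, float(v0.max()))
    return worst


# ---------------------------------------------------------------------------
# Inner cross-validation tuner


_MORE_REGULARIZED_IS_LARGER = {"ridge": True, "lasso": True, "sgl": True,
                               "pcr": False, "plsr": False}


def _cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::n_folds] for i in range(n_folds)]


def tune_by_inner_cv(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    grid: TuningGrid,
    partition: GroupPartition | None = None,
    alpha: float = 0.05,
) -> LinearFit:
    """Select the hyperparameter by seeded k-fold CV and refit on all rows.

    The candidate with the smallest mean validation MSE wins; exact ties go
    to the more regularized candidate (larger penalty, fewer components).
    """
    X, y = _as_xy(X, y)
    if method not in _MORE_REGULARIZED_IS_LARGER:
        raise ValueError(f"unknown method {method!r}")
    n = X.shape[0]
    if n < grid.n_folds:
        raise ValueError("fewer training rows than folds")
    folds = _cv_folds(n, grid.n_folds, grid.seed)
    cands = np.asarray(grid.candidates, dtype=float)
    if method in ("pcr", "plsr"):
        # inner folds must retain rank: cap components at min(n - n_folds, 50)
        cap = min(n - grid.n_folds, 50, _pls_max_components(X))
        cands = cands[cands <= cap]
        if cands.size == 0:
            cands = np.array([1.0])
    sse = np.zeros(len(cands))
    for val in folds:
        tr = np.setdiff1d(np.arange(n), val)
        Xtr, ytr, Xval, yval = X[tr], y[tr], X[val], y[val]
        preds = _candidate_predictions(method, Xtr, ytr, Xval, cands, partition, alpha)
        sse += np.sum((preds - yval[None, :]) ** 2, axis=1)
    trace = sse / n
    best = float(np.min(trace))
    tied = np.flatnonzero(trace == best)
    if _MORE_REGULARIZED_IS_LARGER[method]:
        winner = cands[tied[np.argmax(cands[tied])]]
    else:
        winner = cands[tied[np.argmin(cands[tied])]]
    fit = _fit_one(method, X, y, winner, partition, alpha)
    return LinearFit(fit.intercept, fit.effects, tuning=float(winner), cv_trace=trace)


def _fit_one(method, X, y, value, partition, alpha) -> LinearFit:
    if method == "ridge":
        return fit_ridge(X, y, value)
    if method == "lasso":
        return fit_lasso(X, y, value)
    if method == "pcr":
        return fit_pcr(X, y, int(round(value)))
    if method == "plsr":
        return fit_plsr(X, y, int(round(value)))
    if method == "sgl":
        if partition is None:
            raise ValueError("sgl requires a GroupPartition")
        return fit_sparse_group_lasso(X, y, partition, value, alpha=alpha)
    raise ValueError(method)


def _candidate_predictions(method, Xtr, ytr, Xval, cands, partition, alpha):
    """Validation predictions for every candidate, sharing work along the path."""
    if method == "ridge":
        return _ridge_path_predict(Xtr, ytr, Xval, cands)
    if method == "lasso":
        order = np.argsort(cands)[::-1]  # lasso_path wants decreasing alphas
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(
                Xtr, ytr, alphas=cands[order], tol=1e-4, max_iter=3000
            )
        preds = np.empty((len(cands), Xval.shape[0]))
        for pos, idx in enumerate(order):
            preds[idx] = Xval @ coefs[:, pos]
        return preds
    if method in ("pcr", "plsr"):
        kmax = int(np.max(cands))
        preds = np.empty((len(cands), Xval.shape[0]))
        if method == "pcr":
            U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
            rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
            uty = U.T @ ytr
            XvV = Xval @ Vt.T
            for i, c in enumerate(cands):
                k = min(int(round(c)), rank)
                preds[i] = XvV[:, :k] @ (uty[:k] / s[:k]) if k > 0 else 0.0
        else:
            kmax = min(kmax, _pls_max_components(Xtr))
            K = Xtr @ Xtr.T
            T, Uy = _kernel_pls_scores(K, ytr, kmax)
            Kv = Xval @ Xtr.T
            for i, c in enumerate(cands):
                k = min(int(round(c)), kmax)
                M = T[:, :k].T @ K @ Uy[:, :k]
                dual = Uy[:, :k] @ np.linalg.solve(M, T[:, :k].T @ ytr)
                preds[i] = Kv @ dual
        return preds
    if method == "sgl":
        preds = np.empty((len(cands), Xval.shape[0]))
        order = np.argsort(cands)[::-1]
        beta = np.zeros(Xtr.shape[1])
        for pos in order:
            fit = fit_sparse_group_lasso(
                Xtr, ytr, partition, cands[pos], alpha=alpha, beta0=beta
            )
            beta = fit.effects.copy()
            preds[pos] = Xval @ fit.effects
        return preds
    raise ValueError(method)
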