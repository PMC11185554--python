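"""Transcriptomic relationship matrices and the (GO-)TBLUP mixed models.

The transcriptomic relationship matrix (TRM) is ``T = W W' / m`` where W
holds the expression of m genes standardized to variance 1 (n-1
denominator), so ``trace(T) = n - 1``. TBLUP is the mixed model
``y = t + e`` with ``t ~ N(0, T sigma_t^2)``; GO-TBLUP carries two random
effects, one for the genes of a GO term and one for all remaining genes,
each with its own TRM built over its own gene count.

Variance components are estimated by Gibbs sampling in the eigenbasis of
each kernel (scaled-inverse-chi-squared full conditionals, prior scales
calibrated from the expected proportion of explained variance R2).
Held-out phenotypes are handled by data augmentation: the kernel is built
over all lines, test phenotypes are treated as missing and imputed from
their conditional each sweep, and the prediction is the posterior mean of
the test lines' transcriptomic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import McmcSchedule, _trace_summary
from .core import ExpressionMatrix

__all__ = [
    "Kernel",
    "KernelFit",
    "build_trm",
    "fit_tblup",
    "fit_go_tblup",
    "predict_kernel_masked",
    "blup_conditional_mean",
]

_DF_HYPER = 5.0


@dataclass(frozen=True)
class Kernel:
    """An n x n similarity matrix over lines (a TRM or sub-TRM)."""

    line_ids: tuple[str, ...]
    values: np.ndarray
    n_genes_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "line_ids", tuple(map(str, self.line_ids)))
        n = len(self.line_ids)
        if v.shape != (n, n):
            raise ValueError(f"kernel shape {v.shape} does not match {n} lines")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("kernel is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition with a positive-semidefiniteness check."""
        d, U = np.linalg.eigh(0.5 * (self.values + self.values.T))
        if d[-1] > 0 and d[0] < -1e-8 * d[-1]:
            raise ValueError(f"kernel is not PSD (min eigenvalue {d[0]:.3g})")
        return np.clip(d, 0.0, None), U


def build_trm(
    X: ExpressionMatrix, gene_subset: list[str] | None = None
) -> Kernel:
    """T = W W' / m over the chosen gene subset of a standardized matrix."""
    if not X.standardized:
        raise ValueError("build_trm requires a column-standardized matrix")
    if gene_subset is None:
        W = X.values
        m = X.n_genes
    else:
        idx = X.gene_index(gene_subset)
        if idx.size == 0:
            raise ValueError("gene subset is empty")
        W = X.values[:, idx]
        m = idx.size
    return Kernel(X.line_ids, W @ W.T / m, n_genes_used=m)


@dataclass(frozen=True)
class KernelFit:
    """Posterior summaries of a (GO-)TBLUP fit."""

    var_components: dict
    fitted_t: np.ndarray
    components: dict = field(default_factory=dict)
    schedule: McmcSchedule | None = None
    predictions: np.ndarray | None = None


def _kernel_gibbs(
    y_obs: np.ndarray,
    mask: np.ndarray | None,
    kernels: list[Kernel],
    schedule: McmcSchedule,
    names: list[str],
) -> KernelFit:
    """Gibbs sampler for one or two kernel random effects with missing y.

    Each component is sampled in its own eigenbasis (O(n^2) per sweep for
    the rotations, O(n) for the conditional draws); masked phenotypes are
    imputed from N(t_total, sigma_e^2) every sweep.
    """
    n = y_obs.shape[0]
    C = len(kernels)
    obs = np.ones(n, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    vy = float(np.var(y_obs[obs], ddof=1))
    if vy <= 0:
        raise ValueError("observed phenotype has zero variance")

    eigs = [k.eig() for k in kernels]
    ranks = [int(np.sum(d > 1e-10 * max(d[-1], 1e-300))) for d, _ in eigs]
    mean_diag = [max(float(np.mean(np.diag(k.values))), 1e-12) for k in kernels]

    S_t = [vy * (schedule.R2 / C) * (_DF_HYPER + 2.0) / md for md in mean_diag]
    S_e = vy * (1.0 - schedule.R2) * (_DF_HYPER + 2.0)

    rng = np.random.default_rng(int(schedule.seed) % (2**31 - 1))
    sig_t = [s / (_DF_HYPER + 2.0) for s in S_t]
    sig_e = S_e / (_DF_HYPER + 2.0)
    t = [np.zeros(n) for _ in range(C)]
    y_cur = y_obs.copy()
    y_cur[~obs] = 0.0

    n_ret = schedule.retained
    t_sum = [np.zeros(n) for _ in range(C)]
    sigt_trace = np.zeros((n_ret, C))
    sige_trace = np.zeros(n_ret)
    ret = 0
    for it in range(schedule.n_iter):
        for c in range(C):
            d, U = eigs[c]
            y_star = y_cur - sum(t[cc] for cc in range(C) if cc != c)
            z = U.T @ y_star
            lam = d * sig_t[c]
            denom = lam + sig_e
            post_mean = np.where(d > 0, lam / denom * z, 0.0)
            post_sd = np.where(d > 0, np.sqrt(lam * sig_e / denom), 0.0)
            tz = post_mean + post_sd * rng.standard_normal(n)
            t[c] = U @ tz
            ss = float(np.sum(np.where(d > 0, tz**2 / np.maximum(d, 1e-300), 0.0)))
            sig_t[c] = (S_t[c] + ss) / rng.chisquare(_DF_HYPER + ranks[c])
        t_tot = sum(t)
        resid = y_cur - t_tot
        sig_e = (S_e + float(resid @ resid)) / rng.chisquare(_DF_HYPER + n)
        if not obs.all():
            y_cur[~obs] = t_tot[~obs] + np.sqrt(sig_e) * rng.standard_normal(
                int((~obs).sum())
            )
        if it >= schedule.burn_in and (it - schedule.burn_in + 1) % schedule.thin == 0:
            for c in range(C):
                t_sum[c] += t[c]
            sigt_trace[ret] = sig_t
            sige_trace[ret] = sig_e
            ret += 1

    assert ret == n_ret
    comp_means = {names[c]: t_sum[c] / n_ret for c in range(C)}
    fitted = sum(comp_means.values())
    var_components: dict = {}
    share_trace = sigt_trace.sum(axis=1) / (sigt_trace.sum(axis=1) + sige_trace)
    for c in range(C):
        var_components[f"sigma_t2_{names[c]}" if C > 1 else "sigma_t2"] = (
            _trace_summary(sigt_trace[:, c])
        )
    var_components["sigma_e2"] = _trace_summary(sige_trace)
    var_components["variance_share"] = _trace_summary(share_trace)
    return KernelFit(
        var_components=var_components,
        fitted_t=fitted,
        components=comp_means,
        schedule=schedule,
    )


def fit_tblup(
    y: np.ndarray,
    T: Kernel,
    schedule: McmcSchedule,
    mask: np.ndarray | None = None,
) -> KernelFit:
    """Single-kernel TBLUP with Bayesian variance-component estimation."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != T.n_lines:
        raise ValueError("y length does not match the kernel")
    return _kernel_gibbs(y, mask, [T], schedule, ["t"])


def fit_go_tblup(
    y: np.ndarray,
    T_go: Kernel,
    T_notgo: Kernel,
    schedule: McmcSchedule,
    mask: np.ndarray | None = None,
) -> KernelFit:
    """Two-kernel TBLUP: a GO-term random effect plus a background effect."""
    y = np.asarray(y, dtype=float).ravel()
    if T_go.line_ids != T_notgo.line_ids:
        raise ValueError("kernels are defined over different line sets")
    if y.shape[0] != T_go.n_lines:
        raise ValueError("y length does not match the kernels")
    return _kernel_gibbs(y, mask, [T_go, T_notgo], schedule, ["go", "not_go"])


def blup_conditional_mean(
    T: np.ndarray, y_train: np.ndarray, train: np.ndarray, test: np.ndarray, rho: float
) -> np.ndarray:
    """Closed-form BLUP prediction at a fixed variance ratio rho = se2/st2.

    ``T_test,train (T_train,train + rho I)^-1 y_train`` — the conditional
    mean of the test lines' transcriptomic values.
    """
    Ttt = T[np.ix_(train, train)]
    Tst = T[np.ix_(test, train)]
    alpha = np.linalg.solve(Ttt + rho * np.eye(train.size), y_train)
    return Tst @ alpha


def predict_kernel_masked(
    y_train: np.ndarray,
    kernels: list[Kernel] | Kernel,
    schedule: McmcSchedule,
    test_line_ids: list[str],
    oracle_rho: float | None = None,
) -> np.ndarray:
    """Predict masked lines' phenotypes from a kernel over train+test lines.

    ``y_train`` is aligned to the training lines (all kernel lines not in
    ``test_line_ids``, in kernel order). With ``oracle_rho`` given, the
    closed-form conditional mean at that fixed variance ratio is returned
    (single kernel only); otherwise the Gibbs sampler treats the test
    phenotypes as missing data.
    """
    ks = [kernels] if isinstance(kernels, Kernel) else list(kernels)
    ids = ks[0].line_ids
    test_set = set(test_line_ids)
    missing = test_set - set(ids)
    if missing:
        raise ValueError(f"test ids absent from kernel: {sorted(missing)[:5]}")
    mask = np.array([i in test_set for i in ids])
    y_train = np.asarray(y_train, dtype=float).ravel()
    if y_train.shape[0] != int((~mask).sum()):
        raise ValueError("y_train length does not match the unmasked lines")
    y_full = np.zeros(len(ids))
    y_full[~mask] = y_train

    if oracle_rho is not None:
        if len(ks) != 1:
            raise ValueError("oracle mode supports a single kernel")
        pred_all = np.zeros(len(ids))
        pred_all[mask] = blup_conditional_mean(
            ks[0].values, y_train, np.flatnonzero(~mask), np.flatnonzero(mask),
            oracle_rho,
        )
        return pred_all[mask][_order_for(ids, mask, test_line_ids)]

    if len(ks) == 1:
        fit = fit_tblup(y_full, ks[0], schedule, mask=mask)
    elif len(ks) == 2:
        fit = fit_go_tblup(y_full, ks[0], ks[1], schedule, mask=mask)
    else:
        raise ValueError("at most two kernels are supported")
    return fit.fitted_t[mask][_order_for(ids, mask, test_line_ids)]


def _order_for(ids, mask, test_line_ids) -> np.ndarray:
    masked_ids = [i for i, m in zip(ids, mask) if m]
    pos = {lid: k for k, lid in enumerate(masked_ids)}
    return np.array([pos[t] for t in test_line_ids], dtype=int)
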