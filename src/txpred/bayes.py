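"""Bayesian sparse regressions: spike-and-slab Gibbs sampling and its
variational relatives.

Four methods share the regression ``y = X beta + e`` on centered data but
differ in prior and inference:

- ``fit_bayesc``: spike-and-slab prior
  ``beta_j ~ pi N(0, sigma_b^2) + (1 - pi) delta_0`` with scaled-inverse-
  chi-squared hyperpriors on both variances and a Beta hyperprior on pi,
  sampled by single-site Gibbs (the BayesC model).
- ``fit_go_bayesc``: the same model with independent (pi, slab variance)
  pairs for the genes of one GO term and for all remaining genes.
- ``fit_vb_spike_slab``: the same spike-and-slab likelihood handled by
  mean-field coordinate-ascent variational inference over a grid of prior
  inclusion log-odds, grid points combined by their ELBOs.
- ``fit_veb_mixture``: adaptive-shrinkage prior — a point mass plus a
  scale mixture of normals — with mixture weights estimated from the data
  by variational empirical Bayes.

Hyperprior scales are calibrated from the expected proportion of variance
explained by the predictors (``R2``, set to the trait's broad-sense
heritability): the prior modes of the residual and the total genetic
variance are ``(1 - R2) var(y)`` and ``R2 var(y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import mixture_pass, spike_slab_gibbs, vb_spike_slab_pass
from .core import GroupPartition
from .linear import LinearFit

__all__ = [
    "SpikeSlabPrior",
    "MixturePrior",
    "McmcSchedule",
    "PosteriorSummary",
    "fit_bayesc",
    "fit_go_bayesc",
    "fit_vb_spike_slab",
    "fit_veb_mixture",
    "default_logodds_grid",
    "default_mixture_grid",
]

_DF_HYPER = 5.0  # degrees of freedom of both scaled-inv-chi^2 hyperpriors
_PI_WEIGHT = 10.0  # prior "counts" of the Beta hyperprior on pi
_PI_MEAN = 0.5


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Spike-and-slab prior settings; ``None`` means 'give it a hyperprior'."""

    pi: float | None = None
    fix_pi: bool = False
    sigma_beta2: float | None = None
    sigma_e2: float | None = None
    fix_variances: bool = False

    def __post_init__(self) -> None:
        if self.pi is not None and not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must be in (0, 1]")
        if self.sigma_beta2 is not None and self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")


@dataclass(frozen=True)
class MixturePrior:
    """Point mass at zero plus K normal components with increasing variance."""

    grid: np.ndarray  # K+1 variances, grid[0] == 0
    weights: np.ndarray  # simplex over the K+1 components

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "weights", w)
        if g[0] != 0.0 or np.any(np.diff(g[1:]) <= 0) or np.any(g[1:] <= 0):
            raise ValueError("grid must be (0, v1 < v2 < ... < vK) with vk > 0")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be a simplex vector")


@dataclass(frozen=True)
class McmcSchedule:
    """Gibbs chain length, burn-in, thinning and the R2 calibration target."""

    n_iter: int = 130_000
    burn_in: int = 30_000
    thin: int = 50
    R2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.retained < 100:
            raise ValueError(
                f"schedule retains {self.retained} draws; at least 100 required"
            )
        if not (0.0 < self.R2 < 1.0):
            raise ValueError("R2 must be in (0, 1)")

    @property
    def retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summaries of a fitted sparse regression."""

    effect_mean: np.ndarray
    pip: np.ndarray
    var_components: dict
    retained_draws: int
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.effect_mean


def _trace_summary(trace: np.ndarray) -> tuple[float, float]:
    trace = np.asarray(trace, dtype=float)
    mean = float(trace.mean())
    mcse = float(trace.std(ddof=1) / np.sqrt(trace.size)) if trace.size > 1 else 0.0
    return mean, mcse


def _as_xy(X, y):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    return X, y


# ---------------------------------------------------------------------------
# Gibbs samplers


def _run_spike_slab_chain(
    X: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    n_groups: int,
    schedule: McmcSchedule,
    prior: SpikeSlabPrior,
    r2_split: np.ndarray,
) -> PosteriorSummary:
    n, m = X.shape
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype has zero variance")
    pi_mean = prior.pi if prior.pi is not None else _PI_MEAN
    a_pi = np.full(n_groups, _PI_WEIGHT * pi_mean)
    b_pi = np.full(n_groups, _PI_WEIGHT * (1.0 - pi_mean))
    pi_init = np.full(n_groups, pi_mean)
    fix_pi = bool(prior.fix_pi or prior.pi == 1.0)

    colvar = X.var(axis=0, ddof=1)
    msx = np.array(
        [max(colvar[group == g].sum(), 1e-12) for g in range(n_groups)]
    )
    S_b = vy * r2_split * (_DF_HYPER + 2.0) / (msx * pi_mean)
    S_e = vy * (1.0 - schedule.R2) * (_DF_HYPER + 2.0)

    if prior.sigma_beta2 is not None:
        sb2_init = np.full(n_groups, float(prior.sigma_beta2))
    else:
        sb2_init = S_b / (_DF_HYPER + 2.0)
    se2_init = (
        float(prior.sigma_e2)
        if prior.sigma_e2 is not None
        else S_e / (_DF_HYPER + 2.0)
    )

    seed = int(schedule.seed) % (2**31 - 1)
    (
        effect_sum,
        incl_sum,
        sb2_trace,
        se2_trace,
        pi_trace,
        gvar_trace,
        n_ret,
    ) = spike_slab_gibbs(
        X,
        y,
        group.astype(np.int64),
        n_groups,
        schedule.n_iter,
        schedule.burn_in,
        schedule.thin,
        _DF_HYPER,
        S_b,
        _DF_HYPER,
        S_e,
        a_pi,
        b_pi,
        pi_init,
        fix_pi,
        sb2_init,
        se2_init,
        bool(prior.fix_variances),
        seed,
    )
    if n_ret != schedule.retained:
        raise RuntimeError("retained draw count does not match the schedule")
    if not np.all(np.isfinite(effect_sum)):
        raise RuntimeError("non-finite effect draws in the Gibbs chain")

    var_components: dict = {}
    diagnostics: dict = {}
    labels = ["in_go", "not_go"] if n_groups == 2 else [""]
    for g in range(n_groups):
        suffix = f"_{labels[g]}" if labels[g] else ""
        var_components[f"sigma_beta2{suffix}"] = float(sb2_trace[:, g].mean())
        var_components[f"pi{suffix}"] = float(pi_trace[:, g].mean())
        var_components[f"explained_var{suffix}"] = float(gvar_trace[:, g].mean())
        diagnostics[f"sigma_beta2{suffix}"] = _trace_summary(sb2_trace[:, g])
        diagnostics[f"pi{suffix}"] = _trace_summary(pi_trace[:, g])
        diagnostics[f"explained_var{suffix}"] = _trace_summary(gvar_trace[:, g])
    var_components["sigma_e2"] = float(se2_trace.mean())
    diagnostics["sigma_e2"] = _trace_summary(se2_trace)

    return PosteriorSummary(
        effect_mean=effect_sum / n_ret,
        pip=incl_sum / n_ret,
        var_components=var_components,
        retained_draws=int(n_ret),
        diagnostics=diagnostics,
    )


def fit_bayesc(
    X: np.ndarray,
    y: np.ndarray,
    schedule: McmcSchedule,
    prior: SpikeSlabPrior | None = None,
) -> PosteriorSummary:
    """Spike-and-slab Gibbs sampler over all genes (BayesC)."""
    X, y = _as_xy(X, y)
    prior = prior or SpikeSlabPrior()
    group = np.zeros(X.shape[1], dtype=np.int64)
    return _run_spike_slab_chain(
        X, y, group, 1, schedule, prior, np.array([schedule.R2])
    )


def fit_go_bayesc(
    X: np.ndarray,
    y: np.ndarray,
    partition: GroupPartition,
    schedule: McmcSchedule,
    prior: SpikeSlabPrior | None = None,
) -> PosteriorSummary:
    """Two-group spike-and-slab Gibbs sampler (GO term vs all other genes).

    The prior expected explained variance R2 is split equally between the
    two groups; each group samples its own inclusion probability and slab
    variance.
    """
    X, y = _as_xy(X, y)
    if partition.n_genes != X.shape[1]:
        raise ValueError("partition does not match the number of genes")
    prior = prior or SpikeSlabPrior()
    group = np.empty(X.shape[1], dtype=np.int64)
    group[partition.in_group] = 0
    group[partition.out_group] = 1
    r2_split = np.array([schedule.R2 / 2.0, schedule.R2 / 2.0])
    return _run_spike_slab_chain(X, y, group, 2, schedule, prior, r2_split)


# ---------------------------------------------------------------------------
# Variational spike-and-slab (VARBVS-style)


def default_logodds_grid(m: int, n_points: int = 9) -> np.ndarray:
    """Base-10 prior inclusion log-odds spanning [-log10(m), -1]."""
    lo = -np.log10(max(m, 10))
    return np.linspace(lo, -1.0, n_points)


def _vb_elbo(d, y, Xr, alpha, mu, s2, sigma2, sa2, pi):
    n = y.shape[0]
    rbar = alpha * mu
    var_b = alpha * (s2 + mu**2) - rbar**2
    rss = float(np.sum((y - Xr) ** 2))
    elbo = -0.5 * n * np.log(2.0 * np.pi * sigma2) - (rss + float(d @ var_b)) / (
        2.0 * sigma2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = alpha * (np.log(pi) - np.log(np.maximum(alpha, 1e-300))) + (
            1.0 - alpha
        ) * (np.log1p(-pi) - np.log(np.maximum(1.0 - alpha, 1e-300)))
    elbo += float(np.sum(ent))
    slab = sigma2 * sa2
    elbo += 0.5 * float(
        np.sum(alpha * (1.0 + np.log(s2 / slab) - (s2 + mu**2) / slab))
    )
    return elbo


def fit_vb_spike_slab(
    X: np.ndarray,
    y: np.ndarray,
    logodds_grid: np.ndarray | None = None,
    sigma2: float | None = None,
    sa2: float | None = None,
    update_hyper: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> PosteriorSummary:
    """Mean-field variational spike-and-slab over a prior log-odds grid.

    Each grid point runs coordinate ascent on (alpha_j, mu_j, s_j^2) —
    with empirical-Bayes updates of the residual variance and the slab
    scale unless fixed — until the ELBO improves by less than ``tol``.
    Grid points are combined with normalized weights proportional to
    exp(ELBO). The ELBO is checked to be non-decreasing; a decrease beyond
    1e-8 signals an update bug and raises.
    """
    X, y = _as_xy(X, y)
    n, m = X.shape
    if logodds_grid is None:
        logodds_grid = default_logodds_grid(m)
    logodds_grid = np.atleast_1d(np.asarray(logodds_grid, dtype=float))
    if logodds_grid.size == 0:
        raise ValueError("logodds_grid must be non-empty")
    d = np.sum(X**2, axis=0)

    elbos = np.empty(logodds_grid.size)
    alphas = np.empty((logodds_grid.size, m))
    mus = np.empty((logodds_grid.size, m))
    sig2_init = float(np.var(y, ddof=1)) if sigma2 is None else float(sigma2)
    sa2_init = 1.0 if sa2 is None else float(sa2)

    for gi, lo10 in enumerate(logodds_grid):
        pi = 1.0 / (1.0 + 10.0 ** (-lo10))
        lo_nat = np.log(10.0) * lo10
        alpha = np.full(m, pi)
        mu = np.zeros(m)
        s2 = np.full(m, sig2_init / (d + 1.0 / sa2_init))
        sig2, sa2_cur = sig2_init, sa2_init
        Xr = X @ (alpha * mu)
        prev = -np.inf
        for _ in range(max_iter):
            vb_spike_slab_pass(X, d, y, Xr, alpha, mu, s2, sig2, sa2_cur, lo_nat)
            if update_hyper and sigma2 is None:
                rbar = alpha * mu
                var_b = alpha * (s2 + mu**2) - rbar**2
                num = (
                    float(np.sum((y - Xr) ** 2))
                    + float(d @ var_b)
                    + float(np.sum(alpha * (s2 + mu**2))) / sa2_cur
                )
                sig2 = num / (n + float(np.sum(alpha)))
            if update_hyper and sa2 is None:
                s_alpha = float(np.sum(alpha))
                if s_alpha > 1e-12:
                    sa2_cur = float(np.sum(alpha * (s2 + mu**2))) / (
                        sig2 * s_alpha
                    )
                    sa2_cur = max(sa2_cur, 1e-12)
            cur = _vb_elbo(d, y, Xr, alpha, mu, s2, sig2, sa2_cur, pi)
            if cur < prev - 1e-8:
                raise RuntimeError(
                    f"ELBO decreased from {prev:.10g} to {cur:.10g}"
                )
            if cur - prev < tol:
                prev = cur
                break
            prev = cur
        elbos[gi] = prev
        alphas[gi] = alpha
        mus[gi] = mu

    w = np.exp(elbos - elbos.max())
    w /= w.sum()
    pip = w @ alphas
    effect = w @ (alphas * mus)
    return PosteriorSummary(
        effect_mean=effect,
        pip=pip,
        var_components={"elbo_max": float(elbos.max())},
        retained_draws=0,
        diagnostics={"grid_weights": (w, elbos)},
    )


# ---------------------------------------------------------------------------
# Variational empirical Bayes mixture of normals (MR.ASH-style)


def default_mixture_grid(X: np.ndarray, y: np.ndarray, K: int = 20) -> np.ndarray:
    """Variance grid (0, then K geometric values) spanned by the data scale.

    The anchor is ``s_hat = max_j |x_j' y| / n`` — the largest univariate
    signal — and the grid runs geometrically from ``(0.01 s_hat)^2`` to
    ``(2 s_hat)^2``.
    """
    X, y = _as_xy(X, y)
    s_hat = float(np.max(np.abs(X.T @ y)) / X.shape[0])
    if s_hat <= 0:
        s_hat = 1.0
    return np.concatenate([[0.0], np.geomspace((0.01 * s_hat) ** 2, (2.0 * s_hat) ** 2, K)])


def _mixture_elbo(d, y, Xr, b, post_m2, resp, mu_mat, s2_mat, pi, grid_var, sigma2):
    """Evidence lower bound at the stored variational state."""
    n = y.shape[0]
    var_b = post_m2 - b**2
    rss = float(np.sum((y - Xr) ** 2))
    elbo = -0.5 * n * np.log(2.0 * np.pi * sigma2) - (rss + float(d @ var_b)) / (
        2.0 * sigma2
    )
    kl = 0.0
    for k in range(grid_var.size):
        phi = resp[:, k]
        nz = phi > 0
        if not np.any(nz):
            continue
        lp = np.log(max(pi[k], 1e-300))
        term = phi[nz] * (np.log(phi[nz]) - lp)
        if grid_var[k] > 0:
            mu_k = mu_mat[nz, k]
            s2_k = s2_mat[nz, k]
            term = term + phi[nz] * 0.5 * (
                np.log(grid_var[k] / s2_k) + (s2_k + mu_k**2) / grid_var[k] - 1.0
            )
        kl += float(np.sum(term))
    return elbo - kl


def fit_veb_mixture(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 20,
    init: LinearFit | np.ndarray | None = None,
    grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    update_weights: bool = True,
    sigma2: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PosteriorSummary:
    """Coordinate-ascent variational EB with a mixture-of-normals prior.

    The E-step computes each gene's exact single-coordinate posterior
    (component responsibilities and moments) given the others; the M-step
    re-estimates the simplex of mixture weights and the residual variance.
    Stops when the relative ELBO change falls below ``tol`` or after
    ``max_iter`` sweeps (the weight updates have a notoriously flat tail,
    so the cap usually binds on large problems, as in the reference
    empirical-Bayes shrinkage implementations).
    """
    X, y = _as_xy(X, y)
    n, m = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    d = np.sum(X**2, axis=0)
    grid_var = default_mixture_grid(X, y, K) if grid is None else np.asarray(grid, float)
    K1 = grid_var.size
    pi = np.full(K1, 1.0 / K1) if weights is None else np.asarray(weights, float).copy()
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise RuntimeError("mixture weights left the simplex")

    if init is None:
        b = np.zeros(m)
    elif isinstance(init, LinearFit):
        b = np.asarray(init.effects, dtype=float).copy()
    else:
        b = np.asarray(init, dtype=float).copy()
    post_m2 = b**2
    resp = np.zeros((m, K1))
    mu_mat = np.zeros((m, K1))
    s2_mat = np.zeros((m, K1))
    sig2 = float(np.var(y, ddof=1)) if sigma2 is None else float(sigma2)
    Xr = X @ b

    prev = -np.inf
    elbo = prev
    n_it = 0
    for n_it in range(1, max_iter + 1):
        mixture_pass(
            X, d, y, Xr, b, post_m2, resp, mu_mat, s2_mat, pi, grid_var, sig2, True
        )
        if update_weights:
            pi = resp.mean(axis=0)
            pi = np.maximum(pi, 0.0)
            pi /= pi.sum()
        if sigma2 is None:
            var_b = post_m2 - b**2
            sig2 = (float(np.sum((y - Xr) ** 2)) + float(d @ var_b)) / n
        elbo = _mixture_elbo(
            d, y, Xr, b, post_m2, resp, mu_mat, s2_mat, pi, grid_var, sig2
        )
        if elbo < prev - 1e-8:
            raise RuntimeError(f"ELBO decreased from {prev:.10g} to {elbo:.10g}")
        if np.isfinite(prev) and abs(elbo - prev) <= tol * max(1.0, abs(elbo)):
            prev = elbo
            break
        prev = elbo

    return PosteriorSummary(
        effect_mean=b,
        pip=1.0 - resp[:, 0],
        var_components={
            "sigma_e2": sig2,
            "pi0": float(pi[0]),
            "elbo": float(elbo),
            "n_iterations": float(n_it),
        },
        retained_draws=0,
        diagnostics={"weights": pi, "grid": grid_var},
    )
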