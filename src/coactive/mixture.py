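"""Gamma-normal mixture modelling of log2CPM expression values.

Each gene's non-zero log2CPM values are modelled as a two-component mixture:
a gamma component for lowly expressed cells and a normal component for highly
expressed ("active") cells,

    f(x) = (1 - rho) * Gamma(x; alpha, beta) + rho * Normal(x; mu, sigma^2),

with beta a rate parameter.  The fit is obtained by EM on the zero-stripped
values; the membership posterior z_i of the normal component drives the
ternary call: 0 for zero counts, 1 for the gamma component, 2 for the normal
component (z_i >= 0.5), and NA when a gene has too few non-zero cells to fit.

The M-step updates mu, sigma^2 and rho in closed form; the gamma shape is
recovered by inverting the digamma function in the weighted score equation
digamma(alpha) = log(beta) + weighted mean of log x, using the previous
iteration's rate, after which the rate is updated from the new shape.  Both
are exact conditional maximisations, so the observed-data log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, polygamma

SIGMA2_FLOOR = 1e-6
RHO_BOUNDARY = 1e-6


@dataclass(frozen=True)
class EMConfig:
    """Convergence and calling controls for the per-gene EM fit.

    Parameters
    ----------
    max_iter : maximum EM iterations per gene.
    tol : relative parameter-change threshold declaring convergence.
    min_nonzero_cells : genes with fewer non-zero cells than this are not
        fitted (they become NA, or candidates for contextualization).
    seed : drives the Bernoulli(0.5) initialization of the posteriors.
    z_call_threshold : posterior cut-off for the "high" call (inclusive).
    """

    max_iter: int = 500
    tol: float = 1e-6
    min_nonzero_cells: int = 10
    seed: int = 0
    z_call_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.min_nonzero_cells < 2:
            raise ValueError("min_nonzero_cells must be >= 2")
        if not 0.0 < self.z_call_threshold < 1.0:
            raise ValueError("z_call_threshold must be in (0, 1)")


@dataclass
class MixtureFit:
    """Per-gene gamma-normal mixture estimate.

    ``z`` holds the posterior probability of the normal (high) component for
    each non-zero cell, in the order the values were supplied after zero
    removal.  ``single_component`` is None for a genuine two-component fit,
    or "gamma"/"normal" when the mixing weight collapsed to a boundary.
    """

    alpha: float
    beta: float
    mu: float
    sigma2: float
    rho: float
    z: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_used: int
    n_iter: int
    single_component: str | None = None


class InsufficientCellsError(ValueError):
    """Raised when a gene has too few non-zero cells to fit the mixture."""


def log2cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Shifted-log counts-per-million transform, y = log2(1 + 1e6 * r / libsize).

    ``counts`` is genes x cells with non-negative integer entries.  Every
    cell must have a positive total count.
    """
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    totals = values.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = ", ".join(str(counts.columns[i]) for i in dead[:5])
        raise ValueError(f"cells with zero total count: {names}")
    y = np.log2(1.0 + 1e6 * values / totals)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


def gamma_log_density(x, alpha: float, beta: float):
    """Log density of Gamma(alpha, rate=beta) at x > 0."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma parameters must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma density requires x > 0")
    return alpha * np.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(x) - beta * x


def normal_log_density(x, mu: float, sigma2: float):
    """Log density of Normal(mu, sigma2) at x."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2.0 * np.pi * sigma2) - (x - mu) ** 2 / (2.0 * sigma2)


def inverse_digamma(y, tol: float = 1e-12, max_iter: int = 60):
    """Invert the digamma function: return w > 0 with digamma(w) = y.

    Newton iteration with the standard piecewise initialisation
    (exp(y) + 0.5 for y >= -2.22, else -1/(y + Euler-Mascheroni)); digamma is
    monotone and concave on (0, inf) so the iteration converges for any real y.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y + np.euler_gamma))
    w = np.maximum(w, np.finfo(float).tiny)
    for _ in range(max_iter):
        resid = digamma(w) - y
        if np.all(np.abs(resid) < tol):
            break
        step = resid / polygamma(1, w)
        w_new = w - step
        # digamma is concave so Newton can only overshoot past zero from the
        # left tail; fall back to halving w, which keeps the iterate positive.
        w = np.where(w_new > 0, w_new, w / 2.0)
    return float(w[0]) if scalar else w


def e_step(x, alpha, beta, mu, sigma2, rho):
    """Posterior probability of the normal (high) component for each value.

    z_i = rho f_N(x_i) / (rho f_N(x_i) + (1 - rho) f_G(x_i)), evaluated in
    log space as the logistic of eta_i = logit(rho) + log f_N - log f_G.
    Boundary mixing weights return constant posteriors rather than erroring.
    """
    x = np.asarray(x, dtype=float)
    if rho <= 0.0:
        return np.zeros_like(x)
    if rho >= 1.0:
        return np.ones_like(x)
    log_n = normal_log_density(x, mu, sigma2)
    log_g = gamma_log_density(x, alpha, beta)
    if np.any(np.isnan(log_n)) or np.any(np.isnan(log_g)):
        raise FloatingPointError("NaN encountered in component densities")
    eta = np.log(rho) - np.log1p(-rho) + log_n - log_g
    return expit(eta)


#: shape cap for degenerate gamma fits (weighted sample nearly constant)
ALPHA_CAP = 1e8


def _weighted_gamma_mle(wmean_x: float, wmean_logx: float) -> tuple[float, float]:
    """Solve the weighted gamma score equations
    digamma(alpha) = log(beta) + weighted mean log x and
    beta = alpha / weighted mean x, i.e. the profile root of
    log(alpha) - digamma(alpha) = log(mean x) - mean log x,
    by generalised Newton iteration on 1/alpha."""
    s = np.log(wmean_x) - wmean_logx  # >= 0 by Jensen; 0 iff sample constant
    if s <= 1e-12:
        return ALPHA_CAP, ALPHA_CAP / wmean_x
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(60):
        num = np.log(a) - digamma(a) - s
        den = 1.0 / a - polygamma(1, a)
        a_new = 1.0 / (1.0 / a + num / (a * a * den))
        if not np.isfinite(a_new) or a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) <= 1e-12 * max(a, 1.0):
            a = a_new
            break
        a = a_new
    a = min(float(a), ALPHA_CAP)
    return a, a / wmean_x


def m_step(x, z):
    """Maximisation step of the EM algorithm.

    Normal mean/variance and the mixing weight have closed-form weighted
    updates; the gamma shape and rate jointly solve the weighted score
    equations digamma(alpha) = log(beta) + weighted mean of log x and
    beta = alpha * sum(1-z) / sum((1-z) x).  Solving the pair to its fixed
    point makes the step an exact conditional maximisation, so the
    observed-data log-likelihood trace is monotone.

    Returns (alpha, beta, mu, sigma2, rho).  When one component carries no
    weight, its parameters are left at neutral placeholders and rho signals
    the collapse (0 or 1).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    sum_z = z.sum()
    sum_w = n - sum_z
    rho = sum_z / n

    if sum_z > 0:
        mu = float(np.sum(z * x) / sum_z)
        sigma2 = float(np.sum(z * (x - mu) ** 2) / sum_z)
        sigma2 = max(sigma2, SIGMA2_FLOOR)
    else:
        mu, sigma2 = 0.0, 1.0

    if sum_w > 0:
        w = 1.0 - z
        wmean_x = float(np.sum(w * x) / sum_w)
        wmean_logx = float(np.sum(w * np.log(x)) / sum_w)
        alpha, beta = _weighted_gamma_mle(wmean_x, wmean_logx)
    else:
        alpha, beta = 1.0, 1.0

    return alpha, beta, mu, sigma2, rho


def _observed_loglik(x, alpha, beta, mu, sigma2, rho):
    log_g = gamma_log_density(x, alpha, beta)
    log_n = normal_log_density(x, mu, sigma2)
    with np.errstate(divide="ignore"):
        a = np.log1p(-rho) + log_g if rho < 1.0 else np.full_like(x, -np.inf)
        b = np.log(rho) + log_n if rho > 0.0 else np.full_like(x, -np.inf)
    return float(np.logaddexp(a, b).sum())


def _em_once(x: np.ndarray, z0: np.ndarray, config: EMConfig) -> MixtureFit:
    """One EM run from a given posterior initialisation."""
    n = x.size
    z = z0
    params = None
    trace: list[float] = []
    converged = False
    single: str | None = None
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        alpha, beta, mu, sigma2, rho = m_step(x, z)
        new_params = (alpha, beta, mu, sigma2, rho)
        trace.append(_observed_loglik(x, alpha, beta, mu, sigma2, rho))

        if rho < RHO_BOUNDARY:
            single = "gamma"
            params = (alpha, beta, mu, sigma2, 0.0)
            z = np.zeros(n)
            break
        if rho > 1.0 - RHO_BOUNDARY:
            single = "normal"
            params = (alpha, beta, mu, sigma2, 1.0)
            z = np.ones(n)
            break

        if params is not None:
            rel = max(
                abs(a - b) / max(abs(b), 1e-8) for a, b in zip(new_params, params)
            )
            if rel < config.tol:
                params = new_params
                converged = True
                z = e_step(x, *params)
                break
        params = new_params
        z = e_step(x, *params)

    alpha, beta, mu, sigma2, rho = params
    return MixtureFit(
        alpha=alpha,
        beta=beta,
        mu=mu,
        sigma2=sigma2,
        rho=rho,
        z=np.asarray(z, dtype=float),
        loglik_trace=np.asarray(trace, dtype=float),
        converged=converged or single is not None,
        n_used=n,
        n_iter=n_iter,
        single_component=single,
    )


def _swapped(fit: MixtureFit) -> bool:
    """True when the gamma component sits above the normal component.

    The model is interpreted with the gamma as the low-expression component
    and the normal as the high one; EM started from random memberships can
    converge to the mirrored mode (a large-shape gamma is nearly normal), so
    the orientation constraint gamma mean <= normal mean identifies the fit.
    """
    if fit.single_component is not None:
        return False
    return fit.alpha / fit.beta > fit.mu


def fit_gamma_normal(x_all, config: EMConfig = EMConfig()) -> MixtureFit:
    """Fit the gamma-normal mixture to one gene's log2CPM values by EM.

    Zeros are stripped before fitting.  The posteriors are initialised by
    seeded Bernoulli(0.5) draws; E and M steps alternate until the maximum
    relative parameter change drops below ``config.tol`` or ``max_iter`` is
    reached.  If the mixing weight collapses to a boundary the fit is frozen
    there and flagged single-component.  A converged fit whose gamma mean
    lies above the normal mean is label-switched; it is re-run once from the
    mirrored posteriors to restore the low-gamma / high-normal orientation.

    Raises
    ------
    InsufficientCellsError
        if fewer than ``config.min_nonzero_cells`` values are non-zero.
    """
    x_all = np.asarray(x_all, dtype=float)
    x = x_all[x_all > 0]
    n = x.size
    if n < config.min_nonzero_cells:
        raise InsufficientCellsError(
            f"{n} non-zero cells < min_nonzero_cells={config.min_nonzero_cells}"
        )

    rng = np.random.default_rng(config.seed)
    z0 = rng.integers(0, 2, size=n).astype(float)
    # Degenerate initial draws (all 0s or all 1s) would collapse immediately;
    # nudge one entry so both components start with weight.
    if z0.sum() == 0:
        z0[0] = 1.0
    elif z0.sum() == n:
        z0[0] = 0.0

    fit = _em_once(x, z0, config)
    if _swapped(fit):
        refit = _em_once(x, 1.0 - fit.z, config)
        if not _swapped(refit):
            fit = refit
    return fit


def classify_cells(fit: MixtureFit, threshold: float = 0.5) -> np.ndarray:
    """Ternary call for each non-zero cell: 2 ("high") iff z >= threshold, else 1."""
    return np.where(fit.z >= threshold, 2, 1)


def build_ternary_matrix(
    logexpr: pd.DataFrame, config: EMConfig = EMConfig()
) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Fit every gene and assemble the ternary state matrix.

    Entries are 0 where log2CPM is 0, 1/2 from the per-gene mixture call, and
    NaN (the NA state) at the non-zero positions of genes with too few
    non-zero cells.  Per-gene seeds are derived from ``config.seed`` so the
    whole matrix is reproducible.  Returns the ternary matrix and the per-gene
    fits for the genes that could be fitted.
    """
    values = logexpr.to_numpy()
    out = np.zeros(values.shape, dtype=float)
    fits: dict[str, MixtureFit] = {}
    gene_seeds = (
        np.random.SeedSequence(config.seed).generate_state(values.shape[0]) % 2**31
    )
    for i, gene in enumerate(logexpr.index):
        row = values[i]
        nz = row > 0
        if not nz.any():
            continue
        gene_config = EMConfig(
            max_iter=config.max_iter,
            tol=config.tol,
            min_nonzero_cells=config.min_nonzero_cells,
            seed=int(gene_seeds[i]),
            z_call_threshold=config.z_call_threshold,
        )
        try:
            fit = fit_gamma_normal(row, gene_config)
        except InsufficientCellsError:
            out[i, nz] = np.nan
            continue
        fits[gene] = fit
        out[i, nz] = classify_cells(fit, config.z_call_threshold)
    return pd.DataFrame(out, index=logexpr.index, columns=logexpr.columns), fits
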