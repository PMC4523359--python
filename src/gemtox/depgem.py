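"""Covariate-dependent GEM model driven by latent Gaussian processes.

Each stick fraction V_j(X) is tied to a latent Gaussian process Z_j(X) with
a squared-exponential covariance over the (rescaled) covariate, through the
Gaussian-copula link

    V_j(X) = 1 - (1 - Phi(Z_j(X)))^(1/M),

which makes every V_j(X) marginally Beta(1, M) — the GEM requirement —
while the GP correlation structure makes compositions evolve smoothly with
the covariate.  The bandwidth is, informally, the covariate distance one has
to travel before the community can change substantially.

Posterior sampling is a Gibbs sweep with Metropolis-Hastings steps for the
nonconjugate conditionals:

* each stick row Z_j: an under-relaxed autoregressive proposal
  Z' = sqrt(1-eps^2) Z + eps eta with eta drawn from the GP prior, which
  leaves the prior exactly invariant so the acceptance ratio reduces to the
  multinomial likelihood ratio;
* the precision M: random-walk MH on log M under a Gamma hyperprior;
* the bandwidth: whitened random-walk MH on the log scale under a
  log-normal hyperprior — the standardized field L^-1 Z is held fixed and
  the rows move with the kernel, so the bandwidth and the latent surfaces
  mix jointly.

Predictions at unobserved covariate values use, per retained draw, the GP
conditional (kriging) mean of each Z_j given its values at the observed
sites, followed by the copula transform and stick-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, ndtri

from gemtox.ensemble import PosteriorEnsemble
from gemtox.gem import GEMHyperparams, MCMCConfig, stick_break

__all__ = [
    "DepGEMConfig",
    "gp_covariance",
    "transform_to_sticks",
    "log_likelihood",
    "run_depgem",
    "fit_summary",
]

_JITTER = 1e-8
_VMIN, _VMAX = 1e-300, 1.0 - 1e-16


def default_prediction_grid(grid_max: float = 25_000.0, step: float = 625.0) -> np.ndarray:
    """Covariate grid 0..grid_max inclusive in the given step (mg/kg)."""
    return np.arange(0.0, grid_max + step / 2, step)


@dataclass(frozen=True)
class DepGEMConfig:
    """Configuration of the dependent-GEM fit.

    ``bandwidth_log_mean``/``bandwidth_log_sd`` parameterize the log-normal
    bandwidth hyperprior on the internally rescaled covariate (divided by
    its maximum, so 1.0 is the full observed range); the default centres the
    prior on a quarter of the range.  ``J`` defaults to the number of
    retained OTUs plus ``extra_sticks`` spare sticks for unobserved taxa.
    """

    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    m_hyper: GEMHyperparams = field(default_factory=GEMHyperparams)
    J: int | None = None
    extra_sticks: int = 25
    bandwidth_log_mean: float = float(np.log(0.25))
    bandwidth_log_sd: float = 1.0
    prediction_grid: np.ndarray = field(default_factory=default_prediction_grid)
    eps_init: float = 0.1
    m_step_init: float = 0.3
    bw_step_init: float = 0.3
    covariate_scale: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.prediction_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("prediction_grid must be a 1-D vector of >= 2 values")
        if (np.diff(grid) <= 0).any():
            raise ValueError("prediction_grid must be strictly increasing")
        if (grid < 0).any():
            raise ValueError("prediction_grid values must be nonnegative")
        object.__setattr__(self, "prediction_grid", grid)


def gp_covariance(x: np.ndarray, bandwidth: float, gp_variance: float = 1.0,
                  jitter: float = _JITTER) -> np.ndarray:
    """Squared-exponential kernel matrix over covariate locations.

    k(x, x') = gp_variance * exp(-(x - x')^2 / (2 bandwidth^2)), with a small
    diagonal jitter so Cholesky factorization is stable.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if gp_variance <= 0:
        raise ValueError("gp_variance must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    diff = x[:, None] - x[None, :]
    K = gp_variance * np.exp(-0.5 * (diff / bandwidth) ** 2)
    if jitter:
        K = K + jitter * np.eye(x.size)
    return K


def _cross_covariance(x: np.ndarray, g: np.ndarray, bandwidth: float) -> np.ndarray:
    diff = np.asarray(x, float)[:, None] - np.asarray(g, float)[None, :]
    return np.exp(-0.5 * (diff / bandwidth) ** 2)


def transform_to_sticks(Z: np.ndarray, M: float) -> np.ndarray:
    """Map latent Gaussians to stick fractions: V = 1 - (1 - Phi(Z))^(1/M).

    This is the Beta(1, M) quantile of Phi(Z), so standard-normal Z gives
    exactly Beta(1, M) marginals; monotone increasing in Z.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    a = log_ndtr(-np.asarray(Z, dtype=float)) / M  # log(1 - Phi(Z)) / M
    return np.clip(-np.expm1(a), _VMIN, _VMAX)


def log_likelihood(table, otu_probs: np.ndarray) -> float:
    """Multinomial log likelihood sum_i sum_j N_i(j) log p_j(X_i).

    ``otu_probs`` has shape (n_sites, K) with K >= n_otus; column k < n_otus
    is the probability of table OTU k at each site (extra columns — spare
    sticks or tail mass — carry no observations and are ignored).
    """
    p = np.asarray(otu_probs, dtype=float)
    if p.ndim != 2 or p.shape[0] != table.n_sites or p.shape[1] < table.n_otus:
        raise ValueError(
            f"otu_probs must be (n_sites={table.n_sites}, >= n_otus={table.n_otus})"
        )
    used = p[:, : table.n_otus]
    counts = table.counts.T  # (site, otu)
    if ((used <= 0) & (counts > 0)).any():
        raise ValueError("zero probability assigned to an observed OTU")
    with np.errstate(divide="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.where(used > 0, used, 1.0)), 0.0)
    ll = float(terms.sum())
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log likelihood")
    return ll


def _row_loglik(logV: np.ndarray, log1mV: np.ndarray,
                n: np.ndarray, m: np.ndarray) -> np.ndarray:
    # per-stick-row likelihood contribution; the multinomial factorizes as
    # sum_i [ n_ji log V_ji + (counts after j at i) log(1 - V_ji) ]
    return (n * logV + m * log1mV).sum(axis=1)


def run_depgem(table, cov, config: DepGEMConfig | None = None, seed: int = 0,
               prior_only: bool = False, progress: bool = False) -> PosteriorEnsemble:
    """Fit the dependent GEM model and predict over the covariate grid.

    Parameters
    ----------
    table : OTUCountTable (already abundance-filtered).
    cov : CovariateVector with pairwise-distinct jittered values (or raw
        values already distinct).
    config : DepGEMConfig; defaults to the full-length MCMC settings and a 0-25,000 mg/kg
        grid in steps of 625.
    seed : master seed; all proposal streams derive from it.
    prior_only : switch the likelihood off (used to verify that the sampler
        leaves the GP-copula prior invariant).

    Returns
    -------
    PosteriorEnsemble with points = prediction grid (plus per-site fitted
    compositions in ``site_compositions``) and M / bandwidth traces.
    """
    config = config or DepGEMConfig()
    mcmc = config.mcmc
    x_raw = np.asarray(cov.values, dtype=float)
    if len(np.unique(x_raw)) != x_raw.size:
        raise ValueError("covariates must be pairwise distinct (jitter ties first)")
    if not prior_only and (table.site_totals == 0).any():
        raise ValueError("every site must have at least one count")
    if table.n_sites != x_raw.size:
        raise ValueError("table and covariates disagree on the number of sites")

    n_otus, n_sites = table.n_otus, table.n_sites
    J = config.J if config.J is not None else n_otus + config.extra_sticks
    if J < n_otus:
        raise ValueError("truncation J must be at least the number of OTUs")

    grid = config.prediction_grid
    scale = config.covariate_scale or max(float(x_raw.max()), float(grid.max()), 1.0)
    x = x_raw / scale
    g = grid / scale
    # grid points that coincide with an observed site: copy, don't solve
    match = np.full(g.size, -1, dtype=np.int64)
    for gi in range(g.size):
        hits = np.flatnonzero(np.abs(x - g[gi]) < 1e-12)
        if hits.size:
            match[gi] = hits[0]

    order = np.argsort(-table.otu_totals, kind="stable")
    stick_of_otu = np.empty(n_otus, dtype=np.int64)
    stick_of_otu[order] = np.arange(n_otus)
    n = np.zeros((J, n_sites))
    n[:n_otus] = table.counts[order].astype(float)
    if prior_only:
        n[:] = 0.0
    tail = np.flip(np.cumsum(np.flip(n, axis=0), axis=0), axis=0)
    m = np.vstack([tail[1:], np.zeros((1, n_sites))])  # counts after stick j

    rng = np.random.default_rng(int(seed) % (2**31))
    hyper = config.m_hyper
    M = hyper.M
    bandwidth = float(np.exp(config.bandwidth_log_mean))
    K = gp_covariance(x, bandwidth)
    L = cholesky(K, lower=True)

    # smooth data-informed start: pooled (covariate-free) shrunk stick
    # fractions mapped through the inverse copula, constant across sites.
    # A flat start is exactly compatible with any bandwidth, so the
    # bandwidth and the rows can relax jointly toward the data.
    V0 = (1.0 + n.sum(axis=1)) / (2.0 + n.sum(axis=1) + m.sum(axis=1))
    V0 = np.clip(V0, 1e-6, 1.0 - 1e-6)
    z0 = np.clip(ndtri(-np.expm1(M * np.log1p(-V0))), -8.0, 8.0)
    Z = np.repeat(z0[:, None], n_sites, axis=1)

    def recompute(Zc: np.ndarray, Mc: float):
        log1mPhi = log_ndtr(-Zc)
        a = log1mPhi / Mc
        V = np.clip(-np.expm1(a), _VMIN, _VMAX)
        return log1mPhi, a, V, np.log(V)

    log1mPhi, a, V, logV = recompute(Z, M)
    row_ll = _row_loglik(logV, a, n, m)

    eps = np.full(J, config.eps_init)
    m_step = config.m_step_init
    bw_step = config.bw_step_init
    acc_rows = np.zeros(J)
    acc_rows_win = np.zeros(J)
    acc_M = acc_bw = 0
    acc_M_win = acc_bw_win = 0
    window = 100

    n_draws = mcmc.n_draws
    comps_grid = np.empty((n_draws, grid.size, J + 1))
    comps_site = np.empty((n_draws, n_sites, J + 1))
    M_trace = np.empty(n_draws)
    bw_trace = np.empty(n_draws)
    d = 0

    a_g, b_g = hyper.M_prior_shape, hyper.M_prior_rate

    for it in range(mcmc.iterations):
        # (a) stick rows: prior-preserving under-relaxed proposal
        eta = rng.standard_normal((J, n_sites)) @ L.T
        Zp = np.sqrt(1.0 - eps ** 2)[:, None] * Z + eps[:, None] * eta
        log1mPhi_p = log_ndtr(-Zp)
        a_p = log1mPhi_p / M
        Vp = np.clip(-np.expm1(a_p), _VMIN, _VMAX)
        logVp = np.log(Vp)
        row_ll_p = _row_loglik(logVp, a_p, n, m)
        acc = np.log(rng.random(J)) < (row_ll_p - row_ll)
        if acc.any():
            Z[acc] = Zp[acc]
            log1mPhi[acc] = log1mPhi_p[acc]
            a[acc] = a_p[acc]
            V[acc] = Vp[acc]
            logV[acc] = logVp[acc]
            row_ll[acc] = row_ll_p[acc]
        acc_rows += acc
        acc_rows_win += acc

        # (b) precision M: MH on the log scale, Gamma hyperprior
        logM_new = np.log(M) + m_step * rng.standard_normal()
        M_new = float(np.exp(logM_new))
        a_new = log1mPhi / M_new
        V_new = np.clip(-np.expm1(a_new), _VMIN, _VMAX)
        logV_new = np.log(V_new)
        ll_cur = float(row_ll.sum())
        ll_new = float(_row_loglik(logV_new, a_new, n, m).sum())
        log_ratio = (ll_new - ll_cur
                     + a_g * (logM_new - np.log(M)) - b_g * (M_new - M))
        if np.log(rng.random()) < log_ratio:
            M = M_new
            a, V, logV = a_new, V_new, logV_new
            row_ll = _row_loglik(logV, a, n, m)
            acc_M += 1
            acc_M_win += 1

        # (c) bandwidth: whitened MH on the log scale.  The rows are moved
        # along with the kernel (W = L^-1 Z held fixed, Z' = L' W), which
        # leaves the GP prior density of the rows unchanged, so the ratio is
        # the likelihood ratio times the log-normal hyperprior ratio.  This
        # joint move is what lets the bandwidth and the latent surfaces mix
        # together instead of the conditional update racing to zero.
        logbw_new = np.log(bandwidth) + bw_step * rng.standard_normal()
        bw_new = float(np.exp(logbw_new))
        try:
            L_new = cholesky(gp_covariance(x, bw_new), lower=True)
        except np.linalg.LinAlgError:
            L_new = None
        if L_new is not None:
            W = solve_triangular(L, Z.T, lower=True)  # (I, J)
            Z_new = (L_new @ W).T
            log1mPhi_new = log_ndtr(-Z_new)
            a_bw = log1mPhi_new / M
            V_bw = np.clip(-np.expm1(a_bw), _VMIN, _VMAX)
            logV_bw = np.log(V_bw)
            row_ll_bw = _row_loglik(logV_bw, a_bw, n, m)
            pr = -0.5 * (((logbw_new - config.bandwidth_log_mean) ** 2
                          - (np.log(bandwidth) - config.bandwidth_log_mean) ** 2)
                         / config.bandwidth_log_sd ** 2)
            if np.log(rng.random()) < (row_ll_bw.sum() - row_ll.sum() + pr):
                bandwidth, L = bw_new, L_new
                Z = Z_new
                log1mPhi, a, V, logV = log1mPhi_new, a_bw, V_bw, logV_bw
                row_ll = row_ll_bw
                acc_bw += 1
                acc_bw_win += 1

        if not np.isfinite(row_ll.sum()):
            raise FloatingPointError(
                f"divergent (non-finite) log posterior at iteration {it}"
            )

        # adapt proposal scales during burn-in only
        if it < mcmc.burnin and (it + 1) % window == 0:
            rates = acc_rows_win / window
            eps[rates < 0.20] *= 0.8
            eps[rates > 0.50] *= 1.25
            np.clip(eps, 1e-3, 0.999, out=eps)
            if acc_M_win / window < 0.20:
                m_step *= 0.8
            elif acc_M_win / window > 0.50:
                m_step *= 1.25
            if acc_bw_win / window < 0.20:
                bw_step *= 0.8
            elif acc_bw_win / window > 0.50:
                bw_step *= 1.25
            acc_rows_win[:] = 0
            acc_M_win = acc_bw_win = 0

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
            comps_site[d] = stick_break(
                np.clip(V.T, _VMIN, _VMAX))  # (site, J) -> (site, J+1)
            Kxg = _cross_covariance(x, g, bandwidth)
            A = cho_solve((L, True), Kxg)  # (I, G)
            Zg = Z @ A
            for gi, si in enumerate(match):
                if si >= 0:
                    Zg[:, gi] = Z[:, si]
            Vg = transform_to_sticks(Zg, M)  # (J, G)
            comps_grid[d] = stick_break(Vg.T)
            M_trace[d] = M
            bw_trace[d] = bandwidth
            d += 1
        if progress and (it + 1) % 1000 == 0:
            print(f"  iter {it + 1}/{mcmc.iterations}  "
                  f"acc(rows)={acc_rows[:n_otus].mean() / (it + 1):.2f} "
                  f"acc(M)={acc_M / (it + 1):.2f} acc(bw)={acc_bw / (it + 1):.2f}")

    rates = {
        "stick_rows": float(acc_rows[:n_otus].mean() / mcmc.iterations),
        "M": acc_M / mcmc.iterations,
        "bandwidth": acc_bw / mcmc.iterations,
    }
    for name, r in rates.items():
        if r < 0.01:
            warnings.warn(f"acceptance rate for {name} below 1% ({r:.3f})",
                          stacklevel=2)

    return PosteriorEnsemble(
        compositions=comps_grid,
        grid=grid,
        M_trace=M_trace,
        bandwidth_trace=bw_trace,
        otu_ids=tuple(table.otu_ids),
        stick_of_otu=stick_of_otu,
        site_ids=tuple(table.site_ids),
        genera=table.genera,
        acceptance_rates=rates,
        meta={"model": "depgem", "seed": int(seed), "J": int(J),
              "iterations": mcmc.iterations, "burnin": mcmc.burnin,
              "thin": mcmc.thin, "covariate_scale": scale,
              "prior_only": bool(prior_only)},
        site_compositions=comps_site,
        site_covariates=x_raw,
    )


def autocorrelation(trace: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Empirical autocorrelation function of a 1-D trace (lag 0 .. max_lag)."""
    trace = np.asarray(trace, dtype=float)
    ndraw = trace.size
    if max_lag is None:
        max_lag = min(ndraw - 1, 100)
    centred = trace - trace.mean()
    var = centred @ centred
    if var == 0:
        return np.full(max_lag + 1, np.nan)
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = (centred[: ndraw - k] @ centred[k:]) / var
    return acf


def effective_sample_size(trace: np.ndarray) -> float:
    """ESS via the initial-positive-sequence estimator on the ACF."""
    acf = autocorrelation(trace)
    if np.isnan(acf).any():
        return float("nan")
    s = 0.0
    for k in range(1, acf.size):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(trace.size / (1.0 + 2.0 * s))


def fit_summary(ensemble: PosteriorEnsemble, max_lag: int = 20) -> dict:
    """Convergence diagnostics for the hyperparameter traces.

    Returns effective sample sizes, acceptance rates and lag-k
    autocorrelations for the M (and, if present, bandwidth) traces.
    """
    if ensemble.n_draws < 10:
        raise ValueError("need at least 10 draws for diagnostics")
    out: dict = {"n_draws": ensemble.n_draws,
                 "acceptance_rates": dict(ensemble.acceptance_rates)}
    traces = {"M": np.asarray(ensemble.M_trace, dtype=float)}
    if ensemble.bandwidth_trace is not None:
        traces["bandwidth"] = np.asarray(ensemble.bandwidth_trace, dtype=float)
    for name, tr in traces.items():
        if tr.ndim > 1:  # per-site traces: summarize the pooled mean trace
            tr = tr.mean(axis=1)
        lag = min(max_lag, tr.size - 1)
        acf = autocorrelation(tr, lag)
        ess = effective_sample_size(tr)
        degenerate = bool(np.isnan(acf).any())
        if degenerate:
            warnings.warn(f"{name} trace is constant; ESS is degenerate",
                          stacklevel=2)
        out[name] = {"ess": ess, "autocorrelation": acf.tolist(),
                     "degenerate": degenerate}
    return out
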