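"""GEM (Griffiths-Engen-McCloskey) stick-breaking machinery.

The GEM(M) distribution puts a prior on an infinite vector of probability
weights via the stick-breaking construction: independent fractions
V_j ~ Beta(1, M) split what remains of a unit stick, giving

    p_j = V_j * prod_{l<j} (1 - V_l).

The precision parameter M governs evenness: small M concentrates mass on the
first few taxa, large M spreads it out (a more diverse community).  In
practice the construction is truncated at J sticks; the undetected tail mass
r = prod_j (1 - V_j) is carried along explicitly so p_1..p_J plus r always
sum to one.

This module provides prior sampling, the Shannon index and its closed-form
prior expectation psi(M+1) - psi(1), and the independent per-site GEM
posterior sampler used as the non-dependent comparator model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np
from scipy.special import digamma

__all__ = [
    "GEMHyperparams",
    "MCMCConfig",
    "stick_break",
    "sample_stick_fractions",
    "sample_gem_prior",
    "shannon_index",
    "prior_shannon_expectation",
    "fit_gem_independent",
]


@dataclass(frozen=True)
class GEMHyperparams:
    """Precision parameter M and its Gamma(shape, rate) hyperprior.

    The default Gamma(2, 0.1) (mean 20, variance 200) is weakly informative
    on the scale of a few-hundred-OTU community.
    """

    M: float = 20.0
    M_prior_shape: float = 2.0
    M_prior_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.M <= 0 or self.M_prior_shape <= 0 or self.M_prior_rate <= 0:
            raise ValueError("GEM hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length settings.  Defaults: 50,000 iterations, burn-in 10,000,
    thinning 5.  Tests and desk-scale runs use 5,000 / 1,000 / 2."""

    iterations: int = 50_000
    burnin: int = 10_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


def stick_break(V: np.ndarray) -> np.ndarray:
    """Turn stick fractions into probability weights plus a tail slot.

    Parameters
    ----------
    V : array, shape (..., J), every entry strictly in (0, 1).

    Returns
    -------
    array, shape (..., J+1): weights p_j = V_j * prod_{l<j}(1 - V_l) followed
    by the residual tail mass prod_l (1 - V_l).  Sums to 1 along the last
    axis by the telescoping identity.
    """
    V = np.asarray(V, dtype=float)
    if V.size == 0:
        raise ValueError("V must be non-empty")
    if (V <= 0).any() or (V >= 1).any():
        raise ValueError("stick fractions must lie strictly in (0, 1)")
    # cumulative remaining stick before each break, computed in log space for
    # numerical stability at large J
    log1mV = np.log1p(-V)
    log_remaining = np.concatenate(
        [np.zeros(V.shape[:-1] + (1,)), np.cumsum(log1mV, axis=-1)], axis=-1
    )
    out = np.empty(V.shape[:-1] + (V.shape[-1] + 1,))
    out[..., :-1] = V * np.exp(log_remaining[..., :-1])
    out[..., -1] = np.exp(log_remaining[..., -1])
    return out


def sample_stick_fractions(M: float, J: int, rng: np.random.Generator) -> np.ndarray:
    """Draw V_j ~ Beta(1, M) i.i.d. via inverse-CDF (1 - U^(1/M))."""
    if M <= 0:
        raise ValueError("M must be positive")
    if J < 1:
        raise ValueError("J must be >= 1")
    U = rng.random(J)
    # Beta(1, M) quantile of U; clip away exact endpoints
    V = -np.expm1(np.log1p(-U) / M)
    return np.clip(V, 1e-300, 1.0 - 1e-16)


def sample_gem_prior(M: float, J: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """One draw from the truncated GEM(M) prior.

    Returns weights of length J+1 (last slot = tail mass).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return stick_break(sample_stick_fractions(M, J, rng))


def shannon_index(p: np.ndarray) -> float | np.ndarray:
    """Shannon diversity H = -sum_j p_j log p_j (natural log, 0 log 0 := 0).

    ``p`` is interpreted as the weight vector to be summed over as given:
    pass a composition *without* its tail slot to reproduce the convention
    that the undetected tail mass is excluded.  Works over the last axis for
    stacked draws.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    H = terms.sum(axis=-1)
    return float(H) if H.ndim == 0 else H


def prior_shannon_expectation(M: float) -> float:
    """Closed-form prior expectation of the Shannon index under GEM(M).

    E[H] = psi(M+1) - psi(1), where psi is the digamma function.  Follows
    from size-biased sampling: the expected value of sum_j p_j (-log p_j)
    equals E[-log W] for W ~ Beta(1, M).  Monotone increasing in M; tends to
    0 as M -> 0 (all mass on one atom) and to infinity like log M.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    return float(digamma(M + 1.0) - digamma(1.0))


def _site_rng(master_seed: int, site_id: str) -> np.random.Generator:
    # per-site stream keyed by site label so draws are invariant to column order
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(site_id.encode())])
    )


def _log_m_conditional(M: float, V: np.ndarray, hyper: GEMHyperparams) -> float:
    # log p(M | V) up to a constant: Gamma(a, b) prior x prod_j M (1-V_j)^(M-1)
    if M <= 0:
        return -np.inf
    a, b = hyper.M_prior_shape, hyper.M_prior_rate
    return float(
        (a - 1.0) * np.log(M) - b * M
        + V.size * np.log(M) + (M - 1.0) * np.log1p(-V).sum()
    )


def fit_gem_independent(table, hyper: GEMHyperparams | None = None,
                        mcmc: MCMCConfig | None = None, seed: int = 0,
                        J: int | None = None, extra_sticks: int = 25,
                        covariates: np.ndarray | None = None):
    """Fit independent GEM(M) models, one per site, by Gibbs sampling.

    OTUs are mapped to stick indices in decreasing order of total abundance
    (GEM weights are stochastically decreasing, so this ordering maximises
    prior-data agreement).  Given M, each stick fraction has the conjugate
    full conditional

        V_j | counts ~ Beta(1 + n_j, M + sum_{l>j} n_l),

    and M is updated by a random-walk Metropolis-Hastings step on log M
    under its Gamma hyperprior, with the proposal scale adapted to a
    20-50% acceptance rate during burn-in.

    Returns a :class:`~gemtox.ensemble.PosteriorEnsemble` whose points are
    the observed sites (``grid`` holds the per-site covariates when given,
    otherwise the site index) and whose ``M_trace`` has shape
    (draws, n_sites).
    """
    from gemtox.ensemble import PosteriorEnsemble

    hyper = hyper or GEMHyperparams()
    mcmc = mcmc or MCMCConfig()
    if (table.site_totals == 0).any():
        raise ValueError("every site must have at least one count")
    n_otus, n_sites = table.n_otus, table.n_sites
    if J is None:
        J = n_otus + extra_sticks
    if J < n_otus:
        raise ValueError("truncation J must be at least the number of OTUs")

    order = np.argsort(-table.otu_totals, kind="stable")  # stick <- otu
    stick_of_otu = np.empty(n_otus, dtype=np.int64)
    stick_of_otu[order] = np.arange(n_otus)

    n_draws = mcmc.n_draws
    comps = np.empty((n_draws, n_sites, J + 1))
    M_trace = np.empty((n_draws, n_sites))
    accept = np.zeros(n_sites)

    counts_sticks = np.zeros((n_sites, J), dtype=np.int64)
    counts_sticks[:, :n_otus] = table.counts[order].T
    # m_j = counts on sticks after j at this site
    tail_counts = np.flip(np.cumsum(np.flip(counts_sticks, axis=1), axis=1), axis=1)
    m_after = np.concatenate(
        [tail_counts[:, 1:], np.zeros((n_sites, 1), dtype=np.int64)], axis=1
    )

    for s in range(n_sites):
        rng = _site_rng(seed, table.site_ids[s])
        M = hyper.M
        step = 0.5
        n_acc = 0
        a_beta = 1.0 + counts_sticks[s]
        d = 0
        for it in range(mcmc.iterations):
            V = rng.beta(a_beta, M + m_after[s])
            V = np.clip(V, 1e-300, 1.0 - 1e-16)
            # MH on log M
            logM_new = np.log(M) + step * rng.normal()
            M_new = np.exp(logM_new)
            log_ratio = (
                _log_m_conditional(M_new, V, hyper)
                - _log_m_conditional(M, V, hyper)
                + logM_new - np.log(M)  # log-scale proposal Jacobian
            )
            if np.log(rng.random()) < log_ratio:
                M = M_new
                n_acc += 1
            if it < mcmc.burnin:
                if (it + 1) % 200 == 0:  # adapt proposal scale during burn-in
                    rate = n_acc / (it + 1)
                    if rate < 0.20:
                        step *= 0.8
                    elif rate > 0.50:
                        step *= 1.25
            elif (it - mcmc.burnin) % mcmc.thin == 0:
                comps[d, s] = stick_break(V)
                M_trace[d, s] = M
                d += 1
        accept[s] = n_acc / mcmc.iterations

    otu_ids_sticks = tuple(table.otu_ids[i] for i in order)
    if covariates is None:
        grid = np.arange(n_sites, dtype=float)
    else:
        grid = np.asarray(covariates, dtype=float)
        if grid.shape != (n_sites,):
            raise ValueError("covariates must have one value per site")
    return PosteriorEnsemble(
        compositions=comps,
        grid=grid,
        M_trace=M_trace,
        bandwidth_trace=None,
        otu_ids=tuple(table.otu_ids),
        stick_of_otu=stick_of_otu,
        site_ids=tuple(table.site_ids),
        genera=table.genera,
        acceptance_rates={"M": float(accept.mean())},
        meta={"model": "gem", "seed": int(seed), "J": int(J),
              "iterations": mcmc.iterations, "burnin": mcmc.burnin,
              "thin": mcmc.thin, "ordered_otu_ids": list(otu_ids_sticks)},
    )
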