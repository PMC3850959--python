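"""Deterministic quadrature posterior for reduced toy models.

The reduced model is the joint model collapsed to a single age group and a
single registry, with the variance hyperparameters fixed (so u, v and the
spline machinery drop out):

    cases  ~ Poisson(exp(a) * PY)
    deaths ~ Poisson(exp(a + b) * PY)
    national deaths ~ Poisson(exp(g) * PY_nat)

with independent Normal(0, prior_sd^2) priors on whichever of (a, b, g) are
free.  With at most three free parameters the posterior is integrated on a
dense tensor grid, giving means, SDs and equal-tailed intervals that serve
as the independent oracle for the MCMC machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import McmcSettings, run_ensemble

_PARAMS = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class ToyData:
    """Single-age, single-registry counts."""

    cases: int
    deaths: int
    person_years: float
    nds_deaths: int
    nds_person_years: float


@dataclass(frozen=True)
class MarginalSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def _toy_log_posterior(data: ToyData, a, b, g, prior_sd: float):
    mu_inc = np.exp(a) * data.person_years
    mu_mort = np.exp(a + b) * data.person_years
    mu_nds = np.exp(g) * data.nds_person_years
    ll = (
        data.cases * np.log(mu_inc) - mu_inc
        + data.deaths * np.log(mu_mort) - mu_mort
        + data.nds_deaths * np.log(mu_nds) - mu_nds
    )
    prior = -(a ** 2 + b ** 2 + g ** 2) / (2.0 * prior_sd ** 2)
    return ll + prior


def _centers(data: ToyData) -> dict[str, float]:
    a0 = np.log((data.cases + 0.5) / data.person_years)
    b0 = np.log((data.deaths + 0.5) / (data.cases + 0.5))
    g0 = np.log((data.nds_deaths + 0.5) / data.nds_person_years)
    return {"alpha": a0, "beta": b0, "gamma": g0}


def _half_widths(data: ToyData) -> dict[str, float]:
    # generous +/- range in posterior-SD units; Fisher info ~ the count
    w = lambda c: 10.0 / np.sqrt(c + 1.0) + 1.0
    return {
        "alpha": w(data.cases),
        "beta": w(min(data.cases, data.deaths)),
        "gamma": w(data.nds_deaths),
    }


def grid_posterior_oracle(
    data: ToyData,
    free: tuple[str, ...] = ("alpha", "beta", "gamma"),
    fixed: dict[str, float] | None = None,
    prior_sd: float = 100.0,
    n_grid: int = 241,
    ci: float = 0.95,
) -> dict[str, MarginalSummary]:
    """Posterior marginals of the reduced model by tensor-grid quadrature."""
    fixed = dict(fixed or {})
    if len(free) > 3:
        raise ValueError("quadrature oracle supports at most 3 free parameters")
    unknown = set(free) - set(_PARAMS)
    if unknown or set(fixed) & set(free):
        raise ValueError(f"bad parameter specification: free={free}, fixed={fixed}")
    for p in _PARAMS:
        if p not in free and p not in fixed:
            raise ValueError(f"parameter {p!r} must be free or fixed")

    centers, widths = _centers(data), _half_widths(data)
    axes = [
        np.linspace(centers[p] - widths[p], centers[p] + widths[p], n_grid)
        for p in free
    ]
    mesh = np.meshgrid(*axes, indexing="ij") if free else []
    vals = {p: fixed[p] for p in fixed}
    for p, m in zip(free, mesh):
        vals[p] = m
    lp = _toy_log_posterior(data, vals["alpha"], vals["beta"], vals["gamma"], prior_sd)
    p_unnorm = np.exp(lp - lp.max())
    p_unnorm /= p_unnorm.sum()

    out: dict[str, MarginalSummary] = {}
    tail = (1.0 - ci) / 2.0
    for k, pname in enumerate(free):
        other = tuple(d for d in range(len(free)) if d != k)
        marg = p_unnorm.sum(axis=other) if other else p_unnorm
        grid = axes[k]
        mean = float((grid * marg).sum())
        sd = float(np.sqrt(((grid - mean) ** 2 * marg).sum()))
        cdf = np.cumsum(marg)
        lo = float(np.interp(tail, cdf, grid))
        hi = float(np.interp(1.0 - tail, cdf, grid))
        out[pname] = MarginalSummary(mean=mean, sd=sd, ci_low=lo, ci_high=hi)
    return out


def fit_reduced(
    data: ToyData,
    free: tuple[str, ...] = ("alpha", "beta", "gamma"),
    fixed: dict[str, float] | None = None,
    prior_sd: float = 100.0,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample the reduced model with the production ensemble machinery.

    Returns draws of shape (n_draws, len(free)), ordered as ``free``.
    """
    fixed = dict(fixed or {})
    if settings is None:
        settings = McmcSettings(
            burn_in=1_000, thin=10, sampling_iterations=2_000, n_walkers=32
        )

    idx = {p: i for i, p in enumerate(free)}

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        vals = {}
        for p in _PARAMS:
            vals[p] = theta[:, idx[p]] if p in idx else np.full(theta.shape[0], fixed[p])
        return _toy_log_posterior(
            data, vals["alpha"], vals["beta"], vals["gamma"], prior_sd
        )

    centers = _centers(data)
    theta0 = np.array([centers[p] for p in free])
    chain = run_ensemble(log_prob, theta0, settings, seed, scatter=0.05)
    return chain.reshape(-1, len(free))


__all__ = ["MarginalSummary", "ToyData", "fit_reduced", "grid_posterior_oracle"]
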