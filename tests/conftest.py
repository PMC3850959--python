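"""Shared fixtures: a small synthetic stratum and one reusable MCMC fit.

MCMC fits are expensive, so tests that only consume posterior draws share a
single session-scoped fit on a reduced-scale stratum; tests of pure
draw-to-estimate arithmetic build lightweight stand-in posterior objects
instead of running the sampler.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import miburden as mb
from miburden.fit import McmcSettings


TRUE_MI = 0.7


@pytest.fixture(scope="session")
def age_grid():
    return mb.AgeGrid()


@pytest.fixture(scope="session")
def basis(age_grid):
    return mb.build_basis(age_grid)


@pytest.fixture(scope="session")
def tiny_settings():
    """Short schedule for structural MCMC tests (not for recovery accuracy)."""
    return McmcSettings(burn_in=800, thin=10, sampling_iterations=800)


@pytest.fixture(scope="session")
def small_stratum(basis):
    """Reduced-scale synthetic stratum with constant true MI = 0.7."""
    alpha = mb.smooth_truth_from_template(
        mb.template_incidence_curve("all_sites_male"), basis
    )
    beta = np.full(19, np.log(TRUE_MI))
    cfg = mb.GeneratorConfig(
        true_alpha=alpha,
        true_beta=beta,
        true_gamma=alpha + beta,
        n_registries=5,
        registry_person_years=1e5,
        national_person_years=1e6,
        seed=314,
        center_random_effects=True,
    )
    regs, nat, truth = mb.generate_stratum(cfg)
    return SimpleNamespace(cfg=cfg, registries=regs, national=nat, truth=truth)


@pytest.fixture(scope="session")
def fitted(small_stratum, basis):
    """One shared posterior fit of the small stratum (2000-step schedule)."""
    import warnings

    settings = McmcSettings(burn_in=2000, thin=20, sampling_iterations=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        samples = mb.fit(
            small_stratum.registries,
            small_stratum.national,
            basis,
            settings=settings,
            seed=99,
        )
    return samples


def make_samples(beta_curves, gamma_curves, basis):
    """Duck-typed posterior-draw object for draw-to-estimate arithmetic.

    ``beta_curves``/``gamma_curves`` are (n_draws, n_ages) arrays of the log
    MI ratio and log national mortality rate.
    """
    beta_curves = np.atleast_2d(np.asarray(beta_curves, dtype=float))
    gamma_curves = np.atleast_2d(np.asarray(gamma_curves, dtype=float))
    return SimpleNamespace(
        basis=basis,
        beta_draws=beta_curves,
        gamma_draws=gamma_curves,
        mi_draws=np.exp(beta_curves),
        alpha_draws=np.zeros_like(beta_curves),
    )
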