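"""Sensitivity analyses and internal validation on constructed strata."""

import warnings

import numpy as np
import pytest

import miburden as mb
from miburden.fit import McmcSettings
from miburden.sensitivity import (
    age_restriction_comparison,
    constrained_comparison,
    internal_validation,
    leave_one_registry_out,
    nds_overlap_mi,
)

from conftest import make_samples


SETTINGS = McmcSettings(burn_in=1500, thin=15, sampling_iterations=1500)


def _quiet_call(fn, *args, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fn(*args, **kw)


@pytest.fixture(scope="module")
def population():
    return np.full(19, 1e6)


@pytest.fixture(scope="module")
def loo_report(basis, population):
    """4-registry stratum: R1-R3 identical twins, R4 a strong outlier.

    Three twins keep the between-registry variance identified when one of
    them is dropped; with fewer registries the fit destabilizes and the
    leave-one-out contrasts are dominated by that instability rather than
    by the excluded registry.
    """
    alpha = mb.smooth_truth_from_template(
        mb.template_incidence_curve("all_sites_male"), basis
    )
    rng = np.random.default_rng(11)
    py = np.full(19, 5e4)
    base_cases = rng.poisson(np.exp(alpha) * py)
    base_deaths = rng.poisson(0.7 * np.exp(alpha) * py)
    twins = [
        mb.RegistryTable(rid, py, base_cases, base_deaths)
        for rid in ("R1", "R2", "R3")
    ]
    outlier = mb.RegistryTable(
        "R4", py,
        rng.poisson(2.2 * np.exp(alpha) * py),
        rng.poisson(2.2 * 1.3 * np.exp(alpha) * py),  # inflated u and MI
    )
    nat = mb.NationalMortalityTable(
        rng.poisson(0.7 * np.exp(alpha) * 1e6), np.full(19, 1e6)
    )
    return _quiet_call(
        leave_one_registry_out, twins + [outlier], nat, basis, population,
        SETTINGS, seed=30,
    )


class TestLeaveOneOut:
    def test_outlier_exclusion_has_largest_effect(self, loo_report):
        diffs = {r["excluded"]: abs(r["relative_diff_pct"]) for r in loo_report.rows}
        assert diffs["R4"] > max(diffs["R1"], diffs["R2"], diffs["R3"])

    def test_duplicate_registries_have_matching_effect(self, loo_report):
        diffs = {r["excluded"]: r["relative_diff_pct"] for r in loo_report.rows}
        # identical registries: exclusion effects equal up to MC error
        spread = max(diffs[r] for r in ("R1", "R2", "R3")) - min(
            diffs[r] for r in ("R1", "R2", "R3")
        )
        assert spread < 6.0

    def test_single_registry_rejected(self, basis, population):
        reg = mb.RegistryTable("R", np.full(19, 1e4), np.full(19, 5), np.full(19, 3))
        nat = mb.NationalMortalityTable(np.full(19, 50), np.full(19, 1e6))
        with pytest.raises(ValueError, match="two registries"):
            leave_one_registry_out([reg], nat, basis, population, SETTINGS)


class TestConstrainedComparison:
    def test_inactive_constraint_changes_little(self, basis, population):
        """True MI well below 1 with large counts: the logit constraint is
        inactive and both variants agree."""
        alpha = mb.smooth_truth_from_template(
            mb.template_incidence_curve("all_sites_male"), basis
        )
        beta = np.full(19, np.log(0.5))
        cfg = mb.GeneratorConfig(
            true_alpha=alpha, true_beta=beta, true_gamma=alpha + beta,
            n_registries=4, registry_person_years=2e5,
            national_person_years=1e6, seed=33, center_random_effects=True,
        )
        regs, nat, _ = mb.generate_stratum(cfg)
        report = _quiet_call(
            constrained_comparison, regs, nat, basis, population, SETTINGS, seed=40
        )
        row = report.rows[0]
        assert abs(row["relative_diff_pct"]) < 10.0
        assert row["max_mi_draw"] < 1.0
        assert {"variant", "estimate", "relative_diff_pct", "ci_low", "ci_high"} <= set(row)

    def test_capping_mi_above_one_inflates_incidence(self, basis, population):
        """Where true MI > 1, the constrained fit caps it below truth, so
        predicted incidence (mortality / MI) rises."""
        i = np.arange(1, 20)
        alpha = mb.smooth_truth_from_template(
            mb.template_incidence_curve("all_sites_male"), basis
        )
        beta = np.log(0.9 + 0.4 / (1 + np.exp(-(i - 14))))  # up to ~1.3 when old
        cfg = mb.GeneratorConfig(
            true_alpha=alpha, true_beta=beta, true_gamma=alpha + beta,
            n_registries=4, registry_person_years=2e5,
            national_person_years=1e6, seed=34, center_random_effects=True,
        )
        regs, nat, _ = mb.generate_stratum(cfg)
        report = _quiet_call(
            constrained_comparison, regs, nat, basis, population, SETTINGS, seed=41
        )
        assert report.rows[0]["relative_diff_pct"] > 0.0


class TestAgeRestriction:
    def test_adult_cancer_estimates_stable_under_age_cut(
        self, age_grid, basis, population
    ):
        """With essentially no incidence below 20, dropping young ages leaves
        the total unchanged up to the (zero) young-age contribution."""
        alpha = mb.smooth_truth_from_template(
            mb.template_incidence_curve("liver_male"), basis
        )
        alpha = alpha.copy()
        beta = np.full(19, np.log(0.8))
        cfg = mb.GeneratorConfig(
            true_alpha=alpha, true_beta=beta, true_gamma=alpha + beta,
            n_registries=4, registry_person_years=3e5,
            national_person_years=1e7, seed=35, center_random_effects=True,
        )
        regs, nat, _ = mb.generate_stratum(cfg)
        report = _quiet_call(
            age_restriction_comparison, regs, nat, age_grid, population,
            SETTINGS, min_age_years=20.0, seed=42,
        )
        row = report.rows[0]
        assert row["n_age_groups"] == 14
        # young-age true contribution is < 0.1% of the total here
        assert abs(row["relative_diff_pct"]) < 10.0

    def test_misaligned_cut_rejected(self, age_grid, basis, population):
        regs = [mb.RegistryTable("R", np.full(19, 1e4), np.full(19, 5), np.full(19, 3))]
        nat = mb.NationalMortalityTable(np.full(19, 50), np.full(19, 1e6))
        with pytest.raises(ValueError, match="boundary"):
            age_restriction_comparison(
                regs * 2, nat, age_grid, population, SETTINGS, min_age_years=22.0
            )


class TestNdsOverlap:
    def test_full_overlap_consistent_data_agrees_with_primary(
        self, basis, population
    ):
        """When every registry covers NDS areas and registry mortality is
        consistent with the NDS rates, the overlap-based estimate matches the
        primary estimate up to Monte Carlo error."""
        alpha = mb.smooth_truth_from_template(
            mb.template_incidence_curve("all_sites_male"), basis
        )
        beta = np.full(19, np.log(0.7))
        cfg = mb.GeneratorConfig(
            true_alpha=alpha, true_beta=beta, true_gamma=alpha + beta,
            n_registries=4, registry_person_years=2e5,
            national_person_years=1e7, seed=36, center_random_effects=True,
        )
        regs, nat, _ = mb.generate_stratum(cfg)
        regs = [
            mb.RegistryTable(t.registry_id, t.population, t.incident_cases,
                             t.deaths, nds_overlap=True)
            for t in regs
        ]
        report = _quiet_call(
            nds_overlap_mi, regs, nat, basis, population, SETTINGS, seed=43
        )
        row = report.rows[0]
        assert abs(row["relative_diff_pct"]) < 10.0
        assert {"ci_low", "ci_high", "mi_mean"} <= set(row)

    def test_empty_subset_rejected(self, basis, population):
        regs = [mb.RegistryTable("R", np.full(19, 1e4), np.full(19, 5), np.full(19, 3))]
        nat = mb.NationalMortalityTable(np.full(19, 50), np.full(19, 1e6))
        with pytest.raises(ValueError, match="NDS"):
            nds_overlap_mi(regs, nat, basis, population, SETTINGS)


class TestInternalValidation:
    def test_consistent_mi_gives_zero_percent_difference(self, basis):
        samples = make_samples(
            np.full((50, 19), np.log(0.5)), np.full((50, 19), -6.0), basis
        )
        registry = mb.RegistryTable(
            "SH", np.full(19, 1e5), np.full(19, 100), np.full(19, 50)
        )
        out = internal_validation(registry, samples)
        assert out["pct_difference"].mean == pytest.approx(0.0, abs=1e-9)

    def test_underregistered_cases_show_positive_difference(self, basis):
        samples = make_samples(
            np.full((50, 19), np.log(0.5)), np.full((50, 19), -6.0), basis
        )
        registry = mb.RegistryTable(
            "QD", np.full(19, 1e5), np.full(19, 90), np.full(19, 50)
        )
        out = internal_validation(registry, samples)
        assert out["pct_difference"].mean == pytest.approx(100 / 9, abs=1e-6)

    def test_zero_observed_cases_rejected(self, basis):
        samples = make_samples(np.zeros((5, 19)), np.zeros((5, 19)), basis)
        registry = mb.RegistryTable(
            "Z", np.full(19, 1e5), np.zeros(19), np.full(19, 5)
        )
        with pytest.raises(ValueError, match="cases"):
            internal_validation(registry, samples)
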