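"""Draw-wise burden arithmetic: incidence prediction, MI summaries, ASR,
stratum combination, and the draw-then-summarize ordering."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import miburden as mb
from miburden.estimation import (
    BurdenEstimate,
    CredibleSummary,
    age_standardized_rate,
    asr_draws,
    combine_strata,
    crude_mi_draws,
    mi_ratio_summary,
    national_incidence_draws,
)

from conftest import make_samples


class TestNationalIncidence:
    def test_equal_gamma_and_beta_give_rate_one(self, basis):
        rng = np.random.default_rng(0)
        curves = rng.normal(-6, 1, size=(20, 19))
        s = make_samples(curves, curves, basis)
        pop = np.full(19, 1234.0)
        cases = national_incidence_draws(s, pop)
        np.testing.assert_allclose(cases, np.broadcast_to(pop, (20, 19)), atol=1e-10)

    def test_hand_arithmetic(self, basis):
        s = make_samples(
            np.full((5, 19), np.log(0.5)), np.full((5, 19), np.log(0.001)), basis
        )
        cases = national_incidence_draws(s, np.full(19, 1e5))
        np.testing.assert_allclose(cases, 200.0, atol=1e-10)

    def test_population_shape_mismatch_rejected(self, basis):
        s = make_samples(np.zeros((2, 19)), np.zeros((2, 19)), basis)
        with pytest.raises(ValueError):
            national_incidence_draws(s, np.ones(7))


class TestMiSummary:
    def test_beta_zero_gives_mi_exactly_one(self, basis):
        rng = np.random.default_rng(1)
        s = make_samples(np.zeros((30, 19)), rng.normal(-6, 0.5, (30, 19)), basis)
        out = mi_ratio_summary(s, national_person_years=np.full(19, 1e5))
        for summary in out["per_age"]:
            assert summary.mean == 1.0
            assert summary.ci_high - summary.ci_low == 0.0
        assert out["crude"].mean == pytest.approx(1.0)

    def test_constant_mi_invariant_to_weights(self, basis):
        rng = np.random.default_rng(2)
        s = make_samples(
            np.full((10, 19), np.log(0.74)), rng.normal(-6, 1.0, (10, 19)), basis
        )
        py = rng.uniform(1e4, 1e6, 19)
        out = mi_ratio_summary(s, national_person_years=py)
        np.testing.assert_allclose(out["crude_draws"], 0.74, atol=1e-12)

    def test_crude_is_ratio_of_sums(self, basis):
        rng = np.random.default_rng(3)
        beta = rng.normal(np.log(0.7), 0.2, (8, 19))
        gamma = rng.normal(-6, 0.8, (8, 19))
        s = make_samples(beta, gamma, basis)
        py = np.full(19, 2e5)
        got = crude_mi_draws(s, py)
        deaths = np.exp(gamma) * py
        cases = np.exp(gamma - beta) * py
        np.testing.assert_allclose(got, deaths.sum(1) / cases.sum(1), atol=1e-12)


class TestAsr:
    def test_equal_rates_return_the_rate(self):
        std = mb.world_standard()
        rates = np.full((12, 19), 3e-4)
        out = age_standardized_rate(rates, std)
        assert out.mean == pytest.approx(30.0, abs=1e-9)
        assert out.ci_low == pytest.approx(30.0, abs=1e-9)

    def test_two_age_hand_arithmetic(self):
        w = np.zeros(19)
        w[:2] = 0.5
        std = mb.StandardPopulation(w)
        rates = np.zeros((1, 19))
        rates[0, :2] = (1e-4, 3e-4)
        assert asr_draws(rates, std)[0] == pytest.approx(20.0)

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(4)
        std = mb.StandardPopulation(rng.uniform(0.1, 1, 19))
        rates = rng.uniform(0, 1e-3, (25, 19))
        oracle = 1e5 * np.einsum("di,i->d", rates, std.weights)
        np.testing.assert_allclose(asr_draws(rates, std), oracle, atol=1e-10)

    def test_weight_age_mismatch_rejected(self):
        std = mb.world_standard()
        with pytest.raises(ValueError):
            asr_draws(np.zeros((3, 7)), std)


class TestDrawWiseOrdering:
    def test_summaries_computed_per_draw_not_from_summaries(self, basis):
        """With a skewed posterior, transform-then-summarize differs from
        summarize-then-transform; the pipeline must do the former."""
        rng = np.random.default_rng(5)
        beta = rng.normal(np.log(0.6), 0.6, (4000, 19))  # heavy exp skew
        gamma = np.full((4000, 19), -6.0)
        s = make_samples(beta, gamma, basis)
        pop = np.full(19, 1e6)
        draws_total = national_incidence_draws(s, pop).sum(axis=1)
        correct = CredibleSummary.from_draws(draws_total)
        # the wrong order: transform the summarized curves
        wrong_mean = (np.exp(gamma.mean(0) - beta.mean(0)) * pop).sum()
        assert correct.mean == pytest.approx(draws_total.mean())
        assert abs(correct.mean - wrong_mean) / correct.mean > 0.05

    def test_percentile_interval_converges_with_draws(self):
        rng = np.random.default_rng(6)
        true_width = 2 * 1.959963984540054
        errs = []
        for n in (50, 50_000):
            d = rng.normal(size=n)
            s = CredibleSummary.from_draws(d)
            errs.append(abs((s.ci_high - s.ci_low) - true_width))
        assert errs[1] < errs[0]

    @given(st.integers(0, 2 ** 32 - 1))
    @hyp_settings(max_examples=25, deadline=None)
    def test_interval_brackets_mean(self, seed):
        draws = np.random.default_rng(seed).gamma(2.0, size=400)
        s = CredibleSummary.from_draws(draws)
        assert s.ci_low <= s.mean <= s.ci_high


def _fake_estimate(basis, rate, mi, pop, site="Lung", stratum="urban"):
    n_draws = rate.shape[0]
    return BurdenEstimate(
        site=site,
        stratum=stratum,
        population=pop,
        mi_age_draws=mi,
        incidence_rate_draws=rate,
        deaths_rate_draws=rate * mi,
        standard=mb.world_standard(),
        age_indices=np.arange(1, 20),
    )


class TestCombineStrata:
    def test_identical_strata_double_the_cases(self, basis):
        rng = np.random.default_rng(7)
        rate = rng.uniform(1e-5, 1e-3, (30, 19))
        mi = np.full((30, 19), 0.7)
        pop = np.full(19, 1e6)
        urban = _fake_estimate(basis, rate, mi, pop, stratum="urban")
        rural = _fake_estimate(basis, rate, mi, pop, stratum="rural")
        combined = combine_strata([urban, rural])
        np.testing.assert_allclose(
            combined.cases_draws, 2 * urban.cases_draws, rtol=1e-12
        )
        # equal rates in both strata leave the ASR unchanged
        np.testing.assert_allclose(combined.asr_draws, urban.asr_draws, rtol=1e-12)

    def test_zero_stratum_leaves_other_unchanged(self, basis):
        rng = np.random.default_rng(8)
        rate = rng.uniform(1e-5, 1e-3, (10, 19))
        mi = np.full((10, 19), 0.5)
        pop = np.full(19, 1e6)
        a = _fake_estimate(basis, rate, mi, pop)
        b = _fake_estimate(basis, np.zeros_like(rate), mi, pop)
        combined = combine_strata([a, b])
        np.testing.assert_allclose(combined.cases_draws, a.cases_draws, rtol=1e-12)

    def test_combined_asr_matches_pooled_rate_oracle(self, basis):
        rng = np.random.default_rng(9)
        pop_u, pop_r = np.full(19, 3e6), np.full(19, 7e6)
        rate_u = rng.uniform(1e-5, 5e-4, (15, 19))
        rate_r = rng.uniform(1e-5, 5e-4, (15, 19))
        mi = np.full((15, 19), 0.6)
        combined = combine_strata(
            [
                _fake_estimate(basis, rate_u, mi, pop_u, stratum="urban"),
                _fake_estimate(basis, rate_r, mi, pop_r, stratum="rural"),
            ]
        )
        pooled_rate = (rate_u * pop_u + rate_r * pop_r) / (pop_u + pop_r)
        oracle = 1e5 * pooled_rate @ mb.world_standard().weights
        np.testing.assert_allclose(combined.asr_draws, oracle, rtol=1e-12)

    def test_mismatched_sites_rejected(self, basis):
        rate = np.full((5, 19), 1e-4)
        mi = np.full((5, 19), 0.5)
        pop = np.full(19, 1e6)
        with pytest.raises(ValueError, match="sites"):
            combine_strata(
                [
                    _fake_estimate(basis, rate, mi, pop, site="Lung"),
                    _fake_estimate(basis, rate, mi, pop, site="Liver"),
                ]
            )

    def test_table_row_rounding_conventions(self, basis):
        rate = np.full((5, 19), 1e-4)
        mi = np.full((5, 19), 0.637)
        est = _fake_estimate(basis, rate, mi, np.full(19, 1e6))
        row = est.table_row()
        assert row["mi"] == 0.64          # 2 decimals
        assert row["asr"] == 10.0         # 1 decimal
        assert isinstance(row["cases_1000s"], float)
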