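"""Matrix population model: structure, eigen analysis, phenology
weighting, discrete sensitivity and the survival sweep."""

import numpy as np
import pytest

from sealphen.errors import ConfigurationError, ModelError
from sealphen.mpm import (VitalRates, asymptotic_analysis, breeder_weights,
                          build_projection_matrix,
                          calibrate_juvenile_survival, default_stage_dates,
                          default_vital_rates, mean_date_of,
                          perturbation_sensitivity, population_mean_pupping_date,
                          power_iteration, survival_sweep)


@pytest.fixture(scope="module")
def rates():
    return default_vital_rates()


@pytest.fixture(scope="module")
def dates():
    return default_stage_dates()


class TestBuildMatrix:
    def test_placement_contract(self):
        r = VitalRates((0.5,) * 4, (0.5,) * 3, (1.0, 1.0, 1.0))
        A = build_projection_matrix(r)
        assert np.count_nonzero(A) == 10
        assert np.allclose(np.diag(A, k=-1), 0.5)
        assert A[6, 6] == 0.5
        assert np.allclose(A[0, 4:7], 1.0)
        assert A[0, :4].sum() == 0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            VitalRates((0.5,) * 4, (0.5,) * 3, (1.0, -0.1, 1.0))
        with pytest.raises(ConfigurationError):
            VitalRates((0.5,) * 4, (0.9995,) * 3, (1.0, 1.0, 1.0))


class TestAsymptotic:
    def test_two_stage_toy(self):
        st = asymptotic_analysis(np.array([[0.0, 2.0], [0.5, 0.0]]))
        assert st.lam == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(st.w, [2 / 3, 1 / 3], atol=1e-12)

    def test_eigen_matches_power_iteration_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r = VitalRates(tuple(rng.uniform(0.2, 0.95, 4)),
                           tuple(rng.uniform(0.5, 0.95, 3)),
                           tuple(rng.uniform(0.1, 1.5, 3)))
            A = build_projection_matrix(r)
            eig = asymptotic_analysis(A)
            pit = power_iteration(A, n_steps=10_000)
            assert abs(eig.lam - pit.lam) < 1e-10
            assert np.abs(eig.w - pit.w).max() < 1e-10
            assert np.abs(A @ eig.w - eig.lam * eig.w).max() < 1e-10

    def test_reducible_rejected(self):
        with pytest.raises(ModelError, match="reducible"):
            asymptotic_analysis(np.array([[1.0, 1.0], [0.0, 1.0]]))

    def test_default_rates_hit_calibrated_growth(self, rates):
        st = asymptotic_analysis(build_projection_matrix(rates))
        assert st.lam == pytest.approx(1.07, abs=5e-3)
        assert st.w.min() > 0
        assert st.w.sum() == pytest.approx(1.0)

    def test_calibration_unreachable_target_rejected(self, rates):
        with pytest.raises(ConfigurationError):
            calibrate_juvenile_survival(rates, 5.0)


class TestMeanDate:
    def test_constant_dates_give_constant_mean(self, rates):
        assert mean_date_of(rates, (92.0, 92.0, 92.0)) == pytest.approx(92.0)

    def test_single_fertile_stage_pins_the_date(self):
        r = VitalRates((0.6, 0.8, 0.8, 0.85), (0.9, 0.9, 0.9),
                       (0.0, 0.0, 0.8))
        assert mean_date_of(r, (95.0, 93.0, 90.0)) == pytest.approx(90.0)

    def test_all_sterile_is_undefined(self):
        r = VitalRates((0.6, 0.8, 0.8, 0.85), (0.9, 0.9, 0.9),
                       (0.5, 0.5, 0.5))
        st = asymptotic_analysis(build_projection_matrix(r))
        with pytest.raises(ModelError):
            population_mean_pupping_date(
                st, r.replace(fertility=(0.0, 0.0, 0.0)), (95.0, 93.0, 90.0))

    def test_matches_projection_simulation_oracle(self):
        """Project a 3-stage toy to stationarity and average the birth
        dates of simulated pups; must agree with the stable-structure
        weighting to < 0.01 day."""
        A = np.array([[0.0, 1.0, 1.2],
                      [0.5, 0.0, 0.0],
                      [0.0, 0.8, 0.8]])
        st = asymptotic_analysis(A)
        f = np.array([1.0, 1.2])
        stage_dates = np.array([95.0, 90.0])
        weights = st.w[1:] * f
        analytic = weights @ stage_dates / weights.sum()

        n = np.array([1.0, 0.0, 0.0])
        for _ in range(100_000):
            n = A @ n
            n /= n.sum()
        births = np.array([f[0] * n[1], f[1] * n[2]])
        simulated = births @ stage_dates / births.sum()
        assert abs(analytic - simulated) < 0.01

    def test_mean_within_stage_date_range(self, rates):
        d = (95.0, 93.0, 90.0)
        for mode in ("pup_weighted", "stable_only"):
            m = mean_date_of(rates, d, mode=mode)
            assert min(d) <= m <= max(d)

    def test_weight_modes_sum_to_one(self, rates):
        st = asymptotic_analysis(build_projection_matrix(rates))
        for mode in ("pup_weighted", "stable_only"):
            w = breeder_weights(st, rates, mode=mode)
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()


class TestSensitivity:
    def test_constant_dates_zero_everywhere(self, rates):
        table = perturbation_sensitivity(rates, (92.0, 92.0, 92.0))
        nz = table.dropna(subset=["delta_days"])
        assert np.allclose(nz["delta_days"], 0.0, atol=1e-12)
        assert (table.loc[table["delta_days"].isna(), "sign"] == "none").all()

    def test_direction_pattern_with_age_declining_dates(self, rates, dates):
        """Older-adult survival boosts advance the season; young-adult
        survival boosts delay it."""
        table = perturbation_sensitivity(rates, dates).set_index(
            ["from_stage", "to_stage"])
        assert table.loc[("A5", "A6"), "delta_days"] < 0
        assert table.loc[("A6", "A6"), "delta_days"] < 0
        assert table.loc[("A4", "A5"), "delta_days"] > 0

    def test_impossible_transitions_reported_none(self, rates, dates):
        table = perturbation_sensitivity(rates, dates)
        assert len(table) == 49
        assert (table["sign"] == "none").sum() == 49 - 10

    def test_matches_brute_force_on_toy(self):
        """Elementwise recomputation oracle on a small two-adult-stage
        parameterization."""
        r = VitalRates((0.6, 0.7, 0.8, 0.85), (0.9, 0.85, 0.8),
                       (0.3, 0.5, 0.7))
        d = (94.0, 92.0, 89.0)
        table = perturbation_sensitivity(r, d, delta=0.1).set_index(
            ["from_stage", "to_stage"])
        base = mean_date_of(r, d)
        # brute force one survival and one fertility element by hand
        r2 = VitalRates((0.66, 0.7, 0.8, 0.85), r.adult_survival, r.fertility)
        assert table.loc[("J0", "J1"), "delta_days"] == pytest.approx(
            mean_date_of(r2, d) - base, abs=1e-12)
        r3 = VitalRates(r.juvenile_survival, r.adult_survival,
                        (0.3, 0.55, 0.7))
        assert table.loc[("A5", "J0"), "delta_days"] == pytest.approx(
            mean_date_of(r3, d) - base, abs=1e-12)

    def test_survival_capped_at_ceiling(self, dates):
        r = VitalRates((0.6, 0.7, 0.8, 0.85), (0.9, 0.9, 0.995),
                       (0.3, 0.5, 0.7))
        table = perturbation_sensitivity(r, dates)
        # perturbing the 0.995 self-loop must cap at 0.999, not 1.0945
        capped = VitalRates(r.juvenile_survival, (0.9, 0.9, 0.999),
                            r.fertility)
        expected = mean_date_of(capped, dates) - mean_date_of(r, dates)
        got = table.set_index(["from_stage", "to_stage"]).loc[
            ("A6", "A6"), "delta_days"]
        assert got == pytest.approx(expected, abs=1e-12)


class TestSweep:
    def test_baseline_at_ceiling_gives_zero_shift(self, rates, dates):
        out = survival_sweep(rates, dates, baseline_grid=[0.999])
        assert out["shift_days"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_shift_magnitude_monotone_in_baseline(self, rates, dates):
        out = survival_sweep(rates, dates)
        shifts = out["shift_days"].to_numpy()
        assert (shifts <= 1e-12).all()  # advances
        assert (np.diff(np.abs(shifts)) <= 1e-9).all()

    def test_constant_dates_zero_shifts(self, rates):
        out = survival_sweep(rates, (92.0, 92.0, 92.0))
        assert np.allclose(out["shift_days"], 0.0, atol=1e-12)

    def test_empty_grid_rejected(self, rates, dates):
        with pytest.raises(ConfigurationError):
            survival_sweep(rates, dates, baseline_grid=[])

    def test_achievable_advance_below_observed_shift(self, rates, dates):
        """Pushing old-adult survival to its ceiling cannot reproduce
        the ~7.6-day advance seen at the population level: the stable
        structure alone underdetermines the observed shift."""
        out = survival_sweep(rates, dates)
        assert out["shift_days"].abs().max() < 7.6


def test_default_stage_dates_follow_age_slope():
    d = default_stage_dates(anchor_date=90.0, age_slope=-1.0,
                            a6_effective_age=9.0)
    assert d == (90.0, 89.0, 85.5)
    assert d[0] > d[1] > d[2]
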