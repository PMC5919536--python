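"""Boostering-regime plateau analysis."""

import numpy as np
import pytest
from scipy.optimize import brentq

from antird import (
    DAYS_PER_YEAR,
    DonorParameters,
    booster_envelope,
    booster_saturation,
    default_population,
    regime_table,
    steady_state,
)

REFERENCE_GAINS = (4.26, 0.73, 0.38, 0.20)
REFERENCE_PLATEAUS = (8.28, 10.16, 11.31)  # at 0.5, 1, 1.5 boosters per year


def fixed_point_by_root(frequency, donor, pop):
    """Independent oracle: solve gain(T) = |D| * interval with a root finder."""
    interval = DAYS_PER_YEAR / frequency
    env = booster_envelope(interval, pop.timing_rate)

    def balance(t):
        return (
            donor.decline_rate * interval
            + 2 * pop.max_effect * env * booster_saturation(t, donor.saturation_speed)
        )

    if balance(0.0) <= 0:
        return 0.0
    return brentq(balance, 0.0, 30.0, xtol=1e-12)


class TestSteadyState:
    @pytest.mark.parametrize("frequency", [0.5, 1.0, 1.5, 3.0])
    def test_fixed_point_matches_root_finder(self, pop, frequency):
        ss = steady_state(frequency, pop.mean_donor, pop)
        assert ss.converged
        assert ss.trough_titer == pytest.approx(
            fixed_point_by_root(frequency, pop.mean_donor, pop), abs=1e-8
        )

    def test_gain_balances_decline_at_plateau(self, pop):
        ss = steady_state(1.0, pop.mean_donor, pop)
        interval = DAYS_PER_YEAR
        gain = (
            2
            * pop.max_effect
            * booster_envelope(interval, pop.timing_rate)
            * booster_saturation(ss.trough_titer, pop.mean_donor.saturation_speed)
        )
        assert gain == pytest.approx(-pop.mean_decline * interval, abs=1e-8)

    def test_annual_cycle_matches_published_plateau(self, pop):
        """The calibrated average donor boostered annually cycles between
        about 9.90 (trough) and 10.40 (peak), averaging about 10.16."""
        ss = steady_state(1.0, pop.mean_donor, pop)
        assert ss.trough_titer == pytest.approx(9.90, abs=0.05)
        assert ss.peak_titer == pytest.approx(10.40, abs=0.05)
        assert ss.mean_titer == pytest.approx(10.16, abs=0.05)

    def test_ordering_and_frequency_monotonicity(self, pop):
        rng = np.random.default_rng(0)
        for _ in range(10):
            donor = DonorParameters(
                -abs(rng.normal(1.5e-3, 8e-4)), abs(rng.normal(0.33, 0.08))
            )
            means = []
            for f in (0.5, 1.0, 1.5):
                ss = steady_state(f, donor, pop)
                assert ss.trough_titer <= ss.mean_titer <= ss.peak_titer
                means.append(ss.mean_titer)
            assert means[0] < means[1] < means[2]

    def test_perturbed_start_returns_to_same_plateau(self, pop):
        # the gain decreases with titer, so the map contracts back
        base = steady_state(1.0, pop.mean_donor, pop)
        for delta in (-1.0, 1.0):
            interval = DAYS_PER_YEAR
            env = booster_envelope(interval, pop.timing_rate)
            t = base.trough_titer + delta
            for _ in range(5000):
                t = max(
                    t
                    + pop.mean_decline * interval
                    + 2
                    * pop.max_effect
                    * env
                    * booster_saturation(max(t, 0.0), pop.mean_donor.saturation_speed),
                    0.0,
                )
            assert t == pytest.approx(base.trough_titer, abs=1e-6)

    def test_weak_responder_converges_to_zero_trough(self, pop):
        # even the maximal gain (B at titer 0) cannot offset the interval
        # decline, so the trough sinks to 0 without oscillation
        from dataclasses import replace

        weak_pop = replace(pop, max_effect=0.5)
        donor = DonorParameters(-1.0 / 365.0, weak_pop.mean_saturation)
        ss = steady_state(1.0, donor, weak_pop)
        assert ss.converged
        assert ss.trough_titer == 0.0
        assert ss.mean_titer < ss.peak_titer <= 0.5

    def test_invalid_frequency_rejected(self, pop):
        with pytest.raises(ValueError):
            steady_state(0.0, pop.mean_donor, pop)


def _pop_params(pop):
    return {
        "max_effect": pop.max_effect,
        "timing_rate": pop.timing_rate,
        "annual_mean_decline": pop.annual_mean_decline,
        "mean_saturation": pop.mean_saturation,
        "sd_decline": pop.sd_decline,
        "sd_saturation": pop.sd_saturation,
        "residual_sd": pop.residual_sd,
    }


class TestRegimeTable:
    def test_population_row_reproduces_reference_gains(self, pop):
        table = regime_table(_pop_params(pop))
        row = table.iloc[0]
        for t0, ref in zip((3, 9, 11, 13), REFERENCE_GAINS):
            assert row[f"gain_at_{t0}"] == pytest.approx(ref, abs=0.08)

    def test_population_row_reproduces_reference_plateaus(self, pop):
        table = regime_table(_pop_params(pop))
        row = table.iloc[0]
        for f, ref in zip((0.5, 1, 1.5), REFERENCE_PLATEAUS):
            assert row[f"plateau_mean_{f:g}_per_year"] == pytest.approx(ref, abs=0.05)

    def test_percent_conversions_appended(self, pop):
        row = regime_table(_pop_params(pop)).iloc[0]
        assert round(row["gain_at_3_pct"]) == 1816
        assert round(row["gain_at_9_pct"]) == 66
        assert round(row["gain_at_11_pct"]) == 30
        assert round(row["gain_at_13_pct"]) == 15
        assert round(row["annual_decline_pct"]) == -32

    def test_quantile_rows_ordered(self, pop, recovery_runs):
        fit = recovery_runs[0][1].final
        table = regime_table(fit.params, fit.per_donor)
        assert list(table["row"]) == [
            "population average",
            "upper 25th percentile",
            "median",
            "lower 25th percentile",
        ]
        # the favourable tail has the shallower decline and the larger gains
        upper, median, lower = table.iloc[1], table.iloc[2], table.iloc[3]
        assert upper["annual_decline"] > median["annual_decline"] > lower["annual_decline"]
        for col in ("gain_at_11", "plateau_mean_1_per_year"):
            assert upper[col] > median[col] > lower[col]

    def test_zero_frequency_rejected(self, pop):
        with pytest.raises(ValueError):
            regime_table(_pop_params(pop), frequencies=(0.0, 1.0))
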