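"""Core response equations: envelope, saturation, gain, trajectories, peaks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antird import (
    DonorParameters,
    PopulationParameters,
    booster_envelope,
    booster_gain,
    booster_saturation,
    log2_change,
    peak_day,
    percent_change,
    predict_trajectory,
)

POP = PopulationParameters(
    max_effect=7.0,
    timing_rate=0.2,
    mean_decline=-0.55 / 365,
    sd_decline=0.4 / 365,
    mean_saturation=0.33,
    sd_saturation=0.08,
    residual_sd=0.62,
)


class TestEnvelope:
    @pytest.mark.parametrize(
        "t, h, expected",
        [
            (0.0, 0.2, 0.0),  # no effect at the booster instant
            (-30.0, 0.2, 0.0),  # and none before it
            (26.0, 0.2, 0.98903),  # 2(1/(1+e^{-5.2}) - 1/2), evaluated directly
            (1e6, 0.2, 1.0),  # asymptote
        ],
    )
    def test_values(self, t, h, expected):
        assert booster_envelope(t, h) == pytest.approx(expected, abs=1e-5)

    @given(
        h=st.floats(0.01, 0.4),
        t1=st.floats(0.1, 50.0),
        dt=st.floats(0.1, 20.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_increasing(self, h, t1, dt):
        e1, e2 = booster_envelope(t1, h), booster_envelope(t1 + dt, h)
        assert 0.0 < e1 < 1.0
        assert e2 > e1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            booster_envelope(np.nan, 0.2)
        with pytest.raises(ValueError):
            booster_envelope(10.0, -0.1)


class TestSaturation:
    @pytest.mark.parametrize(
        "t0, l, expected",
        [
            (0.0, 0.3, 0.5),  # half the maximum at titer 0
            (0.0, 2.0, 0.5),
            (10.0, 0.3, 0.04743),  # 1/(1+e^3)
            (1e6, 0.3, 0.0),
        ],
    )
    def test_values(self, t0, l, expected):
        assert booster_saturation(t0, l) == pytest.approx(expected, abs=1e-5)

    @given(l=st.floats(0.05, 1.0), t0=st.floats(0.0, 18.0), dt=st.floats(0.1, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_decreasing_in_titer(self, l, t0, dt):
        s1, s2 = booster_saturation(t0, l), booster_saturation(t0 + dt, l)
        assert 0.0 < s2 < s1 <= 0.5

    def test_negative_titer_rejected(self):
        with pytest.raises(ValueError):
            booster_saturation(-0.5, 0.3)


class TestGain:
    def test_zero_at_booster_instant(self):
        assert booster_gain(5.0, 0.0, POP, POP.mean_donor) == 0.0

    def test_asymptotic_gain_at_zero_titer_is_max_effect(self):
        # 2B * 1 * 1/2 = B: the quoted "maximum boostering effect"
        g = booster_gain(0.0, 1e7, POP, POP.mean_donor)
        assert g == pytest.approx(POP.max_effect, rel=1e-9)

    def test_composes_envelope_and_saturation(self):
        donor = DonorParameters(-0.55 / 365, 0.33)
        expected = 2 * 7.0 * booster_envelope(26.0, 0.2) * (1 / (1 + math.exp(0.33 * 8)))
        assert booster_gain(8.0, 26.0, POP, donor) == pytest.approx(expected, rel=1e-12)

    @given(t0=st.floats(0.0, 15.0), dt=st.floats(0.1, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_starting_titer(self, t0, dt):
        g1 = booster_gain(t0, 40.0, POP, POP.mean_donor)
        g2 = booster_gain(t0 + dt, 40.0, POP, POP.mean_donor)
        assert g2 < g1
        assert g1 < POP.max_effect  # any single booster's gain is below B


def _brute_force_trajectory(boosters, baseline, donor, pop, eval_days):
    """Independent oracle: recompute every booster term at every day."""
    starts = []
    for j, xj in enumerate(boosters):
        val = baseline + donor.decline_rate * xj
        for ll, xl in enumerate(boosters[:j]):
            val += (
                2.0
                * pop.max_effect
                * booster_envelope(xj - xl, pop.timing_rate)
                * booster_saturation(max(starts[ll], 0.0), donor.saturation_speed)
            )
        starts.append(max(val, 0.0))
    out = []
    for t in eval_days:
        val = baseline + donor.decline_rate * t
        for j, xj in enumerate(boosters):
            val += (
                2.0
                * pop.max_effect
                * booster_envelope(t - xj, pop.timing_rate)
                * booster_saturation(starts[j], donor.saturation_speed)
            )
        out.append(max(val, 0.0))
    return np.array(out)


class TestTrajectory:
    def test_pure_decline_without_boosters(self):
        donor = DonorParameters(-0.55 / 365, 0.33)
        traj = predict_trajectory([], 11.0, donor, POP, [365.0])
        assert traj.titers[0] == pytest.approx(11.0 - 0.55, rel=1e-12)

    def test_clamped_at_zero(self):
        donor = DonorParameters(-0.55 / 365, 0.33)
        traj = predict_trajectory([], 0.2, donor, POP, [365.0])
        assert traj.titers[0] == 0.0
        assert traj.unclamped[0] == pytest.approx(0.2 - 0.55, rel=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            m = rng.integers(0, 6)
            boosters = np.sort(rng.uniform(0, 900, m))
            baseline = rng.uniform(0, 14)
            donor = DonorParameters(rng.normal(-1.5e-3, 1e-3), abs(rng.normal(0.33, 0.1)))
            days = np.sort(rng.uniform(0, 1100, 12))
            traj = predict_trajectory(boosters, baseline, donor, POP, days)
            oracle = _brute_force_trajectory(boosters, baseline, donor, POP, days)
            np.testing.assert_allclose(traj.titers, oracle, atol=1e-10)
            assert np.all(traj.titers >= 0)

    def test_removing_a_booster_never_raises_the_curve(self):
        donor = DonorParameters(-1.5e-3, 0.33)
        boosters = [0.0, 200.0, 420.0]
        days = np.linspace(0, 900, 200)
        full = predict_trajectory(boosters, 6.0, donor, POP, days)
        for drop in range(3):
            reduced = predict_trajectory(
                [b for i, b in enumerate(boosters) if i != drop], 6.0, donor, POP, days
            )
            assert np.all(reduced.titers <= full.titers + 1e-12)

    def test_clamp_idempotent(self):
        donor = DonorParameters(-3e-3, 0.33)
        traj = predict_trajectory([100.0], 1.0, donor, POP, np.linspace(0, 900, 50))
        assert np.all(traj.titers >= 0)
        np.testing.assert_array_equal(np.maximum(traj.titers, 0.0), traj.titers)

    def test_unsorted_boosters_rejected(self):
        with pytest.raises(ValueError):
            predict_trajectory([200.0, 100.0], 5.0, POP.mean_donor, POP, [300.0])


class TestPeakDay:
    def test_no_finite_peak_without_decline(self):
        assert math.isinf(peak_day(1.5, 0.15, 0.0))
        assert math.isinf(peak_day(1.5, 0.15, 1e-4))

    def test_peak_at_zero_when_decline_dominates(self):
        # -D >= B H / 2: response falls from the start
        assert peak_day(1.0, 0.1, -0.06) == 0.0

    @pytest.mark.parametrize(
        "b, h, d",
        [(1.5, 0.15, -0.0015), (0.38, 0.17, -0.0015), (8.0, 0.31, -0.0015), (2.0, 0.05, -0.004)],
    )
    def test_matches_grid_search(self, b, h, d):
        grid = np.arange(0.0, 400.0, 0.01)
        response = 2 * b * (1 / (1 + np.exp(-h * grid)) - 0.5) + d * grid
        assert peak_day(b, h, d) == pytest.approx(grid[np.argmax(response)], abs=0.1)


class TestScaleConversions:
    @pytest.mark.parametrize(
        "delta, pct",
        [(-0.55, -32), (0.0, 0), (4.26, 1816), (0.73, 66), (0.20, 15), (0.72, 65), (0.42, 34)],
    )
    def test_printed_values(self, delta, pct):
        assert round(percent_change(delta)) == pct

    @given(d=st.floats(-5.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, d):
        assert log2_change(percent_change(d)) == pytest.approx(d, abs=1e-12)

    def test_sign_preserved(self):
        assert percent_change(-0.1) < 0 < percent_change(0.1)
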