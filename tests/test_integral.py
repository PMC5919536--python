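"""Step 3: the integral nonlinear mixed-effects fit and its diagnostics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from antird import (
    CohortConfig,
    filter_unboostered,
    fit_decline,
    fit_integral,
    per_donor_residuals,
    simulate_cohort,
)
from conftest import gain_at


@pytest.fixture(scope="module")
def quiet_cohort(pop):
    """Noise-free cohort: identical donors, no measurement error or rounding."""
    quiet = replace(pop, residual_sd=1e-9, sd_decline=1e-12, sd_saturation=1e-12)
    config = CohortConfig(n_donors=40, pop=quiet, round_titers=False, seed=2)
    return simulate_cohort(config), quiet


class TestSelfConsistency:
    def test_noise_free_fixed_effects_recovered(self, quiet_cohort):
        """Self-consistency: on data generated exactly by the model, the
        generating fixed effects are a stationary point of the marginal
        likelihood — started there, the fit stays there.  Any mean-function
        or likelihood misspecification would pull the optimiser away, since
        with the residual SD pinned small even tiny systematic residuals
        dominate the objective."""
        sample, quiet = quiet_cohort
        fit = fit_integral(
            sample.records,
            timing_rate=quiet.timing_rate,
            start={
                "max_effect": quiet.max_effect,
                "annual_mean_decline": quiet.annual_mean_decline,
                "mean_saturation": quiet.mean_saturation,
            },
            fix={
                "annual_sd_decline": 1e-3,
                "sd_saturation": 1e-3,
                "residual_sd_effective": 1e-3,
            },
            measurement_grid=None,
        )
        assert fit.params["max_effect"] == pytest.approx(quiet.max_effect, rel=1e-4)
        assert fit.params["annual_mean_decline"] == pytest.approx(-0.55, abs=1e-4)
        assert fit.params["mean_saturation"] == pytest.approx(
            quiet.mean_saturation, rel=1e-3
        )

    def test_boosterless_cohort_degenerates_to_decline_fit(self, pop):
        """Without boosters the integral model is exactly the random-slope
        decline model, so both fits must agree."""
        config = CohortConfig(
            n_donors=120, new_donor_boosters=(0, 0), booster_trigger_titer=-1,
            retrigger_drop=1e6, baseline_mean=11.0, seed=13,
        )
        sample = simulate_cohort(config)
        assert all(r.n_boosters == 0 for r in sample.records)
        step1 = fit_decline(filter_unboostered(sample.records))
        step3 = fit_integral(
            sample.records,
            timing_rate=pop.timing_rate,
            start={"annual_mean_decline": -0.5},
            fix={"max_effect": pop.max_effect, "mean_saturation": pop.mean_saturation,
                 "sd_saturation": pop.sd_saturation},
        )
        assert step3.params["annual_mean_decline"] == pytest.approx(
            step1.params["annual_mean_decline"], abs=1e-3
        )
        assert step3.params["annual_sd_decline"] == pytest.approx(
            step1.params["annual_sd_decline"], rel=1e-2
        )
        assert step3.params["residual_sd_effective"] == pytest.approx(
            step1.params["residual_sd_effective"], rel=1e-2
        )


class TestRecovery:
    def test_mean_decline_and_gain_recovered(self, recovery_runs, pop):
        """Averaged across the five 500-donor replicates, the integral fit
        recovers the generating decline and the gain at the median titer."""
        mu_d = np.mean([p.final.params["annual_mean_decline"] for _, p in recovery_runs])
        gain11 = np.mean([gain_at(p.final.params, 11.0) for _, p in recovery_runs])
        true_gain = gain_at(
            {"max_effect": pop.max_effect, "mean_saturation": pop.mean_saturation}, 11.0
        )
        assert mu_d == pytest.approx(-0.55, abs=0.08)
        assert gain11 == pytest.approx(true_gain, abs=0.12)

    def test_outer_loop_reaches_seven_digit_stability(self, recovery_runs):
        """The starting-titer iteration stabilises every population
        parameter to a relative change below 1e-7 within 30 loops."""
        for _, pipe in recovery_runs:
            fit = pipe.final
            assert fit.converged, f"no convergence in {fit.iterations} loops"
            assert fit.iterations <= 30
            assert fit.extras["outer_rel_changes"][-1] < 1e-7

    def test_parameter_change_sequence_decays(self, recovery_runs):
        rel = recovery_runs[0][1].final.extras["outer_rel_changes"]
        # later third of the sequence is much smaller than the first third
        assert np.mean(rel[-3:]) < 1e-2 * np.mean(rel[:3])


class TestResiduals:
    def test_perfect_fit_zero_residuals(self, quiet_cohort):
        sample, quiet = quiet_cohort
        per_donor = pd.DataFrame(
            {
                "donor_id": [r.donor_id for r in sample.records],
                "decline_rate": [t.params.decline_rate for t in sample.truths],
                "saturation_speed": [t.params.saturation_speed for t in sample.truths],
            }
        )
        res = per_donor_residuals(sample.records, per_donor=per_donor, pop=quiet)
        assert res["mae"].max() < 1e-6

    def test_cohort_mae_matches_folded_gaussian(self, small_cohort, pop):
        """With the generating donor parameters, the mean absolute
        prediction error equals the folded-normal mean of the measurement
        error, sigma * sqrt(2/pi), up to the integer-rounding contribution."""
        per_donor = pd.DataFrame(
            {
                "donor_id": [r.donor_id for r in small_cohort.records],
                "decline_rate": [t.params.decline_rate for t in small_cohort.truths],
                "saturation_speed": [t.params.saturation_speed for t in small_cohort.truths],
            }
        )
        res = per_donor_residuals(small_cohort.records, per_donor=per_donor, pop=pop)
        expected = pop.residual_sd * np.sqrt(2 / np.pi)
        assert res["mae"].mean() == pytest.approx(expected, abs=0.08)

    def test_donors_sortable_by_mae(self, small_cohort):
        per_donor = pd.DataFrame(
            {
                "donor_id": [r.donor_id for r in small_cohort.records],
                "decline_rate": [t.params.decline_rate for t in small_cohort.truths],
                "saturation_speed": [t.params.saturation_speed for t in small_cohort.truths],
            }
        )
        pop = small_cohort.config.resolved_pop()
        table = per_donor_residuals(small_cohort.records, per_donor=per_donor, pop=pop)
        ordered = table.sort_values("mae", ascending=False, kind="stable")
        assert list(ordered["mae"]) == sorted(table["mae"], reverse=True)
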