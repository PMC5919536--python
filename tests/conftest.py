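"""Shared fixtures.

The expensive session fixtures (multi-seed parameter-recovery fits and the
split-sample validation) are shared between the unit tests and the
acceptance tests so the heavy mixed-effects fits run once each.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from antird import (
    CohortConfig,
    default_population,
    per_donor_residuals,
    run_pipeline,
    simulate_cohort,
    split_validate,
)

_hyp_settings.register_profile("deterministic", database=None, derandomize=True)
_hyp_settings.load_profile("deterministic")

RECOVERY_SEEDS = (1, 2, 3, 4, 5)
RECOVERY_N_DONORS = 500


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture(scope="session")
def small_cohort():
    """150-donor default cohort for structural (non-recovery) tests."""
    return simulate_cohort(CohortConfig(n_donors=150, seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    """30-donor cohort for smoke-level tests."""
    return simulate_cohort(CohortConfig(n_donors=30, seed=5))


@pytest.fixture(scope="session")
def default_cohort_timing():
    """Step-2A fit on the default cohort (default config, seed 0)."""
    from antird import filter_unboostered, fit_decline, fit_timing, extract_post_booster

    sample = simulate_cohort(CohortConfig())
    step1 = fit_decline(filter_unboostered(sample.records))
    return fit_timing(extract_post_booster(sample.records), step1.params["mean_decline"])


@pytest.fixture(scope="session")
def recovery_runs():
    """Full staged pipelines on 500-donor cohorts across five seeds.

    Returns a list of (CohortSample, PipelineResult); the generating
    parameters are the calibrated defaults.
    """
    runs = []
    for seed in RECOVERY_SEEDS:
        sample = simulate_cohort(CohortConfig(n_donors=RECOVERY_N_DONORS, seed=seed))
        pipe = run_pipeline(sample.records)
        runs.append((sample, pipe))
    return runs


@pytest.fixture(scope="session")
def split_validation():
    """755-donor cohort: full fit, then a 500/255 split refit + MAP.

    The full-cohort fit serves as the reference against which the subset
    fit's hyperparameter shifts are measured.
    """
    sample = simulate_cohort(CohortConfig(n_donors=755, seed=21))
    full = run_pipeline(sample.records)
    report = split_validate(sample.records, n_fit=500, seed=3, reference_fit=full.final)
    return sample, report


def gain_at(params: dict, t0: float) -> float:
    """Asymptotic booster gain at a starting titer, from fitted parameters."""
    return float(
        2.0 * params["max_effect"] / (1.0 + np.exp(t0 * params["mean_saturation"]))
    )
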