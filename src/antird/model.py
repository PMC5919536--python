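"""Core equations of anti-RhD titer dynamics in hyper-immunised donors.

The model tracks the log2 anti-RhD titer of a plasma donor as the sum of a
donor-specific log-linear decline and saturating responses to booster events
(deliberate re-exposure to RhD-positive red cells).  For donor *i* with
decline rate ``D_i`` (log2 units per day), saturation speed ``L_i`` (per log2
unit) and boosters at days ``x_1 < x_2 < ...``, the predicted titer is

    T_i(t) = T_i(0) + D_i * t
             + sum_{j : x_j <= t}  2 B * env(t - x_j; H) * sat(T_i(x_j); L_i)

where ``env(t; H) = 2 (1/(1+exp(-H t)) - 1/2)`` is the logistic time envelope
of a booster's effect (0 at the booster instant, asymptote 1), and
``sat(T0; L) = 1 - 1/(1+exp(-L T0))`` is the logistic saturation of the gain
with the titer at boostering (1/2 at T0 = 0, decreasing).  ``B`` (log2 units)
and ``H`` (per day) are population-level: ``B`` is the maximum asymptotic
gain of a single booster administered at titer 0, and ``H`` sets how fast the
gain develops.  Predicted titers below 0 are clamped to 0, as is the starting
titer fed into the saturation term.

All titers are on the log2 dilution scale; absolute titer = 2**(log2 titer).
Internal time unit is days; reported rates use 365 days per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DAYS_PER_YEAR",
    "DonorParameters",
    "PopulationParameters",
    "DonorRecord",
    "Trajectory",
    "booster_envelope",
    "booster_saturation",
    "booster_gain",
    "predict_trajectory",
    "peak_day",
    "response_peak_day",
    "percent_change",
    "log2_change",
]

DAYS_PER_YEAR = 365.0

#: Minimum spacing between donations (days); donors may donate every two weeks.
MIN_DONATION_GAP = 14


def _require_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class DonorParameters:
    """Individual-level kinetic parameters.

    Parameters
    ----------
    decline_rate
        Natural log-linear rate of titer change ``D_i``, in log2 units per
        day.  Negative for declining donors.
    saturation_speed
        Speed ``L_i`` at which the booster gain shrinks with the titer at
        boostering, per log2 unit.  Non-negative for responsive donors.
    """

    decline_rate: float
    saturation_speed: float

    def __post_init__(self) -> None:
        _require_finite("decline_rate", self.decline_rate)
        _require_finite("saturation_speed", self.saturation_speed)

    @property
    def annual_decline(self) -> float:
        """Decline rate expressed per year (exactly ``decline_rate * 365``)."""
        return self.decline_rate * DAYS_PER_YEAR

    @classmethod
    def from_annual(cls, annual_decline: float, saturation_speed: float) -> "DonorParameters":
        return cls(annual_decline / DAYS_PER_YEAR, saturation_speed)


@dataclass(frozen=True)
class PopulationParameters:
    """Population-level (fixed and random-effect) parameters.

    ``max_effect`` (B, log2 units) and ``timing_rate`` (H, per day) are shared
    by all donors.  Individual ``(D_i, L_i)`` are drawn from a bivariate
    normal with means ``mean_decline`` / ``mean_saturation``, standard
    deviations ``sd_decline`` / ``sd_saturation`` and covariance
    ``cov_decline_saturation``.  ``residual_sd`` is the Gaussian measurement
    error of a single titer determination (log2 units).
    """

    max_effect: float
    timing_rate: float
    mean_decline: float
    sd_decline: float
    mean_saturation: float
    sd_saturation: float
    residual_sd: float
    cov_decline_saturation: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "max_effect",
            "timing_rate",
            "mean_decline",
            "sd_decline",
            "mean_saturation",
            "sd_saturation",
            "residual_sd",
            "cov_decline_saturation",
        ):
            _require_finite(name, getattr(self, name))
        if self.max_effect <= 0:
            raise ValueError("max_effect must be > 0")
        if self.timing_rate <= 0:
            raise ValueError("timing_rate must be > 0")
        if self.sd_decline <= 0 or self.sd_saturation <= 0 or self.residual_sd <= 0:
            raise ValueError("sd_decline, sd_saturation and residual_sd must be > 0")
        if abs(self.cov_decline_saturation) > self.sd_decline * self.sd_saturation:
            raise ValueError("covariance of (D, L) must give a positive semi-definite matrix")

    @property
    def random_effects_cov(self) -> np.ndarray:
        """2x2 covariance matrix of (decline_rate, saturation_speed)."""
        return np.array(
            [
                [self.sd_decline**2, self.cov_decline_saturation],
                [self.cov_decline_saturation, self.sd_saturation**2],
            ]
        )

    @property
    def mean_donor(self) -> DonorParameters:
        return DonorParameters(self.mean_decline, self.mean_saturation)

    @property
    def annual_mean_decline(self) -> float:
        return self.mean_decline * DAYS_PER_YEAR

    @property
    def annual_sd_decline(self) -> float:
        return self.sd_decline * DAYS_PER_YEAR


@dataclass(frozen=True)
class DonorRecord:
    """One donor's longitudinal record.

    ``obs_days`` are days since the donor's first record, strictly increasing
    and at least 14 days apart (the minimum donation interval).
    ``measured_titers`` are the non-negative log2 titers measured at those
    donations (discrete integer dilution steps, stored as floats).
    ``booster_days`` are the days of booster events, sorted ascending;
    boosters are administered at donations, so each booster day is normally
    also an observation day.
    """

    donor_id: str
    obs_days: np.ndarray
    measured_titers: np.ndarray
    booster_days: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs_days", np.asarray(self.obs_days, dtype=float))
        object.__setattr__(self, "measured_titers", np.asarray(self.measured_titers, dtype=float))
        object.__setattr__(self, "booster_days", np.asarray(self.booster_days, dtype=float))
        if self.obs_days.ndim != 1 or self.measured_titers.shape != self.obs_days.shape:
            raise ValueError("obs_days and measured_titers must be 1-D and equally long")
        gaps = np.diff(self.obs_days)
        if np.any(gaps <= 0):
            raise ValueError(f"obs_days must be strictly increasing (donor {self.donor_id})")
        if np.any(gaps < MIN_DONATION_GAP):
            raise ValueError(
                f"donation days must be >= {MIN_DONATION_GAP} days apart (donor {self.donor_id})"
            )
        if np.any(self.measured_titers < 0):
            raise ValueError(f"measured titers must be >= 0 (donor {self.donor_id})")
        if np.any(np.diff(self.booster_days) < 0):
            raise ValueError(f"booster_days must be sorted (donor {self.donor_id})")

    @property
    def n_obs(self) -> int:
        return len(self.obs_days)

    @property
    def n_boosters(self) -> int:
        return len(self.booster_days)

    def titer_at(self, day: float) -> float:
        """Measured titer at ``day``: exact match, else last measurement before.

        Booster events coincide with donations, so an exact match is the
        normal case; the carry-back fallback covers externally supplied data
        where a booster day was logged without a same-day titer.
        """
        idx = np.searchsorted(self.obs_days, day, side="right") - 1
        if idx < 0:
            raise ValueError(f"no measurement at or before day {day} (donor {self.donor_id})")
        return float(self.measured_titers[idx])


@dataclass(frozen=True)
class Trajectory:
    """Model-predicted titer curve for one donor.

    ``titers`` are clamped at 0; ``unclamped`` keeps the raw model values.
    ``booster_start_titers`` are the model's own (clamped) starting titers at
    each booster event.
    """

    eval_days: np.ndarray
    titers: np.ndarray
    unclamped: np.ndarray
    booster_days: np.ndarray
    booster_start_titers: np.ndarray = field(default_factory=lambda: np.empty(0))


def booster_envelope(days_since_booster, timing_rate: float):
    """Logistic time envelope of a booster's effect, in [0, 1).

    ``2 (1/(1+exp(-H t)) - 1/2) = tanh(H t / 2)`` for t > 0, and exactly 0
    for t <= 0: a booster has no effect before (or at the instant of) its
    administration.
    """
    _require_finite("days_since_booster", days_since_booster)
    _require_finite("timing_rate", timing_rate)
    if timing_rate <= 0:
        raise ValueError("timing_rate must be > 0")
    t = np.asarray(days_since_booster, dtype=float)
    out = np.where(t > 0, np.tanh(timing_rate * t / 2.0), 0.0)
    return out if out.ndim else float(out)


def booster_saturation(starting_titer, saturation_speed: float):
    """Logistic saturation of the booster gain with the titer at boostering.

    ``1 - 1/(1+exp(-L T0))``: equals 1/2 at T0 = 0 and decreases towards 0
    as the starting titer grows (for L > 0).  Starting titers are clamped to
    be non-negative upstream; negative inputs are rejected here.
    """
    _require_finite("starting_titer", starting_titer)
    _require_finite("saturation_speed", saturation_speed)
    t0 = np.asarray(starting_titer, dtype=float)
    if np.any(t0 < 0):
        raise ValueError("starting_titer must be >= 0 (clamp upstream)")
    out = expit(-saturation_speed * t0)
    return out if out.ndim else float(out)


def booster_gain(
    starting_titer,
    days_since_booster,
    pop: PopulationParameters,
    donor: DonorParameters,
):
    """Log2 titer gain of a single booster: ``2 B * env * sat``.

    The asymptotic (t -> inf) gain at starting titer 0 equals ``B``: with the
    ``4B (logistic - 1/2) sat`` parameterisation the envelope tends to 1 and
    the saturation to 1/2, so the quoted "maximum boostering effect" is ``B``
    itself, not ``2B``.
    """
    env = booster_envelope(days_since_booster, pop.timing_rate)
    sat = booster_saturation(starting_titer, donor.saturation_speed)
    return 2.0 * pop.max_effect * env * sat


def predict_trajectory(
    booster_schedule,
    baseline_titer: float,
    donor: DonorParameters,
    pop: PopulationParameters,
    eval_days,
) -> Trajectory:
    """Predict a donor's titer over time from baseline and booster schedule.

    Starting titers at boosters are computed forward-sequentially: the titer
    at booster *j* is the model's own prediction at that day using only
    boosters 1..j-1, clamped at 0 before entering the saturation term.  Only
    boosters at or before an evaluation day contribute to it (the envelope is
    0 at the booster instant, so the boundary is immaterial).  Final
    predictions are clamped at 0; raw values are kept in ``unclamped``.

    ``booster_schedule`` may be a :class:`DonorRecord` (its ``booster_days``
    are used) or an array of booster days.
    """
    if isinstance(booster_schedule, DonorRecord):
        boosters = np.asarray(booster_schedule.booster_days, dtype=float)
    else:
        boosters = np.asarray(booster_schedule, dtype=float)
    if boosters.ndim != 1:
        raise ValueError("booster schedule must be 1-D")
    if np.any(np.diff(boosters) < 0):
        raise ValueError("booster days must be sorted ascending")
    _require_finite("baseline_titer", baseline_titer)
    eval_days = np.atleast_1d(np.asarray(eval_days, dtype=float))
    if np.any(eval_days < 0):
        raise ValueError("eval_days must be >= 0")

    b, h, ll, dd = pop.max_effect, pop.timing_rate, donor.saturation_speed, donor.decline_rate

    # forward-sequential starting titers (clamped for the saturation input)
    starts = np.empty(len(boosters))
    for j, xj in enumerate(boosters):
        pred = baseline_titer + dd * xj
        for l in range(j):
            pred += 2.0 * b * booster_envelope(xj - boosters[l], h) * booster_saturation(starts[l], ll)
        starts[j] = max(pred, 0.0)

    raw = baseline_titer + dd * eval_days
    for j, xj in enumerate(boosters):
        raw = raw + 2.0 * b * booster_envelope(eval_days - xj, h) * booster_saturation(starts[j], ll)
    return Trajectory(
        eval_days=eval_days,
        titers=np.maximum(raw, 0.0),
        unclamped=raw,
        booster_days=boosters,
        booster_start_titers=starts,
    )


def peak_day(max_effect: float, timing_rate: float, decline_rate: float) -> float:
    """Day of maximum titer after a booster, for ``2B (logistic(Ht)-1/2) + D t``.

    Solves the stationarity condition ``2 B H s (1 - s) = -D`` on the
    ``s > 1/2`` branch of the logistic.  Returns ``inf`` ("no finite peak")
    when the decline rate is non-negative (response is monotone increasing),
    and 0 when the decline dominates from the outset (``-D >= B H / 2``).
    """
    if timing_rate <= 0:
        raise ValueError("timing_rate must be > 0")
    b, h, d = float(max_effect), float(timing_rate), float(decline_rate)
    if d >= 0:
        return math.inf
    c = -d / (2.0 * b * h)
    if c >= 0.25:  # derivative at t=0 already <= 0
        return 0.0
    s = 0.5 * (1.0 + math.sqrt(1.0 - 4.0 * c))
    return math.log(s / (1.0 - s)) / h


def response_peak_day(
    pop: PopulationParameters, donor: DonorParameters, starting_titer: float
) -> float:
    """Day of a donor's peak titer after one booster at ``starting_titer``.

    The post-booster curve ``2B env(t) sat(T0) + D t`` has the canonical
    ``2 B' (logistic(H t) - 1/2) + D t`` shape with effective amplitude
    ``B' = 2 B sat(T0)`` (the asymptotic gain at that starting titer), so
    this simply delegates to :func:`peak_day`.
    """
    amp = 2.0 * pop.max_effect * booster_saturation(starting_titer, donor.saturation_speed)
    return peak_day(amp, pop.timing_rate, donor.decline_rate)


def percent_change(delta_log2):
    """Convert a log2 titer change to percent change of the absolute titer.

    ``100 (2**d - 1)``; sign-preserving, inverse is :func:`log2_change`.
    A decline of 0.55 log2 per year is a 32% annual loss of absolute titer.
    """
    _require_finite("delta_log2", delta_log2)
    d = np.asarray(delta_log2, dtype=float)
    out = 100.0 * (np.exp2(d) - 1.0)
    return out if out.ndim else float(out)


def log2_change(percent):
    """Inverse of :func:`percent_change`: ``log2(1 + p/100)``."""
    _require_finite("percent", percent)
    p = np.asarray(percent, dtype=float)
    if np.any(p <= -100):
        raise ValueError("percent change must be > -100")
    out = np.log2(1.0 + p / 100.0)
    return out if out.ndim else float(out)
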