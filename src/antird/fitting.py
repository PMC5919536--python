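"""Staged estimation of the titer-dynamics model from longitudinal records.

The pipeline mirrors how the model is identified in practice:

1. **Decline** — on donations at least 100 days after any booster (when the
   booster envelope has saturated), fit the random-slope model
   ``C = D_i t + error`` by marginal maximum likelihood, where ``C`` is the
   titer change from the first compliant measurement of each inter-booster
   segment.
2. **Booster timing** — on titer changes up to 200 days after isolated
   boosters, fit ``C = 2B (logistic(H t) - 1/2) + D t`` by nonlinear least
   squares with the Step-1 decline fixed, yielding the envelope rate ``H``
   and the day of peak response.
3. **Booster magnitude** — on peak changes (first measurement 26-50 days
   after boostering) versus the titer at boostering, fit
   ``C = 2B (1 - logistic(L T0)) + t D``, yielding the saturation curve.
4. **Integral model** — fit the full trajectory model to all differences
   from each donor's first measurement by marginal maximum likelihood with
   donor-level random effects (D_i, L_i); the latent starting titers at
   boostering are iterated between fits (measured titers initially, model
   predictions thereafter) until the parameters are stable in the first
   seven digits, with at most 30 loops.

Out-of-sample donors are fitted by MAP estimation of (D_i, L_i) under the
bivariate-normal population prior, with the same starting-titer iteration.

Measurement error enters differences of noisy titers, so two observations
sharing an origin are correlated: the residual covariance of a segment's
differences is ``sigma_eps^2 (I + J)`` (J the all-ones matrix), not
``sigma_eps^2 I``.  All marginal likelihoods here account for this.  Because
titers are read on an integer log2 dilution grid, the reported residual SD
applies Sheppard's correction (subtracting grid^2/12 from the fitted
variance); the uncorrected value is reported alongside.

Difference observations are held in pandas DataFrames with columns
``donor_id, segment, origin_day, origin_titer, t, dc`` (and
``booster_day`` / ``start`` where applicable): one row per titer change,
``t`` in days since the local origin, ``dc`` in log2 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize, minimize_scalar
from scipy.special import expit

from .model import (
    DAYS_PER_YEAR,
    DonorParameters,
    DonorRecord,
    PopulationParameters,
    booster_envelope,
    peak_day,
    predict_trajectory,
)

__all__ = [
    "StageFitResult",
    "PipelineResult",
    "MapFitResult",
    "SplitValidationReport",
    "filter_unboostered",
    "extract_post_booster",
    "extract_peak_changes",
    "fit_decline",
    "decline_loglik",
    "pooled_decline_slope",
    "fit_timing",
    "fit_magnitude",
    "fit_integral",
    "per_donor_residuals",
    "map_fit_donor",
    "split_validate",
    "run_pipeline",
]

_SD_FLOOR = 1e-6


@dataclass
class StageFitResult:
    """Estimates and diagnostics of one fitting stage."""

    stage: str
    params: dict
    per_donor: pd.DataFrame | None = None
    loglik: float | None = None
    iterations: int = 0
    converged: bool = False
    extras: dict = field(default_factory=dict)

    def population(self) -> PopulationParameters:
        """Assemble a :class:`PopulationParameters` from the fitted values.

        Missing components (e.g. the envelope rate in a magnitude-only fit)
        must be present in ``params``; stages that do not estimate them copy
        them from their inputs.
        """
        p = self.params
        return PopulationParameters(
            max_effect=p["max_effect"],
            timing_rate=p["timing_rate"],
            mean_decline=p["mean_decline"],
            sd_decline=p["sd_decline"],
            mean_saturation=p["mean_saturation"],
            sd_saturation=p["sd_saturation"],
            residual_sd=p["residual_sd_effective"],
            cov_decline_saturation=p.get("cov_decline_saturation", 0.0),
        )


def _require_days(records: Sequence) -> None:
    for rec in records:
        if getattr(rec, "obs_days", None) is None:
            raise ValueError(
                f"record {getattr(rec, 'donor_id', '?')} carries no day information "
                "(anonymised dialect); day-resolved records are required for fitting — "
                "missing column: day"
            )


# ---------------------------------------------------------------------------
# observation extraction


def filter_unboostered(
    records: Sequence[DonorRecord], min_days_since_booster: float = 100.0
) -> pd.DataFrame:
    """Titer changes unaffected by boostering.

    Keeps only donations at least ``min_days_since_booster`` days after the
    donor's most recent *earlier* booster.  A donation on a booster day is
    measured before that booster is administered (the envelope is zero at
    the booster instant), so it closes the preceding segment; keeping it is
    also what makes a titer-triggered boostering policy ignorable for the
    likelihood — the observation that fired the trigger stays in the data.
    Follow-up restarts after every booster: within each inter-booster
    segment the first compliant donation is the origin and the titer changes
    of the later compliant donations are taken against it.
    """
    _require_days(records)
    rows = []
    for rec in records:
        seg = np.searchsorted(rec.booster_days, rec.obs_days, side="left")
        if rec.n_boosters:
            last = np.where(seg > 0, rec.booster_days[np.maximum(seg - 1, 0)], -np.inf)
        else:
            last = np.full(len(rec.obs_days), -np.inf)
        eligible = (seg == 0) | (rec.obs_days - last >= min_days_since_booster)
        for s in np.unique(seg):
            mask = eligible & (seg == s)
            days = rec.obs_days[mask]
            titers = rec.measured_titers[mask]
            if len(days) < 2:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "donor_id": rec.donor_id,
                        "segment": int(s),
                        "origin_day": days[0],
                        "origin_titer": titers[0],
                        "t": days[1:] - days[0],
                        "dc": titers[1:] - titers[0],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["donor_id", "segment", "origin_day", "origin_titer", "t", "dc"]
        )
    return pd.concat(rows, ignore_index=True)


def extract_post_booster(
    records: Sequence[DonorRecord],
    horizon: float = 200.0,
    prior_booster_exclusion: float = 100.0,
) -> pd.DataFrame:
    """Titer changes following isolated boosters, for the timing fit.

    For every booster at least ``prior_booster_exclusion`` days after the
    previous one (or with no previous booster), the origin is the measured
    titer at the booster day and observations run up to ``horizon`` days
    after it, truncated strictly before the next booster event.
    """
    _require_days(records)
    rows = []
    for rec in records:
        x = rec.booster_days
        for j, xj in enumerate(x):
            if j > 0 and xj - x[j - 1] < prior_booster_exclusion:
                continue
            nxt = x[j + 1] if j + 1 < len(x) else np.inf
            mask = (rec.obs_days > xj) & (rec.obs_days <= xj + horizon) & (rec.obs_days < nxt)
            if not mask.any():
                continue
            origin = rec.titer_at(xj)
            rows.append(
                pd.DataFrame(
                    {
                        "donor_id": rec.donor_id,
                        "booster_day": xj,
                        "origin_titer": origin,
                        "t": rec.obs_days[mask] - xj,
                        "dc": rec.measured_titers[mask] - origin,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["donor_id", "booster_day", "origin_titer", "t", "dc"])
    return pd.concat(rows, ignore_index=True)


def extract_peak_changes(
    records: Sequence[DonorRecord],
    window: tuple[float, float] = (26.0, 50.0),
    pre_exclusion: float = 50.0,
) -> pd.DataFrame:
    """(starting titer, peak change) pairs for the magnitude fit.

    The peak change of a booster is the first measurement ``window[0]`` to
    ``window[1]`` days (inclusive) after it, minus the titer at boostering.
    Boosters less than ``pre_exclusion`` days after a previous booster are
    excluded; *subsequent* boosters are deliberately not excluded (dropping
    them would thin out the low-starting-titer region, where new donors are
    boostered repeatedly), so the extracted gain is an upper estimate of a
    single booster's effect.
    """
    _require_days(records)
    rows = []
    for rec in records:
        x = rec.booster_days
        for j, xj in enumerate(x):
            if j > 0 and xj - x[j - 1] < pre_exclusion:
                continue
            mask = (rec.obs_days >= xj + window[0]) & (rec.obs_days <= xj + window[1])
            if not mask.any():
                continue
            day = rec.obs_days[mask][0]
            start = rec.titer_at(xj)
            rows.append(
                {
                    "donor_id": rec.donor_id,
                    "booster_day": xj,
                    "start": start,
                    "t": day - xj,
                    "dc": rec.measured_titers[np.flatnonzero(mask)[0]] - start,
                }
            )
    return pd.DataFrame(rows, columns=["donor_id", "booster_day", "start", "t", "dc"])


# ---------------------------------------------------------------------------
# Step 1: random-slope decline fit


class _DeclineData:
    """Per-donor sufficient statistics for the random-slope likelihood."""

    def __init__(self, donor_df: pd.DataFrame):
        self.t = donor_df["t"].to_numpy(float)
        self.c = donor_df["dc"].to_numpy(float)
        self.n = len(self.t)
        segs = donor_df["segment"].to_numpy()
        self.seg_sizes = []
        self.seg_slices = []
        start = 0
        for s in pd.unique(segs):
            size = int((segs == s).sum())
            self.seg_slices.append(slice(start, start + size))
            self.seg_sizes.append(size)
            start += size
        self.tt = float(self.t @ self.t)
        self.tc = float(self.t @ self.c)
        self.cc = float(self.c @ self.c)
        self.ut = np.array([self.t[sl].sum() for sl in self.seg_slices])
        self.uc = np.array([self.c[sl].sum() for sl in self.seg_slices])
        self.ns = np.array(self.seg_sizes, dtype=float)

    def nll(self, mu: float, sd2: float, se2: float, shared_origin: bool) -> float:
        r_t = self.tc - mu * self.tt  # t' r
        rr = self.cc - 2 * mu * self.tc + mu * mu * self.tt
        if shared_origin:
            k = len(self.ns) + 1
            # U = [segment indicators, t];  Sigma = se2 I + U S U', S = diag(se2.., sd2)
            g = np.empty((k, k))
            g[:-1, :-1] = np.diag(self.ns)
            g[:-1, -1] = self.ut
            g[-1, :-1] = self.ut
            g[-1, -1] = self.tt
            m = g / se2
            m[np.arange(k - 1), np.arange(k - 1)] += 1.0 / se2
            m[-1, -1] += 1.0 / sd2
            v = np.append(self.uc - mu * self.ut, r_t)
            sol = np.linalg.solve(m, v)
            quad = rr / se2 - v @ sol / se2**2
            sign, logdet_m = np.linalg.slogdet(m)
            logdet = self.n * np.log(se2) + (k - 1) * np.log(se2) + np.log(sd2) + logdet_m
        else:
            m = 1.0 / sd2 + self.tt / se2
            quad = rr / se2 - r_t**2 / m / se2**2
            logdet = self.n * np.log(se2) + np.log(sd2) + np.log(m)
        return 0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)

    def eb_mode(self, mu: float, sd2: float, se2: float, shared_origin: bool) -> float:
        if shared_origin:
            w = 1.0 / (1.0 + self.ns)
            t_si_t = (self.tt - np.sum(w * self.ut**2)) / se2
            t_si_c = (self.tc - np.sum(w * self.ut * self.uc)) / se2
        else:
            t_si_t = self.tt / se2
            t_si_c = self.tc / se2
        return (t_si_c + mu / sd2) / (t_si_t + 1.0 / sd2)


def _sheppard(sd_eff: float, grid: float | None) -> float:
    if not grid:
        return sd_eff
    return float(np.sqrt(max(sd_eff**2 - grid**2 / 12.0, _SD_FLOOR**2)))


def decline_loglik(
    diffs: pd.DataFrame,
    mean_decline: float,
    sd_decline: float,
    residual_sd: float,
    shared_origin: bool = True,
) -> float:
    """Marginal log-likelihood of the random-slope decline model.

    Rates are per day; ``residual_sd`` is the effective per-measurement SD.
    """
    donors = [_DeclineData(g) for _, g in diffs.groupby("donor_id", sort=True)]
    return -sum(
        d.nll(mean_decline, sd_decline**2, residual_sd**2, shared_origin) for d in donors
    )


def pooled_decline_slope(diffs: pd.DataFrame) -> float:
    """Naive pooled through-origin OLS slope (per day), ignoring donors.

    Donors who decline slowly stay unboostered longer and contribute more
    (and higher) late observations, so this pooled estimate is biased
    towards 0 relative to the random-effects estimate.
    """
    t = diffs["t"].to_numpy(float)
    c = diffs["dc"].to_numpy(float)
    return float(t @ c / (t @ t))


def fit_decline(
    diffs: pd.DataFrame,
    shared_origin: bool = True,
    measurement_grid: float | None = 1.0,
    x0: tuple[float, float, float] | None = None,
) -> StageFitResult:
    """Step-1 marginal ML fit of the random-slope decline model.

    Returns the population decline (mean and SD, per day and per year), the
    residual SD (effective, and Sheppard-corrected for the integer titer
    grid), and the empirical-Bayes posterior-mode decline rate per donor.
    ``shared_origin`` keeps the correlation that differences sharing an
    origin measurement have through the origin's error; with ``False`` the
    residuals are treated as independent (the classic random-slope model).
    """
    if diffs.empty:
        raise ValueError("no difference observations supplied")
    groups = {k: _DeclineData(g) for k, g in diffs.groupby("donor_id", sort=True)}
    donors = list(groups.values())
    if len(donors) < 2 or sum(d.n >= 2 for d in donors) < 2:
        warnings.warn("fewer than 2 donors with 2+ observations; estimates may be degenerate")
    if all(len(np.unique(d.t)) < 2 for d in donors) and len(donors) < 2:
        raise ValueError("degenerate design: a single time point cannot identify a slope")

    slope0 = pooled_decline_slope(diffs)
    resid0 = diffs["dc"].to_numpy(float) - slope0 * diffs["t"].to_numpy(float)
    se0 = max(float(np.std(resid0)), 0.05)
    if x0 is None:
        x0 = (slope0 * DAYS_PER_YEAR, 0.4, se0)

    def nll(theta):
        mu = theta[0] / DAYS_PER_YEAR
        sd2 = (np.exp(theta[1]) / DAYS_PER_YEAR) ** 2
        se2 = np.exp(theta[2]) ** 2
        return sum(d.nll(mu, sd2, se2, shared_origin) for d in donors)

    res = minimize(
        nll,
        x0=[x0[0], np.log(max(x0[1], 1e-4)), np.log(max(x0[2], 1e-4))],
        method="L-BFGS-B",
        bounds=[(None, None), (np.log(1e-4), np.log(10.0)), (np.log(1e-4), np.log(10.0))],
    )
    mu_yr, sd_yr, se = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    mu, sd = mu_yr / DAYS_PER_YEAR, sd_yr / DAYS_PER_YEAR

    eb = {
        k: d.eb_mode(mu, sd**2, se**2, shared_origin) for k, d in groups.items()
    }
    per_donor = pd.DataFrame(
        {
            "donor_id": list(eb),
            "decline_rate": list(eb.values()),
            "annual_decline": [v * DAYS_PER_YEAR for v in eb.values()],
            "n_obs": [groups[k].n for k in eb],
        }
    )
    return StageFitResult(
        stage="decline",
        params={
            "mean_decline": mu,
            "annual_mean_decline": mu_yr,
            "sd_decline": sd,
            "annual_sd_decline": sd_yr,
            "residual_sd": _sheppard(se, measurement_grid),
            "residual_sd_effective": se,
        },
        per_donor=per_donor,
        loglik=-float(res.fun),
        iterations=int(res.nit),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Steps 2A / 2B: nonlinear least squares


def _nls_stderr(sol) -> np.ndarray:
    """Asymptotic standard errors from a least_squares solution.

    Directions in which the Jacobian is numerically rank-deficient carry no
    information, so their standard error is infinite (not zero).
    """
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    informative = s > 1e-10 * s[0]
    inv_s2 = 1.0 / np.where(informative, s, 1.0) ** 2
    var = (vt[informative].T ** 2) @ inv_s2[informative]
    uninformative_load = (np.abs(vt[~informative]) > 1e-12).any(axis=0)
    var = np.where(uninformative_load, np.inf, var)
    dof = max(len(sol.fun) - len(sol.x), 1)
    sigma2 = 2.0 * sol.cost / dof
    return np.sqrt(sigma2 * var)


def fit_timing(
    post_diffs: pd.DataFrame,
    decline_rate: float,
    x0: tuple[float, float] | None = None,
) -> StageFitResult:
    """Step-2A NLS fit of the booster time envelope.

    Model: ``dc = 2B (logistic(H t) - 1/2) + D t`` with the population
    decline ``D`` (per day) fixed from Step 1.  Reports the day of the peak
    titer after boostering implied by (B, H, D).  The squared-error surface
    in H can have several local minima (a near-step envelope also fits data
    whose earliest lags are two weeks out), so by default the fit is
    multi-started over a spread of envelope rates and the lowest-SSE
    solution is kept; pass ``x0`` to use a single start.
    """
    if post_diffs.empty:
        raise ValueError("no post-booster observations supplied")
    t = post_diffs["t"].to_numpy(float)
    c = post_diffs["dc"].to_numpy(float)
    if len(np.unique(t)) < 3:
        raise ValueError("observations must span at least 3 distinct lags")

    def resid(p):
        b, h = p
        return 2.0 * b * (expit(h * t) - 0.5) + decline_rate * t - c

    starts = [x0] if x0 is not None else [(2.0, h0) for h0 in (0.03, 0.07, 0.15, 0.3, 1.0)]
    sol = None
    for s0 in starts:
        cand = least_squares(resid, x0=s0, bounds=([1e-6, 1e-4], [50.0, 5.0]))
        if sol is None or cand.cost < sol.cost - 1e-12:
            sol = cand
    b, h = sol.x
    se_b, se_h = _nls_stderr(sol)
    return StageFitResult(
        stage="timing",
        params={
            "max_effect": float(b),
            "timing_rate": float(h),
            "peak_day": peak_day(b, h, decline_rate),
            "decline_rate": decline_rate,
            "sse": float(2.0 * sol.cost),
            "stderr_max_effect": float(se_b),
            "stderr_timing_rate": float(se_h),
        },
        loglik=None,
        iterations=int(sol.nfev),
        converged=bool(sol.success),
        extras={"last_iterate": sol.x},
    )


def fit_magnitude(
    peak_changes: pd.DataFrame,
    decline_rate: float,
    x0: tuple[float, float] = (5.0, 0.3),
) -> StageFitResult:
    """Step-2B NLS fit of booster-gain saturation with the starting titer.

    Model: ``dc = 2B (1 - logistic(L T0)) + t D`` with ``D`` fixed and ``t``
    the actual lag of each peak measurement (26-50 days).
    """
    if peak_changes.empty:
        raise ValueError("no peak-change observations supplied")
    t0 = peak_changes["start"].to_numpy(float)
    t = peak_changes["t"].to_numpy(float)
    c = peak_changes["dc"].to_numpy(float)

    def resid(p):
        b, l = p
        return 2.0 * b * expit(-l * t0) + decline_rate * t - c

    sol = least_squares(resid, x0=x0, bounds=([1e-6, 1e-4], [50.0, 5.0]))
    b, l = sol.x
    se_b, se_l = _nls_stderr(sol)
    return StageFitResult(
        stage="magnitude",
        params={
            "max_effect": float(b),
            "mean_saturation": float(l),
            "decline_rate": decline_rate,
            "sse": float(2.0 * sol.cost),
            "stderr_max_effect": float(se_b),
            "stderr_saturation": float(se_l),
        },
        loglik=None,
        iterations=int(sol.nfev),
        converged=bool(sol.success),
        extras={"last_iterate": sol.x},
    )


# ---------------------------------------------------------------------------
# Step 3: integral nonlinear mixed-effects fit


class _IntegralDonor:
    """Precomputed per-donor arrays for the integral-model likelihood.

    Differences are taken from the donor's first measurement (single origin),
    so the residual covariance is ``se2 (I + J)``; the envelope matrix
    ``E[k, j] = env(t_k - x_j; H)`` is fixed because H is not refitted.

    The random saturation speed is integrated by *adaptive* Gauss-Hermite
    quadrature: the nodes are centred and scaled per donor at the posterior
    mode and curvature of L (refreshed once per outer loop, when the latent
    starting titers are also refreshed), which keeps the rule accurate even
    when a donor's likelihood is much sharper than the population prior.
    With the rule frozen within a loop, the envelope-times-saturation matrix
    at the nodes is a constant and is cached.
    """

    def __init__(self, rec: DonorRecord, timing_rate: float):
        self.donor_id = rec.donor_id
        day0 = rec.obs_days[0]
        self.t = rec.obs_days[1:] - day0
        self.c = rec.measured_titers[1:] - rec.measured_titers[0]
        self.n = len(self.t)
        self.x = rec.booster_days - day0
        self.m = len(self.x)
        self.first_titer = float(rec.measured_titers[0])
        if self.m and self.n:
            self.E = booster_envelope(self.t[:, None] - self.x[None, :], timing_rate)
        else:
            self.E = np.zeros((self.n, self.m))
        self.s = np.array([max(rec.titer_at(xj + day0), 0.0) for xj in rec.booster_days])
        # envelope between boosters, for the forward starting-titer recursion
        if self.m:
            self.Exx = booster_envelope(self.x[:, None] - self.x[None, :], timing_rate)
        else:
            self.Exx = np.zeros((0, 0))
        self.tt = float(self.t @ self.t) if self.n else 0.0
        self.tsum = float(self.t.sum()) if self.n else 0.0
        self.node_center: float | None = None
        self.node_scale: float | None = None
        self.l_nodes: np.ndarray | None = None
        self._es: np.ndarray | None = None  # E @ sat(s, L_k), cached per rule

    # -- quadrature rule ---------------------------------------------------

    def set_rule(self, center: float, scale: float, z: np.ndarray) -> None:
        self.node_center = float(center)
        self.node_scale = float(scale)
        self.l_nodes = center + np.sqrt(2.0) * scale * z
        self.refresh_cache()

    def refresh_cache(self) -> None:
        if self.l_nodes is None:
            return
        if self.m and self.n:
            self._es = self.E @ expit(-np.outer(self.s, self.l_nodes))
        else:
            self._es = np.zeros((self.n, len(self.l_nodes)))

    # -- likelihood pieces -------------------------------------------------

    def _gauss_logpdf(self, mean: np.ndarray, sd_d: float, se2: float) -> np.ndarray:
        """log N(C; mean_k, sd_d^2 t t' + se2 (I + J)) for node means (n, K)."""
        n = self.n
        r = self.c[:, None] - mean
        v0 = r.sum(axis=0)
        v1 = self.t @ r
        sd2 = max(sd_d, _SD_FLOOR) ** 2
        # Woodbury with U = [1, t], S = diag(se2, sd2)
        a = (1.0 + n) / se2
        bb = self.tsum / se2
        d = 1.0 / sd2 + self.tt / se2
        det = a * d - bb * bb
        quad_v = (d * v0 * v0 - 2.0 * bb * v0 * v1 + a * v1 * v1) / det
        rr = np.einsum("ij,ij->j", r, r)
        quad = rr / se2 - quad_v / se2**2
        logdet = n * np.log(se2) + np.log(se2 * sd2) + np.log(det)
        return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    def integrand_logpdf(
        self,
        l: float,
        b: float,
        mu_d: float,
        sd_d: float,
        mu_l: float,
        sd_l: float,
        rho: float,
        se2: float,
    ) -> float:
        """log of the L-integrand at a single point (for rule adaptation)."""
        mu_d_l = mu_d + (rho * sd_d / sd_l) * (l - mu_l)
        sd_d_cond = sd_d * np.sqrt(max(1.0 - rho**2, 1e-12))
        if self.m and self.n:
            g = 2.0 * b * (self.E @ expit(-self.s * l))
        else:
            g = np.zeros(self.n)
        mean = (mu_d_l * self.t + g)[:, None]
        log_gauss = float(self._gauss_logpdf(mean, sd_d_cond, se2)[0])
        log_prior = -0.5 * np.log(2 * np.pi * sd_l**2) - 0.5 * ((l - mu_l) / sd_l) ** 2
        return log_gauss + log_prior

    def eb_mode(
        self,
        b: float,
        mu_d: float,
        sd_d: float,
        mu_l: float,
        sd_l: float,
        rho: float,
        se2: float,
        warm: float | None = None,
    ) -> tuple[float, float]:
        """Joint posterior mode of (D_i, L_i); D profiled in closed form.

        The 1-D profile over L is solved by a safeguarded Newton iteration
        from ``warm`` when supplied (the optimum moves very little between
        outer loops), falling back to bounded scalar minimisation.
        """
        n = self.n
        if n == 0:
            return mu_d, mu_l
        w = 1.0 / (n + 1.0)
        t_si_t = (self.tt - w * self.tsum**2) / se2
        tau2 = max(sd_d * np.sqrt(max(1.0 - rho**2, 1e-12)), _SD_FLOOR) ** 2

        def neg_log_post(l):
            if self.m:
                g = 2.0 * b * (self.E @ expit(-self.s * l))
            else:
                g = 0.0
            r0 = self.c - g
            mu_d_l = mu_d + (rho * sd_d / sd_l) * (l - mu_l)
            t_si_r = (self.t @ r0 - w * self.tsum * r0.sum()) / se2
            d_hat = (t_si_r + mu_d_l / tau2) / (t_si_t + 1.0 / tau2)
            r = r0 - d_hat * self.t
            quad = (r @ r - w * r.sum() ** 2) / se2
            return (
                0.5 * quad
                + 0.5 * (d_hat - mu_d_l) ** 2 / tau2
                + 0.5 * (l - mu_l) ** 2 / sd_l**2
            )

        def _newton(l0: float) -> float | None:
            h = 1e-6
            l = l0
            for _ in range(12):
                f0, fp, fm = neg_log_post(l), neg_log_post(l + h), neg_log_post(l - h)
                grad = (fp - fm) / (2.0 * h)
                curv = (fp - 2.0 * f0 + fm) / h**2
                if curv <= 0:
                    return None
                step = np.clip(-grad / curv, -0.5 * sd_l, 0.5 * sd_l)
                l += step
                if abs(step) < 1e-11:
                    return float(l)
            return None

        if self.m:
            l_hat = _newton(warm) if warm is not None else None
            if l_hat is None:
                sol = minimize_scalar(
                    neg_log_post,
                    bounds=(mu_l - 8.0 * sd_l, mu_l + 8.0 * sd_l),
                    method="bounded",
                    options={"xatol": 1e-11},
                )
                l_hat = float(sol.x)
        else:
            l_hat = mu_l  # no boosters: the likelihood carries no information on L
        if self.m:
            g = 2.0 * b * (self.E @ expit(-self.s * l_hat))
        else:
            g = 0.0
        r0 = self.c - g
        mu_d_l = mu_d + (rho * sd_d / sd_l) * (l_hat - mu_l)
        t_si_r = (self.t @ r0 - w * self.tsum * r0.sum()) / se2
        d_hat = (t_si_r + mu_d_l / tau2) / (t_si_t + 1.0 / tau2)
        return float(d_hat), l_hat


class _BatchedLikelihood:
    """Padded, donor-batched evaluation of the Step-3 marginal likelihood.

    The per-donor Woodbury algebra (rank-2 covariance over the white
    ``se2 I`` base) vectorises over donors and quadrature nodes once the
    observation vectors are zero-padded to a common length; padded entries
    are masked out of every residual reduction, so they contribute nothing.
    """

    def __init__(self, active: list[_IntegralDonor], n_quad: int):
        self.donors = active
        n = len(active)
        nmax = max(d.n for d in active)
        self.T = np.zeros((n, nmax))
        self.C = np.zeros((n, nmax))
        self.mask = np.zeros((n, nmax))
        for i, d in enumerate(active):
            self.T[i, : d.n] = d.t
            self.C[i, : d.n] = d.c
            self.mask[i, : d.n] = 1.0
        self.n_arr = np.array([d.n for d in active], dtype=float)
        self.tsum = np.array([d.tsum for d in active])
        self.tt = np.array([d.tt for d in active])
        self.L = np.zeros((n, n_quad))
        self.log_scale = np.zeros(n)
        self.ES = np.zeros((n, nmax, n_quad))

    def refresh_rules(self) -> None:
        for i, d in enumerate(self.donors):
            self.L[i] = d.l_nodes
            self.log_scale[i] = np.log(np.sqrt(2.0) * d.node_scale)
            self.ES[i, : d.n, :] = d._es

    def nll(
        self,
        b: float,
        mu_d: float,
        sd_d: float,
        mu_l: float,
        sd_l: float,
        rho: float,
        se2: float,
        z: np.ndarray,
        log_w: np.ndarray,
    ) -> float:
        mu_d_nodes = mu_d + (rho * sd_d / sd_l) * (self.L - mu_l)  # (N, K)
        sd_d_cond = sd_d * np.sqrt(max(1.0 - rho**2, 1e-12))
        sd2 = max(sd_d_cond, _SD_FLOOR) ** 2
        mean = self.T[:, :, None] * mu_d_nodes[:, None, :] + (2.0 * b) * self.ES
        r = (self.C[:, :, None] - mean) * self.mask[:, :, None]
        v0 = r.sum(axis=1)  # (N, K)
        v1 = np.einsum("nt,ntk->nk", self.T, r)
        rr = np.einsum("ntk,ntk->nk", r, r)
        a = (1.0 + self.n_arr) / se2
        bb = self.tsum / se2
        dd = 1.0 / sd2 + self.tt / se2
        det = a * dd - bb * bb
        quad_v = (
            dd[:, None] * v0 * v0 - 2.0 * bb[:, None] * v0 * v1 + a[:, None] * v1 * v1
        ) / det[:, None]
        quad = rr / se2 - quad_v / se2**2
        logdet = self.n_arr * np.log(se2) + np.log(se2 * sd2) + np.log(det)
        log_gauss = -0.5 * (
            self.n_arr[:, None] * np.log(2 * np.pi) + logdet[:, None] + quad
        )
        log_prior = -0.5 * np.log(2 * np.pi * sd_l**2) - 0.5 * ((self.L - mu_l) / sd_l) ** 2
        lse = log_w[None, :] + (z * z)[None, :] + log_gauss + log_prior
        top = lse.max(axis=1)
        ll = top + np.log(np.exp(lse - top[:, None]).sum(axis=1)) + self.log_scale
        return -float(ll.sum())


_INTEGRAL_PARAM_NAMES = (
    "max_effect",
    "annual_mean_decline",
    "annual_sd_decline",
    "mean_saturation",
    "sd_saturation",
    "residual_sd_effective",
)


def _update_start_titers(
    donors: list[_IntegralDonor],
    eb: dict[str, tuple[float, float]],
    b: float,
    damping: float = 1.0,
) -> float:
    """Replace latent starting titers by the model's own predictions.

    Uses each donor's empirical-Bayes (D_i, L_i) and the forward-sequential
    recursion (each booster sees only earlier boosters; starting titers
    below 0 are clamped to 0).  The anchoring first measurement carries its
    own measurement error, which every difference of the donor shares; its
    empirical-Bayes estimate (minus the mean residual, shrunk by n+1) is
    subtracted from the anchor before predicting, so the latent starting
    titers are not attenuated by the anchor's noise.  Returns the largest
    absolute change of any starting titer, for convergence monitoring.
    """
    max_change = 0.0
    for dd in donors:
        if dd.m == 0:
            continue
        d_i, l_i = eb[dd.donor_id]
        if dd.n:
            g = 2.0 * b * (dd.E @ expit(-dd.s * l_i))
            resid = dd.c - d_i * dd.t - g
            eps0_hat = -resid.sum() / (dd.n + 1.0)
        else:
            eps0_hat = 0.0
        baseline = dd.first_titer - eps0_hat
        s_new = np.empty(dd.m)
        for j in range(dd.m):
            val = baseline + d_i * dd.x[j]
            if j:
                val += 2.0 * b * (dd.Exx[j, :j] @ expit(-l_i * s_new[:j]))
            s_new[j] = max(val, 0.0)
        if 0.0 < damping < 1.0:
            s_new = np.maximum((1.0 - damping) * dd.s + damping * s_new, 0.0)
        max_change = max(max_change, float(np.max(np.abs(s_new - dd.s))))
        dd.s = s_new
    return max_change


def fit_integral(
    records: Sequence[DonorRecord],
    timing_rate: float,
    start: dict | None = None,
    n_quad: int = 16,
    max_outer: int = 30,
    outer_tol: float = 1e-7,
    estimate_correlation: bool = False,
    fix: dict | None = None,
    measurement_grid: float | None = 1.0,
    latent_prior_scale: float = 1.0,
    damping: float = 0.5,
    initial_start_titers: dict | None = None,
) -> StageFitResult:
    """Step-3 marginal ML fit of the full trajectory model.

    The marginal likelihood integrates the donor random effects: the decline
    ``D_i`` exactly (the model is linear in it) and the saturation ``L_i`` by
    adaptive Gauss-Hermite quadrature with ``n_quad`` nodes centred and
    scaled per donor at the posterior of L.  The envelope rate ``H`` is
    fixed (its likelihood surface is flat in this model and it is supplied
    from the timing fit).  The latent starting titers at boostering are the
    measured titers initially and the model's own predictions in subsequent
    outer loops (override the initial values with ``initial_start_titers``,
    a donor_id -> array mapping); each update is under-relaxed by
    ``damping`` — the undamped map can 2-cycle — and looping stops when
    every population parameter's relative change is below ``outer_tol``
    (agreement in the first seven digits by default) or after ``max_outer``
    loops, in which case ``converged`` is False.

    ``fix`` maps parameter names (as in the result's ``params``) to frozen
    values; ``estimate_correlation`` adds the (D, L) random-effects
    correlation as a free parameter (by default it is fixed at 0);
    ``latent_prior_scale`` widens the prior used for the per-donor
    empirical-Bayes estimates that drive the starting-titer update (1.0 =
    the fitted population prior).
    """
    _require_days(records)
    if timing_rate <= 0:
        raise ValueError("timing_rate must be > 0")
    donors = [_IntegralDonor(r, timing_rate) for r in records]
    if initial_start_titers:
        for d in donors:
            if d.donor_id in initial_start_titers:
                d.s = np.asarray(initial_start_titers[d.donor_id], dtype=float)
    active = [d for d in donors if d.n >= 1]
    if not active:
        raise ValueError("no donor has two or more measurements")

    defaults = {
        "max_effect": 5.0,
        "annual_mean_decline": -0.5,
        "annual_sd_decline": 0.4,
        "mean_saturation": 0.3,
        "sd_saturation": 0.08,
        "residual_sd_effective": 0.7,
        "rho": 0.0,
    }
    if start:
        defaults.update({k: v for k, v in start.items() if v is not None})
    fix = dict(fix or {})
    if not estimate_correlation and "rho" not in fix:
        fix["rho"] = defaults["rho"]

    names = [n for n in (*_INTEGRAL_PARAM_NAMES, "rho") if n not in fix]
    log_scale = {"max_effect", "annual_sd_decline", "sd_saturation", "residual_sd_effective"}
    _bounds = {
        "max_effect": (np.log(1e-3), np.log(100.0)),
        "annual_mean_decline": (-20.0, 20.0),
        "annual_sd_decline": (np.log(1e-5), np.log(20.0)),
        "mean_saturation": (-2.0, 10.0),
        "sd_saturation": (np.log(1e-5), np.log(10.0)),
        "residual_sd_effective": (np.log(1e-5), np.log(20.0)),
        "rho": (-0.99, 0.99),
    }
    bounds = [_bounds[n] for n in names]

    def pack(values: dict) -> np.ndarray:
        out = []
        for n in names:
            v = values[n]
            out.append(np.log(max(v, _SD_FLOOR)) if n in log_scale else v)
        return np.array(out)

    def unpack(x: np.ndarray) -> dict:
        values = dict(fix)
        for n, v in zip(names, x):
            values[n] = float(np.exp(v)) if n in log_scale else float(v)
        return values

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(w)
    batch = _BatchedLikelihood(active, n_quad)

    def nll(x: np.ndarray) -> float:
        p = unpack(x)
        return batch.nll(
            p["max_effect"],
            p["annual_mean_decline"] / DAYS_PER_YEAR,
            max(p["annual_sd_decline"], _SD_FLOOR) / DAYS_PER_YEAR,
            p["mean_saturation"],
            max(p["sd_saturation"], _SD_FLOOR),
            p["rho"],
            max(p["residual_sd_effective"], _SD_FLOOR) ** 2,
            z,
            log_w,
        )

    def _update_rules(p: dict, eb: dict) -> None:
        """Re-centre/re-scale each donor's quadrature at its L posterior.

        The scale comes from the curvature of the log integrand at the mode
        (a Laplace approximation of the posterior SD), clipped to a sane
        multiple of the population SD; donors whose likelihood carries no
        information on L (no boosters) fall back to the prior rule.
        """
        b = p["max_effect"]
        mu_d = p["annual_mean_decline"] / DAYS_PER_YEAR
        sd_d = max(p["annual_sd_decline"], _SD_FLOOR) / DAYS_PER_YEAR
        mu_l, sd_l = p["mean_saturation"], max(p["sd_saturation"], _SD_FLOOR)
        se2 = max(p["residual_sd_effective"], _SD_FLOOR) ** 2
        rho = p["rho"]
        delta = 0.5 * sd_l
        for d in donors:
            if d.m == 0 or d.n == 0:
                d.set_rule(mu_l, sd_l, z)
                continue
            center = eb[d.donor_id][1]
            phi = [
                d.integrand_logpdf(center + k * delta, b, mu_d, sd_d, mu_l, sd_l, rho, se2)
                for k in (-1, 0, 1)
            ]
            curv = (phi[0] - 2.0 * phi[1] + phi[2]) / delta**2
            scale = np.sqrt(-1.0 / curv) if curv < 0 else sd_l
            d.set_rule(center, float(np.clip(scale, 0.1 * sd_l, 3.0 * sd_l)), z)
        batch.refresh_rules()

    def _eb_args(p: dict, prior_scale: float = 1.0) -> tuple:
        return (
            p["max_effect"],
            p["annual_mean_decline"] / DAYS_PER_YEAR,
            p["annual_sd_decline"] / DAYS_PER_YEAR * prior_scale,
            p["mean_saturation"],
            p["sd_saturation"] * prior_scale,
            p["rho"],
            p["residual_sd_effective"] ** 2,
        )

    def _eb_all(p: dict, prior_scale: float = 1.0) -> dict:
        args = _eb_args(p, prior_scale)
        out = {}
        for d in donors:
            pair = d.eb_mode(*args, warm=getattr(d, "_l_warm", None))
            d._l_warm = pair[1]
            out[d.donor_id] = pair
        return out

    theta = {k: defaults[k] for k in (*_INTEGRAL_PARAM_NAMES, "rho")}
    theta.update(fix)
    x = pack(theta)
    _update_rules(theta, _eb_all(theta, latent_prior_scale))
    trace: list[dict] = []
    rel_changes: list[float] = []
    converged = False
    best_fun = np.inf
    x_last: np.ndarray | None = None
    dx_last: np.ndarray | None = None
    last_ext = -10
    aitken_log: list[float] = []
    damp = damping
    for outer in range(1, max_outer + 1):
        # re-optimise against the current starting titers; keep the previous
        # iterate unless the (deterministic) objective genuinely improves, so
        # the outer loop can reach an exact fixed point instead of random-
        # walking at the optimiser's termination noise.  Cheap forward-
        # difference gradients suffice while the loop still moves a lot;
        # central differences take over for the final digits.
        f_here = nll(x)
        jac = "2-point" if not rel_changes or rel_changes[-1] > 1e-3 else "3-point"
        res = minimize(
            nll,
            x,
            method="L-BFGS-B",
            jac=jac,
            bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-8, "maxfun": 20000},
        )
        if res.fun < f_here - 1e-6:
            x = res.x
            best_fun = float(res.fun)
        else:
            # at the termination noise floor of the optimiser: keep the
            # previous iterate so the loop can register exact stability
            best_fun = min(f_here, float(res.fun))
        # the inner sweeps slave the starting titers to the parameters, so
        # the outer loop is a fixed-point map on the parameter vector alone;
        # Aitken extrapolation along a stabilised geometric mode removes the
        # slow contraction without changing the fixed point
        if x_last is not None:
            dx = x - x_last
            if dx_last is not None and outer >= last_ext + 2:
                denom = float(dx_last @ dx_last)
                if denom > 1e-30:
                    ratio = float(dx @ dx_last) / denom
                    aitken_log.append(ratio)
                    if 0.1 < abs(ratio) < 0.95:
                        x = x + dx * (ratio / (1.0 - ratio))
                        last_ext = outer
                        dx = None
            dx_last = dx
        x_last = x.copy()
        new_theta = unpack(x)
        # inner self-consistency: for fixed population parameters each
        # donor's (empirical-Bayes estimate, latent starting titers) pair is
        # an independent fixed point; iterate it per donor so the optimiser
        # always sees fully self-consistent starting titers
        args = _eb_args(new_theta, latent_prior_scale)
        eb: dict[str, tuple[float, float]] = {}
        s_change = 0.0
        for dd in donors:
            first_step = 0.0
            pair = (args[1], args[3])
            for sweep in range(25):
                pair = dd.eb_mode(*args, warm=getattr(dd, "_l_warm", None))
                dd._l_warm = pair[1]
                step = _update_start_titers(
                    [dd], {dd.donor_id: pair}, new_theta["max_effect"], damping=damp
                )
                if sweep == 0:
                    first_step = step
                if step < 1e-10:
                    break
            eb[dd.donor_id] = pair
            s_change = max(s_change, first_step)
        _update_rules(new_theta, eb)
        rel = (
            max(abs(new_theta[n] - theta[n]) / max(abs(theta[n]), 1e-12) for n in names)
            if names
            else 0.0
        )
        trace.append({k: new_theta[k] for k in (*_INTEGRAL_PARAM_NAMES, "rho")})
        rel_changes.append(rel)
        theta = new_theta
        if rel < outer_tol:
            converged = True
            break
        # adaptive under-relaxation: if the change two loops back (the same
        # phase of a potential 2-cycle) has not shrunk, the s<->theta map is
        # oscillating at the current step size — halve it
        if outer >= 4 and rel > 100 * outer_tol and rel >= 0.9 * rel_changes[-3]:
            damp = max(0.5 * damp, 0.05)

    p = theta
    eb = _eb_all(p)
    per_donor = pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in donors],
            "decline_rate": [eb[d.donor_id][0] for d in donors],
            "annual_decline": [eb[d.donor_id][0] * DAYS_PER_YEAR for d in donors],
            "saturation_speed": [eb[d.donor_id][1] for d in donors],
            "n_obs": [d.n + 1 for d in donors],
            "n_boosters": [d.m for d in donors],
        }
    )
    params = {
        "max_effect": p["max_effect"],
        "timing_rate": timing_rate,
        "mean_decline": p["annual_mean_decline"] / DAYS_PER_YEAR,
        "annual_mean_decline": p["annual_mean_decline"],
        "sd_decline": p["annual_sd_decline"] / DAYS_PER_YEAR,
        "annual_sd_decline": p["annual_sd_decline"],
        "mean_saturation": p["mean_saturation"],
        "sd_saturation": p["sd_saturation"],
        "residual_sd": _sheppard(p["residual_sd_effective"], measurement_grid),
        "residual_sd_effective": p["residual_sd_effective"],
        "rho": p["rho"],
        "cov_decline_saturation": p["rho"]
        * (p["annual_sd_decline"] / DAYS_PER_YEAR)
        * p["sd_saturation"],
    }
    return StageFitResult(
        stage="integral",
        params=params,
        per_donor=per_donor,
        loglik=-float(best_fun) if np.isfinite(best_fun) else None,
        iterations=len(trace),
        converged=converged,
        extras={
            "outer_trace": trace,
            "outer_rel_changes": rel_changes,
            "aitken_ratios": aitken_log,
            "start_titers": {d.donor_id: d.s.copy() for d in donors},
            "timing_rate": timing_rate,
        },
    )


# ---------------------------------------------------------------------------
# diagnostics, MAP fitting, validation


def per_donor_residuals(
    records: Sequence[DonorRecord],
    fit: StageFitResult | None = None,
    per_donor: pd.DataFrame | None = None,
    pop: PopulationParameters | None = None,
) -> pd.DataFrame:
    """Mean absolute and squared prediction error per donor.

    Each donor's measurements are predicted from the first measured titer,
    the booster schedule and the donor's fitted (D_i, L_i), with predictions
    below 0 clamped to 0; the anchoring first measurement (zero residual by
    construction) is excluded.  Supply either a Step-3 ``fit`` or an explicit
    ``per_donor`` table (columns donor_id, decline_rate, saturation_speed)
    plus ``pop``.
    """
    if fit is not None:
        per_donor = fit.per_donor
        pop = fit.population()
    if per_donor is None or pop is None:
        raise ValueError("either fit or (per_donor, pop) must be supplied")
    table = per_donor.set_index("donor_id")
    rows = []
    for rec in records:
        d_i = float(table.loc[rec.donor_id, "decline_rate"])
        l_i = float(table.loc[rec.donor_id, "saturation_speed"])
        day0 = rec.obs_days[0]
        traj = predict_trajectory(
            rec.booster_days - day0,
            float(rec.measured_titers[0]),
            DonorParameters(d_i, l_i),
            pop,
            rec.obs_days - day0,
        )
        resid = rec.measured_titers[1:] - traj.titers[1:]
        rows.append(
            {
                "donor_id": rec.donor_id,
                "n_obs": rec.n_obs,
                "mae": float(np.mean(np.abs(resid))) if len(resid) else 0.0,
                "mse": float(np.mean(resid**2)) if len(resid) else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MapFitResult:
    donor_id: str
    params: DonorParameters
    iterations: int
    converged: bool
    flagged: bool  # True when the record was too short and the prior mean was returned


def map_fit_donor(
    record: DonorRecord,
    reference: StageFitResult | dict,
    iterations: int = 50,
    tol: float = 1e-9,
    timing_rate: float | None = None,
) -> MapFitResult:
    """MAP estimate of one donor's (D_i, L_i) under the population prior.

    Maximises the product of the bivariate-normal prior density of
    ``(D_i, L_i)`` (means, SDs and covariance from ``reference``) and the
    Gaussian likelihood of the donor's titer differences, iterating the
    latent starting titers at boostering exactly as in the main fit
    (measured titers initially, model predictions thereafter; at most
    ``iterations`` updates, stopping early once the estimate is stable).
    Donors with fewer than two measurements get the prior mean, flagged.
    """
    params = reference.params if isinstance(reference, StageFitResult) else dict(reference)
    h = timing_rate if timing_rate is not None else params["timing_rate"]
    mu_d = params["mean_decline"]
    sd_d = params["sd_decline"]
    mu_l = params["mean_saturation"]
    sd_l = params["sd_saturation"]
    cov = params.get("cov_decline_saturation", 0.0)
    rho = cov / (sd_d * sd_l) if sd_d > 0 and sd_l > 0 else 0.0
    rho = float(np.clip(rho, -0.99, 0.99))
    se2 = params["residual_sd_effective"] ** 2

    if record.n_obs < 2:
        return MapFitResult(record.donor_id, DonorParameters(mu_d, mu_l), 0, False, True)

    dd = _IntegralDonor(record, h)
    d_hat, l_hat = mu_d, mu_l
    n_iter = 0
    converged = False
    for n_iter in range(1, iterations + 1):
        d_new, l_new = dd.eb_mode(
            params["max_effect"], mu_d, sd_d, mu_l, sd_l, rho, se2, warm=l_hat if n_iter > 1 else None
        )
        change = max(
            abs(d_new - d_hat) / max(abs(d_hat), 1e-12),
            abs(l_new - l_hat) / max(abs(l_hat), 1e-12),
        )
        d_hat, l_hat = d_new, l_new
        _update_start_titers([dd], {dd.donor_id: (d_hat, l_hat)}, params["max_effect"])
        if change < tol:
            converged = True
            break
    return MapFitResult(record.donor_id, DonorParameters(d_hat, l_hat), n_iter, converged, False)


@dataclass
class PipelineResult:
    """Results of the full staged fit (Steps 1, 2A, 2B, 3)."""

    decline: StageFitResult
    timing: StageFitResult | None
    magnitude: StageFitResult | None
    integral: StageFitResult | None

    @property
    def final(self) -> StageFitResult:
        return self.integral if self.integral is not None else self.decline


def run_pipeline(
    records: Sequence[DonorRecord],
    min_unboostered_days: float = 100.0,
    boosters: bool = True,
    **integral_kwargs,
) -> PipelineResult:
    """Run the staged fit end to end.

    Step 1 estimates the decline; Step 2A the envelope rate H (fixed in all
    later stages); Step 2B starting values for the saturation; Step 3 the
    integral mixed-effects model, started from the earlier stages.  With
    ``boosters=False`` (or when no record has any booster) only Step 1 runs.
    """
    diffs = filter_unboostered(records, min_unboostered_days)
    step1 = fit_decline(diffs)
    if not boosters or not any(r.n_boosters for r in records):
        return PipelineResult(step1, None, None, None)

    mu_d = step1.params["mean_decline"]
    step2a = fit_timing(extract_post_booster(records), mu_d)
    step2b = fit_magnitude(extract_peak_changes(records), mu_d)
    start = {
        "max_effect": step2b.params["max_effect"],
        "annual_mean_decline": step1.params["annual_mean_decline"],
        "annual_sd_decline": step1.params["annual_sd_decline"],
        "mean_saturation": step2b.params["mean_saturation"],
        "sd_saturation": max(0.25 * step2b.params["mean_saturation"], 0.02),
        "residual_sd_effective": step1.params["residual_sd_effective"],
    }
    step3 = fit_integral(
        records, timing_rate=step2a.params["timing_rate"], start=start, **integral_kwargs
    )
    return PipelineResult(step1, step2a, step2b, step3)


@dataclass
class SplitValidationReport:
    n_fit: int
    n_held_out: int
    seed: int
    pipeline: PipelineResult
    in_sample_mae: float
    held_out_mae: float
    in_sample_residuals: pd.DataFrame
    held_out_residuals: pd.DataFrame
    held_out_params: pd.DataFrame
    hyperparameter_shifts: dict | None = None


def split_validate(
    records: Sequence[DonorRecord],
    n_fit: int = 500,
    seed: int = 0,
    reference_fit: StageFitResult | None = None,
    **pipeline_kwargs,
) -> SplitValidationReport:
    """Refit on a random donor subset and MAP-fit the held-out donors.

    The pipeline (Steps 1, 2A, 2B, 3) runs on ``n_fit`` randomly chosen
    donors; the remaining donors' (D_i, L_i) are then MAP-fitted under the
    subset fit's population distribution, whose (D, L) covariance is taken
    from the empirical covariance of the subset's per-donor estimates
    (boostered donors only — unboostered donors carry no information on L).
    Reports in-sample and held-out mean absolute errors and, when a
    ``reference_fit`` is given, the relative hyperparameter shifts.
    """
    rng = np.random.default_rng(seed)
    n_fit = min(n_fit, len(records))
    idx = rng.permutation(len(records))
    fit_records = [records[i] for i in sorted(idx[:n_fit])]
    held_records = [records[i] for i in sorted(idx[n_fit:])]

    pipe = run_pipeline(fit_records, **pipeline_kwargs)
    fit3 = pipe.final
    in_res = per_donor_residuals(fit_records, fit3)
    in_mae = float(in_res["mae"].mean())

    prior = dict(fit3.params)
    pd_table = fit3.per_donor
    boosted = pd_table[pd_table["n_boosters"] > 0] if "n_boosters" in pd_table else pd_table
    if len(boosted) >= 3:
        prior["cov_decline_saturation"] = float(
            np.cov(boosted["decline_rate"], boosted["saturation_speed"])[0, 1]
        )

    held_rows, map_rows = [], []
    for rec in held_records:
        mf = map_fit_donor(rec, prior)
        map_rows.append(
            {
                "donor_id": rec.donor_id,
                "decline_rate": mf.params.decline_rate,
                "annual_decline": mf.params.annual_decline,
                "saturation_speed": mf.params.saturation_speed,
                "iterations": mf.iterations,
                "flagged": mf.flagged,
            }
        )
    held_params = pd.DataFrame(
        map_rows,
        columns=[
            "donor_id",
            "decline_rate",
            "annual_decline",
            "saturation_speed",
            "iterations",
            "flagged",
        ],
    )
    if held_records:
        held_res = per_donor_residuals(
            held_records, per_donor=held_params, pop=fit3.population()
        )
        held_mae = float(held_res["mae"].mean())
    else:
        held_res = pd.DataFrame(columns=["donor_id", "n_obs", "mae", "mse"])
        held_mae = float("nan")

    shifts = None
    if reference_fit is not None:
        shifts = {}
        for k in _INTEGRAL_PARAM_NAMES:
            ref = reference_fit.params[k]
            new = fit3.params[k]
            shifts[k] = (new - ref) / max(abs(ref), 1e-12)
    return SplitValidationReport(
        n_fit=len(fit_records),
        n_held_out=len(held_records),
        seed=seed,
        pipeline=pipe,
        in_sample_mae=in_mae,
        held_out_mae=held_mae,
        in_sample_residuals=in_res,
        held_out_residuals=held_res,
        held_out_params=held_params,
        hyperparameter_shifts=shifts,
    )
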