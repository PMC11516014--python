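"""Probabilistic calibration of single radiocarbon determinations.

A conventional age ``d +/- sigma`` is inverted through a calibration curve
``theta -> (mu(theta), sigma_c(theta))`` by evaluating, on every grid year,

    L(theta) = exp(-(d - mu(theta))^2 / (2 (sigma^2 + sigma_c(theta)^2)))
               / sqrt(2 pi (sigma^2 + sigma_c(theta)^2))

i.e. the Gaussian measurement likelihood with the curve's own error folded
into the variance.  Normalised mode rescales to unit sum over the axis;
unnormalised mode keeps raw likelihood heights times the grid step (the two
conventions give visibly different summed distributions, which is why both
are exposed).

The module also carries the forward model (``uncalibrate``): given a true
calendar year, draw a measured age from Normal(mu(theta), sqrt(lab_error^2 +
sigma_c(theta)^2)).  The synthetic generator and the exponential-null test
both rely on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chrono_io import CalendarAxis, CalibrationCurve, RadiocarbonDate, bce_to_calbp

__all__ = [
    "CalibratedDensity",
    "TruncationWarning",
    "calibrate",
    "calibrate_many",
    "sample_calendar_year",
    "uncalibrate",
]


class TruncationWarning(UserWarning):
    """More than 0.1% of a date's calibrated mass falls outside the axis."""


@dataclass
class CalibratedDensity:
    """Probability mass per calendar grid year for one date."""

    axis: CalendarAxis
    mass: np.ndarray
    normalized: bool
    truncated_fraction: float = 0.0

    def __post_init__(self):
        self.mass = np.asarray(self.mass, float)
        if self.mass.shape != (len(self.axis),):
            raise ValueError("mass must match axis length")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")
        if self.normalized and abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("normalized density must sum to 1 within 1e-9")

    def median_bce(self) -> float:
        """Mass-weighted median calendar year (BCE)."""
        c = np.cumsum(self.mass)
        c = c / c[-1]
        i = int(np.searchsorted(c, 0.5))
        return float(self.axis.years_bce[i])

    def mode_bce(self) -> float:
        return float(self.axis.years_bce[int(np.argmax(self.mass))])


def _likelihood_matrix(c14_ages, errors, curve: CalibrationCurve, axis: CalendarAxis):
    """(n_dates, n_grid) Gaussian likelihood of each date at each grid year."""
    theta = bce_to_calbp(axis.years_bce).astype(float)
    mu = curve.interp_mu(theta)
    sc = curve.interp_sigma(theta)
    d = np.atleast_1d(np.asarray(c14_ages, float))[:, None]
    var = np.asarray(errors, float).reshape(-1, 1) ** 2 + sc[None, :] ** 2
    return np.exp(-((d - mu[None, :]) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)


def _truncated_fraction(date, curve, axis):
    """Fraction of the date's full-coverage mass lost to the axis window,
    approximated on the curve's own knot spacing."""
    lo = max(curve.theta_min, axis.cal_bp.min() - 2000)
    hi = min(curve.theta_max, axis.cal_bp.max() + 2000)
    theta = np.arange(lo, hi + 1.0)
    mu = curve.interp_mu(theta)
    sc = curve.interp_sigma(theta)
    var = date.error**2 + sc**2
    L = np.exp(-((date.c14_age - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
    total = L.sum()
    if total == 0:
        return 1.0
    inside = L[(theta >= axis.cal_bp.min()) & (theta <= axis.cal_bp.max())].sum()
    return float(1.0 - inside / total)


def calibrate(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    axis: CalendarAxis,
    normalized: bool = True,
    check_truncation: bool = True,
) -> CalibratedDensity:
    """Calibrate one determination onto a calendar axis."""
    if not date.error > 0:
        raise ValueError("error must be > 0")
    if not curve.covers(bce_to_calbp(np.array([axis.start_bce, axis.end_bce]))):
        raise ValueError("axis lies outside calibration-curve coverage")
    L = _likelihood_matrix([date.c14_age], [date.error], curve, axis)[0]
    trunc = _truncated_fraction(date, curve, axis) if check_truncation else 0.0
    if trunc > 1e-3:
        warnings.warn(
            f"{date.lab_id or date.c14_age}: {trunc:.2%} of calibrated mass "
            "falls outside the axis; density renormalised over the window",
            TruncationWarning,
            stacklevel=2,
        )
    if normalized:
        total = L.sum()
        if total == 0:
            raise ValueError("degenerate density: zero mass on axis")
        mass = L / total
    else:
        mass = L * axis.step
    return CalibratedDensity(axis, mass, normalized, truncated_fraction=trunc)


def calibrate_many(dates, curve, axis, normalized: bool = True) -> np.ndarray:
    """Vectorised calibration: (n_dates, n_grid) mass matrix.

    Skips the per-date truncation diagnostic; intended for the SPD/KDE
    ensemble machinery where the axis is already padded.
    """
    ages = np.array([d.c14_age for d in dates], float)
    errs = np.array([d.error for d in dates], float)
    L = _likelihood_matrix(ages, errs, curve, axis)
    if normalized:
        tot = L.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            bad = [dates[i].lab_id for i in np.flatnonzero(tot[:, 0] == 0)]
            raise ValueError(f"zero calibrated mass on axis for: {bad}")
        return L / tot
    return L * axis.step


def sample_calendar_year(density: CalibratedDensity, rng: np.random.Generator, size=None):
    """Draw calendar years (BCE) proportional to the calibrated mass."""
    total = density.mass.sum()
    if total <= 0:
        raise ValueError("degenerate density: all-zero mass")
    p = density.mass / total
    return rng.choice(density.axis.years_bce, size=size, p=p)


def uncalibrate(
    true_year_bce,
    curve: CalibrationCurve,
    lab_error: float,
    rng: np.random.Generator,
    lab_id: str = "",
    **meta,
) -> RadiocarbonDate:
    """Forward-model a measured age for a known calendar year.

    measured ~ Normal(mu(theta), sqrt(lab_error^2 + sigma_c(theta)^2)) at
    theta = cal BP of the true year.
    """
    if not lab_error > 0:
        raise ValueError("lab_error must be > 0")
    theta = float(bce_to_calbp(int(true_year_bce)))
    if not curve.covers(theta):
        raise ValueError(f"year {true_year_bce} BCE outside curve coverage")
    mu = float(curve.interp_mu(theta))
    sd = float(np.hypot(lab_error, curve.interp_sigma(theta)))
    age = float(rng.normal(mu, sd)) if sd > 0 else mu
    return RadiocarbonDate(
        lab_id=lab_id or f"SIM-{int(true_year_bce)}",
        c14_age=max(age, 1e-6),
        error=lab_error,
        **meta,
    )


def uncalibrate_many(true_years_bce, curve, lab_errors, rng):
    """Vectorised forward model; returns (c14_ages, errors) arrays."""
    theta = bce_to_calbp(np.asarray(true_years_bce, int)).astype(float)
    if not curve.covers(theta):
        raise ValueError("some years outside curve coverage")
    mu = curve.interp_mu(theta)
    sd = np.hypot(np.asarray(lab_errors, float), curve.interp_sigma(theta))
    ages = rng.normal(mu, sd)
    return np.maximum(ages, 1e-6), np.asarray(lab_errors, float)
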