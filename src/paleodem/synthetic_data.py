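"""Synthetic multi-proxy datasets from known ground truth.

Every pipeline stage (calibration, SPD/KDE, aoristic sums, openness PCA,
cross-proxy statistics) can be exercised against data whose generating
trajectory is known exactly:

* ``simulate_dates`` draws occupation events from a population trajectory
  and forward-models each through a calibration curve to a measured
  14C age +/- error (the dates-as-data premise run forwards);
* ``simulate_artifacts`` draws deposition years from a trajectory and
  assigns each artifact the typochronological span containing it;
* ``simulate_pollen`` drives a two-end-member (forest vs open) multinomial
  mixture with a known openness trajectory and noisy sample ages.

All generators are deterministic under a fixed ``numpy`` Generator and
return a provenance dict (family, parameters) alongside the records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aoristic import AoristicRecord, TypochronologyTable
from .calibration import uncalibrate_many
from .chrono_io import CalendarAxis, CalibrationCurve, RadiocarbonDate, bce_to_calbp
from .openness import PollenSample

__all__ = [
    "PopulationTrajectory",
    "synthetic_curve",
    "identity_curve",
    "simulate_dates",
    "simulate_artifacts",
    "simulate_pollen",
]


@dataclass
class PopulationTrajectory:
    """Relative (unnormalised) population density per grid year."""

    axis: CalendarAxis
    density: np.ndarray
    family: str = "custom"
    params: dict | None = None

    def __post_init__(self):
        self.density = np.asarray(self.density, float)
        if self.density.shape != (len(self.axis),):
            raise ValueError("density must match axis length")
        if np.any(self.density < 0) or not np.any(self.density > 0):
            raise ValueError("density must be >= 0 with at least one positive cell")

    @classmethod
    def constant(cls, axis: CalendarAxis, level: float = 1.0):
        return cls(axis, np.full(len(axis), level), "constant", {"level": level})

    @classmethod
    def exponential(cls, axis: CalendarAxis, rate: float):
        """Growth at ``rate`` per year forward in time."""
        t = np.arange(len(axis), dtype=float) * axis.step
        return cls(axis, np.exp(rate * t), "exponential", {"rate": rate})

    @classmethod
    def logistic(cls, axis: CalendarAxis, rate: float, midpoint_bce: float,
                 carrying: float = 1.0):
        t = np.arange(len(axis), dtype=float) * axis.step
        t_mid = float(axis.start_bce - midpoint_bce)
        d = carrying / (1.0 + np.exp(-rate * (t - t_mid)))
        return cls(axis, d, "logistic",
                   {"rate": rate, "midpoint_bce": midpoint_bce, "carrying": carrying})

    @classmethod
    def piecewise_boom_bust(cls, axis: CalendarAxis, segments):
        """Piecewise-constant density from [(start_bce, end_bce, level), ...]."""
        years = axis.years_bce
        d = np.zeros(len(axis))
        for start, end, level in segments:
            d[(years <= start) & (years >= end)] = level
        return cls(axis, d, "piecewise_boom_bust", {"segments": list(segments)})

    def sample_years(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.density / self.density.sum()
        return rng.choice(self.axis.years_bce, size=n, p=p)

    def provenance(self) -> dict:
        return {"family": self.family, "params": self.params,
                "axis": (self.axis.start_bce, self.axis.end_bce, self.axis.step)}


def synthetic_curve(theta_min: float = 2000.0, theta_max: float = 6000.0,
                    sigma: float = 10.0, wiggle_amp: float = 0.0,
                    wiggle_period: float = 300.0,
                    plateau: tuple | None = None,
                    knot_step: float = 5.0) -> CalibrationCurve:
    """Identity-like calibration curve with optional wiggle and plateau.

    ``plateau=(lo_calbp, hi_calbp)`` flattens mu over that interval, mimicking
    the real curve's plateau artefact (e.g. ~2450-2200 BCE) that spreads
    calibrated probability across the flat stretch.
    """
    theta = np.arange(theta_min, theta_max + knot_step, knot_step)
    mu = theta.astype(float).copy()
    if wiggle_amp:
        mu += wiggle_amp * np.sin(2 * np.pi * theta / wiggle_period)
    if plateau is not None:
        lo, hi = plateau
        mask = (theta >= lo) & (theta <= hi)
        if mask.any():
            mu[mask] = mu[mask].mean()
    return CalibrationCurve(theta, mu, np.full(len(theta), float(sigma)),
                            name="synthetic")


def identity_curve(theta_min: float = 1000.0, theta_max: float = 8000.0,
                   sigma: float = 0.0) -> CalibrationCurve:
    """mu(theta) = theta with constant curve error (0 by default)."""
    theta = np.array([theta_min, theta_max])
    return CalibrationCurve(theta, theta.copy(), np.full(2, float(sigma)),
                            name="identity")


def _draw_lab_errors(model, n, rng):
    if np.isscalar(model):
        return np.full(n, float(model))
    if isinstance(model, tuple) and model and model[0] == "uniform":
        _, lo, hi = model
        return rng.uniform(lo, hi, size=n)
    pool = np.asarray(model, float)  # empirical error pool
    return rng.choice(pool, size=n)


def simulate_dates(traj: PopulationTrajectory, n: int, curve: CalibrationCurve,
                   lab_error_model=40.0, site_model=(50, 1.0),
                   rng: np.random.Generator | None = None, region: str = "",
                   material: str = "short-lived", site_type: str = "settlement"):
    """Forward-model ``n`` radiocarbon dates from a population trajectory.

    ``lab_error_model``: a scalar (fixed error), ``("uniform", lo, hi)``, or
    an array of observed errors to resample (empirical mode).
    ``site_model``: ``(k, concentration)`` — site labels drawn from a
    k-category Dirichlet-multinomial; small concentration concentrates
    dates on few sites, as excavation practice does.

    Returns ``(dates, provenance)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng()
    theta_range = bce_to_calbp(
        np.array([traj.axis.end_bce, traj.axis.start_bce]))
    if not curve.covers(theta_range):
        raise ValueError("trajectory axis outside curve coverage")
    years = traj.sample_years(n, rng)
    errs = _draw_lab_errors(lab_error_model, n, rng)
    ages, errs = uncalibrate_many(years, curve, errs, rng)
    k, conc = site_model
    site_w = rng.dirichlet(np.full(k, conc))
    site_ids = rng.choice(k, size=n, p=site_w)
    dates = [
        RadiocarbonDate(
            lab_id=f"SIM-{i:05d}", c14_age=float(a), error=float(e),
            site_id=f"site-{s:03d}", region=region, material=material,
            site_type=site_type,
        )
        for i, (a, e, s) in enumerate(zip(ages, errs, site_ids))
    ]
    prov = {"generator": "simulate_dates", "n": n, "trajectory": traj.provenance(),
            "lab_error_model": str(lab_error_model), "site_model": site_model}
    return dates, prov


def simulate_artifacts(traj: PopulationTrajectory, typology: TypochronologyTable,
                       n_per_category: dict, rng: np.random.Generator | None = None,
                       misdating_jitter: float = 0.0, region: str = "",
                       context: str = "grave"):
    """Draw artifact deposition years from a trajectory and date them
    typologically.

    Each artifact's true year (plus optional Gaussian misdating jitter) is
    matched against the typology's spans for its category; ties between
    overlapping spans go to the narrowest.  Years covered by no span are
    dropped and counted.

    Returns ``(records, n_dropped, provenance)``.
    """
    rng = rng or np.random.default_rng()
    spans_by_cat: dict[str, list] = {}
    for (cat, code), (a, b) in typology.items():
        spans_by_cat.setdefault(cat, []).append((code, a, b))
    records = []
    dropped = 0
    i = 0
    for category, n in n_per_category.items():
        spans = spans_by_cat.get(category, [])
        years = traj.sample_years(n, rng)
        if misdating_jitter > 0:
            years = np.round(years + rng.normal(0, misdating_jitter, n)).astype(int)
        for y in years:
            hits = [(a - b, code, a, b) for code, a, b in spans if b <= y <= a]
            if not hits:
                dropped += 1
                continue
            _, code, a, b = min(hits)  # narrowest span wins
            records.append(
                AoristicRecord(
                    artifact_id=f"ART-{i:05d}", category=category,
                    type_code=code, span_start=a, span_end=b,
                    region=region, context=context,
                )
            )
            i += 1
    prov = {"generator": "simulate_artifacts", "n_per_category": dict(n_per_category),
            "trajectory": traj.provenance(), "misdating_jitter": misdating_jitter}
    return records, dropped, prov


DEFAULT_FOREST_PROFILE = {
    "Quercus": 0.28, "Tilia": 0.14, "Ulmus": 0.10, "Fagus": 0.10,
    "Corylus": 0.14, "Alnus": 0.10, "Betula": 0.09, "Poaceae": 0.05,
}
DEFAULT_OPEN_PROFILE = {
    "Poaceae": 0.45, "Calluna": 0.20, "Plantago_lanceolata": 0.10,
    "Rumex": 0.05, "Artemisia": 0.05, "Betula": 0.05, "Corylus": 0.05,
    "Quercus": 0.05,
}


def simulate_pollen(openness_traj, m_records: int = 3, samples_per_record: int = 40,
                    grains_per_sample: int = 300, forest_profile=None,
                    open_profile=None, age_jitter_sd: float = 25.0,
                    rng: np.random.Generator | None = None, region: str = ""):
    """Multinomial pollen counts from a forest/open two-end-member mixture.

    ``openness_traj`` is a ``(axis, o)`` pair (or PopulationTrajectory whose
    density is on [0, 1]): the expected taxon proportions at true age t are
    ``o(t) * open_profile + (1 - o(t)) * forest_profile``; each sample draws
    ``grains_per_sample`` grains from that multinomial, and its reported age
    is the true age plus Normal(0, age_jitter_sd) noise — mimicking
    age-depth-model uncertainty.

    Returns ``(samples, provenance)``.
    """
    rng = rng or np.random.default_rng()
    if isinstance(openness_traj, PopulationTrajectory):
        axis, o = openness_traj.axis, openness_traj.density
    else:
        axis, o = openness_traj
    o = np.asarray(o, float)
    if np.any((o < 0) | (o > 1)):
        raise ValueError("openness trajectory must lie in [0, 1]")
    forest_profile = forest_profile or DEFAULT_FOREST_PROFILE
    open_profile = open_profile or DEFAULT_OPEN_PROFILE
    taxa = sorted(set(forest_profile) | set(open_profile))
    fvec = np.array([forest_profile.get(t, 0.0) for t in taxa])
    ovec = np.array([open_profile.get(t, 0.0) for t in taxa])
    for name, v in (("forest_profile", fvec), ("open_profile", ovec)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")

    years = axis.years_bce
    samples = []
    for r in range(m_records):
        # evenly spaced true ages across the record's span
        true_ages = np.linspace(years[0], years[-1], samples_per_record)
        for j, ta in enumerate(true_ages):
            o_t = float(np.interp(-ta, -years, o))
            p = o_t * ovec + (1.0 - o_t) * fvec
            counts = rng.multinomial(grains_per_sample, p / p.sum())
            age = float(ta + rng.normal(0, age_jitter_sd)) if age_jitter_sd else float(ta)
            samples.append(
                PollenSample(
                    record_id=f"core-{r:02d}", sample_id=f"core-{r:02d}/{j:03d}",
                    age_bce=age,
                    taxa_counts=dict(zip(taxa, (int(c) for c in counts))),
                    region=region,
                )
            )
    prov = {"generator": "simulate_pollen", "m_records": m_records,
            "samples_per_record": samples_per_record,
            "grains_per_sample": grains_per_sample,
            "age_jitter_sd": age_jitter_sd}
    return samples, prov
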