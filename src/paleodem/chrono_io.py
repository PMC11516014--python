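"""Calendar conventions, input tables and calibration-curve IO.

Every module in the package shares a single calendar convention: time is
carried as integer years BCE on a :class:`CalendarAxis`, and conversion to
the radiocarbon community's cal BP scale uses ``cal BP = BCE + 1949`` (1 BCE
is 1950 cal BP; there is no year zero).  All curve lookups convert at the
boundary, so the +/-1 ambiguity between the two scales cannot drift through
the pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CalendarAxis",
    "RadiocarbonDate",
    "CalibrationCurve",
    "CurveParseError",
    "SchemaError",
    "RowError",
    "bce_to_calbp",
    "calbp_to_bce",
    "read_calcurve",
    "read_dates_csv",
    "write_dates_csv",
    "read_series_csv",
    "write_series_csv",
]

#: offset between the years-BCE axis and cal BP (1 BCE == 1950 cal BP)
BP_OFFSET = 1949

REGION_SCHEMES = {
    "geomorphic": ("SB", "DI", "EJ", "WJ"),
    "pollen": ("NJ", "SJ", "Zealand"),
}

MATERIAL_CLASSES = (
    "short-lived",
    "bone-human",
    "bone-animal",
    "food-remains",
    "shell",
    "other",
)


class CurveParseError(ValueError):
    """A calibration-curve file could not be parsed or validated."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass(frozen=True)
class RowError:
    """One unparseable row of an input table."""

    row: int
    message: str


def bce_to_calbp(year_bce):
    """Convert years BCE to cal BP (vectorised).

    Raises ``ValueError`` for years < 1: the BCE scale has no year zero.
    """
    y = np.asarray(year_bce)
    if np.any(y < 1):
        raise ValueError("years BCE must be >= 1 (no year zero)")
    out = y + BP_OFFSET
    return out if out.ndim else out.item()


def calbp_to_bce(cal_bp):
    """Inverse of :func:`bce_to_calbp`; exact for integer input."""
    b = np.asarray(cal_bp)
    if np.any(b < 1 + BP_OFFSET):
        raise ValueError(f"cal BP must be >= {1 + BP_OFFSET} to map into BCE")
    out = b - BP_OFFSET
    return out if out.ndim else out.item()


@dataclass(frozen=True)
class CalendarAxis:
    """Annual (or coarser) grid of years BCE, newest convention: BCE counts
    down toward the present, so ``start_bce > end_bce`` and the grid runs
    forward in time."""

    start_bce: int
    end_bce: int
    step: int = 1

    def __post_init__(self):
        if self.start_bce <= self.end_bce:
            raise ValueError("start_bce must be > end_bce (BCE counts down)")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if (self.start_bce - self.end_bce) % self.step:
            raise ValueError("step must divide the window length")

    def __len__(self):
        return (self.start_bce - self.end_bce) // self.step + 1

    @property
    def years_bce(self) -> np.ndarray:
        """Grid years in forward-time order (decreasing BCE)."""
        return np.arange(self.start_bce, self.end_bce - 1, -self.step)

    @property
    def cal_bp(self) -> np.ndarray:
        return self.years_bce + BP_OFFSET

    def pad(self, years: int) -> "CalendarAxis":
        """Widen the window on both ends (same step)."""
        years = (years // self.step) * self.step
        return replace(
            self, start_bce=self.start_bce + years, end_bce=self.end_bce - years
        )

    def index_of(self, year_bce) -> np.ndarray:
        """Grid index of (an array of) years BCE; caller guarantees in-range."""
        return (self.start_bce - np.asarray(year_bce)) // self.step


#: the observation window used throughout the study, padded +/-100 years
#: against boundary effects when calibrating.
OBSERVATION_WINDOW = CalendarAxis(2850, 1700)


@dataclass(frozen=True)
class RadiocarbonDate:
    """A single laboratory determination: conventional age ``d`` +/- 1-sigma."""

    lab_id: str
    c14_age: float
    error: float
    site_id: str = ""
    region: str = ""
    material: str = "other"
    site_type: str = "other"

    def __post_init__(self):
        if not self.error > 0:
            raise ValueError(f"{self.lab_id}: error must be > 0")
        if not self.c14_age > 0:
            raise ValueError(f"{self.lab_id}: c14_age must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Empirical mapping cal BP -> (expected 14C age, curve error).

    ``theta`` is strictly increasing cal BP; lookups interpolate linearly in
    both the mean and the error between knots.
    """

    theta: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, float))
        object.__setattr__(self, "mu", np.asarray(self.mu, float))
        object.__setattr__(self, "sigma_curve", np.asarray(self.sigma_curve, float))
        if self.theta.ndim != 1 or len(self.theta) < 2:
            raise CurveParseError("curve needs at least two knots")
        d = np.diff(self.theta)
        if np.any(d == 0):
            raise CurveParseError("duplicate theta knots in calibration curve")
        if not (np.all(d > 0)):
            raise CurveParseError("theta must be strictly monotone")
        if np.any(self.sigma_curve < 0):
            raise CurveParseError("sigma_curve must be >= 0")

    @property
    def theta_min(self):
        return float(self.theta[0])

    @property
    def theta_max(self):
        return float(self.theta[-1])

    def interp_mu(self, theta):
        return np.interp(theta, self.theta, self.mu)

    def interp_sigma(self, theta):
        return np.interp(theta, self.theta, self.sigma_curve)

    def covers(self, theta) -> bool:
        t = np.asarray(theta)
        return bool(np.all((t >= self.theta_min) & (t <= self.theta_max)))


def read_calcurve(path, dialect: str = "intcal14c", name: str | None = None) -> CalibrationCurve:
    """Read a calibration curve.

    ``intcal14c``: the standard ``.14c`` layout — comment lines starting
    ``#``, then comma-separated columns CAL BP, 14C age, Error (extra columns
    such as Delta14C are ignored).  ``plain_csv``: a headered CSV with
    columns ``cal_bp, c14_age, error``.
    """
    if dialect == "intcal14c":
        rows = []
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p for p in line.replace(",", " ").split() if p]
                if len(parts) < 3:
                    raise CurveParseError(f"line {lineno}: expected >=3 columns")
                try:
                    rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
                except ValueError as exc:
                    raise CurveParseError(f"line {lineno}: {exc}") from exc
        if not rows:
            raise CurveParseError("no data rows in curve file")
        arr = np.array(rows)
    elif dialect == "plain_csv":
        df = pd.read_csv(path)
        missing = {"cal_bp", "c14_age", "error"} - set(df.columns)
        if missing:
            raise SchemaError(f"curve CSV missing columns: {sorted(missing)}")
        arr = df[["cal_bp", "c14_age", "error"]].to_numpy(float)
    else:
        raise ValueError(f"unknown curve dialect {dialect!r}")

    order = np.argsort(arr[:, 0])
    arr = arr[order]
    return CalibrationCurve(
        arr[:, 0], arr[:, 1], arr[:, 2], name=name or str(path)
    )


DATE_SCHEMA = {
    "lab_id": "lab_id",
    "c14_age": "c14_age",
    "error": "error",
    "site_id": "site_id",
    "region": "region",
    "material": "material",
    "site_type": "site_type",
}


def read_dates_csv(path, schema: dict | None = None):
    """Read a radiocarbon determination table.

    ``schema`` maps internal field names to the file's column names (defaults
    to identical names).  Returns ``(dates, errors)`` where ``errors`` is a
    list of :class:`RowError` for rows whose age/error would not parse; no
    row is ever dropped silently.
    """
    colmap = dict(DATE_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"dates CSV missing required columns: {missing}")

    dates: list[RadiocarbonDate] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # row 1 = header
        rec = {k: row[v] for k, v in colmap.items()}
        try:
            dates.append(
                RadiocarbonDate(
                    lab_id=rec["lab_id"],
                    c14_age=float(rec["c14_age"]),
                    error=float(rec["error"]),
                    site_id=rec["site_id"],
                    region=rec["region"],
                    material=rec["material"],
                    site_type=rec["site_type"],
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return dates, errors


def write_dates_csv(path, dates, schema: dict | None = None) -> None:
    colmap = dict(DATE_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.DataFrame(
        {
            colmap[k]: [getattr(d, k) for d in dates]
            for k in DATE_SCHEMA
        }
    )
    df.to_csv(path, index=False)


def write_series_csv(path, year_bce, value, lower=None, upper=None, meta: dict | None = None):
    """Export a time series as CSV (year_bce, value[, lower, upper]).

    ``meta`` key/values are written as ``# key: value`` provenance headers.
    """
    buf = io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    cols = {"year_bce": np.asarray(year_bce), "value": np.asarray(value)}
    if lower is not None:
        cols["lower"] = np.asarray(lower)
    if upper is not None:
        cols["upper"] = np.asarray(upper)
    pd.DataFrame(cols).to_csv(buf, index=False)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
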