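"""PCA vegetation-openness scores from pollen count tables.

Terrestrial pollen assemblages ordinate, on the first principal component,
into shade/forest taxa (oak, lime, elm, beech...) versus light-demanding
taxa (grasses, heather, ribwort plantain...).  The PC1 score of a sample,
oriented so the open-land indicators load positive, is therefore a proxy
for vegetation openness and, indirectly, human land use.  Scores are
computed per sample on count proportions, then interpolated record-by-record
onto a 50-year regional grid and averaged across records.

The model/results split follows the usual estimator pattern:
``OpennessPCA(samples, ...).fit()`` returns an :class:`OpennessResults`
holding per-sample scores, taxon loadings and diagnostics, from which
:meth:`OpennessResults.regional` builds the gridded regional series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .chrono_io import CalendarAxis

__all__ = [
    "PollenSample",
    "OpennessPCA",
    "OpennessResults",
    "OpennessSeries",
    "load_default_taxa",
    "regional_openness",
]


@dataclass(frozen=True)
class PollenSample:
    """One counted pollen sample with an externally modelled calendar age."""

    record_id: str
    sample_id: str
    age_bce: float
    taxa_counts: dict
    region: str = ""
    projection_only: bool = False

    def __post_init__(self):
        if any(v < 0 for v in self.taxa_counts.values()):
            raise ValueError(f"{self.sample_id}: negative pollen count")
        if sum(self.taxa_counts.values()) <= 0:
            raise ValueError(f"{self.sample_id}: zero total count")


def load_default_taxa():
    """(selected_taxa, open_indicators) from the bundled config."""
    ref = resources.files("paleodem").joinpath("data/taxa.yaml")
    with ref.open("rt", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return list(cfg["selected_taxa"]), list(cfg["open_indicators"])


class OpennessPCA:
    """PCA openness model over a window of pollen samples.

    Parameters
    ----------
    samples : list of PollenSample
    taxa : list of str, optional
        Terrestrial taxa selection; defaults to the bundled list, restricted
        to taxa actually present.  Taxa absent from every sample are dropped
        with a warning.
    open_indicators : list of str, optional
        Taxa whose mean PC1 loading must be positive (sign rule); defaults
        to grasses, heather and ribwort plantain.
    window : CalendarAxis, optional
        Samples outside the window are excluded from the decomposition
        (default 4800-700 BCE, where the taxa relationships are stable).
    sqrt_transform : bool, default False
        Square-root transform the proportions before centring.
    """

    DEFAULT_WINDOW = CalendarAxis(4800, 700)

    def __init__(self, samples, taxa=None, open_indicators=None, window=None,
                 sqrt_transform: bool = False):
        if taxa is None or open_indicators is None:
            default_taxa, default_open = load_default_taxa()
            taxa = taxa or default_taxa
            open_indicators = open_indicators or default_open
        self.window = window or self.DEFAULT_WINDOW
        self.sqrt_transform = sqrt_transform

        in_window = [s for s in samples
                     if self.window.end_bce <= s.age_bce <= self.window.start_bce]
        if len(in_window) < 2:
            raise ValueError("need >= 2 samples inside the PCA window")
        present = {t for s in in_window for t, c in s.taxa_counts.items() if c > 0}
        kept = [t for t in taxa if t in present]
        dropped = [t for t in taxa if t not in present]
        if dropped:
            warnings.warn(f"taxa absent from all samples dropped: {dropped}")
        if len(kept) < 2:
            raise ValueError("need >= 2 selected taxa present in the samples")
        self.samples = in_window
        self.taxa = kept
        self.open_indicators = [t for t in open_indicators if t in kept]

    def _proportions(self, samples) -> np.ndarray:
        X = np.array(
            [[s.taxa_counts.get(t, 0.0) for t in self.taxa] for s in samples],
            float,
        )
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            bad = [s.sample_id for s, t in zip(samples, totals[:, 0]) if t == 0]
            raise ValueError(f"samples with zero selected-taxa count: {bad}")
        X = X / totals
        if self.sqrt_transform:
            X = np.sqrt(X)
        return X

    def fit(self) -> "OpennessResults":
        fit_samples = [s for s in self.samples if not s.projection_only]
        if len(fit_samples) < 2:
            raise ValueError("need >= 2 non-projection samples to fit the PCA")
        X = self._proportions(fit_samples)
        mean = X.mean(axis=0)
        Xc = X - mean
        if np.allclose(Xc, 0):
            raise ValueError("degenerate PCA: constant proportion matrix")
        # economy SVD; PC1 loading = first right-singular vector
        _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[0]
        if self.open_indicators:
            open_idx = [self.taxa.index(t) for t in self.open_indicators]
            if loadings[open_idx].mean() < 0:
                loadings = -loadings
        explained = svals**2 / np.sum(svals**2)

        all_X = self._proportions(self.samples)
        scores = (all_X - mean) @ loadings
        return OpennessResults(
            model=self,
            scores=scores,
            loadings=dict(zip(self.taxa, loadings)),
            explained_variance_ratio=explained,
            center=mean,
        )


@dataclass
class OpennessResults:
    """Per-sample PC1 openness scores and taxon loadings."""

    model: OpennessPCA
    scores: np.ndarray
    loadings: dict
    explained_variance_ratio: np.ndarray
    center: np.ndarray

    @property
    def samples(self):
        return self.model.samples

    def loading_separation(self) -> float:
        """Mean open-indicator loading minus mean loading of the rest.

        A diagnostic for regions where the openness gradient fails to
        project onto PC1 (small or negative separation means the score
        should not be interpreted as openness there).
        """
        taxa = self.model.taxa
        open_set = set(self.model.open_indicators)
        lv = np.array([self.loadings[t] for t in taxa])
        is_open = np.array([t in open_set for t in taxa])
        if not is_open.any() or is_open.all():
            return float("nan")
        return float(lv[is_open].mean() - lv[~is_open].mean())

    def regional(self, region_map=None, step: int = 50, smooth: bool = False,
                 window: CalendarAxis | None = None):
        """Aggregate per-sample scores to per-region 50-yr series.

        ``region_map`` maps record_id -> region; by default each sample's
        own ``region`` field is used.
        """
        return regional_openness(
            self.samples, self.scores, region_map=region_map, step=step,
            smooth=smooth, window=window or self.model.window,
        )

    def summary(self) -> str:
        evr = self.explained_variance_ratio
        lines = [
            "Openness PCA",
            "-" * 40,
            f"samples: {len(self.samples)}   taxa: {len(self.model.taxa)}",
            f"PC1 variance explained: {evr[0]:.1%}"
            + (f" (PC2 {evr[1]:.1%})" if len(evr) > 1 else ""),
            f"open/forest loading separation: {self.loading_separation():+.3f}",
            "top loadings:",
        ]
        for t, v in sorted(self.loadings.items(), key=lambda kv: -abs(kv[1]))[:6]:
            lines.append(f"  {t:<22}{v:+.3f}")
        return "\n".join(lines)


@dataclass
class OpennessSeries:
    """Regional openness on a coarse calendar grid.

    Bins with no contributing record hold NaN (missing, not zero).
    """

    axis: CalendarAxis
    score: np.ndarray
    n_records: np.ndarray
    region: str = ""

    @property
    def years_bce(self):
        return self.axis.years_bce


def _interp_record(ages, scores, grid):
    """Linear interpolation restricted to the record's own age span."""
    order = np.argsort(ages)[::-1]  # oldest (largest BCE) first = forward time
    a, v = np.asarray(ages, float)[order], np.asarray(scores, float)[order]
    out = np.full(len(grid), np.nan)
    inside = (grid <= a[0]) & (grid >= a[-1])
    if inside.any():
        # np.interp needs ascending x; BCE grid descends, so negate
        out[inside] = np.interp(-grid[inside], -a, v)
    return out


def regional_openness(samples, scores, region_map=None, step: int = 50,
                      smooth: bool = False, window: CalendarAxis | None = None):
    """Per-region openness series on a coarse grid.

    Each record's sample scores are linearly interpolated onto the grid,
    restricted to that record's own age span; the regional series is the
    unweighted mean across records per bin; optional smoothing is a centred
    3-bin moving average.  Returns {region: OpennessSeries}.
    """
    window = window or OpennessPCA.DEFAULT_WINDOW
    start = (window.start_bce // step) * step
    end = -(-window.end_bce // step) * step
    axis = CalendarAxis(start, end, step)
    grid = axis.years_bce.astype(float)

    by_record: dict[str, list] = {}
    for s, sc in zip(samples, scores):
        by_record.setdefault(s.record_id, []).append((s, sc))

    regions: dict[str, list[np.ndarray]] = {}
    for rec_id, pairs in by_record.items():
        ages = [s.age_bce for s, _ in pairs]
        vals = [sc for _, sc in pairs]
        series = _interp_record(ages, vals, grid)
        if region_map is not None:
            region = region_map.get(rec_id, "")
        else:
            region = pairs[0][0].region
        regions.setdefault(region, []).append(series)

    out = {}
    for region, stack in regions.items():
        arr = np.vstack(stack)
        n = np.sum(~np.isnan(arr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
        if smooth:
            mean = _moving_average3(mean)
        out[region] = OpennessSeries(axis, mean, n, region=region)
    return out


def _moving_average3(x):
    """Centred 3-bin moving average, NaN-aware, endpoints use 2 bins."""
    x = np.asarray(x, float)
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        lo, hi = max(0, i - 1), min(len(x), i + 2)
        w = x[lo:hi]
        if np.all(np.isnan(w)):
            continue
        out[i] = np.nanmean(w)
    return out
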