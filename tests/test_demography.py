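"""SPD, composite KDE, growth rates and the exponential-null test."""

import numpy as np
import pytest

from paleodem.calibration import calibrate
from paleodem.chrono_io import CalendarAxis
from paleodem.demography import (
    CompositeKDE,
    ExponentialNullModel,
    FilterConfig,
    GrowthSeries,
    _growth_rows,
    apply_filters,
    kde_growth,
    spd,
    spd_correlation,
)
from paleodem.synthetic_data import (
    PopulationTrajectory,
    identity_curve,
    simulate_dates,
    synthetic_curve,
)
from .conftest import make_date


class TestFilters:
    def test_toy_rules(self, ident_curve):
        dates = [
            make_date(4000, err=150.0),            # error rule
            make_date(4000, err=30, material="shell"),  # marine rule
            make_date(4000, err=30),               # ~2050 BCE, in window
            make_date(4400, err=30),               # ~2450 BCE, in window
        ]
        kept, audit = apply_filters(dates, ident_curve)
        assert len(kept) == 2
        assert audit["error"] == 1 and audit["marine"] == 1 and audit["window"] == 0

    def test_window_rule_uses_calibrated_median(self, ident_curve):
        inside = make_date(4000, err=30)       # median ~2051 BCE
        outside = make_date(5600, err=30)      # median ~3651 BCE
        kept, audit = apply_filters([inside, outside], ident_curve)
        assert kept == [inside]
        assert audit["window"] == 1

    def test_empty_input(self, ident_curve):
        kept, audit = apply_filters([], ident_curve)
        assert kept == [] and audit["n_output"] == 0
        assert audit["error"] == audit["marine"] == audit["window"] == 0

    def test_order_of_application(self, ident_curve):
        # a shell date with error 150 must be counted under the error rule
        d = make_date(4000, err=150.0, material="shell")
        _, audit = apply_filters([d], ident_curve)
        assert audit["error"] == 1 and audit["marine"] == 0


class TestSPD:
    def test_single_date_equals_density(self, wiggly_curve, axis):
        d = make_date(4300)
        s = spd([d], wiggly_curve, axis)
        dens = calibrate(d, wiggly_curve, axis, check_truncation=False)
        assert np.allclose(s.value, dens.mass)

    def test_additivity_and_mass(self, wiggly_curve, axis, toy_dates):
        sa = spd(toy_dates[:5], wiggly_curve, axis)
        sb = spd(toy_dates[5:], wiggly_curve, axis)
        sall = spd(toy_dates, wiggly_curve, axis)
        assert np.allclose(sall.value, sa.value + sb.value)
        assert sall.total_mass() == pytest.approx(10.0, abs=1e-6)

    def test_disjoint_supports_sum_to_two(self, axis):
        curve = identity_curve(sigma=0.0)
        s = spd([make_date(4100, err=10), make_date(4500, err=10)], curve, axis)
        assert s.total_mass() == pytest.approx(2.0, abs=1e-6)

    def test_matches_loop_oracle(self, wiggly_curve, axis, toy_dates):
        s = spd(toy_dates, wiggly_curve, axis)
        oracle = np.zeros(len(axis))
        for d in toy_dates:
            oracle += calibrate(d, wiggly_curve, axis, check_truncation=False).mass
        assert np.allclose(s.value, oracle, atol=1e-12)

    def test_correlation_trivial_and_errors(self, wiggly_curve, axis, toy_dates):
        s = spd(toy_dates, wiggly_curve, axis)
        assert spd_correlation(s, s) == pytest.approx(1.0)
        flat = spd(toy_dates, wiggly_curve, axis)
        flat.value = np.ones_like(flat.value)
        with pytest.raises(ValueError):
            spd_correlation(s, flat)


class TestCompositeKDE:
    def test_degenerate_input_mode(self, padded_axis):
        curve = identity_curve(sigma=0.0)
        dates = [make_date(4300, err=2.0) for _ in range(20)]
        res = CompositeKDE(dates, curve, padded_axis, n_sim=50).fit(seed=0)
        mode = res.years_bce[np.argmax(res.mean)]
        true_year = 4300 - 1949
        assert abs(mode - true_year) <= 50  # within one bandwidth

    def test_rows_integrate_to_one(self, wiggly_curve, padded_axis, toy_dates):
        res = CompositeKDE(toy_dates, wiggly_curve, padded_axis, n_sim=20).fit(seed=1)
        sums = res.ensemble.sum(axis=1) * padded_axis.step
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert np.all(res.envelope_lo <= res.mean + 1e-12)
        assert np.all(res.mean <= res.envelope_hi + 1e-12)

    def test_doubling_dataset_leaves_shape(self, wiggly_curve, padded_axis, axis):
        traj = PopulationTrajectory.exponential(axis, 0.001)
        dates, _ = simulate_dates(traj, 300, wiggly_curve,
                                  rng=np.random.default_rng(5))
        r1 = CompositeKDE(dates, wiggly_curve, padded_axis, n_sim=200).fit(seed=2)
        r2 = CompositeKDE(dates * 2, wiggly_curve, padded_axis, n_sim=200).fit(seed=3)
        rng_span = r1.mean.max() - r1.mean.min()
        rms = np.sqrt(np.mean((r1.mean - r2.mean) ** 2))
        assert rms < 0.05 * rng_span

    def test_ensemble_size_stability_without_bootstrap(
        self, wiggly_curve, padded_axis, axis
    ):
        traj = PopulationTrajectory.exponential(axis, 0.001)
        dates, _ = simulate_dates(traj, 300, wiggly_curve,
                                  rng=np.random.default_rng(6))
        r1 = CompositeKDE(dates, wiggly_curve, padded_axis, n_sim=1000,
                          boot=False).fit(seed=10)
        r2 = CompositeKDE(dates, wiggly_curve, padded_axis, n_sim=2000,
                          boot=False).fit(seed=11)
        rng_span = r1.mean.max() - r1.mean.min()
        rms = np.sqrt(np.mean((r1.mean - r2.mean) ** 2))
        assert rms < 0.02 * rng_span

    def test_config_errors(self, wiggly_curve, padded_axis, toy_dates):
        with pytest.raises(ValueError):
            CompositeKDE(toy_dates[:1], wiggly_curve, padded_axis)
        with pytest.raises(ValueError):
            CompositeKDE(toy_dates, wiggly_curve, padded_axis, n_sim=1)

    def test_summary_mentions_parameters(self, wiggly_curve, padded_axis, toy_dates):
        res = CompositeKDE(toy_dates, wiggly_curve, padded_axis, n_sim=20).fit(seed=4)
        s = res.summary()
        assert "bandwidth" in s and "20 simulations" in s


class TestGrowth:
    def test_constant_curve_zero_growth(self):
        K = np.ones((3, 200))
        g = _growth_rows(K, 25)
        assert np.allclose(g, 0.0)

    def test_exponential_closed_form(self):
        r = 0.002
        t = np.arange(300, dtype=float)
        K = np.exp(r * t)[None, :]
        g = _growth_rows(K, 25)
        assert np.allclose(g, np.exp(r) - 1.0, atol=1e-12)

    def test_matches_cellwise_oracle(self, rng):
        K = rng.uniform(0.5, 2.0, size=(4, 120))
        w = 10
        g = _growth_rows(K, w)
        for i in range(4):
            for t in range(120 - w):
                expected = (K[i, t + w] / K[i, t]) ** (1 / w) - 1
                assert g[i, t] == pytest.approx(expected, rel=1e-12)

    def test_zero_cells_masked(self):
        K = np.array([[1.0, 0.0, 1.0, 1.0, 1.0]])
        g = _growth_rows(K, 1)
        assert np.isnan(g[0, 1]) and np.isfinite(g[0, 2])

    def test_from_kde_results(self, wiggly_curve, padded_axis, toy_dates):
        res = CompositeKDE(toy_dates, wiggly_curve, padded_axis, n_sim=30).fit(seed=5)
        g = kde_growth(res, window=25)
        assert isinstance(g, GrowthSeries)
        assert len(g.years_bce) == len(padded_axis) - 25
        ok = ~np.isnan(g.rate)
        assert np.all(g.envelope_lo[ok] <= g.envelope_hi[ok] + 1e-12)


class TestExponentialNull:
    def test_definitional_consistency(self, wiggly_curve, axis):
        # data drawn from an exponential: typically inside the envelope
        traj = PopulationTrajectory.exponential(axis, 0.0008)
        dates, _ = simulate_dates(traj, 150, wiggly_curve,
                                  rng=np.random.default_rng(8))
        res = ExponentialNullModel(dates, wiggly_curve, axis).fit(
            n_sim=100, seed=9
        )
        inside = np.all(
            (res.observed.value <= res.envelope_hi)
            & (res.observed.value >= res.envelope_lo)
        )
        if inside:
            assert res.deviation_intervals == []
            assert res.pvalue > 0.05
        # intervals, if any, must coincide with envelope exits
        for s, e, sign in res.deviation_intervals:
            idx = np.flatnonzero(
                (res.observed.axis.years_bce <= s)
                & (res.observed.axis.years_bce >= e)
            )
            if sign == "positive":
                assert np.all(res.observed.value[idx] > res.envelope_hi[idx])
            else:
                assert np.all(res.observed.value[idx] < res.envelope_lo[idx])

    def test_power_against_injected_boom(self, wiggly_curve, axis):
        # 3x boom over 150 years on a flat background
        traj = PopulationTrajectory.piecewise_boom_bust(
            axis, [(2850, 1700, 1.0), (2400, 2250, 3.0)]
        )
        dates, _ = simulate_dates(traj, 400, wiggly_curve,
                                  rng=np.random.default_rng(12))
        res = ExponentialNullModel(dates, wiggly_curve, axis).fit(
            n_sim=100, seed=13
        )
        pos = [iv for iv in res.deviation_intervals if iv[2] == "positive"]
        assert pos, "expected a positive deviation interval"
        overlaps = any(s >= 2250 and e <= 2400 for s, e, _ in pos)
        assert overlaps

    def test_needs_ten_dates(self, wiggly_curve, axis, toy_dates):
        with pytest.raises(ValueError):
            ExponentialNullModel(toy_dates[:5], wiggly_curve, axis)
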