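"""Arrhenius transform, broken-stick fitting and cardiac summaries."""

import numpy as np
import pandas as pd
import pytest

from allometherm import (CardiacSeries, DataError, GeneratorConfig,
                         arrhenius_transform, fit_breakpoint,
                         generate_cohort, simulate_cardiac_series,
                         summarize_cardiac)
from allometherm.cardiac import celsius_to_x, rising_limb, x_to_celsius


def make_series(temps, fhmax, arr_last=True, fish_id="C01"):
    flags = np.zeros(len(temps), dtype=bool)
    if arr_last:
        flags[-1] = True
    return CardiacSeries(fish_id, pd.DataFrame({
        "temp_c": np.asarray(temps, float),
        "fhmax_bpm": np.asarray(fhmax, float),
        "fhmax_sd": 1.0,
        "arrhythmia_flag": flags,
    }))


def grid_oracle(x, y, min_pts=3):
    """Independent exhaustive RSS search over the documented candidate
    protocol: per-interval midpoints + 50 uniform candidates, then a
    201-point refinement around the coarse winner."""
    xs = np.sort(np.asarray(x, float))
    ys = np.asarray(y, float)[np.argsort(x)]
    lo, hi = xs[min_pts - 1], xs[len(xs) - min_pts]

    def rss_at(c):
        X = np.column_stack([np.ones_like(xs), xs,
                             np.maximum(xs - c, 0.0)])
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        r = ys - X @ beta
        return float(r @ r)

    cands = []
    for a, b in zip(xs[:-1], xs[1:]):
        a_, b_ = max(a, lo), min(b, hi)
        if b_ <= a_:
            continue
        cands.extend(np.linspace(a_, b_, 52)[1:-1].tolist())
        cands.append(0.5 * (a_ + b_))
    grid = np.unique(np.array(cands))
    grid = grid[(grid > lo) & (grid < hi)]
    rss = np.array([rss_at(c) for c in grid])
    i = int(np.argmin(rss))
    fine = np.linspace(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)],
                       201)
    rss_f = np.array([rss_at(c) for c in fine])
    stacked = np.concatenate([grid, fine])
    rss_all = np.concatenate([rss, rss_f])
    return float(stacked[int(np.argmin(rss_all))])


class TestArrheniusTransform:
    def test_unit_conversion_and_log(self):
        series = make_series([16.0, 17.0], [100.0, 110.0], arr_last=False)
        x, y = arrhenius_transform(series)
        assert x[0] == pytest.approx(1000.0 / 289.15)
        assert y[0] == pytest.approx(np.log(100.0))
        # ordered by increasing temperature = decreasing x
        assert x[0] > x[1]

    def test_arrhythmic_observation_excluded(self):
        series = make_series(np.arange(16.0, 28.0),
                             np.linspace(80, 150, 12))
        x, _ = arrhenius_transform(series)
        assert len(x) == 11
        assert x.min() == pytest.approx(celsius_to_x(26.0))

    def test_nonpositive_fhmax_rejected(self):
        series = make_series([16.0, 17.0, 18.0], [100.0, -5.0, 120.0],
                             arr_last=False)
        with pytest.raises(DataError):
            arrhenius_transform(series)


class TestBreakpointFit:
    def test_exact_broken_line_recovered(self):
        temps = np.arange(16.0, 27.0)
        x = celsius_to_x(temps)
        x0 = celsius_to_x(21.3)
        y = 4.0 + 6.0 * (x.max() - x) - 4.4 * np.maximum(x0 - x, 0.0)
        fit = fit_breakpoint(x, y, seed=1)
        assert fit.identified
        assert fit.t_ab == pytest.approx(21.3, abs=0.02)
        assert fit.ci_halfwidth_c == pytest.approx(0.0, abs=1e-9)
        assert not fit.excluded

    def test_pure_line_not_identified(self):
        x = celsius_to_x(np.arange(16.0, 27.0))
        y = 4.0 + 5.0 * (x.max() - x)
        fit = fit_breakpoint(x, y, seed=2)
        assert not fit.identified
        assert fit.excluded and fit.exclusion_reason == "not_identified"

    def test_too_few_points_returns_not_identified(self):
        x = celsius_to_x(np.arange(16.0, 21.0))
        y = np.linspace(4.0, 4.5, 5)
        fit = fit_breakpoint(x, y, seed=3)
        assert not fit.identified
        assert fit.exclusion_reason == "too_few_points"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_grid_oracle(self, seed):
        cfg = GeneratorConfig(n_fish=4, seed=seed)
        for fish in generate_cohort(cfg):
            series, _ = simulate_cardiac_series(fish, cfg)
            x, y = rising_limb(*arrhenius_transform(series))
            if len(x) < 6:
                continue
            fit = fit_breakpoint(x, y, seed=seed)
            assert fit.breakpoint_x == pytest.approx(grid_oracle(x, y),
                                                     abs=1e-10)

    def test_zero_noise_recovery_of_latents(self):
        cfg = GeneratorConfig(n_fish=5, seed=9).zero_noise()
        for fish in generate_cohort(cfg):
            series, truth = simulate_cardiac_series(fish, cfg)
            x, y = rising_limb(*arrhenius_transform(series))
            fit = fit_breakpoint(x, y, seed=5)
            assert fit.identified
            assert fit.t_ab == pytest.approx(truth["t_ab"], abs=0.01)
            s = summarize_cardiac(series, fit)
            assert s.t_peak == truth["t_peak_grid"]
            assert s.t_arr == truth["t_arr_grid"]
            assert s.peak_fhmax == pytest.approx(truth["peak_fhmax_clean"])

    def test_lowering_ci_limit_never_includes_an_excluded_fit(self):
        cfg = GeneratorConfig(n_fish=10, seed=13)
        included = {limit: 0 for limit in (2.0, 1.5, 1.0, 0.5)}
        for fish in generate_cohort(cfg):
            series, _ = simulate_cardiac_series(fish, cfg)
            x, y = rising_limb(*arrhenius_transform(series))
            for limit in included:
                fit = fit_breakpoint(x, y, ci_limit_c=limit, seed=21)
                included[limit] += int(fit.identified and not fit.excluded)
        counts = [included[k] for k in sorted(included)]
        assert counts == sorted(counts)

    def test_bootstrap_ci_coverage_near_nominal(self):
        """Over >= 200 noisy series the 95% breakpoint CI should cover the
        latent T_AB in 90-99% of identified fits."""
        rng = np.random.default_rng(99)
        hits = n_id = n_series = 0
        for seed in range(7):
            cfg = GeneratorConfig(n_fish=30, seed=seed)
            for fish in generate_cohort(cfg):
                series, truth = simulate_cardiac_series(fish, cfg)
                n_series += 1
                x, y = rising_limb(*arrhenius_transform(series))
                if len(x) < 6:
                    continue
                fit = fit_breakpoint(x, y, n_boot=300, rng=rng)
                if fit.identified:
                    n_id += 1
                    lo, hi = fit.ci_celsius
                    hits += int(lo <= truth["t_ab"] <= hi)
        assert n_series >= 200
        coverage = hits / n_id
        assert 0.90 <= coverage <= 0.99


class TestCardiacSummary:
    def test_peak_and_arrhythmia_by_construction(self):
        temps = np.arange(16.0, 28.0)
        fh = np.concatenate([np.linspace(90, 150, 9),
                             [140.0, 130.0, 100.0]])
        s = summarize_cardiac(make_series(temps, fh))
        assert s.peak_fhmax == 150.0
        assert s.t_peak == 24.0
        assert s.t_arr == 27.0

    def test_monotone_series_peaks_at_last_pre_arrhythmia_step(self):
        temps = np.arange(16.0, 23.0)
        fh = np.linspace(90, 140, 7)
        s = summarize_cardiac(make_series(temps, fh))
        assert s.t_peak == 21.0

    def test_tie_resolved_to_lowest_temperature(self):
        temps = np.arange(20.0, 27.0)
        fh = [100, 110, 120, 150, 130, 150, 90]
        s = summarize_cardiac(make_series(temps, fh))
        assert s.t_peak == 23.0

    def test_invariants_on_generated_series(self):
        cfg = GeneratorConfig(n_fish=12, seed=31)
        for fish in generate_cohort(cfg):
            series, _ = simulate_cardiac_series(fish, cfg)
            s = summarize_cardiac(series)
            assert s.t_peak <= s.t_arr
            pre = series.pre_arrhythmia()["fhmax_bpm"]
            assert s.peak_fhmax >= pre.max() - 1e-12
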