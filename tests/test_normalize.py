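"""Trend fitting, MSD shift selection and whole-day re-indexing."""

import numpy as np
import pandas as pd
import pytest

from dapd.normalize import (DevelopmentalNormalizer, FitError, MSDProfile,
                            apply_shift, area_adjustment, daily_summary,
                            fit_leaf_trend, impute_series, msd_profile,
                            population_mean_trend, select_shift)
from dapd.series import TraitSeries


def make_series(das, leaf, area=None, plant_id="p"):
    das = np.asarray(das)
    leaf = np.asarray(leaf, dtype=float)
    area = np.full_like(leaf, np.nan) if area is None else np.asarray(area, float)
    return TraitSeries(plant_id=plant_id, das=das, leaf=leaf, area=area)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_msd(series, trend, k_range=(-7, 7), min_overlap=5):
    """Independent per-day loop over the MSD definition."""
    ks, msds, ns = [], [], []
    for k in range(k_range[0], k_range[1] + 1):
        sq = []
        for j, t in enumerate(trend.timeline):
            v = series.leaf_at(int(t) - k)
            if np.isfinite(v):
                d = v - trend.mean_leaf_trend[j]
                sq.append(d * d)
        if len(sq) >= min_overlap:
            ks.append(k)
            msds.append(np.mean(np.array(sq)))
            ns.append(len(sq))
    return ks, msds, ns


def brute_force_select(ks, msds):
    best = None
    for k, m in zip(ks, msds):
        key = (m, abs(k), k)
        if best is None or key < best:
            best = key
    return best[2]


def brute_force_delta(series, trend, s, delta_range=(-2, 2), min_overlap=5):
    best = None
    for d in range(delta_range[0], delta_range[1] + 1):
        sq = []
        for j, t in enumerate(trend.timeline):
            v = series.area_at(int(t) - s + d)
            ref = trend.mean_area_trend[j]
            if np.isfinite(v) and v > 0 and ref > 0:
                r = np.log(v) - np.log(ref)
                sq.append(r * r)
        if len(sq) >= min_overlap:
            key = (np.mean(np.array(sq)), abs(d), d)
            if best is None or key < best:
                best = key
    return 0 if best is None else best[2]


# ---------------------------------------------------------------------------


class TestDailySummary:
    def test_median_and_missing(self):
        frames = pd.DataFrame({
            "das": [12, 12, 12, 14],
            "time_of_day": [540, 720, 900, 720],
            "leaf_count": [4, 5, 5, 6],
            "area": [10.0, 12.0, 14.0, 20.0],
        })
        s = daily_summary(frames, timeline=(12, 14))
        assert s.leaf_at(12) == 5          # median of {4,5,5}
        assert s.area_at(12) == 12.0       # mean
        assert np.isnan(s.leaf_at(13))     # missing day flagged, not zero
        assert s.leaf_at(14) == 6


class TestImpute:
    def test_no_missing_identity(self):
        s = make_series(range(10, 20), np.arange(10.0, 20))
        out = impute_series(s, "spline")
        assert np.array_equal(out.leaf, s.leaf)

    def test_linear_gap_restored(self):
        leaf = np.arange(10.0, 20)
        leaf[4] = np.nan
        s = make_series(range(10, 20), leaf)
        out = impute_series(s, "spline")
        assert out.leaf[4] == pytest.approx(14.0, abs=1e-9)

    def test_exponential_gap_curve_fit(self):
        das = np.arange(10, 22)
        leaf = 2.0 * np.exp(0.2 * das)
        leaf[5] = np.nan
        s = make_series(das, leaf)
        out = impute_series(s, "curve_fit")
        assert out.leaf[5] == pytest.approx(2.0 * np.exp(0.2 * das[5]), rel=1e-6)

    def test_no_extrapolation(self):
        leaf = np.arange(10.0, 20)
        leaf[0] = np.nan
        s = make_series(range(10, 20), leaf)
        out = impute_series(s, "upsample")
        assert np.isnan(out.leaf[0])

    def test_too_few_points_rejected(self):
        leaf = np.full(6, np.nan)
        leaf[:3] = [2, 3, 4]
        with pytest.raises(FitError):
            impute_series(make_series(range(6), leaf), "spline")


class TestFitLeafTrend:
    def test_exact_exponential_recovery(self):
        das = np.arange(0, 11)
        s = make_series(das, 2.0 * np.exp(0.25 * das))
        m = fit_leaf_trend(s, leaf_range=(0.5, 100.0))
        assert m.a == pytest.approx(2.0, abs=1e-9)
        assert m.b == pytest.approx(0.25, abs=1e-9)
        assert m.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_series(self):
        s = make_series(range(5), [3.0] * 5)
        m = fit_leaf_trend(s)
        assert m.a == pytest.approx(3.0) and m.b == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        das = np.arange(10, 26)
        leaf = np.round(0.9 * np.exp(0.11 * (das - 1))
                        * (1 + rng.normal(0, 0.05, das.size)))
        s = make_series(das, np.clip(leaf, 1, None))
        m = fit_leaf_trend(s, leaf_range=(1.0, 50.0))
        # 200 x 200 grid over the log-space objective
        sel = (s.leaf >= 1) & (s.leaf <= 50)
        t, y = das[sel].astype(float), np.log(s.leaf[sel])
        a_grid = np.linspace(0.3, 2.5, 200)
        b_grid = np.linspace(0.01, 0.3, 200)
        obj = ((np.log(a_grid[:, None, None]) + b_grid[None, :, None] * t)
               - y) ** 2
        obj = obj.sum(axis=2)
        ia, ib = np.unravel_index(np.argmin(obj), obj.shape)
        assert m.a == pytest.approx(a_grid[ia], abs=np.diff(a_grid)[0])
        assert m.b == pytest.approx(b_grid[ib], abs=np.diff(b_grid)[0])

    def test_insufficient_points_rejected(self):
        with pytest.raises(FitError):
            fit_leaf_trend(make_series([1, 2], [3.0, 4.0]))


class TestPopulationTrend:
    def test_single_model_identity(self):
        s = make_series(np.arange(12), 2.0 * np.exp(0.1 * np.arange(12)))
        m = fit_leaf_trend(s, leaf_range=(0.1, 100.0))
        trend = population_mean_trend([m], np.arange(12))
        assert np.allclose(trend.mean_leaf_trend, s.leaf, rtol=1e-9)

    def test_two_constant_models_average(self):
        s1 = make_series(range(5), [1.0] * 5)
        s2 = make_series(range(5), [3.0] * 5)
        m1 = fit_leaf_trend(s1, leaf_range=(0.5, 10))
        m2 = fit_leaf_trend(s2, leaf_range=(0.5, 10))
        trend = population_mean_trend([m1, m2], np.arange(5))
        assert np.allclose(trend.mean_leaf_trend, 2.0)

    def test_matches_direct_summation(self, rng):
        models = [fit_leaf_trend(
            make_series(np.arange(15),
                        a * np.exp(b * np.arange(15))),
            leaf_range=(0.01, 1e6))
            for a, b in rng.uniform([0.5, 0.05], [2.0, 0.15], (5, 2))]
        tl = np.arange(15)
        trend = population_mean_trend(models, tl)
        direct = sum(m.a * np.exp(m.b * tl) for m in models) / 5
        assert np.allclose(trend.mean_leaf_trend, direct, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_mean_trend([], np.arange(5))


class TestMSDAndShift:
    def _trend(self):
        das = np.arange(12, 33)
        vals = 0.9 * np.exp(0.085 * das)
        from dapd.normalize import PopulationTrend
        return PopulationTrend(1, das, vals)

    def test_shifted_construction_zero_msd(self):
        trend = self._trend()
        das = np.arange(12, 33)
        series = make_series(das, 0.9 * np.exp(0.085 * (das + 3)))
        prof = msd_profile(series, trend, k_range=(-5, 5))
        at3 = prof.msd_values[prof.k_values == 3]
        assert at3[0] == pytest.approx(0.0, abs=1e-18)
        assert select_shift(prof) == 3

    def test_flat_profile_tie_breaks_to_zero(self):
        prof = MSDProfile(np.arange(-3, 4), np.ones(7), np.full(7, 10))
        assert select_shift(prof) == 0

    def test_symmetric_tie_prefers_negative(self):
        ks = np.array([-2, 2])
        prof = MSDProfile(ks, np.array([1.0, 1.0]), np.array([9, 9]))
        assert select_shift(prof) == -2

    def test_min_overlap_excludes_extreme_delays(self):
        trend = self._trend()
        das = np.arange(12, 33)
        series = make_series(das, 0.9 * np.exp(0.085 * das))
        prof = msd_profile(series, trend, k_range=(-20, 20), min_overlap=5)
        assert prof.k_values.min() >= -16 and prof.k_values.max() <= 16
        assert (prof.n_overlap >= 5).all()

    def test_oracle_equivalence_random_series(self, rng):
        """MSD values, shifts and area adjustments equal brute-force loops."""
        trend_das = np.arange(12, 33)
        from dapd.normalize import PopulationTrend
        for _ in range(100):
            a = rng.uniform(0.5, 1.5)
            b = rng.uniform(0.05, 0.12)
            trend = PopulationTrend(
                1, trend_das, a * np.exp(b * trend_das),
                mean_area_trend=5 * a * np.exp(2 * b * trend_das))
            das = np.arange(12, 33)
            leaf = np.round(np.clip(
                a * np.exp(b * das) * (1 + rng.normal(0, 0.1, das.size)),
                0, None))
            area = 5 * a * np.exp(2 * b * das) \
                * (1 + rng.normal(0, 0.1, das.size))
            drop = rng.random(das.size) < 0.1
            leaf[drop] = np.nan
            series = make_series(das, leaf, area)
            prof = msd_profile(series, trend)
            ks, msds, ns = brute_force_msd(series, trend)
            assert prof.k_values.tolist() == ks
            assert prof.msd_values.tolist() == msds  # exact float equality
            assert prof.n_overlap.tolist() == ns
            s = select_shift(prof)
            assert s == brute_force_select(ks, msds)
            d = area_adjustment(series, trend, s)
            assert d == brute_force_delta(series, trend, s)


class TestAreaAdjustment:
    def _trend(self):
        from dapd.normalize import PopulationTrend
        das = np.arange(12, 33)
        return PopulationTrend(1, das, 0.9 * np.exp(0.085 * das),
                               mean_area_trend=4.0 * np.exp(0.2 * das))

    def test_aligned_series_zero(self):
        trend = self._trend()
        das = np.arange(12, 33)
        s = make_series(das, np.ones(das.size), 4.0 * np.exp(0.2 * das))
        assert area_adjustment(s, trend, 0) == 0

    def test_offset_by_one_day(self):
        trend = self._trend()
        das = np.arange(12, 33)
        # area built from the trend at t - s - 1 with s = 0
        s = make_series(das, np.ones(das.size),
                        4.0 * np.exp(0.2 * (das - 1)))
        assert area_adjustment(s, trend, 0) == 1

    def test_insufficient_overlap_warns_zero(self):
        trend = self._trend()
        s = make_series([12, 13], [1.0, 1.0], [5.0, 6.0])
        with pytest.warns(UserWarning):
            assert area_adjustment(s, trend, 0, min_overlap=5) == 0


class TestApplyShift:
    def _series(self):
        das = np.arange(12, 33)
        sub = pd.DataFrame({
            "das": np.repeat(das, 2),
            "time_of_day": np.tile([600, 840], das.size),
            "leaf_count": np.repeat(np.arange(das.size, dtype=float), 2),
            "area": np.arange(das.size * 2, dtype=float),
        })
        return TraitSeries("p", das, np.arange(das.size, dtype=float),
                           np.arange(das.size, dtype=float) * 10, subdaily=sub)

    def test_identity(self):
        s = self._series()
        out = apply_shift(s, 0, 0)
        assert np.array_equal(out.leaf, s.leaf)
        assert np.array_equal(out.area, s.area)

    def test_reindexing_contract(self):
        s = self._series()
        out = apply_shift(s, 2, 0, reference_timeline=s.das)
        # normalized day 14 holds the value measured on day 12
        assert out.leaf_at(14) == s.leaf_at(12)
        kept = out.leaf[np.isfinite(out.leaf)]
        assert set(kept) <= set(s.leaf)  # values are a subset, never altered

    def test_area_delta_reindexing(self):
        s = self._series()
        out = apply_shift(s, 2, 1, reference_timeline=s.das)
        assert out.area_at(20) == s.area_at(19)   # t - s + delta = 20-2+1

    def test_subdaily_rows_preserved(self):
        s = self._series()
        out = apply_shift(s, 1, 0, reference_timeline=s.das)
        sub = out.subdaily
        orig = s.subdaily
        # a shifted day keeps its within-day pattern untouched
        day = 20
        got = sub[sub["das"] == day]["area"].to_numpy()
        exp = orig[orig["das"] == day - 1]["area"].to_numpy()
        assert np.array_equal(got, exp)


class TestNormalizer:
    def test_identical_plants_all_zero_shift(self):
        das = np.arange(12, 33)
        plants = [make_series(das, np.round(0.9 * np.exp(0.085 * das)),
                              4 * np.exp(0.2 * das), plant_id=f"p{i}")
                  for i in range(6)]
        norm = DevelopmentalNormalizer().fit(plants)
        assert all(sol.s == 0 for sol in norm.solutions_.values())
        out = norm.transform(plants)
        assert np.array_equal(out[0].leaf, plants[0].leaf, equal_nan=True)

    def test_known_shift_recovery(self, clean_population):
        dataset, shifts = clean_population
        norm = DevelopmentalNormalizer().fit(dataset)
        rec = np.array([norm.solutions_[s.plant_id].s for s in dataset])
        assert np.mean(rec == -shifts) >= 0.95

    def test_failed_fit_flagged_and_passed_through(self):
        das = np.arange(12, 33)
        good = [make_series(das, np.round(0.9 * np.exp(0.085 * das)),
                            4 * np.exp(0.2 * das), plant_id=f"g{i}")
                for i in range(4)]
        dead = make_series(das, np.zeros(das.size), np.zeros(das.size),
                           plant_id="dead")
        norm = DevelopmentalNormalizer().fit(good + [dead])
        assert "fit_failed" in norm.solutions_["dead"].flags
        out = norm.transform([dead])[0]
        assert out.flags["shift_s"] == 0

    def test_report_schema(self, small_population):
        dataset, _ = small_population
        norm = DevelopmentalNormalizer().fit(dataset)
        rep = norm.report()
        assert list(rep.columns) == ["plant_id", "s", "delta_t", "min_msd",
                                     "flags"]
        assert len(rep) == len(dataset)

    def test_sklearn_params_roundtrip(self):
        norm = DevelopmentalNormalizer(k_range=(-5, 5), n_refine=2)
        params = norm.get_params()
        assert params["k_range"] == (-5, 5)
        norm.set_params(min_overlap=6)
        assert norm.min_overlap == 6
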