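import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest

from microscape.homerange import (
    TelemetryTrack,
    UtilizationDistribution,
    activity_metrics,
    kde_homerange,
    load_telemetry,
    mwu_test,
    overlap_matrix,
    reference_bandwidth,
    write_telemetry,
)

# Table of nine desert kangaroo-rat home ranges (ha) used as a worked input
MALE_AREAS = [0.441, 0.328, 0.277, 2.652, 0.271, 0.204]
FEMALE_AREAS = [0.150, 0.341]


def track(xs, ys, iid="R1", sex="M", start=None):
    start = start or datetime(2017, 6, 1, 21, 0)
    stamps = [start + timedelta(minutes=30 * k) for k in range(len(xs))]
    return TelemetryTrack(iid, sex, np.asarray(xs, float),
                          np.asarray(ys, float), stamps)


def normal_track(n, sigma=10.0, seed=0, center=(0.0, 0.0), **kw):
    rng = np.random.default_rng(seed)
    return track(rng.normal(center[0], sigma, n), rng.normal(center[1], sigma, n),
                 **kw)


class TestBandwidth:
    def test_reference_formula(self):
        # sample sd exactly 4 in both axes, n = 64 -> h = 4 * 64^(-1/6) = 2
        n = 64
        c = 4.0 * np.sqrt((n - 1) / n)
        base = np.tile([1.0, -1.0], n // 2)
        x = c * base
        y = c * base[::-1]
        assert np.std(x, ddof=1) == pytest.approx(4.0)
        assert reference_bandwidth(x, y) == pytest.approx(2.0, rel=1e-12)


class TestKdeHomerange:
    def test_ud_integrates_to_one(self):
        t = normal_track(50, seed=1)
        ud, _ = kde_homerange(t)
        total = ud.density.values.sum() * ud.density.cell_size**2
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_area_closed_form(self):
        # 95% region of an isotropic normal has area 5.991 * pi * sigma^2
        t = normal_track(1000, sigma=10.0, seed=2)
        _, hr = kde_homerange(t, level=0.95)
        expected_m2 = 5.991 * np.pi * 100.0
        assert hr.area_ha * 1e4 == pytest.approx(expected_m2, rel=0.15)

    def test_isopleth_areas_nested(self):
        t = normal_track(200, seed=3)
        ud, hr95 = kde_homerange(t, level=0.95)
        _, hr50 = kde_homerange(t, level=0.50)
        assert hr50.area_ha < hr95.area_ha
        assert ud.isopleth_mask(0.5).sum() < ud.isopleth_mask(0.95).sum()

    def test_minimum_fixes_and_zero_variance(self):
        with pytest.raises(ValueError, match="5 fixes"):
            kde_homerange(track([0, 1, 2], [0, 1, 2]))
        with pytest.raises(ValueError, match="identical"):
            kde_homerange(track([1] * 6, [2] * 6))

    def test_area_grows_with_dispersion(self):
        areas = []
        for sigma in (5.0, 10.0, 20.0):
            vals = [kde_homerange(normal_track(60, sigma=sigma, seed=s))[1].area_ha
                    for s in range(4)]
            areas.append(np.mean(vals))
        assert areas[0] < areas[1] < areas[2]


class TestOverlap:
    def test_identical_uds_100_percent(self):
        t = normal_track(40, seed=4)
        ud, _ = kde_homerange(t)
        ud2 = UtilizationDistribution("R2", ud.density, ud.h, ud.fixes)
        out = overlap_matrix([ud, ud2])
        assert out.loc["R1", "R2"] == pytest.approx(100.0)
        assert out.loc["R2", "R1"] == pytest.approx(100.0)
        assert out.loc["R1", "R1"] == 100.0

    def test_disjoint_ranges_zero(self):
        a, _ = kde_homerange(normal_track(40, sigma=5, seed=5, iid="A"))
        b, _ = kde_homerange(
            normal_track(40, sigma=5, seed=6, center=(5000, 5000), iid="B")
        )
        out = overlap_matrix([a, b])
        assert out.loc["A", "B"] == 0.0
        assert out.loc["B", "A"] == 0.0

    def test_nested_rectangles_oracle(self):
        # uniform densities on constructed rectangles: B inside A with half
        # A's area -> overlap(B->A) = 100, overlap(A->B) = 50
        class RectUD(UtilizationDistribution):
            def __init__(self, iid, x0, x1, y0, y1):
                from microscape.surfaces import GridSurface

                dens = GridSurface(np.ones((4, 4)), 5.0, origin=(x0, y1))
                super().__init__(iid, dens, 1.0,
                                 np.array([[x0, y0], [x1, y1]]))
                self.box = (x0, x1, y0, y1)

            def evaluate(self, x, y):
                x0, x1, y0, y1 = self.box
                inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
                return inside / ((x1 - x0) * (y1 - y0))

        a = RectUD("A", 0.0, 40.0, 0.0, 40.0)
        b = RectUD("B", 0.0, 40.0, 0.0, 20.0)
        out = overlap_matrix([a, b], level=0.95)
        assert out.loc["B", "A"] == pytest.approx(100.0, abs=3.0)
        assert out.loc["A", "B"] == pytest.approx(50.0, abs=3.0)

    def test_asymmetry_tight_inside_broad(self):
        broad, _ = kde_homerange(normal_track(80, sigma=30, seed=7, iid="A"))
        tight, _ = kde_homerange(normal_track(80, sigma=3, seed=8, iid="B"))
        out = overlap_matrix([broad, tight])
        assert out.loc["B", "A"] > 95.0
        assert out.loc["A", "B"] < 50.0


class TestActivity:
    def test_collinear_equal_steps(self):
        t = track(np.arange(6) * 5.0, np.zeros(6))
        steps = activity_metrics(t)
        assert np.allclose(steps["distance_m"], 5.0)

    def test_three_four_five_triangle(self):
        t = track([0.0, 30.0, 30.0], [0.0, 40.0, 40.0])
        steps = activity_metrics(t)
        assert steps["distance_m"].tolist() == [50.0, 0.0]
        night_max = steps[steps["is_night_max"]]
        assert night_max["distance_m"].iloc[0] == 50.0

    def test_steps_do_not_cross_nights(self):
        stamps = [datetime(2017, 6, 1, 22, 0), datetime(2017, 6, 1, 23, 0),
                  datetime(2017, 6, 2, 22, 0)]
        t = TelemetryTrack("R1", "M", np.array([0.0, 3.0, 100.0]),
                           np.array([0.0, 4.0, 0.0]), stamps)
        steps = activity_metrics(t)
        assert len(steps) == 1  # only the within-night step
        assert steps["distance_m"].iloc[0] == 5.0

    def test_midnight_crossing_same_night(self):
        stamps = [datetime(2017, 6, 1, 23, 30), datetime(2017, 6, 2, 0, 30)]
        t = TelemetryTrack("R1", "M", np.array([0.0, 6.0]),
                           np.array([0.0, 8.0]), stamps)
        steps = activity_metrics(t)
        assert len(steps) == 1
        assert steps["distance_m"].iloc[0] == 10.0

    def test_timestamps_must_increase(self):
        stamps = [datetime(2017, 6, 1, 22, 0)] * 2
        with pytest.raises(ValueError, match="increasing"):
            TelemetryTrack("R1", "M", np.zeros(2), np.zeros(2), stamps)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mwu_test([10, 11, 12], [1, 2])
        assert res["U_a"] == 6.0
        assert res["U"] == 0.0

    def test_home_range_table_enumeration(self):
        # direct pair counting: 6 male vs 2 female areas, U_male = 8
        res = mwu_test(MALE_AREAS, FEMALE_AREAS)
        count = sum(m > f for m, f in itertools.product(MALE_AREAS,
                                                        FEMALE_AREAS))
        assert count == 8
        assert res["U_a"] == 8.0
        assert res["U"] == 4.0

    def test_exact_matches_brute_force(self):
        a = [3.1, 5.2, 7.9]
        b = [1.0, 4.4, 6.2, 8.8, 9.9]
        res = mwu_test(a, b)
        # brute force: all assignments of ranks to group a; counting
        # min(U_a, U_b) <= observed covers both tails at once
        vals = np.array(a + b)
        na = len(a)
        ranks = np.argsort(np.argsort(vals)) + 1
        u_obs = res["U"]
        count = total = 0
        for combo in itertools.combinations(range(len(vals)), na):
            ra = ranks[list(combo)].sum()
            ua = ra - na * (na + 1) / 2
            u = min(ua, na * len(b) - ua)
            total += 1
            count += u <= u_obs
        assert res["p"] == pytest.approx(count / total, abs=1e-9)

    def test_scipy_cross_check(self):
        from scipy.stats import mannwhitneyu

        a = [0.3, 1.2, 2.2, 3.3, 4.1]
        b = [0.9, 1.8, 2.9, 5.5]
        ours = mwu_test(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours["U_a"] == ref.statistic
        assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])


def test_telemetry_round_trip(tmp_path):
    tracks = [normal_track(8, seed=1, iid="R1", sex="M"),
              normal_track(8, seed=2, iid="R2", sex="F")]
    path = tmp_path / "tel.csv"
    write_telemetry(tracks, path)
    back = load_telemetry(path)
    assert [t.individual_id for t in back] == ["R1", "R2"]
    assert np.allclose(back[0].x, tracks[0].x)
    assert back[0].timestamps == tracks[0].timestamps
    assert back[1].sex == "F"
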