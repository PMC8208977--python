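import numpy as np
import pandas as pd
import pytest

import elemove as em
from elemove.metrics import _coverage
from tests.conftest import make_trajectory


def steps_frame(times, lengths, states=None):
    df = pd.DataFrame(
        {
            "individual_id": "a",
            "burst": 0,
            "t_local": pd.to_datetime(times),
            "length": np.asarray(lengths, dtype=float),
            "angle": np.nan,
            "zero_flag": False,
        }
    )
    if states is not None:
        df["state"] = states
    return df


class TestMovementDistance:
    def test_collinear_fixes(self):
        tr = em.segment_bursts(
            em.Trajectory(
                "a",
                fixes=pd.DataFrame(
                    {
                        "t_utc": pd.date_range("2016-01-01", periods=3, freq="h"),
                        "t_local": pd.date_range("2016-01-01", periods=3, freq="h"),
                        "x": [0.0, 1000.0, 2000.0],
                        "y": 0.0,
                        "burst": -1,
                    }
                ),
            )
        )
        assert em.movement_distance(em.build_step_series(tr)) == pytest.approx(2.0)

    def test_square_loop_perimeter(self):
        coords = [(0, 0), (1000, 0), (1000, 1000), (0, 1000), (0, 0)]
        t = pd.date_range("2016-01-01", periods=5, freq="h")
        x, y = zip(*coords)
        tr = em.segment_bursts(
            em.Trajectory(
                "a",
                fixes=pd.DataFrame(
                    {"t_utc": t, "t_local": t, "x": x, "y": y, "burst": -1}
                ),
            )
        )
        assert em.movement_distance(em.build_step_series(tr)) == pytest.approx(4.0)

    def test_stationary_is_zero(self):
        s = steps_frame(["2016-01-01 00:00", "2016-01-01 01:00"], [0.0, 0.0])
        assert em.movement_distance(s) == 0.0

    def test_empty_is_missing(self):
        assert np.isnan(em.movement_distance(steps_frame([], [])))


class TestReferenceBandwidth:
    def test_unit_variance_closed_form(self):
        # n = 64 points with per-axis sample variance exactly 1
        base = np.array([-1.0, 1.0] * 32)
        scale = np.sqrt(1.0 / np.var(base, ddof=1))
        pts = np.column_stack([base * scale, np.roll(base, 1) * scale])
        assert em.reference_bandwidth(pts) == pytest.approx(64 ** (-1 / 6.0))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 100, (50, 2))
        assert em.reference_bandwidth(2 * pts) == pytest.approx(
            2 * em.reference_bandwidth(pts)
        )

    def test_agrees_with_formula_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 200))
            pts = rng.normal(0, rng.uniform(10, 2000), (n, 2))
            expected = np.sqrt(
                0.5 * (np.var(pts[:, 0], ddof=1) + np.var(pts[:, 1], ddof=1))
            ) * n ** (-1 / 6.0)
            assert em.reference_bandwidth(pts) == pytest.approx(expected, rel=1e-12)

    def test_identical_points_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            em.reference_bandwidth(np.zeros((10, 2)))


class TestKdeHomeRange:
    def test_gaussian_cloud_matches_analytic_area(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(0, 1000.0, (10_000, 2))
        hr = em.kde_home_range(pts, h=150.0)
        analytic = -2 * np.log(0.05) * np.pi * 1.0  # km^2 at sigma = 1 km
        assert hr.area_km2 == pytest.approx(analytic, rel=0.10)

    def test_isopleth_monotone(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 500.0, (500, 2))
        a95 = em.kde_home_range(pts, h=200.0, isopleth=0.95).area_km2
        a50 = em.kde_home_range(pts, h=200.0, isopleth=0.50).area_km2
        assert a95 >= a50

    def test_translation_invariance_on_lattice(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 400.0, (300, 2))
        hr0 = em.kde_home_range(pts, h=200.0, cell=250.0)
        hr1 = em.kde_home_range(pts + np.array([2500.0, -5000.0]), h=200.0, cell=250.0)
        assert hr1.area_km2 == pytest.approx(hr0.area_km2)
        shifted = {(ix + 10, iy - 20) for ix, iy in hr0.cells}
        assert shifted == set(hr1.cells)

    def test_area_increases_with_bandwidth(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 400.0, (200, 2))
        areas = [em.kde_home_range(pts, h=h).area_km2 for h in (100.0, 300.0, 900.0)]
        assert areas[0] < areas[1] < areas[2]

    def test_mass_normalisation(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 300.0, (100, 2))
        hr = em.kde_home_range(pts, h=150.0, keep_grid=True)
        # density integrates to ~1 over the padded grid
        total = (hr.grid["density"] * hr.cell**2).sum()
        assert total == pytest.approx(1.0, abs=0.02)
        inside = hr.grid["mass"].nlargest(len(hr.cells)).sum()
        assert inside >= 0.95

    def test_bad_inputs(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        with pytest.raises(Exception):
            em.kde_home_range(pts, h=-1.0)
        with pytest.raises(ValueError):
            em.kde_home_range(np.zeros((1, 2)), h=100.0)


class TestSiteFidelity:
    def _hr(self, cells, cell=250.0):
        return em.HomeRange(
            individual_id="a", label="m", h=100.0, cell=cell,
            isopleth=0.95, cells=frozenset(cells), n_points=10,
        )

    def test_identical_ranges(self):
        hr = self._hr({(0, 0), (1, 0), (0, 1)})
        assert em.site_fidelity(hr, hr) == 1.0

    def test_disjoint_ranges(self):
        a = self._hr({(0, 0), (1, 0)})
        b = self._hr({(10, 10), (11, 10)})
        assert em.site_fidelity(a, b) == 0.0

    def test_half_overlap(self):
        prev = self._hr({(0, 0), (1, 0), (0, 1), (1, 1)})  # unit square (4 cells)
        curr = self._hr({(1, 0), (1, 1)})  # right half
        assert em.site_fidelity(curr, prev) == pytest.approx(0.5)

    def test_symmetric_option(self):
        prev = self._hr({(0, 0), (1, 0)})
        curr = self._hr({(1, 0), (2, 0)})
        assert em.site_fidelity(curr, prev, symmetric=True) == pytest.approx(1 / 3)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            em.site_fidelity(self._hr({(0, 0)}), self._hr({(0, 0)}, cell=500.0))

    def test_wkt_export_geometry_area(self):
        from shapely import wkt as shapely_wkt

        hr = self._hr({(0, 0), (1, 0), (0, 1)})
        geom = shapely_wkt.loads(hr.to_wkt())
        assert geom.area == pytest.approx(3 * 250.0**2)


class TestDiurnality:
    def test_exclusively_diurnal_is_plus_one(self):
        times = [f"2016-01-01 {h:02d}:00" for h in range(24)]
        lengths = [1000.0 if 6 <= h < 18 else 0.0 for h in range(24)]
        assert em.diurnality(steps_frame(times, lengths)) == 1.0

    def test_exclusively_nocturnal_is_minus_one(self):
        times = [f"2016-01-01 {h:02d}:00" for h in range(24)]
        lengths = [0.0 if 6 <= h < 18 else 1000.0 for h in range(24)]
        assert em.diurnality(steps_frame(times, lengths)) == -1.0

    def test_three_to_one_ratio(self):
        s = steps_frame(
            ["2016-01-01 10:00", "2016-01-01 20:00"], [3000.0, 1000.0]
        )
        assert em.diurnality(s) == pytest.approx(0.5)

    def test_boundary_hours(self):
        # 06:00 is day; 18:00 is night
        s = steps_frame(["2016-01-01 06:00", "2016-01-01 18:00"], [1.0, 1.0])
        assert em.diurnality(s) == pytest.approx(0.0)

    def test_zero_movement_days_missing(self):
        s = steps_frame(["2016-01-01 10:00"], [0.0])
        assert np.isnan(em.diurnality(s))

    def test_averaged_across_days(self):
        s = steps_frame(
            ["2016-01-01 10:00", "2016-01-02 22:00"], [1000.0, 1000.0]
        )
        assert em.diurnality(s) == pytest.approx(0.0)  # (+1 and -1)/2

    def test_bounds_on_random_windows(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            t0 = pd.Timestamp("2016-01-01") + pd.to_timedelta(
                rng.integers(0, 24 * 30), unit="h"
            )
            s = steps_frame(
                t0 + pd.to_timedelta(np.arange(n), unit="h"),
                rng.gamma(1.0, 500.0, n),
            )
            d = em.diurnality(s)
            assert -1.0 <= d <= 1.0


class TestExploratoryProportion:
    def test_all_exploratory(self):
        assert em.exploratory_proportion(np.ones(10, dtype=int)) == 1.0

    def test_counting(self):
        states = np.array([1, 1, 1] + [0] * 9)
        assert em.exploratory_proportion(states) == 0.25

    def test_complement_sums_to_one(self):
        rng = np.random.default_rng(4)
        states = rng.integers(0, 2, 100)
        p = em.exploratory_proportion(states)
        q = np.mean(states == 0)
        assert p + q == pytest.approx(1.0)

    def test_empty_missing(self):
        assert np.isnan(em.exploratory_proportion(np.array([])))


@pytest.fixture(scope="module")
def population():
    """Three individuals tracked gap-free across all of 2016."""
    trajs = [
        make_trajectory(24 * 366, start="2016-01-01", seed=i, individual_id=f"e{i}")
        for i in range(3)
    ]
    p = em.HmmParams(mu=[100, 1000], sigma=[80, 600], kappa=[0.5, 2.0])
    steps = em.pool_step_series([em.build_step_series(t) for t in trajs])
    steps["state"] = em.viterbi_decode(p, steps)
    return trajs, steps


class TestAssembleBehaviorTable:
    def test_monthly_record_counts_and_bounds(self, population):
        trajs, steps = population
        tab = em.assemble_behavior_table(trajs, steps, scale="monthly")
        # the 12 months of 2016; the single 2017-01-01 00:00 fix is excluded
        assert set(tab["individual_id"]) == {"e0", "e1", "e2"}
        assert len(tab) == 3 * 12
        assert tab["site_fidelity"].dropna().between(0, 1).all()
        assert tab["diurnality"].dropna().between(-1, 1).all()
        assert tab["exploratory_prop"].dropna().between(0, 1).all()
        # first month of each individual has no preceding range
        firsts = tab.sort_values("window").groupby("individual_id").nth(0)
        assert firsts["site_fidelity"].isna().all()

    def test_annual_requires_full_calendar_year(self, population):
        trajs, steps = population
        tab = em.assemble_behavior_table(trajs, steps, scale="annual")
        assert (tab["window"] == "2016").all()
        assert len(tab) == 3

    def test_monthly_distances_sum_to_annual(self, population):
        trajs, steps = population
        monthly = em.assemble_behavior_table(trajs, steps, scale="monthly")
        annual = em.assemble_behavior_table(trajs, steps, scale="annual")
        for ind in ("e0", "e1", "e2"):
            m2016 = monthly[
                (monthly["individual_id"] == ind)
                & monthly["window"].str.startswith("2016")
            ]
            a = annual.loc[annual["individual_id"] == ind, "distance_km"].iloc[0]
            assert m2016["distance_km"].sum() == pytest.approx(a, rel=1e-12)

    def test_fidelity_requires_successive_months(self):
        # months Jan, Feb, Apr: fidelity defined for Feb only
        pieces = []
        for start, hours in (("2016-01-01", 744), ("2016-02-01", 696), ("2016-04-01", 720)):
            tr = make_trajectory(hours - 1, start=start, seed=1, individual_id="e0")
            pieces.append(tr.fixes)
        f = pd.concat(pieces, ignore_index=True)
        f["burst"] = -1
        tr = em.segment_bursts(
            em.Trajectory("e0", sex="female", region="r", fixes=f)
        )
        steps = em.build_step_series(tr)
        steps["state"] = 0
        tab = em.assemble_behavior_table([tr], steps, scale="monthly")
        by_window = tab.set_index("window")["site_fidelity"]
        assert np.isnan(by_window["2016-01"])
        assert not np.isnan(by_window["2016-02"])
        assert np.isnan(by_window["2016-04"])

    def test_low_coverage_months_excluded(self):
        tr = make_trajectory(24 * 40, start="2016-01-01", seed=3)
        # keep only the first 5 days of February: ~17% coverage
        f = tr.fixes
        feb = f["t_local"].dt.to_period("M").astype(str) == "2016-02"
        keep = ~feb | (f["t_local"] < pd.Timestamp("2016-02-06"))
        tr2 = em.segment_bursts(
            em.Trajectory("e1", fixes=f[keep].reset_index(drop=True).assign(burst=-1))
        )
        steps = em.build_step_series(tr2)
        steps["state"] = 0
        tab = em.assemble_behavior_table([tr2], steps, scale="monthly")
        assert "2016-02" not in set(tab["window"])
        reasons = [e["reason"] for e in tab.attrs["exclusions"]]
        assert any("coverage" in r for r in reasons)

    def test_h_override(self, population):
        trajs, steps = population
        tab = em.assemble_behavior_table(
            trajs, steps, scale="monthly", h_override=920.0
        )
        assert tab.attrs["h_used"] == 920.0


def test_coverage_helper():
    p = pd.Period("2016-02", "M")  # 696 h (leap February)
    t = pd.Series(pd.date_range("2016-02-01", periods=348, freq="h"))
    assert _coverage(t, p) == pytest.approx(0.5)
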