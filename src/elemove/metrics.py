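"""The five movement behaviors, per individual per time step.

* movement distance — summed Euclidean displacement (km)
* home range — area of the 95% isopleth of a fixed-bandwidth bivariate
  normal kernel density estimate (km^2)
* site fidelity — proportion of the previous time step's range overlapped
  by the current one
* diurnality — (day - night)/total daily distance, day = 06:00-18:00
  local, averaged over days; +1 exclusively diurnal, -1 nocturnal
* exploratory behavior — proportion of decoded steps in the exploratory
  state

Home-range grids are aligned to absolute multiples of the cell size, so
the 95% regions of different time steps of one individual live on a
common lattice and overlap is a plain cell-set intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import ConfigurationError, Trajectory

logger = logging.getLogger("elemove")

DAY_START_HOUR = 6
DAY_END_HOUR = 18


# ---------------------------------------------------------------------------
# home ranges

@dataclass
class HomeRange:
    """95% (by default) kernel-density region as a set of grid cells.

    ``cells`` holds (ix, iy) indices on the absolute lattice with spacing
    ``cell`` metres; cell (ix, iy) covers [ix*cell, (ix+1)*cell) x
    [iy*cell, (iy+1)*cell).
    """

    individual_id: str
    label: str
    h: float
    cell: float
    isopleth: float
    cells: frozenset
    n_points: int
    grid: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def area_km2(self) -> float:
        return len(self.cells) * self.cell**2 / 1e6

    def contains(self, x, y) -> np.ndarray:
        ix = np.floor(np.asarray(x, dtype=float) / self.cell).astype(int)
        iy = np.floor(np.asarray(y, dtype=float) / self.cell).astype(int)
        return np.fromiter(
            ((a, b) in self.cells for a, b in zip(ix.ravel(), iy.ravel())),
            dtype=bool,
            count=ix.size,
        ).reshape(ix.shape)

    def to_wkt(self) -> str:
        """Well-known-text geometry of the region (union of its cells)."""
        from shapely import box, unary_union

        polys = [
            box(ix * self.cell, iy * self.cell,
                (ix + 1) * self.cell, (iy + 1) * self.cell)
            for ix, iy in self.cells
        ]
        return unary_union(polys).wkt


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth h = sigma * n^(-1/6).

    ``sigma`` is the square root of the mean of the two coordinate
    (sample) variances.  This is the per-window h; the pipeline then
    fixes a single h per temporal scale as the mean over all windows.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    vx = np.var(pts[:, 0], ddof=1)
    vy = np.var(pts[:, 1], ddof=1)
    if vx + vy <= 0:
        raise ValueError("all points identical: zero variance")
    return float(np.sqrt(0.5 * (vx + vy)) * len(pts) ** (-1.0 / 6.0))


def kde_home_range(
    points: np.ndarray,
    h: float,
    cell: float = 250.0,
    isopleth: float = 0.95,
    individual_id: str = "",
    label: str = "",
    keep_grid: bool = False,
) -> HomeRange:
    """Home range: smallest set of highest-density cells holding ``isopleth`` mass.

    A bivariate normal kernel of SD ``h`` (metres) is evaluated at the
    centres of all lattice cells within 3h of the point bounding box; the
    separable kernel makes the evaluation a single matrix product.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    if h <= 0:
        raise ConfigurationError("bandwidth h must be positive")
    if not 0 < isopleth < 1:
        raise ConfigurationError("isopleth must lie in (0, 1)")
    pad = 3.0 * h
    ix0 = int(np.floor((pts[:, 0].min() - pad) / cell))
    ix1 = int(np.floor((pts[:, 0].max() + pad) / cell))
    iy0 = int(np.floor((pts[:, 1].min() - pad) / cell))
    iy1 = int(np.floor((pts[:, 1].max() + pad) / cell))
    cx = (np.arange(ix0, ix1 + 1) + 0.5) * cell
    cy = (np.arange(iy0, iy1 + 1) + 0.5) * cell
    # separable kernel: density = A @ B.T with per-axis Gaussian factors
    ax = np.exp(-((cx[:, None] - pts[None, :, 0]) ** 2) / (2 * h * h))
    by = np.exp(-((cy[:, None] - pts[None, :, 1]) ** 2) / (2 * h * h))
    dens = ax @ by.T  # (nx, ny), unnormalised
    total = dens.sum()
    if total <= 0:
        raise FloatingPointError("kernel density vanished on the grid")
    mass = (dens / total).ravel()
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, isopleth) + 1)
    sel = order[:k]
    nx, ny = dens.shape
    sel_ix = ix0 + sel // ny
    sel_iy = iy0 + sel % ny
    grid = None
    if keep_grid:
        gx, gy = np.meshgrid(np.arange(ix0, ix1 + 1), np.arange(iy0, iy1 + 1), indexing="ij")
        grid = pd.DataFrame(
            {
                "ix": gx.ravel(),
                "iy": gy.ravel(),
                "density": dens.ravel() / (len(pts) * 2 * np.pi * h * h),
                "mass": mass,
            }
        )
    return HomeRange(
        individual_id=individual_id,
        label=label,
        h=float(h),
        cell=float(cell),
        isopleth=float(isopleth),
        cells=frozenset(zip(sel_ix.tolist(), sel_iy.tolist())),
        n_points=len(pts),
        grid=grid,
    )


def site_fidelity(hr_t: HomeRange, hr_prev: HomeRange, symmetric: bool = False) -> float:
    """Overlap of consecutive ranges: area(t AND t-1) / area(t-1).

    ``symmetric=True`` uses intersection over union instead.
    """
    if hr_t.cell != hr_prev.cell:
        raise ValueError("home ranges must share a grid geometry (equal cell size)")
    inter = len(hr_t.cells & hr_prev.cells)
    denom = len(hr_t.cells | hr_prev.cells) if symmetric else len(hr_prev.cells)
    if denom == 0:
        return float("nan")
    return inter / denom


# ---------------------------------------------------------------------------
# scalar behaviors

def movement_distance(steps: pd.DataFrame) -> float:
    """Total path length (km): sum of step lengths; never bridges bursts."""
    if len(steps) == 0:
        logger.info("movement_distance: no steps in window")
        return float("nan")
    return float(steps["length"].sum() / 1000.0)


def diurnality(
    steps: pd.DataFrame, day_start: int = DAY_START_HOUR, day_end: int = DAY_END_HOUR
) -> float:
    """Daily (day - night)/total distance, averaged over days with movement.

    A step is day or night by the local clock hour of its start fix;
    daytime is [day_start, day_end).  Days with zero total distance are
    skipped; the index is NaN if no day moved.
    """
    if len(steps) == 0:
        return float("nan")
    hours = pd.DatetimeIndex(steps["t_local"]).hour
    is_day = (hours >= day_start) & (hours < day_end)
    df = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(steps["t_local"]).date,
            "day_len": np.where(is_day, steps["length"], 0.0),
            "night_len": np.where(~is_day, steps["length"], 0.0),
        }
    )
    g = df.groupby("date", sort=False).sum()
    tot = g["day_len"] + g["night_len"]
    moved = tot > 0
    if not moved.any():
        logger.info("diurnality: all days have zero distance")
        return float("nan")
    d = (g.loc[moved, "day_len"] - g.loc[moved, "night_len"]) / tot[moved]
    return float(d.mean())


def exploratory_proportion(states: np.ndarray) -> float:
    """Fraction of decoded steps in the exploratory state (1)."""
    states = np.asarray(states)
    if states.size == 0:
        return float("nan")
    return float(np.mean(states == 1))


# ---------------------------------------------------------------------------
# table assembly

def _coverage(t_local: pd.Series, period: pd.Period) -> float:
    """Fraction of hours in the period with at least one fix."""
    hours_with_fix = pd.DatetimeIndex(t_local).floor("h").nunique()
    n_hours = int((period.end_time - period.start_time) / pd.Timedelta(hours=1)) + 1
    return hours_with_fix / n_hours


def assemble_behavior_table(
    trajs: list[Trajectory],
    steps: pd.DataFrame,
    scale: str = "monthly",
    rasters: dict | None = None,
    min_coverage: float = 0.5,
    h_override: float | None = None,
    cell: float = 250.0,
    isopleth: float = 0.95,
    symmetric_overlap: bool = False,
) -> pd.DataFrame:
    """One row of the five behaviors per individual x time step.

    ``steps`` is the pooled, Viterbi-decoded step series (column
    ``state``).  Inclusion: monthly windows need at least ``min_coverage``
    of their hours holding a fix; annual windows need every month of a
    calendar year to meet that bar.  Site fidelity is defined only for a
    window directly following a retained window.  The kernel bandwidth is
    fixed across windows at the scale level: the mean of the per-window
    reference bandwidths, unless ``h_override`` gives the value directly.
    Excluded windows are logged and listed in ``result.attrs["exclusions"]``.
    """
    if scale not in ("monthly", "annual"):
        raise ConfigurationError("scale must be 'monthly' or 'annual'")
    freq = "M" if scale == "monthly" else "Y"
    exclusions: list[dict] = []
    windows: list[dict] = []

    for tr in trajs:
        f = tr.fixes
        t_local = pd.DatetimeIndex(f["t_local"])
        periods = t_local.to_period("M")
        month_cov = {
            p: _coverage(f.loc[periods == p, "t_local"], p) for p in periods.unique()
        }
        if scale == "monthly":
            candidates = sorted(month_cov)
            ok = []
            for p in candidates:
                if month_cov[p] >= min_coverage:
                    ok.append(p)
                else:
                    exclusions.append(
                        {
                            "individual_id": tr.individual_id,
                            "window": str(p),
                            "reason": f"coverage {month_cov[p]:.2f} < {min_coverage}",
                        }
                    )
        else:
            years = sorted({p.year for p in month_cov})
            ok = []
            for yr in years:
                months = [pd.Period(f"{yr}-{m:02d}", "M") for m in range(1, 13)]
                if all(month_cov.get(m, 0.0) >= min_coverage for m in months):
                    ok.append(pd.Period(str(yr), "Y"))
                else:
                    exclusions.append(
                        {
                            "individual_id": tr.individual_id,
                            "window": str(yr),
                            "reason": "not a full calendar year of fixes",
                        }
                    )
        for p in ok:
            in_win = t_local.to_period(freq) == p
            pts = f.loc[in_win, ["x", "y"]].to_numpy()
            if len(pts) < 2 or (np.ptp(pts[:, 0]) == 0 and np.ptp(pts[:, 1]) == 0):
                exclusions.append(
                    {
                        "individual_id": tr.individual_id,
                        "window": str(p),
                        "reason": "fewer than 2 distinct fixes",
                    }
                )
                continue
            windows.append(
                {
                    "traj": tr,
                    "period": p,
                    "points": pts,
                    "h_ref": reference_bandwidth(pts),
                }
            )

    if not windows:
        raise ValueError("no windows pass the inclusion rules")

    h_used = float(h_override) if h_override is not None else float(
        np.mean([w["h_ref"] for w in windows])
    )
    for exc in exclusions:
        logger.info(
            "excluded %s %s: %s", exc["individual_id"], exc["window"], exc["reason"]
        )

    steps = steps.copy()
    step_periods = pd.DatetimeIndex(steps["t_local"]).to_period(freq)

    ranges: dict[tuple[str, pd.Period], HomeRange] = {}
    rows = []
    for w in windows:
        tr: Trajectory = w["traj"]
        p: pd.Period = w["period"]
        hr = kde_home_range(
            w["points"], h_used, cell=cell, isopleth=isopleth,
            individual_id=tr.individual_id, label=str(p),
        )
        ranges[(tr.individual_id, p)] = hr
        in_win = (steps["individual_id"] == tr.individual_id) & (step_periods == p)
        s_win = steps.loc[in_win]
        prev = ranges.get((tr.individual_id, p - 1))
        fidelity = (
            site_fidelity(hr, prev, symmetric=symmetric_overlap)
            if prev is not None
            else float("nan")
        )
        row = {
            "individual_id": tr.individual_id,
            "sex": tr.sex,
            "region": tr.region,
            "scale": scale,
            "window": str(p),
            "distance_km": movement_distance(s_win),
            "home_range_km2": hr.area_km2,
            "site_fidelity": fidelity,
            "diurnality": diurnality(s_win),
            "exploratory_prop": (
                exploratory_proportion(s_win["state"].to_numpy())
                if "state" in s_win.columns
                else float("nan")
            ),
        }
        if rasters is not None:
            from .rasters import extract_covariates

            row.update(extract_covariates(rasters, hr, str(p), scale))
        rows.append(row)

    out = pd.DataFrame(rows)
    out.attrs["h_used"] = h_used
    out.attrs["scale"] = scale
    out.attrs["exclusions"] = exclusions
    return out
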