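"""Covariate rasters: grid container, derived layers, zonal means, scaling.

Layers live on regular planar grids in the same metric frame as the
trajectories.  Text I/O uses the ESRI ASCII grid format so fixtures stay
plain text and files remain readable by standard GIS tooling.

Covariates enter the behavior models as the mean raster value within each
individual's 95% home range for the matching time step: the human
footprint index (HFI) and temperature seasonality as static layers,
rainfall and NDVI as monthly or annual layers depending on the scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("elemove")


@dataclass
class RasterGrid:
    """Single-band regular raster.

    ``values[r, c]`` covers the cell with lower-left corner
    ``(x0 + c*cell, y0 + (nrows-1-r)*cell)``: row 0 is the northern edge,
    as in the ASCII grid convention.  ``mask`` flags missing cells.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray
    mask: np.ndarray | None = None
    label: str = ""
    time_index: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.cell <= 0 or self.values.ndim != 2:
            raise ValueError("cell size must be positive and values 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        nr, nc = self.values.shape
        cx = self.x0 + (np.arange(nc) + 0.5) * self.cell
        cy = self.y0 + (nr - 1 - np.arange(nr) + 0.5) * self.cell
        return cx, cy

    def value_at(self, x, y):
        """Nearest-cell lookup; NaN outside the extent or where masked."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nr, nc = self.values.shape
        c = np.floor((x - self.x0) / self.cell).astype(int)
        r = nr - 1 - np.floor((y - self.y0) / self.cell).astype(int)
        ok = (c >= 0) & (c < nc) & (r >= 0) & (r < nr)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        rr = np.clip(r, 0, nr - 1)
        cc = np.clip(c, 0, nc - 1)
        vals = np.where(self.mask[rr, cc], np.nan, self.values[rr, cc])
        out = np.where(ok, vals, np.nan)
        return out

    # -- text I/O -----------------------------------------------------------

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        nr, nc = self.values.shape
        vals = np.where(self.mask, nodata, self.values)
        header = (
            f"ncols {nc}\nnrows {nr}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.cell}\nNODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path, label: str = "", time_index: str = "") -> "RasterGrid":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value", -9999.0)
        mask = vals == nodata
        vals = np.where(mask, np.nan, vals)
        return cls(
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            cell=meta["cellsize"],
            values=vals,
            mask=mask,
            label=label,
            time_index=time_index,
        )


# ---------------------------------------------------------------------------
# derived layers

def temperature_seasonality(monthly_temps: list[RasterGrid]) -> RasterGrid:
    """Per-cell standard deviation of the 12 monthly mean temperatures.

    Population SD over n = 12 months; a cell missing in any month is
    masked in the output.
    """
    if len(monthly_temps) != 12:
        raise ValueError("need exactly 12 monthly temperature layers")
    ref = monthly_temps[0]
    stack = np.stack([g.values for g in monthly_temps])
    mask = np.any([g.mask for g in monthly_temps], axis=0)
    sd = np.where(mask, np.nan, np.std(stack, axis=0, ddof=0))
    return replace(ref, values=sd, mask=mask, label="temp_seasonality", time_index="")


def ndvi_gapfill(monthly_ndvi: list[RasterGrid]) -> list[RasterGrid]:
    """Fill missing NDVI cells from the previous month's (filled) layer.

    Observed values are never altered; leading missing cells stay masked.
    The count of masked cells is non-increasing through the sequence.
    """
    filled: list[RasterGrid] = []
    prev: RasterGrid | None = None
    for g in monthly_ndvi:
        vals = g.values.copy()
        mask = g.mask.copy()
        if prev is not None:
            take = mask & ~prev.mask
            vals[take] = prev.values[take]
            mask = mask & prev.mask
        vals = np.where(mask, np.nan, vals)
        prev = replace(g, values=vals, mask=mask)
        filled.append(prev)
    return filled


def annual_ndvi(filled_monthly: list[RasterGrid]) -> RasterGrid:
    """Mean of the gap-filled monthly layers; all-missing cells stay masked."""
    stack = np.stack([g.values for g in filled_monthly])
    masks = np.stack([g.mask for g in filled_monthly])
    n_ok = (~masks).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(masks, 0.0, stack), axis=0) / np.where(n_ok > 0, n_ok, 1)
    mask = n_ok == 0
    if mask.any():
        logger.warning("annual NDVI: %d cells missing in every month", int(mask.sum()))
    mean = np.where(mask, np.nan, mean)
    return replace(filled_monthly[0], values=mean, mask=mask, label="ndvi_annual", time_index="")


# ---------------------------------------------------------------------------
# zonal extraction

def mean_within_range(raster: RasterGrid, hr) -> float:
    """Mean raster value over cells whose centres fall in the 95% region.

    ``hr`` is a :class:`~elemove.metrics.HomeRange`; masked raster cells
    are excluded.  NaN (logged) when no unmasked centre lies inside.
    """
    cx, cy = raster.cell_centers()
    # rows index y from the top: broadcast centres in the row-major layout
    gy = np.repeat(cy[:, None], len(cx), axis=1)
    gx = np.repeat(cx[None, :], len(cy), axis=0)
    inside = hr.contains(gx.ravel(), gy.ravel()).reshape(raster.shape)
    ok = inside & ~raster.mask
    if not ok.any():
        logger.info("mean_within_range: no unmasked cell centre inside range %s", hr.label)
        return float("nan")
    return float(raster.values[ok].mean())


def extract_covariates(rasters: dict, hr, window: str, scale: str) -> dict:
    """Mean-within-range covariates for one behavior record.

    ``rasters`` keys: ``hfi``, ``temp_seasonality``, ``annual_rainfall``,
    ``annual_ndvi`` and dicts ``monthly_rainfall``/``monthly_ndvi`` keyed
    by 'YYYY-MM' labels.  Monthly records pair with their month's layers,
    annual records with the annual layers.
    """
    out = {}
    out["hfi"] = mean_within_range(rasters["hfi"], hr)
    out["temp_seasonality"] = mean_within_range(rasters["temp_seasonality"], hr)
    if scale == "monthly":
        rain = rasters.get("monthly_rainfall", {}).get(window)
        ndvi = rasters.get("monthly_ndvi", {}).get(window)
    else:
        rain = rasters.get("annual_rainfall")
        ndvi = rasters.get("annual_ndvi")
    out["rainfall"] = mean_within_range(rain, hr) if rain is not None else float("nan")
    out["ndvi"] = mean_within_range(ndvi, hr) if ndvi is not None else float("nan")
    return out


# ---------------------------------------------------------------------------
# predictor / response scaling

@dataclass
class Scaler:
    """Z-scoring (centre + scale) or SD-units (scale only) transform."""

    mean: float
    sd: float
    mode: str = "z"

    def transform(self, x):
        x = np.asarray(x, dtype=float)
        return (x - self.mean) / self.sd if self.mode == "z" else x / self.sd

    def inverse(self, z):
        z = np.asarray(z, dtype=float)
        return z * self.sd + self.mean if self.mode == "z" else z * self.sd


def standardize(column, mode: str = "z", name: str = "") -> tuple[np.ndarray, Scaler]:
    """Standardize a predictor or response column.

    ``mode='z'`` (default) is (x - mean)/SD; ``mode='sd'`` divides by the
    SD without centring.  Raises on zero variance, naming the column.
    """
    x = np.asarray(column, dtype=float)
    ok = np.isfinite(x)
    mu = float(np.mean(x[ok]))
    sd = float(np.std(x[ok], ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"column {name or '<unnamed>'!r} has zero variance")
    sc = Scaler(mean=mu if mode == "z" else 0.0, sd=sd, mode=mode)
    return sc.transform(x), sc
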