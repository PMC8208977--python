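"""Synthetic landscape, population and behavior-table generators.

The tracking data this pipeline was designed around are not publicly
deposited, so every end-to-end exercise runs on synthetic data with known
ground truth.  Two generators are provided:

``simulate_population``
    an individual-structured, state-switching, biased correlated random
    walk.  Each animal carries latent modifiers drawn from an
    among-individual covariance matrix (step scale, transition bias,
    diurnal amplitude, home-range attraction), switches between encamped
    and exploratory movement via a Markov chain whose logits respond to
    raster covariates and an hour-of-day harmonic, and is pulled toward a
    fixed home-range centre — the simplest mechanism that produces
    bounded, site-faithful ranges.

``simulate_behavior_table``
    a direct draw from the Gaussian mixed model the statistical stage
    assumes (fixed effects + individual/region/month intercepts +
    residual), univariate or multi-trait; the route used to validate the
    samplers against known variance components.

All draws are reproducible from the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .hmm import HmmParams, wrap_angle
from .rasters import RasterGrid
from .tracks import ConfigurationError, Trajectory

logger = logging.getLogger("elemove")

TRAIT_NAMES = ("distance", "home_range", "diurnality", "exploratory")


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix; exact zeros stay zero."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    return v * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RasterSpec:
    """Synthetic landscape geometry and texture."""

    nx: int = 60
    ny: int = 60
    cell: float = 1000.0          # metres
    x0: float = 0.0
    y0: float = 0.0
    n_bumps: int = 15
    smoothness: float = 0.2       # bump SD as a fraction of the extent
    ndvi_missing_frac: float = 0.1

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.cell, self.ny * self.cell


def _default_sigma_i() -> np.ndarray:
    # latent modifiers: (log step scale, transition logit, diurnal amp, attraction logit)
    sd = np.array([0.20, 0.30, 0.20, 0.30])
    return np.diag(sd**2)


@dataclass
class SimConfig:
    """Study-population generating conditions.

    Defaults emulate the collaring program the analysis targets: 96
    individuals across 7 regions at 1-hour fixes, with monthly-scale
    records spanning ``months`` months.
    """

    n_individuals: int = 96
    months: int = 18
    start: str = "2016-01"
    fixes_per_hour: int = 1
    sex_ratio: float = 0.5
    n_regions: int = 7
    seed: int = 0
    hmm: HmmParams = field(
        default_factory=lambda: HmmParams(
            mu=np.array([100.0, 1000.0]),
            sigma=np.array([80.0, 600.0]),
            angle_mean=np.array([0.0, 0.0]),
            kappa=np.array([0.5, 2.0]),
            tpm=np.array([[0.9, 0.1], [0.1, 0.9]]),
        )
    )
    sigma_i_sim: np.ndarray = field(default_factory=_default_sigma_i)
    beta_sim: dict = field(
        default_factory=lambda: {
            "hfi": -0.3,
            "ndvi": 0.2,
            "rainfall": 0.3,
            "temp_seasonality": -0.2,
        }
    )
    diurnal_amplitude: float = 0.4
    attraction_rho: float = 0.4
    raster_spec: RasterSpec = field(default_factory=RasterSpec)

    def validate(self) -> None:
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if not 0 <= self.attraction_rho < 1:
            raise ConfigurationError("attraction_rho must lie in [0, 1)")
        s = np.asarray(self.sigma_i_sim, dtype=float)
        if s.shape != (4, 4) or not np.allclose(s, s.T):
            raise ConfigurationError("sigma_i_sim must be symmetric 4x4")
        if np.linalg.eigvalsh(s).min() < -1e-10:
            raise ConfigurationError("sigma_i_sim must be positive semi-definite")
        self.hmm.validate()

    @property
    def month_labels(self) -> list[str]:
        p0 = pd.Period(self.start, "M")
        return [str(p0 + k) for k in range(self.months)]


@dataclass
class SimTruth:
    """Everything needed to score a recovery test against the generator."""

    u: np.ndarray                     # (n_individuals, 4) latent modifiers
    centres: np.ndarray               # (n_individuals, 2) home-range centres
    regions: np.ndarray
    sexes: np.ndarray
    states: dict = field(default_factory=dict)   # individual -> true state path
    params: dict = field(default_factory=dict)
    n_clamped: int = 0


# ---------------------------------------------------------------------------
# rasters

def _random_field(spec: RasterSpec, rng: np.random.Generator, lo: float, hi: float) -> np.ndarray:
    """Smooth field as a sum of Gaussian bumps, min-max scaled to [lo, hi]."""
    w, hgt = spec.extent
    cx = spec.x0 + (np.arange(spec.nx) + 0.5) * spec.cell
    cy = spec.y0 + (spec.ny - 1 - np.arange(spec.ny) + 0.5) * spec.cell
    gx = np.repeat(cx[None, :], spec.ny, axis=0)
    gy = np.repeat(cy[:, None], spec.nx, axis=1)
    field_ = np.zeros((spec.ny, spec.nx))
    sd = spec.smoothness * max(w, hgt)
    for _ in range(max(spec.n_bumps, 1)):
        bx = spec.x0 + rng.random() * w
        by = spec.y0 + rng.random() * hgt
        amp = rng.normal()
        field_ += amp * np.exp(-((gx - bx) ** 2 + (gy - by) ** 2) / (2 * sd * sd))
    rng_span = field_.max() - field_.min()
    if rng_span < 1e-12:
        return np.full_like(field_, 0.5 * (lo + hi))
    return lo + (hi - lo) * (field_ - field_.min()) / rng_span


def generate_rasters(
    spec: RasterSpec, seed: int | None = None, months: list[str] | None = None
) -> dict:
    """Synthetic covariate layers on a shared grid.

    Returns ``hfi``, ``temp_seasonality``, ``annual_rainfall`` (static),
    plus per-month ``monthly_rainfall`` and ``monthly_ndvi`` dicts keyed
    by 'YYYY-MM'.  NDVI carries a seasonal sinusoid, noise, and a
    configurable fraction of missing cells to exercise gap-filling.
    """
    if spec.nx <= 0 or spec.ny <= 0 or spec.cell <= 0:
        raise ConfigurationError("raster dimensions must be positive")
    rng = np.random.default_rng(seed)
    if months is None:
        months = [str(pd.Period("2016-01", "M") + k) for k in range(12)]

    def grid(vals, label, t=""):
        return RasterGrid(
            x0=spec.x0, y0=spec.y0, cell=spec.cell, values=vals, label=label, time_index=t
        )

    out = {
        "hfi": grid(_random_field(spec, rng, 0.0, 50.0), "hfi"),
        "temp_seasonality": grid(_random_field(spec, rng, 0.4, 1.6), "temp_seasonality"),
        "annual_rainfall": grid(_random_field(spec, rng, 1400.0, 2650.0), "annual_rainfall"),
        "monthly_rainfall": {},
        "monthly_ndvi": {},
    }
    rain_base = _random_field(spec, rng, 1.0, 8.0)       # mm/day
    ndvi_base = _random_field(spec, rng, 0.55, 0.85)
    for m in months:
        mm = pd.Period(m, "M").month
        season = np.sin(2 * np.pi * (mm - 1) / 12.0)
        rain = np.clip(rain_base * (1 + 0.6 * season) + rng.normal(0, 0.3, rain_base.shape), 0, None)
        out["monthly_rainfall"][m] = grid(rain, "rainfall", m)
        ndvi = np.clip(
            ndvi_base + 0.08 * season + rng.normal(0, 0.02, ndvi_base.shape), 0.0, 1.0
        )
        mask = rng.random(ndvi.shape) < spec.ndvi_missing_frac
        ndvi = np.where(mask, np.nan, ndvi)
        out["monthly_ndvi"][m] = grid(ndvi, "ndvi", m)
    return out


# ---------------------------------------------------------------------------
# trajectory simulation

def _standardize_field(g: RasterGrid) -> RasterGrid:
    v = g.values[~g.mask]
    sd = v.std() if v.std() > 0 else 1.0
    return replace(g, values=(g.values - v.mean()) / sd)


def simulate_population(cfg: SimConfig, rasters: dict) -> tuple[list[Trajectory], SimTruth]:
    """Hourly state-switching trajectories for a structured population.

    Per individual: latent modifiers u ~ N(0, Sigma_I_sim) shift the log
    step-length means, the toward-exploratory transition logit, the
    diurnal amplitude and the home-attraction weight (logit scale).
    Transition logits add covariate terms (standardized raster values at
    the current position, weighted by ``beta_sim``) and a noon-centred
    cosine scaled by the individual's diurnal amplitude.  Headings are
    von Mises around a rho-weighted compromise between the previous
    heading and the bearing to the individual's centre.  Positions that
    leave the raster extent are clamped (counted in the truth record).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.raster_spec
    w, hgt = spec.extent
    n = cfg.n_individuals

    z_layers = {
        name: _standardize_field(rasters[name])
        for name in ("hfi", "temp_seasonality")
        if name in rasters and name in cfg.beta_sim
    }
    z_monthly = {
        name: {m: _standardize_field(g) for m, g in rasters.get(f"monthly_{name}", {}).items()}
        for name in ("rainfall", "ndvi")
        if name in cfg.beta_sim
    }

    u = (_psd_sqrt(cfg.sigma_i_sim) @ rng.standard_normal((4, n))).T
    # region centres spread over the landscape; individuals cluster near them
    reg_centres = np.column_stack(
        [
            spec.x0 + w * (0.15 + 0.7 * rng.random(cfg.n_regions)),
            spec.y0 + hgt * (0.15 + 0.7 * rng.random(cfg.n_regions)),
        ]
    )
    regions = rng.integers(0, cfg.n_regions, n)
    centres = reg_centres[regions] + rng.normal(0, 0.06 * min(w, hgt), (n, 2))
    centres[:, 0] = np.clip(centres[:, 0], spec.x0, spec.x0 + w)
    centres[:, 1] = np.clip(centres[:, 1], spec.y0, spec.y0 + hgt)
    sexes = np.where(rng.random(n) < cfg.sex_ratio, "female", "male")

    p0 = pd.Period(cfg.start, "M")
    t_start = p0.start_time
    n_hours = int(
        ((p0 + cfg.months - 1).end_time - t_start) / pd.Timedelta(hours=1)
    )
    times = t_start + pd.to_timedelta(np.arange(n_hours + 1), unit="h")
    month_of_hour = times.to_period("M").astype(str)
    hour_of_day = times.hour.to_numpy()
    base_logit_expl = special.logit(cfg.hmm.tpm[:, 1])  # per current state
    logit_rho = special.logit(np.clip(cfg.attraction_rho, 1e-6, 1 - 1e-6))

    trajs: list[Trajectory] = []
    truth = SimTruth(
        u=u,
        centres=centres,
        regions=regions,
        sexes=sexes,
        params={"config_seed": cfg.seed, "hmm": cfg.hmm.to_dict()},
    )
    n_clamped = 0
    for i in range(n):
        ind = f"elephant_{i:03d}"
        mu_i = cfg.hmm.mu * np.exp(u[i, 0])
        sigma_i = cfg.hmm.sigma * np.exp(u[i, 0])
        shape_i = (mu_i / sigma_i) ** 2
        scale_i = sigma_i**2 / mu_i
        amp_i = cfg.diurnal_amplitude + u[i, 2]
        rho_i = special.expit(logit_rho + u[i, 3])
        pos = centres[i].copy()
        xy = np.empty((n_hours + 1, 2))
        xy[0] = pos
        states = np.empty(n_hours, dtype=np.int8)
        state = int(rng.random() < cfg.hmm.delta[1])
        heading = rng.uniform(-np.pi, np.pi)
        for t in range(n_hours):
            cov_term = 0.0
            for name, g in z_layers.items():
                v = g.value_at(pos[0], pos[1])
                if np.isfinite(v):
                    cov_term += cfg.beta_sim[name] * float(v)
            for name, by_month in z_monthly.items():
                g = by_month.get(month_of_hour[t])
                if g is not None:
                    v = g.value_at(pos[0], pos[1])
                    if np.isfinite(v):
                        cov_term += cfg.beta_sim[name] * float(v)
            harmonic = np.cos(2 * np.pi * (hour_of_day[t] - 12) / 24.0)
            eta = base_logit_expl[state] + u[i, 1] + cov_term + amp_i * harmonic
            state = int(rng.random() < special.expit(eta))
            states[t] = state
            step = rng.gamma(shape_i[state], scale_i[state])
            to_centre = np.arctan2(centres[i, 1] - pos[1], centres[i, 0] - pos[0])
            tx = (1 - rho_i) * np.cos(heading) + rho_i * np.cos(to_centre)
            ty = (1 - rho_i) * np.sin(heading) + rho_i * np.sin(to_centre)
            target = np.arctan2(ty, tx)
            heading = wrap_angle(
                target
                + cfg.hmm.angle_mean[state]
                + rng.vonmises(0.0, max(cfg.hmm.kappa[state], 1e-12))
            )
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            if not (spec.x0 <= pos[0] <= spec.x0 + w and spec.y0 <= pos[1] <= spec.y0 + hgt):
                pos[0] = np.clip(pos[0], spec.x0, spec.x0 + w)
                pos[1] = np.clip(pos[1], spec.y0, spec.y0 + hgt)
                n_clamped += 1
            xy[t + 1] = pos
        fixes = pd.DataFrame(
            {
                "t_utc": times,
                "t_local": times,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "burst": -1,
            }
        )
        trajs.append(
            Trajectory(
                individual_id=ind,
                sex=str(sexes[i]),
                region=f"region_{regions[i]}",
                fixes=fixes,
            )
        )
        truth.states[ind] = states
    if n_clamped:
        logger.warning("simulate_population: clamped %d positions at the raster edge", n_clamped)
    truth.n_clamped = n_clamped
    return trajs, truth


# ---------------------------------------------------------------------------
# behavior-table simulation

def simulate_behavior_table(
    n_individuals: int,
    n_months: int,
    beta: np.ndarray | dict,
    sigma_individual,
    v_region: float,
    v_month: float,
    sigma_residual,
    seed: int | None = None,
    n_regions: int = 7,
    trait_names: tuple[str, ...] | None = None,
    start: str = "2016-01",
) -> tuple[pd.DataFrame, dict]:
    """Draw a behavior table directly from the hierarchical Gaussian model.

    ``y = X beta + u_individual + r_region + m_month + e`` with
    covariates drawn standard normal per record and sex assigned per
    individual.  ``sigma_individual`` and ``sigma_residual`` may be
    scalars (variances; univariate or shared-diagonal multivariate) or
    full trait x trait covariance matrices.  Returns the table plus a
    ground-truth dict with every latent draw.
    """
    rng = np.random.default_rng(seed)
    covs = ("ndvi", "hfi", "temp_seasonality", "rainfall")

    def as_cov(s, t):
        s = np.asarray(s, dtype=float)
        if s.ndim == 0:
            return np.eye(t) * float(s)
        if s.shape != (t, t) or not np.allclose(s, s.T):
            raise ValueError("covariance must be scalar or symmetric (t, t)")
        if np.linalg.eigvalsh(s).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        return s

    if isinstance(beta, dict):
        raise ValueError("pass beta as an array (n_fixed,) or (n_fixed, n_traits)")
    beta_mat = np.atleast_2d(np.asarray(beta, dtype=float))
    if beta_mat.shape[0] == 1 and beta_mat.shape[1] == len(covs) + 1:
        beta_mat = beta_mat.T  # univariate row vector -> column
    n_fixed = beta_mat.shape[0]
    if n_fixed != len(covs) + 1:
        raise ValueError(f"beta must have {len(covs) + 1} rows: sex + {covs}")
    t = beta_mat.shape[1]
    if trait_names is None:
        trait_names = ("y",) if t == 1 else TRAIT_NAMES[:t]
    if len(trait_names) != t:
        raise ValueError("trait_names length mismatch")
    if v_region < 0 or v_month < 0:
        raise ValueError("variances must be non-negative")

    sig_i = as_cov(sigma_individual, t)
    sig_e = as_cov(sigma_residual, t)

    months = [str(pd.Period(start, "M") + k) for k in range(n_months)]
    sex = rng.integers(0, 2, n_individuals)  # 1 = male
    region = rng.integers(0, n_regions, n_individuals)

    def mvn(cov, size):
        return (_psd_sqrt(cov) @ rng.standard_normal((t, size))).T

    u_ind = mvn(sig_i, n_individuals)
    r_reg = rng.normal(0, np.sqrt(v_region), (n_regions, t))
    m_mon = rng.normal(0, np.sqrt(v_month), (n_months, t))

    rows_ind = np.repeat(np.arange(n_individuals), n_months)
    rows_mon = np.tile(np.arange(n_months), n_individuals)
    n_obs = len(rows_ind)
    x_cont = rng.standard_normal((n_obs, len(covs)))
    x = np.column_stack([sex[rows_ind].astype(float), x_cont])
    e = mvn(sig_e, n_obs)
    y = x @ beta_mat + u_ind[rows_ind] + r_reg[region[rows_ind]] + m_mon[rows_mon] + e

    table = pd.DataFrame(
        {
            "individual_id": [f"elephant_{i:03d}" for i in rows_ind],
            "sex": np.where(sex[rows_ind] == 1, "male", "female"),
            "region": [f"region_{r}" for r in region[rows_ind]],
            "scale": "monthly",
            "window": [months[m] for m in rows_mon],
        }
    )
    for j, c in enumerate(covs):
        table[c] = x_cont[:, j]
    for j, name in enumerate(trait_names):
        table[name] = y[:, j]
    truth = {
        "beta": beta_mat,
        "fixed_names": ("sex",) + covs,
        "sigma_individual": sig_i,
        "v_region": v_region,
        "v_month": v_month,
        "sigma_residual": sig_e,
        "u_individual": u_ind,
        "r_region": r_reg,
        "m_month": m_mon,
        "trait_names": trait_names,
    }
    return table, truth
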