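"""Bayesian Gaussian mixed models for single behaviors.

Each behavior (optionally log-transformed, then scaled to SD units) is
modelled as

    y = X beta + u_individual + u_region [+ u_month] + e

with independent Gaussian random intercepts and residuals.  Inference is
a bespoke conjugate Gibbs sampler: normal updates for the coefficients
and intercepts, scaled-inverse-chi-squared (inverse-gamma) updates for
the variances, and parameter expansion on each random-effect variance —
a working multiplier alpha ~ N(0, alpha_v) that keeps the chain mixing
when a variance sits near zero.  The implied prior on each random-effect
variance is the heavy-tailed scaled-F family; the residual variance
carries the standard weak inverse-gamma prior (V = 1, nu = 0.002).

Derived quantities — adjusted repeatability, marginal/conditional R^2,
credible-interval effect summaries, low-to-high percent changes — are
computed per posterior draw so their intervals propagate all parameter
uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .rasters import Scaler, standardize
from .tracks import ConfigurationError

logger = logging.getLogger("elemove")

CONTINUOUS_COVARIATES = ("ndvi", "hfi", "temp_seasonality", "rainfall")

TERM_COLUMNS = {"individual": "individual_id", "region": "region", "month": "window"}


@dataclass(frozen=True)
class McmcPreset:
    iterations: int = 850_000
    burnin: int = 50_000
    thin: int = 400

    def __post_init__(self):
        if (self.iterations - self.burnin) % self.thin != 0:
            raise ConfigurationError("thin must divide (iterations - burnin)")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burnin) // self.thin


#: full-length production run
FULL_PRESET = McmcPreset(850_000, 50_000, 400)
#: short preset for test suites and demos
TEST_PRESET = McmcPreset(8_500, 500, 4)


@dataclass
class ModelSpec:
    """Specification of one univariate behavior model."""

    response: str
    transform: str = "identity"           # "identity" | "log"
    fixed: tuple = ("sex",) + CONTINUOUS_COVARIATES
    random: tuple = ("individual", "region", "month")
    resid_prior_v: float = 1.0
    resid_prior_nu: float = 0.002
    rand_prior_v: float = 1.0
    rand_prior_nu: float = 1.0
    alpha_v: float = 625.0
    mcmc: McmcPreset = field(default_factory=lambda: TEST_PRESET)
    seed: int | None = None
    response_scaling: str = "z"           # "z" | "sd" (scale-only)

    def validate(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ConfigurationError("transform must be 'identity' or 'log'")
        if min(self.resid_prior_v, self.resid_prior_nu, self.rand_prior_v,
               self.rand_prior_nu, self.alpha_v) <= 0:
            raise ConfigurationError("prior constants must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus the metadata needed for derived summaries.

    ``df`` columns: one per fixed-effect coefficient (``b_*``), one
    variance per random term (``V_<term>``), ``V_residual`` and the
    per-draw fixed-effect linear-predictor variance ``V_fixed``.
    """

    df: pd.DataFrame
    spec: ModelSpec
    beta_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def variance_columns(self) -> list[str]:
        return [f"V_{t}" for t in self.spec.random] + ["V_residual"]


def _invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def prepare_model_frame(table: pd.DataFrame, spec: ModelSpec):
    """Standardized design matrix and response from a behavior table.

    Rows with a missing response or covariate are dropped (logged).  The
    response is transformed then scaled; continuous predictors are
    z-scored; sex enters as a male dummy.
    """
    cols = [spec.response] + [c for c in spec.fixed if c != "sex"]
    if "sex" in spec.fixed:
        cols.append("sex")
    needed = cols + [TERM_COLUMNS[t] for t in spec.random]
    sub = table[needed].copy()
    ok = sub.notna().all(axis=1)
    ok &= np.isfinite(sub[spec.response].to_numpy(dtype=float))
    if spec.transform == "log":
        ok &= sub[spec.response].to_numpy(dtype=float) > 0
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("%s: dropped %d rows with missing response/covariates",
                    spec.response, n_drop)
    sub = sub[ok]
    if len(sub) == 0:
        raise ValueError(f"no complete rows for response {spec.response!r}")

    y_raw = sub[spec.response].to_numpy(dtype=float)
    if spec.transform == "log":
        y_raw = np.log(y_raw)
    y, y_scaler = standardize(y_raw, mode=spec.response_scaling, name=spec.response)

    x_cols = [np.ones(len(sub))]
    beta_names = ["b_intercept"]
    scalers: dict[str, Scaler] = {}
    cov_range_z: dict[str, tuple[float, float]] = {}
    for c in spec.fixed:
        if c == "sex":
            x_cols.append((sub["sex"].astype(str) == "male").to_numpy(dtype=float))
            beta_names.append("b_sex_male")
        else:
            z, sc = standardize(sub[c].to_numpy(dtype=float), name=c)
            scalers[c] = sc
            cov_range_z[c] = (float(z.min()), float(z.max()))
            x_cols.append(z)
            beta_names.append(f"b_{c}")
    x = np.column_stack(x_cols)
    groups = {
        t: pd.factorize(sub[TERM_COLUMNS[t]].astype(str))[0] for t in spec.random
    }
    meta = {
        "response_scaler": y_scaler,
        "cov_scalers": scalers,
        "cov_range_z": cov_range_z,
        "n_rows": len(sub),
        "n_dropped": n_drop,
        "group_sizes": {t: int(g.max()) + 1 for t, g in groups.items()},
    }
    return y, x, beta_names, groups, meta


def fit_univariate(
    table: pd.DataFrame,
    spec: ModelSpec,
    fix_variances: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Parameter-expanded Gibbs sampler for one behavior model.

    ``fix_variances`` pins named variance components (keys = random term
    names and/or ``"residual"``) at given values and skips their updates;
    with every component pinned the coefficient draws target the exact
    closed-form GLS posterior, which is how the sampler is validated.
    """
    spec.validate()
    y, x, beta_names, groups, meta = prepare_model_frame(table, spec)
    n, p = x.shape
    rng = np.random.default_rng(spec.seed)
    fix_variances = fix_variances or {}

    xtx = x.T @ x
    xtx_inv = linalg.inv(xtx)
    c_beta = linalg.cholesky(xtx_inv, lower=True)

    terms = list(spec.random)
    g_codes = {t: groups[t] for t in terms}
    g_sizes = {t: int(g_codes[t].max()) + 1 for t in terms}

    utilde = {t: np.zeros(g_sizes[t]) for t in terms}
    alpha = {t: 1.0 for t in terms}
    s2t = {t: fix_variances.get(t, float(np.var(y)) / (len(terms) + 1) + 1e-6)
           for t in terms}
    s2e = fix_variances.get("residual", float(np.var(y)) / 2 + 1e-6)
    beta = xtx_inv @ (x.T @ y)

    nu_r, v_r = spec.resid_prior_nu, spec.resid_prior_v
    nu_u, v_u = spec.rand_prior_nu, spec.rand_prior_v

    mc = spec.mcmc
    n_draws = mc.n_draws
    out = np.empty((n_draws, p + len(terms) + 2))
    contrib = {t: alpha[t] * utilde[t][g_codes[t]] for t in terms}
    d = 0
    for it in range(1, mc.iterations + 1):
        # --- fixed effects
        r = y - sum(contrib.values())
        mean_b = xtx_inv @ (x.T @ r)
        beta = mean_b + np.sqrt(s2e) * (c_beta @ rng.standard_normal(p))
        xb = x @ beta

        # --- random terms (working scale + multiplier)
        for t in terms:
            g = g_codes[t]
            gsz = g_sizes[t]
            r_t = y - xb - sum(contrib[s] for s in terms if s != t)
            if t in fix_variances:
                # plain conjugate update at the pinned variance (alpha = 1)
                prec = np.bincount(g, minlength=gsz) / s2e + 1.0 / s2t[t]
                mean_u = (np.bincount(g, weights=r_t, minlength=gsz) / s2e) / prec
                utilde[t] = mean_u + rng.standard_normal(gsz) / np.sqrt(prec)
                alpha[t] = 1.0
            else:
                a = alpha[t]
                prec = np.bincount(g, minlength=gsz) * a * a / s2e + 1.0 / s2t[t]
                mean_u = (a * np.bincount(g, weights=r_t, minlength=gsz) / s2e) / prec
                utilde[t] = mean_u + rng.standard_normal(gsz) / np.sqrt(prec)
                w = utilde[t][g]
                prec_a = (w @ w) / s2e + 1.0 / spec.alpha_v
                mean_a = (w @ r_t / s2e) / prec_a
                alpha[t] = mean_a + rng.standard_normal() / np.sqrt(prec_a)
                ssq = utilde[t] @ utilde[t]
                s2t[t] = _invgamma(rng, (nu_u + gsz) / 2.0, (nu_u * v_u + ssq) / 2.0)
            contrib[t] = alpha[t] * utilde[t][g_codes[t]]

        # --- residual variance
        resid = y - xb - sum(contrib.values())
        if "residual" not in fix_variances:
            s2e = _invgamma(rng, (nu_r + n) / 2.0, (nu_r * v_r + resid @ resid) / 2.0)

        if it > mc.burnin and (it - mc.burnin) % mc.thin == 0:
            v_terms = [alpha[t] ** 2 * s2t[t] for t in terms]
            out[d, :p] = beta
            out[d, p:p + len(terms)] = v_terms
            out[d, p + len(terms)] = s2e
            out[d, p + len(terms) + 1] = np.var(xb)
            d += 1

    cols = beta_names + [f"V_{t}" for t in terms] + ["V_residual", "V_fixed"]
    df = pd.DataFrame(out[:d], columns=cols)
    draws = PosteriorDraws(df=df, spec=spec, beta_names=beta_names, meta=meta)

    ess = effective_sample_size(df[[f"V_{t}" for t in terms] + ["V_residual"]])
    low = ess[ess < 100]
    if len(low) and not fix_variances:
        logger.warning(
            "%s: low effective sample size on %s — treat summaries with caution",
            spec.response, ", ".join(f"{k} ({v:.0f})" for k, v in low.items()),
        )
        draws.meta["convergence_warning"] = low.to_dict()
    return draws


# ---------------------------------------------------------------------------
# derived summaries

def _ci(v: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    return float(np.quantile(v, a)), float(np.quantile(v, 1 - a))


def _kde_mode(v: np.ndarray) -> float:
    if np.ptp(v) == 0:
        return float(v[0])
    kde = stats.gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def repeatability(draws: PosteriorDraws) -> dict:
    """Adjusted repeatability: V_individual over total phenotypic variance.

    Computed per draw as V_I / (V_I + V_region [+ V_month] + V_residual),
    i.e. the among-individual share after controlling for fixed effects;
    summarised by posterior mean, kernel-density mode and equal-tailed
    95% interval.
    """
    df = draws.df
    denom = sum(df[f"V_{t}"] for t in draws.spec.random) + df["V_residual"]
    r = (df["V_individual"] / denom).to_numpy()
    lo, hi = _ci(r)
    return {"mean": float(r.mean()), "mode": _kde_mode(r), "ci_low": lo, "ci_high": hi}


def fixed_effect_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, 95% CI and CI-excludes-zero flag per coefficient.

    Effects are on the standardized response/predictor scale and hence
    comparable across behaviors.
    """
    rows = []
    for name in draws.beta_names:
        v = draws.df[name].to_numpy()
        lo, hi = _ci(v)
        rows.append(
            {
                "coefficient": name,
                "mean": float(v.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def percent_change(
    draws: PosteriorDraws,
    table: pd.DataFrame,
    covariate: str,
    transform: str | None = None,
) -> dict:
    """Predicted percent change of the raw-scale response, covariate low -> high.

    Predictions at the observed covariate minimum and maximum with other
    covariates at their means and sex at the female reference, back-
    transformed to the raw response scale (inverse scaling, then exp for
    log-modelled responses); reported as 100 * (high - low)/low with a
    posterior credible interval.
    """
    name = f"b_{covariate}"
    if name not in draws.beta_names:
        raise ValueError(f"covariate {covariate!r} not in the fitted model")
    transform = transform or draws.spec.transform
    z_lo, z_hi = draws.meta["cov_range_z"][covariate]
    b0 = draws.df["b_intercept"].to_numpy()
    b = draws.df[name].to_numpy()
    scaler: Scaler = draws.meta["response_scaler"]
    pred_lo = scaler.inverse(b0 + b * z_lo)
    pred_hi = scaler.inverse(b0 + b * z_hi)
    if transform == "log":
        pred_lo = np.exp(pred_lo)
        pred_hi = np.exp(pred_hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (pred_hi - pred_lo) / np.abs(pred_lo)
    lo, hi = _ci(pc)
    return {"mean": float(np.mean(pc)), "ci_low": lo, "ci_high": hi}


def r_squared(draws: PosteriorDraws) -> dict:
    """Marginal and conditional R^2 from the variance decomposition.

    Per draw: marginal = V_fixed / (V_fixed + sum V_random + V_residual);
    conditional adds the random-effect variances to the numerator.
    """
    df = draws.df
    v_rand = sum(df[f"V_{t}"] for t in draws.spec.random)
    denom = df["V_fixed"] + v_rand + df["V_residual"]
    marg = (df["V_fixed"] / denom).to_numpy()
    cond = ((df["V_fixed"] + v_rand) / denom).to_numpy()
    mlo, mhi = _ci(marg)
    clo, chi = _ci(cond)
    return {
        "marginal": float(marg.mean()),
        "marginal_ci": (mlo, mhi),
        "conditional": float(cond.mean()),
        "conditional_ci": (clo, chi),
    }


def effective_sample_size(draws) -> pd.Series | float:
    """Geyer initial-positive-sequence ESS per parameter.

    Autocorrelations are summed in consecutive pairs until a pair sum
    turns non-positive; a constant chain reports ESS 0 with a warning.
    Accepts a 1-D array (returns a float) or a DataFrame (per column).
    """
    if isinstance(draws, pd.DataFrame):
        return pd.Series({c: effective_sample_size(draws[c].to_numpy()) for c in draws})
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws")
    x = x - x.mean()
    if np.ptp(x) == 0:
        logger.warning("effective_sample_size: constant chain")
        return 0.0
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    tau = -1.0
    t = 0
    while 2 * t + 1 < n:
        pair = rho[2 * t] + rho[2 * t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 1
    tau = max(tau, 1e-12)
    return float(n / tau)
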