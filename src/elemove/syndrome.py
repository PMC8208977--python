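"""Multi-response hierarchical model and behavioral-syndrome axes.

Four monthly behaviors (distance, home range, diurnality, exploratory
proportion — the traits with non-negligible among-individual variance)
are modelled jointly with unstructured covariance matrices at the
individual, region, month and residual levels:

    y_i = B' x_i + u_ind(i) + u_reg(i) + u_mon(i) + e_i

Inference is a conjugate Gibbs sampler: matrix-normal updates for the
coefficient block and the group intercepts, inverse-Wishart updates for
the residual covariance, and parameter-expanded updates for the random
levels: u = diag(alpha) u_work with a working inverse-Wishart covariance
and a normal prior on the trait-wise multipliers alpha.  Parameter
expansion is the default because a plain inverse-Wishart prior on a
near-zero variance level drags the variances toward its mode and, through
the correlation ratio, pushes |r_I| toward 1; the expanded prior keeps
small-variance levels honest (a plain-IW mode remains available via
``MultiSpec(px=False)``).

The among-individual matrix Sigma_I is the object of interest: its
correlations r_I(x, y) = COV_I(x, y)/sqrt(V_I(x) V_I(y)) quantify
behavioral syndromes, and its eigen decomposition — performed on every
posterior draw, with eigenvectors sign-aligned to the point axes —
yields syndrome axes with credible intervals on loadings and on
eigenvalue shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .mixed import TERM_COLUMNS, TEST_PRESET, McmcPreset, _ci
from .rasters import standardize
from .tracks import ConfigurationError

logger = logging.getLogger("elemove")

SYNDROME_TRAITS = ("distance_km", "home_range_km2", "diurnality", "exploratory_prop")


@dataclass
class MultiSpec:
    """Specification of the multi-response model."""

    traits: tuple = SYNDROME_TRAITS
    transforms: dict = field(default_factory=dict)      # trait -> "log"
    fixed: tuple = ("sex", "ndvi", "hfi", "temp_seasonality", "rainfall")
    random: tuple = ("individual", "region", "month")
    prior_scale: float = 0.01
    prior_df_offset: float = 1.0   # df = n_traits + offset
    px: bool = True                # parameter-expanded random-level priors
    alpha_v: float = 625.0         # prior variance of the expansion multipliers
    mcmc: McmcPreset = field(default_factory=lambda: TEST_PRESET)
    seed: int | None = None


@dataclass
class CovMatrixDraws:
    """Posterior draws of the level-specific covariance matrices.

    ``levels`` maps each random term plus ``"residual"`` to an array of
    shape (n_draws, T, T); ``beta`` holds the coefficient block draws.
    """

    traits: tuple
    levels: dict
    beta: np.ndarray
    beta_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.levels.values())).shape[0]


@dataclass
class SyndromeAxes:
    """Eigen decomposition of the among-individual covariance matrix."""

    traits: tuple
    eigenvalues: np.ndarray            # point, descending
    shares: np.ndarray                 # eigenvalue / trace, point
    loadings: np.ndarray               # (T, T), column j = axis j
    shares_ci: np.ndarray              # (T, 2)
    loadings_ci: np.ndarray            # (T, T, 2)
    degenerate: bool = False


def _prepare(table: pd.DataFrame, spec: MultiSpec):
    cols = list(spec.traits) + [c for c in spec.fixed if c != "sex"]
    needed = cols + (["sex"] if "sex" in spec.fixed else [])
    needed += [TERM_COLUMNS[t] for t in spec.random]
    sub = table[needed].copy()
    for tr, how in spec.transforms.items():
        if how == "log":
            vals = sub[tr].to_numpy(dtype=float)
            sub[tr] = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
    ok = sub.notna().all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("multivariate model: dropped %d incomplete rows", n_drop)
    sub = sub[ok]
    if len(sub) == 0:
        raise ValueError("no complete rows for the multivariate model")

    y = np.column_stack(
        [standardize(sub[tr].to_numpy(dtype=float), name=tr)[0] for tr in spec.traits]
    )
    x_cols = [np.ones(len(sub))]
    beta_names = ["b_intercept"]
    for c in spec.fixed:
        if c == "sex":
            x_cols.append((sub["sex"].astype(str) == "male").to_numpy(dtype=float))
            beta_names.append("b_sex_male")
        else:
            x_cols.append(standardize(sub[c].to_numpy(dtype=float), name=c)[0])
            beta_names.append(f"b_{c}")
    x = np.column_stack(x_cols)
    groups = {t: pd.factorize(sub[TERM_COLUMNS[t]].astype(str))[0] for t in spec.random}
    return y, x, beta_names, groups, {"n_rows": len(sub), "n_dropped": n_drop}


def fit_multivariate(table: pd.DataFrame, spec: MultiSpec | None = None) -> CovMatrixDraws:
    """Gibbs sampler for the multi-response mixed model.

    Covariates act as fixed effects on each response separately (a full
    coefficient block); every random level carries an unstructured
    covariance matrix updated by conjugate inverse-Wishart draws.
    Numerically non-positive-definite posterior precision matrices are
    jittered and retried (logged); persistent failure raises.
    """
    spec = spec or MultiSpec()
    y, x, beta_names, groups, meta = _prepare(table, spec)
    n, t = y.shape
    p = x.shape[1]
    rng = np.random.default_rng(spec.seed)

    xtx_inv = linalg.inv(x.T @ x)
    c_beta = linalg.cholesky(xtx_inv, lower=True)
    terms = list(spec.random)
    g_codes = {k: groups[k] for k in terms}
    g_sizes = {k: int(g_codes[k].max()) + 1 for k in terms}
    g_counts = {k: np.bincount(g_codes[k], minlength=g_sizes[k]) for k in terms}

    s0 = spec.prior_scale * np.eye(t)
    df0 = t + spec.prior_df_offset
    # working-scale prior for the parameter-expanded levels
    s0_px = np.eye(t)
    df0_px = t + 1.0

    uw = {k: np.zeros((g_sizes[k], t)) for k in terms}    # working-scale intercepts
    alpha = {k: np.ones(t) for k in terms}                 # expansion multipliers
    sigma_w = {k: 0.1 * np.eye(t) for k in terms}          # working covariances
    resid0 = y - x @ (xtx_inv @ (x.T @ y))
    r_mat = np.cov(resid0.T) + 1e-6 * np.eye(t)

    def actual_u(k):
        return uw[k] * alpha[k]

    def chol_jitter(a, name):
        for j in range(4):
            try:
                return linalg.cholesky(a + (0.0 if j == 0 else 10.0**-(10 - 2 * j)) * np.eye(t),
                                       lower=True)
            except linalg.LinAlgError:
                logger.info("jittering non-PD matrix in %s (attempt %d)", name, j + 1)
        raise RuntimeError(f"persistently non-positive-definite matrix at level {name}")

    mc = spec.mcmc
    n_draws = mc.n_draws
    level_out = {k: np.empty((n_draws, t, t)) for k in terms + ["residual"]}
    beta_out = np.empty((n_draws, p, t))
    d = 0
    for it in range(1, mc.iterations + 1):
        # --- coefficient block (matrix normal given R)
        e0 = y - sum(actual_u(k)[g_codes[k]] for k in terms)
        b_hat = xtx_inv @ (x.T @ e0)
        lr = chol_jitter(r_mat, "residual")
        b = b_hat + c_beta @ rng.standard_normal((p, t)) @ lr.T
        xb = x @ b

        # --- group intercepts, level by level
        r_inv = linalg.inv(r_mat)
        for k in terms:
            g = g_codes[k]
            a_k = alpha[k]
            rk = y - xb - sum(actual_u(j)[g_codes[j]] for j in terms if j != k)
            s = np.zeros((g_sizes[k], t))
            np.add.at(s, g, rk)
            # working intercepts: emission design is diag(alpha)
            lam_rinv = r_inv * a_k[:, None]          # diag(a) R^{-1}
            lam_rinv_lam = lam_rinv * a_k[None, :]   # diag(a) R^{-1} diag(a)
            m = s @ lam_rinv.T                       # rows = diag(a) R^{-1} s_g
            sig_inv = linalg.inv(sigma_w[k])
            u_new = np.empty_like(uw[k])
            for c in np.unique(g_counts[k]):
                idx = np.flatnonzero(g_counts[k] == c)
                cov_c = linalg.inv(c * lam_rinv_lam + sig_inv)
                l_c = chol_jitter(cov_c, k)
                u_new[idx] = m[idx] @ cov_c.T + rng.standard_normal((len(idx), t)) @ l_c.T
            uw[k] = u_new

            if spec.px:
                # multipliers: GLS regression of the level's residual on
                # the working intercepts, trait by trait but jointly via R
                ug = uw[k][g]
                prec_a = r_inv * (ug.T @ ug) + np.eye(t) / spec.alpha_v
                rhs = ((rk @ r_inv) * ug).sum(axis=0)
                cov_a = linalg.inv(prec_a)
                l_a = chol_jitter(cov_a, f"alpha_{k}")
                alpha[k] = cov_a @ rhs + l_a @ rng.standard_normal(t)
                sigma_w[k] = stats.invwishart.rvs(
                    df=df0_px + g_sizes[k],
                    scale=s0_px + uw[k].T @ uw[k],
                    random_state=rng,
                )
            else:
                alpha[k] = np.ones(t)
                sigma_w[k] = stats.invwishart.rvs(
                    df=df0 + g_sizes[k],
                    scale=s0 + uw[k].T @ uw[k],
                    random_state=rng,
                )

        # --- residual covariance
        e = y - xb - sum(actual_u(k)[g_codes[k]] for k in terms)
        r_mat = stats.invwishart.rvs(df=df0 + n, scale=s0 + e.T @ e, random_state=rng)

        if it > mc.burnin and (it - mc.burnin) % mc.thin == 0:
            for k in terms:
                a_k = alpha[k]
                level_out[k][d] = sigma_w[k] * np.outer(a_k, a_k)
            level_out["residual"][d] = r_mat
            beta_out[d] = b
            d += 1

    meta["spec"] = spec
    return CovMatrixDraws(
        traits=tuple(spec.traits),
        levels={k: v[:d] for k, v in level_out.items()},
        beta=beta_out[:d],
        beta_names=beta_names,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# derived syndrome quantities

def among_individual_correlations(draws: CovMatrixDraws, level: str = "individual") -> dict:
    """Among-individual correlations r_I with 95% CIs, plus V_I and COV_I.

    Correlations are computed per posterior draw and then summarised, so
    the intervals reflect the full joint uncertainty of the covariance
    matrix.  Returns point/CI DataFrames indexed by trait.
    """
    s = draws.levels[level]
    t = s.shape[1]
    dg = np.sqrt(np.einsum("dii->di", s))
    corr = s / (dg[:, :, None] * dg[:, None, :])
    traits = list(draws.traits)

    def summarise(a):
        mean = pd.DataFrame(a.mean(axis=0), index=traits, columns=traits)
        lo = pd.DataFrame(np.quantile(a, 0.025, axis=0), index=traits, columns=traits)
        hi = pd.DataFrame(np.quantile(a, 0.975, axis=0), index=traits, columns=traits)
        return mean, lo, hi

    c_mean, c_lo, c_hi = summarise(corr)
    v_mean, v_lo, v_hi = summarise(s)
    sig = (c_lo > 0) | (c_hi < 0)
    np.fill_diagonal(sig.values, False)
    return {
        "correlation": c_mean,
        "correlation_ci_low": c_lo,
        "correlation_ci_high": c_hi,
        "covariance": v_mean,
        "covariance_ci_low": v_lo,
        "covariance_ci_high": v_hi,
        "significant": sig,
    }


def correlation_from_components(cov_xy: float, v_x: float, v_y: float) -> float:
    """r_I(x, y) = COV_I(x, y) / sqrt(V_I(x) * V_I(y))."""
    if v_x <= 0 or v_y <= 0:
        raise ValueError("variances must be positive")
    return cov_xy / np.sqrt(v_x * v_y)


def table2_style(draws: CovMatrixDraws) -> pd.DataFrame:
    """Matrix summary: V_I on the diagonal, COV_I below, r_I above (with CIs)."""
    r = among_individual_correlations(draws)
    traits = list(draws.traits)
    t = len(traits)
    out = pd.DataFrame(index=traits, columns=traits, dtype=object)

    def fmt(mean, lo, hi, i, j):
        return f"{mean.iloc[i, j]:.2f} ({lo.iloc[i, j]:.2f}, {hi.iloc[i, j]:.2f})"

    for i in range(t):
        for j in range(t):
            if i == j:
                out.iloc[i, j] = fmt(r["covariance"], r["covariance_ci_low"],
                                     r["covariance_ci_high"], i, j)
            elif i < j:
                out.iloc[i, j] = fmt(r["correlation"], r["correlation_ci_low"],
                                     r["correlation_ci_high"], i, j)
            else:
                out.iloc[i, j] = fmt(r["covariance"], r["covariance_ci_low"],
                                     r["covariance_ci_high"], i, j)
    return out


def eigen_syndrome(draws: CovMatrixDraws, level: str = "individual") -> SyndromeAxes:
    """Syndrome axes: eigen decomposition with posterior credible intervals.

    Point axes come from the posterior-mean among-individual matrix; each
    draw's matrix is decomposed, its eigenvectors sign-aligned to the
    point axes (positive dot product), and loading-wise / share-wise
    quantiles give the 95% CIs.  The sign convention makes each point
    axis's largest-magnitude loading positive.
    """
    s = draws.levels[level]
    n_draws, t, _ = s.shape
    s_bar = s.mean(axis=0)
    vals, vecs = np.linalg.eigh(s_bar)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(t):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    shares_pt = vals / vals.sum()

    all_loadings = np.empty((n_draws, t, t))
    all_shares = np.empty((n_draws, t))
    for di in range(n_draws):
        v, w = np.linalg.eigh(s[di])
        o = np.argsort(v)[::-1]
        v = v[o]
        w = w[:, o]
        for j in range(t):
            if w[:, j] @ vecs[:, j] < 0:
                w[:, j] = -w[:, j]
        all_loadings[di] = w
        all_shares[di] = v / v.sum()

    shares_ci = np.stack(
        [np.quantile(all_shares, 0.025, axis=0), np.quantile(all_shares, 0.975, axis=0)],
        axis=1,
    )
    loadings_ci = np.stack(
        [np.quantile(all_loadings, 0.025, axis=0), np.quantile(all_loadings, 0.975, axis=0)],
        axis=2,
    )
    degenerate = bool(shares_ci[0, 0] <= shares_ci[1, 1])
    if degenerate:
        logger.warning(
            "eigen_syndrome: leading eigenvalue-share CIs overlap; axes weakly identified"
        )
    return SyndromeAxes(
        traits=tuple(draws.traits),
        eigenvalues=vals,
        shares=shares_pt,
        loadings=vecs,
        shares_ci=shares_ci,
        loadings_ci=loadings_ci,
        degenerate=degenerate,
    )


def loadings_table(axes: SyndromeAxes, n_axes: int = 2) -> pd.DataFrame:
    """Per-trait loadings on the leading axes with CIs (one row per trait)."""
    rows = []
    for j in range(min(n_axes, len(axes.traits))):
        for i, tr in enumerate(axes.traits):
            rows.append(
                {
                    "axis": f"PC{j + 1}",
                    "trait": tr,
                    "loading": axes.loadings[i, j],
                    "ci_low": axes.loadings_ci[i, j, 0],
                    "ci_high": axes.loadings_ci[i, j, 1],
                    "eigenvalue_share": axes.shares[j],
                }
            )
    return pd.DataFrame(rows)
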