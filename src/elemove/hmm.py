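"""Two-state hidden Markov movement model.

Movement steps are classified as *encamped* (short steps, high turning
angles: resting/foraging) or *exploratory* (long, directionally persistent
steps: transit between patches).  Emissions are a gamma distribution on
step length — with an optional discrete mass at exactly-zero steps, where
the gamma density is undefined — times a von Mises distribution on turning
angle; missing angles (burst starts) contribute a likelihood factor of 1.

Fitting is direct numerical maximisation of the forward log-likelihood
over unconstrained transforms (log for means/SDs/concentrations, logit
for transition probabilities and zero masses), from several perturbed
moment-based starts.  The initial state distribution is fixed at the
stationary distribution of the transition matrix.  The state label
"exploratory" is resolved, after fitting, as the state with the larger
mean step length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, special, stats

from .tracks import ConfigurationError, Trajectory

logger = logging.getLogger("elemove")

ENCAMPED, EXPLORATORY = 0, 1
STATE_NAMES = ("encamped", "exploratory")

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameters

@dataclass
class HmmParams:
    """Emission and transition parameters of the 2-state movement model.

    Gamma step lengths are parametrised by mean ``mu`` and standard
    deviation ``sigma`` (metres), the common movement-HMM convention;
    they are converted to shape/scale internally.  ``kappa`` is the von
    Mises concentration (0 = uniform angles), ``angle_mean`` in
    (-pi, pi].  ``zero_mass`` is the probability of an exactly-zero step.
    State order is (encamped, exploratory).
    """

    mu: np.ndarray
    sigma: np.ndarray
    angle_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    kappa: np.ndarray = field(default_factory=lambda: np.array([0.5, 1.0]))
    zero_mass: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tpm: np.ndarray = field(default_factory=lambda: np.array([[0.9, 0.1], [0.1, 0.9]]))

    def __post_init__(self):
        for name in ("mu", "sigma", "angle_mean", "kappa", "zero_mass", "tpm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> None:
        if self.mu.shape != (2,) or self.sigma.shape != (2,) or self.tpm.shape != (2, 2):
            raise ConfigurationError("HmmParams arrays must be length-2 (tpm 2x2)")
        if not (np.all(self.mu > 0) and np.all(self.sigma > 0)):
            raise ConfigurationError("mu and sigma must be positive")
        if not np.all(self.kappa >= 0):
            raise ConfigurationError("kappa must be non-negative")
        if not (np.all(self.zero_mass >= 0) and np.all(self.zero_mass < 1)):
            raise ConfigurationError("zero_mass must lie in [0, 1)")
        if not (np.all(self.tpm >= 0) and np.allclose(self.tpm.sum(axis=1), 1.0)):
            raise ConfigurationError("tpm rows must lie on the simplex")
        if not np.isfinite(np.concatenate([self.mu, self.sigma, self.kappa,
                                           self.angle_mean, self.tpm.ravel()])).all():
            raise ConfigurationError("non-finite HMM parameter")

    @property
    def delta(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        g = self.tpm
        denom = g[0, 1] + g[1, 0]
        if denom <= 0:
            return np.array([0.5, 0.5])
        return np.array([g[1, 0] / denom, g[0, 1] / denom])

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.mu / self.sigma) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.sigma**2 / self.mu

    def relabelled(self) -> "HmmParams":
        """Return params with the larger-mu state in the exploratory slot."""
        if self.mu[EXPLORATORY] >= self.mu[ENCAMPED]:
            return self
        perm = [1, 0]
        return HmmParams(
            mu=self.mu[perm],
            sigma=self.sigma[perm],
            angle_mean=self.angle_mean[perm],
            kappa=self.kappa[perm],
            zero_mass=self.zero_mass[perm],
            tpm=self.tpm[np.ix_(perm, perm)],
        )

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "angle_mean": self.angle_mean.tolist(),
            "kappa": self.kappa.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "tpm": self.tpm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


# ---------------------------------------------------------------------------
# step series construction

def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out


def build_step_series(traj: Trajectory) -> pd.DataFrame:
    """Step lengths and turning angles from a burst-segmented trajectory.

    One row per step (displacement between consecutive fixes within a
    burst).  The turning angle — signed change of bearing, counter-
    clockwise positive — is defined from the second step of each burst,
    and only where both adjacent steps have nonzero length.  Bursts of
    fewer than 2 fixes contribute no steps.

    Columns: individual_id, burst, t_local (step start), length (m),
    angle (rad, NaN where undefined), zero_flag.
    """
    f = traj.fixes
    if (f["burst"] < 0).any():
        raise ValueError("bursts not populated; run segment_bursts first")
    frames = []
    for b, grp in f.groupby("burst", sort=True):
        if len(grp) < 2:
            continue
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        dx = np.diff(x)
        dy = np.diff(y)
        length = np.hypot(dx, dy)
        bearing = np.arctan2(dy, dx)
        angle = np.full(len(length), np.nan)
        if len(length) > 1:
            turn = wrap_angle(bearing[1:] - bearing[:-1])
            ok = (length[1:] > 0) & (length[:-1] > 0)
            angle[1:] = np.where(ok, turn, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": traj.individual_id,
                    "burst": int(b),
                    "t_local": grp["t_local"].to_numpy()[:-1],
                    "length": length,
                    "angle": angle,
                    "zero_flag": length == 0.0,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["individual_id", "burst", "t_local", "length", "angle", "zero_flag"]
        )
    return pd.concat(frames, ignore_index=True)


def pool_step_series(series: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-individual step series, re-keying bursts globally."""
    frames = []
    offset = 0
    for s in series:
        if len(s) == 0:
            continue
        s = s.copy()
        codes = pd.factorize(s["burst"])[0]
        s["burst"] = codes + offset
        offset += codes.max() + 1
        frames.append(s)
    if not frames:
        return pd.DataFrame(
            columns=["individual_id", "burst", "t_local", "length", "angle", "zero_flag"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# likelihood

def _emission_logdens(params: HmmParams, length, angle) -> np.ndarray:
    """(n, 2) log emission density: zero-mixed gamma x von Mises."""
    length = np.asarray(length, dtype=float)
    angle = np.asarray(angle, dtype=float)
    n = len(length)
    logB = np.zeros((n, 2))
    zero = length == 0.0
    for s in range(2):
        lb = np.empty(n)
        if zero.any():
            with np.errstate(divide="ignore"):
                lb[zero] = np.log(params.zero_mass[s]) if params.zero_mass[s] > 0 else -np.inf
        pos = ~zero
        if pos.any():
            lg = stats.gamma.logpdf(
                length[pos], a=params.gamma_shape[s], scale=params.gamma_scale[s]
            )
            lb[pos] = np.log1p(-params.zero_mass[s]) + lg
        # von Mises; kappa = 0 reduces to the circular uniform 1/(2 pi)
        have = np.isfinite(angle)
        k = params.kappa[s]
        vm = np.zeros(n)
        vm[have] = (
            k * np.cos(angle[have] - params.angle_mean[s])
            - LOG_2PI
            - np.log(special.i0e(k))
            - k
        )
        logB[:, s] = lb + vm
    return logB


@njit(cache=False)
def _forward_kernel(logB, burst_start, log_delta, log_tpm):  # pragma: no cover
    n = logB.shape[0]
    ll = 0.0
    p0 = 0.0
    p1 = 0.0
    for i in range(n):
        if burst_start[i]:
            a0 = log_delta[0] + logB[i, 0]
            a1 = log_delta[1] + logB[i, 1]
        else:
            t0 = p0 + log_tpm[0, 0]
            u0 = p1 + log_tpm[1, 0]
            m0 = t0 if t0 > u0 else u0
            t1 = p0 + log_tpm[0, 1]
            u1 = p1 + log_tpm[1, 1]
            m1 = t1 if t1 > u1 else u1
            a0 = m0 + np.log(np.exp(t0 - m0) + np.exp(u0 - m0)) + logB[i, 0]
            a1 = m1 + np.log(np.exp(t1 - m1) + np.exp(u1 - m1)) + logB[i, 1]
        m = a0 if a0 > a1 else a1
        c = m + np.log(np.exp(a0 - m) + np.exp(a1 - m))
        ll += c
        p0 = a0 - c
        p1 = a1 - c
    return ll


@njit(cache=False)
def _viterbi_kernel(logB, burst_start, log_delta, log_tpm):  # pragma: no cover
    n = logB.shape[0]
    path = np.zeros(n, dtype=np.int64)
    back = np.zeros((n, 2), dtype=np.int64)
    v0 = 0.0
    v1 = 0.0
    seg_start = 0
    for i in range(n + 1):
        end_of_seg = i == n or (i > seg_start and burst_start[i])
        if end_of_seg:
            # backtrace segment [seg_start, i)
            j = i - 1
            # tie toward encamped (state 0)
            s = 0 if v0 >= v1 else 1
            path[j] = s
            while j > seg_start:
                s = back[j, s]
                j -= 1
                path[j] = s
            seg_start = i
        if i == n:
            break
        if burst_start[i] or i == seg_start:
            v0 = log_delta[0] + logB[i, 0]
            v1 = log_delta[1] + logB[i, 1]
        else:
            c00 = v0 + log_tpm[0, 0]
            c10 = v1 + log_tpm[1, 0]
            if c00 >= c10:
                n0 = c00 + logB[i, 0]
                back[i, 0] = 0
            else:
                n0 = c10 + logB[i, 0]
                back[i, 0] = 1
            c01 = v0 + log_tpm[0, 1]
            c11 = v1 + log_tpm[1, 1]
            if c01 >= c11:
                n1 = c01 + logB[i, 1]
                back[i, 1] = 0
            else:
                n1 = c11 + logB[i, 1]
                back[i, 1] = 1
            v0 = n0
            v1 = n1
    return path


def _burst_start_flags(steps: pd.DataFrame) -> np.ndarray:
    b = steps["burst"].to_numpy()
    flags = np.ones(len(b), dtype=np.bool_)
    if len(b) > 1:
        flags[1:] = b[1:] != b[:-1]
    return flags


def forward_loglik(params: HmmParams, steps: pd.DataFrame) -> float:
    """Exact forward log-likelihood; bursts are independent realisations."""
    params.validate()
    if len(steps) == 0:
        return 0.0
    logB = _emission_logdens(params, steps["length"].to_numpy(), steps["angle"].to_numpy())
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.delta)
        log_tpm = np.log(params.tpm)
    ll = _forward_kernel(logB, _burst_start_flags(steps), log_delta, log_tpm)
    if np.isnan(ll):
        raise FloatingPointError("forward log-likelihood is NaN")
    return float(ll)


def viterbi_decode(params: HmmParams, steps: pd.DataFrame) -> np.ndarray:
    """Most probable state path per burst (0 = encamped, 1 = exploratory).

    Exact dynamic-programming argmax; ties resolved toward encamped.
    """
    params.validate()
    if len(steps) == 0:
        return np.zeros(0, dtype=int)
    logB = _emission_logdens(params, steps["length"].to_numpy(), steps["angle"].to_numpy())
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.delta)
        log_tpm = np.log(params.tpm)
    return np.asarray(
        _viterbi_kernel(logB, _burst_start_flags(steps), log_delta, log_tpm), dtype=int
    )


def state_posteriors(params: HmmParams, steps: pd.DataFrame) -> np.ndarray:
    """(n, 2) forward-backward posterior state probabilities."""
    params.validate()
    n = len(steps)
    logB = _emission_logdens(params, steps["length"].to_numpy(), steps["angle"].to_numpy())
    flags = _burst_start_flags(steps)
    with np.errstate(divide="ignore"):
        ld = np.log(params.delta)
        lt = np.log(params.tpm)
    la = np.zeros((n, 2))
    for i in range(n):
        if flags[i]:
            la[i] = ld + logB[i]
        else:
            la[i] = special.logsumexp(la[i - 1][:, None] + lt, axis=0) + logB[i]
    lb = np.zeros((n, 2))
    for i in range(n - 2, -1, -1):
        if flags[i + 1]:
            lb[i] = 0.0
        else:
            lb[i] = special.logsumexp(lt + (logB[i + 1] + lb[i + 1])[None, :], axis=1)
    lp = la + lb
    lp -= special.logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)


# ---------------------------------------------------------------------------
# fitting

def _pack(params: HmmParams, fit_zero_mass: bool) -> np.ndarray:
    logit = lambda p: np.log(p) - np.log1p(-p)
    vec = [
        np.log(params.mu),
        np.log(params.sigma),
        params.angle_mean,
        np.log(np.maximum(params.kappa, 1e-8)),
        [logit(np.clip(params.tpm[0, 1], 1e-6, 1 - 1e-6)),
         logit(np.clip(params.tpm[1, 0], 1e-6, 1 - 1e-6))],
    ]
    if fit_zero_mass:
        vec.append(logit(np.clip(params.zero_mass, 1e-8, 1 - 1e-8)))
    return np.concatenate([np.atleast_1d(np.asarray(v, dtype=float)) for v in vec])


def _unpack(vec: np.ndarray, fit_zero_mass: bool) -> HmmParams:
    expit = special.expit
    mu = np.exp(vec[0:2])
    sigma = np.exp(vec[2:4])
    # single unconstrained angle parameter, wrapped into (-pi, pi] via atan2
    angle_mean = np.arctan2(np.sin(vec[4:6]), np.cos(vec[4:6]))
    kappa = np.exp(vec[6:8])
    g01 = expit(vec[8])
    g10 = expit(vec[9])
    zero_mass = expit(vec[10:12]) if fit_zero_mass else np.zeros(2)
    return HmmParams(
        mu=mu,
        sigma=sigma,
        angle_mean=angle_mean,
        kappa=kappa,
        zero_mass=zero_mass,
        tpm=np.array([[1 - g01, g01], [g10, 1 - g10]]),
    )


def _kappa_from_resultant(r: float) -> float:
    """Best-practice approximation to the inverse of A(kappa) = I1/I0."""
    r = min(max(r, 1e-6), 0.999)
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def _moment_start(steps: pd.DataFrame) -> HmmParams:
    length = steps["length"].to_numpy()
    pos = length[length > 0]
    med = np.median(pos)
    lo = pos[pos <= med]
    hi = pos[pos > med]
    angle = steps["angle"].to_numpy()
    angle = angle[np.isfinite(angle)]
    if len(angle):
        r = float(np.hypot(np.mean(np.cos(angle)), np.mean(np.sin(angle))))
        k = _kappa_from_resultant(r)
    else:
        k = 0.5
    zm = float(np.mean(length == 0.0))
    return HmmParams(
        mu=np.array([np.mean(lo), np.mean(hi)]),
        sigma=np.array([max(np.std(lo), 1e-3 * np.mean(lo)),
                        max(np.std(hi), 1e-3 * np.mean(hi))]),
        angle_mean=np.zeros(2),
        kappa=np.array([max(k, 0.05), max(2 * k, 0.1)]),
        zero_mass=np.array([zm, zm]),
        tpm=np.array([[0.9, 0.1], [0.1, 0.9]]),
    )


def fit_hmm(
    steps: pd.DataFrame,
    n_restarts: int = 10,
    seed: int | None = None,
    start: HmmParams | None = None,
) -> tuple[HmmParams, dict]:
    """Maximum-likelihood fit of the 2-state movement HMM.

    Pools all supplied steps into one model (the common scale on which
    every step is classified).  Runs ``n_restarts`` L-BFGS maximisations
    from multiplicatively perturbed moment-based starts and keeps the
    best; the zero-step mass is estimated only when exact zeros occur in
    the data.  Returns label-resolved parameters (exploratory = larger
    mean step) and a convergence report.
    """
    if len(steps) < 50:
        raise ValueError("need at least 50 steps to fit the HMM")
    fit_zero_mass = bool((steps["length"].to_numpy() == 0.0).any())
    rng = np.random.default_rng(seed)
    base = start if start is not None else _moment_start(steps)

    def nll(vec):
        try:
            p = _unpack(vec, fit_zero_mass)
            return -forward_loglik(p, steps)
        except (FloatingPointError, ConfigurationError):
            return 1e12

    best = None
    n_converged = 0
    results = []
    for k in range(n_restarts):
        p0 = base
        if k > 0:
            p0 = replace(
                base,
                mu=base.mu * np.exp(rng.normal(0, 0.3, 2)),
                sigma=base.sigma * np.exp(rng.normal(0, 0.3, 2)),
                kappa=base.kappa * np.exp(rng.normal(0, 0.4, 2)),
                angle_mean=wrap_angle(base.angle_mean + rng.normal(0, 0.5, 2)),
            )
        x0 = _pack(p0, fit_zero_mass)
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        results.append(res)
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all HMM restarts failed: " + "; ".join(r.message for r in results))
    if n_converged == 0:
        logger.warning("fit_hmm: no restart reported clean convergence; using best found")
    params = _unpack(best.x, fit_zero_mass).relabelled()
    if params.kappa.max() > 500 or params.tpm.min() < 1e-5:
        logger.warning("fit_hmm: parameter at or near boundary; data may be single-state")
    report = {
        "loglik": -float(best.fun),
        "n_restarts": n_restarts,
        "n_converged": n_converged,
        "n_steps": len(steps),
        "fit_zero_mass": fit_zero_mass,
    }
    return params, report


# ---------------------------------------------------------------------------
# simulation

def simulate_hmm_track(
    params: HmmParams, n_steps: int, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one burst of steps from the model; returns (steps, states).

    States follow the Markov chain from the stationary initial law; the
    first step's angle is undefined, as in real step series.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    states = np.zeros(n_steps, dtype=int)
    states[0] = rng.choice(2, p=params.delta)
    for i in range(1, n_steps):
        states[i] = rng.choice(2, p=params.tpm[states[i - 1]])
    length = rng.gamma(params.gamma_shape[states], params.gamma_scale[states])
    zero = rng.random(n_steps) < params.zero_mass[states]
    length = np.where(zero, 0.0, length)
    angle = wrap_angle(
        rng.vonmises(params.angle_mean[states], np.maximum(params.kappa[states], 1e-12))
    )
    kappa0 = params.kappa[states] == 0
    if kappa0.any():
        angle[kappa0] = rng.uniform(-np.pi, np.pi, int(kappa0.sum()))
    angle[0] = np.nan
    t0 = pd.Timestamp("2016-01-01")
    steps = pd.DataFrame(
        {
            "individual_id": "sim",
            "burst": 0,
            "t_local": t0 + pd.to_timedelta(np.arange(n_steps), unit="h"),
            "length": length,
            "angle": angle,
            "zero_flag": length == 0.0,
        }
    )
    return steps, states
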