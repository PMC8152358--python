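"""3-state hidden Markov model for behavioural segmentation of tracks.

States (rest, forage, travel) emit gamma-distributed step lengths and von
Mises turn angles.  Fitting is direct maximization of the forward-algorithm
log-likelihood from multiple random restarts, in an unconstrained
parametrization (log scale for gamma mean/sd and concentration, row-softmax
for the transition matrix, free angle for the turn mean).  Trips are
independent chains: the initial distribution is re-applied at every trip
boundary.

Zero step lengths are floored at 1 m before gamma evaluation (the density is
undefined at 0 and 1 m is far below any behavioural scale).  The first turn
angle of each trip is missing, not zero; missing turns contribute only the
step density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, stats

from .synthetic import FORAGE, REST, STATE_NAMES, TRAVEL

N_STATES = 3
MIN_STEP_KM = 0.001  # 1 m floor for zero-length steps

#: Default "realistic limits" for random restart initial values.
DEFAULT_LIMITS = {
    "step_mean": (0.01, 2.0),
    "step_sd": (0.01, 2.0),
    "kappa": (0.1, 10.0),
}


class HMMFitError(RuntimeError):
    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


@dataclass
class HMMParams:
    """Emission and transition parameters, states ordered rest/forage/travel."""

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mu: np.ndarray
    turn_kappa: np.ndarray
    transition: np.ndarray
    initial: np.ndarray

    def validate(self) -> None:
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma means and sds must be positive")
        if np.any(self.turn_kappa < 0):
            raise ValueError("von Mises concentration must be >= 0")
        if not np.allclose(np.asarray(self.transition).sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(np.sum(self.initial), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")

    def permuted(self, order) -> "HMMParams":
        order = np.asarray(order)
        return HMMParams(
            step_mean=self.step_mean[order],
            step_sd=self.step_sd[order],
            turn_mu=self.turn_mu[order],
            turn_kappa=self.turn_kappa[order],
            transition=self.transition[np.ix_(order, order)],
            initial=self.initial[order],
        )

    def canonical(self) -> "HMMParams":
        """Reorder states by ascending gamma step mean (rest < forage < travel)."""
        return self.permuted(np.argsort(self.step_mean, kind="stable"))


@dataclass
class StateSequence:
    """Decoded states aligned to HMM observations (one per step)."""

    labels: np.ndarray  # most-probable state per observation
    posteriors: np.ndarray  # (T, 3) forward-backward posteriors
    seq_bounds: np.ndarray  # start index of each trip's slice, plus T
    trip_ids: list

    def per_trip_labels(self, i: int) -> np.ndarray:
        return self.labels[self.seq_bounds[i] : self.seq_bounds[i + 1]]


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------


def steps_and_turns(trip) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths (km) and signed turn angles (rad) for a regularized trip.

    Step i is the Euclidean distance fix i -> i+1; turn i is the heading
    change step i-1 -> step i wrapped to (-pi, pi].  The first turn is NaN.
    """
    fixes = trip.fixes if hasattr(trip, "fixes") else trip
    if len(fixes) < 3:
        raise ValueError("need at least 3 fixes for steps and turns")
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dx, dy)
    turns = np.full(steps.size, np.nan)
    turns[1:] = wrap_angle(np.diff(headings))
    return steps, turns


def collect_data(trips) -> list[tuple[np.ndarray, np.ndarray]]:
    """steps_and_turns over a list of trips (each an independent chain)."""
    return [steps_and_turns(t) for t in trips]


def _log_emissions(params: HMMParams, steps: np.ndarray, turns: np.ndarray) -> np.ndarray:
    s = np.maximum(steps, MIN_STEP_KM)
    shape = (params.step_mean / params.step_sd) ** 2
    scale = params.step_sd**2 / params.step_mean
    logB = np.empty((s.size, N_STATES))
    for k in range(N_STATES):
        logB[:, k] = stats.gamma.logpdf(s, shape[k], scale=scale[k])
        ok = ~np.isnan(turns)
        if ok.any():
            logB[ok, k] += stats.vonmises.logpdf(
                turns[ok], params.turn_kappa[k], loc=params.turn_mu[k]
            )
    return logB


# ---------------------------------------------------------------------------
# Numba cores
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_ll(logB, logA, logpi):
    T, K = logB.shape
    alpha = logpi + logB[0]
    work = np.empty(K)
    for t in range(1, T):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = alpha[j] + logA[j, k]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(alpha[j] + logA[j, k] - m)
            work[k] = m + np.log(s) + logB[t, k]
        alpha = work.copy()
    m = alpha.max()
    return m + np.log(np.sum(np.exp(alpha - m)))


@njit(cache=True)
def _viterbi(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for k in range(K):
            best, arg = -np.inf, 0
            for j in range(K):
                v = delta[j] + logA[j, k]
                if v > best:
                    best, arg = v, j
            new[k] = best + logB[t, k]
            back[t, k] = arg
        delta = new
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, delta.max()


@njit(cache=True)
def _forward_backward(logB, logA, logpi):
    T, K = logB.shape
    la = np.empty((T, K))
    la[0] = logpi + logB[0]
    for t in range(1, T):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = la[t - 1, j] + logA[j, k]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(la[t - 1, j] + logA[j, k] - m)
            la[t, k] = m + np.log(s) + logB[t, k]
    lb = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        for k in range(K):
            m = -np.inf
            for j in range(K):
                v = logA[k, j] + logB[t + 1, j] + lb[t + 1, j]
                if v > m:
                    m = v
            s = 0.0
            for j in range(K):
                s += np.exp(logA[k, j] + logB[t + 1, j] + lb[t + 1, j] - m)
            lb[t, k] = m + np.log(s)
    post = la + lb
    for t in range(T):
        m = post[t].max()
        z = m + np.log(np.sum(np.exp(post[t] - m)))
        post[t] = np.exp(post[t] - z)
    return post


# ---------------------------------------------------------------------------
# Likelihood / decoding
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_ll_fast(log_steps, steps, turns, has_turn, A, pi,
                     am1, inv_scale, lng, kappa, mu, lnv):
    """Scaled linear-space forward pass with inline emission evaluation.

    Emission log-densities are computed from precomputed per-state constants
    (gamma shape-1, 1/scale, log normalizers; von Mises kappa, mu, log
    normalizer), row-shifted by their max before exponentiation for safety.
    """
    T = steps.size
    K = pi.size
    alpha = np.empty(K)
    work = np.empty(K)
    lb = np.empty(K)
    ll = 0.0
    for t in range(T):
        for k in range(K):
            v = am1[k] * log_steps[t] - steps[t] * inv_scale[k] + lng[k]
            if has_turn[t]:
                v += kappa[k] * np.cos(turns[t] - mu[k]) + lnv[k]
            lb[k] = v
        m = lb[0]
        for k in range(1, K):
            if lb[k] > m:
                m = lb[k]
        if t == 0:
            for k in range(K):
                work[k] = pi[k] * np.exp(lb[k] - m)
        else:
            for k in range(K):
                s = 0.0
                for j in range(K):
                    s += alpha[j] * A[j, k]
                work[k] = s * np.exp(lb[k] - m)
        c = 0.0
        for k in range(K):
            c += work[k]
        if c <= 0.0 or not np.isfinite(c):
            return -np.inf
        ll += m + np.log(c)
        for k in range(K):
            alpha[k] = work[k] / c
    return ll


def _emission_constants(params: HMMParams):
    from scipy.special import gammaln, i0e

    shape = (params.step_mean / params.step_sd) ** 2
    scale = params.step_sd**2 / params.step_mean
    am1 = shape - 1.0
    inv_scale = 1.0 / scale
    lng = -shape * np.log(scale) - gammaln(shape)
    kappa = params.turn_kappa
    # log(2*pi*I0(k)) computed overflow-free via the scaled Bessel function
    lnv = -(np.log(2 * np.pi) + np.log(i0e(kappa)) + kappa)
    return am1, inv_scale, lng, kappa, params.turn_mu, lnv


def _prepare_sequences(data):
    """Cache floored steps, their logs and turn masks per sequence."""
    prepped = []
    for steps, turns in data:
        s = np.maximum(np.asarray(steps, dtype=float), MIN_STEP_KM)
        t = np.asarray(turns, dtype=float)
        has_turn = ~np.isnan(t)
        prepped.append((np.log(s), s, np.where(has_turn, t, 0.0), has_turn))
    return prepped


def _loglik_prepped(params: HMMParams, prepped) -> float:
    A = np.asarray(params.transition, dtype=float)
    pi = np.asarray(params.initial, dtype=float)
    am1, inv_scale, lng, kappa, mu, lnv = _emission_constants(params)
    total = 0.0
    for log_s, s, t, has_turn in prepped:
        total += _forward_ll_fast(log_s, s, t, has_turn, A, pi, am1, inv_scale, lng, kappa, mu, lnv)
    return float(total)


def hmm_loglik(params: HMMParams, data) -> float:
    """Forward-algorithm log-likelihood over independent trip sequences."""
    params.validate()
    return _loglik_prepped(params, _prepare_sequences(data))


def decode_states(params: HMMParams, data, trip_ids=None) -> StateSequence:
    """Viterbi most-probable path plus forward-backward posteriors."""
    params.validate()
    logA = np.log(np.asarray(params.transition, dtype=float))
    logpi = np.log(np.asarray(params.initial, dtype=float))
    labels, posts, bounds = [], [], [0]
    for steps, turns in data:
        logB = _log_emissions(params, steps, turns)
        path, _ = _viterbi(logB, logA, logpi)
        labels.append(path)
        posts.append(_forward_backward(logB, logA, logpi))
        bounds.append(bounds[-1] + steps.size)
    if trip_ids is None:
        trip_ids = [str(i) for i in range(len(data))]
    return StateSequence(
        labels=np.concatenate(labels) if labels else np.empty(0, dtype=int),
        posteriors=np.vstack(posts) if posts else np.empty((0, N_STATES)),
        seq_bounds=np.asarray(bounds),
        trip_ids=list(trip_ids),
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _pack(params: HMMParams) -> np.ndarray:
    tr = np.asarray(params.transition, dtype=float)
    traw = np.log(tr[:, :2] / tr[:, 2:3]).ravel()
    return np.concatenate(
        [
            np.log(params.step_mean),
            np.log(params.step_sd),
            params.turn_mu,
            np.log(np.maximum(params.turn_kappa, 1e-8)),
            traw,
        ]
    )


def _unpack(theta: np.ndarray) -> HMMParams:
    step_mean = np.exp(theta[0:3])
    step_sd = np.exp(theta[3:6])
    turn_mu = wrap_angle(theta[6:9])
    turn_kappa = np.exp(theta[9:12])
    traw = theta[12:18].reshape(3, 2)
    logits = np.concatenate([traw, np.zeros((3, 1))], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    transition = expl / expl.sum(axis=1, keepdims=True)
    vals, vecs = np.linalg.eig(transition.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    initial = v / v.sum()
    return HMMParams(step_mean, step_sd, turn_mu, turn_kappa, transition, initial)


@dataclass
class RestartDiagnostic:
    restart: int
    converged: bool
    nll: float
    message: str


@dataclass
class FitResult:
    params: HMMParams
    loglik: float
    n_restarts: int
    diagnostics: list = field(default_factory=list)
    best_restart: int = -1


def _random_init(rng, limits) -> np.ndarray:
    lo_m, hi_m = limits["step_mean"]
    lo_s, hi_s = limits["step_sd"]
    lo_k, hi_k = limits["kappa"]
    step_mean = np.sort(np.exp(rng.uniform(np.log(lo_m), np.log(hi_m), 3)))
    step_sd = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), 3))
    turn_mu = rng.uniform(-np.pi, np.pi, 3)
    kappa = np.exp(rng.uniform(np.log(lo_k), np.log(hi_k), 3))
    traw = rng.normal(0.0, 1.0, 6)
    return np.concatenate(
        [np.log(step_mean), np.log(step_sd), turn_mu, np.log(kappa), traw]
    )


def fit_hmm(
    data,
    n_restarts: int = 25,
    seed: int = 0,
    limits: dict | None = None,
    init: HMMParams | None = None,
    maxiter: int = 500,
    coarse_maxiter: int = 60,
    polish_top: int = 3,
) -> FitResult:
    """Fit the 3-state HMM by multi-restart quasi-Newton likelihood ascent.

    Restart initial values are drawn uniformly (log-uniform for positive
    parameters) within ``limits``.  Every restart gets a coarse L-BFGS run
    (``coarse_maxiter`` iterations); the ``polish_top`` best are then run to
    full convergence and the overall best wins.  Returned parameters are
    canonically ordered by ascending step mean (rest < forage < travel).
    """
    limits = {**DEFAULT_LIMITS, **(limits or {})}
    rng = np.random.default_rng(seed)
    prepped = _prepare_sequences(data)

    # coarse restarts run on a prefix of each sequence (enough to locate the
    # basin); polishing always uses the full data
    total_obs = sum(p[1].size for p in prepped)
    coarse_cap = 20000
    if total_obs > coarse_cap:
        frac = coarse_cap / total_obs
        prepped_coarse = [
            tuple(a[: max(int(a.shape[0] * frac), 500)] for a in p) for p in prepped
        ]
    else:
        prepped_coarse = prepped

    def make_nll(pr):
        def nll(theta):
            try:
                with np.errstate(over="ignore", invalid="ignore"):
                    v = -_loglik_prepped(_unpack(theta), pr)
                return v if np.isfinite(v) else 1e12
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return 1e12

        return nll

    nll = make_nll(prepped)
    nll_coarse = make_nll(prepped_coarse)

    diagnostics: list[RestartDiagnostic] = []
    inits = []
    if init is not None:
        inits.append(_pack(init))
    while len(inits) < n_restarts:
        inits.append(_random_init(rng, limits))

    coarse = []
    for r, x0 in enumerate(inits):
        res = optimize.minimize(
            nll_coarse, x0, method="L-BFGS-B", options={"maxiter": coarse_maxiter, "maxfun": 20000}
        )
        coarse.append((float(res.fun), res.x, r))
        diagnostics.append(
            RestartDiagnostic(r, bool(res.success), float(res.fun), str(res.message))
        )

    coarse.sort(key=lambda c: c[0])
    best = None
    n_polish = max(1, min(polish_top, len(coarse)))
    for fun0, x0, r in coarse[:n_polish]:
        if not np.isfinite(fun0):
            continue
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 50000}
        )
        diagnostics.append(
            RestartDiagnostic(r, bool(res.success), float(res.fun), "polish: " + str(res.message))
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x, r)

    if best is None or not np.isfinite(best[0]) or best[0] >= 1e12:
        raise HMMFitError("all restarts failed to converge", diagnostics)
    params = _unpack(best[1]).canonical()
    return FitResult(
        params=params,
        loglik=-best[0],
        n_restarts=len(inits),
        diagnostics=diagnostics,
        best_restart=best[2],
    )


# ---------------------------------------------------------------------------
# Downstream extraction / validation
# ---------------------------------------------------------------------------


def fix_labels_for_trip(seq: StateSequence, i: int) -> np.ndarray:
    """Per-fix labels for trip i: fix j takes the state of its outgoing step."""
    obs = seq.per_trip_labels(i)
    return np.append(obs, obs[-1])


def extract_foraging(seq: StateSequence, trips) -> tuple:
    """Foraging-only fixes and per-trip time-in-state proportions.

    Returns (foraging fixes DataFrame, proportions DataFrame with columns
    prop_rest / prop_forage / prop_travel summing to 1 per trip).
    """
    import pandas as pd

    forage_rows, prop_rows = [], []
    for i, trip in enumerate(trips):
        obs = seq.per_trip_labels(i)
        counts = np.bincount(obs, minlength=N_STATES)
        props = counts / counts.sum()
        prop_rows.append(
            {
                "trip_id": trip.trip_id,
                "bird_id": trip.bird_id,
                "prop_rest": props[REST],
                "prop_forage": props[FORAGE],
                "prop_travel": props[TRAVEL],
            }
        )
        labels = fix_labels_for_trip(seq, i)
        sub = trip.fixes.loc[labels == FORAGE].copy()
        sub["trip_id"] = trip.trip_id
        forage_rows.append(sub)
    props = pd.DataFrame(prop_rows)
    fixes = (
        pd.concat(forage_rows, ignore_index=True)
        if forage_rows
        else pd.DataFrame(columns=["timestamp", "x", "y", "trip_id"])
    )
    return fixes, props


@dataclass
class StateValidationReport:
    evaluable: bool
    dive_rate_per_h: dict
    wet_fraction: dict
    passed: bool | None


def validate_states(
    fix_states: np.ndarray,
    dive_counts: np.ndarray,
    wet_fraction: np.ndarray | None,
    dt_s: float = 30.0,
) -> StateValidationReport:
    """Contrast dive rate (and wet fraction) across decoded states.

    ``dive_counts`` holds dives matched to each fix; passes when the
    forage-state dive rate exceeds the travel-state rate.  With no sensor
    data the report is flagged not evaluable.
    """
    fix_states = np.asarray(fix_states)
    dive_counts = np.asarray(dive_counts, dtype=float)
    if fix_states.size == 0 or dive_counts.sum() == 0:
        return StateValidationReport(False, {}, {}, None)
    rates, wets = {}, {}
    for k, name in enumerate(STATE_NAMES):
        mask = fix_states == k
        hours = mask.sum() * dt_s / 3600.0
        rates[name] = float(dive_counts[mask].sum() / hours) if hours > 0 else np.nan
        if wet_fraction is not None:
            wf = np.asarray(wet_fraction, dtype=float)[mask]
            wets[name] = float(np.nanmean(wf)) if wf.size else np.nan
    passed = bool(rates.get("forage", 0) > rates.get("travel", 0))
    return StateValidationReport(True, rates, wets, passed)


# ---------------------------------------------------------------------------
# Simulation (for recovery tests and acceptance checks)
# ---------------------------------------------------------------------------


def simulate(params: HMMParams, n: int, seed: int = 0, first_turn_missing: bool = True):
    """Simulate (steps, turns, states) of length n from the model itself."""
    rng = np.random.default_rng(seed)
    A = np.asarray(params.transition, dtype=float)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(N_STATES, p=np.asarray(params.initial, dtype=float))
    cum = np.cumsum(A, axis=1)
    u = rng.random(n)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    shape = (params.step_mean / params.step_sd) ** 2
    scale = params.step_sd**2 / params.step_mean
    steps = rng.gamma(shape[states], scale[states])
    turns = rng.vonmises(params.turn_mu[states], params.turn_kappa[states])
    turns = wrap_angle(turns)
    if first_turn_missing:
        turns[0] = np.nan
    return steps, turns, states
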