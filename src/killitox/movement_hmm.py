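"""Hidden Markov model of larval swimming states.

Larval movement is modelled as a K-state HMM (default 3: slow, medium, fast)
over per-frame observations of step length and turning angle.  Emissions are
conditionally independent given the state: gamma step lengths and von Mises
turning angles — the standard movement-HMM choice.  Parameters are shared
across larvae (independent chains pooled in one likelihood), matching
group-level analyses where transition probabilities are treatment endpoints.

Fitting is Baum-Welch EM with multiple jittered moment-based restarts;
decoding is Viterbi.  The forward/backward/Viterbi recursions are
numba-compiled; both are validated elsewhere against exhaustive enumeration
over all K^T hidden paths on short series.

State labels are canonicalized after fitting so that mean step length is
increasing with state index (slow < medium < fast).  Viterbi ties resolve
to the lowest state index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, special

from .synthetic_data import MovementHMMParams

logger = logging.getLogger("killitox")

STEP_FLOOR_MM = 1e-6  # gamma support excludes 0; zero steps are floored


# ---------------------------------------------------------------------------
# Observation series
# ---------------------------------------------------------------------------

def series_from_trajectory(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Step-length and turning-angle series from a position table.

    Steps have length ``n - 1``; the turning angle aligned with step ``t`` is
    the turn executed into that step (NaN for the first step and wherever a
    zero-length displacement leaves the heading undefined).
    """
    x = traj["x_mm"].to_numpy(dtype=float)
    y = traj["y_mm"].to_numpy(dtype=float)
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    angles = np.full(len(steps), np.nan)
    for t in range(1, len(steps)):
        if steps[t - 1] > 0 and steps[t] > 0:
            cross = dx[t - 1] * dy[t] - dy[t - 1] * dx[t]
            dot = dx[t - 1] * dx[t] + dy[t - 1] * dy[t]
            angles[t] = np.arctan2(cross, dot)
    return steps, angles


def _normalize_series(series) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(series, tuple) and len(series) == 2 and np.ndim(series[0]) == 1:
        series = [series]
    out = []
    for steps, angles in series:
        steps = np.asarray(steps, dtype=float)
        angles = np.asarray(angles, dtype=float)
        if steps.shape != angles.shape:
            raise ValueError("step and angle series must align")
        if not np.all(np.isfinite(steps)):
            raise ValueError("non-finite step lengths in observation series")
        if np.any(steps < 0):
            raise ValueError("negative step lengths in observation series")
        n_floored = int((steps < STEP_FLOOR_MM).sum())
        if n_floored:
            logger.debug("flooring %d zero/near-zero steps at %g mm", n_floored, STEP_FLOOR_MM)
        steps = np.maximum(steps, STEP_FLOOR_MM)
        out.append((steps, angles))
    if not out:
        raise ValueError("need at least one observation series")
    return out


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------

def _gamma_shape_scale(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _log_emission(steps, angles, step_params, angle_params) -> np.ndarray:
    """log p(obs_t | state k), shape (T, K).  Missing angles contribute 0
    (they are marginalized out)."""
    K = step_params.shape[0]
    T = len(steps)
    logB = np.empty((T, K))
    logx = np.log(steps)
    have_angle = np.isfinite(angles)
    a = angles[have_angle]
    for k in range(K):
        shape, scale = _gamma_shape_scale(step_params[k, 0], step_params[k, 1])
        logB[:, k] = (
            (shape - 1.0) * logx - steps / scale - shape * np.log(scale) - special.gammaln(shape)
        )
        mu, kappa = angle_params[k]
        if kappa > 0:
            logB[have_angle, k] += (
                kappa * np.cos(a - mu) - np.log(2 * np.pi) - np.log(special.i0e(kappa)) - kappa
            )
        else:
            logB[have_angle, k] += -np.log(2 * np.pi)
    return logB


# ---------------------------------------------------------------------------
# Core recursions (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(pi, A, B):  # pragma: no cover - exercised via wrappers
    """Scaled forward-backward.  B rows are emission likelihoods rescaled so
    each row's max is 1; returns the loglik of the rescaled problem plus
    posteriors gamma (T, K) and summed transition posteriors xisum (K, K)."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    xisum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                xisum[i, j] += ai * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    return np.log(c).sum(), gamma, xisum


@njit(cache=True)
def _viterbi_core(logpi, logA, logB):  # pragma: no cover - exercised via wrappers
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best = -1e308
            arg = 0
            for i in range(K):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: ties keep the lowest state index
                    best = v
                    arg = i
            new[j] = best + logB[t, j]
            psi[t, j] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    best = -1e308
    arg = 0
    for i in range(K):
        if delta[i] > best:
            best = delta[i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def _estep_sequence(pi, A, logB):
    """Run scaled forward-backward on one sequence; returns true loglik."""
    rowmax = logB.max(axis=1)
    B = np.exp(logB - rowmax[:, None])
    ll, gamma, xisum = _forward_backward(pi, A, B)
    return ll + rowmax.sum(), gamma, xisum


def forward_loglik(pi, A, logB) -> float:
    """Marginal log-likelihood of one observation sequence (forward algorithm)."""
    ll, _, _ = _estep_sequence(np.asarray(pi, float), np.asarray(A, float), logB)
    return float(ll)


# ---------------------------------------------------------------------------
# Weighted emission MLEs (M-step)
# ---------------------------------------------------------------------------

_MAX_GAMMA_SHAPE = 1e8
_MAX_KAPPA = 1e4


def _weighted_gamma_mle(x: np.ndarray, logx: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE; returns (mean, sd)."""
    W = w.sum()
    wm = float((w * x).sum() / W)
    d = np.log(wm) - float((w * logx).sum() / W)
    if d <= 1e-12:
        shape = _MAX_GAMMA_SHAPE
    else:
        shape = (3.0 - d + np.sqrt((d - 3.0) ** 2 + 24.0 * d)) / (12.0 * d)
        for _ in range(100):
            f = np.log(shape) - special.digamma(shape) - d
            fp = 1.0 / shape - special.polygamma(1, shape)
            step = f / fp
            new = shape - step
            if new <= 0:
                new = shape / 2.0
            if abs(new - shape) < 1e-12 * shape:
                shape = new
                break
            shape = new
        shape = min(shape, _MAX_GAMMA_SHAPE)
    return wm, wm / np.sqrt(shape)


def _weighted_vonmises_mle(a: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted von Mises MLE; returns (mean direction, concentration)."""
    W = w.sum()
    if W <= 0 or len(a) == 0:
        return 0.0, 0.0
    C = float((w * np.cos(a)).sum() / W)
    S = float((w * np.sin(a)).sum() / W)
    mu = float(np.arctan2(S, C))
    R = float(np.hypot(C, S))
    if R < 1e-10:
        return mu, 0.0

    def f(k):
        return special.i1e(k) / special.i0e(k) - R

    if f(_MAX_KAPPA) < 0:
        return mu, _MAX_KAPPA
    kappa = float(optimize.brentq(f, 1e-10, _MAX_KAPPA))
    return mu, kappa


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class MovementHMMFit:
    """Result of a pooled Baum-Welch fit.

    ``step_params`` rows are (mean mm, sd mm); ``angle_params`` rows are
    (mean direction rad, concentration); states are ordered by increasing
    step mean.  ``stay_probabilities`` is the transition-matrix diagonal.
    """

    transition_matrix: np.ndarray
    step_params: np.ndarray
    angle_params: np.ndarray
    startprob: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_restarts: int
    dt: float = 1.0 / 30.0

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def log_likelihood(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def stay_probabilities(self) -> np.ndarray:
        return np.diag(self.transition_matrix)

    @property
    def params(self) -> MovementHMMParams:
        return MovementHMMParams(
            transition_matrix=self.transition_matrix,
            step_params=self.step_params,
            angle_params=self.angle_params,
            dt=self.dt,
        )

    def state_names(self) -> list[str]:
        if self.n_states == 3:
            return ["slow", "medium", "fast"]
        if self.n_states == 2:
            return ["slow", "fast"]
        return [f"state{k + 1}" for k in range(self.n_states)]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _init_params(steps_all, rng, K):
    """Moment-based initialization from step-magnitude quantile bins, jittered."""
    qs = np.quantile(steps_all, np.linspace(0, 1, K + 1))
    step_params = np.empty((K, 2))
    for k in range(K):
        lo, hi = qs[k], qs[k + 1]
        sel = steps_all[(steps_all >= lo) & (steps_all <= hi)]
        m = float(sel.mean()) if len(sel) else float(steps_all.mean())
        s = float(sel.std()) if len(sel) > 1 else m / 2.0
        s = max(s, m / 10.0)
        step_params[k] = (
            m * np.exp(rng.normal(0.0, 0.2)),
            s * np.exp(rng.normal(0.0, 0.2)),
        )
    step_params = step_params[np.argsort(step_params[:, 0])]
    angle_params = np.column_stack(
        [rng.normal(0.0, 0.3, size=K), np.exp(rng.normal(0.0, 0.5, size=K))]
    )
    if K > 1:
        # dwell-heavy rows with Dirichlet jitter
        base = 0.7 * np.eye(K) + 0.3 / K
        A = np.vstack([rng.dirichlet(base[i] * 40) for i in range(K)])
    else:
        A = np.ones((1, 1))
    pi = np.full(K, 1.0 / K)
    return pi, A, step_params, angle_params


def _canonicalize(pi, A, step_params, angle_params):
    order = np.argsort(step_params[:, 0], kind="stable")
    return (
        pi[order],
        A[np.ix_(order, order)],
        step_params[order],
        angle_params[order],
    )


def fit_movement_hmm(
    series,
    n_states: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MovementHMMFit:
    """Fit the movement HMM to one or more (step, angle) series by EM.

    Parameters are pooled: all series share one transition matrix and one
    emission set, with an estimated common initial-state distribution.  The
    best of ``n_restarts`` jittered moment-based starts (by final
    log-likelihood) is returned, with states relabelled so step means
    increase.  Non-convergence within ``max_iter`` is flagged, and the best
    iterate is still returned.
    """
    seqs = _normalize_series(series)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    for steps, _ in seqs:
        if len(steps) < n_states:
            raise ValueError("each series needs at least n_states observations")
    for _, angles in seqs:
        bad = ~(np.isfinite(angles) | np.isnan(angles))
        if np.any(bad):
            raise ValueError("angles must be finite or NaN")
    steps_all = np.concatenate([s for s, _ in seqs])
    logx_all = np.log(steps_all)
    angles_cat = np.concatenate([a for _, a in seqs])
    amask = np.isfinite(angles_cat)
    a_all = angles_cat[amask]

    root = np.random.default_rng(seed)
    restart_seeds = root.integers(0, 2**31 - 1, size=max(n_restarts, 1))

    best = None
    for rs in restart_seeds:
        rng = np.random.default_rng(int(rs))
        pi, A, step_params, angle_params = _init_params(steps_all, rng, n_states)
        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            ll_total = 0.0
            gam0 = np.zeros(n_states)
            xisum = np.zeros((n_states, n_states))
            wlist = []
            for (steps, angles) in seqs:
                logB = _log_emission(steps, angles, step_params, angle_params)
                ll, gamma, xs = _estep_sequence(pi, A, logB)
                ll_total += ll
                gam0 += gamma[0]
                xisum += xs
                wlist.append(gamma)
            trace.append(ll_total)
            if len(trace) > 1:
                delta = trace[-1] - trace[-2]
                if delta < -1e-6 * (1.0 + abs(trace[-1])):
                    logger.warning("EM log-likelihood decreased by %g; stopping", -delta)
                    break
                if abs(delta) < tol * (1.0 + abs(trace[-1])):
                    converged = True
                    break
            # M-step
            pi = gam0 / gam0.sum()
            if n_states > 1:
                A = xisum / xisum.sum(axis=1, keepdims=True)
            for k in range(n_states):
                w = np.concatenate([g[:, k] for g in wlist])
                step_params[k] = _weighted_gamma_mle(steps_all, logx_all, w)
                angle_params[k] = _weighted_vonmises_mle(a_all, w[amask])
        cand = (trace[-1], pi, A, step_params.copy(), angle_params.copy(),
                np.asarray(trace), converged, len(trace))
        if best is None or cand[0] > best[0]:
            best = cand

    _, pi, A, step_params, angle_params, trace, converged, n_iter = best
    pi, A, step_params, angle_params = _canonicalize(pi, A, step_params, angle_params)
    if not converged:
        logger.warning("movement HMM EM did not converge in %d iterations", n_iter)
    return MovementHMMFit(
        transition_matrix=A,
        step_params=step_params,
        angle_params=angle_params,
        startprob=pi,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        n_restarts=len(restart_seeds),
    )


def score(fit: MovementHMMFit, series) -> float:
    """Pooled forward-algorithm log-likelihood of series under a fit."""
    seqs = _normalize_series(series)
    total = 0.0
    for steps, angles in seqs:
        logB = _log_emission(steps, angles, fit.step_params, fit.angle_params)
        total += forward_loglik(fit.startprob, fit.transition_matrix, logB)
    return total


# ---------------------------------------------------------------------------
# Decoding and endpoints
# ---------------------------------------------------------------------------

def decode_states(fit: MovementHMMFit, series):
    """Viterbi state paths plus per-state occupancy fractions.

    Returns ``(paths, occupancy)`` where paths is a list of int arrays (one
    per series) and occupancy the pooled fraction of steps per state.
    Ties between equally likely paths resolve to the lowest state index.
    """
    seqs = _normalize_series(series)
    with np.errstate(divide="ignore"):
        logpi = np.log(fit.startprob)
        logA = np.log(fit.transition_matrix)
    paths = []
    counts = np.zeros(fit.n_states)
    for steps, angles in seqs:
        logB = _log_emission(steps, angles, fit.step_params, fit.angle_params)
        path, _ = _viterbi_core(logpi, logA, logB)
        paths.append(np.asarray(path))
        counts += np.bincount(path, minlength=fit.n_states)
    occupancy = counts / counts.sum()
    return paths, occupancy


def viterbi_path(fit: MovementHMMFit, series) -> np.ndarray:
    """Single-series convenience wrapper around :func:`decode_states`."""
    paths, _ = decode_states(fit, [series] if isinstance(series, tuple) else series)
    return paths[0]


def hmm_behavior_endpoints(fit: MovementHMMFit, group: str | None = None) -> pd.DataFrame:
    """HMM behavior endpoints from a fitted model, named per state:
    staying probabilities P(i->i), all transition probabilities P(i->j),
    per-state step-length mean/variation (sd), and per-state turning-angle
    mean and variation (circular variance, 1 - I1(kappa)/I0(kappa))."""
    names = fit.state_names()
    rows = []
    for i, si in enumerate(names):
        rows.append((f"hmm_stay_prob_{si}", fit.transition_matrix[i, i]))
        for j, sj in enumerate(names):
            if i != j:
                rows.append((f"hmm_trans_prob_{si}_to_{sj}", fit.transition_matrix[i, j]))
    for k, sk in enumerate(names):
        rows.append((f"hmm_step_length_mean_{sk}", fit.step_params[k, 0]))
        rows.append((f"hmm_step_length_sd_{sk}", fit.step_params[k, 1]))
        mu, kappa = fit.angle_params[k]
        circvar = 1.0 - special.i1e(kappa) / special.i0e(kappa)
        rows.append((f"hmm_turn_angle_mean_{sk}", mu))
        rows.append((f"hmm_turn_angle_circvar_{sk}", circvar))
    out = pd.DataFrame(rows, columns=["endpoint", "value"])
    if group is not None:
        out.insert(0, "group", group)
    return out
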