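"""Synthetic inputs for the whole pipeline.

Emulates the three larval assays and the brain expression counts with the
statistical structure the downstream analyses assume:

* multi-state correlated random walks — a hidden Markov chain over ordered
  movement states (slow < medium < fast by mean step length), gamma step
  lengths and von Mises turning angles per state;
* the visual-motor-response (VMR) variant, which switches parameter sets at
  light/dark period boundaries;
* feeding assays — Poisson encounters with Bernoulli attempt/capture and
  positive Gaussian reaction distances and handling times;
* negative-binomial count matrices with planted log2 fold-changes.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory_endpoints import PeriodDesign

__all__ = [
    "MovementHMMParams",
    "FeedingParams",
    "CountSimSpec",
    "gen_trajectory",
    "gen_vmr_trajectory",
    "gen_feeding_events",
    "gen_counts",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _as_matrix(m) -> np.ndarray:
    return np.atleast_2d(np.asarray(m, dtype=float))


@dataclass(frozen=True)
class MovementHMMParams:
    """Generating parameters of a K-state movement HMM.

    ``step_params``  — per-state (mean mm, sd mm) of the gamma step-length law.
    ``angle_params`` — per-state (mean direction rad, von Mises concentration);
                       concentration may be ``inf`` for a deterministic turn.
    ``dt``           — seconds per step (default 1/30 s, a typical tracking
                       frame rate).
    States must be ordered slow < medium < fast: step means strictly
    increasing with state index.
    """

    transition_matrix: np.ndarray
    step_params: np.ndarray
    angle_params: np.ndarray
    dt: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "transition_matrix", _as_matrix(self.transition_matrix))
        object.__setattr__(self, "step_params", _as_matrix(self.step_params))
        object.__setattr__(self, "angle_params", _as_matrix(self.angle_params))
        A = self.transition_matrix
        k = A.shape[0]
        if A.shape != (k, k):
            raise ValueError("transition matrix must be square")
        if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be probabilities summing to 1")
        if self.step_params.shape != (k, 2) or self.angle_params.shape != (k, 2):
            raise ValueError("need one (mean, spread) pair per state")
        means = self.step_params[:, 0]
        if np.any(means <= 0) or np.any(self.step_params[:, 1] < 0):
            raise ValueError("step means must be > 0 and sds >= 0")
        if k > 1 and np.any(np.diff(means) <= 0):
            raise ValueError("step means must be strictly increasing (slow < medium < fast)")
        if np.any(self.angle_params[:, 1] < 0):
            raise ValueError("angle concentrations must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass(frozen=True)
class FeedingParams:
    """Feeding-assay generating parameters (rates per minute, mm, s)."""

    encounter_rate: float = 2.0
    p_attempt: float = 0.8
    p_capture: float = 0.5
    reaction_distance: tuple[float, float] = (4.0, 1.0)
    handling_time: tuple[float, float] = (5.0, 1.5)

    def __post_init__(self) -> None:
        for p, name in ((self.p_attempt, "p_attempt"), (self.p_capture, "p_capture")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.encounter_rate < 0:
            raise ValueError("encounter_rate must be >= 0")
        for mean, sd in (self.reaction_distance, self.handling_time):
            if mean <= 0 or sd < 0:
                raise ValueError("means must be > 0 and sds >= 0")


@dataclass(frozen=True)
class CountSimSpec:
    """Negative-binomial count-matrix simulation: ``n_genes`` genes over two
    groups of ``n_per_group`` samples, a fraction ``de_fraction`` of genes
    carrying a planted ``log2_fc`` in group 2, shared NB ``dispersion``
    (var = mu + dispersion * mu^2).  ``size_factor_sd`` > 0 adds lognormal
    library-size variation; ``per_gene_dispersion`` spreads dispersions
    lognormally around the shared value."""

    n_genes: int = 2000
    n_per_group: int = 6
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    log2_fc: float = 1.0
    seed: int = 0
    size_factor_sd: float = 0.0
    per_gene_dispersion: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ValueError("n_genes and n_per_group must be >= 1")


# ---------------------------------------------------------------------------
# Trajectory generators
# ---------------------------------------------------------------------------

def _draw_steps(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, mean / shape, size=n)


def _draw_turns(rng: np.random.Generator, mu: float, kappa: float, n: int) -> np.ndarray:
    if np.isinf(kappa):
        return np.full(n, mu)
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, size=n)
    return rng.vonmises(mu, kappa, size=n)


def _simulate_chain(rng: np.random.Generator, A: np.ndarray, pi: np.ndarray, n: int) -> np.ndarray:
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(len(pi), p=pi)
    for t in range(1, n):
        states[t] = rng.choice(A.shape[0], p=A[states[t - 1]])
    return states


def _emit(rng, params: MovementHMMParams, states: np.ndarray, heading0: float):
    """Correlated random walk: heading accumulates per-step turning angles."""
    n = len(states)
    steps = np.empty(n)
    turns = np.empty(n)
    for k in range(params.n_states):
        idx = states == k
        m = int(idx.sum())
        steps[idx] = _draw_steps(rng, *params.step_params[k], m)
        turns[idx] = _draw_turns(rng, *params.angle_params[k], m)
    headings = heading0 + np.cumsum(turns)
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    return dx, dy, headings[-1] if n else heading0


def gen_trajectory(
    params: MovementHMMParams,
    n_steps: int,
    seed: int,
    larva_id: str = "L1",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one larva's trajectory of ``n_steps`` moves from the movement
    HMM.  Returns the position table (``n_steps + 1`` rows, starting at the
    origin) and the hidden state sequence (one per move)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    pi = params.stationary_distribution()
    states = _simulate_chain(rng, params.transition_matrix, pi, n_steps)
    heading0 = rng.uniform(-np.pi, np.pi)
    dx, dy, _ = _emit(rng, params, states, heading0)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    t = np.arange(n_steps + 1) * params.dt
    traj = pd.DataFrame({"larva_id": larva_id, "t_s": t, "x_mm": x, "y_mm": y})
    return traj, states


def gen_vmr_trajectory(
    light_params: MovementHMMParams,
    dark_params: MovementHMMParams,
    period_design: PeriodDesign,
    seed: int,
    larva_id: str = "L1",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a VMR trajectory: the movement HMM switches between the light
    and dark parameter sets at period boundaries; the hidden chain and the
    position/heading run continuously across boundaries.  Every emitted point
    carries its period label and light flag."""
    if light_params.n_states != dark_params.n_states:
        raise ValueError("light and dark parameter sets must share n_states")
    if abs(light_params.dt - dark_params.dt) > 1e-12:
        raise ValueError("light and dark parameter sets must share dt")
    dt = light_params.dt
    rng = np.random.default_rng(seed)
    t0 = period_design.periods[0].start_s
    t_end = period_design.periods[-1].end_s
    n_steps = int(round((t_end - t0) / dt))
    times = t0 + np.arange(n_steps + 1) * dt
    light_flags = period_design.light_of(times[:-1])  # regime of each move

    pi = (light_params if light_flags[0] else dark_params).stationary_distribution()
    states = np.empty(n_steps, dtype=np.int64)
    prev = rng.choice(len(pi), p=pi)
    states[0] = prev
    for t in range(1, n_steps):
        A = (light_params if light_flags[t] else dark_params).transition_matrix
        prev = rng.choice(A.shape[0], p=A[prev])
        states[t] = prev

    steps = np.empty(n_steps)
    turns = np.empty(n_steps)
    for t in range(n_steps):
        p = light_params if light_flags[t] else dark_params
        k = states[t]
        steps[t] = _draw_steps(rng, *p.step_params[k], 1)[0]
        turns[t] = _draw_turns(rng, *p.angle_params[k], 1)[0]
    headings = rng.uniform(-np.pi, np.pi) + np.cumsum(turns)
    x = np.concatenate([[0.0], np.cumsum(steps * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(steps * np.sin(headings))])
    traj = pd.DataFrame(
        {
            "larva_id": larva_id,
            "t_s": times,
            "x_mm": x,
            "y_mm": y,
            "period": period_design.period_of(times),
            "light": period_design.light_of(times).astype(int),
        }
    )
    return traj, states


# ---------------------------------------------------------------------------
# Feeding events
# ---------------------------------------------------------------------------

def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian truncated to (0, inf)."""
    if sd == 0.0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_feeding_events(
    params: FeedingParams,
    duration: float,
    seed: int,
    larva_id: str = "L1",
) -> pd.DataFrame:
    """Simulate a feeding assay of ``duration`` minutes: a Poisson number of
    prey encounters, each attacked with ``p_attempt`` and captured (given an
    attempt) with ``p_capture``.  Reaction distances are recorded for
    attempted prey, handling times for captured prey."""
    if duration <= 0:
        raise ValueError("duration must be > 0 minutes")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(params.encounter_rate * duration))
    attempted = rng.random(n) < params.p_attempt
    captured = attempted & (rng.random(n) < params.p_capture)
    rd = np.full(n, np.nan)
    rd[attempted] = _positive_normal(rng, *params.reaction_distance, int(attempted.sum()))
    ht = np.full(n, np.nan)
    ht[captured] = _positive_normal(rng, *params.handling_time, int(captured.sum()))
    return pd.DataFrame(
        {
            "larva_id": larva_id,
            "event_idx": np.arange(n),
            "attempted": attempted.astype(int),
            "captured": captured.astype(int),
            "reaction_distance_mm": rd,
            "handling_time_s": ht,
        }
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def gen_counts(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample NB count matrix with planted fold-changes.

    Returns ``(counts, design, truth)``: counts indexed by gene with sample
    columns; design with columns ``sample``/``treatment`` (groups "control"
    and "treatment"); truth with per-gene ``is_de`` flag and ``log2_fc``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    samples = [f"ctl{j}" for j in range(spec.n_per_group)] + [
        f"trt{j}" for j in range(spec.n_per_group)
    ]
    group2 = np.array([False] * spec.n_per_group + [True] * spec.n_per_group)

    n_de = int(round(spec.de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    is_de[rng.choice(n, size=n_de, replace=False)] = True
    lfc = np.where(is_de, spec.log2_fc, 0.0)

    if spec.size_factor_sd > 0:
        sf = rng.lognormal(0.0, spec.size_factor_sd, size=len(samples))
        sf /= sf.mean()
    else:
        sf = np.ones(len(samples))

    if spec.per_gene_dispersion:
        disp = rng.lognormal(np.log(spec.dispersion), 0.5, size=n)
    else:
        disp = np.full(n, spec.dispersion)

    mu = spec.baseline_mean * np.power(2.0, np.outer(lfc, group2.astype(float)))
    mu = mu * sf[None, :]
    r = (1.0 / disp)[:, None]
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    design = pd.DataFrame(
        {"sample": samples, "treatment": np.where(group2, "treatment", "control")}
    )
    truth = pd.DataFrame(
        {"gene": genes, "is_de": is_de, "log2_fc": lfc, "dispersion": disp}
    ).set_index("gene")
    return counts_df, design, truth
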