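"""Per-larva behavior endpoints from 2-D swim trajectories and feeding events.

A trajectory is a time-ordered table of positions for one or more larvae
(columns ``larva_id``, ``t_s``, ``x_mm``, ``y_mm`` and, for assays with a
light regime, ``period`` and ``light``).  This module turns such tables into
the behavior endpoint catalogue used downstream: distance traveled, swimming
bouts, step lengths, turning angles, startle magnitude, and the five feeding
endpoints (capture attempts, capture probability, capture attempt ratio,
reaction distance, handling time).

Conventions
-----------
* Time is 0-based; period windows are half-open ``[start, end)``.
* An endpoint that cannot be computed (too few positions, zero attempts)
  is reported as ``NaN`` — an undefined-value sentinel, never silently 0.
* "Variation" endpoints are standard deviations; turning-angle summaries
  use circular statistics because angles wrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("killitox")

UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# Period design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Period:
    """One assay period: half-open time window [start_s, end_s) with a light flag."""

    label: str
    start_s: float
    end_s: float
    light: bool

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"period {self.label!r}: start must be < end")


@dataclass(frozen=True)
class PeriodDesign:
    """Ordered, non-overlapping assay periods (VMR, locomotion, or feeding)."""

    periods: tuple[Period, ...]
    assay: str = "vmr"

    def __post_init__(self) -> None:
        if self.assay not in ("vmr", "locomotion", "feeding"):
            raise ValueError(f"unknown assay kind {self.assay!r}")
        if len(self.periods) < 1:
            raise ValueError("need at least one period")
        prev_end = -np.inf
        for p in self.periods:
            if p.start_s < prev_end:
                raise ValueError(f"period {p.label!r} overlaps the previous period")
            prev_end = p.end_s

    @property
    def total_duration_s(self) -> float:
        return self.periods[-1].end_s - self.periods[0].start_s

    def period_of(self, t: np.ndarray) -> np.ndarray:
        """Period label for each time (object array; None outside all periods)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, None, dtype=object)
        for p in self.periods:
            out[(t >= p.start_s) & (t < p.end_s)] = p.label
        return out

    def light_of(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for p in self.periods:
            if p.light:
                out[(t >= p.start_s) & (t < p.end_s)] = True
        return out


def vmr_design(period_s: float = 60.0, n_periods: int = 5) -> PeriodDesign:
    """Default visual-motor-response design: equal periods alternating
    dark-light-dark-light-dark (odd periods dark), labelled "1".."n"."""
    periods = tuple(
        Period(str(i + 1), i * period_s, (i + 1) * period_s, light=(i % 2 == 1))
        for i in range(n_periods)
    )
    return PeriodDesign(periods, assay="vmr")


def locomotion_design(duration_s: float = 300.0) -> PeriodDesign:
    """Free-swimming locomotion assay: a single lit period."""
    return PeriodDesign((Period("1", 0.0, duration_s, light=True),), assay="locomotion")


# ---------------------------------------------------------------------------
# Kinematic primitives
# ---------------------------------------------------------------------------

def _window_slice(traj: pd.DataFrame, window: tuple[float, float] | Period | None) -> pd.DataFrame:
    if window is None:
        return traj
    if isinstance(window, Period):
        lo, hi = window.start_s, window.end_s
    else:
        lo, hi = window
    return traj[(traj["t_s"] >= lo) & (traj["t_s"] < hi)]


def step_lengths(traj: pd.DataFrame) -> np.ndarray:
    """Per-frame displacement magnitudes (mm), length n-1."""
    dx = np.diff(traj["x_mm"].to_numpy(dtype=float))
    dy = np.diff(traj["y_mm"].to_numpy(dtype=float))
    return np.hypot(dx, dy)


def speeds(traj: pd.DataFrame) -> np.ndarray:
    """Instantaneous speed (mm/s) for each inter-frame interval, length n-1."""
    dt = np.diff(traj["t_s"].to_numpy(dtype=float))
    if np.any(dt <= 0):
        raise ValueError("trajectory times must be strictly increasing")
    return step_lengths(traj) / dt


def total_distance(traj: pd.DataFrame, window: tuple[float, float] | Period | None = None) -> float:
    """Total distance traveled (mm): the sum of consecutive Euclidean
    displacements.  Returns NaN (not 0) if the window holds < 2 positions."""
    sub = _window_slice(traj, window)
    if len(sub) < 2:
        return UNDEFINED
    return float(step_lengths(sub).sum())


def detect_bouts(
    traj: pd.DataFrame,
    speed_threshold: float,
    min_pause: float = 0.2,
) -> list[tuple[float, float]]:
    """Swimming bouts: maximal intervals with speed >= threshold, after
    merging pauses shorter than ``min_pause`` seconds.

    Each inter-frame interval is attributed to its start time.  Returns a
    list of ``(start_s, end_s)`` intervals.
    """
    if len(traj) < 2:
        return []
    t = traj["t_s"].to_numpy(dtype=float)
    moving = speeds(traj) >= speed_threshold
    bouts: list[tuple[float, float]] = []
    start = None
    for i, m in enumerate(moving):
        if m and start is None:
            start = t[i]
        elif not m and start is not None:
            bouts.append((start, t[i]))
            start = None
    if start is not None:
        bouts.append((start, t[-1]))
    # merge across short pauses
    merged: list[tuple[float, float]] = []
    for b in bouts:
        if merged and b[0] - merged[-1][1] < min_pause:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    return merged


def bout_statistics(
    traj: pd.DataFrame,
    speed_threshold: float,
    min_pause: float = 0.2,
) -> dict[str, float]:
    """Bout count, per-second frequency, mean duration and total time swimming."""
    if len(traj) < 2:
        return {
            "bout_count": UNDEFINED,
            "bout_frequency_per_s": UNDEFINED,
            "bout_duration_mean_s": UNDEFINED,
            "total_time_swimming_s": UNDEFINED,
        }
    bouts = detect_bouts(traj, speed_threshold, min_pause)
    t = traj["t_s"].to_numpy(dtype=float)
    record = t[-1] - t[0]
    durations = np.array([e - s for s, e in bouts])
    return {
        "bout_count": float(len(bouts)),
        "bout_frequency_per_s": float(len(bouts) / record) if record > 0 else UNDEFINED,
        "bout_duration_mean_s": float(durations.mean()) if len(bouts) else UNDEFINED,
        "total_time_swimming_s": float(durations.sum()),
    }


def turning_angles(traj: pd.DataFrame) -> np.ndarray:
    """Signed turning angles (rad, in (-pi, pi]) between consecutive
    displacement vectors.  Angles adjacent to a zero-length displacement are
    skipped (and logged) because the heading is undefined there."""
    if len(traj) < 3:
        raise ValueError("need >= 3 positions to compute turning angles")
    dx = np.diff(traj["x_mm"].to_numpy(dtype=float))
    dy = np.diff(traj["y_mm"].to_numpy(dtype=float))
    norm = np.hypot(dx, dy)
    angles = []
    n_skipped = 0
    for i in range(1, len(dx)):
        if norm[i - 1] == 0.0 or norm[i] == 0.0:
            n_skipped += 1
            continue
        cross = dx[i - 1] * dy[i] - dy[i - 1] * dx[i]
        dot = dx[i - 1] * dx[i] + dy[i - 1] * dy[i]
        angles.append(np.arctan2(cross, dot))
    if n_skipped:
        logger.debug("turning_angles: skipped %d angles at zero-length steps", n_skipped)
    return np.asarray(angles, dtype=float)


def circular_summary(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular variance (1 - mean resultant length)."""
    if len(angles) == 0:
        return UNDEFINED, UNDEFINED
    mean = float(stats.circmean(angles, high=np.pi, low=-np.pi))
    var = float(stats.circvar(angles, high=np.pi, low=-np.pi))
    return mean, var


def startle_magnitude(traj: pd.DataFrame, transition_time: float, window: float = 2.0) -> float:
    """Startle response at a light transition: distance traveled in
    ``(t, t+window]`` minus distance in the preceding equal window.  May be
    negative.  Raises if either window extends beyond the record."""
    t = traj["t_s"].to_numpy(dtype=float)
    if not (t[0] <= transition_time <= t[-1]):
        raise ValueError("transition_time outside the trajectory record")
    if transition_time - window < t[0] or transition_time + window > t[-1]:
        raise ValueError("startle window extends beyond the trajectory record")

    def dist_closed(lo: float, hi: float) -> float:
        sub = traj[(traj["t_s"] >= lo - 1e-12) & (traj["t_s"] <= hi + 1e-12)]
        d = total_distance(sub)
        return 0.0 if np.isnan(d) else d

    # closed windows sharing the transition point: every step falls in
    # exactly one window
    post = dist_closed(transition_time, transition_time + window)
    pre = dist_closed(transition_time - window, transition_time)
    return post - pre


# ---------------------------------------------------------------------------
# Feeding endpoints
# ---------------------------------------------------------------------------

def feeding_endpoints(events: pd.DataFrame) -> dict[str, float]:
    """The five feeding-assay endpoints from an event table.

    ``capture_probability`` = captures / attempts (NaN when no attempts);
    ``capture_attempt_ratio`` = attempts / encounters.
    """
    n_enc = len(events)
    if n_enc == 0:
        raise ValueError("feeding endpoints need >= 1 encounter")
    attempts = int(events["attempted"].sum())
    captures = int(events["captured"].sum())
    attempted = events["attempted"].to_numpy(dtype=bool)
    return {
        "capture_attempts": float(attempts),
        "capture_probability": captures / attempts if attempts > 0 else UNDEFINED,
        "capture_attempt_ratio": attempts / n_enc,
        "reaction_distance_mm": float(events.loc[attempted, "reaction_distance_mm"].mean())
        if attempts > 0
        else UNDEFINED,
        "handling_time_s": float(events.loc[events["captured"].astype(bool), "handling_time_s"].mean())
        if captures > 0
        else UNDEFINED,
    }


# ---------------------------------------------------------------------------
# Endpoint registry and the long-format endpoint table
# ---------------------------------------------------------------------------

# name -> callable(traj, **cfg) returning a scalar; extensible so assay
# catalogues beyond the documented core can be registered by users.
_EXTRA_ENDPOINTS: dict[str, Callable[..., float]] = {}


def register_endpoint(name: str, func: Callable[..., float]) -> None:
    """Register an extra trajectory endpoint (e.g. a user-defined
    "feeding lunge ratio", whose definition the core catalogue does not fix)."""
    _EXTRA_ENDPOINTS[name] = func


def _trajectory_endpoint_block(
    traj: pd.DataFrame,
    speed_threshold: float,
    min_pause: float,
) -> dict[str, float]:
    vals: dict[str, float] = {"total_distance_mm": total_distance(traj)}
    vals.update(bout_statistics(traj, speed_threshold, min_pause))
    steps = step_lengths(traj) if len(traj) >= 2 else np.array([])
    vals["step_length_mean_mm"] = float(steps.mean()) if len(steps) else UNDEFINED
    vals["step_length_sd_mm"] = float(steps.std(ddof=1)) if len(steps) > 1 else UNDEFINED
    if len(traj) >= 3:
        mean, var = circular_summary(turning_angles(traj))
    else:
        mean, var = UNDEFINED, UNDEFINED
    vals["turn_angle_mean_rad"] = mean
    vals["turn_angle_circvar"] = var
    for name, func in _EXTRA_ENDPOINTS.items():
        vals[name] = func(traj)
    return vals


def endpoint_table(
    data: pd.DataFrame,
    design: PeriodDesign,
    speed_threshold: float = 5.0,
    min_pause: float = 0.2,
    startle_window: float = 2.0,
) -> pd.DataFrame:
    """Evaluate the endpoint catalogue per larva, overall and per period.

    ``data`` is a trajectory table (``larva_id``, ``t_s``, ``x_mm``,
    ``y_mm``) for vmr/locomotion assays, or a feeding-event table for the
    feeding assay.  Returns a long-format table with columns
    ``larva_id``, ``endpoint``, ``period`` ("overall" or the period label)
    and ``value``.
    """
    rows: list[tuple] = []
    if design.assay == "feeding":
        for larva, ev in data.groupby("larva_id", sort=True):
            for name, val in feeding_endpoints(ev).items():
                rows.append((larva, name, "overall", val))
        return pd.DataFrame(rows, columns=["larva_id", "endpoint", "period", "value"])

    for larva, traj in data.groupby("larva_id", sort=True):
        traj = traj.sort_values("t_s")
        for name, val in _trajectory_endpoint_block(traj, speed_threshold, min_pause).items():
            rows.append((larva, name, "overall", val))
        if len(design.periods) > 1:
            for p in design.periods:
                sub = _window_slice(traj, p)
                for name, val in _trajectory_endpoint_block(sub, speed_threshold, min_pause).items():
                    rows.append((larva, name, p.label, val))
            # startle at every light-regime change, attributed to the period
            # that begins at the transition
            t = traj["t_s"].to_numpy(dtype=float)
            for prev, cur in zip(design.periods[:-1], design.periods[1:]):
                if prev.light == cur.light:
                    continue
                tt = cur.start_s
                if tt - startle_window < t[0] or tt + startle_window > t[-1]:
                    continue
                rows.append(
                    (larva, "startle_magnitude_mm", cur.label,
                     startle_magnitude(traj, tt, startle_window))
                )
    return pd.DataFrame(rows, columns=["larva_id", "endpoint", "period", "value"])


def write_endpoints(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trajectory(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
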