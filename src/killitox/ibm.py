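"""Individual-based model of larval-to-juvenile cohort survival and growth.

Simulates 2500 larvae per replicate from hatch until they reach juvenile
length or 100 days, whichever comes first, with 10 replicates per scenario.
Treatment effects enter exclusively through behavior multipliers — the
treatment/control ratios of swimming speed, prey capture success, prey
handling time and reactive distance measured in the assays.

Daily cycle per larva:

1. *Foraging.*  Prey encounters are Poisson with mean
   ``prey_density x pi (RD)^2 x SS x foraging time`` — a 2-D search-area
   model where reactive distance RD and swimming speed SS scale with body
   length and carry their multipliers.  Captures are binomial with
   probability ``p_capture x capture multiplier`` (clipped to 1), and intake
   is capped both by the handling budget ``foraging time / handling time``
   and by an allometric, temperature-scaled maximum consumption.
2. *Bioenergetics.*  ``dW = assimilation x C - R(W, T)`` with allometric
   respiration ``R = resp_a W^resp_exp exp(q (T - Tref))``.  Length follows
   weight by the length-weight allometry and never decreases.
3. *Mortality.*  Size-dependent predation with hazard ``mu(L) = a L^b``
   (b < 0: bigger larvae are safer), plus starvation when weight falls below
   a fraction of the expected weight-at-length.

Individual stochasticity only (no parameter uncertainty): Poisson/binomial
foraging, Bernoulli mortality, and a fixed per-larva lognormal foraging
ability.  Each replicate draws from an independent child of the root seed,
so a run is bit-reproducible given its seed.

All biological coefficients live in :class:`IBMConfig` and are deliberately
overridable: the defaults are a documented stand-in parameterization
calibrated to put control cohort survival in the low single-digit percent
range (see docs/methods.md), not a measured parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class BehaviorMultipliers:
    """Treatment/control ratios applied to the four foraging channels."""

    swim_speed: float = 1.0
    capture_success: float = 1.0
    handling_time: float = 1.0
    reactive_distance: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"multiplier {name} must be > 0")

    @classmethod
    def control(cls) -> "BehaviorMultipliers":
        return cls(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class Scenario:
    """Season scenario: daily temperature series (°C), prey density (#/L,
    scalar or daily series) and foraging hours per day."""

    season: str
    temperature_c: np.ndarray
    prey_density_per_l: np.ndarray
    foraging_hours: float = 12.0

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.temperature_c, dtype=float))
        d = np.atleast_1d(np.asarray(self.prey_density_per_l, dtype=float))
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "prey_density_per_l", d)
        if np.any(t < -2) or np.any(t > 40):
            raise ValueError("temperatures outside physiological bounds")
        if np.any(d < 0):
            raise ValueError("prey densities must be >= 0")
        if self.foraging_hours <= 0 or self.foraging_hours > 24:
            raise ValueError("foraging_hours must be in (0, 24]")

    def temp_on(self, day: int) -> float:
        return float(self.temperature_c[min(day, len(self.temperature_c) - 1)])

    def density_on(self, day: int) -> float:
        return float(self.prey_density_per_l[min(day, len(self.prey_density_per_l) - 1)])


def make_scenario(
    season: str = "spring",
    n_days: int = 100,
    base_temp_c: float = 16.0,
    amplitude_c: float = 6.0,
    summer_offset_c: float = 4.0,
    prey_density_per_l: float = 4.4,
    foraging_hours: float = 12.0,
) -> Scenario:
    """Default seasonal scenarios: a rising sinusoidal temperature segment
    (spring), with summer the same shape warmer by a fixed offset; prey
    density constant."""
    if season not in ("spring", "summer"):
        raise ValueError("season must be 'spring' or 'summer'")
    days = np.arange(n_days)
    temp = base_temp_c + amplitude_c * np.sin(0.5 * np.pi * days / max(n_days - 1, 1))
    if season == "summer":
        temp = temp + summer_offset_c
    return Scenario(season, temp, np.full(n_days, prey_density_per_l), foraging_hours)


@dataclass(frozen=True)
class IBMConfig:
    """All biological constants of the simulator (units in field names).

    Lengths in mm, weights in mg dry, energy in prey dry-mass equivalents.
    """

    n_larvae: int = 2500
    n_replicates: int = 10
    max_days: int = 100
    hatch_length_mm: float = 5.0
    juvenile_length_mm: float = 15.0
    # length-weight allometry W = a L^b
    lw_a: float = 0.004
    lw_b: float = 3.0
    # foraging
    swim_speed_bl_per_s: float = 2.0
    reactive_distance_bl: float = 1.0
    base_capture_prob: float = 0.4
    handling_time_s: float = 30.0
    prey_mass_mg: float = 0.0025
    assimilation_efficiency: float = 0.7
    # bioenergetics: Cmax and respiration, allometric with exponential
    # temperature scaling exp(q (T - Tref))
    cmax_a: float = 0.33
    cmax_exp: float = 0.8
    resp_a: float = 0.08
    resp_exp: float = 0.8
    temp_coeff_per_c: float = 0.05
    ref_temp_c: float = 20.0
    # mortality
    mortality_a: float = 1.95
    mortality_exp: float = -1.3
    starvation_fraction: float = 0.7
    # fixed per-larva lognormal foraging-ability spread (individual quality)
    ability_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_larvae < 1 or self.n_replicates < 1 or self.max_days < 1:
            raise ValueError("cohort sizes and horizon must be >= 1")
        if self.juvenile_length_mm <= self.hatch_length_mm:
            raise ValueError("juvenile length must exceed hatch length")
        if not 0 < self.assimilation_efficiency <= 1:
            raise ValueError("assimilation_efficiency must be in (0, 1]")
        if self.mortality_exp >= 0:
            raise ValueError("mortality exponent must be < 0 (bigger is safer)")
        if not 0 <= self.starvation_fraction < 1:
            raise ValueError("starvation_fraction must be in [0, 1)")

    def weight_at_length(self, L: np.ndarray) -> np.ndarray:
        return self.lw_a * np.asarray(L, dtype=float) ** self.lw_b

    def length_at_weight(self, W: np.ndarray) -> np.ndarray:
        return (np.asarray(W, dtype=float) / self.lw_a) ** (1.0 / self.lw_b)

    @classmethod
    def from_yaml(cls, path: str) -> "IBMConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


#: Default per-treatment multiplier sets.  Sign structure follows the assay
#: results: PCB126 slows swimming, lengthens prey handling and lowers capture
#: success (most severely in the reference SCO population); parental MeHg
#: raises capture success and reaction distance while slightly slowing
#: swimming; the NBH lineage baseline swims less but captures better than
#: SCO.  Magnitudes are part of the calibration stand-in (docs/methods.md).
DEFAULT_MULTIPLIERS: dict[str, BehaviorMultipliers] = {
    "SCO-Ctrl": BehaviorMultipliers(1.0, 1.0, 1.0, 1.0),
    "SCO-MeHg": BehaviorMultipliers(0.95, 1.12, 1.0, 1.08),
    "SCO-PCB": BehaviorMultipliers(0.60, 0.85, 1.80, 0.95),
    "NBH-Ctrl": BehaviorMultipliers(0.84, 1.06, 1.0, 1.02),
    "NBH-PCB": BehaviorMultipliers(0.74, 1.00, 1.30, 0.98),
}


# ---------------------------------------------------------------------------
# Daily submodels (vectorized over the cohort)
# ---------------------------------------------------------------------------

def derive_multipliers(
    treatment_means: Mapping[str, float], control_means: Mapping[str, float]
) -> BehaviorMultipliers:
    """Element-wise treatment/control ratios on the four behavior channels.

    Both mappings need keys ``swim_speed``, ``capture_success``,
    ``handling_time``, ``reactive_distance`` (assay endpoint means); control
    means must be positive.
    """
    vals = {}
    for key in ("swim_speed", "capture_success", "handling_time", "reactive_distance"):
        c = float(control_means[key])
        if not c > 0:
            raise ValueError(f"control mean for {key} must be > 0")
        vals[key] = float(treatment_means[key]) / c
    return BehaviorMultipliers(**vals)


#: endpoint-table names feeding each multiplier channel
_CHANNEL_ENDPOINTS = {
    "swim_speed": "step_length_mean_mm",  # locomotion assay, per-frame speed proxy
    "capture_success": "capture_probability",
    "handling_time": "handling_time_s",
    "reactive_distance": "reaction_distance_mm",
}


def multipliers_from_endpoints(
    treatment_table: pd.DataFrame, control_table: pd.DataFrame
) -> BehaviorMultipliers:
    """Derive multipliers from two long-format endpoint tables (treatment and
    control), averaging each channel's endpoint over larvae ("overall" rows)."""

    def channel_means(tab: pd.DataFrame) -> dict[str, float]:
        out = {}
        for channel, endpoint in _CHANNEL_ENDPOINTS.items():
            sel = tab[(tab["endpoint"] == endpoint) & (tab["period"] == "overall")]
            if sel.empty:
                raise ValueError(f"endpoint table lacks {endpoint!r} (channel {channel})")
            out[channel] = float(sel["value"].mean())
        return out

    return derive_multipliers(channel_means(treatment_table), channel_means(control_table))


def daily_encounters(
    lengths_mm: np.ndarray,
    prey_density_per_l: float,
    foraging_s: float,
    mult: BehaviorMultipliers,
    cfg: IBMConfig,
    rng: np.random.Generator,
    ability: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Poisson prey encounters for one day.  The searched volume is the 2-D
    detection disc pi RD^2 swept at swimming speed SS for the foraging time,
    with RD and SS proportional to body length (mm^3 -> L at 1e6)."""
    L = np.asarray(lengths_mm, dtype=float)
    rd = cfg.reactive_distance_bl * L * mult.reactive_distance
    ss = cfg.swim_speed_bl_per_s * L * mult.swim_speed
    lam = prey_density_per_l * np.pi * rd**2 * ss * foraging_s / 1e6
    return rng.poisson(lam * ability)


def daily_consumption(
    encounters: np.ndarray,
    lengths_mm: np.ndarray,
    weights_mg: np.ndarray,
    temp_c: float,
    foraging_s: float,
    mult: BehaviorMultipliers,
    cfg: IBMConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Prey consumed in one day, in mg dry mass.

    Captures are binomial over encounters; the number eaten is capped by the
    handling budget ``foraging_s / (HT x handling multiplier)`` and by the
    temperature- and mass-scaled maximum consumption."""
    enc = np.asarray(encounters)
    p = min(cfg.base_capture_prob * mult.capture_success, 1.0)
    captures = rng.binomial(enc, p) if p > 0 else np.zeros_like(enc)
    handling_cap = foraging_s / (cfg.handling_time_s * mult.handling_time)
    tf = np.exp(cfg.temp_coeff_per_c * (temp_c - cfg.ref_temp_c))
    cmax_cap = cfg.cmax_a * np.asarray(weights_mg, dtype=float) ** cfg.cmax_exp * tf
    eaten = np.minimum(captures, np.minimum(handling_cap, cmax_cap / cfg.prey_mass_mg))
    return eaten * cfg.prey_mass_mg


def bioenergetics_step(
    weights_mg: np.ndarray,
    lengths_mm: np.ndarray,
    intake_mg: np.ndarray,
    temp_c: float,
    cfg: IBMConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One day of growth: dW = assimilation x C - R(W, T); length follows the
    allometry but never shrinks.  Returns (new weights, new lengths)."""
    W = np.asarray(weights_mg, dtype=float)
    if not np.all(np.isfinite(W)) or not np.all(W > 0):
        raise ValueError("non-finite or non-positive larval weights")
    resp = (
        cfg.resp_a
        * W**cfg.resp_exp
        * np.exp(cfg.temp_coeff_per_c * (temp_c - cfg.ref_temp_c))
    )
    W_new = np.maximum(W + cfg.assimilation_efficiency * np.asarray(intake_mg) - resp, 1e-9)
    L_new = np.maximum(np.asarray(lengths_mm, dtype=float), cfg.length_at_weight(W_new))
    return W_new, L_new


def apply_mortality(
    lengths_mm: np.ndarray,
    weights_mg: np.ndarray,
    cfg: IBMConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean death indicators for one day: size-dependent predation with
    daily probability ``1 - exp(-a L^b)`` plus certain death by starvation
    when weight drops below ``starvation_fraction`` of the expected
    weight-at-length."""
    L = np.asarray(lengths_mm, dtype=float)
    W = np.asarray(weights_mg, dtype=float)
    mu = cfg.mortality_a * L**cfg.mortality_exp
    predated = rng.random(L.shape) < 1.0 - np.exp(-mu)
    starved = W < cfg.starvation_fraction * cfg.weight_at_length(L)
    return predated | starved


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Per-replicate cohort outcomes.

    ``survival_pct`` counts larvae alive at the horizon plus juveniles that
    graduated; ``growth_mm_per_day`` is the survivor mean of
    (final length - hatch length) / days tracked.  ``survival_curves`` holds
    the daily surviving fraction (percent) per replicate.
    """

    survival_pct: np.ndarray
    growth_mm_per_day: np.ndarray
    n_graduated: np.ndarray
    n_died: np.ndarray
    n_alive_end: np.ndarray
    survival_curves: np.ndarray
    replicate_seeds: list[int]
    season: str
    multipliers: BehaviorMultipliers
    juvenile_length_mm: float

    @property
    def mean_survival_pct(self) -> float:
        return float(self.survival_pct.mean())

    @property
    def mean_growth_mm_per_day(self) -> float:
        return float(np.nanmean(self.growth_mm_per_day))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.survival_pct)),
                "season": self.season,
                "survival_pct": self.survival_pct,
                "growth_mm_per_day": self.growth_mm_per_day,
                "n_graduated": self.n_graduated,
                "n_died": self.n_died,
                "n_alive_end": self.n_alive_end,
            }
        )


def run_cohort(
    cfg: IBMConfig,
    scenario: Scenario,
    mult: BehaviorMultipliers,
    seed: int,
) -> CohortResult:
    """Run the full cohort simulation: ``cfg.n_replicates`` independent
    replicates of ``cfg.n_larvae`` larvae tracked daily from hatch to
    juvenile length or ``cfg.max_days``."""
    foraging_s = scenario.foraging_hours * 3600.0
    n = cfg.n_larvae
    root = np.random.SeedSequence(seed)
    children = root.spawn(cfg.n_replicates)

    survival_pct = np.empty(cfg.n_replicates)
    growth = np.empty(cfg.n_replicates)
    n_grad = np.empty(cfg.n_replicates, dtype=int)
    n_died = np.empty(cfg.n_replicates, dtype=int)
    n_alive = np.empty(cfg.n_replicates, dtype=int)
    curves = np.empty((cfg.n_replicates, cfg.max_days + 1))

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        L = np.full(n, cfg.hatch_length_mm)
        W = cfg.weight_at_length(L)
        alive = np.ones(n, dtype=bool)
        graduated = np.zeros(n, dtype=bool)
        days_tracked = np.full(n, cfg.max_days)
        if cfg.ability_sd > 0:
            ability = rng.lognormal(-0.5 * cfg.ability_sd**2, cfg.ability_sd, size=n)
        else:
            ability = np.ones(n)
        curves[rep, 0] = 100.0

        for day in range(cfg.max_days):
            active = alive & ~graduated
            if np.any(active):
                idx = np.where(active)[0]
                temp = scenario.temp_on(day)
                dens = scenario.density_on(day)
                enc = daily_encounters(
                    L[idx], dens, foraging_s, mult, cfg, rng, ability[idx]
                )
                intake = daily_consumption(
                    enc, L[idx], W[idx], temp, foraging_s, mult, cfg, rng
                )
                W[idx], L[idx] = bioenergetics_step(W[idx], L[idx], intake, temp, cfg)
                dead = apply_mortality(L[idx], W[idx], cfg, rng)
                alive[idx[dead]] = False
                days_tracked[idx[dead]] = day + 1
                just_grad = idx[~dead][L[idx[~dead]] >= cfg.juvenile_length_mm]
                graduated[just_grad] = True
                days_tracked[just_grad] = day + 1
            curves[rep, day + 1] = 100.0 * alive.sum() / n

        survivors = alive  # includes graduated juveniles
        survival_pct[rep] = 100.0 * survivors.sum() / n
        if survivors.any():
            growth[rep] = float(
                np.mean((L[survivors] - cfg.hatch_length_mm) / days_tracked[survivors])
            )
        else:
            growth[rep] = np.nan
        n_grad[rep] = int(graduated.sum())
        n_died[rep] = int((~alive).sum())
        n_alive[rep] = int((alive & ~graduated).sum())

    return CohortResult(
        survival_pct=survival_pct,
        growth_mm_per_day=growth,
        n_graduated=n_grad,
        n_died=n_died,
        n_alive_end=n_alive,
        survival_curves=curves,
        replicate_seeds=[int(c.generate_state(1)[0] % (2**31)) for c in children],
        season=scenario.season,
        multipliers=mult,
        juvenile_length_mm=cfg.juvenile_length_mm,
    )


def run_treatments(
    cfg: IBMConfig,
    scenario: Scenario,
    multipliers: Mapping[str, BehaviorMultipliers],
    seed: int,
) -> pd.DataFrame:
    """Run several treatments under one scenario with the same root seed
    (paired replicates) and return a tidy per-replicate summary."""
    frames = []
    for name, mult in multipliers.items():
        res = run_cohort(cfg, scenario, mult, seed)
        f = res.summary_frame()
        f.insert(0, "treatment", name)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
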