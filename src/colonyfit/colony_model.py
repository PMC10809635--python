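"""Deterministic matrix projection of a *C. elegans* colony on a finite food patch.

The colony is represented per generation (1 = P0 founders, 2 = F1, 3 = F2, ...)
as a vector of expected counts over hourly age classes: one class per hour of
the egg and larval stages, then one class per hour of adulthood up to a
terminal absorbing class.  Each hour every generation is advanced by the same
aging-chain transition matrix; eggs laid by generation *g* adults are credited
to generation *g + 1* at egg age 0.  There is no mortality, and food scarcity
does not feed back on development: the trajectory runs over the full horizon
and the bust hour — when cumulative food consumption first reaches the patch
size — is read off afterwards.

Counts are real-valued expectations.  On configurations with integer
fecundity the projection coincides exactly with an individual-based
enumeration of every worm, which is how the model is validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .life_history import (
    ConsumptionRates,
    FecunditySchedule,
    LifeHistoryConfig,
    StageID,
    StageSchedule,
    validate_config,
)

__all__ = [
    "PopulationState",
    "ColonyTrajectory",
    "BustSummary",
    "build_transition_matrix",
    "step_population",
    "hourly_consumption",
    "simulate_colony",
    "detect_bust",
    "founder_sweep",
]

logger = logging.getLogger(__name__)

#: Generations tracked as separate vectors; eggs of later generations are
#: pooled into the last one (with a logged warning).
DEFAULT_MAX_GENERATIONS = 4


class ConfigurationError(ValueError):
    """Raised when a simulation is requested with an invalid configuration."""


@dataclass
class PopulationState:
    """Expected counts per (generation, hourly age class) at one instant.

    ``counts[g - 1, i]`` is the expected number of generation-``g`` worms in
    age class ``i`` (class 0 = first hour as an egg; the last class is the
    absorbing terminal adult class).
    """

    counts: np.ndarray  # shape (n_generations, n_classes)
    schedule: StageSchedule

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.schedule.n_classes:
            raise ValueError(
                f"counts must have shape (n_generations, {self.schedule.n_classes})"
            )

    @property
    def n_generations(self) -> int:
        return self.counts.shape[0]

    def stage_counts(self, stage: StageID) -> np.ndarray:
        """Per-generation totals for one stage."""
        return self.counts[:, self.schedule.stage_slice(stage)].sum(axis=1)

    def total(self) -> float:
        return float(self.counts.sum())

    def adults_past(self, adult_age_hr: int) -> float:
        """Total adults whose adult age is >= ``adult_age_hr``."""
        start = self.schedule.preadult_hr + adult_age_hr
        if start >= self.schedule.n_classes:
            return 0.0
        return float(self.counts[:, start:].sum())


@dataclass
class ColonyTrajectory:
    """Hourly states plus the food ledger of one simulated colony.

    ``hourly_consumption[t]`` is the food eaten during hour ``t`` (the step
    from ``t - 1`` to ``t``, computed from the state at ``t - 1``); hour 0
    therefore consumes nothing.  ``cumulative_consumption`` is its running
    sum.
    """

    counts: np.ndarray  # shape (horizon + 1, n_generations, n_classes)
    hourly_consumption: np.ndarray  # shape (horizon + 1,)
    founder_number: int
    config: LifeHistoryConfig

    @property
    def horizon_hr(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def cumulative_consumption(self) -> np.ndarray:
        return np.cumsum(self.hourly_consumption)

    def state_at(self, hour: int) -> PopulationState:
        if not 0 <= hour <= self.horizon_hr:
            raise IndexError(f"hour {hour} outside [0, {self.horizon_hr}]")
        return PopulationState(self.counts[hour].copy(), self.config.stages)

    def eggs_laid_into(self, generation: int) -> float:
        """Total eggs ever credited to ``generation`` over the whole run.

        With no mortality this equals the generation's final total count,
        except for generation 1 whose members are the founders.
        """
        if generation == 1:
            return 0.0
        g = generation - 1
        if g >= self.counts.shape[1]:
            return 0.0
        return float(self.counts[-1, g, :].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_hr, generation, stage, count, consumption."""
        schedule = self.config.stages
        rows = []
        cum = self.cumulative_consumption
        for t in range(self.horizon_hr + 1):
            for g in range(self.counts.shape[1]):
                for stage in StageID:
                    c = self.counts[t, g, schedule.stage_slice(stage)].sum()
                    rows.append(
                        (t, g + 1, stage.name, c, self.hourly_consumption[t], cum[t])
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "time_hr",
                "generation",
                "stage",
                "count",
                "hourly_consumption",
                "cumulative_consumption",
            ],
        )


@dataclass
class BustSummary:
    """When (and in what state) the colony exhausted its patch."""

    bust_hr: Optional[int]
    state_at_bust: Optional[PopulationState]
    founder_number: int


def build_transition_matrix(schedule: StageSchedule) -> np.ndarray:
    """Hourly aging chain over one generation's age classes.

    Every age class advances to the next with weight 1; the terminal adult
    class is absorbing.  Fecundity is *not* part of this matrix — eggs cross
    generations and are handled by :func:`step_population`.
    """
    n = schedule.n_classes
    if n < 2:
        raise ConfigurationError("schedule must define at least two age classes")
    m = np.zeros((n, n))
    idx = np.arange(n - 1)
    m[idx + 1, idx] = 1.0
    m[n - 1, n - 1] = 1.0
    return m


def step_population(
    state: PopulationState,
    matrix: np.ndarray,
    fecundity: FecunditySchedule,
    *,
    max_generations: Optional[int] = None,
) -> PopulationState:
    """Advance the colony by one hour.

    Each generation's vector is aged by ``matrix``; eggs laid this hour by
    generation ``g`` adults (fecundity by adult age) appear in generation
    ``g + 1`` at egg age 0.  Eggs from the last tracked generation are pooled
    back into it, with a warning.
    """
    schedule = state.schedule
    n_gen = state.n_generations if max_generations is None else max_generations
    old = state.counts
    new = np.zeros((n_gen, schedule.n_classes))
    for g in range(min(old.shape[0], n_gen)):
        new[g] = matrix @ old[g]

    # the absorbing terminal class pools all older ages and must be
    # post-reproductive, so fecundity never applies to it
    adult0 = schedule.preadult_hr
    span = min(fecundity.span_hr, schedule.adult_tracking_hr - 1)
    for g in range(min(old.shape[0], n_gen)):
        eggs = float(old[g, adult0 : adult0 + span] @ fecundity.eggs_per_hr[:span])
        if eggs <= 0:
            continue
        target = g + 1
        if target >= n_gen:
            target = n_gen - 1
            logger.warning(
                "eggs from generation %d pooled into last tracked generation %d",
                g + 1,
                n_gen,
            )
        new[target, 0] += eggs
    return PopulationState(new, schedule)


def hourly_consumption(state: PopulationState, rates: ConsumptionRates) -> float:
    """Food units eaten per hour by the whole colony in ``state``."""
    total = 0.0
    for stage, rate in rates.as_dict().items():
        total += rate * float(state.stage_counts(stage).sum())
    return total


def _rate_vector(schedule: StageSchedule, rates: ConsumptionRates) -> np.ndarray:
    vec = np.empty(schedule.n_classes)
    for stage, rate in rates.as_dict().items():
        vec[schedule.stage_slice(stage)] = rate
    return vec


def simulate_colony(
    founder_number: int,
    cfg: LifeHistoryConfig,
    horizon_hr: Optional[int] = None,
    *,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> ColonyTrajectory:
    """Project a colony founded by L4 worms hour by hour over the horizon.

    Founders are generation 1 and start in the final hourly class of the L4
    stage, so they molt to adults after one step.  States and the food ledger
    are recorded every hour; the trajectory is never truncated at bust.
    """
    if founder_number < 0:
        raise ConfigurationError(f"founder_number must be >= 0, got {founder_number}")
    problems = validate_config(cfg)
    if problems:
        raise ConfigurationError("invalid config:\n  " + "\n  ".join(problems))
    horizon = cfg.patch.horizon_hr if horizon_hr is None else int(horizon_hr)
    schedule = cfg.stages

    matrix = build_transition_matrix(schedule)
    rate_vec = _rate_vector(schedule, cfg.consumption)

    counts = np.zeros((horizon + 1, max_generations, schedule.n_classes))
    counts[0, 0, schedule.preadult_hr - 1] = float(founder_number)

    hourly = np.zeros(horizon + 1)
    state = PopulationState(counts[0].copy(), schedule)

    class _Once(logging.Filter):
        seen = False

        def filter(self, record: logging.LogRecord) -> bool:
            if "pooled" in record.getMessage():
                if self.seen:
                    return False
                self.seen = True
            return True

    once = _Once()
    logger.addFilter(once)
    try:
        for t in range(1, horizon + 1):
            hourly[t] = float((state.counts * rate_vec).sum())
            state = step_population(
                state, matrix, cfg.fecundity, max_generations=max_generations
            )
            counts[t] = state.counts
    finally:
        logger.removeFilter(once)
    return ColonyTrajectory(counts, hourly, int(founder_number), cfg)


def detect_bust(traj: ColonyTrajectory, patch_units: Optional[float] = None) -> BustSummary:
    """First hour at which cumulative consumption reaches the patch size.

    Returns ``bust_hr=None`` if the patch outlasts the horizon.
    """
    if patch_units is None:
        patch_units = traj.config.patch.patch_units
    cum = traj.cumulative_consumption
    reached = np.nonzero(cum >= patch_units)[0]
    if reached.size == 0:
        return BustSummary(None, None, traj.founder_number)
    bust = int(reached[0])
    return BustSummary(bust, traj.state_at(bust), traj.founder_number)


def founder_sweep(
    founder_numbers: Sequence[int],
    cfg: LifeHistoryConfig,
    horizon_hr: Optional[int] = None,
) -> list[tuple[int, Optional[int], BustSummary, ColonyTrajectory]]:
    """Simulate one colony per founder number and detect each bust.

    Returns one ``(founder_number, bust_hr, BustSummary, ColonyTrajectory)``
    row per entry, in input order.  Deterministic.
    """
    if len(founder_numbers) == 0:
        raise ConfigurationError("founder_numbers must be non-empty")
    rows = []
    for n in founder_numbers:
        traj = simulate_colony(n, cfg, horizon_hr)
        bust = detect_bust(traj)
        rows.append((int(n), bust.bust_hr, bust, traj))
    return rows
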