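"""Population-structure summaries of simulated colony trajectories.

Derives the quantities the colony model is actually consulted for: the
stage-by-generation composition of the colony at a given hour (typically
the bust hour), which generation the L1 pool belongs to (dauers form from
L1s, so this is the model's prediction of the dauer generation), the
pre-dauer pool (L1 + L2 larvae, the model's proxy for potential dauer
yield), and the share of food consumption that was futile — eaten by worms
that could not contribute to dauer yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colony_model import ColonyTrajectory, PopulationState
from .life_history import StageID

__all__ = [
    "StructureSummary",
    "structure_at",
    "dominant_l1_generation",
    "predauer_pool",
    "futile_consumption_share",
]


@dataclass
class StructureSummary:
    """Counts and proportions per (stage, generation) at one hour.

    Proportions are over hatched worms (L1..adult); eggs are tallied but
    carry proportion NaN so they never distort the stage composition.
    """

    table: pd.DataFrame  # columns: stage, generation, count, proportion
    hour: int

    def count(self, stage: StageID, generation: int | None = None) -> float:
        t = self.table[self.table["stage"] == stage.name]
        if generation is not None:
            t = t[t["generation"] == generation]
        return float(t["count"].sum())

    def l1_by_generation(self) -> pd.Series:
        t = self.table[self.table["stage"] == StageID.L1.name]
        return t.set_index("generation")["count"]


def structure_at(traj: ColonyTrajectory, hour: int) -> StructureSummary:
    """Stage-by-generation composition of the colony at ``hour``.

    Counts aggregate the hourly age classes within each stage; proportions
    are normalized over all non-egg worms.
    """
    if not 0 <= hour <= traj.horizon_hr:
        raise IndexError(f"hour {hour} outside [0, {traj.horizon_hr}]")
    state = traj.state_at(hour)
    return summarize_state(state, hour)


def summarize_state(state: PopulationState, hour: int = 0) -> StructureSummary:
    rows = []
    for g in range(state.n_generations):
        for stage in StageID:
            c = float(
                state.counts[g, state.schedule.stage_slice(stage)].sum()
            )
            rows.append((stage.name, g + 1, c))
    table = pd.DataFrame(rows, columns=["stage", "generation", "count"])
    worms = table.loc[table["stage"] != StageID.EGG.name, "count"].sum()
    table["proportion"] = np.where(
        table["stage"] == StageID.EGG.name,
        np.nan,
        table["count"] / worms if worms > 0 else 0.0,
    )
    return StructureSummary(table, hour)


def dominant_l1_generation(summary: StructureSummary) -> int:
    """Generation holding the most L1 larvae; ties go to the lower index.

    Because dauers form from L1s, this is the model's prediction of which
    generation the dauers will come from.  Raises ``ValueError`` when no
    L1 is present (the statistic is undefined).
    """
    l1 = summary.l1_by_generation().sort_index()
    if float(l1.sum()) <= 0:
        raise ValueError("dominant L1 generation undefined: no L1 present")
    return int(l1.idxmax())  # idxmax takes the first (lowest) index on ties


def predauer_pool(summary: StructureSummary) -> float:
    """L1 + L2 larvae across all generations — potential dauer yield."""
    return summary.count(StageID.L1) + summary.count(StageID.L2)


def futile_consumption_share(
    traj: ColonyTrajectory,
    bust_hr: int,
    *,
    window_hr: int = 10,
) -> float:
    """Fraction of pre-bust consumption that could not feed into dauer yield.

    Two components are counted as futile:

    1. consumption by post-reproductive adults (adult age beyond the
       reproductive span) at any hour up to bust, and
    2. consumption during the final ``window_hr`` hours before bust by
       every stage other than L1/L2 — worms too advanced (or too young,
       i.e. still eggs, which eat nothing anyway) to arrest as dauers
       before the food runs out.

    Hours in the window avoid double counting: post-reproductive adults
    there are counted once.  Returns 0 for a colony that never consumed.
    """
    if bust_hr is None:
        raise ValueError("futile consumption share requires a bust hour")
    schedule = traj.config.stages
    rates = traj.config.consumption.as_dict()
    span = traj.config.fecundity.span_hr
    post_start = schedule.preadult_hr + span

    futile = 0.0
    total = 0.0
    window_from = max(1, bust_hr - window_hr + 1)
    for t in range(1, bust_hr + 1):
        state = traj.counts[t - 1]  # hour-t consumption comes from state at t-1
        hour_total = 0.0
        hour_futile = 0.0
        for stage in StageID:
            c = float(state[:, schedule.stage_slice(stage)].sum())
            hour_total += rates[stage] * c
        post_repro = float(state[:, post_start:].sum()) if post_start < schedule.n_classes else 0.0
        hour_futile += rates[StageID.ADULT] * post_repro
        if t >= window_from:
            for stage in (StageID.L3, StageID.L4):
                hour_futile += rates[stage] * float(
                    state[:, schedule.stage_slice(stage)].sum()
                )
            pre_repro_adults = (
                float(state[:, schedule.stage_slice(StageID.ADULT)].sum()) - post_repro
            )
            hour_futile += rates[StageID.ADULT] * pre_repro_adults
        total += hour_total
        futile += hour_futile
    if total <= 0:
        return 0.0
    return float(futile / total)
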