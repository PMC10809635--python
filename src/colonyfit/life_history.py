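"""Life-history parameterization of a *C. elegans* colony at 25 °C.

The colony model advances worms through hourly age classes spanning the
egg, four larval stages (L1--L4) and adulthood.  Everything the projection
needs is collected here: how long each stage lasts, how many eggs an adult
lays per hour of adult age, how much food each stage eats per hour, and
the size of the food patch the colony subsists on.

Defaults describe wild-type hermaphrodites at 25 °C: an egg-to-adult time
of 44 h, a 170-egg brood laid over five reproductive days with a peak on
day two, and stage food-consumption rates doubling from 1 unit/h (L1) to
16 units/h (adult).  All values can be overridden from a YAML/JSON config.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "StageID",
    "StageSchedule",
    "FecunditySchedule",
    "ConsumptionRates",
    "PatchConfig",
    "LifeHistoryConfig",
    "default_config",
    "validate_config",
    "load_config",
]


class StageID(enum.Enum):
    """Developmental stages, in order. ADULT is terminal."""

    EGG = 0
    L1 = 1
    L2 = 2
    L3 = 3
    L4 = 4
    ADULT = 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Stages that have a finite duration (everything except ADULT).
PRE_ADULT_STAGES = (StageID.EGG, StageID.L1, StageID.L2, StageID.L3, StageID.L4)


@dataclass(frozen=True)
class StageSchedule:
    """Stage durations in whole hours plus the number of tracked adult age classes.

    ``adult_tracking_hr`` controls how many hourly adult age classes the
    transition matrix distinguishes; the last class is absorbing.  It must
    cover the reproductive span so that fecundity lookups by adult age are
    exact.
    """

    egg_hr: int = 9
    l1_hr: int = 14
    l2_hr: int = 8
    l3_hr: int = 8
    l4_hr: int = 10
    adult_tracking_hr: int = 160

    @property
    def durations(self) -> dict[StageID, int]:
        return {
            StageID.EGG: self.egg_hr,
            StageID.L1: self.l1_hr,
            StageID.L2: self.l2_hr,
            StageID.L3: self.l3_hr,
            StageID.L4: self.l4_hr,
        }

    @property
    def preadult_hr(self) -> int:
        """Hours from egg laid to the L4 → adult molt."""
        return self.egg_hr + self.l1_hr + self.l2_hr + self.l3_hr + self.l4_hr

    @property
    def n_classes(self) -> int:
        """Dimension of the hourly age-class vector for one generation."""
        return self.preadult_hr + self.adult_tracking_hr

    def stage_of_class(self, idx: int) -> StageID:
        """Stage of hourly age class ``idx`` (0 = first hour as egg)."""
        bound = 0
        for stage in PRE_ADULT_STAGES:
            bound += self.durations[stage]
            if idx < bound:
                return stage
        return StageID.ADULT

    def stage_slice(self, stage: StageID) -> slice:
        """Slice of the age-class vector occupied by ``stage``."""
        start = 0
        for s in PRE_ADULT_STAGES:
            if s is stage:
                return slice(start, start + self.durations[s])
            start += self.durations[s]
        return slice(start, start + self.adult_tracking_hr)


@dataclass(frozen=True)
class FecunditySchedule:
    """Eggs laid per hour as a function of adult age.

    ``eggs_per_hr[a]`` is the expected number of eggs an adult lays during
    its ``a``-th hour of adulthood (age 0 = first hour after the L4 → adult
    molt).  Entries beyond the array are zero, so the array length is the
    reproductive span in hours.
    """

    eggs_per_hr: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eggs_per_hr", np.asarray(self.eggs_per_hr, dtype=float)
        )

    @property
    def span_hr(self) -> int:
        return int(self.eggs_per_hr.size)

    @property
    def total_brood(self) -> float:
        return float(self.eggs_per_hr.sum())

    def rate_at(self, adult_age_hr: int) -> float:
        if 0 <= adult_age_hr < self.span_hr:
            return float(self.eggs_per_hr[adult_age_hr])
        return 0.0


def _default_fecundity() -> np.ndarray:
    """Unimodal 170-egg brood over a 120-h reproductive span, peaking on day 2.

    Oviposition starts ~8 h after the L4 → adult molt, ramps linearly to a
    peak at adult age 30 h (day 2 of the span) and decays exponentially
    (28-h scale) thereafter.  The 170-egg total matches 34,000 F1 progeny
    from 200 founders.
    """
    span, onset, peak, decay = 120, 8, 30, 28.0
    age = np.arange(span, dtype=float)
    rate = np.zeros(span)
    ramp = (age >= onset) & (age <= peak)
    rate[ramp] = (age[ramp] - onset + 1) / (peak - onset + 1)
    rate[age > peak] = np.exp(-(age[age > peak] - peak) / decay)
    return rate * (170.0 / rate.sum())


@dataclass(frozen=True)
class ConsumptionRates:
    """Food units consumed per worm per hour, by stage.

    Eggs do not feed (embryos are closed systems); larval rates double per
    stage from 1 unit/h at L1 to 16 units/h for adults.
    """

    egg: float = 0.0
    l1: float = 1.0
    l2: float = 2.0
    l3: float = 4.0
    l4: float = 8.0
    adult: float = 16.0

    def as_dict(self) -> dict[StageID, float]:
        return {
            StageID.EGG: self.egg,
            StageID.L1: self.l1,
            StageID.L2: self.l2,
            StageID.L3: self.l3,
            StageID.L4: self.l4,
            StageID.ADULT: self.adult,
        }

    def as_tuple(self) -> tuple[float, ...]:
        return (self.egg, self.l1, self.l2, self.l3, self.l4, self.adult)


@dataclass(frozen=True)
class PatchConfig:
    """The virtual food patch and the simulation window."""

    patch_units: float = 10_000_000.0
    horizon_hr: int = 200
    founder_numbers: tuple[int, ...] = (1, 3, 10, 50, 200)


@dataclass(frozen=True)
class LifeHistoryConfig:
    """Bundle of all four parameter blocks."""

    stages: StageSchedule = field(default_factory=StageSchedule)
    fecundity: FecunditySchedule = field(
        default_factory=lambda: FecunditySchedule(_default_fecundity())
    )
    consumption: ConsumptionRates = field(default_factory=ConsumptionRates)
    patch: PatchConfig = field(default_factory=PatchConfig)


def default_config() -> LifeHistoryConfig:
    """Package defaults for wild-type hermaphrodites at 25 °C.

    Returns
    -------
    LifeHistoryConfig
        Stage durations EGG 9 h, L1 14 h, L2 8 h, L3 8 h, L4 10 h;
        a 170-egg brood over 120 h peaking on day 2; consumption
        (0, 1, 2, 4, 8, 16) units/h for EGG..ADULT; a 10-million-unit
        patch simulated for 200 h with founder numbers (1, 3, 10, 50, 200).
    """
    return LifeHistoryConfig()


def validate_config(cfg: LifeHistoryConfig) -> list[str]:
    """Check every invariant; return human-readable violations (empty = valid)."""
    violations: list[str] = []
    st = cfg.stages
    for stage, dur in st.durations.items():
        if not (isinstance(dur, (int, np.integer)) and dur >= 1):
            violations.append(
                f"stage duration {stage.name} must be a positive integer, got {dur!r}"
            )
    if not (isinstance(st.adult_tracking_hr, (int, np.integer)) and st.adult_tracking_hr >= 1):
        violations.append(
            f"adult_tracking_hr must be a positive integer, got {st.adult_tracking_hr!r}"
        )

    fec = cfg.fecundity
    if fec.eggs_per_hr.ndim != 1:
        violations.append("fecundity eggs_per_hr must be a 1-D array")
    elif np.any(fec.eggs_per_hr < 0):
        bad = int(np.argmin(fec.eggs_per_hr >= 0))
        violations.append(
            f"fecundity eggs_per_hr[{bad}] is negative ({fec.eggs_per_hr[bad]})"
        )
    if fec.span_hr > st.adult_tracking_hr - 1:
        violations.append(
            "adult_tracking_hr must exceed the reproductive span (the terminal "
            f"absorbing class is post-reproductive; {st.adult_tracking_hr} <= {fec.span_hr})"
        )

    rates = cfg.consumption.as_dict()
    for stage, rate in rates.items():
        if rate < 0:
            violations.append(f"consumption rate for {stage.name} is negative ({rate})")

    patch = cfg.patch
    if not patch.patch_units > 0:
        violations.append(f"patch_units must be positive, got {patch.patch_units!r}")
    if not (isinstance(patch.horizon_hr, (int, np.integer)) and patch.horizon_hr >= 1):
        violations.append(f"horizon_hr must be a positive integer, got {patch.horizon_hr!r}")
    if any(f <= 0 or int(f) != f for f in patch.founder_numbers):
        violations.append(
            f"founder_numbers must be positive integers, got {patch.founder_numbers!r}"
        )
    if st.preadult_hr >= patch.horizon_hr:
        violations.append(
            "total pre-adult duration must be shorter than the simulation horizon "
            f"({st.preadult_hr} >= {patch.horizon_hr})"
        )
    return violations


def load_config(path: Union[str, Path]) -> LifeHistoryConfig:
    """Read a config file (YAML or JSON) and merge it over the defaults.

    Recognized keys: ``stage_durations_hr`` (mapping EGG/L1/L2/L3/L4, plus
    optional ``ADULT_TRACKING``), ``fecundity_eggs_per_hr`` (list),
    ``consumption_units_per_hr`` (mapping EGG..ADULT), ``patch_units``,
    ``horizon_hr``, ``founder_numbers``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    base = default_config()
    stages = base.stages
    if "stage_durations_hr" in raw:
        d = {str(k).upper(): v for k, v in raw["stage_durations_hr"].items()}
        stages = StageSchedule(
            egg_hr=d.get("EGG", stages.egg_hr),
            l1_hr=d.get("L1", stages.l1_hr),
            l2_hr=d.get("L2", stages.l2_hr),
            l3_hr=d.get("L3", stages.l3_hr),
            l4_hr=d.get("L4", stages.l4_hr),
            adult_tracking_hr=d.get("ADULT_TRACKING", stages.adult_tracking_hr),
        )
    fecundity = base.fecundity
    if "fecundity_eggs_per_hr" in raw:
        fecundity = FecunditySchedule(np.asarray(raw["fecundity_eggs_per_hr"], dtype=float))
    consumption = base.consumption
    if "consumption_units_per_hr" in raw:
        c = {str(k).upper(): float(v) for k, v in raw["consumption_units_per_hr"].items()}
        consumption = ConsumptionRates(
            egg=c.get("EGG", consumption.egg),
            l1=c.get("L1", consumption.l1),
            l2=c.get("L2", consumption.l2),
            l3=c.get("L3", consumption.l3),
            l4=c.get("L4", consumption.l4),
            adult=c.get("ADULT", consumption.adult),
        )
    patch = PatchConfig(
        patch_units=float(raw.get("patch_units", base.patch.patch_units)),
        horizon_hr=int(raw.get("horizon_hr", base.patch.horizon_hr)),
        founder_numbers=tuple(
            int(f) for f in raw.get("founder_numbers", base.patch.founder_numbers)
        ),
    )
    cfg = LifeHistoryConfig(stages=stages, fecundity=fecundity, consumption=consumption, patch=patch)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid life-history config:\n  " + "\n  ".join(problems))
    return cfg
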