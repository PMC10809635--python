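import logging

import numpy as np
import pandas as pd
import pytest

from colonyfit.assay_analysis import AssayDataset, PLATE_COLUMNS
from colonyfit.life_history import (
    ConsumptionRates,
    FecunditySchedule,
    LifeHistoryConfig,
    PatchConfig,
    StageSchedule,
    default_config,
)

# generation-overflow warnings are expected in long default runs
logging.getLogger("colonyfit.colony_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


def make_toy_config(
    egg=2,
    l1=1,
    l2=1,
    l3=1,
    l4=1,
    tracking=4,
    fecundity=(0, 2, 1),
    patch_units=100.0,
    horizon=20,
):
    """Small integer-fecundity config for oracle comparisons."""
    return LifeHistoryConfig(
        stages=StageSchedule(egg, l1, l2, l3, l4, tracking),
        fecundity=FecunditySchedule(np.asarray(fecundity, dtype=float)),
        consumption=ConsumptionRates(),
        patch=PatchConfig(patch_units=patch_units, horizon_hr=horizon, founder_numbers=(1,)),
    )


@pytest.fixture
def toy_cfg():
    return make_toy_config()


def random_toy_config(rng):
    durations = rng.integers(1, 4, size=5)
    tracking = int(rng.integers(2, 6))
    fec = rng.integers(0, 4, size=int(rng.integers(1, tracking)))
    horizon = int(rng.integers(10, 51))
    return LifeHistoryConfig(
        stages=StageSchedule(*[int(d) for d in durations], tracking),
        fecundity=FecunditySchedule(fec.astype(float)),
        consumption=ConsumptionRates(),
        patch=PatchConfig(patch_units=50.0, horizon_hr=max(horizon, int(durations.sum()) + 1)),
    )


def plates_frame(rows):
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


@pytest.fixture
def small_dataset():
    """Three founder numbers x 3 replicates x 2 timepoints, hand-sized numbers."""
    rows = []
    busts = {1: (150.0, 155.0, 160.0), 3: (120.0, 125.0, 130.0), 10: (90.0, 95.0, 100.0)}
    base = {1: 100, 3: 200, 10: 50}
    for fn in (1, 3, 10):
        for r in range(3):
            rep = f"F{fn}_R{r+1}"
            for tp, factor in ((72, 1.0), (144, 2.0)):
                c = int(base[fn] * factor) + r
                rows.append((fn, rep, busts[fn][r], tp, c, c + 1, c + 2, 5.0, False))
    return AssayDataset(plates_frame(rows))
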