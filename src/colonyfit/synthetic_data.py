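"""Synthetic colony-fitness assay datasets.

Generates plate-level records with the statistical structure of the real
assay: per-founder-number bust times, dauer-yield time courses with a peak
at 144 h post bust, triplicate 1-ml aliquot counts, lawn-QC measurements
and dauer body lengths with a late recovery shift.  Default parameters are
anchored to the published group means (bust 159 h for 1 founder down to
51 h for 200; 72-h yields 1540 / 2837 / 310 / 232 / 1050 for founders
1 / 3 / 10 / 50 / 200; lawn area 9.9 ± 0.48 cm², OD600 0.346 ± 0.020).

Noise model (an emulation choice, not a measured property): bust times are
normal truncated at zero.  Dauer yields vary severalfold between trials, so
yield noise is decomposed into a lognormal between-replicate batch effect
shared across a replicate's whole time course (the dominant component) and
a smaller lognormal within-plate component; aliquot counts are Poisson
around yield/volume; lengths are normal with a +40 µm shift from 144 h on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import assay_analysis as aa
from .assay_analysis import AssayDataset

__all__ = ["GeneratorParams", "default_params", "generate", "round_trip"]

FOUNDERS = (1, 3, 10, 50, 200)
TIMEPOINTS = (48, 72, 96, 120, 144, 168)

#: Yield time-course shape relative to the 72-h anchor: dauers appear from
#: 48 h, rise to a peak at 144 h, then decline at 168 h.
_SHAPE = {48: 0.15, 72: 1.0, 96: 1.5, 120: 2.0, 144: 2.4, 168: 1.9}


def _bust_means() -> dict[int, float]:
    """Log-linear interpolation in founder number between the printed anchors.

    Anchors: 159 h at 1 founder and 51 h at 200 founders; intermediate
    founder numbers fall on the straight line in (log n, log hours).  Only
    the ordering is load-bearing.
    """
    lo_n, lo_t, hi_n, hi_t = 1.0, 159.0, 200.0, 51.0
    slope = np.log(hi_t / lo_t) / np.log(hi_n / lo_n)
    return {n: float(lo_t * (n / lo_n) ** slope) for n in FOUNDERS}


@dataclass
class GeneratorParams:
    """All knobs of the synthetic assay generator."""

    bust_mean_hr: Mapping[int, float]
    bust_sd_hr: Mapping[int, float]
    yield_mean: Mapping[tuple[int, int], float]  # (founder, timepoint) -> mean
    yield_cv_between: float = 0.35  # between-replicate (trial) batch effect
    yield_cv_within: float = 0.15  # residual plate-to-plate scatter
    volume_ml: float = 5.0
    lawn_area_mean: float = 9.9
    lawn_area_sd: float = 0.48
    lawn_od_mean: float = 0.346
    lawn_od_sd: float = 0.020
    lawn_n: int = 10
    length_baseline_um: float = 400.0
    length_sd_um: float = 20.0
    length_late_shift_um: float = 40.0
    length_shift_from_hr: int = 144
    length_n_per_timepoint: int = 20
    replicates: int = 3

    def validate(self) -> None:
        if any(sd < 0 for sd in self.bust_sd_hr.values()):
            raise ValueError("noise SDs must be non-negative")
        if self.yield_cv_between < 0 or self.yield_cv_within < 0:
            raise ValueError("yield CVs must be non-negative")
        if any(m < 0 for m in self.yield_mean.values()):
            raise ValueError("yield means must be non-negative")


def default_params(replicates: int = 3) -> GeneratorParams:
    """Defaults anchored to the published group means (see module docstring)."""
    anchors_72 = {1: 1540.0, 3: 2837.0, 10: 310.0, 50: 232.0, 200: 1050.0}
    yield_mean = {
        (fn, tp): anchors_72[fn] * _SHAPE[tp] for fn in FOUNDERS for tp in TIMEPOINTS
    }
    busts = _bust_means()
    return GeneratorParams(
        bust_mean_hr=busts,
        bust_sd_hr={n: 0.05 * m for n, m in busts.items()},
        yield_mean=yield_mean,
        replicates=replicates,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))


def generate(params: GeneratorParams, seed: int) -> AssayDataset:
    """Draw one synthetic assay dataset; identical seeds give identical data.

    Per (founder, replicate): one bust time ~ Normal(mean, sd) truncated at
    0, and one lognormal batch multiplier (mean 1, the between-trial CV)
    shared by every timepoint of that replicate.  Per plate: a latent yield
    = mean x batch x lognormal within-plate factor, decomposed into three
    aliquot counts ~ Poisson(yield / volume).  Zero SDs and CVs reproduce
    the means exactly (counts then equal yield/volume deterministically).
    """
    params.validate()
    rng = np.random.default_rng(seed)

    founders = sorted({fn for fn, _ in params.yield_mean})
    timepoints = sorted({tp for _, tp in params.yield_mean})
    rows = []
    for fn in founders:
        for r in range(1, params.replicates + 1):
            rep = f"F{fn}_R{r}"
            bust = max(
                0.0,
                float(rng.normal(params.bust_mean_hr[fn], params.bust_sd_hr[fn])),
            )
            batch = _lognormal_factor(rng, params.yield_cv_between)
            stochastic = params.yield_cv_between > 0 or params.yield_cv_within > 0
            for tp in timepoints:
                mean = params.yield_mean[(fn, tp)]
                latent = mean * batch * _lognormal_factor(rng, params.yield_cv_within)
                lam = latent / params.volume_ml
                if stochastic:
                    counts = tuple(int(c) for c in rng.poisson(lam, size=3))
                else:
                    counts = (lam, lam, lam)
                rows.append(
                    (fn, rep, round(bust, 1), tp, *counts, params.volume_ml, False)
                )
    plates = pd.DataFrame(rows, columns=aa.PLATE_COLUMNS)

    lawn = pd.DataFrame(
        {
            "plate_id": [f"QC{i+1}" for i in range(params.lawn_n)],
            "area_cm2": rng.normal(params.lawn_area_mean, params.lawn_area_sd, params.lawn_n),
            "od600": rng.normal(params.lawn_od_mean, params.lawn_od_sd, params.lawn_n),
        }
    )

    lrows = []
    for tp in timepoints:
        shift = params.length_late_shift_um if tp >= params.length_shift_from_hr else 0.0
        vals = rng.normal(
            params.length_baseline_um + shift,
            params.length_sd_um,
            params.length_n_per_timepoint,
        )
        for i, v in enumerate(vals):
            lrows.append((tp, f"T{tp}_W{i+1}", round(float(v), 1)))
    lengths = pd.DataFrame(lrows, columns=aa.LENGTH_COLUMNS)

    return AssayDataset(plates, lawn, lengths)


@dataclass
class RecoveryReport:
    """How well the analysis pipeline recovers the generator's parameters."""

    bust: pd.DataFrame  # founder_number, true_mean, recovered_mean, rel_err
    yields: pd.DataFrame  # founder_number, timepoint_hr, true_mean, recovered_mean, rel_err
    peak_hr: dict[int, Optional[int]]
    speed_order_recovered: bool
    tradeoff_detected: bool
    length_increase: bool


def round_trip(
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    reference_timepoint: int = 72,
) -> RecoveryReport:
    """Generate a dataset and push it through the full assay analysis.

    Reports the relative error of every recovered group mean, the detected
    yield peak per founder number, whether the speed (bust-time) ordering
    matches the generator's, and whether the speed-versus-yield trade-off
    flag is raised.
    """
    if params is None:
        params = default_params()
    ds = generate(params, seed)
    summary = aa.summarize(ds)

    bust = summary.bust.copy()
    bust["true_mean"] = bust["founder_number"].map(params.bust_mean_hr)
    bust["rel_err"] = (bust["mean"] - bust["true_mean"]).abs() / bust["true_mean"]
    bust = bust.rename(columns={"mean": "recovered_mean"})[
        ["founder_number", "true_mean", "recovered_mean", "rel_err"]
    ]

    yields = summary.dauer_yield.copy()
    yields["true_mean"] = [
        params.yield_mean[(fn, tp)]
        for fn, tp in zip(yields["founder_number"], yields["timepoint_hr"])
    ]
    yields["rel_err"] = np.where(
        yields["true_mean"] > 0,
        (yields["mean"] - yields["true_mean"]).abs() / yields["true_mean"],
        yields["mean"].abs(),
    )
    yields = yields.rename(columns={"mean": "recovered_mean"})[
        ["founder_number", "timepoint_hr", "true_mean", "recovered_mean", "rel_err"]
    ]

    founders = sorted({fn for fn, _ in params.yield_mean})
    peaks = {fn: yield_timecourse_peak(ds, fn) for fn in founders}

    true_order = sorted(founders, key=lambda n: params.bust_mean_hr[n])
    rec_order = list(
        summary.bust.sort_values("mean")["founder_number"]
    )
    trade = aa.tradeoff_table(summary, reference_timepoint)
    recov = aa.recovery_check(ds.lengths)
    return RecoveryReport(
        bust,
        yields,
        peaks,
        rec_order == true_order,
        trade.tradeoff_detected,
        recov.length_increase,
    )


def yield_timecourse_peak(ds: AssayDataset, founder_number: int) -> Optional[int]:
    tc = aa.yield_timecourse(ds, founder_number)
    return tc.peak_hr
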