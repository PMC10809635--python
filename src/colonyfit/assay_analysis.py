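"""Analysis of colony fitness assays: time to bust and dauer yield.

The experimental unit is a plate: a colony founded by a known number of L4
hermaphrodites on a standard bacterial lawn, monitored until the food patch
is exhausted (bust), then assayed for dauer larvae at fixed hours post
bust.  Dauers are counted in three 1-ml aliquots of a worm suspension of
known volume, so the plate-level yield estimate is ``mean(counts) x
volume_ml``.  Contaminated plates are excluded from every statistic.

Group comparisons follow the assay's standard design: one-way ANOVA over
founder numbers (or two-way over founder x timepoint) with Tukey's multiple
comparisons; unbalanced groups use the Tukey-Kramer studentized-range
procedure, with the mean square error pooled from the fitted ANOVA model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "AssayPlate",
    "AssayDataset",
    "FitnessSummary",
    "ComparisonResult",
    "TradeoffTable",
    "ContaminatedPlateError",
    "scale_dauer_count",
    "summarize",
    "compare_groups",
    "yield_timecourse",
    "recovery_check",
    "lawn_qc",
    "tradeoff_table",
]

PLATE_COLUMNS = [
    "founder_number",
    "replicate_id",
    "bust_hr",
    "timepoint_hr",
    "count1",
    "count2",
    "count3",
    "volume_ml",
    "contaminated",
]
LAWN_COLUMNS = ["plate_id", "area_cm2", "od600"]
LENGTH_COLUMNS = ["timepoint_hr", "worm_id", "length_um"]


class ContaminatedPlateError(ValueError):
    """Raised when a statistic is requested from a contaminated plate."""


@dataclass(frozen=True)
class AssayPlate:
    """One plate-level record of the dauer-yield assay."""

    founder_number: int
    replicate_id: str
    bust_hr: Optional[float]
    timepoint_hr: int
    raw_counts: tuple[int, int, int]
    suspension_volume_ml: float
    contaminated: bool = False

    def __post_init__(self) -> None:
        if len(self.raw_counts) != 3:
            raise ValueError("raw_counts must hold exactly three aliquot counts")
        if any(c < 0 for c in self.raw_counts):
            raise ValueError("aliquot counts must be non-negative")
        if not self.suspension_volume_ml > 0:
            raise ValueError("suspension_volume_ml must be positive")


@dataclass
class AssayDataset:
    """Plate records plus the lawn-QC and dauer-length side tables."""

    plates: pd.DataFrame
    lawn_qc: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LAWN_COLUMNS)
    )
    lengths: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LENGTH_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.plates.columns]
        if missing:
            raise ValueError(f"plates table missing columns: {missing}")

    def usable_plates(self) -> pd.DataFrame:
        """Plates that enter statistics (contaminated ones excluded)."""
        mask = self.plates["contaminated"].astype(bool)
        return self.plates.loc[~mask].copy()

    def n_excluded(self) -> int:
        return int(self.plates["contaminated"].astype(bool).sum())

    def with_yields(self) -> pd.DataFrame:
        """Usable plates with the scaled dauer-yield column added."""
        t = self.usable_plates()
        t["dauer_yield"] = (
            t[["count1", "count2", "count3"]].mean(axis=1) * t["volume_ml"]
        )
        return t


def scale_dauer_count(plate: AssayPlate) -> float:
    """Estimated total dauers on the plate.

    Counts are dauers per 1-ml aliquot, so the total is the mean of the
    three counts scaled by the suspension volume in ml.
    """
    if plate.contaminated:
        raise ContaminatedPlateError(
            f"plate {plate.replicate_id!r} (founders={plate.founder_number}) is "
            "contaminated; its counts are excluded from all statistics"
        )
    return float(np.mean(plate.raw_counts) * plate.suspension_volume_ml)


@dataclass
class FitnessSummary:
    """Per-group means, sample SDs and n for both fitness metrics.

    ``bust`` is indexed by founder number (one value per replicate colony);
    ``dauer_yield`` by (founder number, hours post bust).  ``missing``
    lists analyzed cells with no usable plate — they are reported, never
    imputed.
    """

    bust: pd.DataFrame
    dauer_yield: pd.DataFrame
    missing: list[tuple] = field(default_factory=list)


def _group_stats(values: pd.Series) -> tuple[float, float, int]:
    n = int(values.size)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def summarize(dataset: AssayDataset, metric: str = "both") -> FitnessSummary:
    """Group means ± sample SD for bust time and/or dauer yield.

    Bust time is summarized per founder number over replicate colonies
    (plates sharing a replicate are one colony; plates with missing
    ``bust_hr`` are excluded from the speed metric only).  Dauer yield is
    summarized per (founder number, timepoint).
    """
    if metric not in ("bust_hr", "dauer_yield", "both"):
        raise ValueError(f"unknown metric {metric!r}")
    t = dataset.with_yields()

    bust_rows, missing = [], []
    if metric in ("bust_hr", "both"):
        per_colony = (
            t.dropna(subset=["bust_hr"])
            .groupby(["founder_number", "replicate_id"], as_index=False)["bust_hr"]
            .first()
        )
        for fn, grp in per_colony.groupby("founder_number"):
            mean, sd, n = _group_stats(grp["bust_hr"])
            bust_rows.append((fn, mean, sd, n))
        for fn in sorted(t["founder_number"].unique()):
            if not any(r[0] == fn for r in bust_rows):
                missing.append(("bust_hr", fn))
    bust = pd.DataFrame(bust_rows, columns=["founder_number", "mean", "sd", "n"])

    yield_rows = []
    if metric in ("dauer_yield", "both"):
        for (fn, tp), grp in t.groupby(["founder_number", "timepoint_hr"]):
            mean, sd, n = _group_stats(grp["dauer_yield"])
            yield_rows.append((fn, tp, mean, sd, n))
    dauer_yield = pd.DataFrame(
        yield_rows, columns=["founder_number", "timepoint_hr", "mean", "sd", "n"]
    )
    return FitnessSummary(bust, dauer_yield, missing)


@dataclass
class ComparisonResult:
    """ANOVA table plus Tukey pairwise comparisons."""

    design: str  # "one-way" or "two-way"
    anova: pd.DataFrame
    pairwise: pd.DataFrame  # group1, group2, mean_diff, q, p_adj [, timepoint_hr]


def _tukey_kramer(
    means: pd.Series, ns: pd.Series, mse: float, df_resid: float
) -> pd.DataFrame:
    """All pairwise studentized-range comparisons given a pooled MSE."""
    levels = list(means.index)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append((a, b, diff, float(q), min(p, 1.0)))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "q", "p_adj"])


def compare_groups(
    dataset: AssayDataset, metric: str, design: str = "one-way"
) -> ComparisonResult:
    """ANOVA over founder numbers followed by Tukey's multiple comparisons.

    One-way: ``metric`` ~ founder number.  Two-way: dauer yield ~ founder x
    timepoint, with Tukey comparisons between founder numbers within each
    timepoint (pooling the error term over the whole model).  Unbalanced
    groups are handled by the Tukey-Kramer form of the studentized-range
    test.
    """
    t = dataset.with_yields()
    if metric == "bust_hr":
        t = (
            t.dropna(subset=["bust_hr"])
            .groupby(["founder_number", "replicate_id"], as_index=False)["bust_hr"]
            .first()
        )
        value = "bust_hr"
    elif metric == "dauer_yield":
        value = "dauer_yield"
    else:
        raise ValueError(f"unknown metric {metric!r}")

    if design == "one-way":
        sizes = t.groupby("founder_number")[value].size()
        small = sizes[sizes < 2]
        if len(sizes) < 2:
            raise ValueError("one-way design needs at least two founder-number groups")
        if not small.empty:
            raise ValueError(
                f"degenerate design: founder group(s) {list(small.index)} have n < 2"
            )
        model = ols(f"{value} ~ C(founder_number)", data=t).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
        df_resid = float(anova.loc["Residual", "df"])
        means = t.groupby("founder_number")[value].mean()
        pairwise = _tukey_kramer(means, sizes, mse, df_resid)
        return ComparisonResult("one-way", anova, pairwise)

    if design == "two-way":
        if value != "dauer_yield":
            raise ValueError("two-way design applies to dauer yield")
        sizes = t.groupby(["founder_number", "timepoint_hr"])[value].size()
        small = sizes[sizes < 2]
        if not small.empty:
            raise ValueError(
                f"degenerate design: cell(s) {list(small.index)} have n < 2"
            )
        model = ols(
            f"{value} ~ C(founder_number) * C(timepoint_hr)", data=t
        ).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
        df_resid = float(anova.loc["Residual", "df"])
        frames = []
        for tp, grp in t.groupby("timepoint_hr"):
            means = grp.groupby("founder_number")[value].mean()
            ns = grp.groupby("founder_number")[value].size()
            if len(means) < 2:
                continue
            pw = _tukey_kramer(means, ns, mse, df_resid)
            pw.insert(0, "timepoint_hr", tp)
            frames.append(pw)
        pairwise = pd.concat(frames, ignore_index=True)
        return ComparisonResult("two-way", anova, pairwise)

    raise ValueError(f"unknown design {design!r}")


@dataclass
class TimeCourse:
    """Per-timepoint dauer-yield statistics and the yield peak."""

    founder_number: int
    table: pd.DataFrame  # timepoint_hr, mean, sd, n
    peak_hr: Optional[int]
    peak_defined: bool


def yield_timecourse(dataset: AssayDataset, founder_number: int) -> TimeCourse:
    """Mean ± SD dauer yield per timepoint and the peak hour.

    ``peak_hr`` is the timepoint with the maximal mean yield; ties break
    toward the earlier timepoint.  With fewer than two timepoints the peak
    is undefined and flagged.
    """
    summary = summarize(dataset, "dauer_yield").dauer_yield
    table = (
        summary[summary["founder_number"] == founder_number]
        .drop(columns="founder_number")
        .sort_values("timepoint_hr")
        .reset_index(drop=True)
    )
    if len(table) < 2:
        return TimeCourse(founder_number, table, None, False)
    best = table.loc[table["mean"].idxmax()]  # idxmax → first occurrence = earliest
    return TimeCourse(founder_number, table, int(best["timepoint_hr"]), True)


@dataclass
class RecoveryReport:
    """Dauer body-length time course after bust.

    A rising mean length at late timepoints is the morphological sign that
    some dauers are exiting diapause.
    """

    means: pd.DataFrame  # timepoint_hr, mean, sd, n
    anova_p: float
    length_increase: bool
    undersized_groups: list[int]


def recovery_check(lengths: pd.DataFrame, min_n: int = 15) -> RecoveryReport:
    """Per-timepoint mean dauer length, one-way ANOVA, and an increase flag.

    The flag is raised when the latest timepoint's mean length exceeds the
    earliest's.  Groups with n < ``min_n`` worms trigger a warning but the
    analysis is still returned.
    """
    if lengths["timepoint_hr"].nunique() < 2:
        raise ValueError("recovery check needs at least two timepoints")
    rows = []
    undersized = []
    for tp, grp in lengths.groupby("timepoint_hr"):
        mean, sd, n = _group_stats(grp["length_um"])
        rows.append((tp, mean, sd, n))
        if n < min_n:
            undersized.append(int(tp))
    if undersized:
        warnings.warn(
            f"timepoint(s) {undersized} have fewer than {min_n} worms", stacklevel=2
        )
    means = pd.DataFrame(rows, columns=["timepoint_hr", "mean", "sd", "n"]).sort_values(
        "timepoint_hr", ignore_index=True
    )
    groups = [g["length_um"].to_numpy() for _, g in lengths.groupby("timepoint_hr")]
    if np.ptp(np.concatenate(groups)) == 0:  # identical lengths: F undefined
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
    flag = bool(means["mean"].iloc[-1] > means["mean"].iloc[0])
    return RecoveryReport(means, anova_p, flag, undersized)


@dataclass
class LawnQCReport:
    """Food-patch constancy check: lawn area and optical density."""

    stats: pd.DataFrame  # variable, mean, sd, min, max, n
    passed: bool
    failures: list[str]


def lawn_qc(
    qc: pd.DataFrame,
    area_band: Optional[tuple[float, float]] = None,
    od_band: Optional[tuple[float, float]] = None,
) -> LawnQCReport:
    """Summary statistics for lawn area (cm²) and OD600, with tolerance bands.

    A band, when given, is the (min, max) range every plate must fall in.
    """
    if len(qc) < 2:
        raise ValueError("lawn QC needs at least two plates")
    rows = []
    failures: list[str] = []
    for col, band in (("area_cm2", area_band), ("od600", od_band)):
        v = qc[col].astype(float)
        rows.append((col, float(v.mean()), float(v.std(ddof=1)), float(v.min()), float(v.max()), int(v.size)))
        if band is not None:
            lo, hi = band
            bad = qc.loc[(v < lo) | (v > hi), "plate_id"].tolist()
            if bad:
                failures.append(f"{col} outside [{lo}, {hi}] on plates {bad}")
    table = pd.DataFrame(rows, columns=["variable", "mean", "sd", "min", "max", "n"])
    return LawnQCReport(table, not failures, failures)


@dataclass
class TradeoffTable:
    """Joint ranking of resource-utilization speed and dauer yield.

    Speed rank 1 = fastest bust; yield rank 1 = highest mean yield at the
    reference timepoint.  ``tradeoff_detected`` is raised when speed is
    monotone in founder number but yield is not — the signature of a
    speed-versus-yield trade-off across founder numbers.
    """

    table: pd.DataFrame
    reference_timepoint_hr: int
    tradeoff_detected: bool


def tradeoff_table(summary: FitnessSummary, reference_timepoint: int) -> TradeoffTable:
    """Rank founder numbers by speed (mean bust) and yield (mean at reference)."""
    bust = summary.bust.set_index("founder_number")["mean"]
    yld = summary.dauer_yield
    yld = yld[yld["timepoint_hr"] == reference_timepoint].set_index("founder_number")[
        "mean"
    ]
    founders = sorted(set(bust.index) & set(yld.index))
    if len(founders) < 3:
        raise ValueError(
            "trade-off table needs both metrics for at least three founder numbers"
        )
    t = pd.DataFrame(
        {
            "founder_number": founders,
            "mean_bust_hr": [bust[f] for f in founders],
            "mean_yield": [yld[f] for f in founders],
        }
    )
    t["speed_rank"] = t["mean_bust_hr"].rank(method="first").astype(int)
    t["yield_rank"] = t["mean_yield"].rank(method="first", ascending=False).astype(int)
    by_founder = t.sort_values("founder_number")
    speed_monotone = (
        by_founder["mean_bust_hr"].is_monotonic_decreasing
        or by_founder["mean_bust_hr"].is_monotonic_increasing
    )
    y = by_founder["mean_yield"]
    yield_monotone = y.is_monotonic_decreasing or y.is_monotonic_increasing
    return TradeoffTable(
        by_founder.reset_index(drop=True),
        reference_timepoint,
        bool(speed_monotone and not yield_monotone),
    )
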