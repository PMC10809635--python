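"""Independent oracles used only by the test suite.

``enumerate_colony`` is an individual-based re-implementation of the colony
dynamics: every worm (and every egg it lays) is an explicit record with a
birth hour and a generation, aged by table lookup.  On configurations with
integer hourly fecundity it must agree *exactly* with the matrix
projection, which it never calls.

``oneway_anova_brute`` / ``twoway_anova_brute_balanced`` / ``tukey_brute``
compute ANOVA tables and studentized-range comparisons from raw sums of
squares, independent of statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from colonyfit.life_history import LifeHistoryConfig, StageID


def enumerate_colony(
    founder_number: int,
    cfg: LifeHistoryConfig,
    horizon_hr: int,
    max_generations: int = 4,
) -> np.ndarray:
    """Per-hour, per-generation, per-age-class counts from explicit worms.

    Returns an int array of shape ``(horizon+1, max_generations, n_classes)``
    directly comparable with ``ColonyTrajectory.counts``.  Requires integer
    fecundity entries.
    """
    schedule = cfg.stages
    fec = cfg.fecundity.eggs_per_hr
    assert np.allclose(fec, np.round(fec)), "oracle needs integer fecundity"
    fec = np.round(fec).astype(int)
    preadult = schedule.preadult_hr
    n_classes = schedule.n_classes

    # worm = (birth_hour, generation); founders sit in the last L4 hour at t=0
    worms: list[tuple[int, int]] = [
        (-(preadult - 1), 1) for _ in range(founder_number)
    ]
    counts = np.zeros((horizon_hr + 1, max_generations, n_classes), dtype=np.int64)

    def record(t: int) -> None:
        for birth, gen in worms:
            age = min(t - birth, n_classes - 1)
            counts[t, gen - 1, age] += 1

    record(0)
    for t in range(0, horizon_hr):
        laid: list[tuple[int, int]] = []
        for birth, gen in worms:
            adult_age = t - birth - preadult
            if 0 <= adult_age < fec.size and fec[adult_age] > 0:
                child_gen = min(gen + 1, max_generations)
                laid.extend((t + 1, child_gen) for _ in range(fec[adult_age]))
        worms.extend(laid)
        record(t + 1)
    return counts


def stage_totals(counts_t: np.ndarray, schedule) -> dict[str, float]:
    """Aggregate one hour's (generation, age-class) counts by stage."""
    out = {}
    for stage in StageID:
        out[stage.name] = float(counts_t[:, schedule.stage_slice(stage)].sum())
    return out


def oneway_anova_brute(groups: dict) -> tuple[float, float, float]:
    """(F, MSE, df_resid) from raw sums of squares."""
    all_v = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    grand = all_v.mean()
    k = len(groups)
    n_total = all_v.size
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    dfb, dfw = k - 1, n_total - k
    return (ssb / dfb) / (ssw / dfw), ssw / dfw, float(dfw)


def twoway_anova_brute_balanced(
    cells: dict,
) -> dict[str, float]:
    """Sums of squares for a balanced two-factor design with replication.

    ``cells[(a, b)]`` is the array of replicate values for factor levels
    (a, b); every cell must have the same n.
    """
    a_levels = sorted({a for a, _ in cells})
    b_levels = sorted({b for _, b in cells})
    n = len(next(iter(cells.values())))
    assert all(len(v) == n for v in cells.values())
    grand = np.mean([x for v in cells.values() for x in v])
    mean_a = {a: np.mean([x for (aa, b) in cells for x in cells[(aa, b)] if aa == a]) for a in a_levels}
    mean_b = {b: np.mean([x for (a, bb) in cells for x in cells[(a, bb)] if bb == b]) for b in b_levels}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_int = n * sum(
        (np.mean(cells[(a, b)]) - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_err = sum(
        ((np.asarray(cells[(a, b)]) - np.mean(cells[(a, b)])) ** 2).sum()
        for a in a_levels
        for b in b_levels
    )
    df_err = len(cells) * (n - 1)
    return {
        "ss_a": ss_a,
        "ss_b": ss_b,
        "ss_int": ss_int,
        "ss_err": ss_err,
        "df_a": len(a_levels) - 1,
        "df_b": len(b_levels) - 1,
        "df_int": (len(a_levels) - 1) * (len(b_levels) - 1),
        "df_err": df_err,
    }


def tukey_brute(groups: dict, mse: float, df_resid: float) -> dict:
    """All pairwise (q, p) from the studentized-range distribution."""
    labels = sorted(groups)
    k = len(labels)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            ma, mb = np.mean(groups[a]), np.mean(groups[b])
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(mb - ma) / se
            out[(a, b)] = (q, float(stats.studentized_range.sf(q, k, df_resid)))
    return out
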