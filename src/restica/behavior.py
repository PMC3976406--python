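"""Exhaustion ratings: VAS pooling, per-subject standardization, 2-way ANOVA.

Exhaustion is rated on two 0-150 visual analogue scales (tiredness and
restedness); the restedness scale is reversed and the two are averaged into
one pooled score. Pooled scores are z-standardized within each participant
(subtract the participant's mean, divide by the participant's sample SD) and
analyzed in a two-way ANOVA with time-of-day (T1 vs T3) and day activity
(FD vs WD) as factors, followed by Bonferroni-adjusted simple main effects.

RSME effort ratings and N-back error counts, when present in a behavior
table, are carried through untouched; their models are standard off-the-shelf
GLM fits outside this module's remit.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def pool_vas(tired: float, rested: float, scale_max: float = 150.0) -> float:
    """Pooled exhaustion: mean of tiredness and the reversed restedness scale."""
    for name, v in (("tired", tired), ("rested", rested)):
        if not 0 <= v <= scale_max:
            raise ValueError(f"{name} VAS {v} outside [0, {scale_max}]")
    return (tired + (scale_max - rested)) / 2.0


def zstandardize(values: np.ndarray) -> np.ndarray:
    """Z-scores of one participant's ratings (sample SD, divisor n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 ratings per participant")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant ratings: participant has no usable variance "
                         "and should be excluded")
    return (values - values.mean()) / sd


def pooled_exhaustion_table(table: pd.DataFrame, scale_max: float = 150.0) -> pd.DataFrame:
    """Add pooled and per-participant standardized exhaustion columns.

    Raw scales are pooled first, then standardized within participant across
    all of that participant's scans.
    """
    out = table.copy()
    out["exhaustion"] = [
        pool_vas(t, r, scale_max) for t, r in zip(out["tired_vas"], out["rested_vas"])
    ]
    out["exhaustion_z"] = (
        out.groupby("subject")["exhaustion"].transform(lambda v: zstandardize(v.to_numpy()))
    )
    return out


def exhaustion_anova(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-way (day x timepoint) ANOVA on standardized exhaustion at T1/T3.

    Expects one row per subject x day x timepoint with an ``exhaustion_z``
    column (see :func:`pooled_exhaustion_table`); only T1 and T3 rows enter.
    Returns main-effect and interaction F/p plus Bonferroni-adjusted simple
    main effects (day contrasted at each timepoint and vice versa, each
    family of 2 comparisons, pooled-error F-tests).
    """
    data = table[table["timepoint"].isin(["T1", "T3"])].copy()
    cells = data.groupby(["day", "timepoint"]).size()
    if len(cells) != 4 or cells.nunique() != 1:
        raise ValueError(f"design must be a balanced 2x2; cell counts: {cells.to_dict()}")
    n_cell = int(cells.iloc[0])
    if n_cell < 3:
        raise ValueError("need >= 3 subjects per cell")

    y = data["exhaustion_z"].to_numpy(dtype=float)
    a = (data["day"] == "WD").to_numpy()  # factor A: day activity
    b = (data["timepoint"] == "T3").to_numpy()  # factor B: time of day
    grand = y.mean()
    n_total = y.size

    def level_mean(mask: np.ndarray) -> float:
        return float(y[mask].mean())

    # balanced two-way fixed-effects decomposition
    ss_a = sum(a_mask.sum() * (level_mean(a_mask) - grand) ** 2
               for a_mask in (a, ~a))
    ss_b = sum(b_mask.sum() * (level_mean(b_mask) - grand) ** 2
               for b_mask in (b, ~b))
    ss_cells = 0.0
    cell_means: dict[tuple[bool, bool], float] = {}
    for av, bv in itertools.product((True, False), repeat=2):
        m = (a == av) & (b == bv)
        cell_means[(av, bv)] = level_mean(m)
        ss_cells += m.sum() * (cell_means[(av, bv)] - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_cells
    df_error = n_total - 4
    ms_error = ss_error / df_error

    def f_test(ss: float, df: int) -> tuple[float, float]:
        if ms_error <= 1e-300:
            return (np.inf, 0.0) if ss > 1e-12 else (0.0, 1.0)
        f = (ss / df) / ms_error
        return float(f), float(stats.f.sf(f, df, df_error))

    f_day, p_day = f_test(ss_a, 1)
    f_time, p_time = f_test(ss_b, 1)
    f_int, p_int = f_test(ss_ab, 1)

    # simple main effects with the pooled error term, Bonferroni x2 per family
    def simple_f(diff: float) -> tuple[float, float]:
        ss = n_cell * diff**2 / 2.0
        if ms_error <= 1e-300:
            return (np.inf, 0.0) if ss > 1e-12 else (0.0, 1.0)
        f = ss / ms_error
        return float(f), float(stats.f.sf(f, 1, df_error))

    simple = []
    for bv, blabel in ((False, "T1"), (True, "T3")):
        diff = cell_means[(True, bv)] - cell_means[(False, bv)]
        f, p = simple_f(diff)
        simple.append({"effect": "day", "at": blabel, "difference": float(diff),
                       "F": f, "p": p, "p_bonferroni": min(1.0, 2 * p)})
    for av, alabel in ((False, "FD"), (True, "WD")):
        diff = cell_means[(av, True)] - cell_means[(av, False)]
        f, p = simple_f(diff)
        simple.append({"effect": "timepoint", "at": alabel, "difference": float(diff),
                       "F": f, "p": p, "p_bonferroni": min(1.0, 2 * p)})

    return {
        "F_day": f_day, "p_day": p_day,
        "F_timepoint": f_time, "p_timepoint": p_time,
        "F_interaction": f_int, "p_interaction": p_int,
        "df": (1, df_error),
        "simple_effects": pd.DataFrame(simple),
    }
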