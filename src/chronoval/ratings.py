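"""Valence-rating analysis: per-participant past/future means, the 2x2 mixed
ANOVA (age group x time category), and Cohen's d for the time effect.

The ANOVA is the classical mixed-design decomposition computed from sums of
squares: the between-subject part on participant averages, the within-subject
part on past/future difference scores.  With two within-levels every within
effect reduces to a statement about the difference score d_i = future_i -
past_i, which keeps the decomposition exact and transparent:

    F_time        = N * dbar^2            / MS_err
    F_interaction = sum_g n_g (dbar_g - dbar)^2 / MS_err
    MS_err        = sum_i (d_i - dbar_g(i))^2 / (N - G)      (all on the d scale)

(the conventional factor 1/2 that maps difference scores onto the cell scale
cancels from every F ratio).  Group means are observation-weighted.  Cohen's d
for the time effect is defined on the within-subject difference scores,
``mean(d_i) / SD(d_i)``, pooled across participants; the package documents
this formula explicitly since paired effect sizes are often left ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DataError

__all__ = ["AnovaReport", "participant_means", "mixed_anova"]

AGE_GROUPS = ("younger", "older")


def participant_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Average each participant's past-word and future-word ratings.

    Returns one row per participant: participant_id, age_group, mean_past,
    mean_future.  A participant lacking either time category raises
    :class:`DataError` naming them.
    """
    required = {"participant_id", "age_group", "time_category", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise DataError(f"rating table lacks column(s): {sorted(missing)}")

    means = (
        ratings.groupby(["participant_id", "age_group", "time_category"], observed=True)["rating"]
        .mean()
        .unstack("time_category")
    )
    for cat in ("past", "future"):
        if cat not in means.columns:
            means[cat] = np.nan
    incomplete = means.index[means[["past", "future"]].isna().any(axis=1)]
    if len(incomplete):
        pid = incomplete[0][0]
        raise DataError(f"participant {pid!r} is missing a time category")
    out = means.reset_index().rename(columns={"past": "mean_past", "future": "mean_future"})
    return out[["participant_id", "age_group", "mean_past", "mean_future"]]


@dataclass
class AnovaReport:
    """Mixed-ANOVA table for the Adult x Time design plus the paired d.

    ``effects`` maps "adult" / "time" / "adult_x_time" to
    (F, df_num, df_den, p).  ``degenerate`` flags a zero error variance, in
    which case any nonzero effect is reported as F = inf, p = 0.
    """

    effects: dict
    d_time: float
    n_by_group: dict
    degenerate: bool = False

    def to_text(self) -> str:
        lines = [f"{'effect':<14}{'F':>12}{'df1':>5}{'df2':>7}{'p':>12}"]
        for name, (f, df1, df2, p) in self.effects.items():
            lines.append(f"{name:<14}{f:>12.4g}{df1:>5d}{df2:>7d}{p:>12.4g}")
        lines.append(f"d_time = {self.d_time:.4f}  (within-subject difference scale)")
        return "\n".join(lines)


def mixed_anova(means: pd.DataFrame) -> AnovaReport:
    """Two-way mixed ANOVA on the participant means table.

    Between-subject factor: age group; within-subject factor: time
    (past vs future).  Requires at least two participants per group.
    """
    groups = means["age_group"].unique()
    if len(groups) != 2:
        raise AnalysisError(f"need exactly two age groups, found {sorted(map(str, groups))}")
    sizes = means["age_group"].value_counts()
    if (sizes < 2).any():
        raise AnalysisError("each age group needs at least two participants")

    n = len(means)
    g = 2
    subj_avg = (means["mean_past"] + means["mean_future"]) / 2.0
    diff = (means["mean_future"] - means["mean_past"]).to_numpy()
    group = means["age_group"].to_numpy()

    # between-subject stratum, on participant averages (x2 for the cell scale)
    grand = subj_avg.mean()
    ss_adult = 0.0
    ss_subjects = 0.0
    for lvl in sizes.index:
        vals = subj_avg[group == lvl]
        ss_adult += 2.0 * len(vals) * (vals.mean() - grand) ** 2
        ss_subjects += 2.0 * ((vals - vals.mean()) ** 2).sum()
    df_between = n - g

    # within-subject stratum, on difference scores
    dbar = diff.mean()
    ss_time_d = n * dbar**2
    ss_int_d = 0.0
    ss_err_d = 0.0
    for lvl in sizes.index:
        vals = diff[group == lvl]
        ss_int_d += len(vals) * (vals.mean() - dbar) ** 2
        ss_err_d += ((vals - vals.mean()) ** 2).sum()
    df_within = n - g

    degenerate = False

    def f_and_p(ss_effect: float, ss_error: float, df_err: int) -> tuple[float, float]:
        nonlocal degenerate
        if ss_error <= 1e-12 * max(ss_effect, 1.0):
            degenerate = True
            if ss_effect <= 1e-12:
                return 0.0, 1.0
            return math.inf, 0.0
        f = (ss_effect / 1.0) / (ss_error / df_err)
        return f, float(stats.f.sf(f, 1, df_err))

    f_adult, p_adult = f_and_p(ss_adult, ss_subjects, df_between)
    f_time, p_time = f_and_p(ss_time_d, ss_err_d, df_within)
    f_int, p_int = f_and_p(ss_int_d, ss_err_d, df_within)

    sd_diff = diff.std(ddof=1)
    d_time = float(dbar / sd_diff) if sd_diff > 0 else math.copysign(math.inf, dbar) if dbar else 0.0

    return AnovaReport(
        effects={
            "adult": (f_adult, 1, df_between, p_adult),
            "time": (f_time, 1, df_within, p_time),
            "adult_x_time": (f_int, 1, df_within, p_int),
        },
        d_time=d_time,
        n_by_group={str(k): int(v) for k, v in sizes.items()},
        degenerate=degenerate,
    )
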