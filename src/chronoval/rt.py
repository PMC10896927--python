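"""Trial-level reaction-time analysis: filtering, condition summaries,
permutation inference on match/congruency/domain effects, and the
first-vs-second-half practice analysis.

Inference replaces mixed-effects likelihood-ratio tests with subject-level
permutation tests: the estimand is the same level-mean contrast (aggregation
order item -> subject -> condition, so subjects are the exchangeable units),
the null is built by flipping each subject's level labels (within-subject
factors) or reshuffling the group assignment (between-subject factors), and
p = (1 + #{|perm| >= |obs|}) / (1 + n_permutations).

Sign conventions follow the printed half-split tables: every effect is
``mismatch - match`` (or incongruent - congruent, time - valence), for RT and
percent-correct alike, so a positive RT effect and a negative PC effect both
mean the match condition is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "FilterReport",
    "EffectReport",
    "HalfSplitReport",
    "filter_outliers",
    "condition_summary",
    "estimate_effect",
    "half_split",
    "speed_accuracy_check",
]

DEFAULT_LOW_MS = 250.0
DEFAULT_HIGH_MS = 2000.0
DEFAULT_N_PERMUTATIONS = 5000

# effect name -> (column, reference level, contrast level); the estimate is
# mean(contrast) - mean(reference)
_EFFECTS = {
    "match": ("match", "match", "mismatch"),
    "congruency": ("congruency", "congruent", "incongruent"),
    "domain": ("domain", "valence", "time"),
}


# ---------------------------------------------------------------------------
# Outlier filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Outcome of the RT outlier filter (run before accuracy partitioning)."""

    n_input: int
    n_below_low: int
    n_above_high: int
    fraction_below: float
    fraction_above: float
    low_ms: float
    high_ms: float
    retained: pd.DataFrame

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def filter_outliers(
    trials: pd.DataFrame, low: float = DEFAULT_LOW_MS, high: float = DEFAULT_HIGH_MS
) -> FilterReport:
    """Discard trials with rt < low or rt > high (boundaries retained).

    Runs on all trials, correct and incorrect, before any accuracy
    partitioning; fractions are relative to the input trial count.
    """
    if low >= high:
        raise ConfigurationError("filter bounds require low < high")
    n = len(trials)
    if n == 0:
        return FilterReport(0, 0, 0, 0.0, 0.0, low, high, trials.copy())
    rt = trials["rt_ms"].to_numpy()
    below = rt < low
    above = rt > high
    retained = trials.loc[~(below | above)].reset_index(drop=True)
    return FilterReport(
        n_input=n,
        n_below_low=int(below.sum()),
        n_above_high=int(above.sum()),
        fraction_below=float(below.sum() / n),
        fraction_above=float(above.sum() / n),
        low_ms=low,
        high_ms=high,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------

def condition_summary(trials: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Cell means per factor combination: mean RT (correct trials only),
    percent correct (all retained trials), and trial counts.

    Cells present in the factor product but without any trials are flagged
    with NaN means and ``n_trials = 0``.
    """
    unknown = [f for f in factors if f not in trials.columns]
    if unknown:
        raise ConfigurationError(f"unknown factor name(s): {unknown}")
    if not factors:
        raise ConfigurationError("at least one factor is required")

    grouped = trials.groupby(factors, observed=False)
    pc = grouped["correct"].mean() * 100.0
    n_all = grouped.size()
    correct_only = trials[trials["correct"]]
    rt = correct_only.groupby(factors, observed=False)["rt_ms"].mean()

    out = pd.DataFrame({"mean_rt_ms": rt, "pc": pc, "n_trials": n_all})
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    out["empty_cell"] = out["n_trials"] == 0
    return out.reset_index()


# ---------------------------------------------------------------------------
# Effect estimation with permutation inference
# ---------------------------------------------------------------------------

@dataclass
class EffectReport:
    """A level-mean contrast with its permutation test."""

    effect_name: str
    estimate: float  # contrast level mean - reference level mean, ms
    level_means: dict
    permutation_p: float
    n_permutations: int
    seed: int
    design: str = "within"  # within | between
    n_subjects: int = 0


def _subject_level_means(trials: pd.DataFrame, column: str) -> pd.DataFrame:
    """Aggregate item -> subject: per subject x level, the mean over item
    means of correct-trial RTs.  Returns subject_id, level, mean_rt columns."""
    correct = trials[trials["correct"]]
    if correct.empty:
        raise AnalysisError("no correct trials to analyse")
    item_means = (
        correct.groupby(["subject_id", column, "item_id"], observed=True)["rt_ms"].mean()
    )
    subj = item_means.groupby(["subject_id", column], observed=True).mean().rename("mean_rt")
    return subj.reset_index()


def estimate_effect(
    trials: pd.DataFrame,
    effect_name: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> EffectReport:
    """Estimate one two-level effect and its permutation p value.

    The factor is treated as within-subject when subjects contribute both
    levels (their level labels are sign-flipped under the null) and as
    between-subject when each subject has exactly one level (subjects are
    reshuffled across groups).  Subjects lacking a level in an otherwise
    within-subject design are dropped from inference.
    """
    if effect_name not in _EFFECTS:
        raise ConfigurationError(f"unknown effect name: {effect_name!r}")
    if seed is None:
        raise ConfigurationError("a permutation seed is mandatory")
    column, ref, contrast = _EFFECTS[effect_name]
    levels = set(trials[column].unique())
    if ref not in levels or contrast not in levels:
        raise AnalysisError(
            f"effect {effect_name!r} needs both levels {ref!r}/{contrast!r}; found {sorted(levels)}"
        )

    subj = _subject_level_means(trials[trials[column].isin([ref, contrast])], column)
    wide = subj.pivot(index="subject_id", columns=column, values="mean_rt")
    rng = np.random.default_rng(seed)

    per_level = {lvl: float(wide[lvl].mean()) for lvl in (ref, contrast)}

    n_both = int(wide.notna().all(axis=1).sum())
    if n_both > 0:
        # within-subject: sign-flip each subject's paired difference
        diffs = (wide[contrast] - wide[ref]).dropna().to_numpy()
        estimate = float(diffs.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, diffs.size))
        perm = (signs * diffs).mean(axis=1)
        design = "within"
        n_subjects = diffs.size
    else:
        # between-subject: reshuffle group labels over subjects
        has_contrast = wide[contrast].notna()
        values = wide[contrast].fillna(wide[ref]).to_numpy()
        labels = has_contrast.to_numpy()
        if labels.all() or not labels.any():
            raise AnalysisError(f"level missing for all subjects in effect {effect_name!r}")
        estimate = float(values[labels].mean() - values[~labels].mean())
        n_contrast = int(labels.sum())
        perm = np.empty(n_permutations)
        order = np.argsort(rng.random((n_permutations, values.size)), axis=1)
        shuffled = values[order]
        perm = shuffled[:, :n_contrast].mean(axis=1) - shuffled[:, n_contrast:].mean(axis=1)
        design = "between"
        n_subjects = values.size

    p = float((1 + np.sum(np.abs(perm) >= abs(estimate))) / (1 + n_permutations))
    return EffectReport(
        effect_name=effect_name,
        estimate=estimate,
        level_means=per_level,
        permutation_p=p,
        n_permutations=n_permutations,
        seed=seed,
        design=design,
        n_subjects=n_subjects,
    )


# ---------------------------------------------------------------------------
# First-vs-second-half practice analysis
# ---------------------------------------------------------------------------

@dataclass
class HalfSplitReport:
    """Match effect per experiment half, for RT and percent correct.

    All effects are mismatch - match: positive RT effects and negative PC
    effects both favour the match condition.  Interaction p values test
    whether the match effect differs between halves, by permutation of half
    labels within subject (within designs) or group labels (between designs).
    """

    cells: pd.DataFrame  # half x match -> mean_rt_ms, pc
    rt_effect: dict  # half -> mismatch - match mean RT
    pc_effect: dict  # half -> mismatch - match PC (percentage points)
    rt_interaction_p: float
    pc_interaction_p: float
    n_permutations: int
    seed: int


def _half_cell_means(trials: pd.DataFrame, value: str) -> pd.DataFrame:
    """Subject-aggregated cell means per half x match condition."""
    if value == "rt":
        data = trials[trials["correct"]]
        col = "rt_ms"
        per_subj = data.groupby(["subject_id", "half", "match"], observed=True)[col].mean()
    else:
        per_subj = (
            trials.groupby(["subject_id", "half", "match"], observed=True)["correct"].mean() * 100.0
        )
    return per_subj.groupby(["half", "match"], observed=True).mean().unstack("match")


def _interaction_p(
    per_subject: pd.DataFrame, rng: np.random.Generator, n_permutations: int
) -> float:
    """Permutation p for the Half x Match interaction.

    ``per_subject`` has columns (half, match) -> one value per subject.  For
    within-subject Match the subject-level interaction score
    (mm2-m2)-(mm1-m1) is sign-flipped; when Match is between subjects the
    subject-level half difference is computed within each subject and group
    labels are reshuffled.
    """
    wide = per_subject
    needed = [("first", "match"), ("first", "mismatch"), ("second", "match"), ("second", "mismatch")]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise AnalysisError(f"missing half x match cell(s): {missing}")
    within_design = bool(wide[needed].notna().all(axis=1).any())
    if within_design:
        scores = (
            (wide[("second", "mismatch")] - wide[("second", "match")])
            - (wide[("first", "mismatch")] - wide[("first", "match")])
        ).dropna().to_numpy()
        if scores.size == 0:
            raise AnalysisError("no subject contributes all four half x match cells")
        obs = scores.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, scores.size))
        perm = (signs * scores).mean(axis=1)
    else:
        # between-subject match: half-difference per subject, compare groups
        diff_mm = (wide[("second", "mismatch")] - wide[("first", "mismatch")]).dropna()
        diff_m = (wide[("second", "match")] - wide[("first", "match")]).dropna()
        if diff_mm.empty or diff_m.empty:
            raise AnalysisError("a match group contributes no complete half pair")
        values = np.concatenate([diff_mm.to_numpy(), diff_m.to_numpy()])
        n_mm = diff_mm.size
        obs = values[:n_mm].mean() - values[n_mm:].mean()
        order = np.argsort(rng.random((n_permutations, values.size)), axis=1)
        shuffled = values[order]
        perm = shuffled[:, :n_mm].mean(axis=1) - shuffled[:, n_mm:].mean(axis=1)
    return float((1 + np.sum(np.abs(perm) >= abs(obs))) / (1 + n_permutations))


def half_split(
    trials: pd.DataFrame,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> HalfSplitReport:
    """Match effect in the first versus the second half of the experiment."""
    for half in ("first", "second"):
        if not (trials["half"] == half).any():
            raise AnalysisError(f"no trials in the {half} half")

    rt_cells = _half_cell_means(trials, "rt")
    pc_cells = _half_cell_means(trials, "pc")
    for cells, label in ((rt_cells, "RT"), (pc_cells, "PC")):
        if cells.isna().any().any():
            raise AnalysisError(f"empty half x match cell in the {label} table")

    rt_effect = {h: float(rt_cells.loc[h, "mismatch"] - rt_cells.loc[h, "match"]) for h in ("first", "second")}
    pc_effect = {h: float(pc_cells.loc[h, "mismatch"] - pc_cells.loc[h, "match"]) for h in ("first", "second")}

    rng = np.random.default_rng(seed)
    correct = trials[trials["correct"]]
    rt_subj = (
        correct.groupby(["subject_id", "half", "match"], observed=True)["rt_ms"]
        .mean()
        .unstack(["half", "match"])
    )
    pc_subj = (
        trials.groupby(["subject_id", "half", "match"], observed=True)["correct"]
        .mean()
        .unstack(["half", "match"])
        * 100.0
    )
    rt_p = _interaction_p(rt_subj, rng, n_permutations)
    pc_p = _interaction_p(pc_subj, rng, n_permutations)

    cells = pd.concat(
        {"mean_rt_ms": rt_cells.stack(), "pc": pc_cells.stack()}, axis=1
    ).reset_index()
    return HalfSplitReport(
        cells=cells,
        rt_effect=rt_effect,
        pc_effect=pc_effect,
        rt_interaction_p=rt_p,
        pc_interaction_p=pc_p,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Speed-accuracy trade-off check
# ---------------------------------------------------------------------------

def speed_accuracy_check(
    trials: pd.DataFrame, effects: tuple[str, ...] = ("match",)
) -> tuple[bool, pd.DataFrame]:
    """True iff, for every effect examined, the RT-faster level is also at
    least as accurate (weak inequality), i.e. no speed-accuracy trade-off."""
    rows = []
    overall = True
    for name in effects:
        if name not in _EFFECTS:
            raise ConfigurationError(f"unknown effect name: {name!r}")
        column, ref, contrast = _EFFECTS[name]
        sub = trials[trials[column].isin([ref, contrast])]
        summary = condition_summary(sub, [column]).set_index(column)
        if summary["empty_cell"].any():
            raise AnalysisError(f"a level of {name!r} has no trials")
        faster = summary["mean_rt_ms"].idxmin()
        slower = contrast if faster == ref else ref
        ok = bool(summary.loc[faster, "pc"] >= summary.loc[slower, "pc"])
        overall &= ok
        rows.append(
            {
                "effect": name,
                "faster_level": faster,
                "faster_rt_ms": summary.loc[faster, "mean_rt_ms"],
                "faster_pc": summary.loc[faster, "pc"],
                "slower_pc": summary.loc[slower, "pc"],
                "no_tradeoff": ok,
            }
        )
    return overall, pd.DataFrame(rows)
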