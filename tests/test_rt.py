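"""RT analysis: outlier filter, cell summaries, permutation effect
estimation, half-split practice analysis, and the speed-accuracy check."""

import numpy as np
import pandas as pd
import pytest

from chronoval.errors import AnalysisError, ConfigurationError
from chronoval.pipeline import table2_trials
from chronoval.rt import (
    condition_summary,
    estimate_effect,
    filter_outliers,
    half_split,
    speed_accuracy_check,
)
from chronoval.synthetic import DesignSpec, RTGenParams, generate_rt_experiment


def _trials(rows):
    defaults = {
        "subject_id": "S001",
        "item_id": "I01",
        "domain": "time",
        "category": "past",
        "match": "match",
        "congruency": "not_applicable",
        "block_index": 0,
        "half": "first",
        "rt_ms": 500.0,
        "correct": True,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFilter:
    def test_boundaries_are_retained(self):
        trials = _trials([{"rt_ms": v} for v in (200.0, 250.0, 1500.0, 2000.0, 2500.0)])
        rep = filter_outliers(trials)
        assert sorted(rep.retained["rt_ms"]) == [250.0, 1500.0, 2000.0]
        assert rep.n_below_low == 1 and rep.n_above_high == 1
        assert rep.fraction_below == pytest.approx(0.2)

    def test_empty_input(self):
        rep = filter_outliers(_trials([]).iloc[0:0])
        assert rep.n_input == 0 and rep.fraction_below == 0.0 and rep.fraction_above == 0.0

    def test_degenerate_generator_has_zero_removals(self, noiseless_params):
        design = DesignSpec.experiment2(n_subjects=4, items_per_category=2)
        trials = generate_rt_experiment(design, noiseless_params)
        rep = filter_outliers(trials)
        assert rep.n_below_low == 0 and rep.n_above_high == 0
        assert rep.n_retained == len(trials)

    def test_idempotence(self, small_trials):
        once = filter_outliers(small_trials).retained
        twice = filter_outliers(once).retained
        assert once.equals(twice)

    def test_invalid_bounds(self, small_trials):
        with pytest.raises(ConfigurationError):
            filter_outliers(small_trials, low=2000.0, high=250.0)


class TestConditionSummary:
    def test_rt_uses_correct_trials_only_pc_uses_all(self):
        trials = _trials(
            [{"rt_ms": 700.0, "correct": True}, {"rt_ms": 900.0, "correct": False}]
        )
        out = condition_summary(trials, ["match"]).set_index("match")
        assert out.loc["match", "mean_rt_ms"] == pytest.approx(700.0)
        assert out.loc["match", "pc"] == pytest.approx(50.0)

    def test_degenerate_generator_cell_difference_exact(self, noiseless_params):
        design = DesignSpec.experiment2(n_subjects=4, items_per_category=2)
        trials = generate_rt_experiment(design, noiseless_params)
        out = condition_summary(trials, ["match"]).set_index("match")
        assert out.loc["mismatch", "mean_rt_ms"] - out.loc["match", "mean_rt_ms"] == pytest.approx(170.0)

    def test_cell_means_match_generator_expectations(self, small_trials):
        out = condition_summary(small_trials, ["match", "domain"]).set_index(["match", "domain"])
        # planted structure: mismatch slower, time domain slower
        assert out.loc[("mismatch", "time"), "mean_rt_ms"] > out.loc[("match", "time"), "mean_rt_ms"]
        assert out.loc[("match", "time"), "mean_rt_ms"] > out.loc[("match", "valence"), "mean_rt_ms"]

    def test_unknown_factor_rejected(self, small_trials):
        with pytest.raises(ConfigurationError):
            condition_summary(small_trials, ["handedness"])


class TestEstimateEffect:
    def test_two_subjects_identical_level_means_give_zero(self):
        rows = []
        for s in ("S001", "S002"):
            for match, rt in (("match", 600.0), ("mismatch", 600.0)):
                rows.append({"subject_id": s, "match": match, "rt_ms": rt})
        rep = estimate_effect(_trials(rows), "match", n_permutations=99, seed=1)
        assert rep.estimate == pytest.approx(0.0)

    def test_within_design_estimate_and_detection(self, small_trials):
        rep = estimate_effect(small_trials, "match", n_permutations=999, seed=3)
        assert rep.design == "within"
        assert 100.0 < rep.estimate < 240.0  # planted 170 ms
        assert rep.permutation_p < 0.05
        assert rep.estimate == pytest.approx(
            rep.level_means["mismatch"] - rep.level_means["match"], abs=15.0
        )

    def test_between_design_detected(self):
        design = DesignSpec.experiment1(n_subjects=20, items_per_category=3)
        trials = generate_rt_experiment(design, RTGenParams(seed=8, subject_sd=30.0))
        rep = estimate_effect(trials, "match", n_permutations=999, seed=4)
        assert rep.design == "between"
        assert rep.permutation_p < 0.05

    def test_sign_flips_when_levels_swapped(self, small_trials):
        rep = estimate_effect(small_trials, "match", n_permutations=199, seed=5)
        swapped = small_trials.copy()
        swapped["match"] = swapped["match"].map({"match": "mismatch", "mismatch": "match"})
        rep2 = estimate_effect(swapped, "match", n_permutations=199, seed=5)
        assert rep2.estimate == pytest.approx(-rep.estimate)

    def test_missing_level_and_missing_seed_rejected(self, small_trials):
        only_match = small_trials[small_trials["match"] == "match"]
        with pytest.raises(AnalysisError):
            estimate_effect(only_match, "match", n_permutations=99, seed=1)
        with pytest.raises(ConfigurationError):
            estimate_effect(small_trials, "match", n_permutations=99)
        with pytest.raises(ConfigurationError):
            estimate_effect(small_trials, "handedness", n_permutations=99, seed=1)


class TestHalfSplit:
    def test_published_worked_examples_reproduced_exactly(self):
        expected = {
            "exp1": (171.0, 160.0),
            "exp2": (210.0, 183.0),
            "exp3": (149.0, 206.0),
        }
        for exp, (first, second) in expected.items():
            rep = half_split(table2_trials(exp), n_permutations=199, seed=1)
            assert rep.rt_effect["first"] == pytest.approx(first)
            assert rep.rt_effect["second"] == pytest.approx(second)

    def test_identical_halves_give_null_interaction(self):
        rows = []
        for s in ("S001", "S002", "S003", "S004"):
            for half in ("first", "second"):
                for match, rt in (("match", 700.0), ("mismatch", 900.0)):
                    for item, off in (("I01", -5.0), ("I02", 5.0)):
                        rows.append(
                            {
                                "subject_id": s,
                                "half": half,
                                "match": match,
                                "item_id": item,
                                "rt_ms": rt + off,
                            }
                        )
        rep = half_split(_trials(rows), n_permutations=199, seed=2)
        assert rep.rt_effect["first"] == rep.rt_effect["second"] == pytest.approx(200.0)
        assert rep.rt_interaction_p > 0.5

    def test_differential_practice_detected(self, small_trials):
        """Speeding up only the second-half match trials grows the match
        effect and the Half x Match interaction becomes significant."""
        trials = small_trials.copy()
        boost = (trials["half"] == "second") & (trials["match"] == "match")
        trials.loc[boost, "rt_ms"] -= 120.0
        rep = half_split(trials, n_permutations=999, seed=3)
        assert rep.rt_effect["second"] > rep.rt_effect["first"]
        assert rep.rt_interaction_p < 0.05

    def test_pc_effect_sign_convention(self, small_trials):
        """Generator plants more errors in mismatch, so mismatch - match PC
        is negative, matching the published sign convention."""
        rep = half_split(small_trials, n_permutations=99, seed=4)
        assert rep.pc_effect["first"] < 0 or rep.pc_effect["second"] < 0

    def test_missing_half_rejected(self, small_trials):
        first_only = small_trials[small_trials["half"] == "first"]
        with pytest.raises(AnalysisError):
            half_split(first_only, n_permutations=99, seed=1)


class TestSpeedAccuracy:
    def test_faster_and_more_accurate_is_clean(self):
        rows = []
        for match, rt, correct_pattern in (
            ("match", 600.0, [True, True, True]),
            ("mismatch", 800.0, [True, False, False]),
        ):
            for k, c in enumerate(correct_pattern):
                rows.append({"match": match, "rt_ms": rt, "correct": c, "item_id": f"I{k}"})
        ok, report = speed_accuracy_check(_trials(rows))
        assert ok
        assert report.iloc[0]["faster_level"] == "match"

    def test_tradeoff_is_flagged(self):
        rows = []
        for match, rt, correct_pattern in (
            ("match", 600.0, [True, False, False]),
            ("mismatch", 800.0, [True, True, True]),
        ):
            for k, c in enumerate(correct_pattern):
                rows.append({"match": match, "rt_ms": rt, "correct": c, "item_id": f"I{k}"})
        ok, _ = speed_accuracy_check(_trials(rows))
        assert not ok

    def test_equal_accuracy_passes_weak_inequality(self):
        rows = [
            {"match": "match", "rt_ms": 600.0, "correct": True},
            {"match": "mismatch", "rt_ms": 800.0, "correct": True},
        ]
        ok, _ = speed_accuracy_check(_trials(rows))
        assert ok
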