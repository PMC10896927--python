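"""Generator contracts: determinism, degenerate limits, design structure,
and Monte-Carlo calibration of the planted effects."""

import numpy as np
import pandas as pd
import pytest

from chronoval.errors import ConfigurationError
from chronoval.synthetic import (
    BlockSpec,
    CorpusSpec,
    DesignSpec,
    RatingGenParams,
    RTGenParams,
    category_pair_counts,
    corpus_to_lines,
    default_vocabulary,
    generate_corpus,
    generate_ratings,
    generate_rt_experiment,
)


class TestRTGenerator:
    def test_degenerate_generator_yields_constant_base_rt(self):
        design = DesignSpec.experiment2(n_subjects=4, items_per_category=2)
        params = RTGenParams(
            match_effect=0.0,
            congruency_effect=0.0,
            domain_effect=0.0,
            practice_slope=0.0,
            subject_sd=0.0,
            item_sd=0.0,
            residual_sigma=0.0,
            seed=1,
        )
        trials = generate_rt_experiment(design, params)
        assert np.allclose(trials["rt_ms"], params.base_rt)

    def test_noiseless_cell_means_add_up(self, noiseless_params):
        design = DesignSpec.experiment2(n_subjects=4, items_per_category=2)
        trials = generate_rt_experiment(design, noiseless_params)
        means = trials.groupby("match")["rt_ms"].mean()
        assert means["mismatch"] - means["match"] == pytest.approx(170.0)

    def test_same_seed_is_bit_identical(self, small_design):
        params = RTGenParams(seed=99)
        a = generate_rt_experiment(small_design, params)
        b = generate_rt_experiment(small_design, params)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_every_subject_contributes_every_block_within(self, small_trials, small_design):
        per_subject = small_trials.groupby("subject_id")["block_index"].nunique()
        assert (per_subject == len(small_design.blocks)).all()

    def test_between_design_splits_subjects_into_groups(self):
        design = DesignSpec.experiment1(n_subjects=8, items_per_category=2)
        trials = generate_rt_experiment(design, RTGenParams(seed=5))
        per_subject = trials.groupby("subject_id")["match"].nunique()
        assert (per_subject == 1).all()
        group_sizes = trials.drop_duplicates("subject_id")["match"].value_counts()
        assert group_sizes["match"] == 4 and group_sizes["mismatch"] == 4

    def test_category_domain_consistency_and_half_labels(self, small_trials):
        time_rows = small_trials["category"].isin(["past", "future"])
        assert (small_trials.loc[time_rows, "domain"] == "time").all()
        assert (small_trials.loc[~time_rows, "domain"] == "valence").all()
        n_blocks = small_trials["block_index"].max() + 1
        derived = np.where(small_trials["block_index"] < n_blocks / 2, "first", "second")
        assert (small_trials["half"] == derived).all()
        assert (small_trials["rt_ms"] > 0).all()

    def test_match_effect_calibration_monte_carlo(self):
        """The planted 170 ms match effect is recovered within 3 SEM over
        replicate generations."""
        design = DesignSpec.experiment2(n_subjects=12, items_per_category=3)
        diffs = []
        for rep in range(40):
            params = RTGenParams(
                congruency_effect=0.0,
                domain_effect=0.0,
                practice_slope=0.0,
                seed=1000 + rep,
            )
            trials = generate_rt_experiment(design, params)
            m = trials.groupby("match")["rt_ms"].mean()
            diffs.append(m["mismatch"] - m["match"])
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 170.0) < 3 * sem + 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 1},
            {"items_per_category": 0},
            {"match_factor": "weird"},
            {"blocks": ()},
            {"trials_per_block": 0},
        ],
    )
    def test_invalid_design_rejected(self, kwargs):
        base = dict(
            n_subjects=4,
            items_per_category=2,
            match_factor="within",
            blocks=(BlockSpec("match"), BlockSpec("mismatch")),
            trials_per_block=8,
        )
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            DesignSpec(**base)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            RTGenParams(base_rt=-5.0)
        with pytest.raises(ConfigurationError):
            RTGenParams(error_base=1.2)
        with pytest.raises(ConfigurationError):
            RTGenParams(subject_sd=-1.0)


class TestRatingGenerator:
    def test_equal_means_zero_noise_gives_zero_differences(self):
        params = RatingGenParams(
            n_young=5,
            n_old=3,
            past_mean=4.0,
            future_mean=4.0,
            between_subject_sd=0.0,
            within_noise_sd=0.0,
            seed=2,
        )
        ratings = generate_ratings(params)
        per = ratings.groupby(["participant_id", "time_category"])["rating"].mean().unstack()
        assert (per["future"] - per["past"] == 0).all()

    def test_ratings_are_integers_on_the_scale(self, tiny_ratings):
        assert tiny_ratings["rating"].between(1, 7).all()
        assert (tiny_ratings["rating"] == tiny_ratings["rating"].astype(int)).all()

    def test_each_participant_rates_all_words(self, tiny_ratings):
        counts = tiny_ratings.groupby(["participant_id", "time_category"]).size()
        assert (counts == 4).all()

    def test_age_interaction_shifts_old_group_future_mean(self):
        params = RatingGenParams(
            n_young=50,
            n_old=50,
            past_mean=4.0,
            future_mean=4.0,
            between_subject_sd=0.0,
            within_noise_sd=0.0,
            age_interaction=1.0,
            seed=3,
        )
        ratings = generate_ratings(params)
        per = ratings.groupby(["participant_id", "age_group", "time_category"])["rating"].mean().unstack()
        diff = (per["future"] - per["past"]).groupby(level="age_group").mean()
        assert diff["younger"] == pytest.approx(0.0)
        assert diff["older"] == pytest.approx(1.0)

    def test_standardized_effect_places_means_symmetrically(self):
        params = RatingGenParams.from_standardized_effect(0.5, center=4.0)
        assert params.past_mean + params.future_mean == pytest.approx(8.0)
        assert params.future_mean > params.past_mean

    def test_zero_group_rejected(self):
        with pytest.raises(ConfigurationError):
            RatingGenParams(n_young=0)

    def test_same_seed_identical(self):
        p = RatingGenParams(n_young=4, n_old=3, seed=5)
        assert generate_ratings(p).equals(generate_ratings(p))


class TestCorpusGenerator:
    def test_fixed_seed_identical_corpus(self, small_corpus_spec):
        a = corpus_to_lines(generate_corpus(small_corpus_spec))
        b = corpus_to_lines(generate_corpus(small_corpus_spec))
        assert a == b

    def test_full_strength_pairs_every_time_word(self):
        spec = CorpusSpec(
            n_documents=20,
            doc_length=30,
            vocabulary=default_vocabulary(words_per_category=3, n_fillers=6),
            association_strength=1.0,
            direction="both",
            seed=4,
        )
        vocab = spec.vocabulary
        partner_of = {w: "negative" for w in vocab["past"]}
        partner_of.update({w: "positive" for w in vocab["future"]})
        members = {cat: set(vocab[cat]) for cat in ("negative", "positive")}
        for doc in generate_corpus(spec):
            for i, tok in enumerate(doc):
                if tok in partner_of:
                    assert i + 1 < len(doc)
                    assert doc[i + 1] in members[partner_of[tok]]

    def test_overlapping_word_lists_rejected(self):
        vocab = default_vocabulary(words_per_category=2, n_fillers=4)
        vocab["future"] = vocab["past"]
        with pytest.raises(ConfigurationError):
            CorpusSpec(vocabulary=vocab)

    def test_association_strength_bounds(self):
        with pytest.raises(ConfigurationError):
            CorpusSpec(association_strength=1.5)
        with pytest.raises(ConfigurationError):
            CorpusSpec(direction="sideways")

    def test_pair_counts_hand_example(self):
        vocab = default_vocabulary(words_per_category=1, n_fillers=2)
        # PAST01 adjacent to NEGA01 twice, POSI01 once; FUTU01 next to POSI01 once
        corpus = [
            ["PAST01", "NEGA01", "PAST01", "FILL001"],
            ["NEGA01", "PAST01", "FILL002"],
            ["POSI01", "PAST01"],
            ["FUTU01", "POSI01"],
        ]
        counts = category_pair_counts(corpus, vocab, window=1)
        assert counts.loc["past", "negative"] == 3
        assert counts.loc["past", "positive"] == 1
        assert counts.loc["future", "positive"] == 1
        assert counts.loc["future", "negative"] == 0

    def test_direction_none_has_no_designed_adjacency_excess(self):
        spec = CorpusSpec(seed=6, association_strength=0.0, direction="none")
        counts = category_pair_counts(generate_corpus(spec), spec.vocabulary)
        total = counts.to_numpy().sum()
        designed = counts.loc["past", "negative"] + counts.loc["future", "positive"]
        # exchangeable null: designed share near 1/2
        assert abs(designed / total - 0.5) < 0.1
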