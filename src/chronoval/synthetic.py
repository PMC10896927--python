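"""Seeded generators for speeded-categorisation trials, valence ratings and corpora.

The generators emulate the three kinds of data the downstream analyses consume:

* factorial Match x Congruency x Domain reaction-time experiments in which
  participants categorise time words (past/future) and valence words
  (negative/positive), with a large RT advantage for blocks where past+negative
  share a response key with each other (the *match* condition);
* two-age-group 7-point valence ratings of past- and future-related words; and
* token corpora with a designed co-occurrence association between time-category
  words and valence-laden context words.

All generators are deterministic given their seed and return plain pandas
DataFrames (trials, ratings) or lists of token lists (corpora), so every
downstream stage is testable without external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "BlockSpec",
    "DesignSpec",
    "RTGenParams",
    "RatingGenParams",
    "CorpusSpec",
    "TRIAL_COLUMNS",
    "RATING_COLUMNS",
    "generate_rt_experiment",
    "generate_ratings",
    "generate_corpus",
    "category_pair_counts",
    "corpus_to_lines",
    "corpus_from_lines",
    "default_vocabulary",
]

# Shifted-lognormal residual: RTs are generated as ``shift + LogNormal`` with the
# lognormal mean pinned to the condition mean minus the shift, so condition
# effects stay additive on the millisecond scale.
RT_SHIFT_MS = 200.0

TRIAL_COLUMNS = [
    "subject_id",
    "item_id",
    "domain",
    "category",
    "match",
    "congruency",
    "block_index",
    "half",
    "rt_ms",
    "correct",
]

RATING_COLUMNS = ["participant_id", "age_group", "word", "time_category", "rating"]

CATEGORIES = ("past", "future", "negative", "positive")
CATEGORY_DOMAIN = {
    "past": "time",
    "future": "time",
    "negative": "valence",
    "positive": "valence",
}
MATCH_LEVELS = ("match", "mismatch")
CONGRUENCY_LEVELS = ("congruent", "incongruent", "not_applicable")


# ---------------------------------------------------------------------------
# Reaction-time experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One experimental block: its match condition and congruency label.

    For manual-response designs the congruency label records whether the
    spatial S-R mapping follows the mental time line / valence-space
    association; vocal designs carry ``not_applicable``.
    """

    match: str
    congruency: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.match not in MATCH_LEVELS:
            raise ConfigurationError(f"unknown match condition: {self.match!r}")
        if self.congruency not in CONGRUENCY_LEVELS:
            raise ConfigurationError(f"unknown congruency condition: {self.congruency!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Block design of one speeded-categorisation experiment.

    ``match_factor`` selects whether Match varies between subjects (each
    subject sees only the blocks of one match condition, groups alternating
    over the subject index) or within subjects (every subject runs all blocks,
    block order reversed for every other subject to counterbalance practice).
    """

    n_subjects: int
    items_per_category: int
    match_factor: str  # "between" | "within"
    blocks: tuple[BlockSpec, ...]
    trials_per_block: int
    response_modality: str = "manual"  # metadata only

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.items_per_category < 1:
            raise ConfigurationError("items_per_category must be at least 1")
        if self.match_factor not in ("between", "within"):
            raise ConfigurationError(f"unknown match_factor: {self.match_factor!r}")
        if not self.blocks:
            raise ConfigurationError("block list must be non-empty")
        if self.trials_per_block < 1:
            raise ConfigurationError("trials_per_block must be positive")
        if self.response_modality not in ("manual", "vocal"):
            raise ConfigurationError(f"unknown response_modality: {self.response_modality!r}")
        if self.match_factor == "between":
            present = {b.match for b in self.blocks}
            if present != set(MATCH_LEVELS):
                raise ConfigurationError(
                    "a between-subject design needs blocks for both match conditions"
                )

    @classmethod
    def experiment1(cls, n_subjects: int = 80, items_per_category: int = 15) -> "DesignSpec":
        """Manual keypress design: Match between subjects, one congruent and
        one incongruent block per subject, every word once per block."""
        return cls(
            n_subjects=n_subjects,
            items_per_category=items_per_category,
            match_factor="between",
            blocks=(
                BlockSpec("match", "congruent"),
                BlockSpec("match", "incongruent"),
                BlockSpec("mismatch", "congruent"),
                BlockSpec("mismatch", "incongruent"),
            ),
            trials_per_block=4 * items_per_category,
            response_modality="manual",
        )

    @classmethod
    def experiment2(cls, n_subjects: int = 40, items_per_category: int = 15) -> "DesignSpec":
        """Vocal-response design: Match within subjects, four blocks
        alternating match/mismatch."""
        return cls(
            n_subjects=n_subjects,
            items_per_category=items_per_category,
            match_factor="within",
            blocks=(
                BlockSpec("match"),
                BlockSpec("mismatch"),
                BlockSpec("match"),
                BlockSpec("mismatch"),
            ),
            trials_per_block=4 * items_per_category,
            response_modality="vocal",
        )

    # The left-hander replication shares the vocal design.
    experiment3 = experiment2


@dataclass(frozen=True)
class RTGenParams:
    """Effect sizes and noise levels of the trial generator, in milliseconds.

    Defaults are calibrated to the manual-keypress experiment's condition
    means: a ~170 ms match effect (785 vs 955 ms), a ~48 ms congruency effect
    (847 vs 895 ms) and a ~158 ms domain effect (valence words 792 ms vs time
    words 950 ms).  ``residual_sigma`` is the log-scale SD of the shifted
    lognormal trial residual (shift 200 ms); the lognormal mean is pinned to
    the condition mean so all effects stay additive in expectation.
    """

    base_rt: float = 680.0
    match_effect: float = 170.0
    congruency_effect: float = 48.0
    domain_effect: float = 158.0
    practice_slope: float = -10.0  # ms per block position
    subject_sd: float = 80.0
    item_sd: float = 25.0
    residual_sigma: float = 0.35
    error_base: float = 0.05
    error_mismatch_increment: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rt <= 0:
            raise ConfigurationError("base_rt must be positive")
        for name in ("subject_sd", "item_sd", "residual_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("error_base", "error_mismatch_increment"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be within [0, 1]")
        if self.error_base + self.error_mismatch_increment > 1.0:
            raise ConfigurationError("error probabilities may not exceed 1 in any condition")


def _item_table(items_per_category: int) -> pd.DataFrame:
    rows = []
    for cat in CATEGORIES:
        prefix = cat[:4].upper()
        for k in range(items_per_category):
            rows.append((f"{prefix}{k + 1:02d}", cat, CATEGORY_DOMAIN[cat]))
    return pd.DataFrame(rows, columns=["item_id", "category", "domain"])


def _subject_blocks(design: DesignSpec, subject_index: int) -> list[BlockSpec]:
    """Block sequence a given subject runs, counterbalanced over subject index."""
    if design.match_factor == "between":
        group = MATCH_LEVELS[subject_index % 2]
        blocks = [b for b in design.blocks if b.match == group]
        # alternate which block comes first within the group
        if (subject_index // 2) % 2 == 1:
            blocks = blocks[::-1]
        return blocks
    blocks = list(design.blocks)
    if subject_index % 2 == 1:
        blocks = blocks[::-1]
    return blocks


def generate_rt_experiment(design: DesignSpec, params: RTGenParams) -> pd.DataFrame:
    """Simulate one full experiment; returns a trial table (one row per trial).

    Expected cell mean RT is ``base_rt`` plus the sum of the applicable
    additive effects (mismatch, incongruent, time-domain, practice) plus the
    subject and item offsets; the trial residual is shifted-lognormal with its
    mean pinned to that cell mean.  Regenerating with the same seed is
    bit-identical.
    """
    rng = np.random.default_rng(params.seed)
    items = _item_table(design.items_per_category)
    n_items = len(items)
    item_offsets = rng.normal(0.0, params.item_sd, size=n_items) if params.item_sd > 0 else np.zeros(n_items)
    # centre item offsets within each category so a planted effect of zero is
    # a true null for between-item factors (domain) and not confounded by the
    # finite item sample
    for c in range(4):
        block = slice(c * design.items_per_category, (c + 1) * design.items_per_category)
        item_offsets[block] -= item_offsets[block].mean()
    subject_offsets = (
        rng.normal(0.0, params.subject_sd, size=design.n_subjects)
        if params.subject_sd > 0
        else np.zeros(design.n_subjects)
    )

    frames: list[pd.DataFrame] = []
    for s in range(design.n_subjects):
        blocks = _subject_blocks(design, s)
        n_blocks = len(blocks)
        for pos, block in enumerate(blocks):
            # each block presents the item list in fresh random order, cycling
            # if trials_per_block exceeds the number of items
            order = np.concatenate(
                [rng.permutation(n_items) for _ in range(math.ceil(design.trials_per_block / n_items))]
            )[: design.trials_per_block]
            block_items = items.iloc[order].reset_index(drop=True)
            is_mismatch = block.match == "mismatch"
            is_incongruent = block.congruency == "incongruent"
            is_time = (block_items["domain"] == "time").to_numpy()

            mean_rt = (
                params.base_rt
                + (params.match_effect if is_mismatch else 0.0)
                + (params.congruency_effect if is_incongruent else 0.0)
                + params.domain_effect * is_time
                + params.practice_slope * pos
                + subject_offsets[s]
                + item_offsets[order]
            )
            rt = _shifted_lognormal(rng, mean_rt, params.residual_sigma)

            p_err = params.error_base + (params.error_mismatch_increment if is_mismatch else 0.0)
            correct = rng.random(design.trials_per_block) >= p_err

            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": f"S{s + 1:03d}",
                        "item_id": block_items["item_id"],
                        "domain": block_items["domain"],
                        "category": block_items["category"],
                        "match": block.match,
                        "congruency": block.congruency,
                        "block_index": pos,
                        "half": "first" if pos < n_blocks / 2 else "second",
                        "rt_ms": rt,
                        "correct": correct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def _shifted_lognormal(rng: np.random.Generator, mean_rt: np.ndarray, sigma: float) -> np.ndarray:
    """Draw RTs with E[rt] = mean_rt from ``RT_SHIFT_MS + LogNormal``.

    The lognormal mean is ``mean_rt - shift`` (floored at 1 ms so extreme
    subject/item offsets cannot produce non-positive RTs); sigma = 0
    degenerates to the exact condition mean.
    """
    mu_lin = np.maximum(np.asarray(mean_rt, dtype=float) - RT_SHIFT_MS, 1.0)
    if sigma == 0.0:
        return RT_SHIFT_MS + mu_lin
    log_mu = np.log(mu_lin) - 0.5 * sigma**2
    return RT_SHIFT_MS + np.exp(rng.normal(log_mu, sigma))


# ---------------------------------------------------------------------------
# Valence ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingGenParams:
    """Generator for two-age-group 7-point valence ratings of time words.

    Each participant rates ``words_per_category`` past- and future-related
    words; the stored rating is the 1..7 integer nearest the latent value
    ``category mean + participant offset + word noise`` (clamped to the scale,
    1 = terrible, 7 = excellent).  ``age_interaction`` shifts the older
    group's future-word mean.
    """

    n_young: int = 826
    n_old: int = 221
    past_mean: float = 4.0
    future_mean: float = 4.2
    between_subject_sd: float = 0.8
    within_noise_sd: float = 1.0
    age_interaction: float = 0.0
    words_per_category: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ConfigurationError("both age groups need at least one participant")
        for name in ("between_subject_sd", "within_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("past_mean", "future_mean"):
            if not 1.0 <= getattr(self, name) <= 7.0:
                raise ConfigurationError(f"{name} must lie on the 1..7 scale")
        if self.words_per_category < 1:
            raise ConfigurationError("words_per_category must be positive")

    @classmethod
    def from_standardized_effect(
        cls,
        d: float,
        center: float = 4.0,
        between_subject_sd: float = 0.8,
        within_noise_sd: float = 1.0,
        words_per_category: int = 15,
        **kwargs,
    ) -> "RatingGenParams":
        """Parameterise the generator so the true within-subject standardized
        past-future difference equals ``d``.

        The participant-level difference score averages ``words_per_category``
        ratings per category; its SD is ``sqrt(2 * (sigma_w^2 + 1/12) / k)``,
        where the 1/12 term is the variance added by rounding latent values to
        the integer scale.  The past/future means are placed symmetrically
        around ``center`` so scale clamping stays symmetric.
        """
        diff_sd = math.sqrt(2.0 * (within_noise_sd**2 + 1.0 / 12.0) / words_per_category)
        delta = d * diff_sd
        return cls(
            past_mean=center - delta / 2.0,
            future_mean=center + delta / 2.0,
            between_subject_sd=between_subject_sd,
            within_noise_sd=within_noise_sd,
            words_per_category=words_per_category,
            **kwargs,
        )


def generate_ratings(params: RatingGenParams) -> pd.DataFrame:
    """Simulate the rating survey; one row per (participant, word) rating."""
    rng = np.random.default_rng(params.seed)
    n = params.n_young + params.n_old
    k = params.words_per_category
    age_group = np.repeat(["younger", "older"], [params.n_young, params.n_old])
    offsets = rng.normal(0.0, params.between_subject_sd, size=n)

    words = [f"PAST{i + 1:02d}" for i in range(k)] + [f"FUTU{i + 1:02d}" for i in range(k)]
    time_category = np.array(["past"] * k + ["future"] * k)

    means = np.where(time_category == "past", params.past_mean, params.future_mean)
    means = np.tile(means, (n, 1))
    means[params.n_young :, time_category == "future"] += params.age_interaction

    latent = means + offsets[:, None] + rng.normal(0.0, params.within_noise_sd, size=(n, 2 * k))
    rating = np.clip(np.rint(latent), 1, 7).astype(int)

    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i + 1:04d}" for i in range(n)], 2 * k),
            "age_group": np.repeat(age_group, 2 * k),
            "word": np.tile(words, n),
            "time_category": np.tile(time_category, n),
            "rating": rating.ravel(),
        }
    )[RATING_COLUMNS]


# ---------------------------------------------------------------------------
# Corpora with designed time-valence co-occurrence structure
# ---------------------------------------------------------------------------

DIRECTIONS = ("past-with-negative", "future-with-positive", "both", "none")

_PARTNERS = {
    "past-with-negative": {"past": "negative"},
    "future-with-positive": {"future": "positive"},
    "both": {"past": "negative", "future": "positive"},
    "none": {},
}


def default_vocabulary(words_per_category: int = 5, n_fillers: int = 40) -> dict[str, list[str]]:
    """Abstract token lists for the four categories plus fillers."""
    vocab = {
        cat: [f"{cat[:4].upper()}{i + 1:02d}" for i in range(words_per_category)]
        for cat in CATEGORIES
    }
    vocab["filler"] = [f"FILL{i + 1:03d}" for i in range(n_fillers)]
    return vocab


@dataclass(frozen=True)
class CorpusSpec:
    """Corpus generator with a tunable time-word/valence-word association.

    Every document carries a latent valence theme (negative or positive):
    theme-specific filler contexts and theme-category valence words dominate
    it.  Whenever ``direction`` pairs a time category with a valence category,
    that time category is drawn into the partner theme's documents -- and
    hence into the partner's characteristic contexts -- at a rate rising with
    ``association_strength`` (probability ``(1+s)/2`` vs ``(1-s)/2``), and a
    partner-category word additionally follows each such time word with
    probability ``s``, so at ``s = 1`` every time-word occurrence is
    immediately accompanied by its designed valence partner.  With
    ``direction='none'`` (or ``s = 0``) the past/future categories are
    exchangeable and all four cross-domain co-occurrence rates share one
    expectation.
    """

    n_documents: int = 200
    doc_length: int = 60
    vocabulary: dict[str, list[str]] = field(default_factory=default_vocabulary)
    association_strength: float = 0.5
    direction: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 1 or self.doc_length < 1:
            raise ConfigurationError("n_documents and doc_length must be positive")
        if not 0.0 <= self.association_strength <= 1.0:
            raise ConfigurationError("association_strength must lie in [0, 1]")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction: {self.direction!r}")
        required = set(CATEGORIES) | {"filler"}
        if set(self.vocabulary) != required:
            raise ConfigurationError(f"vocabulary must define exactly {sorted(required)}")
        seen: set[str] = set()
        for cat, words in self.vocabulary.items():
            if not words:
                raise ConfigurationError(f"empty word list for {cat!r}")
            overlap = seen & set(words)
            if overlap:
                raise ConfigurationError(f"word lists overlap: {sorted(overlap)}")
            seen |= set(words)
        if len(self.vocabulary["filler"]) < 2:
            raise ConfigurationError("need at least two filler tokens (one per theme context)")


# base emission mix within a document: theme fillers / valence words / time words
_P_FILLER = 0.5
_P_VALENCE = 0.25
# how strongly fillers and valence words stick to their document's theme
_THEME_FIDELITY = 0.8


def generate_corpus(spec: CorpusSpec) -> list[list[str]]:
    """Generate ``n_documents`` token-sequence documents.

    Each document contains ``doc_length`` base draws (fillers from the
    document theme's context set, valence words mostly of the theme category,
    time words biased toward the theme by ``association_strength`` under the
    designed ``direction``); inserted partner words extend the document, so
    with ``association_strength=1`` every time-word occurrence is followed by
    a partner-category valence word.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.association_strength
    partners = _PARTNERS[spec.direction]  # time category -> valence category
    paired_time = {v: t for t, v in partners.items()}  # valence theme -> time category
    fillers = spec.vocabulary["filler"]
    half = len(fillers) // 2
    context = {"negative": fillers[:half] or fillers, "positive": fillers[half:] or fillers}
    other_theme = {"negative": "positive", "positive": "negative"}
    other_time = {"past": "future", "future": "past"}

    def pick(words: list[str]) -> str:
        return words[rng.integers(0, len(words))]

    if spec.direction == "none":
        # fully exchangeable null: uniform iid tokens, no theme structure
        pool = [w for words in spec.vocabulary.values() for w in words]
        return [
            [pick(pool) for _ in range(spec.doc_length)] for _ in range(spec.n_documents)
        ]

    docs: list[list[str]] = []
    for doc_index in range(spec.n_documents):
        # alternate themes so the two context sets are exactly balanced
        theme = "negative" if doc_index % 2 == 0 else "positive"
        doc: list[str] = []
        for _ in range(spec.doc_length):
            u = rng.random()
            if u < _P_FILLER:
                pool = context[theme] if rng.random() < _THEME_FIDELITY else context[other_theme[theme]]
                doc.append(pick(pool))
            elif u < _P_FILLER + _P_VALENCE:
                vcat = theme if rng.random() < _THEME_FIDELITY else other_theme[theme]
                doc.append(pick(spec.vocabulary[vcat]))
            else:
                boosted = paired_time.get(theme)
                if boosted is None:
                    tcat = "past" if rng.random() < 0.5 else "future"
                else:
                    tcat = boosted if rng.random() < (1.0 + s) / 2.0 else other_time[boosted]
                doc.append(pick(spec.vocabulary[tcat]))
                partner = partners.get(tcat)
                # random() < 1.0 always holds, so strength 1 pairs every occurrence
                if partner is not None and rng.random() < s:
                    doc.append(pick(spec.vocabulary[partner]))
        docs.append(doc)
    return docs


def category_pair_counts(
    corpus: list[list[str]], vocabulary: dict[str, list[str]], window: int = 1
) -> pd.DataFrame:
    """2x2 co-occurrence pair counts: time category x valence category.

    Counts (time word, valence word) token pairs within ``window`` positions
    of each other inside a document.  The narrow default keeps each time-word
    token's contribution small, so under an exchangeable null the table is a
    valid substrate for a chi-square independence test.
    """
    cat_of = {}
    for cat in CATEGORIES:
        for w in vocabulary[cat]:
            cat_of[w.casefold()] = cat
    table = pd.DataFrame(
        0,
        index=pd.Index(["past", "future"], name="time_category"),
        columns=pd.Index(["negative", "positive"], name="valence_category"),
    )
    for doc in corpus:
        cats = [cat_of.get(tok.casefold()) for tok in doc]
        for i, tcat in enumerate(cats):
            if tcat not in ("past", "future"):
                continue
            for j in range(max(0, i - window), min(len(cats), i + window + 1)):
                vcat = cats[j]
                if j != i and vcat in ("negative", "positive"):
                    table.loc[tcat, vcat] += 1
    return table


def corpus_to_lines(corpus: list[list[str]]) -> str:
    """Serialise a corpus as UTF-8 text, one space-separated document per line."""
    return "\n".join(" ".join(doc) for doc in corpus) + "\n"


def corpus_from_lines(text: str) -> list[list[str]]:
    """Parse the one-document-per-line corpus format (case-folded)."""
    return [line.split() for line in text.casefold().splitlines() if line.strip()]
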