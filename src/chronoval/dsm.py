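"""Toy distributional-semantics stage: LSA and HAL spaces from a corpus,
time-word x valence-word cosine similarities, and the 2x2 category ANOVA.

LSA builds a word-by-document count matrix (optionally log-entropy weighted)
and reduces it by truncated SVD; word vectors are the left singular vectors
scaled by the singular values, so at full rank all pairwise cosines equal
those of the raw count rows.  HAL counts, for each target word, the context
words within a sliding window, summed over left and right contexts and
unweighted by distance (distance weighting is exposed as an option, off by
default).  Tokens are case-folded; no stemming.

A third recipe slot for a predict-style (cbow/word2vec) space is deliberately
left empty: neural training is out of scope for this toy stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import AnalysisError, ConfigurationError, DataError

__all__ = [
    "DSMSpace",
    "build_lsa",
    "build_hal",
    "cosine",
    "pair_cosines",
    "category_anova",
]

Corpus = list[list[str]]


@dataclass
class DSMSpace:
    """A word-vector space: one row of ``vectors`` per vocabulary word."""

    vocabulary: list[str]
    vectors: np.ndarray  # (n_words, n_dims)
    recipe: str  # "lsa" | "hal"
    params: dict

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ConfigurationError("one vector per vocabulary word required")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word.casefold() in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word.casefold()]]
        except KeyError:
            raise DataError(f"word not in vocabulary: {word!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim_{k + 1}": self.vectors[:, k] for k in range(self.vectors.shape[1])}
        return pd.DataFrame({"word": self.vocabulary, **cols})


def _normalise_corpus(corpus: Corpus) -> Corpus:
    docs = [[tok.casefold() for tok in doc] for doc in corpus]
    docs = [doc for doc in docs if doc]
    if not docs:
        raise DataError("empty corpus")
    return docs


def _vocabulary(docs: Corpus) -> list[str]:
    seen: dict[str, None] = {}
    for doc in docs:
        for tok in doc:
            seen.setdefault(tok, None)
    return sorted(seen)


# ---------------------------------------------------------------------------
# LSA: word-by-document counts + truncated SVD
# ---------------------------------------------------------------------------

def build_lsa(corpus: Corpus, n_dimensions: int, weighting: bool = False) -> DSMSpace:
    """Latent-semantic-analysis space from word-by-document counts.

    ``weighting`` applies the classical log-entropy transform
    ``log(1 + count) * (1 - H_w / log n_docs)`` before the SVD.  Retained word
    vectors are ``U_k * s_k``; ``n_dimensions`` may not exceed
    ``min(vocabulary size, document count)``.
    """
    docs = _normalise_corpus(corpus)
    vocab = _vocabulary(docs)
    counts = np.zeros((len(vocab), len(docs)))
    index = {w: i for i, w in enumerate(vocab)}
    for j, doc in enumerate(docs):
        for tok in doc:
            counts[index[tok], j] += 1.0

    max_dims = min(counts.shape)
    if n_dimensions < 1 or n_dimensions > max_dims:
        raise ConfigurationError(
            f"n_dimensions must lie in [1, {max_dims}] for this corpus, got {n_dimensions}"
        )

    x = counts
    if weighting:
        p = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy = -plogp.sum(axis=1)
        global_weight = 1.0 - entropy / np.log(max(len(docs), 2))
        x = np.log1p(counts) * global_weight[:, None]

    u, s, _ = scipy.linalg.svd(x, full_matrices=False)
    vectors = u[:, :n_dimensions] * s[:n_dimensions]
    return DSMSpace(
        vocabulary=vocab,
        vectors=vectors,
        recipe="lsa",
        params={"n_dimensions": n_dimensions, "weighting": weighting},
    )


# ---------------------------------------------------------------------------
# HAL: word-by-word window counts
# ---------------------------------------------------------------------------

def build_hal(corpus: Corpus, window: int = 5, distance_weighting: bool = False) -> DSMSpace:
    """Hyperspace-analogue-to-language space from word-by-word window counts.

    For each target occurrence, every context word within ``window`` positions
    (left and right, not crossing document boundaries) increments the target's
    count for that context word.  With ``distance_weighting`` a context at
    distance d contributes ``window - d + 1`` instead of 1.
    """
    if window < 1:
        raise ConfigurationError("window must be at least 1")
    docs = _normalise_corpus(corpus)
    vocab = _vocabulary(docs)
    index = {w: i for i, w in enumerate(vocab)}
    counts = np.zeros((len(vocab), len(vocab)))
    for doc in docs:
        ids = [index[t] for t in doc]
        n = len(ids)
        for i, target in enumerate(ids):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                w = (window - abs(j - i) + 1) if distance_weighting else 1.0
                counts[target, ids[j]] += w
    return DSMSpace(
        vocabulary=vocab,
        vectors=counts,
        recipe="hal",
        params={"window": window, "distance_weighting": distance_weighting},
    )


# ---------------------------------------------------------------------------
# Cosine similarity
# ---------------------------------------------------------------------------

def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity: dot product over the product of Euclidean norms.

    Identical usage distributions give 1, disjoint contexts give 0 (for
    non-negative count vectors).  A zero vector has no direction, so the
    similarity is undefined and raises rather than silently returning 0.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ConfigurationError("vectors must share dimensionality")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise AnalysisError("cosine similarity is undefined for a zero vector")
    return float(np.dot(v1, v2) / (n1 * n2))


def pair_cosines(space: DSMSpace, word_lists: dict[str, list[str]]) -> pd.DataFrame:
    """Cosines for every cross-domain (time word, valence word) pair.

    ``word_lists`` maps the categories past/future/negative/positive to word
    lists; rows cover the full product of time words x valence words that are
    present in the space's vocabulary.
    """
    required = {"past", "future", "negative", "positive"}
    if set(word_lists) != required:
        raise ConfigurationError(f"word_lists must define exactly {sorted(required)}")
    rows = []
    for tcat in ("past", "future"):
        for vcat in ("negative", "positive"):
            for tw in word_lists[tcat]:
                if tw not in space:
                    continue
                for vw in word_lists[vcat]:
                    if vw not in space:
                        continue
                    rows.append(
                        {
                            "time_word": tw.casefold(),
                            "valence_word": vw.casefold(),
                            "time_category": tcat,
                            "valence_category": vcat,
                            "cosine": cosine(space.vector(tw), space.vector(vw)),
                        }
                    )
    if not rows:
        raise AnalysisError("no cross-domain word pair is covered by the space")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Category ANOVA on the cosine table
# ---------------------------------------------------------------------------

def _two_way_f(table: pd.DataFrame) -> dict[str, tuple[float, int, int, float]]:
    """Classical two-way (Type II) F tests on pair-level cosines."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("cosine ~ C(time_category) * C(valence_category)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(time_category)": "time",
        "C(valence_category)": "valence",
        "C(time_category):C(valence_category)": "time_x_valence",
    }
    df_den = int(anova.loc["Residual", "df"])
    out = {}
    for src, name in rename.items():
        out[name] = (
            float(anova.loc[src, "F"]),
            int(anova.loc[src, "df"]),
            df_den,
            float(anova.loc[src, "PR(>F)"]),
        )
    return out


def _balanced_f_stats(matrix: np.ndarray, t_is_past: np.ndarray, v_is_neg: np.ndarray) -> np.ndarray:
    """F statistics (time, valence, interaction) for a fully crossed cosine
    matrix under balanced 2x2 category labellings; vectorised for permutation."""
    n = matrix.size
    grand = matrix.mean()
    cells = np.empty((2, 2))
    counts = np.empty((2, 2))
    for a, tmask in enumerate((t_is_past, ~t_is_past)):
        for b, vmask in enumerate((v_is_neg, ~v_is_neg)):
            block = matrix[np.ix_(tmask, vmask)]
            cells[a, b] = block.mean()
            counts[a, b] = block.size
    row = (cells * counts).sum(axis=1) / counts.sum(axis=1)
    col = (cells * counts).sum(axis=0) / counts.sum(axis=0)
    ss_t = float((counts.sum(axis=1) * (row - grand) ** 2).sum())
    ss_v = float((counts.sum(axis=0) * (col - grand) ** 2).sum())
    inter = cells - row[:, None] - col[None, :] + grand
    ss_i = float((counts * inter**2).sum())
    resid = matrix.copy().astype(float)
    for a, tmask in enumerate((t_is_past, ~t_is_past)):
        for b, vmask in enumerate((v_is_neg, ~v_is_neg)):
            resid[np.ix_(tmask, vmask)] -= cells[a, b]
    ss_e = float((resid**2).sum())
    df_e = n - 4
    if ss_e <= 0.0:
        return np.array([0.0, 0.0, 0.0])
    ms_e = ss_e / df_e
    return np.array([ss_t / ms_e, ss_v / ms_e, ss_i / ms_e])


def _permutation_p(
    table: pd.DataFrame, n_permutations: int, seed: int
) -> dict[str, float] | None:
    """Word-label permutation p values for the three effects.

    Category labels are permuted over the time words and over the valence
    words (preserving group sizes), which respects the word-level dependence
    of pair cosines; exact under exchangeable words.  Requires a fully
    crossed, balanced word grid; returns None otherwise.
    """
    pivot = table.pivot(index="time_word", columns="valence_word", values="cosine")
    if pivot.isna().any().any():
        return None
    tcat = table.drop_duplicates("time_word").set_index("time_word")["time_category"]
    vcat = table.drop_duplicates("valence_word").set_index("valence_word")["valence_category"]
    t_is_past = (tcat.loc[pivot.index] == "past").to_numpy()
    v_is_neg = (vcat.loc[pivot.columns] == "negative").to_numpy()
    if not (0 < t_is_past.sum() < len(t_is_past)) or not (0 < v_is_neg.sum() < len(v_is_neg)):
        return None
    if t_is_past.sum() * 2 != len(t_is_past) or v_is_neg.sum() * 2 != len(v_is_neg):
        return None  # permutation route assumes equal-sized word groups

    matrix = pivot.to_numpy()
    obs = _balanced_f_stats(matrix, t_is_past, v_is_neg)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    for _ in range(n_permutations):
        # each effect permutes only its own margin: time labels for the time
        # and interaction tests, valence labels for the valence test
        tp = rng.permutation(t_is_past)
        vp = rng.permutation(v_is_neg)
        f_t = _balanced_f_stats(matrix, tp, v_is_neg)
        f_v = _balanced_f_stats(matrix, t_is_past, vp)
        exceed[0] += f_t[0] >= obs[0] - 1e-12
        exceed[1] += f_v[1] >= obs[1] - 1e-12
        exceed[2] += f_t[2] >= obs[2] - 1e-12
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return dict(zip(("time", "valence", "time_x_valence"), p))


def category_anova(
    table: pd.DataFrame, n_permutations: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Two-way ANOVA (time category x valence category) on pair-level cosines.

    Returns one row per effect with the classical F, dfs, p, and the direction
    of each main effect (which level has the higher mean cosine).  Pair
    cosines sharing a word are correlated, which inflates the classical
    main-effect F tests; with ``n_permutations > 0`` a word-label permutation
    p value (``p_perm``) is added per effect, exact under exchangeable words,
    and is the inference the pipeline's null-control guarantees refer to.
    All four category combinations must be populated.
    """
    cells = table.groupby(["time_category", "valence_category"], observed=True)["cosine"].agg(
        ["mean", "size"]
    )
    if len(cells) < 4:
        raise AnalysisError("all four time x valence cells must be populated")

    if table["cosine"].nunique() == 1:
        # all-equal cosines: no variance to partition
        out = pd.DataFrame(
            [
                {"effect": e, "F": 0.0, "df_num": 1, "df_den": len(table) - 4, "p": 1.0}
                for e in ("time", "valence", "time_x_valence")
            ]
        )
        if n_permutations > 0:
            out["p_perm"] = 1.0
    else:
        stats = _two_way_f(table)
        out = pd.DataFrame(
            [
                {"effect": name, "F": f, "df_num": d1, "df_den": d2, "p": p}
                for name, (f, d1, d2, p) in stats.items()
            ]
        )
        if n_permutations > 0:
            perm = _permutation_p(table, n_permutations, seed)
            if perm is None:
                raise AnalysisError(
                    "word-label permutation needs a fully crossed grid with "
                    "equal-sized word groups"
                )
            out["p_perm"] = out["effect"].map(perm)

    tmeans = table.groupby("time_category", observed=True)["cosine"].mean()
    vmeans = table.groupby("valence_category", observed=True)["cosine"].mean()
    direction = {
        "time": f"{tmeans.idxmax()} > {tmeans.idxmin()}",
        "valence": f"{vmeans.idxmax()} > {vmeans.idxmin()}",
        "time_x_valence": "",
    }
    out["direction"] = out["effect"].map(direction)
    return out
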