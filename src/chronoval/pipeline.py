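"""Orchestration: seeded end-to-end runs (generate -> analyse -> report) for
each study component, plus deterministic fixture generation for tests.

A run is described by a :class:`RunConfig` (loadable from YAML), executes one
component's generate+analyse chain into an output directory, and returns a
:class:`RunManifest` echoing the config with per-file SHA-256 checksums, so
any run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dsm, ia, ratings, rt, synthetic
from .errors import ConfigurationError

__all__ = ["RunConfig", "RunManifest", "run", "make_fixtures"]

COMPONENTS = ("exp_rt", "exp_rating", "exp_dsm", "ia_predictions")
FIXTURE_KINDS = ("tiny_trials", "tiny_ratings", "tiny_corpus", "table2_cells")

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: which component, its parameters, where, which seed."""

    component: str
    output_dir: str
    seed: int
    generator: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ConfigurationError(f"unknown component: {self.component!r}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed is mandatory and must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("run config must be a mapping")
        if "seed" not in raw:
            raise ConfigurationError("run config must state a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config: dict
    package_version: str
    files: dict  # relative path -> sha256
    wall_clock_s: float
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> RunManifest:
    """Execute one component's generate+analyse chain.

    All intermediate tables are written as headered CSV into the output
    directory together with a ``manifest.json``; the manifest records the
    failed stage if any stage raises.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = time.perf_counter()
    stage = "setup"
    try:
        if config.component == "exp_rt":
            stage = "generate"
            design_kw = dict(config.generator.get("design", {}))
            template = design_kw.pop("template", "experiment1")
            if template not in ("experiment1", "experiment2", "experiment3"):
                raise ConfigurationError(f"unknown design template: {template!r}")
            design = getattr(synthetic.DesignSpec, template)(**design_kw)
            params = synthetic.RTGenParams(
                seed=config.seed, **config.generator.get("rt_params", {})
            )
            trials = synthetic.generate_rt_experiment(design, params)
            _write_csv(trials, out / "trials.csv")

            stage = "filter"
            report = rt.filter_outliers(trials)
            filtered = report.retained

            stage = "summaries"
            factors = [
                f
                for f in ("match", "congruency", "domain")
                if filtered[f].nunique() > 1
            ]
            _write_csv(rt.condition_summary(filtered, factors), out / "condition_summary.csv")

            stage = "effects"
            n_perm = int(config.analysis.get("n_permutations", rt.DEFAULT_N_PERMUTATIONS))
            effect_rows = []
            for name in ("match", "congruency", "domain"):
                col = rt._EFFECTS[name][0]
                if filtered[col].nunique() < 2:
                    continue
                rep = rt.estimate_effect(filtered, name, n_perm, seed=config.seed + 1)
                effect_rows.append(
                    {
                        "effect": rep.effect_name,
                        "estimate_ms": rep.estimate,
                        "p": rep.permutation_p,
                        "design": rep.design,
                        "n_subjects": rep.n_subjects,
                        "n_permutations": rep.n_permutations,
                    }
                )
            _write_csv(pd.DataFrame(effect_rows), out / "effects.csv")

            stage = "half_split"
            hs = rt.half_split(filtered, n_perm, seed=config.seed + 2)
            _write_csv(hs.cells, out / "half_split_cells.csv")
            (out / "half_split.json").write_text(
                json.dumps(
                    {
                        "rt_effect": hs.rt_effect,
                        "pc_effect": hs.pc_effect,
                        "rt_interaction_p": hs.rt_interaction_p,
                        "pc_interaction_p": hs.pc_interaction_p,
                    },
                    indent=2,
                )
            )

            stage = "run_log"
            (out / "run_log.json").write_text(
                json.dumps(
                    {
                        "seed": config.seed,
                        "filter": {
                            "low_ms": report.low_ms,
                            "high_ms": report.high_ms,
                            "fraction_below": report.fraction_below,
                            "fraction_above": report.fraction_above,
                        },
                        "n_trials": int(report.n_retained),
                    },
                    indent=2,
                )
            )

        elif config.component == "exp_rating":
            stage = "generate"
            params = synthetic.RatingGenParams(
                seed=config.seed, **config.generator.get("rating_params", {})
            )
            table = synthetic.generate_ratings(params)
            _write_csv(table, out / "ratings.csv")
            stage = "analyse"
            means = ratings.participant_means(table)
            _write_csv(means, out / "participant_means.csv")
            report = ratings.mixed_anova(means)
            (out / "anova.txt").write_text(report.to_text() + "\n")

        elif config.component == "exp_dsm":
            stage = "generate"
            corpus_kw = dict(config.generator.get("corpus", {}))
            spec = synthetic.CorpusSpec(seed=config.seed, **corpus_kw)
            corpus = synthetic.generate_corpus(spec)
            (out / "corpus.txt").write_text(synthetic.corpus_to_lines(corpus))
            word_lists = {k: spec.vocabulary[k] for k in ("past", "future", "negative", "positive")}
            stage = "analyse"
            frames = []
            n_dims = int(config.analysis.get("lsa_dimensions", 50))
            window = int(config.analysis.get("hal_window", 5))
            vocab_in_corpus = len({tok.casefold() for doc in corpus for tok in doc})
            k = min(n_dims, vocab_in_corpus, len(corpus))
            for recipe, space in (
                ("lsa", dsm.build_lsa(corpus, n_dimensions=k)),
                ("hal", dsm.build_hal(corpus, window=window)),
            ):
                table = dsm.pair_cosines(space, word_lists)
                _write_csv(table, out / f"cosines_{recipe}.csv")
                anova = dsm.category_anova(
                    table,
                    n_permutations=int(config.analysis.get("n_permutations", 300)),
                    seed=config.seed + 1,
                )
                anova.insert(0, "recipe", recipe)
                frames.append(anova)
            _write_csv(pd.concat(frames, ignore_index=True), out / "category_anova.csv")

        elif config.component == "ia_predictions":
            stage = "simulate"
            overrides = dict(config.generator.get("ia_overrides", {}))
            summaries = []
            for variant in ("model1", "model2"):
                cfg = ia.build_network(variant, **overrides)
                for condition in ("match", "mismatch"):
                    for stim in ia.NODES:
                        trace = ia.accumulate_response(ia.simulate(cfg, stim), condition)
                        _write_csv(
                            trace.to_frame(), out / f"trace_{variant}_{stim}_{condition}.csv"
                        )
                pred = ia.predict_match_effects(cfg)
                for cat, eff in pred.match_effects.items():
                    summaries.append(
                        {
                            "variant": variant,
                            "category": cat,
                            "match_crossing_time": pred.crossing_times[(cat, "match")],
                            "mismatch_crossing_time": pred.crossing_times[(cat, "mismatch")],
                            "match_effect_time_units": eff,
                            "match_effect_display_ms": None
                            if eff is None
                            else ia.time_to_milliseconds(eff, intercept_ms=0.0),
                        }
                    )
            _write_csv(pd.DataFrame(summaries), out / "match_predictions.csv")

        stage = "manifest"
        manifest = RunManifest(
            config=dataclasses.asdict(config),
            package_version=__version__,
            files={
                p.name: _sha256(p)
                for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"
            },
            wall_clock_s=round(time.perf_counter() - start, 3),
        )
    except Exception:
        manifest = RunManifest(
            config=dataclasses.asdict(config),
            package_version=__version__,
            files={},
            wall_clock_s=round(time.perf_counter() - start, 3),
            failed_stage=stage,
        )
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

# Printed half-split worked examples: (first mismatch, first match,
# second mismatch, second match) cell mean RTs per experiment.
TABLE2_CELLS = {
    "exp1": (957.0, 786.0, 936.0, 776.0),
    "exp2": (1014.0, 804.0, 972.0, 789.0),
    "exp3": (934.0, 785.0, 930.0, 724.0),
}


def table2_trials(experiment: str) -> pd.DataFrame:
    """A small trial table whose half x match RT cell means equal the printed
    worked-example values, so half_split reproduces the published match
    effects exactly (all trials correct; PC carries no structure here)."""
    if experiment not in TABLE2_CELLS:
        raise ConfigurationError(f"unknown experiment key: {experiment!r}")
    mm1, m1, mm2, m2 = TABLE2_CELLS[experiment]
    rows = []
    cells = [("first", "mismatch", mm1), ("first", "match", m1), ("second", "mismatch", mm2), ("second", "match", m2)]
    for s in range(4):
        for half, match, mean_rt in cells:
            for t, offset in enumerate((-10.0, 10.0)):
                rows.append(
                    {
                        "subject_id": f"S{s + 1:03d}",
                        "item_id": f"ITEM{t + 1:02d}",
                        "domain": "time",
                        "category": "past",
                        "match": match,
                        "congruency": "not_applicable",
                        "block_index": 0 if half == "first" else 1,
                        "half": half,
                        "rt_ms": mean_rt + offset,
                        "correct": True,
                    }
                )
    return pd.DataFrame(rows)[synthetic.TRIAL_COLUMNS]


def make_fixtures(kind: str, seed: int, output_dir: str | Path) -> list[Path]:
    """Write small deterministic fixture files used by the test suite."""
    if kind not in FIXTURE_KINDS:
        raise ConfigurationError(f"unknown fixture kind: {kind!r}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind == "tiny_trials":
        design = synthetic.DesignSpec.experiment2(n_subjects=4, items_per_category=2)
        params = synthetic.RTGenParams(seed=seed, subject_sd=30.0, item_sd=10.0)
        trials = synthetic.generate_rt_experiment(design, params)
        path = out / "tiny_trials.csv"
        _write_csv(trials, path)
        written.append(path)
    elif kind == "tiny_ratings":
        params = synthetic.RatingGenParams(
            n_young=6, n_old=4, words_per_category=3, seed=seed
        )
        path = out / "tiny_ratings.csv"
        _write_csv(synthetic.generate_ratings(params), path)
        written.append(path)
    elif kind == "tiny_corpus":
        spec = synthetic.CorpusSpec(
            n_documents=10,
            doc_length=12,
            vocabulary=synthetic.default_vocabulary(words_per_category=2, n_fillers=4),
            association_strength=0.8,
            direction="both",
            seed=seed,
        )
        path = out / "tiny_corpus.txt"
        path.write_text(synthetic.corpus_to_lines(synthetic.generate_corpus(spec)))
        written.append(path)
    elif kind == "table2_cells":
        for exp in TABLE2_CELLS:
            path = out / f"table2_{exp}.csv"
            _write_csv(table2_trials(exp), path)
            written.append(path)
    return written
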