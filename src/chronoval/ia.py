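"""Interactive-activation account of the time-valence match effect.

Four nodes represent past time (1), future time (2), negative valence (3) and
positive valence (4).  Antagonists inhibit each other (past-future,
negative-positive); agonists excite each other (past-negative,
future-positive).  A stimulus injects input into its node; the supra-rest
outputs ``O_i = max(a_i - rest, 0)`` of all four nodes drive two response
accumulators whose wiring depends on the match condition:

* match:    A <- O1 + O3,  B <- O2 + O4
* mismatch: A <- O1 + O4,  B <- O2 + O3

Model 1 keeps both agonist links; Model 2 removes the past-negative
excitation, leaving future-positive as the only agonist pair, which predicts a
match effect for future/positive responses but little or none for
past/negative responses.

Node dynamics are a discrete Euler scheme with the standard
interactive-activation saturating update,

    net_i     = sum_j w[i][j] * O_j + I_i
    delta a_i = step * (net_i * (max - a_i) - decay * (a_i - rest))   net_i >= 0
    delta a_i = step * (net_i * (a_i - min) - decay * (a_i - rest))   net_i <  0

with activations clipped to ``[min, max]`` after each step.  Responses
integrate leak-free: ``resp(t+1) = resp(t) + step * gain * (wired outputs)``.
Crossing times are reported in model time units (steps * step size) with
linear interpolation across the threshold; an affine steps->ms mapping is
provided for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "NODES",
    "IAConfig",
    "ActivationTrace",
    "MatchPrediction",
    "build_network",
    "simulate",
    "accumulate_response",
    "predict_match_effects",
    "crossing_time_vs_step",
    "time_to_milliseconds",
]

NODES = ("past", "future", "negative", "positive")
_NODE_INDEX = {name: i for i, name in enumerate(NODES)}
RESPONSE_CATEGORIES = ("past/negative", "future/positive")
_CATEGORY_STIMULI = {
    "past/negative": ("past", "negative"),
    "future/positive": ("future", "positive"),
}

# match wiring: response A collects past+negative outputs, B future+positive;
# mismatch crosses the valence channels
_WIRING = {
    "match": ((0, 2), (1, 3)),
    "mismatch": ((0, 3), (1, 2)),
}


@dataclass(frozen=True)
class IAConfig:
    """Full parameterisation of the four-node network and its response stage."""

    weights: np.ndarray  # 4x4, w[i][j] = influence of node j on node i
    input_strength: float = 0.40
    rest_level: float = 0.0
    min_activation: float = -0.2
    max_activation: float = 1.0
    decay: float = 0.10
    step_size: float = 0.05
    response_gain: float = 1.0
    threshold: float = 0.5
    max_steps: int = 4000
    variant: str = "model1"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4, 4):
            raise ConfigurationError("weights must be a 4x4 matrix")
        object.__setattr__(self, "weights", w)
        if not self.min_activation <= self.rest_level <= self.max_activation:
            raise ConfigurationError("need min_activation <= rest_level <= max_activation")
        if not 0.0 <= self.decay <= 1.0:
            raise ConfigurationError("decay must lie in [0, 1]")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be positive")
        if self.threshold <= self.rest_level:
            raise ConfigurationError("threshold must exceed the resting level")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be positive")
        if self.variant not in ("model1", "model2"):
            raise ConfigurationError(f"unknown variant: {self.variant!r}")
        _check_sign_pattern(w, self.variant)


def _check_sign_pattern(w: np.ndarray, variant: str) -> None:
    """Enforce the antagonist/agonist sign structure of the weight matrix."""
    inhibitory = [(0, 1), (1, 0), (2, 3), (3, 2)]
    excitatory = [(1, 3), (3, 1)]
    past_negative = [(0, 2), (2, 0)]
    for i, j in inhibitory:
        if w[i, j] >= 0:
            raise ConfigurationError(f"w[{i}][{j}] must be negative (mutual inhibition)")
    for i, j in excitatory:
        if w[i, j] <= 0:
            raise ConfigurationError(f"w[{i}][{j}] must be positive (mutual excitation)")
    if variant == "model1":
        for i, j in past_negative:
            if w[i, j] <= 0:
                raise ConfigurationError(
                    f"model1 requires positive past-negative excitation w[{i}][{j}]"
                )
    else:  # model2: past-negative links removed
        for i, j in past_negative:
            if w[i, j] != 0:
                raise ConfigurationError("model2 requires w[past][negative] = w[negative][past] = 0")


@dataclass
class ActivationTrace:
    """Simulated trajectories: node activations/outputs and, once a response
    wiring is applied, the two response accumulators."""

    node_activations: np.ndarray  # (T+1, 4)
    node_outputs: np.ndarray  # (T+1, 4)
    stimulus: str
    config: IAConfig
    match_condition: str | None = None
    response_A: np.ndarray | None = None
    response_B: np.ndarray | None = None
    crossing_step: int | None = None
    crossing_time: float | None = None

    @property
    def n_steps(self) -> int:
        return self.node_activations.shape[0] - 1

    def to_frame(self):
        """Trace as a tidy table (step, a1..a4, O1..O4, respA, respB)."""
        import pandas as pd

        data = {"step": np.arange(self.node_activations.shape[0])}
        for k, name in enumerate(("a1", "a2", "a3", "a4")):
            data[name] = self.node_activations[:, k]
        for k, name in enumerate(("O1", "O2", "O3", "O4")):
            data[name] = self.node_outputs[:, k]
        if self.response_A is not None:
            data["respA"] = self.response_A
            data["respB"] = self.response_B
        return pd.DataFrame(data)


def build_network(variant: str = "model1", **overrides) -> IAConfig:
    """Construct the default network for one model variant.

    ``gamma`` (agonist excitation) and ``beta`` (antagonist inhibition) set
    the weight magnitudes; every scalar field of :class:`IAConfig` may be
    overridden by keyword.  Overrides violating the variant's sign pattern or
    the activation-range invariants raise :class:`ConfigurationError`.
    """
    if variant not in ("model1", "model2"):
        raise ConfigurationError(f"unknown variant: {variant!r}")
    gamma = overrides.pop("gamma", 0.10)
    beta = overrides.pop("beta", 0.10)
    if gamma <= 0 or beta <= 0:
        raise ConfigurationError("gamma and beta must be positive magnitudes")

    w = np.zeros((4, 4))
    # antagonists: past<->future, negative<->positive
    w[0, 1] = w[1, 0] = -beta
    w[2, 3] = w[3, 2] = -beta
    # agonists: future<->positive always; past<->negative only in model 1
    w[1, 3] = w[3, 1] = gamma
    if variant == "model1":
        w[0, 2] = w[2, 0] = gamma

    allowed = {
        "input_strength",
        "rest_level",
        "min_activation",
        "max_activation",
        "decay",
        "step_size",
        "response_gain",
        "threshold",
        "max_steps",
    }
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigurationError(f"unknown override(s): {sorted(unknown)}")
    return IAConfig(weights=w, variant=variant, **overrides)


def simulate(config: IAConfig, stimulus: str) -> ActivationTrace:
    """Integrate the node dynamics for ``max_steps`` under one stimulus.

    The stimulus category's node receives constant input ``input_strength``;
    all other inputs are zero.  Node dynamics do not depend on the response
    stage, so the full trajectory is computed here and response accumulation /
    early stopping at threshold is applied by :func:`accumulate_response`.
    """
    if stimulus not in _NODE_INDEX:
        raise ConfigurationError(f"unknown stimulus category: {stimulus!r}")
    w = config.weights
    rest = config.rest_level
    lo, hi = config.min_activation, config.max_activation
    inputs = np.zeros(4)
    inputs[_NODE_INDEX[stimulus]] = config.input_strength

    a = np.full(4, rest, dtype=float)
    acts = np.empty((config.max_steps + 1, 4))
    outs = np.empty_like(acts)
    acts[0] = a
    outs[0] = np.maximum(a - rest, 0.0)
    for t in range(1, config.max_steps + 1):
        o = np.maximum(a - rest, 0.0)
        net = w @ o + inputs
        grow = net * (hi - a)  # toward ceiling when net excitation
        shrink = net * (a - lo)  # toward floor when net inhibition
        delta = config.step_size * (np.where(net >= 0, grow, shrink) - config.decay * (a - rest))
        a = np.clip(a + delta, lo, hi)
        if not np.all(np.isfinite(a)):
            raise AnalysisError(f"non-finite activation at step {t}")
        acts[t] = a
        outs[t] = np.maximum(a - rest, 0.0)
    return ActivationTrace(node_activations=acts, node_outputs=outs, stimulus=stimulus, config=config)


def accumulate_response(trace: ActivationTrace, match_condition: str) -> ActivationTrace:
    """Drive the two response accumulators from the node outputs.

    Returns a new trace carrying ``response_A``/``response_B`` (leak-free
    integrals of the wired outputs), truncated at the first step where either
    response reaches threshold.  ``crossing_time`` interpolates linearly
    between the bracketing steps, in model time units.
    """
    if match_condition not in _WIRING:
        raise ConfigurationError(f"unknown match condition: {match_condition!r}")
    cfg = trace.config
    (a_nodes, b_nodes) = _WIRING[match_condition]
    scale = cfg.step_size * cfg.response_gain
    # resp(t) integrates outputs at steps 0 .. t-1
    drive_a = trace.node_outputs[:-1, a_nodes].sum(axis=1)
    drive_b = trace.node_outputs[:-1, b_nodes].sum(axis=1)
    resp_a = np.concatenate([[0.0], np.cumsum(scale * drive_a)])
    resp_b = np.concatenate([[0.0], np.cumsum(scale * drive_b)])

    winner = np.maximum(resp_a, resp_b)
    above = np.nonzero(winner >= cfg.threshold)[0]
    crossing_step: int | None = None
    crossing_time: float | None = None
    end = len(winner) - 1
    if above.size:
        crossing_step = int(above[0])
        end = crossing_step
        prev, cur = winner[crossing_step - 1], winner[crossing_step]
        frac = (cfg.threshold - prev) / (cur - prev) if cur > prev else 1.0
        crossing_time = (crossing_step - 1 + frac) * cfg.step_size

    sl = slice(0, end + 1)
    return ActivationTrace(
        node_activations=trace.node_activations[sl],
        node_outputs=trace.node_outputs[sl],
        stimulus=trace.stimulus,
        config=cfg,
        match_condition=match_condition,
        response_A=resp_a[sl],
        response_B=resp_b[sl],
        crossing_step=crossing_step,
        crossing_time=crossing_time,
    )


@dataclass
class MatchPrediction:
    """Crossing times per response category x match condition and the derived
    per-category match effects (mismatch - match, model time units)."""

    variant: str
    crossing_times: dict  # (category, condition) -> float | None
    match_effects: dict  # category -> float | None (None = undefined)
    non_terminating: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"category": cat, "condition": cond, "crossing_time": t}
            for (cat, cond), t in self.crossing_times.items()
        ]
        return pd.DataFrame(rows)


def predict_match_effects(config: IAConfig) -> MatchPrediction:
    """Run the full stimulus-by-condition grid and derive the match effects.

    Each response category's crossing time is the mean over its two stimuli
    (identical under symmetric defaults); a cell whose accumulators never
    reach threshold is flagged and its category effect reported as undefined.
    """
    crossing: dict = {}
    non_terminating: list = []
    for category, stimuli in _CATEGORY_STIMULI.items():
        for condition in ("match", "mismatch"):
            times = []
            for stim in stimuli:
                trace = accumulate_response(simulate(config, stim), condition)
                if trace.crossing_time is None:
                    non_terminating.append((category, condition, stim))
                    times = None
                    break
                times.append(trace.crossing_time)
            crossing[(category, condition)] = None if times is None else float(np.mean(times))

    effects = {}
    for category in RESPONSE_CATEGORIES:
        m, mm = crossing[(category, "match")], crossing[(category, "mismatch")]
        effects[category] = None if m is None or mm is None else mm - m
    return MatchPrediction(
        variant=config.variant,
        crossing_times=crossing,
        match_effects=effects,
        non_terminating=non_terminating,
    )


def crossing_time_vs_step(
    config: IAConfig, stimulus: str, match_condition: str, n_refinements: int = 3
) -> list[float]:
    """Crossing times under successive halvings of the Euler step.

    Each refinement halves ``step_size`` and doubles ``max_steps`` so the same
    span of model time is covered; the sequence converges as the step shrinks.
    """
    times = []
    cfg = config
    for _ in range(n_refinements + 1):
        trace = accumulate_response(simulate(cfg, stimulus), match_condition)
        if trace.crossing_time is None:
            raise AnalysisError("accumulators never reached threshold during refinement")
        times.append(trace.crossing_time)
        cfg = replace(cfg, step_size=cfg.step_size / 2.0, max_steps=cfg.max_steps * 2)
    return times


def time_to_milliseconds(time_units: float, intercept_ms: float = 300.0, slope_ms: float = 300.0) -> float:
    """Affine display mapping from model time units to milliseconds.

    Purely presentational: the model predicts ordinal structure and effect
    ratios, not absolute RTs, so the intercept (residual sensory/motor time)
    and slope are free display choices.
    """
    return intercept_ms + slope_ms * time_units
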