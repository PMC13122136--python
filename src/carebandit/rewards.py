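"""Ground-truth reward models linking user x program context to outcomes.

Three care outcomes are modeled:

* ``call_success`` — completion of the care call, Bernoulli with a logistic
  mean; higher is better.
* ``phq2`` — depressive-symptom screen, integers 0–6 from a linear mean with
  probabilistic rounding; *lower* is better.
* ``srh`` — self-reported health, integers 1–5, same mechanism; higher is
  better.

Coefficients come in two flavours.  In ``ai_call`` mode the sign of every
main effect is fixed from a direction table (mimicking trends observed in an
intervention cohort) with a constant magnitude; in ``random`` mode the main
effects are drawn uniformly, mimicking a population for which no
outcome-program relationship is known.  In both modes the seven
user-by-program interaction effects keep their stated clinical directions.

The bandit maximizes; :func:`orient_reward` maps every outcome onto a common
[0, 1] benefit scale (PHQ-2 reversed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .population import (
    ARM_DUMMY_NAMES,
    DEFAULT_INTERACTIONS,
    DEFAULT_SCHEMA,
    ConfigurationError,
    FeatureSchema,
    InteractionSpec,
)

__all__ = [
    "OUTCOMES",
    "RewardModelSpec",
    "OutcomeValue",
    "DEFAULT_BENEFIT_SIGNS",
    "build_model_ai_call",
    "build_model_random",
    "expected_reward",
    "probabilistic_round",
    "sample_outcome",
    "orient_reward",
    "orient_value",
]

#: outcome -> (family, bounds, higher_is_better, default intercept)
OUTCOMES: dict[str, tuple[str, tuple[int, int], bool, float]] = {
    "call_success": ("binary-logistic", (0, 1), True, -0.25),
    "phq2": ("bounded-integer-linear", (0, 6), False, 2.8),
    "srh": ("bounded-integer-linear", (1, 5), True, 3.0),
}

#: Default magnitudes by family: (main effect, interaction).  The linear
#: magnitudes keep predictions in the interior of the bounded scales for
#: typical profiles, so clipping stays rare and personalization margins
#: survive on the 0–6 / 1–5 scales.
DEFAULT_MAGNITUDES: dict[str, tuple[float, float]] = {
    "binary-logistic": (0.5, 1.0),
    "bounded-integer-linear": (0.3, 0.5),
}

#: Default direction of each main effect on the clinical-benefit scale
#: (+1 improves the outcome, −1 worsens it, 0 no effect).  Health burdens
#: worsen every outcome; women engage slightly better; rural residence is a
#: barrier; among program attributes, health-information content and more
#: frequent calls help on average, intervention content and long calls cost
#: engagement, and voice type is neutral on average.
DEFAULT_BENEFIT_SIGNS: dict[str, int] = {
    "old_old": -1,
    "female": +1,
    "rural": -1,
    "economic_unstable": -1,
    "multimorbidity": -1,
    "functional_difficulty": -1,
    "lonely": -1,
    "cognition_impaired": -1,
    "lives_alone": -1,
    "content_health_information": +1,
    "content_intervention": -1,
    "frequency_high": +1,
    "duration_long": -1,
    "voice_B": 0,
}


@dataclass(frozen=True)
class RewardModelSpec:
    """Ground-truth coefficients and outcome family for one outcome.

    ``beta`` is the full coefficient vector on the outcome's natural scale,
    ordered like the context encoding:
    [intercept | user features | arm dummies | interactions].
    """

    outcome: str
    family: str
    bounds: tuple[int, int]
    higher_is_better: bool
    beta: np.ndarray
    schema: FeatureSchema = DEFAULT_SCHEMA
    interactions: tuple[InteractionSpec, ...] = DEFAULT_INTERACTIONS

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ConfigurationError("bounds must satisfy lo < hi")
        expect = 1 + len(self.schema) + len(ARM_DUMMY_NAMES) + len(self.interactions)
        if len(self.beta) != expect:
            raise ConfigurationError(
                f"coefficient vector length {len(self.beta)} != context dim {expect}"
            )

    @property
    def dim(self) -> int:
        return len(self.beta)

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def beta_user(self) -> np.ndarray:
        return self.beta[1 : 1 + len(self.schema)]

    @property
    def beta_arm(self) -> np.ndarray:
        k = 1 + len(self.schema)
        return self.beta[k : k + len(ARM_DUMMY_NAMES)]

    @property
    def beta_interaction(self) -> np.ndarray:
        return self.beta[1 + len(self.schema) + len(ARM_DUMMY_NAMES) :]


@dataclass(frozen=True)
class OutcomeValue:
    """A realized outcome with the model's noiseless expectation."""

    value: int
    expected: float


def _orientation(outcome: str) -> float:
    """+1 when a larger raw outcome is clinically better, else −1."""
    return 1.0 if OUTCOMES[outcome][2] else -1.0


def _interaction_beta(
    outcome: str,
    magnitude: float,
    interactions: Sequence[InteractionSpec],
) -> np.ndarray:
    """Interaction coefficients on the natural scale of ``outcome``.

    Each interaction's ``benefit_sign`` is a clinical direction; on the raw
    PHQ-2 scale (lower is better) a beneficial pairing therefore gets a
    negative coefficient.
    """
    orient = _orientation(outcome)
    return np.array(
        [it.benefit_sign * orient * magnitude for it in interactions]
    )


def build_model_ai_call(
    outcome: str,
    sign_table: Mapping[str, int] | None = None,
    magnitude_main: float | None = None,
    magnitude_interaction: float | None = None,
    intercept: float | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> RewardModelSpec:
    """Sign-constrained model: every main effect is sign x constant magnitude.

    ``sign_table`` gives the *benefit* direction (+1/0/−1) per user feature
    and arm dummy; on outcomes where lower is better the raw coefficient is
    negated accordingly.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    family, bounds, higher, default_icpt = OUTCOMES[outcome]
    mag_main, mag_inter = DEFAULT_MAGNITUDES[family]
    if magnitude_main is not None:
        mag_main = magnitude_main
    if magnitude_interaction is not None:
        mag_inter = magnitude_interaction
    icpt = default_icpt if intercept is None else intercept
    signs = dict(DEFAULT_BENEFIT_SIGNS) if sign_table is None else dict(sign_table)

    main_names = list(schema.names) + list(ARM_DUMMY_NAMES)
    orient = _orientation(outcome)
    mains = np.empty(len(main_names))
    for i, name in enumerate(main_names):
        s = signs.get(name, 0)
        if s not in (-1, 0, 1):
            raise ConfigurationError(f"sign for {name!r} must be in {{-1, 0, +1}}")
        mains[i] = s * orient * mag_main
    beta = np.concatenate(
        [[icpt], mains, _interaction_beta(outcome, mag_inter, interactions)]
    )
    return RewardModelSpec(
        outcome=outcome,
        family=family,
        bounds=bounds,
        higher_is_better=higher,
        beta=beta,
        schema=schema,
        interactions=tuple(interactions),
    )


#: Baseline operating point of the random-coefficient populations: the mean
#: linear predictor under systematic (uniform-arm) allocation is anchored
#: here, so the outcome scale stays interior regardless of which random main
#: effects are drawn.  Values are the study's baseline (systematic) column:
#: call success rate, mean PHQ-2, mean SRH.
RANDOM_BASELINE_ANCHORS: dict[str, float] = {
    "call_success": 0.5872,
    "phq2": 2.73,
    "srh": 3.18,
}


def build_model_random(
    outcome: str,
    seed: int,
    main_dist: tuple[float, float] = (-0.5, 0.5),
    magnitude_interaction: float | None = None,
    intercept: float | None = None,
    mean_context: np.ndarray | None = None,
    baseline_anchor: float | None = None,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> RewardModelSpec:
    """Random-coefficient model: mains i.i.d. uniform, interactions fixed.

    Main effects (user features and arm dummies) are drawn once, seeded,
    uniformly on ``main_dist``; the seven interaction effects keep their
    clinical directions with the default (or given) magnitude.

    When ``mean_context`` (the population-and-uniform-arm average context
    vector) is supplied, the intercept is calibrated so the mean linear
    predictor equals the outcome's baseline anchor (on the logit scale for
    the logistic family) — the same baseline-centering the fixed-sign mode's
    default intercepts encode, made robust to the random draw.  An explicit
    ``intercept`` overrides calibration.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}")
    lo, hi = main_dist
    if lo > hi:
        raise ConfigurationError("main_dist interval must satisfy lo <= hi")
    family, bounds, higher, default_icpt = OUTCOMES[outcome]
    _, mag_inter = DEFAULT_MAGNITUDES[family]
    if magnitude_interaction is not None:
        mag_inter = magnitude_interaction

    rng = np.random.default_rng(seed)
    n_main = len(schema) + len(ARM_DUMMY_NAMES)
    mains = rng.uniform(lo, hi, size=n_main)
    inter = _interaction_beta(outcome, mag_inter, interactions)

    if intercept is not None:
        icpt = intercept
    elif mean_context is not None:
        anchor = (
            RANDOM_BASELINE_ANCHORS[outcome]
            if baseline_anchor is None
            else baseline_anchor
        )
        if family == "binary-logistic":
            eta0 = float(np.log(anchor / (1.0 - anchor)))
        else:
            eta0 = float(anchor)
        rest = np.concatenate([mains, inter])
        icpt = eta0 - float(rest @ np.asarray(mean_context, dtype=float)[1:])
    else:
        icpt = default_icpt

    beta = np.concatenate([[icpt], mains, inter])
    return RewardModelSpec(
        outcome=outcome,
        family=family,
        bounds=bounds,
        higher_is_better=higher,
        beta=beta,
        schema=schema,
        interactions=tuple(interactions),
    )


def expected_reward(model: RewardModelSpec, x: np.ndarray) -> float:
    """Noiseless expectation of the outcome at context ``x``, natural scale.

    Logistic family: sigmoid(beta'x).  Linear family: beta'x clipped to the
    scale bounds (probabilistic rounding is mean-preserving on the clipped
    prediction, so this is the exact expectation of the integer outcome).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.dim:
        raise ValueError(f"context dim {x.shape[-1]} != model dim {model.dim}")
    eta = x @ model.beta
    if model.family == "binary-logistic":
        return float(1.0 / (1.0 + np.exp(-eta)))
    lo, hi = model.bounds
    return float(np.clip(eta, lo, hi))


def model_to_frame(model: RewardModelSpec):
    """Coefficient vector as a named table (for CSV audit export)."""
    import pandas as pd

    from .population import context_names

    names = context_names(model.schema, interactions=model.interactions)
    return pd.DataFrame({"term": names, "coefficient": model.beta})


def expected_reward_matrix(model: RewardModelSpec, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`expected_reward` over the last axis of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.dim:
        raise ValueError(f"context dim {X.shape[-1]} != model dim {model.dim}")
    eta = X @ model.beta
    if model.family == "binary-logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    lo, hi = model.bounds
    return np.clip(eta, lo, hi)


def oriented_expectation_matrix(
    model: RewardModelSpec, X: np.ndarray
) -> np.ndarray:
    """Expected oriented ([0, 1] benefit-scale) reward for contexts ``X``.

    Orientation is affine, so this equals the expectation of the oriented
    realized reward.
    """
    mu = expected_reward_matrix(model, X)
    lo, hi = model.bounds
    if model.higher_is_better:
        return (mu - lo) / (hi - lo)
    return (hi - mu) / (hi - lo)


def probabilistic_round(
    y: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    """Mean-preserving integer draw: ceil(y) w.p. frac(y), else floor(y).

    ``y`` is first clipped to [lo, hi]; the expectation of the result equals
    the clipped value.
    """
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    y = float(np.clip(y, lo, hi))
    base = int(np.floor(y))
    frac = y - base
    value = base + (1 if rng.random() < frac else 0)
    return min(value, hi)


def sample_outcome(
    model: RewardModelSpec, x: np.ndarray, rng: np.random.Generator
) -> OutcomeValue:
    """Draw one realized outcome at context ``x``."""
    mu = expected_reward(model, x)
    if model.family == "binary-logistic":
        value = int(rng.random() < mu)
    else:
        value = probabilistic_round(mu, *model.bounds, rng)
    return OutcomeValue(value=value, expected=mu)


def orient_value(value: float, model: RewardModelSpec) -> float:
    """Map a raw outcome value onto the common [0, 1] benefit scale.

    call_success: identity; SRH 1–5 -> (v−1)/4; PHQ-2 0–6 -> (6−v)/6.
    Strictly monotone in clinical benefit; accepts real-valued inputs so the
    same map serves realized integers and noiseless expectations.
    """
    lo, hi = model.bounds
    if model.higher_is_better:
        return (float(value) - lo) / (hi - lo)
    return (hi - float(value)) / (hi - lo)


def orient_reward(outcome: OutcomeValue, model: RewardModelSpec) -> float:
    """Oriented [0, 1] reward of a realized outcome (what the bandit sees)."""
    lo, hi = model.bounds
    if not lo <= outcome.value <= hi:
        raise ValueError(f"outcome value {outcome.value} outside bounds")
    return orient_value(outcome.value, model)
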