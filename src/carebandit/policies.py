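"""The four program-allocation strategies behind one select/update interface.

* :class:`CyclicPolicy` — systematic delivery: arms in fixed rotating order,
  ignoring the user (the real-world baseline).
* :class:`SingleBestPolicy` — everyone gets the one arm with the highest
  population-average expected benefit, as if known from an infinitely large
  randomized trial.
* :class:`OraclePolicy` — idealized personalization: the true model's best
  arm for each user (theoretical upper bound; zero regret by construction).
* :class:`LinTSPolicy` — linear Thompson Sampling over the joint user x arm
  context: a Bayesian linear model with Gaussian prior N(0, v^2/lambda I) and
  per-step posterior sampling, learning the reward structure online.

All policies break selection ties to the lowest arm id.  Only Thompson
Sampling ever reads reward feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .population import (
    CareProgram,
    PopulationSpec,
    UserProfile,
    build_context_tensor,
    encode_context,
    profile_space,
)
from .rewards import RewardModelSpec, oriented_expectation_matrix

__all__ = [
    "DEFAULT_TS_V",
    "Decision",
    "CyclicPolicy",
    "SingleBestPolicy",
    "OraclePolicy",
    "LinTSPolicy",
    "cyclic_select",
    "single_best_arm",
    "population_average_rewards",
    "oracle_select",
    "lints_init",
    "lints_select",
    "lints_update",
]


@dataclass(frozen=True)
class Decision:
    """One selection: the chosen arm, with per-arm sampled scores for audit
    (Thompson Sampling only)."""

    arm_id: int
    sampled_scores: np.ndarray | None = None


def _encode_all(
    user: UserProfile, catalog: Sequence[CareProgram], model: RewardModelSpec
) -> np.ndarray:
    return np.stack(
        [encode_context(user, a, model.schema, model.interactions) for a in catalog]
    )


# ---------------------------------------------------------------------------
# Method 1: systematic (cyclic) delivery
# ---------------------------------------------------------------------------

@dataclass
class CyclicPolicy:
    """Fixed rotating assignment order, independent of user context."""

    n_arms: int
    cyclic_index: int = 0

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("catalog must contain at least one arm")

    def select(self, user: UserProfile | None = None, rng=None) -> Decision:
        arm = self.cyclic_index
        self.cyclic_index = (self.cyclic_index + 1) % self.n_arms
        return Decision(arm_id=arm)

    def update(self, x: np.ndarray, r: float) -> None:  # never learns
        pass


def cyclic_select(state: CyclicPolicy, catalog: Sequence[CareProgram]) -> Decision:
    """Select the arm at the cyclic index and advance modulo catalog size."""
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    state.n_arms = len(catalog)
    return state.select()


# ---------------------------------------------------------------------------
# Method 2: single best program (population average)
# ---------------------------------------------------------------------------

def population_average_rewards(
    model: RewardModelSpec,
    spec: PopulationSpec,
    catalog: Sequence[CareProgram],
) -> np.ndarray:
    """Population-average expected oriented reward of every arm.

    Averages the exact per-profile expectation over the population's profile
    distribution (full 2^k product-weighted cube in marginal mode, fixture
    rows in fixture mode).  The logistic mean is nonlinear, so the average
    must sum over profiles rather than plug in mean features.
    """
    profiles, w = profile_space(spec)
    X = build_context_tensor(profiles, catalog, model.schema, model.interactions)
    mu = oriented_expectation_matrix(model, X)  # (profiles, arms)
    return w @ mu


def single_best_arm(
    model: RewardModelSpec,
    spec: PopulationSpec,
    catalog: Sequence[CareProgram],
) -> int:
    """Arm with the highest population-average expected benefit.

    Ties break to the lowest arm id (argmax's first maximum).
    """
    avg = population_average_rewards(model, spec, catalog)
    return int(np.argmax(avg))


@dataclass
class SingleBestPolicy:
    """Assign the precomputed population-best arm to everyone."""

    fixed_arm: int

    def select(self, user: UserProfile | None = None, rng=None) -> Decision:
        return Decision(arm_id=self.fixed_arm)

    def update(self, x: np.ndarray, r: float) -> None:
        pass

    @classmethod
    def from_model(
        cls,
        model: RewardModelSpec,
        spec: PopulationSpec,
        catalog: Sequence[CareProgram],
    ) -> "SingleBestPolicy":
        return cls(fixed_arm=single_best_arm(model, spec, catalog))


# ---------------------------------------------------------------------------
# Method 3: idealized personalized delivery (oracle)
# ---------------------------------------------------------------------------

def oracle_select(
    model: RewardModelSpec,
    user: UserProfile,
    catalog: Sequence[CareProgram],
) -> Decision:
    """The true model's best arm for this user; ties to lowest arm id."""
    X = _encode_all(user, catalog, model)
    mu = oriented_expectation_matrix(model, X)
    return Decision(arm_id=int(np.argmax(mu)))


@dataclass
class OraclePolicy:
    """Perfect-knowledge personalization: argmax of true expected benefit."""

    model: RewardModelSpec
    catalog: Sequence[CareProgram]

    def select(self, user: UserProfile, rng=None) -> Decision:
        return oracle_select(self.model, user, self.catalog)

    def update(self, x: np.ndarray, r: float) -> None:
        pass


# ---------------------------------------------------------------------------
# Method 4: linear Thompson Sampling
# ---------------------------------------------------------------------------

#: Default posterior noise scale v by outcome family, matched to the scale of
#: the oriented-reward observation noise: Bernoulli rewards have sd up to
#: 0.5, while probabilistic rounding on the 0–6 / 1–5 scales leaves oriented
#: noise of sd ~0.1, so a far smaller v avoids gross over-exploration there.
DEFAULT_TS_V: dict[str, float] = {
    "binary-logistic": 0.5,
    "bounded-integer-linear": 0.15,
}

@dataclass
class LinTSPolicy:
    """Bayesian linear bandit with posterior sampling.

    One shared coefficient vector theta over the joint user x arm context
    (arm dummies and interactions carry the arm-specific structure).  The
    posterior after n rank-one updates is
    N(mu_hat, v^2 B^{-1}) with B = lambda I + sum x x', f = sum r x,
    mu_hat = B^{-1} f.  Each decision draws one theta ~ posterior (shared
    across arms) and plays the arm with the highest sampled score.

    For speed the inverse A = B^{-1} is maintained directly through
    Sherman-Morrison updates; B is kept alongside for inspection.
    """

    d: int
    v: float = 0.5
    ridge: float = 1.0
    precision: np.ndarray = field(init=False)       # B
    precision_inv: np.ndarray = field(init=False)   # A = B^-1
    response_acc: np.ndarray = field(init=False)    # f
    posterior_mean: np.ndarray = field(init=False)  # mu_hat

    def __post_init__(self) -> None:
        if self.v <= 0 or self.ridge <= 0:
            raise ValueError("v and ridge must be positive")
        if self.d < 1:
            raise ValueError("context dimension must be >= 1")
        self.precision = self.ridge * np.eye(self.d)
        self.precision_inv = (1.0 / self.ridge) * np.eye(self.d)
        self.response_acc = np.zeros(self.d)
        self.posterior_mean = np.zeros(self.d)

    # -- selection ---------------------------------------------------------

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        """One draw theta ~ N(mu_hat, v^2 B^{-1})."""
        A = 0.5 * (self.precision_inv + self.precision_inv.T)
        L = np.linalg.cholesky(A)
        z = rng.standard_normal(self.d)
        return self.posterior_mean + self.v * (L @ z)

    def select_from_contexts(
        self, X_arms: np.ndarray, rng: np.random.Generator
    ) -> Decision:
        """Choose among precomputed per-arm contexts (n_arms, d)."""
        theta = self.sample_theta(rng)
        scores = X_arms @ theta
        return Decision(arm_id=int(np.argmax(scores)), sampled_scores=scores)

    def select(
        self,
        user: UserProfile,
        catalog: Sequence[CareProgram],
        rng: np.random.Generator,
        model: RewardModelSpec,
    ) -> Decision:
        return self.select_from_contexts(_encode_all(user, catalog, model), rng)

    # -- learning ----------------------------------------------------------

    def update(self, x: np.ndarray, r: float) -> None:
        """Rank-one posterior update with context ``x`` and reward ``r``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.d,):
            raise ValueError(f"context has shape {x.shape}, expected ({self.d},)")
        if not (np.isfinite(x).all() and np.isfinite(r)):
            raise ValueError("non-finite inputs to posterior update")
        self.precision = self.precision + np.outer(x, x)
        Ax = self.precision_inv @ x
        denom = 1.0 + float(x @ Ax)
        self.precision_inv = self.precision_inv - np.outer(Ax, Ax) / denom
        self.response_acc = self.response_acc + r * x
        self.posterior_mean = self.precision_inv @ self.response_acc


def lints_init(d: int, v: float = 0.5, ridge: float = 1.0) -> LinTSPolicy:
    """Fresh Thompson Sampling state: B = ridge * I, f = 0, mu_hat = 0."""
    return LinTSPolicy(d=d, v=v, ridge=ridge)


def lints_select(
    state: LinTSPolicy,
    user: UserProfile,
    catalog: Sequence[CareProgram],
    rng: np.random.Generator,
    model: RewardModelSpec,
) -> Decision:
    """Posterior-sample theta once and play the best-scoring arm."""
    return state.select(user, catalog, rng, model)


def lints_update(state: LinTSPolicy, x: np.ndarray, r: float) -> LinTSPolicy:
    """Absorb one (context, oriented reward) observation; returns the state."""
    state.update(x, r)
    return state
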