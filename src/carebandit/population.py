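"""Synthetic older-adult populations and the care-program catalog.

Two population modes are supported:

* ``marginal-independent`` — every binary feature is drawn independently with
  a configured marginal proportion (used for the Community Health Survey-like
  population, where only aggregate distributions are available).
* ``joint-fixture`` — users are drawn from a finite weighted table of profiles
  whose marginals are pinned exactly to configured values but whose joint
  structure is correlated (used as a stand-in for an intervention cohort whose
  raw joint records are not distributable; see :func:`build_fixture_table`).

The module also builds the full-factorial catalog of care programs
(content x frequency x duration x voice) and the joint user-by-program
context encoding consumed by the reward models and the bandit policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureSchema",
    "PopulationSpec",
    "UserProfile",
    "CareProgram",
    "InteractionSpec",
    "DEFAULT_SCHEMA",
    "DEFAULT_INTERACTIONS",
    "CHS_PROPORTIONS",
    "AI_CALL_MARGINALS",
    "ARM_DUMMY_NAMES",
    "generate_profiles_marginal",
    "build_fixture_table",
    "sample_user",
    "build_arm_catalog",
    "encode_context",
    "context_dim",
    "profiles_to_frame",
]


class ConfigurationError(ValueError):
    """Raised when a population / catalog configuration is inconsistent."""


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of binary user features.

    ``levels`` documents the semantic meaning of the value 1 for each
    feature.  The order is fixed for a run: the context encoding and all
    coefficient vectors depend on it.
    """

    names: tuple[str, ...]
    levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown feature {name!r}") from None


#: Nine binary demographic / health features of the simulated population.
DEFAULT_SCHEMA = FeatureSchema(
    names=(
        "old_old",
        "female",
        "rural",
        "economic_unstable",
        "multimorbidity",
        "functional_difficulty",
        "lonely",
        "cognition_impaired",
        "lives_alone",
    ),
    levels={
        "old_old": "1 = aged 75 or over (old-old)",
        "female": "1 = female",
        "rural": "1 = rural residence",
        "economic_unstable": "1 = economically unstable",
        "multimorbidity": "1 = multiple chronic conditions present",
        "functional_difficulty": "1 = functional difficulty present",
        "lonely": "1 = lonely / socially isolated",
        "cognition_impaired": "1 = cognition not intact",
        "lives_alone": "1 = lives alone",
    },
)

#: Marginal proportions of the CHS-like population (n = 72,812).  Features
#: without published marginals default to 0.5.
CHS_PROPORTIONS: dict[str, float] = {
    "old_old": 0.47,
    "female": 0.584,
    "rural": 0.59,
    "lonely": 0.064,
    "economic_unstable": 0.5,
    "multimorbidity": 0.5,
    "functional_difficulty": 0.5,
    "cognition_impaired": 0.5,
    "lives_alone": 0.5,
}

#: Marginal proportions of the AI care-call cohort (n = 1196).
AI_CALL_MARGINALS: dict[str, float] = {
    "old_old": 0.798,
    "female": 0.772,
    "rural": 0.714,
    "lonely": 0.114,
    "economic_unstable": 0.5,
    "multimorbidity": 0.5,
    "functional_difficulty": 0.5,
    "cognition_impaired": 0.5,
    "lives_alone": 0.5,
}


@dataclass(frozen=True)
class UserProfile:
    """One simulated older adult: a binary feature vector ordered by schema."""

    id: int
    features: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(v not in (0, 1) for v in self.features):
            raise ValueError("profile features must be binary")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.features, dtype=float)


@dataclass
class PopulationSpec:
    """Specification of the user population.

    ``mode`` is ``"marginal-independent"`` (features drawn independently with
    the given ``proportions``) or ``"joint-fixture"`` (profiles drawn from the
    weighted ``fixture_table``, columns = schema features plus ``weight``).
    """

    mode: str
    schema: FeatureSchema = DEFAULT_SCHEMA
    proportions: dict[str, float] | None = None
    fixture_table: pd.DataFrame | None = None
    n_pool: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("marginal-independent", "joint-fixture"):
            raise ConfigurationError(f"unknown population mode {self.mode!r}")
        if self.mode == "marginal-independent":
            if self.proportions is None:
                raise ConfigurationError("marginal mode requires proportions")
            for name in self.schema.names:
                if name not in self.proportions:
                    raise ConfigurationError(
                        f"missing proportion for feature {name!r}"
                    )
            for name, p in self.proportions.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"proportion for {name!r} outside [0, 1]: {p}"
                    )
        else:
            if self.fixture_table is None:
                raise ConfigurationError("fixture mode requires fixture_table")
            w = self.fixture_table["weight"].to_numpy()
            if (w < 0).any():
                raise ConfigurationError("fixture weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError("fixture weights must sum to 1")

    def marginals(self) -> dict[str, float]:
        """Marginal P(feature = 1) implied by the spec."""
        if self.mode == "marginal-independent":
            assert self.proportions is not None
            return {n: self.proportions[n] for n in self.schema.names}
        tab = self.fixture_table
        w = tab["weight"].to_numpy()
        return {n: float(tab[n].to_numpy() @ w) for n in self.schema.names}


# ---------------------------------------------------------------------------
# Profile generation
# ---------------------------------------------------------------------------

def generate_profiles_marginal(
    spec: PopulationSpec, n: int, seed: int
) -> list[UserProfile]:
    """Draw ``n`` profiles with independent Bernoulli features.

    Each feature is an independent draw with its configured proportion;
    the sequence is reproducible under a fixed seed.
    """
    if spec.mode != "marginal-independent":
        raise ConfigurationError("generate_profiles_marginal needs marginal mode")
    rng = np.random.default_rng(seed)
    p = np.array([spec.proportions[f] for f in spec.schema.names])
    draws = (rng.random((n, len(p))) < p).astype(int)
    return [UserProfile(id=i, features=tuple(row)) for i, row in enumerate(draws)]


def profiles_to_frame(
    profiles: Sequence[UserProfile], schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Headered table of profiles (one row per user) for CSV export."""
    data = np.array([p.features for p in profiles], dtype=int)
    frame = pd.DataFrame(data, columns=list(schema.names))
    frame.insert(0, "id", [p.id for p in profiles])
    return frame


def build_fixture_table(
    marginals: Mapping[str, float],
    correlation: float | np.ndarray = 0.2,
    size: int = 100_000,
    seed: int = 0,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PopulationSpec:
    """Construct a correlated joint-fixture population.

    Binary profiles are generated through a Gaussian copula: latent draws
    from N(0, R) are thresholded at each feature's normal quantile, collapsed
    to the distinct profiles observed, and the resulting weights are raked
    (iterative proportional fitting on the nine one-way margins) until every
    marginal matches the requested value to within ``tol``.

    ``correlation`` is either a scalar latent correlation applied to every
    feature pair or a full positive semidefinite latent correlation matrix.
    """
    k = len(schema)
    for name in schema.names:
        if name not in marginals:
            raise ConfigurationError(f"missing marginal for feature {name!r}")
        if not 0.0 < marginals[name] < 1.0:
            raise ConfigurationError(
                f"fixture marginal for {name!r} must be strictly inside (0, 1)"
            )
    if np.isscalar(correlation):
        R = np.full((k, k), float(correlation))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(correlation, dtype=float)
        if R.shape != (k, k):
            raise ConfigurationError("correlation matrix has wrong shape")
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < -1e-10:
        raise ConfigurationError(
            "latent correlation matrix is not positive semidefinite; "
            "reduce the correlations"
        )

    p = np.array([marginals[f] for f in schema.names])
    thresh = stats.norm.ppf(1.0 - p)  # feature = 1 when latent > threshold
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    z = rng.standard_normal((size, k)) @ L.T
    rows = (z > thresh).astype(int)

    # Collapse to unique profiles with empirical weights.
    packed = rows @ (1 << np.arange(k))
    codes, counts = np.unique(packed, return_counts=True)
    profiles = ((codes[:, None] >> np.arange(k)) & 1).astype(int)
    w = counts / counts.sum()

    # Rake the weights so every one-way margin matches exactly.
    for _ in range(max_iter):
        worst = 0.0
        for j in range(k):
            cur = float(profiles[:, j] @ w)
            if cur <= 0.0 or cur >= 1.0:
                raise ConfigurationError(
                    f"fixture degenerate in feature {schema.names[j]!r}; "
                    "increase size or reduce correlation"
                )
            on = profiles[:, j] == 1
            w = np.where(on, w * (p[j] / cur), w * ((1 - p[j]) / (1 - cur)))
            worst = max(worst, abs(cur - p[j]))
        w = w / w.sum()
        if worst < tol:
            break
    else:
        raise ConfigurationError(
            "raking did not converge; the marginal/correlation combination "
            "may be infeasible — reduce the correlation"
        )

    table = pd.DataFrame(profiles, columns=list(schema.names))
    table["weight"] = w
    return PopulationSpec(
        mode="joint-fixture", schema=schema, fixture_table=table, n_pool=size
    )


def sample_user(spec: PopulationSpec, rng: np.random.Generator) -> UserProfile:
    """Draw one profile i.i.d. from the population spec."""
    if spec.mode == "marginal-independent":
        p = np.array([spec.proportions[f] for f in spec.schema.names])
        feats = (rng.random(len(p)) < p).astype(int)
        return UserProfile(id=0, features=tuple(feats))
    tab = spec.fixture_table
    idx = rng.choice(len(tab), p=tab["weight"].to_numpy())
    feats = tab.iloc[idx][list(spec.schema.names)].to_numpy().astype(int)
    return UserProfile(id=int(idx), features=tuple(feats))


# ---------------------------------------------------------------------------
# Care-program catalog
# ---------------------------------------------------------------------------

#: Default attribute levels; the first level of each attribute is the
#: dummy-coding reference (check-in / low / short / voice A).
DEFAULT_ARM_LEVELS: dict[str, tuple[str, ...]] = {
    "content": ("check_in", "health_information", "intervention"),
    "frequency": ("low", "high"),
    "duration": ("short", "long"),
    "voice": ("A", "B"),
}

ARM_ATTRS = ("content", "frequency", "duration", "voice")


@dataclass(frozen=True)
class CareProgram:
    """One assignable care program (a bandit arm)."""

    id: int
    content: str
    frequency: str
    duration: str
    voice: str
    encoding: tuple[float, ...]
    dummy_names: tuple[str, ...]

    @property
    def attributes(self) -> dict[str, str]:
        return {
            "content": self.content,
            "frequency": self.frequency,
            "duration": self.duration,
            "voice": self.voice,
        }


def build_arm_catalog(
    levels: Mapping[str, Sequence[str]] | None = None,
) -> list[CareProgram]:
    """Full factorial catalog over the configured attribute levels.

    Arms are ordered lexicographically by (content, frequency, duration,
    voice) in the configured level order; the first level of each attribute
    is the reference cell of the dummy encoding.
    """
    lv = {a: tuple(DEFAULT_ARM_LEVELS[a]) for a in ARM_ATTRS}
    if levels is not None:
        for a, vals in levels.items():
            if a not in lv:
                raise ConfigurationError(f"unknown arm attribute {a!r}")
            if len(vals) == 0:
                raise ConfigurationError(f"arm attribute {a!r} has no levels")
            lv[a] = tuple(vals)

    dummy_names = tuple(
        f"{attr}_{level}" for attr in ARM_ATTRS for level in lv[attr][1:]
    )
    catalog: list[CareProgram] = []
    arm_id = 0
    for c in lv["content"]:
        for f in lv["frequency"]:
            for d in lv["duration"]:
                for v in lv["voice"]:
                    chosen = {"content": c, "frequency": f, "duration": d, "voice": v}
                    enc = tuple(
                        float(chosen[attr] == level)
                        for attr in ARM_ATTRS
                        for level in lv[attr][1:]
                    )
                    catalog.append(
                        CareProgram(
                            id=arm_id,
                            content=c,
                            frequency=f,
                            duration=d,
                            voice=v,
                            encoding=enc,
                            dummy_names=dummy_names,
                        )
                    )
                    arm_id += 1
    return catalog


#: Dummy names of the default catalog, in encoding order.
ARM_DUMMY_NAMES = build_arm_catalog()[0].dummy_names


# ---------------------------------------------------------------------------
# Context encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionSpec:
    """One user-feature-by-program-attribute interaction term.

    ``arm_factor`` is ``(attribute, level)``; the term's value is the product
    of the user feature and the indicator that the arm has that level.  The
    reference level of an attribute is a legal factor (its indicator is one
    minus the attribute's dummies), which keeps a preference *for* the
    reference program expressible as a single term.

    ``benefit_sign`` is the clinical direction: +1 when the pairing improves
    the outcome, −1 when it worsens it.
    """

    user_feature: str
    arm_factor: tuple[str, str]
    benefit_sign: int

    @property
    def name(self) -> str:
        return f"{self.user_feature}*{self.arm_factor[0]}_{self.arm_factor[1]}"


#: The seven modeled user-by-program interactions, shared by every outcome:
#: women and users with functional limitations benefit from longer calls,
#: rural users from more frequent calls, the old-old and the cognitively
#: impaired from check-in calls, users with chronic disease from
#: health-information calls; lonely users benefit *less* from intervention
#: calls.
DEFAULT_INTERACTIONS: tuple[InteractionSpec, ...] = (
    InteractionSpec("female", ("duration", "long"), +1),
    InteractionSpec("functional_difficulty", ("duration", "long"), +1),
    InteractionSpec("rural", ("frequency", "high"), +1),
    InteractionSpec("old_old", ("content", "check_in"), +1),
    InteractionSpec("cognition_impaired", ("content", "check_in"), +1),
    InteractionSpec("lonely", ("content", "intervention"), -1),
    InteractionSpec("multimorbidity", ("content", "health_information"), +1),
)


def _arm_indicator(arm: CareProgram, attribute: str, level: str) -> float:
    if attribute not in ARM_ATTRS:
        raise ConfigurationError(f"unknown arm attribute {attribute!r}")
    return float(arm.attributes[attribute] == level)


def context_dim(
    schema: FeatureSchema = DEFAULT_SCHEMA,
    catalog: Sequence[CareProgram] | None = None,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> int:
    """d = 1 (intercept) + user features + arm dummies + interactions."""
    n_dummies = len(catalog[0].encoding) if catalog else len(ARM_DUMMY_NAMES)
    return 1 + len(schema) + n_dummies + len(interactions)


def encode_context(
    user: UserProfile,
    arm: CareProgram,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> np.ndarray:
    """Joint context x = [1 | user features | arm dummies | interactions]."""
    for it in interactions:
        schema.index(it.user_feature)  # raises on unknown feature
    inter = [
        float(user.features[schema.index(it.user_feature)])
        * _arm_indicator(arm, *it.arm_factor)
        for it in interactions
    ]
    return np.concatenate(
        [[1.0], user.as_array(), np.asarray(arm.encoding), inter]
    )


def profile_space(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """All distinct profiles of a population with their probabilities.

    Marginal mode enumerates the full 2^k binary cube with product-of-
    marginals weights; fixture mode returns the fixture rows and weights.
    Rows are profile feature vectors ordered by the schema.
    """
    k = len(spec.schema)
    if spec.mode == "marginal-independent":
        p = np.array([spec.proportions[f] for f in spec.schema.names])
        grid = ((np.arange(2**k)[:, None] >> np.arange(k)) & 1).astype(float)
        w = np.prod(np.where(grid == 1, p, 1 - p), axis=1)
        return grid, w
    tab = spec.fixture_table
    return (
        tab[list(spec.schema.names)].to_numpy(dtype=float),
        tab["weight"].to_numpy(dtype=float),
    )


def profile_index(features: np.ndarray, k: int) -> np.ndarray:
    """Pack binary feature rows into integer codes (bit i = feature i)."""
    return (np.asarray(features, dtype=int) @ (1 << np.arange(k))).astype(int)


def build_context_tensor(
    profiles: np.ndarray,
    catalog: Sequence[CareProgram],
    schema: FeatureSchema = DEFAULT_SCHEMA,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> np.ndarray:
    """Context encodings for every (profile, arm) pair.

    Returns an array of shape (n_profiles, n_arms, d) whose [i, j] slice is
    ``encode_context`` of profile i with arm j; vectorized so the simulation
    engine can precompute all encodings once per scenario.
    """
    profiles = np.asarray(profiles, dtype=float)
    n, k = profiles.shape
    arms = np.array([a.encoding for a in catalog], dtype=float)  # (A, m)
    n_arms, m = arms.shape
    d = 1 + k + m + len(interactions)
    X = np.empty((n, n_arms, d))
    X[:, :, 0] = 1.0
    X[:, :, 1 : 1 + k] = profiles[:, None, :]
    X[:, :, 1 + k : 1 + k + m] = arms[None, :, :]
    for t, it in enumerate(interactions):
        uf = profiles[:, schema.index(it.user_feature)]
        ind = np.array([_arm_indicator(a, *it.arm_factor) for a in catalog])
        X[:, :, 1 + k + m + t] = uf[:, None] * ind[None, :]
    return X


def context_names(
    schema: FeatureSchema = DEFAULT_SCHEMA,
    catalog: Sequence[CareProgram] | None = None,
    interactions: Sequence[InteractionSpec] = DEFAULT_INTERACTIONS,
) -> list[str]:
    """Column names of the context encoding, in order."""
    dummies = catalog[0].dummy_names if catalog else ARM_DUMMY_NAMES
    return (
        ["intercept"]
        + list(schema.names)
        + list(dummies)
        + [it.name for it in interactions]
    )
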