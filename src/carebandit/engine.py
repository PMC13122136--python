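"""Simulation engine: replicated sequential assignment runs with regret.

One *scenario* is a dataset mode (``ai_call`` or ``chs``) paired with an
outcome.  A run draws a sequence of users i.i.d. from the scenario's
population, lets a policy assign one program per step, samples the realized
outcome from the ground-truth model, and records the instantaneous regret
(expected oriented benefit of the oracle arm minus that of the chosen arm —
noiseless expectations, the standard bandit regret).

Replications use common random numbers: within a replication every policy
sees the same user sequence and the same outcome-noise stream, so policy
comparisons are not blurred by sampling noise.  Thompson Sampling draws its
posterior samples from a separate, policy-private stream.  All streams
derive deterministically from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .population import (
    AI_CALL_MARGINALS,
    CHS_PROPORTIONS,
    CareProgram,
    PopulationSpec,
    build_arm_catalog,
    build_context_tensor,
    build_fixture_table,
    profile_space,
)
from .rewards import (
    OUTCOMES,
    RewardModelSpec,
    build_model_ai_call,
    build_model_random,
    expected_reward_matrix,
    oriented_expectation_matrix,
)
from .policies import DEFAULT_TS_V, LinTSPolicy, single_best_arm

__all__ = [
    "POLICIES",
    "DATASET_MODES",
    "RunConfig",
    "Scenario",
    "ExperimentResult",
    "build_scenario",
    "run_single",
    "run_experiment",
    "run_full_study",
    "compute_regret_trace",
]

POLICIES = ("cyclic", "single_best", "oracle", "lin_ts")
DATASET_MODES = ("ai_call", "chs")

# Stream tags for seed derivation (master_seed, dataset, outcome, ...).
_STREAM_USERS = 3
_STREAM_NOISE = 4
_STREAM_TS = 5
_DATASET_ID = {"ai_call": 1, "chs": 2}
_OUTCOME_ID = {"call_success": 1, "phq2": 2, "srh": 3}


@dataclass
class RunConfig:
    """Configuration of one scenario's replicated simulation."""

    dataset_mode: str
    outcome: str
    horizon: int = 3000
    replications: int = 100
    master_seed: int = 0
    policies: tuple[str, ...] = POLICIES
    ts_v: float | None = None  # None -> family default (DEFAULT_TS_V)
    ts_ridge: float = 1.0
    fixture_size: int = 100_000
    latent_correlation: float = 0.2
    # Seeds of the ground-truth data-generating mechanism.  These are part
    # of the scenario definition (the same ground truth is compared across
    # master seeds); master_seed drives only the run-time randomness.
    fixture_seed: int = 0
    model_seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset_mode not in DATASET_MODES:
            raise ValueError(f"unknown dataset mode {self.dataset_mode!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.horizon < 0 or self.replications < 1:
            raise ValueError("horizon must be >= 0 and replications >= 1")
        unknown = set(self.policies) - set(POLICIES)
        if unknown:
            raise ValueError(f"unknown policies: {sorted(unknown)}")


def _seed(config: RunConfig, *tags: int) -> np.random.SeedSequence:
    ds = _DATASET_ID[config.dataset_mode]
    oc = _OUTCOME_ID[config.outcome]
    return np.random.SeedSequence(
        entropy=(int(config.master_seed) % (2**31), ds, oc, *tags)
    )


@dataclass
class Scenario:
    """Resolved ground truth of one dataset x outcome simulation.

    Everything a run needs is precomputed over the finite profile space:
    context encodings, expected outcomes (natural and oriented scale), the
    oracle arm per profile, and the population-best arm.
    """

    config: RunConfig
    population: PopulationSpec
    model: RewardModelSpec
    catalog: list[CareProgram]
    profiles: np.ndarray           # (P, k)
    weights: np.ndarray            # (P,)
    contexts: np.ndarray           # (P, A, d)
    mu_natural: np.ndarray         # (P, A) expected outcome, natural scale
    mu_oriented: np.ndarray        # (P, A) expected oriented reward
    oracle_arm: np.ndarray         # (P,) argmax arm per profile
    oracle_oriented: np.ndarray    # (P,) best achievable oriented reward
    best_arm: int                  # population-average best arm

    @property
    def n_arms(self) -> int:
        return len(self.catalog)

    @property
    def dim(self) -> int:
        return self.contexts.shape[-1]


def build_scenario(config: RunConfig) -> Scenario:
    """Materialize population, ground-truth model and lookup tables."""
    catalog = build_arm_catalog()
    if config.dataset_mode == "ai_call":
        pop = build_fixture_table(
            AI_CALL_MARGINALS,
            correlation=config.latent_correlation,
            size=config.fixture_size,
            seed=config.fixture_seed,
        )
    else:
        pop = PopulationSpec(mode="marginal-independent", proportions=CHS_PROPORTIONS)
    profiles, weights = profile_space(pop)
    X = build_context_tensor(profiles, catalog)
    if config.dataset_mode == "ai_call":
        model = build_model_ai_call(config.outcome)
    else:
        # Mean context under systematic allocation: population-weighted over
        # profiles, uniform over arms (anchors the baseline operating point).
        mean_context = weights @ X.mean(axis=1)
        model = build_model_random(
            config.outcome,
            seed=config.model_seed,
            mean_context=mean_context,
        )
    mu_nat = expected_reward_matrix(model, X)
    mu_or = oriented_expectation_matrix(model, X)
    oracle_arm = np.argmax(mu_or, axis=1)
    oracle_or = mu_or[np.arange(len(profiles)), oracle_arm]
    best = single_best_arm(model, pop, catalog)
    return Scenario(
        config=config,
        population=pop,
        model=model,
        catalog=catalog,
        profiles=profiles,
        weights=weights,
        contexts=X,
        mu_natural=mu_nat,
        mu_oriented=mu_or,
        oracle_arm=oracle_arm,
        oracle_oriented=oracle_or,
        best_arm=best,
    )


# ---------------------------------------------------------------------------
# Single runs
# ---------------------------------------------------------------------------

def _replication_streams(
    scenario: Scenario, replication_id: int
) -> tuple[np.ndarray, np.ndarray, np.random.Generator]:
    """Common-random-number streams: user sequence, outcome noise, TS rng."""
    cfg = scenario.config
    T = cfg.horizon
    rng_users = np.random.default_rng(_seed(cfg, _STREAM_USERS, replication_id))
    rng_noise = np.random.default_rng(_seed(cfg, _STREAM_NOISE, replication_id))
    rng_ts = np.random.default_rng(_seed(cfg, _STREAM_TS, replication_id))
    user_idx = rng_users.choice(len(scenario.profiles), size=T, p=scenario.weights)
    noise = rng_noise.random(T)
    return user_idx, noise, rng_ts


def _realize(
    scenario: Scenario, pred: np.ndarray, noise: np.ndarray
) -> np.ndarray:
    """Realized integer outcomes from natural-scale expectations and shared
    uniform noise (Bernoulli threshold / probabilistic rounding)."""
    model = scenario.model
    if model.family == "binary-logistic":
        return (noise < pred).astype(np.int64)
    lo, hi = model.bounds
    base = np.floor(pred).astype(np.int64)
    value = base + (noise < (pred - base)).astype(np.int64)
    return np.minimum(value, hi)


def _run_lin_ts(
    scenario: Scenario,
    user_idx: np.ndarray,
    noise: np.ndarray,
    rng_ts: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential Thompson Sampling loop; returns (arms, realized values)."""
    cfg = scenario.config
    model = scenario.model
    lo, hi = model.bounds
    span = hi - lo
    higher = model.higher_is_better
    logistic = model.family == "binary-logistic"
    X = scenario.contexts
    mu_nat = scenario.mu_natural

    v = cfg.ts_v if cfg.ts_v is not None else DEFAULT_TS_V[model.family]
    policy = LinTSPolicy(d=scenario.dim, v=v, ridge=cfg.ts_ridge)
    T = cfg.horizon
    arms = np.empty(T, dtype=np.int64)
    values = np.empty(T, dtype=np.int64)
    for t in range(T):
        p = user_idx[t]
        decision = policy.select_from_contexts(X[p], rng_ts)
        a = decision.arm_id
        pred = mu_nat[p, a]
        if logistic:
            value = 1 if noise[t] < pred else 0
        else:
            base = math.floor(pred)
            value = base + (1 if noise[t] < pred - base else 0)
            value = min(value, hi)
        r = (value - lo) / span if higher else (hi - value) / span
        policy.update(X[p, a], r)
        arms[t] = a
        values[t] = value
    return arms, values


def run_single(
    config_or_scenario: RunConfig | Scenario,
    replication_id: int,
    policy: str,
) -> pd.DataFrame:
    """One replication of one policy; per-step interaction records.

    Columns: replication, step, user (profile-space row), arm, value
    (natural scale), expected_chosen and expected_oracle (oriented scale),
    regret (their difference, nonnegative).
    """
    scenario = (
        config_or_scenario
        if isinstance(config_or_scenario, Scenario)
        else build_scenario(config_or_scenario)
    )
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    T = scenario.config.horizon
    user_idx, noise, rng_ts = _replication_streams(scenario, replication_id)

    if policy == "lin_ts":
        arms, values = _run_lin_ts(scenario, user_idx, noise, rng_ts)
    else:
        if policy == "cyclic":
            arms = np.arange(T, dtype=np.int64) % scenario.n_arms
        elif policy == "single_best":
            arms = np.full(T, scenario.best_arm, dtype=np.int64)
        else:  # oracle
            arms = scenario.oracle_arm[user_idx]
        values = _realize(scenario, scenario.mu_natural[user_idx, arms], noise)

    expected_chosen = scenario.mu_oriented[user_idx, arms]
    expected_oracle = scenario.oracle_oriented[user_idx]
    return pd.DataFrame(
        {
            "replication": np.full(T, replication_id, dtype=np.int64),
            "step": np.arange(1, T + 1, dtype=np.int64),
            "user": user_idx.astype(np.int64),
            "arm": arms,
            "value": values,
            "expected_chosen": expected_chosen,
            "expected_oracle": expected_oracle,
            "regret": expected_oracle - expected_chosen,
        }
    )


# ---------------------------------------------------------------------------
# Replicated experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Aggregated output of :func:`run_experiment` for one scenario.

    ``summary`` — one row per (policy, replication) with the mean outcome on
    the natural scale; ``regret_trace`` — per-step cumulative regret averaged
    over replications, one column per policy; ``value_counts`` — pooled
    per-call outcome histograms per policy (basis for the statistical
    comparisons); ``records`` — full per-step records if requested.
    """

    config: RunConfig
    scenario: Scenario
    summary: pd.DataFrame
    regret_trace: pd.DataFrame
    value_counts: dict[str, dict[int, int]]
    records: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of per-replication means, one row per policy."""
        g = self.summary.groupby("policy", sort=False)["mean_outcome"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        return out.reset_index()


def run_experiment(
    config: RunConfig, keep_records: bool = False
) -> ExperimentResult:
    """Run all configured policies for R replications under common random
    numbers and aggregate outcomes and regret."""
    scenario = build_scenario(config)
    T, R = config.horizon, config.replications
    rows = []
    trace_sum = {p: np.zeros(T) for p in config.policies}
    counts: dict[str, dict[int, int]] = {p: {} for p in config.policies}
    all_records: list[pd.DataFrame] = []

    for policy in config.policies:
        for rep in range(R):
            rec = run_single(scenario, rep, policy)
            rows.append(
                {
                    "policy": policy,
                    "replication": rep,
                    "mean_outcome": float(rec["value"].mean()) if T else float("nan"),
                    "mean_regret": float(rec["regret"].mean()) if T else 0.0,
                }
            )
            trace_sum[policy] += np.cumsum(rec["regret"].to_numpy())
            vals, n = np.unique(rec["value"].to_numpy(), return_counts=True)
            for v, c in zip(vals, n):
                counts[policy][int(v)] = counts[policy].get(int(v), 0) + int(c)
            if keep_records:
                all_records.append(rec)

    summary = pd.DataFrame(rows)
    trace = pd.DataFrame(
        {p: trace_sum[p] / R for p in config.policies},
        index=pd.RangeIndex(1, T + 1, name="step"),
    )
    return ExperimentResult(
        config=config,
        scenario=scenario,
        summary=summary,
        regret_trace=trace,
        value_counts=counts,
        records=pd.concat(all_records, ignore_index=True) if keep_records else None,
    )


def run_full_study(
    master_seed: int = 0,
    horizon: int = 3000,
    replications: int = 100,
    dataset_modes: Sequence[str] = DATASET_MODES,
    outcomes: Sequence[str] = tuple(OUTCOMES),
    policies: Sequence[str] = POLICIES,
    keep_records: bool = False,
) -> dict[tuple[str, str], ExperimentResult]:
    """All dataset x outcome scenarios under one master seed."""
    results: dict[tuple[str, str], ExperimentResult] = {}
    for ds in dataset_modes:
        for oc in outcomes:
            cfg = RunConfig(
                dataset_mode=ds,
                outcome=oc,
                horizon=horizon,
                replications=replications,
                master_seed=master_seed,
                policies=tuple(policies),
            )
            results[(ds, oc)] = run_experiment(cfg, keep_records=keep_records)
    return results


def compute_regret_trace(records: pd.DataFrame) -> np.ndarray:
    """Per-step cumulative regret averaged over replications.

    ``records`` must contain replication, step and regret columns sorted by
    step within each replication.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    cum = records.sort_values(["replication", "step"]).copy()
    cum["cumulative"] = cum.groupby("replication")["regret"].cumsum()
    return cum.groupby("step")["cumulative"].mean().to_numpy()
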