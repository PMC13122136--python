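"""Allocation policies: cyclic, single-best, oracle, linear Thompson Sampling."""

import numpy as np
import pytest

from carebandit import (
    CHS_PROPORTIONS,
    DEFAULT_SCHEMA,
    CyclicPolicy,
    LinTSPolicy,
    PopulationSpec,
    UserProfile,
    build_context_tensor,
    build_model_ai_call,
    encode_context,
    expected_reward,
    lints_init,
    orient_value,
    oracle_select,
    population_average_rewards,
    single_best_arm,
)
from carebandit.policies import cyclic_select


class TestCyclic:
    def test_each_arm_chosen_equally_over_full_cycles(self, catalog):
        policy = CyclicPolicy(n_arms=24)
        chosen = [cyclic_select(policy, catalog).arm_id for _ in range(48)]
        counts = np.bincount(chosen, minlength=24)
        assert np.all(counts == 2)

    def test_single_arm_catalog(self, catalog):
        policy = CyclicPolicy(n_arms=1)
        assert all(
            cyclic_select(policy, catalog[:1]).arm_id == 0 for _ in range(5)
        )

    def test_index_wraps_around(self, catalog):
        policy = CyclicPolicy(n_arms=24, cyclic_index=23)
        assert cyclic_select(policy, catalog).arm_id == 23
        assert cyclic_select(policy, catalog).arm_id == 0

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            cyclic_select(CyclicPolicy(n_arms=1), [])


class TestSingleBest:
    def test_dominant_attribute_wins_without_interactions(self, catalog, chs_spec):
        # Only frequency matters and high frequency helps: any winning arm
        # must have high frequency; ties go to the lowest arm id.
        signs = {"frequency_high": +1}
        model = build_model_ai_call(
            "call_success", sign_table=signs, magnitude_interaction=0.0
        )
        best = single_best_arm(model, chs_spec, catalog)
        assert catalog[best].frequency == "high"
        first_high = next(a.id for a in catalog if a.frequency == "high")
        assert best == first_high

    def test_matches_bruteforce_profile_enumeration(self, catalog, chs_spec, call_model):
        # Independent oracle: explicit python loops over all 2^9 profiles.
        p = np.array([CHS_PROPORTIONS[f] for f in DEFAULT_SCHEMA.names])
        avg = np.zeros(len(catalog))
        for code in range(2**9):
            feats = tuple((code >> j) & 1 for j in range(9))
            w = float(np.prod([pj if f else 1 - pj for pj, f in zip(p, feats)]))
            user = UserProfile(0, feats)
            for a in catalog:
                mu = expected_reward(call_model, encode_context(user, a))
                avg[a.id] += w * orient_value(mu, call_model)
        np.testing.assert_allclose(
            population_average_rewards(call_model, chs_spec, catalog), avg,
            atol=1e-10,
        )
        assert single_best_arm(call_model, chs_spec, catalog) == int(np.argmax(avg))

    def test_tie_breaks_to_lowest_id(self, catalog, chs_spec, call_model):
        import dataclasses

        twin = dataclasses.replace(catalog[0], id=1)
        best = single_best_arm(call_model, chs_spec, [catalog[0], twin])
        assert best == 0


class TestOracle:
    def test_checkin_preferrers_get_checkin(self, catalog, call_model):
        feats = [0] * 9
        feats[DEFAULT_SCHEMA.index("old_old")] = 1
        feats[DEFAULT_SCHEMA.index("cognition_impaired")] = 1
        user = UserProfile(0, tuple(feats))
        arm = catalog[oracle_select(call_model, user, catalog).arm_id]
        assert arm.content == "check_in"

    def test_single_arm_catalog(self, catalog, call_model):
        user = UserProfile(0, (1,) * 9)
        assert oracle_select(call_model, user, catalog[:1]).arm_id == 0

    def test_agrees_with_bruteforce_argmax(self, catalog, call_model, rng):
        for _ in range(100):
            user = UserProfile(0, tuple(rng.integers(0, 2, size=9)))
            mus = [
                orient_value(
                    expected_reward(call_model, encode_context(user, a)), call_model
                )
                for a in catalog
            ]
            assert oracle_select(call_model, user, catalog).arm_id == int(
                np.argmax(mus)
            )


class TestLinTSState:
    def test_initial_state(self):
        p = lints_init(d=22, v=0.5, ridge=1.0)
        np.testing.assert_array_equal(p.precision, np.eye(22))
        assert not p.posterior_mean.any()
        np.testing.assert_allclose(
            0.5**2 * p.precision_inv, 0.25 * np.eye(22), atol=1e-12
        )

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            lints_init(d=5, v=0.0)
        with pytest.raises(ValueError):
            lints_init(d=5, ridge=-1.0)

    def test_zero_context_update_is_identity(self):
        p = lints_init(d=4)
        before = (p.precision.copy(), p.posterior_mean.copy())
        p.update(np.zeros(4), 0.7)
        np.testing.assert_array_equal(p.precision, before[0])
        np.testing.assert_array_equal(p.posterior_mean, before[1])

    def test_posterior_mean_equals_ridge_solution(self, rng):
        d, n, lam = 8, 60, 1.0
        X = rng.integers(0, 2, size=(n, d)).astype(float)
        beta = rng.normal(size=d)
        r = X @ beta  # noiseless
        p = lints_init(d=d, ridge=lam)
        for i in range(n):
            p.update(X[i], r[i])
        direct = np.linalg.solve(lam * np.eye(d) + X.T @ X, X.T @ r)
        np.testing.assert_allclose(p.posterior_mean, direct, atol=1e-8)

    def test_precision_determinant_nondecreasing(self, rng):
        p = lints_init(d=5)
        last = np.linalg.det(p.precision)
        for _ in range(30):
            p.update(rng.integers(0, 2, size=5).astype(float), rng.random())
            det = np.linalg.det(p.precision)
            assert det >= last - 1e-9
            last = det

    def test_inverse_tracks_precision(self, rng):
        p = lints_init(d=6, ridge=2.0)
        for _ in range(200):
            p.update(rng.integers(0, 2, size=6).astype(float), rng.random())
        np.testing.assert_allclose(
            p.precision @ p.precision_inv, np.eye(6), atol=1e-8
        )

    def test_nonfinite_inputs_rejected(self):
        p = lints_init(d=3)
        with pytest.raises(ValueError):
            p.update(np.array([1.0, np.nan, 0.0]), 1.0)
        with pytest.raises(ValueError):
            p.update(np.ones(3), float("inf"))


class TestLinTSSelection:
    def test_vanishing_v_recovers_greedy(self, catalog, call_model, rng):
        grid = ((np.arange(64)[:, None] >> np.arange(9)) & 1).astype(float)
        pad = np.zeros((64, 9))
        pad[:, :6] = grid[:, :6]
        X = build_context_tensor(pad, catalog)
        p = LinTSPolicy(d=22, v=1e-12)
        train = np.random.default_rng(0)
        for _ in range(300):
            i, j = train.integers(0, 64), train.integers(0, 24)
            p.update(X[i, j], float(train.random()))
        for i in range(10):
            greedy = int(np.argmax(X[i] @ p.posterior_mean))
            assert p.select_from_contexts(X[i], rng).arm_id == greedy

    def test_single_arm_catalog(self, rng):
        p = LinTSPolicy(d=22)
        assert p.select_from_contexts(np.ones((1, 22)), rng).arm_id == 0

    def test_early_steps_explore(self, catalog, call_model):
        user = UserProfile(0, (1, 0, 1, 0, 1, 0, 1, 0, 1))
        X = np.stack([encode_context(user, a) for a in catalog])
        arms = set()
        for s in range(200):
            p = LinTSPolicy(d=22, v=0.5)
            arms.add(p.select_from_contexts(X, np.random.default_rng(s)).arm_id)
        assert len(arms) > 1

    def test_sampled_scores_recorded_for_audit(self, rng):
        p = LinTSPolicy(d=22)
        d = p.select_from_contexts(np.eye(22)[:5], rng)
        assert d.sampled_scores is not None and d.sampled_scores.shape == (5,)


class TestParameterRecovery:
    def test_posterior_concentrates_on_truth(self, catalog):
        """5,000 observations from a known linear model recover every
        coefficient within 0.1 under the default observation noise."""
        rng = np.random.default_rng(2024)
        grid = ((np.arange(512)[:, None] >> np.arange(9)) & 1).astype(float)
        X = build_context_tensor(grid, catalog)
        beta = rng.uniform(-0.5, 0.5, size=22)
        p = lints_init(d=22, v=0.15)
        for _ in range(5000):
            i, j = rng.integers(0, 512), rng.integers(0, 24)
            r = float(X[i, j] @ beta + rng.normal(0, 0.15))
            p.update(X[i, j], r)
        assert np.max(np.abs(p.posterior_mean - beta)) < 0.1
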