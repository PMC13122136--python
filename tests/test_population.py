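"""Population generation, arm catalog and context encoding."""

import numpy as np
import pytest
from scipy import stats

from carebandit import (
    AI_CALL_MARGINALS,
    CHS_PROPORTIONS,
    DEFAULT_INTERACTIONS,
    DEFAULT_SCHEMA,
    PopulationSpec,
    UserProfile,
    build_arm_catalog,
    build_context_tensor,
    build_fixture_table,
    context_dim,
    encode_context,
    generate_profiles_marginal,
    sample_user,
)
from carebandit.population import (
    ConfigurationError,
    FeatureSchema,
    profile_space,
    profiles_to_frame,
)


class TestMarginalGeneration:
    def test_marginals_recovered_within_binomial_ci(self, chs_spec):
        n = 20_000
        profiles = generate_profiles_marginal(chs_spec, n, seed=7)
        arr = np.array([p.features for p in profiles])
        for j, name in enumerate(DEFAULT_SCHEMA.names):
            p = CHS_PROPORTIONS[name]
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(arr[:, j].mean() - p) < half, name

    def test_degenerate_proportion_zero(self):
        props = dict(CHS_PROPORTIONS)
        props["lonely"] = 0.0
        spec = PopulationSpec(mode="marginal-independent", proportions=props)
        profiles = generate_profiles_marginal(spec, 100, seed=1)
        j = DEFAULT_SCHEMA.index("lonely")
        assert all(p.features[j] == 0 for p in profiles)

    def test_features_are_uncorrelated(self):
        spec = PopulationSpec(
            mode="marginal-independent",
            proportions={n: 0.5 for n in DEFAULT_SCHEMA.names},
        )
        arr = np.array(
            [p.features for p in generate_profiles_marginal(spec, 10_000, seed=3)]
        )
        corr = np.corrcoef(arr.T)
        off = corr[~np.eye(len(DEFAULT_SCHEMA), dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_same_seed_is_bit_identical(self, chs_spec):
        a = generate_profiles_marginal(chs_spec, 500, seed=11)
        b = generate_profiles_marginal(chs_spec, 500, seed=11)
        assert [p.features for p in a] == [p.features for p in b]

    def test_missing_proportion_names_the_feature(self):
        props = dict(CHS_PROPORTIONS)
        del props["rural"]
        with pytest.raises(ConfigurationError, match="rural"):
            PopulationSpec(mode="marginal-independent", proportions=props)


class TestFixtureTable:
    def test_marginals_pinned_exactly(self, ai_call_spec):
        marg = ai_call_spec.marginals()
        for name, target in AI_CALL_MARGINALS.items():
            assert abs(marg[name] - target) < 1e-9, name

    def test_zero_correlation_recovers_independence(self):
        schema = FeatureSchema(names=("f1", "f2"))
        spec = build_fixture_table(
            {"f1": 0.3, "f2": 0.6}, correlation=0.0, size=400_000, seed=5,
            schema=schema,
        )
        tab = spec.fixture_table
        p11 = tab.loc[(tab.f1 == 1) & (tab.f2 == 1), "weight"].sum()
        assert p11 == pytest.approx(0.3 * 0.6, abs=0.01)

    def test_positive_latent_correlation_vs_copula_oracle(self):
        # Oracle: P(f1=1, f2=1) = P(Z1 > z, Z2 > z) under the bivariate
        # normal with latent correlation 0.5, computed by numerical CDF.
        schema = FeatureSchema(names=("f1", "f2"))
        p = 0.3
        rho = 0.5
        z = stats.norm.ppf(1 - p)
        oracle = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]]
        ).cdf([-z, -z])
        spec = build_fixture_table(
            {"f1": p, "f2": p}, correlation=rho, size=400_000, seed=5,
            schema=schema,
        )
        tab = spec.fixture_table
        p11 = tab.loc[(tab.f1 == 1) & (tab.f2 == 1), "weight"].sum()
        assert p11 > 0.09  # strictly above the independence product
        assert p11 == pytest.approx(oracle, abs=0.01)

    def test_invalid_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        schema = FeatureSchema(names=("a", "b", "c"))
        with pytest.raises(ConfigurationError, match="correlation"):
            build_fixture_table(
                {"a": 0.5, "b": 0.5, "c": 0.5}, correlation=bad, schema=schema
            )


class TestSampleUser:
    def test_point_mass_fixture(self):
        schema = FeatureSchema(names=("f1", "f2"))
        import pandas as pd

        table = pd.DataFrame({"f1": [1], "f2": [0], "weight": [1.0]})
        spec = PopulationSpec(mode="joint-fixture", schema=schema, fixture_table=table)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert sample_user(spec, rng).features == (1, 0)

    def test_chs_loneliness_marginal(self, chs_spec):
        rng = np.random.default_rng(42)
        n = 50_000
        j = DEFAULT_SCHEMA.index("lonely")
        hits = sum(sample_user(chs_spec, rng).features[j] for _ in range(n))
        assert hits / n == pytest.approx(0.064, abs=2.576 * np.sqrt(0.064 * 0.936 / n))

    def test_identical_seeds_identical_sequences(self, ai_call_spec):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        a = [sample_user(ai_call_spec, rng1).features for _ in range(50)]
        b = [sample_user(ai_call_spec, rng2).features for _ in range(50)]
        assert a == b


class TestArmCatalog:
    def test_default_catalog_is_full_factorial(self, catalog):
        assert len(catalog) == 24
        assert [a.id for a in catalog] == list(range(24))
        combos = {(a.content, a.frequency, a.duration, a.voice) for a in catalog}
        assert len(combos) == 24

    def test_single_level_per_attribute(self):
        arms = build_arm_catalog(
            {"content": ["check_in"], "frequency": ["low"],
             "duration": ["short"], "voice": ["A"]}
        )
        assert len(arms) == 1
        assert arms[0].encoding == ()

    def test_two_content_levels(self):
        arms = build_arm_catalog({"content": ["check_in", "health_information"]})
        assert len(arms) == 2 * 2 * 2 * 2
        # content contributes a single dummy now
        assert sum(n.startswith("content_") for n in arms[0].dummy_names) == 1

    def test_empty_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            build_arm_catalog({"voice": []})


class TestContextEncoding:
    def test_reference_cell_is_intercept_only(self, catalog):
        user = UserProfile(id=0, features=(0,) * 9)
        ref = catalog[0]  # check_in / low / short / A by lexicographic order
        assert (ref.content, ref.frequency, ref.duration, ref.voice) == (
            "check_in", "low", "short", "A",
        )
        x = encode_context(user, ref)
        assert x[0] == 1.0 and not x[1:].any()

    def test_female_long_interaction_is_active(self, catalog):
        feats = [0] * 9
        feats[DEFAULT_SCHEMA.index("female")] = 1
        user = UserProfile(id=0, features=tuple(feats))
        long_arm = next(a for a in catalog if a.duration == "long")
        x = encode_context(user, long_arm)
        names = [it.name for it in DEFAULT_INTERACTIONS]
        idx = 1 + 9 + 5 + names.index("female*duration_long")
        assert x[idx] == 1.0

    def test_dimension_is_22(self, catalog):
        assert context_dim() == 22
        user = UserProfile(id=0, features=(1,) * 9)
        assert encode_context(user, catalog[5]).shape == (22,)

    def test_encoding_is_injective_over_pairs(self, catalog):
        grid = ((np.arange(512)[:, None] >> np.arange(9)) & 1).astype(float)
        X = build_context_tensor(grid, catalog).reshape(512 * 24, 22)
        assert len(np.unique(X, axis=0)) == 512 * 24

    def test_unknown_interaction_feature_rejected(self, catalog):
        from carebandit.population import InteractionSpec

        user = UserProfile(id=0, features=(0,) * 9)
        bad = (InteractionSpec("no_such_feature", ("duration", "long"), +1),)
        with pytest.raises(ConfigurationError, match="no_such_feature"):
            encode_context(user, catalog[0], interactions=bad)


class TestProfileSpace:
    def test_marginal_space_weights_sum_to_one(self, chs_spec):
        grid, w = profile_space(chs_spec)
        assert grid.shape == (512, 9)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # weighted marginals reproduce the configured proportions exactly
        for j, name in enumerate(DEFAULT_SCHEMA.names):
            assert grid[:, j] @ w == pytest.approx(CHS_PROPORTIONS[name], abs=1e-12)

    def test_export_frame_roundtrip(self, chs_spec):
        profiles = generate_profiles_marginal(chs_spec, 10, seed=0)
        frame = profiles_to_frame(profiles)
        assert list(frame.columns) == ["id"] + list(DEFAULT_SCHEMA.names)
        assert frame.shape == (10, 10)
        assert frame.drop(columns="id").isin([0, 1]).all().all()
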