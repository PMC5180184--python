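import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aridflux.ensemble import (ModelEnsemble, ScoreVector, WeightVector,
                               biome_area_fractions, biome_correlations,
                               correlation_matrix, ensemble_weights,
                               leave_one_out_stability, model_score,
                               unweighted_ensemble, weighted_ensemble,
                               weighted_pearson)
from aridflux.errors import ValidationError
from aridflux.grid import BiomeFractions, GriddedCube, GridSpec
from aridflux.synthetic import WorldConfig, ModelSpec, build_world


def brute_force_weighted_r(x, y, w):
    """Explicit weighted-moment sums, kept independent of the library path."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
    return cov / (vx * vy) ** 0.5


class TestWeightedPearson:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            w = rng.uniform(0.1, 2.0, size=100)
            assert weighted_pearson(x, y, w) == pytest.approx(
                brute_force_weighted_r(x, y, w), abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        w = rng.uniform(0.5, 1.5, size=50)
        assert weighted_pearson(2 * x + 3, x, w) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_samples_undefined(self):
        assert np.isnan(weighted_pearson([1, 2], [2, 1], [1, 1]))


def _world_pair(seed=0, nlat=10, nlon=20, **kw):
    return build_world(WorldConfig(seed=seed, nlat=nlat, nlon=nlon, **kw))


class TestBiomeCorrelations:
    def test_proportional_fields_give_unit_r_both_modes(self, small_world):
        w = small_world
        sif = w.sif_monthly
        gpp = GriddedCube(w.grid, 2.0 * sif.values, sif.time, freq="monthly",
                          units="g C m-2 month-1", mask=sif.mask)
        for mode in ("spatial", "temporal"):
            r = biome_correlations(gpp, sif, w.biomes, mode, w.config.training_list)
            np.testing.assert_allclose(r[np.isfinite(r)], 1.0, atol=1e-10)

    def test_independent_noise_gives_null_r(self):
        # 10_000 cells, noise uncorrelated with SIF: |r| < 0.05 ~ 5/sqrt(N)
        grid = GridSpec(np.linspace(-49.5, 49.5, 100), np.linspace(-178.2, 178.2, 100))
        rng = np.random.default_rng(7)
        years = np.array([2000])
        sif = GriddedCube(grid, rng.normal(1, 0.3, (1, 100, 100)), years, units="x")
        gpp = GriddedCube(grid, rng.normal(5, 1.0, (1, 100, 100)), years, units="y")
        biomes = BiomeFractions(grid, np.ones((1, 100, 100)))
        r = biome_correlations(gpp, sif, biomes, "spatial")
        assert abs(r[0]) < 0.05

    def test_checkerboard_equals_subset_oracle(self):
        # 0/1 fractions: the fraction-weighted r must equal the plain r
        # computed on each biome's own cells (equal-area grid)
        # near-equatorial micro-grid: cos(lat) uniform to ~1e-12
        grid = GridSpec(np.linspace(-5e-5, 5e-5, 10), np.linspace(0.5, 9.5, 10))
        rng = np.random.default_rng(3)
        checker = (np.add.outer(np.arange(10), np.arange(10)) % 2).astype(float)
        biomes = BiomeFractions(grid, np.stack([checker, 1 - checker]))
        years = np.array([2000])
        g = rng.normal(10, 3, (1, 10, 10))
        s = 0.4 * g + rng.normal(0, 1, (1, 10, 10))
        gpp = GriddedCube(grid, g, years, units="g")
        sif = GriddedCube(grid, s, years, units="s")
        r = biome_correlations(gpp, sif, biomes, "spatial")
        for j, sel in enumerate([checker == 1, checker == 0]):
            expected = np.corrcoef(g[0][sel], s[0][sel])[0, 1]
            assert r[j] == pytest.approx(expected, abs=1e-10)

    def test_empty_biome_flagged_nan(self, small_world):
        w = small_world
        fr = np.zeros((2,) + w.grid.shape)
        fr[0] = 1.0  # biome 1 has no cells
        biomes = BiomeFractions(w.grid, fr)
        r = biome_correlations(w.models_monthly[w.models.names[0]], w.sif_monthly,
                               biomes, "spatial", w.config.training_list)
        assert np.isfinite(r[0]) and np.isnan(r[1])


class TestModelScore:
    def test_single_biome_identity(self):
        assert model_score(np.array([0.9]), np.array([1.0])) == pytest.approx(0.9)

    def test_two_biome_arithmetic(self):
        score = model_score(np.array([0.8, 0.4]), np.array([0.75, 0.25]))
        assert score == pytest.approx(0.7, abs=1e-12)

    def test_equal_entries_independent_of_areas(self):
        for a in ([0.5, 0.5], [0.9, 0.1], [0.2, 0.8]):
            assert model_score(np.array([0.6, 0.6]), np.array(a)) == pytest.approx(0.6)

    def test_undefined_entries_renormalised(self):
        score = model_score(np.array([0.8, np.nan]), np.array([0.5, 0.5]))
        assert score == pytest.approx(0.8)

    def test_all_undefined_is_error(self):
        with pytest.raises(ValidationError):
            model_score(np.array([np.nan, np.nan]), np.array([0.5, 0.5]))


class TestEnsembleWeights:
    def test_second_order_example(self):
        w = ensemble_weights(np.array([0.8, 0.4]), gamma=2.0)
        np.testing.assert_allclose(w, [0.8, 0.2], atol=1e-12)

    def test_equal_scores_equal_weights(self):
        for gamma in (1.0, 2.0, 4.0):
            w = ensemble_weights(np.full(5, 0.7), gamma)
            np.testing.assert_allclose(w, 0.2, atol=1e-12)

    def test_large_gamma_selects_top_model(self):
        w = ensemble_weights(np.array([0.9, 0.8, 0.7]), gamma=200.0)
        assert w[0] == pytest.approx(1.0, abs=1e-9)

    def test_negative_scores_floored(self):
        w = ensemble_weights(np.array([0.5, -0.3]), gamma=1.0)
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_all_nonpositive_is_error(self):
        with pytest.raises(ValidationError):
            ensemble_weights(np.array([-0.1, 0.0]), gamma=2.0)

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=2, max_size=14),
           st.sampled_from([1.0, 2.0, 4.0]))
    @settings(max_examples=200, deadline=None)
    def test_sum_to_one_property(self, scores, gamma):
        scores = np.asarray(scores)
        if np.all(np.maximum(scores, 0) == 0):
            return
        w = ensemble_weights(scores, gamma)
        assert abs(w.sum() - 1.0) <= 1e-12
        assert np.all(w >= 0)

    def test_monotone_in_own_score(self):
        base = np.array([0.5, 0.6, 0.7])
        for gamma in (1.0, 2.0, 4.0):
            w0 = ensemble_weights(base, gamma)[0]
            bumped = base.copy()
            bumped[0] += 0.1
            assert ensemble_weights(bumped, gamma)[0] >= w0


class TestEnsembleCubes:
    def test_selection_weight(self, small_world):
        m = small_world.models
        wv = WeightVector(list(m.names), np.eye(len(m))[0], gamma=1.0)
        ens = weighted_ensemble(m, wv)
        np.testing.assert_array_equal(ens.values, m[m.names[0]].values)

    def test_convex_bounds(self, small_world):
        m = small_world.models
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.1, 1.0, len(m))
        wv = WeightVector(list(m.names), raw / raw.sum(), gamma=1.0)
        ens = weighted_ensemble(m, wv)
        stack = np.stack([m[n].values for n in m.names])
        assert np.all(ens.values <= stack.max(axis=0) + 1e-9)
        assert np.all(ens.values >= stack.min(axis=0) - 1e-9)

    def test_unweighted_is_mean_and_permutation_invariant(self, small_world):
        m = small_world.models
        ens = unweighted_ensemble(m)
        stack = np.stack([m[n].values for n in m.names])
        np.testing.assert_allclose(ens.values, stack.mean(axis=0), rtol=1e-12)
        perm = m.subset(list(reversed(m.names)))
        np.testing.assert_allclose(unweighted_ensemble(perm).values, ens.values,
                                   rtol=1e-12)

    def test_identical_models_ensemble_identical(self, small_world):
        ref = small_world.models[small_world.models.names[0]]
        names = ["a", "b", "c"]
        m = ModelEnsemble(names, {n: ref for n in names})
        wv = ensemble_weights(ScoreVector(names, np.array([0.5, 0.7, 0.9])), 2.0)
        np.testing.assert_allclose(weighted_ensemble(m, wv).values, ref.values,
                                   rtol=1e-12)


class TestScoreRecovery:
    def test_ranking_matches_truth(self, world):
        from scipy.stats import spearmanr

        a = biome_area_fractions(world.biomes)
        cm = correlation_matrix(world.models_monthly, world.sif_monthly,
                                world.biomes, "spatial", world.config.training_list)
        scores = {n: model_score(cm.row(n), a) for n in world.models.names}
        truth_rank = {n: i for i, n in enumerate(world.quality_ranking)}
        got = [-scores[n] for n in world.models.names]
        want = [truth_rank[n] for n in world.models.names]
        assert spearmanr(got, want).statistic == pytest.approx(1.0)


class TestLeaveOneOut:
    def test_identical_models_zero_sd(self, small_world):
        ref = small_world.models[small_world.models.names[0]]
        names = ["a", "b", "c", "d"]
        m = ModelEnsemble(names, {n: ref for n in names})
        sd_w, sd_u = leave_one_out_stability(
            m, small_world.sif_monthly, small_world.biomes,
            training_years=small_world.config.training_list)
        np.testing.assert_allclose(sd_w.values, 0.0, atol=1e-9)
        np.testing.assert_allclose(sd_u.values, 0.0, atol=1e-9)

    def test_outlier_model_hurts_unweighted_more(self):
        specs = tuple(
            ModelSpec(f"model_{i:02d}", bias=1.0, noise_rel=s)
            for i, s in enumerate((0.05, 0.08, 0.1, 0.12, 3.0))
        )
        w = build_world(WorldConfig(seed=5, nlat=10, nlon=20, models=specs))
        sd_w, sd_u = leave_one_out_stability(
            w.models, w.sif_monthly, w.biomes, gamma=2.0,
            training_years=w.config.training_list)
        frac = np.mean(sd_w.values <= sd_u.values)
        assert frac >= 0.9

    def test_output_on_input_grid(self, small_world):
        sd_w, sd_u = leave_one_out_stability(
            small_world.models, small_world.sif_monthly, small_world.biomes,
            training_years=small_world.config.training_list)
        assert sd_w.grid == small_world.grid and sd_u.grid == small_world.grid
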