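"""OLS/LOOCV regression machinery and the bounded-cardinality GA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssnlet.ga import (GAConfig, Individual, crossover, init_population,
                       loocv_r2, mutate, ols_fit, run_ga)
from ssnlet.types import FCMatrix, SampleMetadata


class TestOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        beta = ols_fit(x, 2 * x + 1)
        assert beta == pytest.approx([1.0, 2.0], abs=1e-10)

    def test_constant_target(self, rng):
        x = rng.normal(size=6)
        beta = ols_fit(x, np.full(6, 3.5))
        assert beta[0] == pytest.approx(3.5, abs=1e-10)
        assert beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        design = np.column_stack([np.ones(10), X])
        expected = np.linalg.pinv(design.T @ design) @ design.T @ y
        assert ols_fit(X, y) == pytest.approx(expected, abs=1e-10)


class TestLOOCV:
    def test_noiseless_linear_recovery(self, rng):
        x = rng.normal(size=10)
        fit = loocv_r2(x, 3 * x - 2)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)
        assert fit.pcc_actual_vs_predicted == pytest.approx(1.0, abs=1e-8)

    def test_irrelevant_feature_never_scores_well(self, rng):
        worst_ok = 0.3  # pure noise should hover at or below zero
        for _ in range(5):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert loocv_r2(x, y).r_squared < worst_ok

    def test_matches_fold_by_fold_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        fit = loocv_r2(X, y)
        preds = np.empty(6)
        for q in range(6):
            mask = [i for i in range(6) if i != q]
            beta = ols_fit(X[mask], y[mask])
            preds[q] = beta[0] + X[q] @ beta[1:]
        r2 = 1 - ((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        np.testing.assert_allclose(fit.loocv_predictions, preds, atol=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_target_is_error(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            loocv_r2(rng.normal(size=5), np.ones(5))

    def test_overfit_region_reported_honestly(self, rng):
        """p >= n-1: training residuals vanish but the LOOCV score is finite
        and reflects generalization, not the perfect in-sample fit."""
        X = rng.normal(size=(8, 10))
        y = rng.normal(size=8)
        fit = loocv_r2(X, y)
        beta = ols_fit(X, y)
        train_resid = y - (beta[0] + X @ beta[1:])
        assert np.abs(train_resid).max() < 1e-8
        assert np.isfinite(fit.r_squared)
        assert fit.r_squared < 1.0


class TestOperators:
    def test_init_sizes_clamped_by_feature_count(self, rng):
        cfg = GAConfig(rng_seed=0, population_size=50)
        pop = init_population(3, cfg, rng)
        assert all(1 <= len(ind.genes) <= 3 for ind in pop)
        assert all(max(ind.genes) < 3 for ind in pop)

    def test_init_size_distribution_uniform(self):
        rng = np.random.default_rng(11)
        cfg = GAConfig(rng_seed=0, population_size=10000)
        pop = init_population(2000, cfg, rng)
        sizes = np.array([len(ind.genes) for ind in pop])
        assert sizes.min() >= 1 and sizes.max() <= 50
        observed = np.bincount(sizes, minlength=51)[1:]
        _, p = stats.chisquare(observed)
        assert p > 0.01
        for ind in pop[:200]:
            assert len(ind.genes) == len(set(ind.genes))

    def test_crossover_small_pool(self):
        rng = np.random.default_rng(2)
        cfg = GAConfig(rng_seed=0)
        a, b = Individual(frozenset({0, 1, 2})), Individual(frozenset({2, 3}))
        for _ in range(100):
            child = crossover(a, b, cfg, rng)
            assert child.genes <= {0, 1, 2, 3}
            assert 1 <= len(child.genes) <= 4

    def test_crossover_large_pool_capped_at_50(self):
        rng = np.random.default_rng(3)
        cfg = GAConfig(rng_seed=0)
        a = Individual(frozenset(range(45)))
        b = Individual(frozenset(range(40, 80)))
        for _ in range(200):
            child = crossover(a, b, cfg, rng)
            assert child.genes <= a.genes | b.genes
            assert 1 <= len(child.genes) <= 50

    @given(seed=st.integers(0, 1000),
           size_a=st.integers(1, 50), size_b=st.integers(1, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_crossover_never_violates_cardinality(self, seed, size_a, size_b):
        rng = np.random.default_rng(seed)
        cfg = GAConfig(rng_seed=0)
        pool = rng.choice(500, size=size_a + size_b, replace=False)
        a = Individual(frozenset(pool[:size_a].tolist()))
        b = Individual(frozenset(pool[size_a:].tolist()))
        child = crossover(a, b, cfg, rng)
        assert 1 <= len(child.genes) <= 50
        assert child.genes <= a.genes | b.genes

    def test_mutation_swaps_exactly_one_gene(self):
        rng = np.random.default_rng(4)
        ind = Individual(frozenset({0, 1, 2}))
        for _ in range(100):
            out = mutate(ind, 6, rng)
            assert len(out.genes) == 3
            assert len(ind.genes - out.genes) == 1
            assert len(out.genes - ind.genes) == 1
            assert (out.genes - ind.genes) <= {3, 4, 5}

    def test_mutation_forced_swap_on_singleton(self):
        rng = np.random.default_rng(5)
        out = mutate(Individual(frozenset({0})), 2, rng)
        assert out.genes == frozenset({1})

    def test_mutation_noop_when_no_unselected_features(self):
        rng = np.random.default_rng(6)
        ind = Individual(frozenset({0, 1, 2}))
        assert mutate(ind, 3, rng).genes == ind.genes


def _meta_and_fc(rng, n_genes=20, n_sf=22, planted=7):
    let = np.sort(rng.uniform(0, 250, n_sf))
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": [f"SF{i}" for i in range(n_sf)] + ["GC1"],
        "group": ["SF"] * n_sf + ["GC"],
        "let_value": list(let) + [np.nan],
        "stage": "tillering"}))
    vals = rng.lognormal(0, 0.3, size=(n_genes, n_sf))
    vals[planted] = 1 + 0.01 * let  # exact linear responder
    fc = FCMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                               columns=meta.sf_ids),
                  mode="level", layer="expression")
    return meta, fc


class TestRunGA:
    CFG = dict(population_size=30, generations=30)

    def test_finds_noiseless_planted_gene(self, rng):
        meta, fc = _meta_and_fc(rng)
        res = run_ga(fc, meta, GAConfig(rng_seed=7, **self.CFG))
        assert res.best.fitness == pytest.approx(1.0, abs=1e-6)
        assert "g7" in res.selected_gene_ids

    def test_identical_seed_gives_identical_result(self, rng):
        meta, fc = _meta_and_fc(rng)
        a = run_ga(fc, meta, GAConfig(rng_seed=3, **self.CFG))
        b = run_ga(fc, meta, GAConfig(rng_seed=3, **self.CFG))
        assert a.selected_gene_ids == b.selected_gene_ids
        assert a.best.fitness == b.best.fitness
        pd.testing.assert_frame_equal(a.fitness_history, b.fitness_history)

    def test_best_so_far_monotone_with_elitism(self, rng):
        meta, fc = _meta_and_fc(rng)
        res = run_ga(fc, meta, GAConfig(rng_seed=5, **self.CFG))
        best = res.fitness_history["best_so_far"].to_numpy()
        assert (np.diff(best) >= 0).all()
        # with elitism >= 1 the per-generation best never regresses either
        assert (np.diff(res.fitness_history["best"].to_numpy()) >= -1e-12).all()

    def test_full_elitism_freezes_population(self, rng):
        meta, fc = _meta_and_fc(rng)
        cfg = GAConfig(rng_seed=9, population_size=10, generations=15,
                       elitism=10)
        res = run_ga(fc, meta, cfg)
        best = res.fitness_history["best"].to_numpy()
        assert (best[1:] == best[1]).all()

    def test_zero_generations_returns_best_of_initial_population(self, rng):
        meta, fc = _meta_and_fc(rng)
        cfg = GAConfig(rng_seed=2, population_size=20, generations=0)
        res = run_ga(fc, meta, cfg)
        assert len(res.fitness_history) == 1
        assert res.best.fitness == res.fitness_history["best"].iloc[0]
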