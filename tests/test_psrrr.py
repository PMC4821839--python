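import numpy as np
import pytest

from conftest import make_groups, standardized
from oracles import group_lasso_pg
from pathrider import genio, phenotype, psrrr, simulate
from pathrider.psrrr import (
    PsRRRConfig,
    fit_rank1,
    group_lasso_solve,
    initial_weights,
    kkt_residual,
    lambda_max,
    rank_pathways,
    stability_select,
    tune_weights,
)


def _instance(rng, n=30, sizes=(4, 4, 4)):
    groups = make_groups(list(sizes))
    X = standardized(rng.standard_normal((n, groups.n_expanded)))
    beta = np.zeros(groups.n_expanded)
    beta[groups.group_index_lists[0]] = rng.standard_normal(sizes[0])
    y = X @ beta + 0.5 * rng.standard_normal(n)
    y -= y.mean()
    return X, y, groups


class TestGroupLassoSolve:
    def test_zero_at_lambda_max(self, rng):
        X, y, groups = _instance(rng)
        w = initial_weights(groups)
        lam = lambda_max(X, y, groups, w)
        b = group_lasso_solve(X, y, groups, w, lam * 1.000001)
        assert not b.any()

    def test_least_squares_at_zero_penalty(self, rng):
        X, y, groups = _instance(rng)
        w = initial_weights(groups)
        b = group_lasso_solve(X, y, groups, w, 0.0, tol=1e-14, max_iter=50000)
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(b, expected, atol=1e-8)

    def test_matches_proximal_gradient_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(2, 6, size=3)
            groups = make_groups(sizes.tolist())
            n, p = 30, groups.n_expanded
            X = standardized(rng.standard_normal((n, p)))
            beta = rng.standard_normal(p) * rng.binomial(1, 0.5, p)
            y = X @ beta + rng.standard_normal(n)
            y -= y.mean()
            w = initial_weights(groups)
            lam = 0.3 * lambda_max(X, y, groups, w)
            ours = group_lasso_solve(X, y, groups, w, lam, tol=1e-14, max_iter=100000)
            ref = group_lasso_pg(
                X, y, groups.group_index_lists, w.weights, lam
            )
            assert np.abs(ours - ref).max() < 1e-6

    def test_kkt_certificate(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y, groups = _instance(rng, sizes=tuple(rng.integers(2, 7, 4)))
            w = initial_weights(groups)
            lam = rng.uniform(0.1, 0.9) * lambda_max(X, y, groups, w)
            b = group_lasso_solve(X, y, groups, w, lam, tol=1e-14, max_iter=100000)
            assert kkt_residual(X, y, groups, w, lam, b) < 1e-6

    def test_monotone_sparsity_in_lambda(self, rng):
        X, y, groups = _instance(rng, sizes=(3, 3, 3, 3))
        w = initial_weights(groups)
        lmax = lambda_max(X, y, groups, w)
        n_active = []
        for frac in np.linspace(0.05, 1.0, 10):
            b = group_lasso_solve(X, y, groups, w, frac * lmax)
            n_active.append(
                sum(np.linalg.norm(b[idx]) > 0 for idx in groups.group_index_lists)
            )
        assert all(a >= b for a, b in zip(n_active, n_active[1:]))

    def test_scale_equivariance(self, rng):
        X, y, groups = _instance(rng)
        w = initial_weights(groups)
        lam = 0.4 * lambda_max(X, y, groups, w)
        b1 = group_lasso_solve(X, y, groups, w, lam, tol=1e-14)
        c = 3.7
        b2 = group_lasso_solve(X, c * y, groups, w, c * lam, tol=1e-14)
        np.testing.assert_allclose(b2, c * b1, atol=1e-6)

    def test_duplicated_columns_handled(self, rng):
        # overlapping-pathway expansion produces exactly duplicated columns
        groups = genio.PathwayGroups(
            ["a", "b"],
            [np.arange(0, 4), np.arange(4, 8)],
            np.array([0, 1, 2, 3, 2, 3, 4, 5]),
            6,
        )
        X0 = standardized(rng.standard_normal((40, 6)))
        X = groups.expand_design(X0)
        y = X0 @ np.array([1.0, -1, 0.5, 0, 0, 0]) + 0.1 * rng.standard_normal(40)
        y -= y.mean()
        w = initial_weights(groups)
        lam = 0.3 * lambda_max(X, y, groups, w)
        b = group_lasso_solve(X, y, groups, w, lam, tol=1e-13, max_iter=50000)
        assert kkt_residual(X, y, groups, w, lam, b) < 1e-6
        collapsed = groups.collapse_coefficients(b)
        assert collapsed.shape == (6,)

    def test_non_finite_rejected(self, rng):
        X, y, groups = _instance(rng)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            group_lasso_solve(X, y, groups, initial_weights(groups), 1.0)


class TestFitRank1:
    def test_single_column_equals_group_lasso(self, rng):
        X, y, groups = _instance(rng)
        w = initial_weights(groups)
        cfg = PsRRRConfig(lambda_fraction=0.5)
        fit = fit_rank1(X, y[:, None], groups, w, cfg)
        lam = 0.5 * lambda_max(X, y, groups, w)
        b = group_lasso_solve(X, y, groups, w, lam)
        np.testing.assert_allclose(fit.snp_coefficients, b, atol=1e-6)
        np.testing.assert_allclose(fit.trait_loadings, [1.0])

    def test_recovers_causal_pathway_noiseless(self):
        cfg = simulate.SimulationConfig(
            n_subjects=150, n_snps=200, n_genes=20, n_pathways=4,
            pathway_size_range=(3, 6), heritability=0.95, seed=8,
        )
        G, _, _ = simulate.simulate_genotypes(cfg)
        ann, _, _ = simulate.simulate_annotation(cfg)
        Y, cov, truth = simulate.simulate_phenotype(G, ann, cfg)
        Yr = phenotype.residualize(Y, cov, ["ga", "pma"])
        gene_sets = {}
        for g, pws in ann.gene_to_pathways.items():
            for pid in pws:
                gene_sets.setdefault(pid, []).append(g)
        groups = genio.build_groups(ann, gene_sets, G.snp_ids)
        Xe = groups.expand_design(standardized(G.dosage))
        fit = fit_rank1(
            Xe, Yr.values - Yr.values.mean(0), groups, initial_weights(groups),
            PsRRRConfig(lambda_fraction=0.5),
        )
        assert fit.selected_pathways == set(truth.causal_pathway_ids)

    def test_objective_trace_non_increasing(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y, groups = _instance(rng, n=40)
            Y = np.column_stack([y, rng.standard_normal(40)])
            Y -= Y.mean(0)
            fit = fit_rank1(
                X, Y, groups, initial_weights(groups),
                PsRRRConfig(lambda_fraction=0.7),
            )
            tr = fit.objective_trace
            assert all(a >= b - 1e-9 for a, b in zip(tr, tr[1:]))

    def test_unit_norm_loadings(self, rng):
        X, y, groups = _instance(rng, n=50)
        Y = np.column_stack([y, 0.5 * y + rng.standard_normal(50)])
        Y -= Y.mean(0)
        fit = fit_rank1(
            X, Y, groups, initial_weights(groups), PsRRRConfig(lambda_fraction=0.5)
        )
        if fit.selected_pathways:
            assert np.linalg.norm(fit.trait_loadings) == pytest.approx(1.0)


class TestTuneWeights:
    def test_zero_iterations_gives_sqrt_sizes(self, rng):
        groups = make_groups([3, 5, 7])
        X = standardized(rng.standard_normal((40, groups.n_expanded)))
        Y = rng.standard_normal((40, 3))
        w = tune_weights(X, Y, groups, PsRRRConfig(tuning_iterations=0))
        np.testing.assert_array_equal(w.weights, np.sqrt([3, 5, 7]))
        assert w.provenance == "initial"

    def test_null_frequency_ratio_moves_toward_one(self):
        # sizes 10 vs 100: tuning should equalize null selection rates
        ratios = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            groups = make_groups([10, 100])
            n = 80
            X = standardized(rng.standard_normal((n, groups.n_expanded)))
            Y = rng.standard_normal((n, 4))
            Y -= Y.mean(0)
            cfg = PsRRRConfig(
                tuning_iterations=10, tuning_fits_per_iteration=60, seed=seed
            )
            w0 = initial_weights(groups)
            wt = tune_weights(X, Y, groups, cfg)
            meas_cfg = PsRRRConfig(seed=seed)

            def null_freq(weights, r):
                counts = np.zeros(2)
                for _ in range(150):
                    Yn = Y[r.permutation(n)]
                    fit = psrrr.fit_rank1(X, Yn, groups, weights, meas_cfg)
                    for g in fit.selected_pathways:
                        counts[groups.group_ids.index(g)] += 1
                return (counts + 0.5) / 150

            f0 = null_freq(w0, np.random.default_rng(seed + 50))
            ft = null_freq(wt, np.random.default_rng(seed + 50))
            ratios.append((abs(np.log(f0[1] / f0[0])), abs(np.log(ft[1] / ft[0]))))
        # on average the imbalance shrinks
        before = np.mean([r[0] for r in ratios])
        after = np.mean([r[1] for r in ratios])
        assert after < before

    def test_exchangeable_pathways_keep_similar_weights(self, rng):
        groups = make_groups([8, 8, 8, 8])
        n = 60
        X = standardized(rng.standard_normal((n, groups.n_expanded)))
        Y = rng.standard_normal((n, 3))
        cfg = PsRRRConfig(tuning_iterations=5, tuning_fits_per_iteration=50, seed=0)
        w = tune_weights(X, Y, groups, cfg)
        assert w.weights.max() / w.weights.min() < 1.2
        assert w.provenance == "tuned"
        assert len(w.tuning_history) == 5


@pytest.fixture(scope="module")
def planted():
    cfg = simulate.SimulationConfig(
        n_subjects=200, n_snps=300, n_genes=30, n_pathways=6,
        pathway_size_range=(4, 6), heritability=0.5, seed=21,
    )
    G, _, _ = simulate.simulate_genotypes(cfg)
    ann, _, _ = simulate.simulate_annotation(cfg)
    Y, cov, truth = simulate.simulate_phenotype(G, ann, cfg)
    Yr = phenotype.residualize(Y, cov, ["ga", "pma"])
    gene_sets = {}
    for g, pws in ann.gene_to_pathways.items():
        for pid in pws:
            gene_sets.setdefault(pid, []).append(g)
    groups = genio.build_groups(ann, gene_sets, G.snp_ids)
    Xe = groups.expand_design(standardized(G.dosage))
    Yc = Yr.values - Yr.values.mean(0)
    return Xe, Yc, groups, truth


class TestStabilitySelect:
    def test_seeded_determinism(self, planted):
        Xe, Yc, groups, truth = planted
        cfg = PsRRRConfig(n_subsamples=10, seed=3)
        w = initial_weights(groups)
        a = stability_select(Xe, Yc, groups, w, cfg)
        b = stability_select(Xe, Yc, groups, w, cfg)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_causal_pathway_dominates(self, planted):
        Xe, Yc, groups, truth = planted
        cfg = PsRRRConfig(n_subsamples=50, seed=4)
        emp = stability_select(Xe, Yc, groups, initial_weights(groups), cfg)
        causal = truth.causal_pathway_ids[0]
        ci = emp.group_ids.index(causal)
        assert emp.frequencies[ci] == emp.frequencies.max()
        assert emp.frequencies[ci] >= 0.8

    def test_null_mode_destroys_signal(self, planted):
        Xe, Yc, groups, truth = planted
        cfg = PsRRRConfig(n_subsamples=50, seed=4)
        null = stability_select(
            Xe, Yc, groups, initial_weights(groups), cfg, null_mode=True
        )
        ci = null.group_ids.index(truth.causal_pathway_ids[0])
        assert null.frequencies[ci] < 0.3

    def test_subsample_too_small(self, rng):
        groups = make_groups([3, 3])
        X = standardized(rng.standard_normal((12, 6)))
        Y = rng.standard_normal((12, 2))
        with pytest.raises(ValueError, match="too small"):
            stability_select(
                X, Y, groups, initial_weights(groups),
                PsRRRConfig(subsample_fraction=0.5),
            )


class TestRankPathways:
    @staticmethod
    def _sf(ids, freqs, corrs):
        return psrrr.SelectionFrequencies(
            group_ids=list(ids),
            frequencies=np.array(freqs, dtype=float),
            mean_abs_correlation=np.array(corrs, dtype=float),
            n_subsamples=10,
        )

    def test_frequency_then_correlation(self):
        emp = self._sf(["a", "b", "c"], [0.3, 0.2, 0.2], [np.nan, 0.5, 0.7])
        null = self._sf(["a", "b", "c"], [0.1, 0.1, 0.1], [0, 0, 0])
        r = rank_pathways(emp, null)
        assert r.group_ids == ["a", "c", "b"]

    def test_full_tie_lexicographic(self):
        emp = self._sf(["z", "a", "m"], [0.2, 0.2, 0.2], [0.5, 0.5, 0.5])
        null = self._sf(["z", "a", "m"], [0.0, 0.0, 0.0], [0, 0, 0])
        assert rank_pathways(emp, null).group_ids == ["a", "m", "z"]

    def test_invariant_to_input_order(self):
        emp1 = self._sf(["a", "b"], [0.1, 0.4], [0.2, 0.3])
        emp2 = self._sf(["b", "a"], [0.4, 0.1], [0.3, 0.2])
        null = self._sf(["a", "b"], [0.05, 0.07], [0, 0])
        assert rank_pathways(emp1, null).group_ids == rank_pathways(emp2, null).group_ids

    def test_mismatched_universe(self):
        emp = self._sf(["a"], [0.1], [0.1])
        null = self._sf(["b"], [0.1], [0.1])
        with pytest.raises(ValueError):
            rank_pathways(emp, null)

    def test_null_frequencies_attached(self):
        emp = self._sf(["a", "b"], [0.5, 0.2], [0.9, 0.1])
        null = self._sf(["b", "a"], [0.07, 0.03], [0, 0])
        r = rank_pathways(emp, null)
        np.testing.assert_allclose(r.null_frequencies, [0.03, 0.07])
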