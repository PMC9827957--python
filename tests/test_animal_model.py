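"""Animal-model fitting: scaling, summaries, and estimation checks."""

import numpy as np
import pandas as pd
import pytest

from evoflor import (
    ModelSpec,
    correlation_matrix,
    fit_animal_model,
    mean_scale,
    posterior_summary,
    simulate_breeding_experiment,
    dalechampia_truth,
)
from evoflor.pedigree import RelatednessMatrix
from evoflor._gibbs import Term, run_gibbs, run_animal_gibbs, sample_inv_wishart


@pytest.fixture(scope="module")
def small_fit():
    """One quick fit on a reduced design, reused across assertions."""
    truth = dalechampia_truth(n_blocks=4, dropout=0.0)
    sim = simulate_breeding_experiment(truth, seed=3)
    spec = ModelSpec(n_iter=600, burnin=200, thin=4, seed=9)
    return sim, fit_animal_model(sim.phenotypes, sim.A, spec)


class TestMeanScale:
    def test_scaling_identity(self):
        df = pd.DataFrame({"GAD": [2.0, 4.0], "GSD": [1.0, 1.0], "ASD": [3.0, 3.0]})
        scaled, means = mean_scale(df)
        np.testing.assert_allclose(scaled["GAD"], [2 / 3, 4 / 3])
        assert means["GAD"] == 3.0
        assert scaled["GAD"].mean() == pytest.approx(1.0)

    def test_variance_scales_by_squared_mean(self, rng):
        x = rng.gamma(5.0, 2.0, size=200)
        df = pd.DataFrame({"GAD": x, "GSD": x + 1, "ASD": x + 2})
        scaled, means = mean_scale(df)
        assert scaled["GAD"].var() == pytest.approx(x.var(ddof=1) / x.mean() ** 2)

    def test_nonpositive_mean_rejected(self):
        df = pd.DataFrame({"GAD": [-1.0, 1.0], "GSD": [1, 1], "ASD": [1, 1]})
        with pytest.raises(ValueError, match="mean-scale"):
            mean_scale(df)


class TestCorrelationMatrix:
    def test_published_correlations(self, published_G):
        r = correlation_matrix(published_G)
        assert round(r[0, 1], 2) == 0.34
        assert round(r[0, 2], 2) == 0.19
        assert round(r[1, 2], 2) == -0.26
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_diagonal_input_gives_identity(self):
        np.testing.assert_allclose(correlation_matrix(np.diag([2.0, 5.0])), np.eye(2))

    def test_zero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            correlation_matrix(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestPosteriorSummary:
    def test_constant_draws_zero_width(self, published_G):
        draws = np.repeat(published_G[None], 150, axis=0)
        tab = posterior_summary(draws)
        assert ((tab["upper"] - tab["lower"]).abs() < 1e-12).all()
        v = tab[(tab.kind == "variance") & (tab.row == "t2")]
        assert v["mean"].iloc[0] == pytest.approx(6.567)

    def test_quantile_interval_matches_sorting_oracle(self, rng):
        x = rng.gamma(4.0, 0.5, size=1000)
        draws = np.zeros((1000, 2, 2))
        draws[:, 0, 0] = x
        draws[:, 1, 1] = 1.0
        tab = posterior_summary(draws, traits=["a", "b"])
        row = tab[(tab.kind == "variance") & (tab.row == "a")].iloc[0]
        xs = np.sort(x)
        assert row["lower"] == pytest.approx(np.quantile(xs, 0.025))
        assert row["upper"] == pytest.approx(np.quantile(xs, 0.975))

    def test_per_draw_correlation_not_correlation_of_mean(self):
        # three hand-checkable draws where averaging order matters
        draws = np.array(
            [
                [[1.0, 0.9], [0.9, 1.0]],
                [[4.0, -0.8], [-0.8, 1.0]],
                [[1.0, 0.0], [0.0, 4.0]],
            ]
        ).repeat(50, axis=0)
        tab = posterior_summary(draws, traits=["x", "y"])
        r = tab[tab.kind == "correlation"]["mean"].iloc[0]
        per_draw = np.mean([0.9 / 1.0, -0.8 / 2.0, 0.0])
        of_mean = (0.9 - 0.8 + 0) / 3 / np.sqrt(2.0 * 2.0)
        assert r == pytest.approx(per_draw)
        assert abs(r - of_mean) > 0.1  # the orders genuinely differ here

    def test_too_few_draws_rejected(self, published_G):
        with pytest.raises(ValueError, match="100"):
            posterior_summary(np.repeat(published_G[None], 50, axis=0))


class TestFitValidation:
    def test_plant_missing_from_A_rejected(self, small_fit):
        sim, _ = small_fit
        bad = sim.phenotypes.copy()
        bad.loc[0, "plant"] = "GHOST"
        with pytest.raises(ValueError, match="absent"):
            fit_animal_model(bad, sim.A, ModelSpec(n_iter=20, burnin=10, seed=0))

    def test_non_psd_A_rejected(self, small_fit):
        sim, _ = small_fit
        bad_A = RelatednessMatrix(sim.A.ids, sim.A.values - 2.0 * np.eye(len(sim.A.ids)))
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_animal_model(sim.phenotypes, bad_A, ModelSpec(n_iter=20, burnin=10))

    def test_invalid_chain_settings(self):
        with pytest.raises(ValueError, match="burn-in"):
            ModelSpec(n_iter=100, burnin=100)
        with pytest.raises(ValueError, match="thinning"):
            ModelSpec(thin=0)


class TestFitBehaviour:
    def test_draw_shapes_and_positive_definiteness(self, small_fit):
        _, post = small_fit
        assert post.n_draws == (600 - 200) // 4
        for name in ("G", "B", "D_date", "Q"):
            d = post.draws[name]
            assert d.shape == (post.n_draws, 3, 3)
            eigs = np.linalg.eigvalsh(d)
            assert (eigs[:, 0] > 0).all()

    def test_same_seed_identical_posterior(self, small_fit):
        sim, post = small_fit
        again = fit_animal_model(
            sim.phenotypes, sim.A, ModelSpec(n_iter=600, burnin=200, thin=4, seed=9)
        )
        np.testing.assert_array_equal(post.draws["G"], again.draws["G"])
        np.testing.assert_array_equal(post.mu, again.mu)

    def test_row_shuffle_invariance(self, small_fit):
        # canonical internal ordering makes the fit independent of row order
        sim, post = small_fit
        shuffled = sim.phenotypes.sample(frac=1.0, random_state=1)
        again = fit_animal_model(
            shuffled, sim.A, ModelSpec(n_iter=600, burnin=200, thin=4, seed=9)
        )
        np.testing.assert_array_equal(post.draws["G"], again.draws["G"])

    def test_constant_phenotypes_shrink_to_prior_floor(self, small_fit):
        sim, _ = small_fit
        flat = sim.phenotypes.copy()
        flat[["GAD", "GSD", "ASD"]] = [5.0, 5.2, 2.8]
        post = fit_animal_model(
            flat, sim.A, ModelSpec(n_iter=400, burnin=150, thin=2, seed=4)
        )
        for name in ("G", "B", "Q"):
            assert np.abs(post.draws[name]).max() < 1e-4  # percent units

    def test_missing_values_handled(self, small_fit):
        sim, _ = small_fit
        holey = sim.phenotypes.copy()
        holey.loc[holey.index[::7], "GSD"] = np.nan
        post = fit_animal_model(
            holey, sim.A, ModelSpec(n_iter=400, burnin=150, thin=2, seed=5)
        )
        assert np.isfinite(post.draws["G"]).all()


def test_bias_small_at_4x_design_scale():
    """With 4x the canonical design (40 blocks), posterior means of all G
    elements land within 20% of the largest trait evolvability of truth."""
    truth = dalechampia_truth(n_blocks=40)
    sim = simulate_breeding_experiment(truth, seed=7)
    post = fit_animal_model(
        sim.phenotypes, sim.A, ModelSpec(n_iter=3000, burnin=1000, thin=4, seed=11)
    )
    bias = np.abs(post.component_mean("G") - truth.G)
    assert bias.max() < 0.2 * truth.G[2, 2]


class TestAgainstOracles:
    def test_single_trait_identity_A_matches_anova(self, rng):
        """One random term, A = I: posterior mean of the between-group
        variance agrees with the one-way ANOVA moment estimator."""
        ng, m = 200, 5
        a = rng.normal(0, np.sqrt(2.0), ng)
        y = (a[:, None] + rng.normal(0, np.sqrt(3.0), (ng, m))).ravel()
        levels = np.repeat(np.arange(ng), m)
        res = run_gibbs(
            y[:, None], [Term("a", levels, ng)],
            n_iter=4000, burnin=1000, thin=4, seed=3,
        )
        Y = y.reshape(ng, m)
        msb = m * np.var(Y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(Y, axis=1, ddof=1))
        anova_va = (msb - msw) / m
        gibbs_va = res.cov["a"][:, 0, 0].mean()
        assert gibbs_va == pytest.approx(anova_va, rel=0.10)
        assert res.cov["residual"][:, 0, 0].mean() == pytest.approx(msw, rel=0.10)

    def test_inverse_wishart_sampler_matches_scipy_moments(self, rng):
        df, S = 12.0, np.array([[4.0, 1.0], [1.0, 3.0]])
        draws = np.stack(
            [sample_inv_wishart(rng, df, S) for _ in range(4000)]
        )
        expected = S / (df - 2 - 1)  # IW mean, k=2
        np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.08)

    def test_collapsed_sampler_recovers_known_variances(self, rng):
        """k=1 diallel with known (va, vb, ve): the collapsed sampler's
        posterior means land near a method-of-moments oracle."""
        from evoflor.pedigree import (
            CrossRecord, additive_relationship_matrix, build_pedigree,
            generate_block_diallel,
        )
        crosses = generate_block_diallel(6, 2)
        recs = []
        for cr in crosses:
            for o in (1, 2):
                recs.append(
                    CrossRecord(f"{cr.offspring_id}_O{o}", cr.sire_id, cr.dam_id)
                )
        ped = build_pedigree(recs)
        A = additive_relationship_matrix(ped)
        n_ind = len(ped.ids)
        La = np.linalg.cholesky(A.values)
        a = La @ rng.normal(0, np.sqrt(2.0), n_ind)
        b = rng.normal(0, 1.0, n_ind)
        oidx = ped.index_of([r.offspring_id for r in recs])
        levels = np.repeat(oidx, 2)
        y = 3.0 + a[levels] + b[levels] + rng.normal(0, np.sqrt(1.5), len(levels))
        res = run_animal_gibbs(
            y[:, None], levels, np.full(len(y), -1), A.values,
            n_iter=6000, burnin=1500, thin=5, seed=8,
        )
        ve = res.cov["residual"][:, 0, 0]
        # residual variance is well identified by within-plant contrasts
        contrasts = y.reshape(-1, 2)
        msw = np.mean(np.var(contrasts, axis=1, ddof=1))
        assert ve.mean() == pytest.approx(msw, rel=0.2)
        # total plant-level variance is identified even when the split is not
        total = res.cov["G"][:, 0, 0] + res.cov["B"][:, 0, 0]
        plant_means = contrasts.mean(axis=1)
        mom_total = np.var(plant_means, ddof=1) - msw / 2
        assert total.mean() == pytest.approx(mom_total, rel=0.5)
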