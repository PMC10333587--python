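"""The three GEBV predictors, with simulation-recovery checks for the
Bayesian marker model."""

import numpy as np
import pytest

from rrsim.genome_core import DosageMatrices, Population, compute_dosages
from rrsim.phenotype import PhenotypeRecord, simulate_phenotypes
from rrsim.prediction import (
    BayesianMarkerModel,
    MCMCConfig,
    MarkerEffectResults,
    fit_bayesian,
    predict_bayesian,
    predict_perfect,
    predict_phenotypic,
)


def simulate_training(
    n, L, h2, seed, maf=(0.1, 0.5)
):
    """Data drawn from the marker model itself: p = mu + g a + d b + eps."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(*maf, size=L)
    geno = (rng.random((n, L, 2)) < freq[None, :, None]).astype(np.int8)
    dos = compute_dosages(Population(genotypes=geno))
    a = rng.normal(0, 1.0, L) * (rng.random(L) < 0.3)
    b = rng.normal(0, 0.5, L) * (rng.random(L) < 0.2)
    v = dos.g @ a + dos.d @ b
    var_v = np.var(v, ddof=1)
    e = rng.normal(0, np.sqrt(var_v * (1 - h2) / h2), n)
    return dos, v, v + e, rng


class TestPerfectAndPhenotypic:
    def test_perfect_is_bitwise_truth(self, toy_arch, toy_individual_full):
        v = predict_perfect(toy_individual_full, toy_arch, "opaque")
        assert v.v[0] == pytest.approx(8.5)
        v_t = predict_perfect(toy_individual_full, toy_arch, "transparent")
        assert v_t.v[0] == pytest.approx(5.5)  # hidden loci ignored

    def test_phenotypic_returns_phenotype(self, desk_study, rng):
        rec = simulate_phenotypes(desk_study.founders, desk_study.architecture, 0.5, "opaque", rng)
        np.testing.assert_array_equal(predict_phenotypic(rec).v, rec.p)

    def test_phenotypic_equals_perfect_at_full_heritability(self, desk_study, rng):
        rec = simulate_phenotypes(desk_study.founders, desk_study.architecture, 1.0, "opaque", rng)
        truth = predict_perfect(desk_study.founders, desk_study.architecture, "opaque")
        np.testing.assert_array_equal(predict_phenotypic(rec).v, truth.v)

    def test_phenotypic_rejects_missing_values(self, desk_study, rng):
        rec = simulate_phenotypes(desk_study.founders, desk_study.architecture, 0.5, "opaque", rng)
        rec.p[0] = np.nan
        with pytest.raises(ValueError):
            predict_phenotypic(rec)

    def test_ranking_accuracy_degrades_with_noise(self):
        """Correlation with truth is lower at H2=0.2 than at H2=0.8 in most
        replicates."""
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            _, v, p_hi, _ = simulate_training(150, 30, 0.8, seed)
            _, v2, p_lo, _ = simulate_training(150, 30, 0.2, seed)
            hi = np.corrcoef(p_hi, v)[0, 1]
            lo = np.corrcoef(p_lo, v2)[0, 1]
            wins += hi > lo
        assert wins >= int(0.8 * n_rep)


class TestBayesianModel:
    def test_constant_phenotypes_give_null_model(self, rng):
        g = rng.integers(0, 3, size=(20, 5)).astype(float)
        dos = DosageMatrices(g=g, d=(g == 1).astype(float))
        with pytest.warns(UserWarning, match="null model"):
            res = fit_bayesian(dos, np.full(20, 3.3))
        assert res.null_model
        assert res.mu_hat == pytest.approx(3.3)
        np.testing.assert_array_equal(res.additive_hat, np.zeros(5))
        np.testing.assert_allclose(predict_bayesian(res, dos).v, np.full(20, 3.3))

    def test_hand_built_model_scores_linearly(self):
        res = MarkerEffectResults(
            mu_hat=1.0,
            additive_hat=np.array([1.0, 0.0]),
            dominance_hat=np.array([0.0, 2.0]),
            variance_hats={},
            mcmc=MCMCConfig(),
            n_obs=1,
        )
        dos = DosageMatrices(g=np.array([[2, 1]]), d=np.array([[0, 1]]))
        assert res.predict(dos).v[0] == pytest.approx(1 + 2 + 2)

    def test_width_mismatch_rejected(self):
        res = MarkerEffectResults(
            mu_hat=0.0,
            additive_hat=np.zeros(3),
            dominance_hat=np.zeros(3),
            variance_hats={},
            mcmc=MCMCConfig(),
            n_obs=1,
        )
        with pytest.raises(ValueError, match="width"):
            res.predict(DosageMatrices(g=np.zeros((1, 2)), d=np.zeros((1, 2))))

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(prior="bayes_z")

    @pytest.mark.parametrize("prior", ["bayes_a", "common"])
    def test_recovery_on_simulated_data(self, prior):
        """Both prior regimes recover predictive accuracy on held-out lines."""
        dos, v, p, _ = simulate_training(350, 60, 0.9, seed=11)
        train, test = slice(0, 250), slice(250, 350)
        model = BayesianMarkerModel(
            p[train], DosageMatrices(g=dos.g[train], d=dos.d[train])
        ).fit(MCMCConfig(iterations=1200, burn_in=400, thin=2, seed=2, prior=prior))
        v_hat = model.predict(DosageMatrices(g=dos.g[test], d=dos.d[test])).v
        assert np.corrcoef(v_hat, v[test])[0, 1] >= 0.8

    def test_permuted_phenotypes_destroy_recovery(self):
        dos, v, p, rng = simulate_training(350, 60, 0.9, seed=11)
        p_perm = rng.permutation(p[:250])
        model = BayesianMarkerModel(
            p_perm, DosageMatrices(g=dos.g[:250], d=dos.d[:250])
        ).fit(MCMCConfig(iterations=1200, burn_in=400, thin=2, seed=2))
        v_hat = model.predict(DosageMatrices(g=dos.g[250:], d=dos.d[250:])).v
        assert abs(np.corrcoef(v_hat, v[250:])[0, 1]) <= 0.3

    def test_training_fit_reproduces_fitted_values(self):
        dos, _, p, _ = simulate_training(120, 20, 0.9, seed=4)
        model = fit_bayesian(dos, p, MCMCConfig(iterations=600, burn_in=200, thin=2, seed=1))
        direct = model.mu_hat + dos.g @ model.additive_hat + dos.d @ model.dominance_hat
        np.testing.assert_allclose(model.predict(dos).v, direct, atol=1e-12)

    def test_small_prior_scale_shrinks_effects(self):
        """Posterior means shrink monotonically as the prior scale shrinks."""
        dos, _, p, _ = simulate_training(150, 10, 0.9, seed=8)
        norms = []
        for scale in (1.0, 1e-3, 1e-6):
            model = fit_bayesian(
                dos,
                p,
                MCMCConfig(
                    iterations=800, burn_in=300, thin=2, seed=3,
                    prior="common", scale_a=scale, scale_d=scale,
                ),
            )
            norms.append(np.abs(model.additive_hat).sum())
        assert norms[0] > norms[1] > norms[2]

    def test_predictions_depend_only_on_observed_dosages(self):
        """The fitted model is a pure function of (p, observed dosages)."""
        dos, _, p, _ = simulate_training(100, 15, 0.9, seed=6)
        cfg = MCMCConfig(iterations=400, burn_in=100, thin=2, seed=9)
        m1 = fit_bayesian(dos, p, cfg)
        m2 = fit_bayesian(DosageMatrices(g=dos.g.copy(), d=dos.d.copy()), p.copy(), cfg)
        np.testing.assert_array_equal(m1.additive_hat, m2.additive_hat)

    def test_high_heritability_large_n_approaches_truth(self):
        """With N >> L and near-noiseless phenotypes accuracy approaches 1."""
        dos, v, p, _ = simulate_training(2000, 50, 0.99, seed=13)
        model = fit_bayesian(dos, p, MCMCConfig(iterations=800, burn_in=300, thin=2, seed=5))
        v_hat = model.predict(dos).v
        assert np.corrcoef(v_hat, v)[0, 1] >= 0.95

    def test_summary_mentions_chain_and_dimensions(self):
        dos, _, p, _ = simulate_training(50, 5, 0.9, seed=2)
        model = fit_bayesian(dos, p, MCMCConfig(iterations=200, burn_in=50, thin=1, seed=0))
        text = model.summary()
        assert "markers:           5" in text
        assert "sigma_e2" in text
        assert model.effects_frame().shape == (5, 3)
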