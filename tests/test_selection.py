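"""Truncation/GCA/SCA selection against brute-force enumeration, and the
test-cross matrix under the three predictors."""

import itertools

import numpy as np
import pytest

from rrsim.founder_synth import SynthesisConfig, generate_trait_architecture
from rrsim.genome_core import FULL, Population
from rrsim.prediction import MCMCConfig
from rrsim.selection import (
    PredictorContext,
    build_testcross_matrix,
    select_gca,
    select_sca,
    true_hybrid_matrix,
    truncation_select,
)


def enumerate_truncation(scores, m):
    best = max(
        itertools.combinations(range(len(scores)), m),
        key=lambda s: sum(scores[i] for i in s),
    )
    return sum(scores[i] for i in best)


def enumerate_gca(values, size):
    means = values.mean(axis=1)
    best = max(
        itertools.combinations(range(values.shape[0]), size),
        key=lambda s: sum(means[i] for i in s),
    )
    return sum(means[i] for i in best)


def enumerate_sca(values, size):
    maxima = values.max(axis=1)
    best = max(
        itertools.combinations(range(values.shape[0]), size),
        key=lambda s: sum(maxima[i] for i in s),
    )
    return sum(maxima[i] for i in best)


class TestTruncation:
    def test_worked_example(self):
        res = truncation_select(np.array([3.0, 1.0, 2.0]), 2)
        assert set(res.selected) == {0, 2}
        assert res.objective == pytest.approx(5.0)

    def test_select_all(self):
        res = truncation_select(np.array([1.0, 2.0]), 2)
        assert set(res.selected) == {0, 1}

    def test_ties_broken_by_lowest_index(self):
        res = truncation_select(np.array([2.0, 2.0, 1.0]), 1)
        assert list(res.selected) == [0]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            truncation_select(np.array([1.0]), 2)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n = rng.integers(2, 13)
            scores = rng.normal(size=n)
            m = int(rng.integers(1, n + 1))
            res = truncation_select(scores, m)
            assert res.objective == pytest.approx(enumerate_truncation(scores, m))


class TestCombiningAbility:
    def test_gca_worked_example(self):
        res = select_gca(np.array([[1.0, 3.0], [2.0, 2.0], [0.0, 1.0]]), 2)
        assert set(res.selected) == {0, 1}
        assert res.objective == pytest.approx(4.0)

    def test_gca_translation_invariance(self, rng):
        v = rng.normal(size=(6, 5))
        base = select_gca(v, 4)
        shifted = select_gca(v + 7.0, 4)
        assert set(base.selected) == set(shifted.selected)
        assert shifted.objective == pytest.approx(base.objective + 4 * 7.0)

    def test_sca_worked_example(self):
        res = select_sca(np.array([[1.0, 9.0], [5.0, 5.0], [0.0, 8.0]]), 2)
        assert set(res.selected) == {0, 2}
        assert res.objective == pytest.approx(17.0)
        assert res.assignment == {0: 1, 2: 1}

    def test_identical_rows_make_gca_and_sca_agree(self):
        v = np.tile(np.array([1.0, 4.0, 2.0]), (4, 1))
        assert set(select_gca(v, 2).selected) == set(select_sca(v, 2).selected)

    def test_single_large_entry_flips_sca_but_not_gca(self):
        """A row with the worst mean but one huge cell wins under SCA only."""
        v = np.full((4, 4), 5.0)
        v[3] = [0.0, 0.0, 0.0, 30.0]  # mean 7.5 -> keep others at mean 5? craft:
        v[0] = [6.0, 6.0, 6.0, 6.0]
        v[1] = [5.5, 5.5, 5.5, 5.5]
        v[2] = [5.2, 5.2, 5.2, 5.2]
        v[3] = [0.0, 0.0, 0.0, 12.0]  # mean 3.0 (lowest), max 12 (highest)
        gca = select_gca(v, 2)
        sca = select_sca(v, 2)
        assert 3 not in set(gca.selected)
        assert 3 in set(sca.selected)
        assert sca.objective == pytest.approx(enumerate_sca(v, 2))

    def test_column_axis_equals_transposed_rows(self, rng):
        v = rng.normal(size=(5, 7))
        by_cols = select_sca(v, 3, axis="cols")
        by_rows = select_sca(v.T, 3, axis="rows")
        assert list(by_cols.selected) == list(by_rows.selected)
        assert by_cols.objective == pytest.approx(by_rows.objective)

    def test_reductions_match_enumeration_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 11))
            size = int(rng.integers(1, min(n, 4) + 1))
            v = rng.normal(size=(n, int(rng.integers(2, 8))))
            assert select_gca(v, size).objective == pytest.approx(enumerate_gca(v, size))
            assert select_sca(v, size).objective == pytest.approx(enumerate_sca(v, size))

    def test_objective_monotone_in_size_for_nonnegative_matrices(self, rng):
        v = rng.uniform(0, 1, size=(8, 6))
        for select in (select_gca, select_sca):
            objs = [select(v, k).objective for k in range(1, 9)]
            assert all(a <= b + 1e-12 for a, b in zip(objs, objs[1:]))


def make_inbred_pool(haps, scope="observed", label=None):
    geno = np.repeat(np.asarray(haps, dtype=np.int8)[:, :, None], 2, axis=2)
    return Population(genotypes=geno, scope=scope, pool_label=label, homozygous=True)


class TestTestCrossMatrix:
    @pytest.fixture
    def small_arch(self):
        return generate_trait_architecture(
            SynthesisConfig(n_founders=10, n_observed=12, n_full=12, seed=3)
        )

    def test_forced_heterozygote_hybrid_hits_calibration_sum(self, small_arch, rng):
        """all-major x all-minor F1 is heterozygous everywhere, so its true
        GEBV is sum(alpha) + sum(beta) = 30 + 20 - 5 = 45."""
        a = make_inbred_pool(np.ones((1, 12)))
        b = make_inbred_pool(np.zeros((1, 12)))
        ctx = PredictorContext(kind="perfect", simulator_mode="transparent")
        tcm = build_testcross_matrix(a, b, ctx, small_arch, rng)
        assert tcm.values[0, 0] == pytest.approx(45.0)

    def test_self_hybrid_equals_parent_value(self, small_arch, rng):
        hap = rng.integers(0, 2, size=(1, 12))
        pool = make_inbred_pool(hap)
        ctx = PredictorContext(kind="perfect", simulator_mode="transparent")
        tcm = build_testcross_matrix(pool, make_inbred_pool(hap.copy()), ctx, small_arch, rng)
        from rrsim.genome_core import true_gebv

        assert tcm.values[0, 0] == pytest.approx(true_gebv(pool, small_arch, "transparent").v[0])

    def test_perfect_matrix_is_rng_invariant(self, small_arch):
        haps_a = np.random.default_rng(0).integers(0, 2, size=(4, 12))
        haps_b = np.random.default_rng(1).integers(0, 2, size=(3, 12))
        ctx = PredictorContext(kind="perfect", simulator_mode="transparent")
        m1 = build_testcross_matrix(
            make_inbred_pool(haps_a), make_inbred_pool(haps_b), ctx, small_arch,
            np.random.default_rng(10),
        )
        m2 = build_testcross_matrix(
            make_inbred_pool(haps_a), make_inbred_pool(haps_b), ctx, small_arch,
            np.random.default_rng(77),
        )
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_matrix_matches_bruteforce_hybrid_scores(self, small_arch, rng):
        """The bilinear shortcut equals explicitly built F1 genotypes."""
        from rrsim.genome_core import compute_gebv

        haps_a = rng.integers(0, 2, size=(3, 12))
        haps_b = rng.integers(0, 2, size=(4, 12))
        v = true_hybrid_matrix(
            make_inbred_pool(haps_a), make_inbred_pool(haps_b), small_arch, "transparent"
        )
        for k in range(3):
            for l in range(4):
                f1 = Population(
                    genotypes=np.stack([haps_a[k], haps_b[l]], axis=1)[None, :, :].astype(np.int8)
                )
                assert v[k, l] == pytest.approx(compute_gebv(f1, small_arch).v[0])

    def test_heterozygous_parents_rejected(self, small_arch, rng):
        geno = np.zeros((2, 12, 2), dtype=np.int8)
        geno[:, :, 0] = 1  # heterozygous everywhere
        het = Population(genotypes=geno)
        ctx = PredictorContext(kind="perfect", simulator_mode="transparent")
        with pytest.raises(ValueError, match="homozygous"):
            build_testcross_matrix(het, het, ctx, small_arch, rng)

    def test_phenotypic_matrix_is_noisy_truth(self, small_arch, rng):
        haps_a = rng.integers(0, 2, size=(6, 12))
        haps_b = rng.integers(0, 2, size=(6, 12))
        a, b = make_inbred_pool(haps_a), make_inbred_pool(haps_b)
        truth = true_hybrid_matrix(a, b, small_arch, "transparent")
        ctx = PredictorContext(kind="phenotypic", simulator_mode="transparent", h2=0.5)
        tcm = build_testcross_matrix(a, b, ctx, small_arch, rng)
        assert not np.allclose(tcm.values, truth)
        # same mean in expectation; loose check at this size
        assert tcm.values.mean() == pytest.approx(truth.mean(), abs=3 * truth.std())

    def test_bayesian_matrix_correlates_with_truth(self, rng):
        arch = generate_trait_architecture(
            SynthesisConfig(n_founders=10, n_observed=30, n_full=30, seed=3)
        )
        haps_a = rng.integers(0, 2, size=(12, 30))
        haps_b = rng.integers(0, 2, size=(12, 30))
        a, b = make_inbred_pool(haps_a), make_inbred_pool(haps_b)
        truth = true_hybrid_matrix(a, b, arch, "transparent")
        ctx = PredictorContext(
            kind="bayesian",
            simulator_mode="transparent",
            h2=0.9,
            mcmc=MCMCConfig(iterations=600, burn_in=200, thin=2, seed=4),
        )
        tcm = build_testcross_matrix(a, b, ctx, arch, rng)
        assert ctx.model is not None
        r = np.corrcoef(tcm.values.ravel(), truth.ravel())[0, 1]
        assert r >= 0.7
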