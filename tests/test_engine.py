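"""Codon-model engine: rate matrix algebra, likelihood, fitting."""

import numpy as np
import pytest

from conftest import brute_force_loglik, random_tree
from omegascan.codons import (
    CODONS,
    IS_NONSYNONYMOUS,
    N_CODONS,
    SINGLE_STEP,
    uniform_frequencies,
)
from omegascan.engine import (
    EngineError,
    OptimizerConfig,
    _Propagator,
    build_rate_matrix,
    fit,
    log_likelihood,
    positive_site_probabilities,
    site_posteriors,
    transition_matrix,
)
from omegascan.io import CodonAlignment
from omegascan.models import SiteClassMix
from omegascan.simulate import SimSpec, simulate
from omegascan.trees import Phylogeny


@pytest.fixture(scope="module")
def pi_random():
    rng = np.random.default_rng(5)
    return rng.dirichlet(np.ones(N_CODONS) * 5)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, pi_random):
        Q = build_rate_matrix(2.0, 0.3, pi_random)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_reversibility_flux_symmetry(self, pi_random):
        Q = build_rate_matrix(3.0, 0.7, pi_random)
        flux = pi_random[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_mean_rate(self, pi_random):
        Q = build_rate_matrix(2.0, 0.3, pi_random)
        assert pi_random @ (-np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_neutral_uniform_rates_equal(self):
        # kappa=1, omega=1: every single-step rate reduces to pi_j
        pi = uniform_frequencies()
        Q = build_rate_matrix(1.0, 1.0, pi, scale=False)
        off = Q[SINGLE_STEP]
        assert np.allclose(off, off[0])
        assert (Q[~SINGLE_STEP & ~np.eye(N_CODONS, dtype=bool)] == 0).all()

    def test_omega_zero_kills_nonsynonymous(self, pi_random):
        Q = build_rate_matrix(2.0, 0.0, pi_random)
        assert (Q[IS_NONSYNONYMOUS] == 0).all()

    def test_unnormalized_pi_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.3, np.ones(N_CODONS))

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrix_stochastic(self, pi_random, t):
        P = transition_matrix(2.0, 0.5, pi_random, t)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert (P >= 0).all()

    def test_zero_time_is_identity(self, pi_random):
        P = transition_matrix(2.0, 0.5, pi_random, 0.0)
        assert np.abs(P - np.eye(N_CODONS)).max() < 1e-10

    def test_pt_flux_symmetry(self, pi_random):
        P = transition_matrix(1.5, 0.4, pi_random, 0.7)
        flux = pi_random[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10


class TestLogLikelihood:
    def test_zero_branch_identical_sequences(self):
        tree = Phylogeny.from_newick("(A:0,B:0);")
        row = ["ATG", "AAA", "TTT"]
        aln = CodonAlignment("g", ("A", "B"), [list(row), list(row)])
        pi = uniform_frequencies()
        lnL = log_likelihood(aln, tree, SiteClassMix.m0(0.5), 2.0, pi)
        expected = sum(np.log(pi[CODONS.index(c)]) for c in row)
        assert lnL == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration(self, tree4, pi_random):
        mix = SiteClassMix.m0(0.4)
        aln, _ = simulate(
            SimSpec(tree=tree4, mix=mix, kappa=2.0, n_sites=8, seed=3, pi=pi_random)
        )
        lnL = log_likelihood(aln, tree4, mix, 2.0, pi_random)
        oracle = brute_force_loglik(aln, tree4, mix, 2.0, pi_random)
        assert lnL == pytest.approx(oracle, abs=1e-8)

    def test_mixture_matches_enumeration_with_marks(self, tree4, pi_random):
        marked = tree4.copy()
        for lf in marked.leaves():
            if lf.label == "A":
                lf.mark = 1
        mix = SiteClassMix.model_a(0.5, 0.3, 0.2, 3.0)
        aln, _ = simulate(
            SimSpec(tree=marked, mix=mix, kappa=1.5, n_sites=6, seed=9, pi=pi_random)
        )
        lnL = log_likelihood(aln, marked, mix, 1.5, pi_random)
        oracle = brute_force_loglik(aln, marked, mix, 1.5, pi_random)
        assert lnL == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_mixture_equals_single_class(self, tree4, pi_random):
        aln, _ = simulate(
            SimSpec(
                tree=tree4,
                mix=SiteClassMix.m0(0.3),
                kappa=2.0,
                n_sites=20,
                seed=4,
                pi=pi_random,
            )
        )
        single = log_likelihood(aln, tree4, SiteClassMix.m0(0.3), 2.0, pi_random)
        degenerate = SiteClassMix.m1a(1.0 - 1e-15, 0.3)
        mixed = log_likelihood(aln, tree4, degenerate, 2.0, pi_random)
        assert mixed == pytest.approx(single, abs=1e-6)

    def test_missing_data_handled(self, tree4, pi_random):
        aln = CodonAlignment(
            "g",
            ("A", "B", "C", "D"),
            [["ATG", "---"], ["ATG", "AAA"], ["ATG", "NNN"], ["ATG", "AAG"]],
        )
        lnL = log_likelihood(aln, tree4, SiteClassMix.m0(0.5), 2.0, pi_random)
        assert np.isfinite(lnL)

    def test_rerooting_invariance_unmarked(self, pi_random):
        """Same unrooted M0 tree under three rootings: identical lnL."""
        rootings = [
            "(A:0.1,B:0.2,(C:0.3,D:0.4):0.15);",
            "((A:0.1,B:0.2):0.15,C:0.3,D:0.4);",
            "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.1);",
        ]
        trees = [Phylogeny.from_newick(s) for s in rootings]
        aln, _ = simulate(
            SimSpec(
                tree=trees[0],
                mix=SiteClassMix.m0(0.5),
                kappa=2.0,
                n_sites=30,
                seed=8,
                pi=pi_random,
            )
        )
        vals = [
            log_likelihood(aln, t, SiteClassMix.m0(0.5), 2.0, pi_random)
            for t in trees
        ]
        assert vals[1] == pytest.approx(vals[0], abs=1e-8)
        assert vals[2] == pytest.approx(vals[0], abs=1e-8)

    def test_likelihood_oracle_random_trees(self):
        """Random 4-taxon trees and parameters against the enumeration oracle."""
        rng = np.random.default_rng(11)
        for rep in range(5):
            tree = random_tree(rng, ["A", "B", "C", "D"])
            kappa = float(rng.uniform(0.5, 8.0))
            omega = float(rng.uniform(0.05, 4.0))
            pi = rng.dirichlet(np.ones(N_CODONS) * 2)
            mix = SiteClassMix.m0(omega)
            aln, _ = simulate(
                SimSpec(tree=tree, mix=mix, kappa=kappa, n_sites=5, seed=100 + rep, pi=pi)
            )
            lnL = log_likelihood(aln, tree, mix, kappa, pi)
            oracle = brute_force_loglik(aln, tree, mix, kappa, pi)
            assert lnL == pytest.approx(oracle, abs=1e-8)


class TestFit:
    def test_m0_parameter_recovery(self, tree6):
        aln, _ = simulate(
            SimSpec(tree=tree6, mix=SiteClassMix.m0(0.3), kappa=2.0, n_sites=500, seed=7)
        )
        res = fit(aln, tree6, "M0", OptimizerConfig(n_starts=1))
        assert 0.2 <= res.omega_foreground <= 0.4
        assert 1.0 <= res.params.kappa <= 4.0

    def test_ma_null_pins_omega2(self, marked_tree6):
        aln, _ = simulate(
            SimSpec(
                tree=marked_tree6,
                mix=SiteClassMix.model_a(0.5, 0.3, 0.2, 1.0, null=True),
                kappa=2.0,
                n_sites=120,
                seed=2,
            )
        )
        res = fit(aln, marked_tree6, "MA_null", OptimizerConfig(n_starts=1))
        for k in (2, 3):
            assert res.mix.classes[k].omega_foreground == 1.0

    def test_nesting_inequalities(self, marked_tree6):
        aln, _ = simulate(
            SimSpec(
                tree=marked_tree6,
                mix=SiteClassMix.model_a(0.5, 0.2, 0.1, 4.0),
                kappa=2.0,
                n_sites=150,
                seed=13,
            )
        )
        cfg = OptimizerConfig(n_starts=1)
        tol = 1e-4
        assert fit(aln, marked_tree6, "two_ratios", cfg).lnL >= fit(
            aln, marked_tree6, "M0", cfg
        ).lnL - tol
        assert fit(aln, marked_tree6, "M2a", cfg).lnL >= fit(
            aln, marked_tree6, "M1a", cfg
        ).lnL - tol
        assert fit(aln, marked_tree6, "MA", cfg).lnL >= fit(
            aln, marked_tree6, "MA_null", cfg
        ).lnL - tol

    def test_branch_model_requires_marks(self, tree6):
        aln, _ = simulate(
            SimSpec(tree=tree6, mix=SiteClassMix.m0(0.3), kappa=2.0, n_sites=30, seed=1)
        )
        with pytest.raises(EngineError):
            fit(aln, tree6, "two_ratios")

    def test_unknown_model_rejected(self, tree6):
        aln, _ = simulate(
            SimSpec(tree=tree6, mix=SiteClassMix.m0(0.3), kappa=2.0, n_sites=10, seed=1)
        )
        with pytest.raises(ValueError):
            fit(aln, tree6, "M8")


class TestSitePosteriors:
    def test_posteriors_normalized_and_informative(self, marked_tree6):
        mix = SiteClassMix.model_a(0.55, 0.25, 0.1, 5.0)
        aln, classes = simulate(
            SimSpec(tree=marked_tree6, mix=mix, kappa=2.0, n_sites=300, seed=21)
        )
        res = fit(aln, marked_tree6, "MA", OptimizerConfig(n_starts=1))
        post = site_posteriors(res, aln, marked_tree6)
        assert post.shape == (300, 4)
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9
        probs = positive_site_probabilities(res, post)
        positive_truth = np.isin(classes, mix.positive_classes)
        assert probs[positive_truth].mean() > probs[~positive_truth].mean()

    def test_unsupported_model_rejected(self, tree6):
        aln, _ = simulate(
            SimSpec(tree=tree6, mix=SiteClassMix.m0(0.3), kappa=2.0, n_sites=20, seed=1)
        )
        res = fit(aln, tree6, "M0", OptimizerConfig(n_starts=1))
        with pytest.raises(EngineError):
            site_posteriors(res, aln, tree6)

    def test_no_positive_class_gives_zero_probability(self, marked_tree6):
        # M1a has no class with omega > 1, so positive mass is identically 0
        aln, _ = simulate(
            SimSpec(
                tree=marked_tree6,
                mix=SiteClassMix.m1a(0.7, 0.2),
                kappa=2.0,
                n_sites=100,
                seed=5,
            )
        )
        res = fit(aln, marked_tree6, "M1a", OptimizerConfig(n_starts=1))
        post = site_posteriors(res, aln, marked_tree6)
        probs = positive_site_probabilities(res, post)
        assert (probs == 0).all()
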