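"""Rate-matrix construction, pruning likelihood, ML estimation, NG86
counting oracle, and the codon-column bootstrap."""

import numpy as np
import pytest
from scipy.linalg import expm

from resevol.alignment_binning import BinnedAlignment
from resevol.codon_evolution import (
    GY94Params,
    PhyloTree,
    bootstrap_se,
    build_gy94_matrix,
    estimate_rates_ml,
    estimate_rates_profile,
    ng86_counts,
    ng86_rates,
    pairwise_log_likelihood_direct,
    tree_log_likelihood,
)
from resevol.codons import CODON_INDEX, N_SENSE, CodonError, sequence_to_indices
from resevol.synthetic_data import simulate_alignment


def alignment_from(taxa, codon_matrix):
    return BinnedAlignment(taxa=tuple(taxa), codons=np.asarray(codon_matrix, dtype=np.intp))


def random_pi(seed):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(N_SENSE) * 5)
    return pi / pi.sum()


class TestGy94Matrix:
    def test_omega_zero_kills_nonsynonymous_entries(self, uniform_pi):
        from resevol.codons import PAIR_I, PAIR_J, PAIR_SYN

        Q, _ = build_gy94_matrix(GY94Params(0.0, 2.0, uniform_pi))
        assert np.all(Q[PAIR_I[~PAIR_SYN], PAIR_J[~PAIR_SYN]] == 0)
        assert np.any(Q[PAIR_I[PAIR_SYN], PAIR_J[PAIR_SYN]] > 0)

    def test_uniform_neutral_matrix_is_symmetric(self, uniform_pi):
        Q, _ = build_gy94_matrix(GY94Params(1.0, 1.0, uniform_pi))
        assert np.allclose(Q, Q.T)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stationary_distribution_is_pi(self, seed):
        pi = random_pi(seed)
        Q, _ = build_gy94_matrix(GY94Params(0.4, 3.1, pi))
        assert np.max(np.abs(pi @ Q)) < 1e-10

    def test_rows_sum_to_zero_and_unit_flux(self, uniform_pi):
        Q, info = build_gy94_matrix(GY94Params(0.3, 2.0, uniform_pi))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.sum(uniform_pi * np.diag(Q)) == pytest.approx(1.0)
        assert info.prop_syn + info.prop_nonsyn == pytest.approx(1.0)

    def test_unnormalized_pi_rejected(self, uniform_pi):
        with pytest.raises(ValueError, match="sum to 1"):
            build_gy94_matrix(GY94Params(0.3, 2.0, uniform_pi * 2))


class TestTreeLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_taxon_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        pi = random_pi(seed)
        params = GY94Params(
            omega=rng.uniform(0.1, 1.5), kappa=rng.uniform(1, 5), pi=pi
        )
        tree = PhyloTree.from_newick("(A:0.07,B:0.11);")
        cod1 = rng.integers(0, N_SENSE, size=12)
        Q, _ = build_gy94_matrix(params)
        P = expm(Q * 0.18)
        cod2 = np.array(
            [rng.choice(N_SENSE, p=P[c] / P[c].sum()) for c in cod1]
        )
        aln = alignment_from(["A", "B"], np.vstack([cod1, cod2]))
        mine = tree_log_likelihood(aln, tree, params)
        direct = pairwise_log_likelihood_direct(cod1, cod2, 0.18, params)
        assert mine == pytest.approx(direct, abs=1e-10)

    def test_zero_branches_identical_sequences(self, uniform_pi):
        tree = PhyloTree.from_newick("((A:0,B:0):0,C:0,D:0);")
        cod = np.tile(np.arange(10), (4, 1))
        aln = alignment_from("ABCD", cod)
        ll = tree_log_likelihood(aln, tree, GY94Params(0.5, 2.0, uniform_pi))
        assert ll == pytest.approx(10 * np.log(1 / N_SENSE), abs=1e-9)

    def test_rerooting_invariance(self, uniform_pi):
        rng = np.random.default_rng(4)
        cod = rng.integers(0, N_SENSE, size=(4, 30))
        params = GY94Params(0.3, 2.5, uniform_pi)
        newicks = [
            "((A:0.1,B:0.2):0.05,C:0.3,D:0.15);",
            "(A:0.1,B:0.2,(C:0.3,D:0.15):0.05);",
            "((A:0.1,B:0.2):0.02,(C:0.3,D:0.15):0.03);",
        ]
        lls = []
        for nwk in newicks:
            tree = PhyloTree.from_newick(nwk)
            taxa_order = list(tree.taxa)
            idx = ["ABCD".index(t) for t in taxa_order]
            lls.append(
                tree_log_likelihood(alignment_from(taxa_order, cod[idx]), tree, params)
            )
        assert lls[0] == pytest.approx(lls[1], abs=1e-10)
        assert lls[0] == pytest.approx(lls[2], abs=1e-10)

    def test_stop_codon_rejected_with_column(self):
        with pytest.raises(CodonError, match="column 2"):
            sequence_to_indices("ATGATGTAA")


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        res = ng86_rates("ATGGCT", "ATGGCT")
        assert res.dn == 0.0 and res.ds == 0.0

    def test_synonymous_single_step(self):
        _, _, sd, nd = ng86_counts("TTT", "TTC")  # Phe -> Phe
        assert sd == pytest.approx(1.0)
        assert nd == pytest.approx(0.0)

    def test_nonsynonymous_single_step(self):
        _, _, sd, nd = ng86_counts("GAA", "GAC")  # Glu -> Asp
        assert nd == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_saturated_proportion_rejected(self):
        # one codon, all syn sites used: pS = 1/(1/3) > 3/4
        with pytest.raises(ValueError, match="3/4"):
            ng86_rates("TTT", "TTC")  # dS correction undefined at saturation

    def test_two_step_pathway_averaging(self):
        # CCT (Pro) vs CAA (Gln): paths CCT->CAT->CAA and CCT->CCA->CAA
        # path 1: Pro->His (N), His->Gln (N); path 2: Pro->Pro (S), Pro->Gln (N)
        _, _, sd, nd = ng86_counts("CCT", "CAA")
        assert nd == pytest.approx(1.5)
        assert sd == pytest.approx(0.5)

    def test_agrees_with_ml_at_low_divergence(self, uniform_pi):
        aln = simulate_alignment(
            0.3,
            3000,
            tree_newick="(A:0.04,B:0.04);",
            kappa=2.0,
            seed=17,
        )
        tree = PhyloTree.from_newick("(A:0.04,B:0.04);")
        ml = estimate_rates_ml(aln, tree, pi_mode="uniform")
        from resevol.codons import indices_to_sequence

        ng = ng86_rates(
            indices_to_sequence(aln.codons[0]), indices_to_sequence(aln.codons[1])
        )
        assert ml.dnds == pytest.approx(ng.dnds, rel=0.25)


class TestEstimateRates:
    def test_invariant_alignment_undefined(self, yeast_tree):
        cod = np.tile(np.arange(12), (4, 1))
        est = estimate_rates_ml(alignment_from(yeast_tree.taxa, cod), yeast_tree)
        assert est.undefined and est.dn == 0.0 and est.ds == 0.0
        assert np.isnan(est.dnds)

    def test_column_permutation_leaves_estimate_unchanged(self, yeast_tree):
        aln = simulate_alignment(0.4, 300, seed=23)
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_codons)
        shuffled = alignment_from(aln.taxa, aln.codons[:, perm])
        a = estimate_rates_ml(aln, yeast_tree)
        b = estimate_rates_ml(shuffled, yeast_tree)
        assert a.dnds == pytest.approx(b.dnds, abs=1e-9)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-6)

    def test_concatenation_consistency(self, yeast_tree):
        aln = simulate_alignment(0.4, 300, seed=29)
        double = alignment_from(aln.taxa, np.hstack([aln.codons, aln.codons]))
        a = estimate_rates_ml(aln, yeast_tree)
        b = estimate_rates_ml(double, yeast_tree)
        assert b.dnds == pytest.approx(a.dnds, rel=1e-4)
        sa = bootstrap_se(aln, yeast_tree, B=400, seed=5, estimate=a, method="profile")
        sb = bootstrap_se(double, yeast_tree, B=400, seed=5, estimate=b, method="profile")
        ratio = sb.se_dnds / sa.se_dnds
        assert 0.5 < ratio < 0.95  # ~1/sqrt(2) up to Monte-Carlo error

    def test_profile_estimate_matches_full_at_mle(self, yeast_tree):
        aln = simulate_alignment(0.25, 400, seed=31)
        full = estimate_rates_ml(aln, yeast_tree)
        prof = estimate_rates_profile(
            aln,
            yeast_tree,
            kappa=full.kappa,
            branch_lengths=full.branch_lengths,
            pi=full.pi,
        )
        assert prof.dnds == pytest.approx(full.dnds, rel=0.02)


class TestBootstrap:
    def test_single_pattern_alignment_has_zero_se(self, yeast_tree):
        # one repeated column with both a synonymous and a nonsynonymous
        # difference: every bootstrap replicate sees identical data
        col = np.array([[CODON_INDEX["ATT"]], [CODON_INDEX["ATC"]],
                        [CODON_INDEX["ATG"]], [CODON_INDEX["ATT"]]])
        aln = alignment_from(yeast_tree.taxa, np.repeat(col, 50, axis=1))
        est = estimate_rates_ml(aln, yeast_tree)
        boot = bootstrap_se(aln, yeast_tree, B=20, seed=1, estimate=est, method="profile")
        assert not boot.unreliable
        assert boot.se_dnds == pytest.approx(0.0, abs=1e-12)
        assert boot.se_ds == pytest.approx(0.0, abs=1e-12)

    def test_seeded_reproducibility(self, yeast_tree):
        aln = simulate_alignment(0.3, 200, seed=37)
        est = estimate_rates_ml(aln, yeast_tree)
        b1 = bootstrap_se(aln, yeast_tree, B=50, seed=99, estimate=est, method="profile")
        b2 = bootstrap_se(aln, yeast_tree, B=50, seed=99, estimate=est, method="profile")
        assert b1.se_dnds == b2.se_dnds
        assert b1.se_ds == b2.se_ds

    def test_minimum_replicates_enforced(self, yeast_tree):
        aln = simulate_alignment(0.3, 50, seed=41)
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_se(aln, yeast_tree, B=1, seed=1)

    def test_profile_and_full_bootstrap_agree(self, yeast_tree):
        aln = simulate_alignment(0.2, 400, seed=43)
        est = estimate_rates_ml(aln, yeast_tree)
        full = bootstrap_se(aln, yeast_tree, B=100, seed=7, estimate=est, method="full")
        prof = bootstrap_se(aln, yeast_tree, B=400, seed=7, estimate=est, method="profile")
        for a, b in [
            (full.se_dnds, prof.se_dnds),
            (full.se_dn, prof.se_dn),
            (full.se_ds, prof.se_ds),
        ]:
            assert b / a == pytest.approx(1.0, abs=0.4)
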