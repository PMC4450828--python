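"""Rate matrix structure, transition probabilities, site opportunities,
and the pruning likelihood's basic contracts."""

import numpy as np
import pytest

from omegascan.alignment import CodonAlignment
from omegascan.likelihood import SiteClassModel, TreeLikelihood, log_likelihood
from omegascan.model import (
    CodonModelParams,
    build_rate_matrix,
    codon_frequencies,
    count_site_opportunities,
    eigen_decompose,
    f3x4_frequencies,
    rate_matrix_unscaled,
    transition_probabilities,
    uniform_frequencies,
)
from omegascan.trees import parse_newick

from conftest import aln_from_codons, random_clean_alignment


@pytest.fixture(scope="module")
def params():
    rng = np.random.default_rng(0)
    pi = rng.dirichlet(np.ones(61))
    return CodonModelParams(kappa=2.5, pi=pi)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, params):
        Q = build_rate_matrix(params, omega=0.7)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, params):
        Q = build_rate_matrix(params, omega=0.7)
        flux = params.pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_unit_mean_rate(self, params):
        Q = build_rate_matrix(params, omega=0.3)
        assert abs(-(params.pi * np.diag(Q)).sum() - 1.0) < 1e-12

    def test_neutral_uniform_rates_all_equal(self, code):
        p = CodonModelParams(1.0, uniform_frequencies())
        Q = rate_matrix_unscaled(p, omega=1.0)
        single = code.ndiff == 1
        vals = Q[single]
        assert np.allclose(vals, vals[0])
        assert np.all(Q[code.ndiff > 1] == 0)

    def test_multi_step_entries_zero(self, params, code):
        Q = build_rate_matrix(params, omega=2.0)
        assert np.all(Q[code.ndiff >= 2] == 0)

    def test_invalid_omega_rejected(self, params):
        with pytest.raises(ValueError):
            rate_matrix_unscaled(params, omega=-1.0)


class TestTransitionProbabilities:
    def test_identity_at_zero(self, params):
        Q = build_rate_matrix(params, 1.0)
        P = transition_probabilities(Q, 0.0, pi=params.pi)
        assert np.abs(P - np.eye(61)).max() < 1e-12

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_rows_stochastic(self, params, t):
        Q = build_rate_matrix(params, 0.5)
        P = transition_probabilities(Q, t, pi=params.pi)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0

    def test_stationarity(self, params):
        Q = build_rate_matrix(params, 0.5)
        P = transition_probabilities(Q, 0.7, pi=params.pi)
        assert np.abs(params.pi @ P - params.pi).max() < 1e-12

    def test_chapman_kolmogorov(self, params):
        Q = build_rate_matrix(params, 1.3)
        eig = eigen_decompose(Q, params.pi)
        P1 = eig.transition_probabilities(0.4)
        P2 = eig.transition_probabilities(0.9)
        P12 = eig.transition_probabilities(1.3)
        assert np.abs(P1 @ P2 - P12).max() < 1e-9

    def test_eigen_path_matches_expm(self, params):
        Q = build_rate_matrix(params, 0.8)
        P_eig = transition_probabilities(Q, 0.5, pi=params.pi)
        P_pade = transition_probabilities(Q, 0.5, pi=None)  # scipy expm
        assert np.abs(P_eig - P_pade).max() < 1e-10

    def test_negative_time_rejected(self, params):
        Q = build_rate_matrix(params, 1.0)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1, pi=params.pi)


class TestSiteOpportunities:
    def test_sum_is_three(self, params):
        S, N = count_site_opportunities(params)
        assert abs(S + N - 3.0) < 1e-12

    def test_uniform_kappa1_matches_enumeration(self, code):
        # independent oracle: enumerate sense->sense single-base pairs
        syn = nonsyn = 0
        for ci in code.codons:
            for pos in range(3):
                for nt in "TCAG":
                    if nt == ci[pos]:
                        continue
                    alt = ci[:pos] + nt + ci[pos + 1:]
                    if code.is_stop(alt):
                        continue
                    if code.translate(alt) == code.translate(ci):
                        syn += 1
                    else:
                        nonsyn += 1
        expected_S = 3.0 * syn / (syn + nonsyn)
        S, N = count_site_opportunities(CodonModelParams(1.0, uniform_frequencies()))
        assert S == pytest.approx(expected_S, abs=1e-12)
        assert (syn, nonsyn) == (134, 392)

    def test_high_kappa_increases_synonymous_opportunity(self):
        pi = uniform_frequencies()
        S1, _ = count_site_opportunities(CodonModelParams(1.0, pi))
        S20, _ = count_site_opportunities(CodonModelParams(20.0, pi))
        assert S20 > S1  # transitions are more often synonymous


class TestFrequencies:
    def test_f3x4_normalised_and_positive(self):
        aln = random_clean_alignment(["a", "b", "c"], 200, seed=11)
        pi = f3x4_frequencies(aln.states)
        assert pi.shape == (61,)
        assert abs(pi.sum() - 1.0) < 1e-12
        assert pi.min() > 0

    def test_f3x4_hand_example(self, code):
        # single codon ATG observed: position frequencies are point masses,
        # so only codons spelled from {A},{T},{G} have mass -> ATG alone
        aln = aln_from_codons({"a": "ATG"})
        pi = f3x4_frequencies(aln.states)
        assert pi[code.codon_index["ATG"]] == pytest.approx(1.0)

    def test_unknown_scheme_rejected(self):
        aln = random_clean_alignment(["a"], 10, seed=1)
        with pytest.raises(ValueError):
            codon_frequencies(aln.states, "f61")


class TestLikelihoodContracts:
    def test_zero_branch_identical_pair_gives_log_pi(self, code):
        aln = aln_from_codons({"A": "ATG", "B": "ATG"})
        tree = parse_newick("(A:0.0,B:0.0);")
        pi = uniform_frequencies()
        params = CodonModelParams(2.0, pi)
        ll = log_likelihood(aln, tree, params,
                            SiteClassModel.one_ratio(1.0, tree))
        assert ll == pytest.approx(np.log(pi[code.codon_index["ATG"]]), abs=1e-9)

    def test_duplicated_column_doubles_contribution(self):
        a1 = aln_from_codons({"A": "ATG", "B": "CTG", "C": "ATA"})
        a2 = aln_from_codons({"A": "ATGATG", "B": "CTGCTG", "C": "ATAATA"})
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        params = CodonModelParams(2.0, uniform_frequencies())
        mix = SiteClassModel.one_ratio(0.5, tree)
        ll1 = log_likelihood(a1, tree, params, mix)
        ll2 = log_likelihood(a2, tree, params, mix)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-10)

    def test_invariance_under_taxon_and_column_permutation(self):
        rng = np.random.default_rng(21)
        aln = random_clean_alignment(["A", "B", "C"], 40, seed=21)
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        params = CodonModelParams(2.0, uniform_frequencies())
        mix = SiteClassModel.one_ratio(0.5, tree)
        base = log_likelihood(aln, tree, params, mix)
        shuffled_cols = CodonAlignment(
            aln.taxa, aln.states[:, rng.permutation(40)], "g")
        reordered_taxa = CodonAlignment(
            [aln.taxa[i] for i in (2, 0, 1)], aln.states[(2, 0, 1), :], "g")
        assert log_likelihood(shuffled_cols, tree, params, mix) == pytest.approx(base, abs=1e-9)
        assert log_likelihood(reordered_taxa, tree, params, mix) == pytest.approx(base, abs=1e-9)

    def test_mixture_of_identical_classes_collapses(self):
        aln = random_clean_alignment(["A", "B", "C"], 30, seed=31)
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        params = CodonModelParams(2.0, uniform_frequencies())
        one = log_likelihood(aln, tree, params, SiteClassModel.one_ratio(1.0, tree))
        om = np.ones((3, tree.n_nodes))
        mix = SiteClassModel(np.array([0.2, 0.5, 0.3]), om)
        assert log_likelihood(aln, tree, params, mix) == pytest.approx(one, abs=1e-9)

    def test_taxa_mismatch_rejected(self):
        aln = random_clean_alignment(["A", "B", "Z"], 5, seed=4)
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        with pytest.raises(ValueError, match="mismatch"):
            TreeLikelihood(aln, tree)

    def test_unclean_alignment_rejected(self):
        aln = aln_from_codons({"A": "AT-", "B": "ATG", "C": "ATG"})
        tree = parse_newick("(A:0.2,B:0.1,C:0.3);")
        with pytest.raises(ValueError, match="QC"):
            TreeLikelihood(aln, tree)
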