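import itertools

import numpy as np
import pytest

from kaksel.ancestral import (
    NucModelParams,
    discrete_gamma_rates,
    fit_nucleotide_model,
    gtr_rate_matrix,
    marginal_ancestral_sequence,
)
from kaksel.errors import CladeError
from kaksel.io_formats import NUCLEOTIDES, NucleotideAlignment, read_newick
from kaksel.synthetic_data import simulate_nucleotide_alignment


def hky_params(tree, kappa=2.0, freqs=None, alpha=None):
    return NucModelParams(
        model="HKY",
        freqs=np.array(freqs) if freqs is not None else np.full(4, 0.25),
        kappa=kappa,
        alpha=alpha,
        branch_lengths=tree.lengths.copy(),
    )


class TestNucleotideModels:
    def test_gamma_category_means_average_to_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha)
            assert rates.mean() == pytest.approx(1.0, abs=1e-8)
            assert np.all(np.diff(rates) > 0)

    def test_rate_matrix_normalized(self):
        freqs = np.array([0.4, 0.2, 0.1, 0.3])
        Q = gtr_rate_matrix(np.array([1, 4, 1, 1, 4, 1.0]), freqs)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -np.sum(freqs * np.diag(Q)) == pytest.approx(1.0)

    def test_identical_sequences_shrink_branches(self):
        tree = read_newick("((A:0.1,B:0.1):0.05,C:0.1);")
        aln = NucleotideAlignment(taxa=["A", "B", "C"],
                                  sequences=["ACGTACGT" * 20] * 3)
        fit = fit_nucleotide_model(aln, tree, model="JC",
                                   optimize_branch_lengths=True)
        assert fit.params.branch_lengths[tree.branches].max() < 1e-4

    def test_hky_kappa_recovery(self):
        tree = read_newick("(((a:0.15,b:0.15):0.1,c:0.2):0.05,(d:0.2,e:0.2):0.1);")
        params = hky_params(tree, kappa=3.0, freqs=[0.3, 0.2, 0.2, 0.3])
        aln, _ = simulate_nucleotide_alignment(tree, params, 2000, seed=13)
        fit = fit_nucleotide_model(aln, tree, model="HKY",
                                   optimize_branch_lengths=False)
        assert 2.4 <= fit.params.kappa <= 3.6

    def test_model_nesting_on_any_dataset(self):
        tree = read_newick("((a:0.2,b:0.25):0.1,(c:0.3,d:0.15):0.1);")
        params = hky_params(tree, kappa=2.5, freqs=[0.35, 0.15, 0.2, 0.3])
        aln, _ = simulate_nucleotide_alignment(tree, params, 500, seed=14)
        lls = {}
        for model in ("JC", "HKY", "GTR"):
            lls[model] = fit_nucleotide_model(
                aln, tree, model=model, optimize_branch_lengths=False
            ).log_likelihood
        assert lls["GTR"] >= lls["HKY"] - 1e-6 >= lls["JC"] - 2e-6

    def test_gamma_improves_fit_on_heterogeneous_data(self):
        tree = read_newick("((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);")
        params = hky_params(tree, kappa=2.0, alpha=0.3)
        aln, _ = simulate_nucleotide_alignment(tree, params, 1500, seed=15)
        plain = fit_nucleotide_model(aln, tree, "HKY",
                                     optimize_branch_lengths=False)
        gamma = fit_nucleotide_model(aln, tree, "HKY", gamma=True,
                                     optimize_branch_lengths=False)
        assert gamma.log_likelihood >= plain.log_likelihood - 1e-6
        assert gamma.n_free_params == plain.n_free_params + 1


def brute_force_posterior(tree, params, leaf_states, node):
    """Bayes-rule enumeration over all internal node states for one site."""
    from kaksel._engine import ReversibleRate

    pi = params.effective_freqs
    rr = ReversibleRate(params.rate_matrix(), np.maximum(pi, 1e-12))
    P = {b: rr.transition(float(params.branch_lengths[b]))
         for b in tree.branches}
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    post = np.zeros(4)
    for assign in itertools.product(range(4), repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(leaf_states)
        prob = pi[states[tree.root]]
        for v in tree.branches:
            prob *= P[v][states[int(tree.parent[v])], states[v]]
        if node in internal:
            post[states[node]] += prob
        else:
            post[leaf_states[node]] += prob
    return post / post.sum()


class TestMarginalReconstruction:
    def test_posterior_matches_bayes_enumeration(self):
        tree = read_newick("((A:0.2,B:0.35):0.15,C:0.4);")
        params = hky_params(tree, kappa=2.5, freqs=[0.35, 0.15, 0.2, 0.3])
        sites = ["AAC", "ACG", "TTT", "AGA", "CCC"]
        aln = NucleotideAlignment(taxa=["A", "B", "C"],
                                  sequences=["".join(s) for s in zip(*sites)])
        fit_like = fit_nucleotide_model(aln, tree, "HKY",
                                        optimize_branch_lengths=False)
        fit_like.params.kappa = 2.5
        fit_like.params.freqs = np.array([0.35, 0.15, 0.2, 0.3])
        rec = marginal_ancestral_sequence(fit_like, ["A", "B"])
        node = tree.mrca(["A", "B"])
        name_to_leaf = {tree.names[i]: i for i in tree.leaves}
        nt = {c: i for i, c in enumerate(NUCLEOTIDES)}
        for s, site in enumerate(sites):
            leaf_states = {name_to_leaf[t]: nt[site[k]]
                           for k, t in enumerate(["A", "B", "C"])}
            expected = brute_force_posterior(tree, fit_like.params,
                                             leaf_states, node)
            assert np.abs(rec.per_site_posteriors[s] - expected).max() < 1e-10

    def test_identical_leaves_recover_ancestor(self):
        tree = read_newick("((A:0.01,B:0.01):0.01,C:0.01);")
        seq = "ACGTACGTACGTACGTACGT"
        aln = NucleotideAlignment(taxa=["A", "B", "C"], sequences=[seq] * 3)
        fit = fit_nucleotide_model(aln, tree, "JC",
                                   optimize_branch_lengths=False)
        rec = marginal_ancestral_sequence(fit, ["A", "B"])
        assert rec.sequence == seq
        assert rec.mean_posterior > 0.99

    def test_symmetric_tie_broken_alphabetically_and_flagged(self):
        """Under JC with equal branch lengths, leaves A/C give an exact
        A-vs-C tie at the root; the alphabetically first state is emitted."""
        tree = read_newick("(x:0.2,y:0.2);")
        aln = NucleotideAlignment(taxa=["x", "y"], sequences=["A", "C"])
        fit = fit_nucleotide_model(aln, tree, "JC",
                                   optimize_branch_lengths=False)
        rec = marginal_ancestral_sequence(fit, ["x", "y"])
        assert rec.sequence == "A"
        assert rec.tied_sites == [0]

    def test_non_monophyletic_clade_rejected(self):
        tree = read_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = NucleotideAlignment(taxa=list("ABCD"), sequences=["ACGT"] * 4)
        fit = fit_nucleotide_model(aln, tree, "JC",
                                   optimize_branch_lengths=False)
        with pytest.raises(CladeError):
            marginal_ancestral_sequence(fit, ["A", "C"])

    def test_reconstruction_accuracy_on_shallow_tree(self):
        """> 90% of sites recovered when root-to-tip depth stays <= 0.3."""
        tree = read_newick(
            "(((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05):0.05,"
            "((e:0.1,f:0.1):0.05,(g:0.1,h:0.1):0.05):0.05);")
        params = hky_params(tree, kappa=2.0, freqs=[0.3, 0.2, 0.2, 0.3])
        accs = []
        for seed in range(3):
            aln, truth = simulate_nucleotide_alignment(tree, params, 600,
                                                       seed=40 + seed)
            fit = fit_nucleotide_model(aln, tree, "HKY",
                                       optimize_branch_lengths=False)
            clade = ["a", "b", "c", "d"]
            rec = marginal_ancestral_sequence(fit, clade)
            true_seq = truth[tree.mrca(clade)]
            acc = np.mean([x == y for x, y in zip(rec.sequence, true_seq)])
            accs.append(acc)
        assert np.mean(accs) > 0.9
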