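import numpy as np
import pytest

from conftest import make_params, random_small_instance
from kaksel.codon_model import (
    FitOptions,
    ModelParams,
    brute_force_likelihood,
    build_rate_matrix,
    codon_frequencies,
    fit_model,
    free_ratio_spec,
    log_likelihood,
    multi_ratio_spec,
    sense_codons,
    transition_probabilities,
    uniform_spec,
)
from kaksel.errors import IdentifierError, ParameterError, SizeGuardError
from kaksel.io_formats import CodonAlignment, read_newick
from kaksel.synthetic_data import simulate_codon_alignment


class TestSenseCodons:
    def test_counts(self, code1, code5):
        assert len(sense_codons(code5)) == 62
        assert len(sense_codons(code1)) == 61

    def test_order_stable_and_sorted(self, code5):
        a, b = sense_codons(code5), sense_codons(code5)
        assert a == b == sorted(a)

    def test_stops_excluded(self, code5):
        assert not set(code5.stop_codons) & set(sense_codons(code5))


class TestCodonFrequencies:
    def test_equal(self, code1):
        aln = CodonAlignment(taxa=["A"], sequences=["ATG"], code=code1)
        freqs = codon_frequencies(aln, "equal")
        assert np.allclose(freqs, 1 / 61)

    def test_f3x4_degenerate_composition(self, code5):
        aln = CodonAlignment(taxa=["A", "B"], sequences=["ATGATG", "ATGATG"],
                             code=code5)
        freqs = codon_frequencies(aln, "F3x4")
        idx = sense_codons(code5).index("ATG")
        assert freqs[idx] == pytest.approx(1.0)

    def test_empirical_direct_count(self, code5):
        aln = CodonAlignment(taxa=["A", "B"], sequences=["ATGTTT", "ATGTTT"],
                             code=code5)
        freqs = codon_frequencies(aln, "empirical")
        codons = sense_codons(code5)
        assert freqs[codons.index("ATG")] == pytest.approx(0.5, abs=1e-6)
        assert freqs[codons.index("TTT")] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("model", ["equal", "F1x4", "F3x4", "empirical"])
    def test_sums_to_one(self, aln3, model):
        assert codon_frequencies(aln3, model).sum() == pytest.approx(1.0)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, mito_freqs, code5):
        rng = np.random.default_rng(0)
        for _ in range(5):
            Q = build_rate_matrix(rng.uniform(0.5, 5), rng.uniform(0.01, 2),
                                  mito_freqs, code5)
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_neutral_equal_freq_symmetry(self, code5):
        """kappa=1, omega=1, equal freqs: all single-step rates equal."""
        n = len(sense_codons(code5))
        Q = build_rate_matrix(1.0, 1.0, np.full(n, 1 / n), code5)
        off = Q[~np.eye(n, dtype=bool)]
        positive = off[off > 1e-15]
        assert np.allclose(positive, positive[0])

    def test_detailed_balance(self, mito_freqs, code5):
        Q = build_rate_matrix(2.3, 0.4, mito_freqs, code5)
        flux = mito_freqs[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_expected_rate(self, mito_freqs, code5):
        Q = build_rate_matrix(2.0, 0.1, mito_freqs, code5)
        assert -np.sum(mito_freqs * np.diag(Q)) == pytest.approx(1.0)

    def test_negative_parameters_rejected(self, mito_freqs, code5):
        with pytest.raises(ParameterError):
            build_rate_matrix(-1.0, 0.5, mito_freqs, code5)
        with pytest.raises(ParameterError):
            build_rate_matrix(2.0, -0.5, mito_freqs, code5)


class TestTransitionProbabilities:
    def test_identity_at_zero(self, mito_freqs, code5):
        Q = build_rate_matrix(2.0, 0.5, mito_freqs, code5)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(len(Q)))

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_rows_are_distributions(self, mito_freqs, code5, t):
        Q = build_rate_matrix(2.0, 0.5, mito_freqs, code5)
        P = transition_probabilities(Q, t)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
        assert P.min() >= 0

    def test_long_branch_reaches_stationarity(self, mito_freqs, code5):
        Q = build_rate_matrix(2.0, 0.5, mito_freqs, code5)
        P = transition_probabilities(Q, 100.0)
        assert np.abs(P - mito_freqs[None, :]).max() < 1e-6

    def test_negative_time_rejected(self, mito_freqs, code5):
        Q = build_rate_matrix(2.0, 0.5, mito_freqs, code5)
        with pytest.raises(ParameterError):
            transition_probabilities(Q, -0.1)


class TestLogLikelihood:
    def test_single_taxon_is_log_freqs(self, code5, mito_freqs):
        tree = read_newick("A;")
        aln = CodonAlignment(taxa=["A"], sequences=["ATGTTT"], code=code5)
        spec = uniform_spec(tree, code5)
        params = make_params(spec, mito_freqs, tree)
        expected = sum(
            np.log(mito_freqs[sense_codons(code5).index(c)])
            for c in ["ATG", "TTT"]
        )
        assert log_likelihood(aln, tree, spec, params) == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self, code5):
        rng = np.random.default_rng(1234)
        for _ in range(5):
            aln, tree, spec, params = random_small_instance(rng, code5)
            ll = log_likelihood(aln, tree, spec, params)
            bf = brute_force_likelihood(aln, tree, spec, params)
            assert abs(ll - bf) < 1e-8

    def test_root_placement_invariance(self, code5, mito_freqs):
        """Reversible model: likelihood depends only on the unrooted tree."""
        t1 = read_newick("((A:1.0,B:2.0):0.5,(C:3.0,D:4.0):0.5);")
        t2 = read_newick("(((A:1.0,B:2.0):1.0,C:3.0):1.0,D:3.0);")
        omega = {b: 0.3 for b in t1.branches}
        aln, _ = simulate_codon_alignment(t1, 2.0, mito_freqs, omega, 40,
                                          code5, seed=5)
        for tree in (t1, t2):
            spec = uniform_spec(tree, code5)
            params = make_params(spec, mito_freqs, tree, omega=0.3)
            tree.ll = log_likelihood(aln, tree, spec, params)
        assert t1.ll == pytest.approx(t2.ll, abs=1e-8)

    def test_taxa_mismatch_rejected(self, tree3, code5, mito_freqs):
        aln = CodonAlignment(taxa=["A", "B", "X"],
                             sequences=["ATG", "ATG", "ATG"], code=code5)
        spec = uniform_spec(tree3, code5)
        params = make_params(spec, mito_freqs, tree3)
        with pytest.raises(IdentifierError):
            log_likelihood(aln, tree3, spec, params)

    def test_brute_force_size_guard(self, tree8, code5, mito_freqs):
        aln = CodonAlignment(
            taxa=list("abcdefgh"), sequences=["ATG"] * 8, code=code5)
        spec = uniform_spec(tree8, code5)
        params = make_params(spec, mito_freqs, tree8)
        with pytest.raises(SizeGuardError):
            brute_force_likelihood(aln, tree8, spec, params)


class TestFitModel:
    def test_recovers_known_omega(self, tree8, code5, mito_freqs):
        omega = {b: 0.2 for b in tree8.branches}
        aln, _ = simulate_codon_alignment(tree8, 2.0, mito_freqs, omega, 500,
                                          code5, seed=42)
        fit = fit_model(aln, tree8, uniform_spec(tree8, code5),
                        FitOptions(optimize_branch_lengths=False, multistart=2))
        assert fit.converged
        assert fit.params.omega_by_class["all"] == pytest.approx(0.2, abs=0.05)

    def test_free_ratio_nesting(self, tree6, code5, mito_freqs):
        """Nested models: the free-ratio maximum can never be lower."""
        omega = {b: 0.25 for b in tree6.branches}
        aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 200,
                                          code5, seed=8)
        opts = FitOptions(optimize_branch_lengths=False, multistart=1)
        f_uni = fit_model(aln, tree6, uniform_spec(tree6, code5), opts)
        f_free = fit_model(aln, tree6, free_ratio_spec(tree6, code5), opts)
        assert f_free.log_likelihood >= f_uni.log_likelihood - 1e-6
        assert f_free.n_free_params > f_uni.n_free_params

    def test_two_ratio_recovers_contrast(self, tree6, code5, mito_freqs):
        """Foreground omega 0.7 vs background 0.07 is recovered in order."""
        fore = [tree6.mrca(["a", "b"])]
        omega = {b: (0.7 if b in fore else 0.07) for b in tree6.branches}
        aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 800,
                                          code5, seed=21)
        spec = multi_ratio_spec(tree6, code5, {"fore": fore})
        fit = fit_model(aln, tree6, spec,
                        FitOptions(optimize_branch_lengths=False, multistart=2))
        assert fit.params.omega_by_class["fore"] > fit.params.omega_by_class["background"]
        assert fit.params.omega_by_class["background"] == pytest.approx(0.07, abs=0.04)

    def test_spec_requires_full_branch_cover(self, tree6, code5):
        from kaksel.codon_model import CodonModelSpec

        spec = CodonModelSpec(freq_model="F3x4", omega_classes=["all"],
                              branch_class_map={}, code=code5)
        with pytest.raises(ParameterError):
            spec.validate_against_tree(tree6)
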