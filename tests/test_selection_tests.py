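import itertools

import numpy as np
import pytest
import scipy.stats

from kaksel.branch_metrics import BranchMetrics
from kaksel.codon_model import (
    FitOptions,
    FitResult,
    ModelParams,
    multi_ratio_spec,
    uniform_spec,
)
from kaksel.errors import EmptyResultError, IdentifierError, NestingError
from kaksel.io_formats import SpeciesMetadata, read_newick
from kaksel.selection_tests import (
    BranchSelector,
    DatasetDef,
    LadderSpec,
    ModelDef,
    compare_groups,
    exact_mwu_pvalue,
    filter_branches,
    likelihood_ratio_test,
    remove_outliers,
    run_model_ladder,
)
from kaksel.synthetic_data import simulate_codon_alignment


def fake_fit(tree, code, lnl, n_free, class_branches=None):
    spec = (uniform_spec(tree, code) if not class_branches
            else multi_ratio_spec(tree, code, class_branches))
    freqs = np.full(62, 1 / 62)
    params = ModelParams(
        kappa=2.0, omega_by_class={c: 0.1 for c in spec.omega_classes},
        codon_freqs=freqs, branch_lengths=tree.lengths.copy())
    return FitResult(params=params, log_likelihood=lnl, n_free_params=n_free,
                     converged=True, spec=spec, tree=tree, n_codons=100)


class TestLikelihoodRatioTest:
    def test_equal_likelihoods_give_p_one(self, tree3, code5):
        fore = [tree3.mrca(["A", "B"])]
        f0 = fake_fit(tree3, code5, -100.0, 2)
        f1 = fake_fit(tree3, code5, -100.0, 3, {"fore": fore})
        res = likelihood_ratio_test(f0, f1)
        assert res.statistic == 0 and res.p_value == 1

    def test_chi_square_quantile(self, tree3, code5):
        fore = [tree3.mrca(["A", "B"])]
        f0 = fake_fit(tree3, code5, -100.0, 2)
        f1 = fake_fit(tree3, code5, -100.0 + 3.841 / 2, 3, {"fore": fore})
        res = likelihood_ratio_test(f0, f1)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.05, abs=1e-4)

    def test_statistic_near_five_point_three(self, tree3, code5):
        """2ΔlnL = 5.33 on one degree of freedom sits at p ≈ 0.021."""
        fore = [tree3.mrca(["A", "B"])]
        f0 = fake_fit(tree3, code5, -100.0, 2)
        f1 = fake_fit(tree3, code5, -100.0 + 5.33 / 2, 3, {"fore": fore})
        assert likelihood_ratio_test(f0, f1).p_value == pytest.approx(0.021, abs=5e-4)

    def test_non_nested_rejected(self, tree3, code5):
        fore_a = [tree3.mrca(["A", "B"])]
        leaves = tree3.leaves
        f0 = fake_fit(tree3, code5, -100.0, 3, {"fore": fore_a})
        f1 = fake_fit(tree3, code5, -99.0, 3, {"other": [leaves[0]]})
        with pytest.raises(NestingError):
            likelihood_ratio_test(f0, f1)

    def test_worse_alternative_triggers_refit_error(self, tree3, code5):
        from kaksel.errors import OptimizationError

        fore = [tree3.mrca(["A", "B"])]
        f0 = fake_fit(tree3, code5, -100.0, 2)
        f1 = fake_fit(tree3, code5, -103.0, 3, {"fore": fore})
        with pytest.raises(OptimizationError):
            likelihood_ratio_test(f0, f1)

    def test_p_monotone_in_statistic(self, tree3, code5):
        fore = [tree3.mrca(["A", "B"])]
        f0 = fake_fit(tree3, code5, -100.0, 2)
        ps = []
        for stat in (0.5, 2.0, 6.0):
            f1 = fake_fit(tree3, code5, -100.0 + stat / 2, 3, {"fore": fore})
            ps.append(likelihood_ratio_test(f0, f1).p_value)
        assert ps[0] > ps[1] > ps[2]


def make_metric(species, n_nonsyn, omega=0.1, terminal=True):
    return BranchMetrics(branch_id=0, is_terminal=terminal, species=species,
                         t=0.1, N=2.2, S=0.8, dN=omega * 0.1, dS=0.1,
                         omega=omega, n_nonsyn_subs=n_nonsyn)


class TestFilterBranches:
    def test_threshold_is_strict(self):
        ms = [make_metric("a", 19.9), make_metric("b", 20.0)]
        kept, report = filter_branches(ms, 20)
        assert [m.species for m in kept] == ["b"]
        assert report.discarded_by_reason == {"below_threshold": 1}

    def test_all_above_threshold_unchanged(self):
        ms = [make_metric(s, 30) for s in "abc"]
        kept, report = filter_branches(ms, 20)
        assert len(kept) == 3 and not report.discarded_by_reason

    def test_counts_by_reason(self):
        ms = [make_metric("a", 25), make_metric("b", 5), make_metric("c", 10),
              make_metric("d", 40), make_metric("e", 21)]
        kept, report = filter_branches(ms, 20)
        assert len(kept) == 3
        assert report.discarded_by_reason == {"below_threshold": 2}

    def test_internal_branches_dropped(self):
        ms = [make_metric(None, 50, terminal=False), make_metric("a", 50)]
        kept, report = filter_branches(ms, 20)
        assert len(kept) == 1
        assert report.discarded_by_reason == {"not_terminal": 1}

    def test_empty_result_is_error(self):
        with pytest.raises(EmptyResultError):
            filter_branches([make_metric("a", 1)], 20)


class TestRemoveOutliers:
    def test_no_outliers_unchanged(self):
        assert remove_outliers([1, 2, 3, 4, 5]) == [1, 2, 3, 4, 5]

    def test_tukey_fence(self):
        """Q1=2, Q3=4 by linear interpolation, upper fence 7: 100 removed."""
        assert remove_outliers([1, 2, 3, 4, 100]) == [1, 2, 3, 4]

    def test_small_samples_returned_unchanged(self):
        assert remove_outliers([1, 2, 100]) == [1, 2, 100]

    def test_second_pass_may_remove_more(self):
        values = [1, 1, 1, 1, 1, 1, 8, 40]
        once = remove_outliers(values)
        twice = remove_outliers(once)
        assert 40 not in once
        assert len(twice) <= len(once)


class TestExactMWU:
    def test_identical_samples(self):
        assert exact_mwu_pvalue([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_fully_separated_samples(self):
        """U = 0; 2 of the C(6,3)=20 rank assignments are as extreme."""
        assert exact_mwu_pvalue([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 5), (3, 3), (4, 6), (5, 5), (8, 8)])
    def test_matches_scipy_exact_without_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        x, y = rng.normal(size=n1), rng.normal(0.5, size=n2)
        ours = exact_mwu_pvalue(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


class TestCompareGroups:
    def metadata(self):
        return [SpeciesMetadata(species=f"{g}{i}", group=group)
                for g, group in (("p", "poor-migrating"), ("f", "free-moving"))
                for i in range(3)]

    def metrics(self, poor, free):
        out = []
        for i, v in enumerate(poor):
            out.append(make_metric(f"p{i}", 30, omega=v))
        for i, v in enumerate(free):
            out.append(make_metric(f"f{i}", 30, omega=v))
        return out

    def test_identical_groups_p_one(self):
        ms = self.metrics([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = compare_groups(ms, self.metadata(), outlier_removal=False)
        assert len(res) == 1
        assert res[0].p_value == 1.0
        assert res[0].test_name == "mann-whitney-exact"

    def test_missing_metadata_rejected(self):
        ms = self.metrics([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        with pytest.raises(IdentifierError, match="p0"):
            compare_groups(ms, self.metadata()[3:])

    def test_small_group_skipped(self):
        ms = [make_metric("p0", 30, 0.1), make_metric("p1", 30, 0.2),
              make_metric("f0", 30, 0.3)]
        res = compare_groups(ms, self.metadata())
        assert res == []

    def test_welch_alternative(self):
        ms = self.metrics([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        res = compare_groups(ms, self.metadata(), test="welch",
                             outlier_removal=False)
        assert res[0].test_name == "welch-t"
        assert 0 <= res[0].p_value <= 1

    def test_raw_and_trimmed_means_reported(self):
        ms = self.metrics([0.1, 0.2, 0.3, 0.25, 5.0],
                          [0.1, 0.2, 0.3])
        meta = self.metadata() + [
            SpeciesMetadata(species="p3", group="poor-migrating"),
            SpeciesMetadata(species="p4", group="poor-migrating")]
        res = compare_groups(ms, meta, outlier_removal=True)
        r = res[0]
        trimmed = {r.group_a: (r.mean_a_raw, r.mean_a),
                   r.group_b: (r.mean_b_raw, r.mean_b)}
        raw_mean, mean = trimmed["poor-migrating"]
        assert raw_mean > mean  # outlier 5.0 trimmed


class TestModelLadder:
    def test_detects_injected_relaxation(self, tree6, code5, mito_freqs):
        fore_node = tree6.mrca(["a", "b"])
        omega = {b: (0.71 if b == fore_node else 0.07) for b in tree6.branches}
        aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 800,
                                          code5, seed=77)
        ladder = LadderSpec(datasets=[DatasetDef(
            name="I",
            models=[
                ModelDef(name="A"),
                ModelDef(name="B", foreground={
                    "omega2": BranchSelector(kind="stem", leaves=["a", "b"])}),
            ],
            comparisons=[("B", "A")],
        )])
        result = run_model_ladder(
            aln, tree6, ladder,
            FitOptions(optimize_branch_lengths=False, multistart=1))
        (lrt,) = result.lrt_results
        assert lrt.p_value < 0.05
        fit_b = result.fits[("I", "B")]
        assert fit_b.params.omega_by_class["omega2"] > \
            fit_b.params.omega_by_class["background"]

    def test_taxon_subset_rung(self, tree6, code5, mito_freqs):
        omega = {b: 0.1 for b in tree6.branches}
        aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 100,
                                          code5, seed=78)
        ladder = LadderSpec(datasets=[DatasetDef(
            name="sub", taxa=["a", "b", "c", "d"],
            models=[ModelDef(name="A"),
                    ModelDef(name="B", foreground={
                        "w2": BranchSelector(kind="stem", leaves=["a", "b"])})],
            comparisons=[("B", "A")],
        )])
        result = run_model_ladder(
            aln, tree6, ladder,
            FitOptions(optimize_branch_lengths=False, multistart=1))
        assert len(result.lrt_results) == 1
        assert result.to_frame().shape[0] == 1

    def test_non_monophyletic_clade_rejected(self, tree6, code5, mito_freqs):
        from kaksel.errors import CladeError

        omega = {b: 0.1 for b in tree6.branches}
        aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 50,
                                          code5, seed=79)
        ladder = LadderSpec(datasets=[DatasetDef(
            name="bad",
            models=[ModelDef(name="B", foreground={
                "w2": BranchSelector(kind="stem", leaves=["a", "e"])})],
            comparisons=[],
        )])
        with pytest.raises(CladeError):
            run_model_ladder(aln, tree6, ladder)
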