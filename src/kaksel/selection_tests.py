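"""Nested-model likelihood ratio tests, branch filtering, and
locomotion-group Ka/Ks comparisons.

The LRT ladder generalizes the classic branch-model scheme for localizing
a relaxation of selective constraint: a uniform-ω model against a
two-ratio model singling out an ancestral branch, repeated across datasets
that splice a reconstructed ancestral sequence in as a terminal taxon, and
a two- vs three-ratio comparison separating the ancestral branch from the
within-clade branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .branch_metrics import BranchMetrics
from .codon_model import (
    CodonAlignment,
    CodonModelSpec,
    FitOptions,
    FitResult,
    fit_model,
    multi_ratio_spec,
    uniform_spec,
)
from .errors import (
    EmptyResultError,
    IdentifierError,
    NestingError,
    OptimizationError,
    ParameterError,
)
from .io_formats import PhyloTree, SpeciesMetadata

LNL_TOLERANCE = 0.5  # alt may trail null by at most this much before refit


# ---------------------------------------------------------------------------
# Likelihood ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    """Outcome of one nested-model likelihood ratio test."""

    null_model: FitResult
    alt_model: FitResult
    lnL0: float
    lnL1: float
    statistic: float
    df: int
    p_value: float
    comparison_label: str = ""


def _is_coarsening(null_map: dict[int, str], alt_map: dict[int, str]) -> bool:
    """True when the alt partition refines the null partition."""
    if set(null_map) != set(alt_map):
        return False
    alt_to_null: dict[str, str] = {}
    for b, alt_class in alt_map.items():
        null_class = null_map[b]
        if alt_to_null.setdefault(alt_class, null_class) != null_class:
            return False
    return True


def likelihood_ratio_test(fit0: FitResult, fit1: FitResult,
                          comparison_label: str = "") -> LRTResult:
    """Chi-square LRT of a null fit against a nested richer fit."""
    if not (fit0.converged and fit1.converged):
        raise OptimizationError("both fits must have converged")
    if not _is_coarsening(fit0.spec.branch_class_map, fit1.spec.branch_class_map):
        raise NestingError(
            "null branch-class partition is not a coarsening of the alternative's"
        )
    df = fit1.n_free_params - fit0.n_free_params
    if df < 1:
        raise NestingError(f"df must be >= 1, got {df}")
    stat = 2.0 * (fit1.log_likelihood - fit0.log_likelihood)
    if stat < -LNL_TOLERANCE:
        raise OptimizationError(
            f"alternative lnL {fit1.log_likelihood:.4f} below null "
            f"{fit0.log_likelihood:.4f}; refit with more starts"
        )
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df))
    return LRTResult(
        null_model=fit0, alt_model=fit1,
        lnL0=fit0.log_likelihood, lnL1=fit1.log_likelihood,
        statistic=stat, df=df, p_value=p, comparison_label=comparison_label,
    )


# ---------------------------------------------------------------------------
# Model ladder
# ---------------------------------------------------------------------------

@dataclass
class BranchSelector:
    """Names a set of branches in a tree.

    kinds: ``stem`` (branch above the clade MRCA), ``within`` (branches
    strictly inside the clade), ``stem_and_within``, ``terminal`` (the
    terminal branch of a single named leaf), ``explicit`` (branch ids).
    """

    kind: str
    leaves: list[str] = field(default_factory=list)
    branch_ids: list[int] = field(default_factory=list)

    def resolve(self, tree: PhyloTree) -> list[int]:
        if self.kind == "explicit":
            return list(self.branch_ids)
        if self.kind == "terminal":
            (leaf,) = self.leaves
            matches = [i for i in tree.leaves if tree.names[i] == leaf]
            if not matches:
                raise IdentifierError(f"leaf {leaf!r} not in tree")
            return matches
        node = tree.require_monophyletic(self.leaves, label=f"clade({self.kind})")
        if self.kind == "stem":
            return [node]
        if self.kind == "within":
            return tree.clade_branches(node, include_stem=False)
        if self.kind == "stem_and_within":
            return tree.clade_branches(node, include_stem=True)
        raise ParameterError(f"unknown selector kind {self.kind!r}")


@dataclass
class ModelDef:
    """One model of a ladder: named foreground classes over a background."""

    name: str
    foreground: dict[str, BranchSelector] = field(default_factory=dict)
    background_label: str = "background"

    def build_spec(self, tree: PhyloTree, code, freq_model: str) -> CodonModelSpec:
        if not self.foreground:
            return uniform_spec(tree, code, freq_model)
        class_branches = {
            label: sel.resolve(tree) for label, sel in self.foreground.items()
        }
        return multi_ratio_spec(tree, code, class_branches,
                                background=self.background_label,
                                freq_model=freq_model)


@dataclass
class DatasetDef:
    """A ladder rung: taxon subset, models to fit, comparisons to test."""

    name: str
    models: list[ModelDef]
    comparisons: list[tuple[str, str]]  # (alt_name, null_name)
    taxa: list[str] | None = None


@dataclass
class LadderSpec:
    datasets: list[DatasetDef]
    freq_model: str = "F3x4"


@dataclass
class LadderResult:
    lrt_results: list[LRTResult]
    fits: dict[tuple[str, str], FitResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.lrt_results:
            rows.append(
                {
                    "comparison": r.comparison_label,
                    "lnL_null": r.lnL0,
                    "lnL_alt": r.lnL1,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                }
            )
        return pd.DataFrame(rows)

    def omega_table(self) -> pd.DataFrame:
        rows = []
        for (dataset, model), fit in self.fits.items():
            for label, om in fit.params.omega_by_class.items():
                rows.append(
                    {"dataset": dataset, "model": model,
                     "omega_class": label, "omega": om,
                     "lnL": fit.log_likelihood}
                )
        return pd.DataFrame(rows)


def _warm_start_map(simpler: FitResult, richer_spec) -> dict[str, float]:
    """Initial omegas for a richer partition taken from a simpler fit:
    each richer class inherits the omega of the simpler class holding the
    majority of its branches."""
    from collections import Counter

    out: dict[str, float] = {}
    for c in richer_spec.omega_classes:
        branches = [b for b, cl in richer_spec.branch_class_map.items()
                    if cl == c]
        if not branches:
            continue
        counts = Counter(simpler.spec.branch_class_map.get(b) for b in branches)
        base = counts.most_common(1)[0][0]
        if base in simpler.params.omega_by_class:
            out[c] = simpler.params.omega_by_class[base]
    return out


def run_model_ladder(
    aln: CodonAlignment, tree: PhyloTree, ladder: LadderSpec,
    options: FitOptions | None = None,
    data_by_dataset: dict[str, tuple[CodonAlignment, PhyloTree]] | None = None,
) -> LadderResult:
    """Fit every model of every ladder rung once and run the declared LRTs.

    Richer models are warm-started from every nested simpler fit of the
    same rung; should an alternative still trail its null, it is refitted
    from the null's optimum (guaranteeing the nested-likelihood ordering
    up to optimizer tolerance). ``data_by_dataset`` supplies pre-assembled
    (alignment, tree) pairs per rung — used when rungs splice in
    reconstructed ancestral sequences rather than plain taxon subsets.
    """
    import dataclasses

    options = options or FitOptions()
    data_by_dataset = data_by_dataset or {}
    fits: dict[tuple[str, str], FitResult] = {}
    results: list[LRTResult] = []
    for dataset in ladder.datasets:
        if dataset.name in data_by_dataset:
            sub_aln, sub_tree = data_by_dataset[dataset.name]
        elif dataset.taxa is not None:
            sub_aln = aln.subset_taxa(dataset.taxa)
            sub_tree = tree.extract_subtree(dataset.taxa)
        else:
            sub_aln, sub_tree = aln, tree
        rung_fits: list[FitResult] = []
        for model in dataset.models:
            spec = model.build_spec(sub_tree, aln.code, ladder.freq_model)
            warm = tuple(
                _warm_start_map(prev, spec) for prev in rung_fits
                if _is_coarsening(prev.spec.branch_class_map,
                                  spec.branch_class_map)
            )
            opts = dataclasses.replace(options, extra_start_omegas=warm)
            fit = fit_model(sub_aln, sub_tree, spec, opts)
            fits[(dataset.name, model.name)] = fit
            rung_fits.append(fit)
        for alt_name, null_name in dataset.comparisons:
            label = f"{alt_name} vs {null_name} [{dataset.name}]"
            fit0 = fits[(dataset.name, null_name)]
            fit1 = fits[(dataset.name, alt_name)]
            if fit1.log_likelihood < fit0.log_likelihood - 1e-9:
                opts = dataclasses.replace(
                    options,
                    extra_start_omegas=(_warm_start_map(fit0, fit1.spec),),
                    init_kappa=fit0.params.kappa,
                )
                refit = fit_model(sub_aln, sub_tree, fit1.spec, opts)
                if refit.log_likelihood > fit1.log_likelihood:
                    fit1 = refit
                    fits[(dataset.name, alt_name)] = refit
            results.append(
                likelihood_ratio_test(fit0, fit1, comparison_label=label)
            )
    return LadderResult(lrt_results=results, fits=fits)


# ---------------------------------------------------------------------------
# Terminal-branch filtering and outlier removal
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    discarded_by_reason: dict[str, int]


def filter_branches(metrics: list[BranchMetrics], min_nonsyn_subs: float = 20.0,
                    terminal_only: bool = True) -> tuple[list[BranchMetrics], FilterReport]:
    """Retain (terminal) branches with defined ω and at least
    ``min_nonsyn_subs`` expected nonsynonymous substitutions.

    Mirrors the practice of discarding species whose terminal branch carries
    too few nonsynonymous substitutions for a stable Ka/Ks estimate.
    """
    reasons = {"not_terminal": 0, "undefined_omega": 0, "below_threshold": 0}
    kept: list[BranchMetrics] = []
    for m in metrics:
        if terminal_only and not m.is_terminal:
            reasons["not_terminal"] += 1
        elif not m.omega_defined or not np.isfinite(m.omega):
            reasons["undefined_omega"] += 1
        elif m.n_nonsyn_subs < min_nonsyn_subs:
            reasons["below_threshold"] += 1
        else:
            kept.append(m)
    if not kept:
        raise EmptyResultError("no branches survive filtering")
    return kept, FilterReport(
        n_input=len(metrics), n_retained=len(kept),
        discarded_by_reason={k: v for k, v in reasons.items() if v},
    )


def remove_outliers(values) -> list[float]:
    """Tukey fences: drop values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation. With fewer than 4 values the input
    is returned unchanged. Not idempotent: a second pass may remove more.
    """
    values = list(values)
    if len(values) < 4:
        return values
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [v for v in values if lo <= v <= hi]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """Pairwise comparison of a Ka/Ks-type metric between two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    mean_a_raw: float
    mean_b_raw: float
    test_name: str
    p_value: float
    metric: str


def exact_mwu_pvalue(x, y) -> float:
    """Two-sided exact Mann–Whitney U p-value by enumerating all rank
    assignments (mid-ranks for ties); intended for small samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            count += 1
    return count / total


def group_test(x, y, test: str = "mwu") -> tuple[str, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if test == "mwu":
        if len(x) + len(y) <= 16:
            return "mann-whitney-exact", exact_mwu_pvalue(x, y)
        stat = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic")
        return "mann-whitney-asymptotic", float(stat.pvalue)
    if test == "welch":
        stat = scipy.stats.ttest_ind(x, y, equal_var=False)
        return "welch-t", float(stat.pvalue)
    raise ParameterError(f"unknown test {test!r}")


def compare_groups(metrics: list[BranchMetrics],
                   metadata: list[SpeciesMetadata],
                   metric: str = "KaKs",
                   test: str = "mwu",
                   outlier_removal: bool = True) -> list[GroupComparisonResult]:
    """All pairwise two-sided group comparisons of terminal-branch Ka/Ks
    (or Ka, Ks). Means and medians are reported after Tukey outlier removal
    when enabled; raw means are always carried alongside.
    """
    by_species = {m.species: m for m in metrics if m.is_terminal}
    meta_by_species = {r.species: r for r in metadata}
    missing = sorted(set(by_species) - set(meta_by_species))
    if missing:
        raise IdentifierError(f"species without metadata: {missing}")

    extract = {
        "KaKs": lambda m: m.omega,
        "Ka": lambda m: m.dN,
        "Ks": lambda m: m.dS,
    }
    if metric not in extract:
        raise ParameterError(f"unknown metric {metric!r}")
    getter = extract[metric]

    groups: dict[str, list[float]] = {}
    for species, m in by_species.items():
        groups.setdefault(meta_by_species[species].group, []).append(getter(m))

    results: list[GroupComparisonResult] = []
    for ga, gb in combinations(sorted(groups), 2):
        raw_a, raw_b = groups[ga], groups[gb]
        if len(raw_a) < 2 or len(raw_b) < 2:
            continue  # group too small for a test
        a = remove_outliers(raw_a) if outlier_removal else list(raw_a)
        b = remove_outliers(raw_b) if outlier_removal else list(raw_b)
        test_name, p = group_test(a, b, test)
        results.append(
            GroupComparisonResult(
                group_a=ga, group_b=gb, n_a=len(a), n_b=len(b),
                mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                median_a=float(np.median(a)), median_b=float(np.median(b)),
                mean_a_raw=float(np.mean(raw_a)), mean_b_raw=float(np.mean(raw_b)),
                test_name=test_name, p_value=p, metric=metric,
            )
        )
    return results


def comparisons_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
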