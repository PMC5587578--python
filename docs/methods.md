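# Methods

## Codon substitution model

The core model is a Goldman–Yang-style Markov process on the sense
codons of a genetic code (62 states under the invertebrate mitochondrial
table 5, 61 under the standard table 1; stop codons are excluded from the
state space, so simulated sequences can never contain them). Instantaneous
rates allow only single-nucleotide changes and factor into a target-codon
frequency π_j, a transition/transversion ratio κ, and a nonsynonymous
multiplier ω judged under the relevant code. The chain is reversible by
construction (detailed balance against π holds entrywise), which the test
suite asserts to 1e-12 and which licenses two implementation choices:
transition matrices via symmetric eigendecomposition rather than a
general `expm`, and likelihood invariance to root placement (checked
against an alternative rooting of the same unrooted tree).

Codon frequencies follow the usual schemes — `equal`, `F1x4`, `F3x4`
(default, the conventional choice for codon models when the data do not
say otherwise) and `empirical` with a vanishing pseudocount. The choice
is recorded in every `FitResult`.

**Scaling.** Q is normalized so one unit of branch length equals one
expected substitution per codon under the *background class* ω; all
classes of a multi-ratio model share that scale, keeping branch lengths
comparable between nested models. The free-ratio model instead scales
each branch by its own ω, so each branch length reads directly as
expected substitutions per codon on that branch. The per-branch
decomposition accounts for the convention in use.

**Branch classes.** ω varies over a declared partition of branches:
uniform, multi-ratio (named foreground branch sets — a clade stem, the
branches within a clade, a single terminal branch, or explicit ids — over
a background), or free-ratio. Class labels can ride on Newick node
labels with a `#` separator (`(A,B)#anc:0.1` labels the stem above that
node), so a single tree file can carry the ω-class partition.

## Likelihood and optimization

Site patterns are compressed before pruning; partial likelihoods are
rescaled per node and pattern to avoid underflow. Gap or ambiguous codons
contribute a partial likelihood of one (missing data) — whole taxa with
partial genes are thereby retained rather than dropped. A brute-force
enumerator over all ancestral state assignments (guarded to ≤ 4 leaves
and ≤ 10 codon columns) serves as the oracle: pruning matches it to
1e-8 log-units on randomized instances.

Uniform and multi-ratio models are fitted by L-BFGS-B on log-transformed
κ, per-class ω and (optionally) branch lengths, with ω bounded to
[1e-6, 50] and boundary hits flagged; the default start set spreads
initial ω over {0.05, 0.5, 1.5} because ω surfaces can be multimodal near
boundaries. Convergence tolerance is 1e-6 on the log-likelihood. Ladder
drivers additionally warm-start each richer model from every nested
simpler fit of the same rung, and refit an alternative from its null's
optimum if it ever trails it — this enforces the nested-likelihood
ordering up to optimizer tolerance.

Branch lengths are estimated jointly by default in `fit_model`; the
end-to-end drivers fix them to the input tree by default
(`fix_branch_lengths: true`), which is appropriate when the tree carries
maximum-likelihood branch lengths already (or, for synthetic studies, the
generating lengths) and keeps the ladder fits to two or three free
parameters.

The free-ratio model (one ω per branch, the source of terminal-branch
Ka/Ks) is fitted by coordinate ascent: a uniform fit supplies κ and a
shared ω start; sweeps then re-optimize each branch's (t, ω) against
cached above/below partial likelihoods — the exact single-branch
contraction A·P(t,ω)·B — with partials recomputed between sweeps and κ
re-optimized after the first sweep. Sweeps stop when a full pass gains
less than 0.01 log-units (at most 5 passes). Within-sweep evaluations use
partials that are stale with respect to earlier updates in the same
sweep; the exact likelihood is recomputed at each sweep's end and the best
snapshot kept, so the reported optimum is always exactly evaluated.

## Ka/Ks decomposition and site counts

Site counts use the model's own mutational opportunity at neutrality:
N/(N+S) is the π- and κ-weighted fraction of single-nucleotide sense
changes that are nonsynonymous, scaled so N + S = 3 per codon (at equal
frequencies and κ = 1 under the standard code this gives the classical
~25% synonymous opportunity). On a branch of effective length t with
class ω, the expected fractions of nonsynonymous vs synonymous events are
ρN = ωW_N/(ωW_N + W_S), ρS = 1 − ρN, and

    Ka = dN = t·ρN / (3N/(N+S)),   Ks = dS = t·ρS / (3S/(N+S)),

whence dN/dS ≡ ω as an algebraic identity — asserted to 1e-6 on every
converged fit. Branches with undefined ω (dS = 0) are flagged and
excluded downstream with a log entry. The expected nonsynonymous
substitution count on a branch is dN·N·(number of codons).

**Nei–Gojobori (1986)** is implemented as an independent counting route:
per-codon site fractions (mutations creating stop codons counted as
nonsynonymous so that s + n = 3 per codon), equal-weight averaging over
minimal mutational pathways for 2–3-difference codons with
stop-traversing pathways excluded (falling back to the unrestricted set
only if every pathway is blocked), and the Jukes–Cantor correction with
p ≥ 3/4 flagged as saturated (distance undefined). On neutral simulated
pairs NG86 Ka/Ks averages 1, and it rank-correlates > 0.9 with pairwise
ML ω across simulated pairs — the dual-route check that the likelihood
and counting implementations agree about ordering.

## Selection tests

Likelihood ratio tests require the null's branch-class partition to be a
coarsening of the alternative's; 2ΔlnL is referred to χ² with df equal to
the difference in free parameter counts (1 for uniform-vs-two-ratio and
two-vs-three-ratio ladders). No boundary-mixture correction is applied —
the relaxation alternatives move ω in the interior, and the null
calibration test confirms the χ² reference is, if anything, slightly
conservative (empirical size ≈ 0.03 at nominal 0.05).

**Terminal-branch filter.** Terminal branches with fewer than 20 expected
nonsynonymous substitutions are discarded before group comparisons
(threshold configurable; the uniform-ω nuclear control gene is analyzed
with the filter disabled, since a short conserved gene would otherwise
lose every branch). **Outlier removal** is the Tukey rule with linearly
interpolated quartiles; it is deliberately not idempotent (a second pass
may trim more), and group means are reported both raw and trimmed.

**Group comparisons** default to the two-sided Mann–Whitney U — exact by
full enumeration of rank assignments (mid-ranks for ties) when the
combined sample is ≤ 16, the tie-corrected normal approximation
otherwise — because terminal Ka/Ks distributions are positive and
right-skewed. Welch's t is available for parity. The three pairwise group
tests are reported without multiple-testing correction (a Holm option
exists, off by default).

## Ancestral reconstruction and the relaxation ladder

Nucleotide models (JC, HKY, GTR; empirical base frequencies; optional
4-category discrete gamma with ML shape, optional invariant-sites
proportion) support *marginal* reconstruction: per-site state posteriors
at a named clade's MRCA from upward/downward partials, mixture-averaged
over rate categories, argmax emitted with ties broken alphabetically
(A<C<G<T) and flagged. Posteriors match Bayes-rule enumeration on small
instances to 1e-10.

The ladder mirrors the three-dataset design for localizing relaxation:
dataset I replaces the focal clade by its reconstructed ancestor (spliced
in as an ordinary taxon keeping the stem branch length — the declared
convention, since no standard protocol exists; in-frame stop codons
arising from nucleotide-level reconstruction are masked to gaps),
testing uniform vs two-ratio on the ancestor's terminal branch; dataset
II repeats this one clade deeper (the marine subclade); dataset III keeps
all extant taxa and contrasts a shared foreground ω on the subclade stem
plus its internal branches (two-ratio) against splitting stem from
within-subclade branches (three-ratio). Reconstruction under a uniform
nucleotide model shrinks the ancestor toward the outgroup, so the
two-ratio ω on the ancestor branch is attenuated relative to the
generating value; the LRT detects the relaxation regardless, which is
what the ladder tests.

## Synthetic studies

The generator emulates the comparative design: a rooted tree with three
monophyletic locomotion-group clades (the poor-migrating clade split into
marine and freshwater subclades so both ladder depths exist), terminal
branch ω drawn log-normally around group means, internal branches at a
background ω, a multi-gene mitochondrial-like set under table 5, a
uniform-ω nuclear-like control under table 1, and an Atp8-like gene whose
relaxation sits on the bivalve-like stem only. Defaults, chosen once as
the study conditions:

| knob | default | rationale |
| --- | --- | --- |
| group mean ω | 0.0559 / 0.0340 / 0.0240 | the group contrasts the analysis targets |
| background / relaxed ω | 0.07 / 0.71 | the ancestral-relaxation magnitudes the ladder must resolve |
| control ω | 0.05 | histone-like strong conservation, group-independent |
| ω log-sd | 0.4 | right-skewed terminal scatter comparable to observed Ka/Ks spreads |
| taxa per group | 15 | desk-scale stand-in for a multi-hundred-genome survey |
| κ | 2.0 | typical mtDNA transition bias |
| codon freqs | per-position product of T/C/A/G = 0.35/0.15/0.30/0.20 | AT-rich mitochondrial composition |
| mito genes | 4 × 300 codons | a pooled multi-gene mitochondrial set |
| Atp8-like gene | 800 codons | sized so the single-branch ladder test has usable power at desk scale |
| terminal / internal branch length | 0.4 / 0.15 subs per codon (log-normal, sd 0.3) | deep divergences typical of phylum-wide mtDNA |

Tree shapes are balanced by default; a pure-birth/birth-death option
(ultrametric before length noise) is available. Identical seeds give
byte-identical FASTA/Newick/TSV output.

What the generator does **not** emulate: indels and alignment error,
recombination, gene-order/strand architecture, doubly uniparental
inheritance, among-site rate or ω heterogeneity within a gene,
composition drift across lineages, and non-monophyletic locomotion
groups. Passing tests therefore demonstrate correctness of the machinery
and power/calibration under the declared generative regime, not
robustness to real-data misspecification.

## Numerical choices and degenerate inputs

- ω ∈ [1e-6, 50], κ ∈ [0.01, 100], branch lengths ∈ [1e-8, 20]; boundary
  hits are flagged in `FitResult.warnings`, not raised.
- Zero-frequency codons are floored at 1e-12 inside the spectral
  decomposition only (unreachable states stay effectively unreachable).
- Non-convergence yields `converged=False` rather than an exception;
  LRTs refuse unconverged fits.
- Degenerate alignments (no resolved codons) raise a data error; a
  column filter that would empty the alignment raises rather than
  returning an empty object.
- Codon column coordinates in filter reports are 0-based half-open.
- All stochastic routines take explicit seeds; pipeline provenance
  records seed, config echo and a config hash in every output table.

## Scope and limitations

Site models and branch-site models, modified counting variants
(LWL85/YN00), RELAX-style k-parameter tests, alignment construction and
tree inference are out of scope — trees and in-frame alignments are
inputs. The simplified codon-column gap/ambiguity filter replaces
block-based alignment trimming; it is declared in its report for
provenance but is not a faithful reimplementation of block heuristics.
The free-ratio optimizer is a coordinate method: its optimum is exact at
the reported likelihood but may, like any multimodal ω surface, admit
better local optima for individual short branches; terminal branches
below the nonsynonymous-count filter are excluded downstream precisely
because such estimates are unstable.
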