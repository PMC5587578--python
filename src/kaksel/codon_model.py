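"""Goldman–Yang-style codon substitution model with branch-class ω.

The instantaneous rate from sense codon *i* to *j* is

    q_ij ∝ 0                      if i, j differ at more than one position
    q_ij ∝ π_j                    synonymous transversion
    q_ij ∝ κ π_j                  synonymous transition
    q_ij ∝ ω π_j                  nonsynonymous transversion
    q_ij ∝ ω κ π_j                nonsynonymous transition

with π the stationary sense-codon frequencies, κ the transition/transversion
rate ratio and ω = dN/dS the selection intensity. Synonymy is judged under
the alignment's genetic code, so the invertebrate mitochondrial code
(table 5, 62 sense codons) and the standard code (table 1, 61) yield
different matrices. ω varies over prespecified branch classes: a uniform
model has one class, a two-ratio model a foreground and a background class,
and the free-ratio model one class per branch.

Scaling convention: Q is normalized so that one unit of branch length is
one expected substitution per codon *under the background class ω*; all
classes share that scale so branch lengths stay comparable across models.
The free-ratio model instead scales each branch by its own ω (each branch
length is expected substitutions per codon on that branch).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.optimize

from ._engine import PruningEngine, ReversibleRate, compress_columns
from .errors import (
    DataError,
    IdentifierError,
    NumericalError,
    ParameterError,
    SizeGuardError,
)
from .io_formats import NUCLEOTIDES, CodonAlignment, GeneticCode, PhyloTree

OMEGA_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
BRLEN_BOUNDS = (1e-8, 20.0)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Code structure (cached per translation table)
# ---------------------------------------------------------------------------

class CodeStructure:
    """Sense-codon state space plus single-step change classification."""

    def __init__(self, code: GeneticCode):
        self.code = code
        self.sense = sense_codons(code)
        self.n = len(self.sense)
        self.index = {c: i for i, c in enumerate(self.sense)}
        n = self.n
        self.single_step = np.zeros((n, n), dtype=bool)
        self.is_transition = np.zeros((n, n), dtype=bool)
        self.is_nonsyn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.sense):
            for j, cj in enumerate(self.sense):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                self.single_step[i, j] = True
                self.is_transition[i, j] = diffs[0] in _TRANSITIONS
                self.is_nonsyn[i, j] = code.translate(ci) != code.translate(cj)


_STRUCT_CACHE: dict[int, CodeStructure] = {}


def code_structure(code: GeneticCode) -> CodeStructure:
    if code.table_id not in _STRUCT_CACHE:
        _STRUCT_CACHE[code.table_id] = CodeStructure(code)
    return _STRUCT_CACHE[code.table_id]


def sense_codons(code: GeneticCode) -> list[str]:
    """All non-stop codons of the code, lexicographically ordered."""
    return sorted(c for c, aa in code.codon_to_aa.items() if aa != "*")


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------

def codon_frequencies(aln: CodonAlignment, freq_model: str = "F3x4") -> np.ndarray:
    """Stationary sense-codon frequencies under one of the standard schemes.

    ``equal``: uniform over sense codons. ``F1x4``/``F3x4``: products of
    pooled / position-specific nucleotide frequencies renormalized over
    sense codons. ``empirical``: observed codon proportions (tiny
    pseudocount keeps unseen codons harmless).
    """
    struct = code_structure(aln.code)
    n = struct.n
    if freq_model == "equal":
        return np.full(n, 1.0 / n)

    nt_index = {c: i for i, c in enumerate(NUCLEOTIDES)}
    pos_counts = np.zeros((3, 4))
    codon_counts = np.zeros(n)
    n_codons_seen = 0
    for seq in aln.sequences:
        for j in range(0, len(seq), 3):
            codon = seq[j : j + 3]
            if all(ch in NUCLEOTIDES for ch in codon):
                n_codons_seen += 1
                for p, ch in enumerate(codon):
                    pos_counts[p, nt_index[ch]] += 1
                if codon in struct.index:
                    codon_counts[struct.index[codon]] += 1
    if n_codons_seen == 0:
        raise DataError("alignment has no fully resolved codons")

    if freq_model == "empirical":
        freqs = codon_counts + 1e-10
    elif freq_model == "F3x4":
        pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        freqs = np.array(
            [
                pos_freqs[0, nt_index[c[0]]]
                * pos_freqs[1, nt_index[c[1]]]
                * pos_freqs[2, nt_index[c[2]]]
                for c in struct.sense
            ]
        )
    elif freq_model == "F1x4":
        pooled = pos_counts.sum(axis=0)
        pooled = pooled / pooled.sum()
        freqs = np.array(
            [pooled[nt_index[c[0]]] * pooled[nt_index[c[1]]] * pooled[nt_index[c[2]]]
             for c in struct.sense]
        )
    else:
        raise ParameterError(f"unknown frequency model {freq_model!r}")
    total = freqs.sum()
    if total <= 0:
        raise DataError("degenerate codon frequencies")
    return freqs / total


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------

class QBuilder:
    """Unnormalized GY94 rate matrices for fixed (κ, π), linear in ω.

    ``Q(ω) = Q_syn + ω Q_nonsyn`` and the π-weighted total rate is
    ``rate(ω) = r_syn + ω r_nonsyn``, which makes ω-scans during
    optimization cheap.
    """

    def __init__(self, kappa: float, codon_freqs: np.ndarray, code: GeneticCode):
        if kappa <= 0:
            raise ParameterError(f"kappa must be > 0, got {kappa}")
        struct = code_structure(code)
        pi = np.asarray(codon_freqs, float)
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ParameterError("codon frequencies must sum to 1")
        base = np.where(struct.single_step,
                        np.where(struct.is_transition, kappa, 1.0), 0.0)
        base = base * pi[None, :]
        self.Q_syn = np.where(struct.is_nonsyn, 0.0, base)
        self.Q_nonsyn = np.where(struct.is_nonsyn, base, 0.0)
        self.pi = pi
        self.r_syn = float(np.sum(pi[:, None] * self.Q_syn))
        self.r_nonsyn = float(np.sum(pi[:, None] * self.Q_nonsyn))

    def rate(self, omega: float) -> float:
        return self.r_syn + omega * self.r_nonsyn

    def Q(self, omega: float, scale: float | None = None) -> np.ndarray:
        """Rate matrix with diagonal set; divided by ``scale`` (default: own rate)."""
        if omega < 0:
            raise ParameterError(f"omega must be >= 0, got {omega}")
        Q = self.Q_syn + omega * self.Q_nonsyn
        np.fill_diagonal(Q, 0.0)
        Q[np.arange(len(Q)), np.arange(len(Q))] = -Q.sum(axis=1)
        if scale is None:
            scale = self.rate(omega)
        if scale <= 0:
            raise ParameterError("degenerate rate matrix (zero total rate)")
        return Q / scale


def build_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                      code: GeneticCode, normalize: bool = True) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to one expected
    substitution per codon per unit time when ``normalize``."""
    builder = QBuilder(kappa, codon_freqs, code)
    return builder.Q(omega, scale=None if normalize else 1.0)


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to one, entries clipped to be nonnegative."""
    if t < 0:
        raise ParameterError(f"branch length must be >= 0, got {t}")
    P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# Model specification and parameters
# ---------------------------------------------------------------------------

@dataclass
class CodonModelSpec:
    """Branch-class layout of a codon model.

    ``omega_classes[0]`` is the background class used for the shared Q
    scaling; ``branch_class_map`` maps every branch id (child node index)
    to a class label. ``scale_per_class`` switches to per-branch scaling
    (free-ratio convention).
    """

    freq_model: str
    omega_classes: list[str]
    branch_class_map: dict[int, str]
    code: GeneticCode
    estimate_kappa: bool = True
    scale_per_class: bool = False
    free_ratio: bool = False

    def __post_init__(self) -> None:
        if not self.omega_classes:
            raise ParameterError("at least one omega class required")
        extra = set(self.branch_class_map.values()) - set(self.omega_classes)
        if extra:
            raise ParameterError(f"branch classes not declared: {sorted(extra)}")

    @property
    def background_class(self) -> str:
        return self.omega_classes[0]

    def validate_against_tree(self, tree: PhyloTree) -> None:
        missing = [b for b in tree.branches if b not in self.branch_class_map]
        if missing:
            raise ParameterError(f"branches without class assignment: {missing}")


def uniform_spec(tree: PhyloTree, code: GeneticCode,
                 freq_model: str = "F3x4") -> CodonModelSpec:
    """One-ratio model: a single ω shared by every branch."""
    return CodonModelSpec(
        freq_model=freq_model,
        omega_classes=["all"],
        branch_class_map={b: "all" for b in tree.branches},
        code=code,
    )


def multi_ratio_spec(tree: PhyloTree, code: GeneticCode,
                     class_branches: dict[str, list[int]],
                     background: str = "background",
                     freq_model: str = "F3x4") -> CodonModelSpec:
    """Multi-ratio model: named foreground branch sets, rest background."""
    branch_map = {b: background for b in tree.branches}
    for label, branches in class_branches.items():
        for b in branches:
            if b not in branch_map:
                raise ParameterError(f"unknown branch id {b}")
            branch_map[b] = label
    return CodonModelSpec(
        freq_model=freq_model,
        omega_classes=[background] + list(class_branches),
        branch_class_map=branch_map,
        code=code,
    )


def free_ratio_spec(tree: PhyloTree, code: GeneticCode,
                    freq_model: str = "F3x4") -> CodonModelSpec:
    """Free-ratio model: every branch its own ω class (``b<node>`` labels)."""
    classes = [f"b{b}" for b in tree.branches]
    return CodonModelSpec(
        freq_model=freq_model,
        omega_classes=classes,
        branch_class_map={b: f"b{b}" for b in tree.branches},
        code=code,
        scale_per_class=True,
        free_ratio=True,
    )


def spec_from_tree_labels(tree: PhyloTree, code: GeneticCode,
                          background: str = "background",
                          freq_model: str = "F3x4") -> CodonModelSpec:
    """Build a spec from ``#class`` labels carried on the tree's branches."""
    branch_map = {}
    for b in tree.branches:
        branch_map[b] = tree.branch_class[b] or background
    classes = [background] + sorted(set(branch_map.values()) - {background})
    return CodonModelSpec(freq_model=freq_model, omega_classes=classes,
                          branch_class_map=branch_map, code=code)


@dataclass
class ModelParams:
    """Numerical parameters of a codon model instance."""

    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray
    branch_lengths: np.ndarray  # indexed by node id; root entry ignored

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be > 0, got {self.kappa}")
        for label, om in self.omega_by_class.items():
            if om < 0:
                raise ParameterError(f"omega[{label}] must be >= 0, got {om}")
        total = float(np.sum(self.codon_freqs))
        if abs(total - 1.0) > 1e-10:
            raise ParameterError(f"codon frequencies sum to {total}, expected 1")


@dataclass
class FitResult:
    """Maximum-likelihood fit of a codon model."""

    params: ModelParams
    log_likelihood: float
    n_free_params: int
    converged: bool
    spec: CodonModelSpec
    tree: PhyloTree
    n_codons: int
    gene_name: str = ""
    per_branch: list | None = None
    warnings: list[str] = field(default_factory=list)

    def branch_omega(self, branch: int) -> float:
        return self.params.omega_by_class[self.spec.branch_class_map[branch]]

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {"parameter": "lnL", "value": self.log_likelihood},
            {"parameter": "kappa", "value": self.params.kappa},
        ]
        rows += [
            {"parameter": f"omega[{c}]", "value": v}
            for c, v in self.params.omega_by_class.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def encode_alignment(aln: CodonAlignment, tree: PhyloTree):
    """Map alignment columns onto tree leaves as state-index patterns."""
    struct = code_structure(aln.code)
    leaf_nodes = tree.leaves
    tree_names = [tree.names[i] for i in leaf_nodes]
    if set(tree_names) != set(aln.taxa):
        raise IdentifierError(
            f"tree/alignment taxa mismatch: only-tree={sorted(set(tree_names) - set(aln.taxa))} "
            f"only-alignment={sorted(set(aln.taxa) - set(tree_names))}"
        )
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    columns = np.full((len(leaf_nodes), aln.n_codons), -1, dtype=np.int64)
    for k, node in enumerate(leaf_nodes):
        seq = aln.sequences[taxon_row[tree.names[node]]]
        for j in range(aln.n_codons):
            codon = seq[3 * j : 3 * j + 3]
            columns[k, j] = struct.index.get(codon, -1)
    patterns, weights = compress_columns(columns)
    leaf_states = {node: patterns[k] for k, node in enumerate(leaf_nodes)}
    return PruningEngine(tree, leaf_states, weights, struct.n)


def _class_rates(spec: CodonModelSpec, params: ModelParams) -> dict[str, ReversibleRate]:
    builder = QBuilder(params.kappa, params.codon_freqs, spec.code)
    pi_safe = np.maximum(params.codon_freqs, 1e-12)
    background_rate = builder.rate(params.omega_by_class[spec.background_class])
    rates = {}
    for label in spec.omega_classes:
        om = params.omega_by_class[label]
        scale = builder.rate(om) if spec.scale_per_class else background_rate
        rates[label] = ReversibleRate(builder.Q(om, scale=scale), pi_safe)
    return rates


def branch_transition_matrices(tree: PhyloTree, spec: CodonModelSpec,
                               params: ModelParams) -> dict[int, np.ndarray]:
    rates = _class_rates(spec, params)
    return {
        b: rates[spec.branch_class_map[b]].transition(float(params.branch_lengths[b]))
        for b in tree.branches
    }


def log_likelihood(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
                   params: ModelParams) -> float:
    """Felsenstein pruning log-likelihood of the alignment on the tree."""
    spec.validate_against_tree(tree)
    engine = encode_alignment(aln, tree)
    P = branch_transition_matrices(tree, spec, params)
    return engine.loglik(P, np.maximum(params.codon_freqs, 1e-300))


def brute_force_likelihood(aln: CodonAlignment, tree: PhyloTree,
                           spec: CodonModelSpec, params: ModelParams) -> float:
    """Exact log-likelihood by enumerating every ancestral codon assignment.

    Test oracle only; guarded to ≤ 4 leaves and ≤ 10 codon columns.
    """
    if len(tree.leaves) > 4 or aln.n_codons > 10:
        raise SizeGuardError("brute-force oracle limited to 4 leaves / 10 codons")
    struct = code_structure(aln.code)
    K = struct.n
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    if K ** len(internal) > 20_000_000:
        raise SizeGuardError("state-space enumeration too large")
    P = branch_transition_matrices(tree, spec, params)
    pi = params.codon_freqs

    grids = np.meshgrid(*[np.arange(K)] * len(internal), indexing="ij")
    states = {node: g.ravel() for node, g in zip(internal, grids)}
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    leaf_state = {
        node: aln.sequences[taxon_row[tree.names[node]]]
        for node in tree.leaves
    }

    total = 0.0
    for site in range(aln.n_codons):
        factors = pi[states[tree.root]].astype(float)
        for v in tree.branches:
            u = int(tree.parent[v])
            if tree.is_leaf(v):
                codon = leaf_state[v][3 * site : 3 * site + 3]
                if codon in struct.index:
                    factors = factors * P[v][states[u], struct.index[codon]]
                # missing data: factor 1
            else:
                factors = factors * P[v][states[u], states[v]]
        site_lik = factors.sum()
        if site_lik <= 0:
            raise NumericalError(f"zero likelihood at codon column {site}")
        total += float(np.log(site_lik))
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer controls for :func:`fit_model`."""

    multistart: int = 3
    init_omegas: tuple[float, ...] = (0.05, 0.5, 1.5)
    #: extra start points, each a mapping class label -> initial omega
    #: (e.g. the optimum of a nested simpler model)
    extra_start_omegas: tuple[dict, ...] = ()
    init_kappa: float = 2.0
    tol: float = 1e-6
    max_iter: int = 500
    fix_kappa: float | None = None
    optimize_branch_lengths: bool = True
    free_ratio_passes: int = 5
    free_ratio_pass_tol: float = 1e-2


def _pack_bounds(n_classes: int, n_branches: int, kappa_free: bool):
    bounds = []
    if kappa_free:
        bounds.append(tuple(np.log(KAPPA_BOUNDS)))
    bounds += [tuple(np.log(OMEGA_BOUNDS))] * n_classes
    bounds += [tuple(np.log(BRLEN_BOUNDS))] * n_branches
    return bounds


def fit_model(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
              options: FitOptions | None = None) -> FitResult:
    """Maximize the pruning likelihood over κ, per-class ω and optionally
    branch lengths (bounded quasi-Newton on log-transformed parameters,
    multistart over spread initial ω)."""
    options = options or FitOptions()
    spec.validate_against_tree(tree)
    if spec.free_ratio:
        return _fit_free_ratio(aln, tree, spec, options)

    engine = encode_alignment(aln, tree)
    freqs = codon_frequencies(aln, spec.freq_model)
    pi_safe = np.maximum(freqs, 1e-300)
    branches = tree.branches
    kappa_free = spec.estimate_kappa and options.fix_kappa is None
    fixed_kappa = options.fix_kappa if options.fix_kappa is not None else options.init_kappa
    n_classes = len(spec.omega_classes)
    opt_bl = options.optimize_branch_lengths
    n_bl = len(branches) if opt_bl else 0
    init_bl = np.clip(tree.lengths[branches], BRLEN_BOUNDS[0] * 10, BRLEN_BOUNDS[1])

    def unpack(x):
        idx = 0
        kappa = float(np.exp(x[idx])) if kappa_free else fixed_kappa
        idx += int(kappa_free)
        omegas = dict(zip(spec.omega_classes, np.exp(x[idx : idx + n_classes])))
        idx += n_classes
        bl = tree.lengths.copy()
        if opt_bl:
            bl[branches] = np.exp(x[idx : idx + n_bl])
        return kappa, omegas, bl

    def negloglik(x):
        kappa, omegas, bl = unpack(x)
        params = ModelParams(kappa=kappa, omega_by_class=omegas,
                             codon_freqs=freqs, branch_lengths=bl)
        try:
            P = branch_transition_matrices(tree, spec, params)
            return -engine.loglik(P, pi_safe)
        except NumericalError:
            return 1e12

    starts: list[dict] = [
        {c: om0 for c in spec.omega_classes}
        for om0 in options.init_omegas[: max(1, options.multistart)]
    ]
    for extra in options.extra_start_omegas:
        starts.append({c: extra.get(c, options.init_omegas[0])
                       for c in spec.omega_classes})
    best = None
    any_success = False
    for start in starts:
        x0 = []
        if kappa_free:
            x0.append(np.log(options.init_kappa))
        x0 += [np.log(np.clip(start[c], *OMEGA_BOUNDS))
               for c in spec.omega_classes]
        if opt_bl:
            x0 += list(np.log(init_bl))
        res = scipy.optimize.minimize(
            negloglik, np.array(x0), method="L-BFGS-B",
            bounds=_pack_bounds(n_classes, n_bl, kappa_free),
            options={"maxiter": options.max_iter, "ftol": options.tol},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    kappa, omegas, bl = unpack(best.x)
    warnings = []
    for label, om in omegas.items():
        if om <= OMEGA_BOUNDS[0] * 2 or om >= OMEGA_BOUNDS[1] * 0.98:
            warnings.append(f"omega[{label}]={om:.3g} at bound")
    params = ModelParams(kappa=kappa, omega_by_class=omegas,
                         codon_freqs=freqs, branch_lengths=bl)
    n_free = int(kappa_free) + n_classes + n_bl
    return FitResult(
        params=params,
        log_likelihood=-float(best.fun),
        n_free_params=n_free,
        converged=any_success and np.isfinite(best.fun),
        spec=spec,
        tree=tree,
        n_codons=aln.n_codons,
        gene_name=aln.gene_name,
        warnings=warnings,
    )


def _fit_free_ratio(aln: CodonAlignment, tree: PhyloTree, spec: CodonModelSpec,
                    options: FitOptions) -> FitResult:
    """Coordinate-ascent fit of the free-ratio model.

    A uniform model is fitted first for κ and a shared ω start; passes then
    sweep the branches, re-optimizing each branch's (t, ω) against cached
    above/below partials (exact single-branch likelihood contractions),
    recomputing the partials between passes. κ is re-optimized after the
    first pass. Stops when a full pass gains less than
    ``free_ratio_pass_tol`` log-units.
    """
    base = uniform_spec(tree, spec.code, spec.freq_model)
    base_opts = replace(options, optimize_branch_lengths=False)
    base_fit = fit_model(aln, tree, base, base_opts)
    kappa = base_fit.params.kappa
    freqs = base_fit.params.codon_freqs
    pi_safe = np.maximum(freqs, 1e-12)
    engine = encode_alignment(aln, tree)
    branches = tree.branches
    omega = {b: base_fit.params.omega_by_class["all"] for b in branches}
    brlen = tree.lengths.copy().astype(float)
    np.clip(brlen, BRLEN_BOUNDS[0] * 10, BRLEN_BOUNDS[1], out=brlen)
    opt_bl = options.optimize_branch_lengths

    log_ob = np.log(OMEGA_BOUNDS)
    log_tb = np.log(BRLEN_BOUNDS)

    def builder_for(kp):
        return QBuilder(kp, freqs, spec.code)

    builder = builder_for(kappa)

    def P_map():
        out = {}
        cache: dict[float, ReversibleRate] = {}
        for b in branches:
            om = omega[b]
            if om not in cache:
                cache[om] = ReversibleRate(builder.Q(om), pi_safe)
            out[b] = cache[om].transition(float(brlen[b]))
        return out

    def full_loglik():
        return engine.loglik(P_map(), pi_safe)

    best_ll = full_loglik()
    best_state = (dict(omega), brlen.copy(), kappa)

    for sweep in range(options.free_ratio_passes):
        context = engine.branch_context(P_map(), pi_safe)
        for b in branches:
            A, B, ls = context[b]

            if opt_bl:
                def neg(z):
                    om, t = float(np.exp(z[0])), float(np.exp(z[1]))
                    P = ReversibleRate(builder.Q(om), pi_safe).transition(t)
                    return -PruningEngine.edge_loglik(A, B, ls, P, engine.weights)

                z0 = np.array([np.log(omega[b]), np.log(brlen[b])])
                res = scipy.optimize.minimize(
                    neg, z0, method="L-BFGS-B",
                    bounds=[tuple(log_ob), tuple(log_tb)],
                    options={"maxiter": 60},
                )
                omega[b] = float(np.exp(res.x[0]))
                brlen[b] = float(np.exp(res.x[1]))
            else:
                def neg1(z):
                    om = float(np.exp(z))
                    P = ReversibleRate(builder.Q(om), pi_safe).transition(float(brlen[b]))
                    return -PruningEngine.edge_loglik(A, B, ls, P, engine.weights)

                res = scipy.optimize.minimize_scalar(
                    neg1, bounds=tuple(log_ob), method="bounded",
                    options={"xatol": 1e-4},
                )
                omega[b] = float(np.exp(res.x))

        if sweep == 0 and spec.estimate_kappa and options.fix_kappa is None:
            def neg_kappa(logk):
                nonlocal builder
                builder = builder_for(float(np.exp(logk)))
                return -full_loglik()

            res = scipy.optimize.minimize_scalar(
                neg_kappa, bounds=tuple(np.log(KAPPA_BOUNDS)), method="bounded",
                options={"xatol": 1e-3},
            )
            kappa = float(np.exp(res.x))
            builder = builder_for(kappa)

        ll = full_loglik()
        if ll > best_ll:
            gain = ll - best_ll
            best_ll = ll
            best_state = (dict(omega), brlen.copy(), kappa)
            if gain < options.free_ratio_pass_tol and sweep > 0:
                break
        else:
            omega, brlen, kappa = dict(best_state[0]), best_state[1].copy(), best_state[2]
            builder = builder_for(kappa)
            break

    omega, brlen, kappa = best_state
    omega_by_class = {f"b{b}": omega[b] for b in branches}
    params = ModelParams(kappa=kappa, omega_by_class=omega_by_class,
                         codon_freqs=freqs, branch_lengths=brlen)
    warnings = [
        f"omega[b{b}]={omega[b]:.3g} at bound"
        for b in branches
        if omega[b] <= OMEGA_BOUNDS[0] * 2 or omega[b] >= OMEGA_BOUNDS[1] * 0.98
    ]
    kappa_free = spec.estimate_kappa and options.fix_kappa is None
    n_free = int(kappa_free) + len(branches) * (2 if opt_bl else 1)
    return FitResult(
        params=params,
        log_likelihood=best_ll,
        n_free_params=n_free,
        converged=True,
        spec=spec,
        tree=tree,
        n_codons=aln.n_codons,
        gene_name=aln.gene_name,
        warnings=warnings,
    )
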