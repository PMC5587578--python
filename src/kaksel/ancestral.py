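"""Nucleotide substitution models and marginal ancestral sequence
reconstruction.

Supports JC, HKY and GTR with empirical base frequencies, an optional
4-category discrete-gamma rate mixture (category means, shape estimated by
ML) and an optional invariant-sites proportion. The marginal
reconstruction at a named internal node combines upward and downward
partial likelihoods into per-site state posteriors and emits the
per-site argmax (ties broken alphabetically A<C<G<T and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from ._engine import PruningEngine, ReversibleRate, compress_columns
from .errors import DataError, IdentifierError, NumericalError, ParameterError
from .io_formats import NUCLEOTIDES, NucleotideAlignment, PhyloTree

_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
# exchangeability slot order for GTR
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
_TS_SLOTS = (1, 4)  # AG and CT are transitions

ALPHA_BOUNDS = (0.05, 50.0)
PINV_BOUNDS = (1e-6, 0.95)
RATE_BOUNDS = (1e-4, 100.0)
BRLEN_BOUNDS = (1e-8, 20.0)


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability categories of a Gamma(α, α) density."""
    if alpha <= 0:
        raise ParameterError("gamma shape must be positive")
    k = n_categories
    edges = scipy.special.gammaincinv(alpha, np.arange(1, k) / k) / alpha
    upper = np.concatenate([edges, [np.inf]])
    lower = np.concatenate([[0.0], edges])
    cdf_hi = scipy.special.gammainc(alpha + 1, alpha * upper)
    cdf_lo = scipy.special.gammainc(alpha + 1, alpha * lower)
    return k * (cdf_hi - cdf_lo)


def gtr_rate_matrix(exchangeabilities: np.ndarray, freqs: np.ndarray,
                    normalize: bool = True) -> np.ndarray:
    """GTR rate matrix ``q_ij = r_ij π_j`` (slots AC, AG, AT, CG, CT, GT)."""
    Q = np.zeros((4, 4))
    for slot, (i, j) in enumerate(_PAIRS):
        Q[i, j] = exchangeabilities[slot] * freqs[j]
        Q[j, i] = exchangeabilities[slot] * freqs[i]
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(4), np.arange(4)] = -Q.sum(axis=1)
    if normalize:
        rate = -float(np.sum(freqs * np.diag(Q)))
        if rate <= 0:
            raise ParameterError("degenerate nucleotide rate matrix")
        Q = Q / rate
    return Q


@dataclass
class NucModelParams:
    model: str                      # JC | HKY | GTR
    freqs: np.ndarray
    kappa: float = 1.0              # HKY
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))  # GTR
    alpha: float | None = None      # gamma shape, None = no rate variation
    p_inv: float | None = None
    branch_lengths: np.ndarray | None = None
    n_gamma_categories: int = 4

    def rate_categories(self) -> list[tuple[float, float]]:
        """(weight, rate) pairs of the site-rate mixture, mean rate 1."""
        cats: list[tuple[float, float]] = []
        p0 = self.p_inv or 0.0
        if p0 > 0:
            cats.append((p0, 0.0))
        if self.alpha is not None:
            rates = discrete_gamma_rates(self.alpha, self.n_gamma_categories)
            w = (1.0 - p0) / self.n_gamma_categories
            cats += [(w, float(r) / (1.0 - p0)) for r in rates]
        else:
            cats.append((1.0 - p0, 1.0 / (1.0 - p0) if p0 > 0 else 1.0))
        return cats

    def rate_matrix(self) -> np.ndarray:
        if self.model == "JC":
            return gtr_rate_matrix(np.ones(6), np.full(4, 0.25))
        if self.model == "HKY":
            ex = np.ones(6)
            ex[list(_TS_SLOTS)] = self.kappa
            return gtr_rate_matrix(ex, self.freqs)
        if self.model == "GTR":
            return gtr_rate_matrix(self.exchangeabilities, self.freqs)
        raise ParameterError(f"unknown nucleotide model {self.model!r}")

    @property
    def effective_freqs(self) -> np.ndarray:
        return np.full(4, 0.25) if self.model == "JC" else self.freqs


@dataclass
class NucFitResult:
    params: NucModelParams
    log_likelihood: float
    n_free_params: int
    converged: bool
    tree: PhyloTree
    alignment: NucleotideAlignment


def encode_nucleotide_alignment(aln: NucleotideAlignment, tree: PhyloTree):
    leaf_nodes = tree.leaves
    tree_names = [tree.names[i] for i in leaf_nodes]
    if set(tree_names) != set(aln.taxa):
        raise IdentifierError("tree/alignment taxa mismatch")
    row = {t: i for i, t in enumerate(aln.taxa)}
    columns = np.full((len(leaf_nodes), aln.n_sites), -1, dtype=np.int64)
    for k, node in enumerate(leaf_nodes):
        seq = aln.sequences[row[tree.names[node]]]
        for j, ch in enumerate(seq):
            columns[k, j] = _NT_INDEX.get(ch, -1)
    patterns, weights = compress_columns(columns)
    leaf_states = {node: patterns[k] for k, node in enumerate(leaf_nodes)}
    return PruningEngine(tree, leaf_states, weights, 4), columns


def empirical_base_freqs(aln: NucleotideAlignment) -> np.ndarray:
    counts = np.zeros(4)
    for seq in aln.sequences:
        for ch in seq:
            if ch in _NT_INDEX:
                counts[_NT_INDEX[ch]] += 1
    if counts.sum() == 0:
        raise DataError("alignment has no resolved nucleotides")
    return counts / counts.sum()


def _mixture_loglik(engine: PruningEngine, tree: PhyloTree,
                    params: NucModelParams) -> float:
    pi = np.maximum(params.effective_freqs, 1e-300)
    Q = params.rate_matrix()
    rr = ReversibleRate(Q, np.maximum(params.effective_freqs, 1e-12))
    bl = params.branch_lengths
    cats = params.rate_categories()
    per_cat = []
    for w, rate in cats:
        P = {b: rr.transition(float(bl[b]) * rate) for b in tree.branches}
        down, ls = engine.down_partials(P)
        root = tree.root
        site = np.maximum(down[root] @ pi, 1e-300)
        per_cat.append((w, np.log(site) + ls[root]))
    logs = np.stack([lg for _, lg in per_cat])
    weights = np.array([w for w, _ in per_cat])
    m = logs.max(axis=0)
    mixed = m + np.log(np.sum(weights[:, None] * np.exp(logs - m), axis=0))
    ll = float(np.sum(engine.weights * mixed))
    if not np.isfinite(ll):
        raise NumericalError("non-finite nucleotide log-likelihood")
    return ll


def fit_nucleotide_model(aln: NucleotideAlignment, tree: PhyloTree,
                         model: str = "HKY", gamma: bool = False,
                         invariant: bool = False,
                         optimize_branch_lengths: bool = True,
                         tol: float = 1e-6, max_iter: int = 500) -> NucFitResult:
    """ML fit of a JC/HKY/GTR model, optionally +Γ(4) and +I.

    Base frequencies are empirical counts (JC forces uniform); κ or the
    GTR exchangeabilities, the gamma shape, the invariant proportion and
    (optionally) branch lengths are estimated by bounded quasi-Newton on
    log-transformed parameters.
    """
    if model not in ("JC", "HKY", "GTR"):
        raise ParameterError(f"unknown nucleotide model {model!r}")
    engine, _ = encode_nucleotide_alignment(aln, tree)
    freqs = empirical_base_freqs(aln)
    branches = tree.branches
    init_bl = np.clip(tree.lengths[branches], 1e-6, BRLEN_BOUNDS[1])

    layout: list[tuple[str, int]] = []
    if model == "HKY":
        layout.append(("kappa", 1))
    elif model == "GTR":
        layout.append(("rates", 5))  # GT exchangeability fixed to 1
    if gamma:
        layout.append(("alpha", 1))
    if invariant:
        layout.append(("p_inv", 1))
    if optimize_branch_lengths:
        layout.append(("brlens", len(branches)))

    def unpack(x) -> NucModelParams:
        idx = 0
        kappa, ex, alpha, p_inv = 2.0, np.ones(6), None, None
        bl = tree.lengths.copy()
        for name, width in layout:
            chunk = x[idx : idx + width]
            idx += width
            if name == "kappa":
                kappa = float(np.exp(chunk[0]))
            elif name == "rates":
                ex = np.ones(6)
                ex[:5] = np.exp(chunk)
            elif name == "alpha":
                alpha = float(np.exp(chunk[0]))
            elif name == "p_inv":
                p_inv = float(scipy.special.expit(chunk[0]))
            elif name == "brlens":
                bl[branches] = np.exp(chunk)
        if gamma and alpha is None:
            alpha = 1.0
        return NucModelParams(model=model, freqs=freqs, kappa=kappa,
                              exchangeabilities=ex, alpha=alpha, p_inv=p_inv,
                              branch_lengths=bl)

    def negloglik(x):
        try:
            return -_mixture_loglik(engine, tree, unpack(x))
        except NumericalError:
            return 1e12

    x0: list[float] = []
    bounds: list[tuple[float, float]] = []
    for name, width in layout:
        if name == "kappa":
            x0 += [np.log(2.0)]
            bounds += [tuple(np.log(RATE_BOUNDS))]
        elif name == "rates":
            x0 += [0.0] * 5
            bounds += [tuple(np.log(RATE_BOUNDS))] * 5
        elif name == "alpha":
            x0 += [0.0]
            bounds += [tuple(np.log(ALPHA_BOUNDS))]
        elif name == "p_inv":
            x0 += [scipy.special.logit(0.1)]
            bounds += [tuple(scipy.special.logit(np.array(PINV_BOUNDS)))]
        elif name == "brlens":
            x0 += list(np.log(init_bl))
            bounds += [tuple(np.log(BRLEN_BOUNDS))] * len(branches)

    if x0:
        res = scipy.optimize.minimize(
            negloglik, np.array(x0), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol},
        )
        params = unpack(res.x)
        ll = -float(res.fun)
        converged = bool(res.success) and np.isfinite(res.fun)
    else:  # JC with fixed branch lengths: nothing to estimate
        params = unpack(np.array([]))
        ll = _mixture_loglik(engine, tree, params)
        converged = True
    n_free = sum(w for _, w in layout)
    return NucFitResult(params=params, log_likelihood=ll, n_free_params=n_free,
                        converged=converged, tree=tree, alignment=aln)


@dataclass
class AncestralReconstruction:
    """Marginal reconstruction at one internal node."""

    node_id: int
    sequence: str
    per_site_posteriors: np.ndarray  # (n_sites, 4), rows sum to 1
    mean_posterior: float
    tied_sites: list[int] = field(default_factory=list)

    def to_fasta(self, path, name: str = "ancestor") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n{self.sequence}\n")

    def posteriors_to_tsv(self, path) -> None:
        df = pd.DataFrame(self.per_site_posteriors, columns=list(NUCLEOTIDES))
        df.insert(0, "site", np.arange(len(df)))
        df["state"] = list(self.sequence)
        df.to_csv(path, sep="\t", index=False)


def marginal_ancestral_sequence(fit: NucFitResult,
                                clade_leaves: list[str]) -> AncestralReconstruction:
    """Marginal posterior state distribution at the MRCA of ``clade_leaves``
    and the argmax sequence. The clade must be monophyletic. Under a rate
    mixture the posterior averages categories by their per-site evidence.
    """
    tree = fit.tree
    node = tree.require_monophyletic(clade_leaves, label="ancestral clade")
    engine, columns = encode_nucleotide_alignment(fit.alignment, tree)
    params = fit.params
    pi = np.maximum(params.effective_freqs, 1e-12)
    rr = ReversibleRate(params.rate_matrix(), pi)
    bl = params.branch_lengths
    cats = params.rate_categories()

    pattern_joint = np.zeros((engine.n_patterns, 4))
    log_norms = []
    per_cat_joint = []
    for w, rate in cats:
        P = {b: rr.transition(float(bl[b]) * rate) for b in tree.branches}
        pre, pre_ls, _, down, down_ls = engine.up_messages(P, pi)
        if node == tree.root:
            joint = down[node] * pi[None, :]
            ls = down_ls[node]
        else:
            joint = pre[node] * down[node]
            ls = pre_ls[node] + down_ls[node]
        per_cat_joint.append((w, joint, ls))
    # combine categories on a common log scale per pattern
    all_ls = np.stack([ls for _, _, ls in per_cat_joint])
    m = all_ls.max(axis=0)
    for w, joint, ls in per_cat_joint:
        pattern_joint += w * joint * np.exp(ls - m)[:, None]
    totals = pattern_joint.sum(axis=1, keepdims=True)
    pattern_post = pattern_joint / np.maximum(totals, 1e-300)

    # map patterns back to sites
    cols = np.ascontiguousarray(columns.T)
    patterns_arr, inverse = np.unique(cols, axis=0, return_inverse=True)
    site_post = pattern_post[inverse]

    best = site_post.argmax(axis=1)
    tied = []
    for s in range(site_post.shape[0]):
        row = site_post[s]
        top = row[best[s]]
        if np.sum(np.isclose(row, top, rtol=0, atol=1e-12)) > 1:
            tied.append(s)
            best[s] = int(np.flatnonzero(np.isclose(row, top, atol=1e-12))[0])
    sequence = "".join(NUCLEOTIDES[i] for i in best)
    return AncestralReconstruction(
        node_id=node,
        sequence=sequence,
        per_site_posteriors=site_post,
        mean_posterior=float(site_post.max(axis=1).mean()),
        tied_sites=tied,
    )
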