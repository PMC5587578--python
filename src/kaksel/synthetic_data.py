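"""Synthetic study generator.

Emulates the comparative design the analysis pipeline targets: a rooted
tree whose leaves fall into three locomotion groups (poor-migrating
bivalve-like, free-moving gastropod-like, fast-swimming cephalopod-like),
mitochondrial-like protein-coding genes (invertebrate mitochondrial code)
whose terminal branches evolve under group-specific ω regimes, a
nuclear-like control gene (standard code) with a group-independent ω, and
an Atp8-like gene with an elevated ω confined to the ancestral branch of
the bivalve-like clade. The poor-migrating clade is split into a marine
and a freshwater subclade so ancestral-branch ladders can be built for
both depths. Ground truth (per-branch ω, every ancestral sequence) is
recorded so each pipeline stage can be verified end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._engine import ReversibleRate
from .codon_model import QBuilder, code_structure
from .errors import ParameterError
from .io_formats import (
    CodonAlignment,
    GeneticCode,
    PhyloTree,
    SpeciesMetadata,
    invertebrate_mito_code,
    read_newick,
    standard_code,
    write_metadata,
    write_newick,
)

GROUP_POOR = "poor-migrating"
GROUP_FREE = "free-moving"
GROUP_FAST = "fast-swimming"

CLASS_ANC_POOR = "anc_bivalvia"
CLASS_ANC_MARINE = "anc_marine"
CLASS_BACKGROUND = "background"


@dataclass
class SimulationSpec:
    """Generative conditions of the synthetic study.

    Group mean Ka/Ks values default to 0.0559 / 0.0340 / 0.0240 and the
    ancestral relaxation pair to 0.71 over a 0.07 background — the regimes
    the analysis is designed to detect. Terminal-branch ω scatter is
    log-normal around the group mean.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {GROUP_POOR: 15, GROUP_FREE: 15, GROUP_FAST: 15}
    )
    group_omega_means: dict[str, float] = field(
        default_factory=lambda: {GROUP_POOR: 0.0559, GROUP_FREE: 0.0340,
                                 GROUP_FAST: 0.0240}
    )
    omega_log_sd: float = 0.4
    background_omega: float = 0.07
    relaxed_omega: float = 0.71
    relaxed_class: str = CLASS_ANC_POOR
    control_omega: float = 0.05
    kappa: float = 2.0
    nt_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 0.35, "C": 0.15, "A": 0.30, "G": 0.20}
    )
    mito_genes: dict[str, int] = field(
        default_factory=lambda: {"cox1_like": 300, "cytb_like": 300,
                                 "nd5_like": 300, "atp6_like": 300}
    )
    control_gene: tuple[str, int] = ("h3_like", 200)
    atp8_gene: tuple[str, int] = ("atp8_like", 800)
    tree_shape: str = "balanced"          # balanced | birth-death
    birth_rate: float = 1.0
    death_rate: float = 0.0
    terminal_t_mean: float = 0.4
    terminal_t_log_sd: float = 0.3
    internal_t_mean: float = 0.15
    internal_t_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ParameterError(f"group {g!r} needs >= 2 taxa, got {n}")
        for name, value in [("background_omega", self.background_omega),
                            ("relaxed_omega", self.relaxed_omega),
                            ("control_omega", self.control_omega),
                            ("kappa", self.kappa)]:
            if value < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.tree_shape not in ("balanced", "birth-death"):
            raise ParameterError(f"unknown tree shape {self.tree_shape!r}")


@dataclass
class SyntheticStudy:
    """A complete simulated study with its ground truth."""

    tree: PhyloTree
    alignments: dict[str, CodonAlignment]
    metadata: list[SpeciesMetadata]
    truth: dict


def mito_like_codon_freqs(spec: SimulationSpec, code: GeneticCode) -> np.ndarray:
    """Sense-codon frequencies from independent per-position nucleotide
    weights (AT-rich by default, as in mollusc mitogenomes)."""
    struct = code_structure(code)
    w = spec.nt_weights
    freqs = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in struct.sense])
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _balanced_newick(names: list[str]) -> str:
    if len(names) == 1:
        return names[0]
    mid = (len(names) + 1) // 2
    return f"({_balanced_newick(names[:mid])},{_balanced_newick(names[mid:])})"


def _birth_death_newick(names: list[str], birth: float, death: float,
                        rng: np.random.Generator) -> str:
    """Topology + ultrametric depths from a simple birth-death simulation
    conditioned on the number of extant tips (death used for thinning)."""
    import dendropy
    from dendropy.model import birthdeath

    py_rng = _PyRandom(rng)
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=len(names),
        rng=py_rng,
    )
    for leaf, name in zip(dtree.leaf_node_iter(), names):
        leaf.taxon.label = name
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


class _PyRandom:
    """Adapter exposing the stdlib-random surface dendropy expects on top of
    a numpy Generator, keeping all randomness under one seed."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def gauss(self, mu, sigma):
        if sigma == 0:
            return mu
        return float(self._rng.normal(mu, sigma))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)


def group_leaf_names(spec: SimulationSpec) -> dict[str, list[str]]:
    n_poor = spec.n_per_group[GROUP_POOR]
    n_marine = (n_poor + 1) // 2
    poor = [f"poor_m{i:02d}" for i in range(1, n_marine + 1)]
    poor += [f"poor_f{i:02d}" for i in range(1, n_poor - n_marine + 1)]
    free = [f"free_{i:02d}" for i in range(1, spec.n_per_group[GROUP_FREE] + 1)]
    fast = [f"fast_{i:02d}" for i in range(1, spec.n_per_group[GROUP_FAST] + 1)]
    return {GROUP_POOR: poor, GROUP_FREE: free, GROUP_FAST: fast}


def simulate_tree(spec: SimulationSpec, seed: int | None = None) -> PhyloTree:
    """Rooted tree with three monophyletic locomotion-group clades.

    The poor-migrating clade is itself split into marine (``poor_m*``) and
    freshwater (``poor_f*``) subclades. Branch classes are pre-assigned:
    terminal branches carry their group name, the bivalve-like stem
    ``anc_bivalvia``, the marine-subclade stem ``anc_marine``, everything
    else ``background``. Branch lengths are log-normal draws around the
    declared terminal/internal means. Deterministic under the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = group_leaf_names(spec)
    marine = [n for n in names[GROUP_POOR] if n.startswith("poor_m")]
    fresh = [n for n in names[GROUP_POOR] if n.startswith("poor_f")]

    if spec.tree_shape == "balanced":
        poor_nwk = f"({_balanced_newick(marine)},{_balanced_newick(fresh)})"
        free_nwk = _balanced_newick(names[GROUP_FREE])
        fast_nwk = _balanced_newick(names[GROUP_FAST])
        topology = f"(({poor_nwk},{free_nwk}),{fast_nwk});"
        tree = read_newick(topology)
    else:
        sub_nwks = []
        for leaf_list in (marine, fresh):
            sub_nwks.append(_strip_lengths(_birth_death_newick(
                leaf_list, spec.birth_rate, spec.death_rate, rng)))
        poor_nwk = f"({sub_nwks[0]},{sub_nwks[1]})"
        free_nwk = _strip_lengths(_birth_death_newick(
            names[GROUP_FREE], spec.birth_rate, spec.death_rate, rng))
        fast_nwk = _strip_lengths(_birth_death_newick(
            names[GROUP_FAST], spec.birth_rate, spec.death_rate, rng))
        topology = f"(({poor_nwk},{free_nwk}),{fast_nwk});"
        tree = read_newick(topology)

    # draw branch lengths
    lengths = tree.lengths.copy()
    for b in tree.branches:
        if tree.is_leaf(b):
            mu, sd = spec.terminal_t_mean, spec.terminal_t_log_sd
        else:
            mu, sd = spec.internal_t_mean, spec.internal_t_log_sd
        lengths[b] = mu * float(np.exp(rng.normal(-0.5 * sd**2, sd)))
    tree = PhyloTree(parent=tree.parent, lengths=lengths, names=tree.names)

    # class labels
    class_map: dict[int, str] = {}
    leaf_group = leaf_group_map(spec)
    for b in tree.branches:
        if tree.is_leaf(b):
            class_map[b] = leaf_group[tree.names[b]]
        else:
            class_map[b] = CLASS_BACKGROUND
    class_map[tree.require_monophyletic(names[GROUP_POOR], "bivalve-like clade")] = CLASS_ANC_POOR
    class_map[tree.require_monophyletic(marine, "marine subclade")] = CLASS_ANC_MARINE
    return tree.with_branch_classes(class_map)


def _strip_lengths(newick: str) -> str:
    import re

    s = re.sub(r":[0-9.eE+-]+", "", newick)
    return s.rstrip(";").strip()


def leaf_group_map(spec: SimulationSpec) -> dict[str, str]:
    names = group_leaf_names(spec)
    return {leaf: group for group, leaves in names.items() for leaf in leaves}


def study_metadata(spec: SimulationSpec) -> list[SpeciesMetadata]:
    records = []
    for group, leaves in group_leaf_names(spec).items():
        for leaf in leaves:
            habitat = "marine"
            if leaf.startswith("poor_f"):
                habitat = "freshwater"
            records.append(SpeciesMetadata(species=leaf, group=group,
                                           habitat=habitat, clade=group))
    return records


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(tree: PhyloTree, kappa: float,
                             codon_freqs: np.ndarray,
                             omega_by_branch: dict[int, float],
                             n_codons: int, code: GeneticCode,
                             seed: int, gene_name: str = "sim"):
    """Simulate codon evolution along the tree.

    Root codons are drawn from π; each branch evolves by sampling from
    P(t) built with that branch's ω (per-branch scaling: t is expected
    substitutions per codon on the branch). The state space contains only
    sense codons, so stop codons can never be emitted. Returns the leaf
    alignment and the true sequences of every node.
    """
    rng = np.random.default_rng(seed)
    struct = code_structure(code)
    pi = np.asarray(codon_freqs, float)
    builder = QBuilder(kappa, pi, code)
    pi_safe = np.maximum(pi, 1e-12)
    rr_cache: dict[float, ReversibleRate] = {}

    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root] = rng.choice(struct.n, size=n_codons, p=pi)
    for node in tree.preorder():
        if node == root:
            continue
        om = omega_by_branch[node]
        if om not in rr_cache:
            rr_cache[om] = ReversibleRate(builder.Q(om), pi_safe)
        P = rr_cache[om].transition(float(tree.lengths[node]))
        rows = P[states[int(tree.parent[node])]]
        cum = np.cumsum(rows, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n_codons)
        states[node] = (u[:, None] > cum).sum(axis=1)

    def decode(arr: np.ndarray) -> str:
        return "".join(struct.sense[i] for i in arr)

    leaf_nodes = tree.leaves
    aln = CodonAlignment(
        taxa=[tree.names[i] for i in leaf_nodes],
        sequences=[decode(states[i]) for i in leaf_nodes],
        code=code,
        gene_name=gene_name,
    )
    truth_seqs = {int(node): decode(arr) for node, arr in states.items()}
    return aln, truth_seqs


def simulate_nucleotide_alignment(tree: PhyloTree, params, n_sites: int,
                                  seed: int, name: str = "sim_nt"):
    """Simulate nucleotide evolution under a :class:`~kaksel.ancestral.NucModelParams`
    (rate mixture included). Returns the leaf alignment and true node sequences."""
    from .io_formats import NUCLEOTIDES, NucleotideAlignment

    rng = np.random.default_rng(seed)
    pi = np.maximum(params.effective_freqs, 1e-12)
    rr = ReversibleRate(params.rate_matrix(), pi)
    cats = params.rate_categories()
    weights = np.array([w for w, _ in cats])
    rates = np.array([r for _, r in cats])
    site_rates = rates[rng.choice(len(cats), size=n_sites, p=weights / weights.sum())]

    bl = params.branch_lengths if params.branch_lengths is not None else tree.lengths
    states: dict[int, np.ndarray] = {}
    states[tree.root] = rng.choice(4, size=n_sites, p=pi / pi.sum())
    for node in tree.preorder():
        if node == tree.root:
            continue
        t = float(bl[node])
        child = np.empty(n_sites, dtype=np.int64)
        for rate in np.unique(site_rates):
            mask = site_rates == rate
            P = rr.transition(t * float(rate))
            rows = P[states[int(tree.parent[node])][mask]]
            cum = np.cumsum(rows, axis=1)
            cum /= cum[:, -1:]
            child[mask] = (rng.random(mask.sum())[:, None] > cum).sum(axis=1)
        states[node] = child

    def decode(arr):
        return "".join(NUCLEOTIDES[i] for i in arr)

    aln = NucleotideAlignment(
        taxa=[tree.names[i] for i in tree.leaves],
        sequences=[decode(states[i]) for i in tree.leaves],
        name=name,
    )
    return aln, {int(k): decode(v) for k, v in states.items()}


def simulate_study(spec: SimulationSpec, seed: int | None = None) -> SyntheticStudy:
    """Generate the full multi-gene study with ground truth.

    Mitochondrial-like genes share one lognormal draw of terminal-branch ω
    per group (internal branches at the background ω); the control gene is
    uniform-ω under the standard code; the Atp8-like gene has the relaxed ω
    on the bivalve-like stem only. Everything is deterministic under the
    seed.
    """
    spec.validate()
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    tree = simulate_tree(spec, seed=int(rng.integers(2**31)))

    mito_code = invertebrate_mito_code()
    nuc_code = standard_code()
    mito_freqs = mito_like_codon_freqs(spec, mito_code)
    control_freqs = np.full(len(code_structure(nuc_code).sense),
                            1.0 / len(code_structure(nuc_code).sense))

    # per-branch omega shared by the mitochondrial genes
    sd = spec.omega_log_sd
    mito_omega: dict[int, float] = {}
    for b in tree.branches:
        cls = tree.branch_class[b]
        if cls in spec.group_omega_means:
            mean = spec.group_omega_means[cls]
            mito_omega[b] = mean * float(np.exp(rng.normal(-0.5 * sd**2, sd)))
        else:
            mito_omega[b] = spec.background_omega

    relaxed_branches = [b for b in tree.branches
                        if tree.branch_class[b] == spec.relaxed_class]
    atp8_omega = {b: spec.background_omega for b in tree.branches}
    for b in relaxed_branches:
        atp8_omega[b] = spec.relaxed_omega

    control_name, control_len = spec.control_gene
    control_omega = {b: spec.control_omega for b in tree.branches}

    alignments: dict[str, CodonAlignment] = {}
    truth: dict = {
        "seed": base_seed,
        "kappa": spec.kappa,
        "omega_by_branch": {},
        "ancestral_sequences": {},
        "spec": _spec_echo(spec),
    }
    for gene, length in spec.mito_genes.items():
        aln, seqs = simulate_codon_alignment(
            tree, spec.kappa, mito_freqs, mito_omega, length, mito_code,
            seed=int(rng.integers(2**31)), gene_name=gene,
        )
        alignments[gene] = aln
        truth["omega_by_branch"][gene] = {int(k): v for k, v in mito_omega.items()}
        truth["ancestral_sequences"][gene] = seqs

    atp8_name, atp8_len = spec.atp8_gene
    aln, seqs = simulate_codon_alignment(
        tree, spec.kappa, mito_freqs, atp8_omega, atp8_len, mito_code,
        seed=int(rng.integers(2**31)), gene_name=atp8_name,
    )
    alignments[atp8_name] = aln
    truth["omega_by_branch"][atp8_name] = {int(k): v for k, v in atp8_omega.items()}
    truth["ancestral_sequences"][atp8_name] = seqs

    aln, seqs = simulate_codon_alignment(
        tree, spec.kappa, control_freqs, control_omega, control_len, nuc_code,
        seed=int(rng.integers(2**31)), gene_name=control_name,
    )
    alignments[control_name] = aln
    truth["omega_by_branch"][control_name] = {int(k): v for k, v in control_omega.items()}
    truth["ancestral_sequences"][control_name] = seqs

    return SyntheticStudy(
        tree=tree,
        alignments=alignments,
        metadata=study_metadata(spec),
        truth=truth,
    )


def _spec_echo(spec: SimulationSpec) -> dict:
    echo = asdict(spec)
    echo["control_gene"] = list(spec.control_gene)
    echo["atp8_gene"] = list(spec.atp8_gene)
    return echo


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write the study as FASTA / Newick / TSV / JSON text files."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for gene, aln in study.alignments.items():
        aln.to_fasta(os.path.join(out_dir, f"{gene}.fasta"))
    write_newick(study.tree, os.path.join(out_dir, "tree.nwk"))
    write_metadata(study.metadata, os.path.join(out_dir, "metadata.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
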