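"""Internal phylogenetic likelihood machinery shared by the codon and
nucleotide models: reversible rate-matrix exponentials via spectral
decomposition, Felsenstein pruning with per-node scaling, and the
upward/downward partials needed for marginal ancestral posteriors and
fast per-branch optimization."""

from __future__ import annotations

import numpy as np

from .errors import NumericalError, ParameterError
from .io_formats import PhyloTree

_TINY = 1e-300


class ReversibleRate:
    """Spectral form of a reversible rate matrix for cheap ``expm(Q t)``.

    ``Q`` must satisfy detailed balance w.r.t. ``pi``; then
    ``S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is symmetric and
    ``P(t) = diag(1/sqrt(pi)) U exp(Λ t) Uᵀ diag(sqrt(pi))``.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, float)
        sq = np.sqrt(self.pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetrize roundoff
        w, U = np.linalg.eigh(S)
        self._w = w
        self._left = U / sq[:, None]    # diag(1/sqrt(pi)) @ U
        self._right = (U * sq[:, None]).T  # U.T @ diag(sqrt(pi))

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ParameterError(f"branch length must be >= 0, got {t}")
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    return ReversibleRate(Q, pi).transition(t)


class PruningEngine:
    """Felsenstein pruning over site patterns on a fixed tree topology.

    Parameters
    ----------
    tree:
        The :class:`PhyloTree`; only topology is used here — branch lengths
        enter through the per-branch transition matrices supplied to
        :meth:`loglik`.
    leaf_states:
        Mapping ``node index -> int array (n_patterns,)`` of observed state
        indices; -1 marks missing data (partial likelihood of ones).
    weights:
        Pattern multiplicities.
    n_states:
        Size of the state space (61/62 codons, 4 nucleotides).
    """

    def __init__(self, tree: PhyloTree, leaf_states: dict[int, np.ndarray],
                 weights: np.ndarray, n_states: int):
        self.tree = tree
        self.leaf_states = leaf_states
        self.weights = np.asarray(weights, float)
        self.n_states = n_states
        self.n_patterns = len(self.weights)
        self._postorder = tree.postorder()
        self._preorder = self._postorder[::-1]
        # Pre-built one-hot leaf partials
        self._leaf_partials: dict[int, np.ndarray] = {}
        for node, states in leaf_states.items():
            L = np.zeros((self.n_patterns, n_states))
            obs = states >= 0
            L[np.arange(self.n_patterns)[obs], states[obs]] = 1.0
            L[~obs, :] = 1.0
            self._leaf_partials[node] = L

    # -- downward (subtree) partials ------------------------------------
    def down_partials(self, P_by_branch: dict[int, np.ndarray]):
        """Return (down, logscale): down[v] has shape (n_patterns, n_states)."""
        down: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        for node in self._postorder:
            if self.tree.is_leaf(node):
                down[node] = self._leaf_partials[node]
                logscale[node] = np.zeros(self.n_patterns)
                continue
            L = np.ones((self.n_patterns, self.n_states))
            ls = np.zeros(self.n_patterns)
            for child in self.tree.children(node):
                L = L * (down[child] @ P_by_branch[child].T)
                ls = ls + logscale[child]
            smax = L.max(axis=1)
            smax = np.where(smax > 0, smax, 1.0)
            L = L / smax[:, None]
            ls = ls + np.log(np.maximum(smax, _TINY))
            down[node] = L
            logscale[node] = ls
        return down, logscale

    def loglik(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray) -> float:
        down, logscale = self.down_partials(P_by_branch)
        root = self.tree.root
        site = down[root] @ pi
        if np.any(site <= 0):
            bad = int(np.flatnonzero(site <= 0)[0])
            raise NumericalError(f"zero site likelihood at pattern {bad}")
        ll = float(np.sum(self.weights * (np.log(site) + logscale[root])))
        if not np.isfinite(ll):
            raise NumericalError("non-finite log-likelihood")
        return ll

    # -- upward (rest-of-tree) messages ---------------------------------
    def up_messages(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray,
                    down=None, down_ls=None):
        """Pre-order messages entering each node from above.

        ``pre[v][s, j]`` ∝ joint probability of all data outside the subtree
        of ``v`` together with state ``j`` at ``v`` (π included at the root);
        ``pre_ls[v]`` carries per-pattern log scale factors. Also returns
        ``to_parent[v] = down[v] @ P_v.T``, the message node ``v`` sends to
        its parent (used to form sibling products cheaply).
        """
        if down is None:
            down, down_ls = self.down_partials(P_by_branch)
        pre: dict[int, np.ndarray] = {}
        pre_ls: dict[int, np.ndarray] = {}
        to_parent: dict[int, np.ndarray] = {}
        for node in self._postorder:
            if self.tree.parent[node] >= 0:
                to_parent[node] = down[node] @ P_by_branch[node].T
        root = self.tree.root
        pre[root] = np.broadcast_to(pi, (self.n_patterns, self.n_states)).copy()
        pre_ls[root] = np.zeros(self.n_patterns)
        for node in self._preorder:
            if self.tree.is_leaf(node):
                continue
            children = self.tree.children(node)
            for child in children:
                T = pre[node].copy()
                ls = pre_ls[node].copy()
                for sib in children:
                    if sib is child:
                        continue
                    T = T * to_parent[sib]
                    ls = ls + down_ls[sib]
                msg = T @ P_by_branch[child]
                smax = msg.max(axis=1)
                smax = np.where(smax > 0, smax, 1.0)
                pre[child] = msg / smax[:, None]
                pre_ls[child] = ls + np.log(np.maximum(smax, _TINY))
        return pre, pre_ls, to_parent, down, down_ls

    def node_posteriors(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray,
                        node: int) -> np.ndarray:
        """Per-pattern marginal state posteriors at ``node`` (rows sum to 1)."""
        pre, pre_ls, _, down, _ = self.up_messages(P_by_branch, pi)
        joint = pre[node] * down[node]
        total = joint.sum(axis=1, keepdims=True)
        return joint / np.maximum(total, _TINY)

    def branch_context(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray):
        """Per-branch (A, B, ls) with sitewise L = Σ_ij A[s,i] P_ij B[s,j] · e^ls.

        ``A`` is the joint above-message at the parent excluding the branch's
        subtree; ``B`` is the subtree partial at the child. Used for cheap
        1-branch likelihood evaluation during coordinate optimization.
        """
        pre, pre_ls, to_parent, down, down_ls = self.up_messages(P_by_branch, pi)
        out = {}
        for v in self.tree.branches:
            u = int(self.tree.parent[v])
            A = pre[u].copy()
            ls = pre_ls[u].copy()
            for sib in self.tree.children(u):
                if sib == v:
                    continue
                A = A * to_parent[sib]
                ls = ls + down_ls[sib]
            out[v] = (A, down[v], ls + down_ls[v])
        return out

    @staticmethod
    def edge_loglik(A: np.ndarray, B: np.ndarray, ls: np.ndarray,
                    P: np.ndarray, weights: np.ndarray) -> float:
        site = np.einsum("si,ij,sj->s", A, P, B, optimize=True)
        site = np.maximum(site, _TINY)
        return float(np.sum(weights * (np.log(site) + ls)))


def compress_columns(columns: np.ndarray):
    """Compress site columns to unique patterns.

    ``columns``: int array (n_taxa, n_sites). Returns (patterns, weights)
    with ``patterns`` shaped (n_taxa, n_patterns).
    """
    cols = np.ascontiguousarray(columns.T)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)
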