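"""Per-branch Ka/Ks decomposition and Nei–Gojobori (1986) pairwise counting.

The model-based route decomposes a fitted branch into Ka (dN) and Ks (dS)
using the mutational-opportunity site counts N and S implied by the fitted
κ and codon frequencies; by construction dN/dS reproduces the branch's
class ω. The NG86 route counts synonymous and nonsynonymous sites and
differences directly from a sequence pair, with equal-weight averaging over
minimal mutational pathways and a Jukes–Cantor multiple-hit correction; it
is independent of the likelihood machinery and serves as a cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_model import FitResult, QBuilder, code_structure
from .errors import DataError, ParameterError
from .io_formats import NUCLEOTIDES, GeneticCode


@dataclass
class BranchMetrics:
    """Substitution summary for one branch of a fitted codon model."""

    branch_id: int
    is_terminal: bool
    species: str | None
    t: float                 # expected substitutions per codon on the branch
    N: float                 # nonsynonymous sites per codon (N + S = 3)
    S: float                 # synonymous sites per codon
    dN: float                # Ka
    dS: float                # Ks
    omega: float             # dN/dS; nan when dS undefined
    n_nonsyn_subs: float     # expected nonsynonymous substitutions on the branch
    omega_defined: bool = True


def model_site_counts(kappa: float, codon_freqs: np.ndarray,
                      code: GeneticCode) -> tuple[float, float]:
    """Model-implied nonsynonymous and synonymous site counts per codon.

    Proportions of nonsynonymous vs synonymous single-nucleotide change
    *opportunity* under the neutral (ω = 1) flow of the fitted model —
    stationary-frequency- and κ-weighted — scaled so N + S = 3.
    """
    builder = QBuilder(kappa, codon_freqs, code)
    n_un, s_un = builder.r_nonsyn, builder.r_syn
    total = n_un + s_un
    if total <= 0:
        raise ParameterError("degenerate site-count weights")
    N = 3.0 * n_un / total
    return N, 3.0 - N


def branch_dn_ds(fit: FitResult) -> list[BranchMetrics]:
    """Decompose every branch of a converged fit into Ka, Ks and site counts.

    On a branch of length ``t`` (expected substitutions per codon under the
    model's scaling) with class ω, the expected proportions of
    nonsynonymous and synonymous substitutions are
    ρN = ωW_N / (ωW_N + W_S) and ρS = 1 − ρN, whence
    dN = t·ρN / (3N/(N+S)) and dS = t·ρS / (3S/(N+S)); dN/dS equals ω
    identically. Branches whose class omits synonymous opportunity
    (dS = 0) are flagged undefined.
    """
    if not fit.converged:
        raise DataError("branch decomposition requires a converged fit")
    params = fit.params
    spec = fit.spec
    tree = fit.tree
    builder = QBuilder(params.kappa, params.codon_freqs, spec.code)
    N, S = model_site_counts(params.kappa, params.codon_freqs, spec.code)
    background_rate = builder.rate(params.omega_by_class[spec.background_class])
    metrics: list[BranchMetrics] = []
    for b in tree.branches:
        omega = params.omega_by_class[spec.branch_class_map[b]]
        t_in = float(params.branch_lengths[b])
        # expected substitutions per codon actually realized on this branch
        if spec.scale_per_class:
            t_eff = t_in
        else:
            t_eff = t_in * builder.rate(omega) / background_rate
        flow_n = omega * builder.r_nonsyn
        flow_s = builder.r_syn
        flow = flow_n + flow_s
        rho_n = flow_n / flow if flow > 0 else 0.0
        rho_s = 1.0 - rho_n
        dN = t_eff * rho_n / (3.0 * N / (N + S))
        dS = t_eff * rho_s / (3.0 * S / (N + S)) if S > 0 else 0.0
        defined = dS > 0 or t_eff == 0
        is_terminal = tree.is_leaf(b)
        metrics.append(
            BranchMetrics(
                branch_id=b,
                is_terminal=is_terminal,
                species=tree.names[b] if is_terminal else None,
                t=t_eff,
                N=N,
                S=S,
                dN=dN,
                dS=dS,
                omega=(dN / dS) if dS > 0 else (0.0 if t_eff == 0 else math.nan),
                n_nonsyn_subs=dN * N * fit.n_codons,
                omega_defined=defined,
            )
        )
    fit.per_branch = metrics
    return metrics


def metrics_to_frame(metrics: list[BranchMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "branch_id": [m.branch_id for m in metrics],
            "species": [m.species for m in metrics],
            "is_terminal": [m.is_terminal for m in metrics],
            "t": [m.t for m in metrics],
            "N": [m.N for m in metrics],
            "S": [m.S for m in metrics],
            "Ka": [m.dN for m in metrics],
            "Ks": [m.dS for m in metrics],
            "KaKs": [m.omega for m in metrics],
            "n_nonsyn_subs": [m.n_nonsyn_subs for m in metrics],
        }
    )


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986
# ---------------------------------------------------------------------------

@dataclass
class NG86Result:
    """Pairwise Nei–Gojobori counts and Jukes–Cantor-corrected rates."""

    Ka: float
    Ks: float
    Sd: float
    Nd: float
    S_sites: float
    N_sites: float
    pN: float
    pS: float
    saturated_syn: bool = False
    saturated_nonsyn: bool = False
    unstable_pathways: bool = False


def _codon_syn_sites(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon: per position, the fraction of the
    three possible changes that are synonymous (changes to stop codons count
    as nonsynonymous)."""
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if not code.is_stop(mutant) and code.translate(mutant) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over minimal mutational
    pathways between two codons, excluding pathways through stop codons
    (all-blocked pairs fall back to including them)."""
    diff_positions = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_positions:
        return 0.0, 0.0
    if len(diff_positions) == 1:
        p = diff_positions[0]
        mutant = c2
        syn = code.translate(c1) == code.translate(mutant)
        return (1.0, 0.0) if syn else (0.0, 1.0)

    def walk(allow_stops: bool):
        path_counts = []
        for order in itertools.permutations(diff_positions):
            current = c1
            sd = nd = 0.0
            blocked = False
            for p in order:
                nxt = current[:p] + c2[p] + current[p + 1 :]
                if code.is_stop(nxt) and not allow_stops:
                    blocked = True
                    break
                if code.is_stop(current) or code.is_stop(nxt):
                    nd += 1.0  # change through a stop is nonsynonymous
                elif code.translate(current) == code.translate(nxt):
                    sd += 1.0
                else:
                    nd += 1.0
                current = nxt
            if not blocked:
                path_counts.append((sd, nd))
        return path_counts

    paths = walk(allow_stops=False) or walk(allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86_pairwise(seq1: str, seq2: str, code: GeneticCode) -> NG86Result:
    """Nei–Gojobori (1986) Ka and Ks between two in-frame coding sequences.

    Site counts are averaged over the two sequences; multi-hit codons are
    resolved by equal-weight averaging over minimal mutational pathways;
    the Jukes–Cantor correction maps raw proportions to distances. Codons
    with gaps or ambiguity in either sequence are skipped.
    """
    if len(seq1) != len(seq2):
        raise ParameterError("sequences must have equal length")
    if len(seq1) % 3:
        raise ParameterError("sequence length must be a multiple of 3")
    seq1 = seq1.upper().replace("U", "T")
    seq2 = seq2.upper().replace("U", "T")
    S_sites = N_sites = Sd = Nd = 0.0
    n_codons = 0
    n_triple_diff = 0
    for j in range(0, len(seq1), 3):
        c1, c2 = seq1[j : j + 3], seq2[j : j + 3]
        if not all(ch in NUCLEOTIDES for ch in c1 + c2):
            continue
        if code.is_stop(c1) or code.is_stop(c2):
            raise ParameterError(f"stop codon at codon index {j // 3}")
        n_codons += 1
        s1 = _codon_syn_sites(c1, code)
        s2 = _codon_syn_sites(c2, code)
        S_sites += 0.5 * (s1 + s2)
        N_sites += 3.0 - 0.5 * (s1 + s2)
        sd, nd = _pathway_counts(c1, c2, code)
        Sd += sd
        Nd += nd
        if sum(a != b for a, b in zip(c1, c2)) == 3:
            n_triple_diff += 1
    if n_codons == 0:
        raise DataError("no comparable codons")
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    Ks, sat_s = _jc_correct(pS)
    Ka, sat_n = _jc_correct(pN)
    return NG86Result(
        Ka=Ka,
        Ks=Ks,
        Sd=Sd,
        Nd=Nd,
        S_sites=S_sites,
        N_sites=N_sites,
        pN=pN,
        pS=pS,
        saturated_syn=sat_s,
        saturated_nonsyn=sat_n,
        unstable_pathways=n_triple_diff > 0.1 * n_codons,
    )
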