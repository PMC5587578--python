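import numpy as np
import pytest

from kaksel.codon_model import (
    FitOptions,
    ModelParams,
    fit_model,
    uniform_spec,
)
from kaksel.io_formats import (
    CodonAlignment,
    invertebrate_mito_code,
    read_newick,
    standard_code,
)
from kaksel.synthetic_data import (
    SimulationSpec,
    mito_like_codon_freqs,
    simulate_codon_alignment,
)


@pytest.fixture(scope="session")
def code5():
    return invertebrate_mito_code()


@pytest.fixture(scope="session")
def code1():
    return standard_code()


@pytest.fixture(scope="session")
def mito_freqs(code5):
    return mito_like_codon_freqs(SimulationSpec(), code5)


@pytest.fixture(scope="session")
def tree3():
    return read_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def tree6():
    return read_newick(
        "(((a:0.25,b:0.25):0.1,(c:0.25,d:0.25):0.1):0.05,(e:0.25,f:0.25):0.15);"
    )


@pytest.fixture(scope="session")
def tree8():
    return read_newick(
        "(((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1):0.1,"
        "((e:0.2,f:0.2):0.1,(g:0.2,h:0.2):0.1):0.1);"
    )


@pytest.fixture(scope="session")
def aln3(code5):
    return CodonAlignment(
        taxa=["A", "B", "C"],
        sequences=["ATGTTTAAA", "ATGTTCAAA", "ATGTTAAAG"],
        code=code5,
    )


def make_params(spec, freqs, tree, kappa=2.0, omega=0.3):
    """ModelParams with one shared omega for every class of the spec."""
    return ModelParams(
        kappa=kappa,
        omega_by_class={c: omega for c in spec.omega_classes},
        codon_freqs=freqs,
        branch_lengths=tree.lengths.copy(),
    )


@pytest.fixture(scope="session")
def small_fit(tree6, code5, mito_freqs):
    """A converged uniform fit on simulated data, shared across tests."""
    omega = {b: 0.25 for b in tree6.branches}
    aln, _ = simulate_codon_alignment(tree6, 2.0, mito_freqs, omega, 300,
                                      code5, seed=97)
    return fit_model(
        aln, tree6, uniform_spec(tree6, code5),
        FitOptions(optimize_branch_lengths=False, multistart=1),
    )


def random_small_instance(rng, code, max_leaves=4, max_codons=10):
    """A random tiny tree + alignment + params for oracle comparisons."""
    from kaksel.codon_model import code_structure

    n_leaves = int(rng.integers(2, max_leaves + 1))
    names = [f"t{i}" for i in range(n_leaves)]
    # random caterpillar/balanced-ish topology by sequential joining
    parts = [f"{n}:{rng.uniform(0.02, 0.6):.4f}" for n in names]
    while len(parts) > 2:
        a = parts.pop(int(rng.integers(len(parts))))
        b = parts.pop(int(rng.integers(len(parts))))
        parts.append(f"({a},{b}):{rng.uniform(0.02, 0.4):.4f}")
    tree = read_newick(f"({parts[0]},{parts[1]});")

    struct = code_structure(code)
    n_codons = int(rng.integers(2, max_codons + 1))
    seqs = []
    for _ in range(n_leaves):
        idx = rng.integers(0, struct.n, size=n_codons)
        codons = [struct.sense[i] for i in idx]
        if rng.random() < 0.3:  # sprinkle missing data
            codons[int(rng.integers(n_codons))] = "---"
        seqs.append("".join(codons))
    aln = CodonAlignment(taxa=names, sequences=seqs, code=code)

    freqs = rng.dirichlet(np.full(struct.n, 2.0))
    spec = uniform_spec(tree, code)
    params = ModelParams(
        kappa=float(rng.uniform(0.5, 5.0)),
        omega_by_class={"all": float(rng.uniform(0.02, 2.0))},
        codon_freqs=freqs,
        branch_lengths=tree.lengths.copy(),
    )
    return aln, tree, spec, params
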