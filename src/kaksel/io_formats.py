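"""Sequence, tree and metadata I/O.

Defines the package's core containers:

* :class:`GeneticCode` -- an NCBI translation table (standard table 1 for
  nuclear genes such as histone H3, invertebrate mitochondrial table 5 for
  mollusc mitochondrial protein-coding genes).
* :class:`CodonAlignment` -- an in-frame codon alignment with its code.
* :class:`NucleotideAlignment` -- a plain nucleotide alignment (used by the
  ancestral-reconstruction module).
* :class:`PhyloTree` -- a rooted tree with branch lengths and optional
  per-branch class labels (the ω-class partition of branch models).
* :class:`SpeciesMetadata` -- species → locomotion group / habitat / clade.

Branch-class convention
-----------------------
ω-class labels ride on Newick node labels with a ``#`` separator: the label
``anc`` in ``((A:0.1,B:0.2)#anc:0.05,C:0.3);`` assigns the branch *above*
that internal node to class ``anc``; a leaf written ``A#fore:0.1`` assigns
its terminal branch to class ``fore``. Unlabelled branches carry no class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    AlignmentShapeError,
    CladeError,
    FrameError,
    IdentifierError,
    NewickParseError,
    ParameterError,
    SchemaError,
    StopCodonError,
)

NUCLEOTIDES = "ACGT"
GAP_CHARS = set("-.?")

#: Controlled vocabulary for locomotion groups.
DEFAULT_GROUPS = ("poor-migrating", "free-moving", "fast-swimming")


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------

def _all_codons() -> list[str]:
    return [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table mapping all 64 codons to amino acids or ``*``."""

    table_id: int
    codon_to_aa: dict[str, str]
    name: str

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ParameterError(
                f"genetic code must map 64 codons, got {len(self.codon_to_aa)}"
            )

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        missing = set(_all_codons()) - set(mapping)
        if missing:  # pragma: no cover - NCBI tables are complete
            raise ParameterError(f"incomplete table {table_id}: missing {missing}")
        return cls(table_id=table_id, codon_to_aa=mapping, name=table.names[0])

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == "*"))


def standard_code() -> GeneticCode:
    """NCBI table 1 (standard nuclear code)."""
    return GeneticCode.from_table_id(1)


def invertebrate_mito_code() -> GeneticCode:
    """NCBI table 5 (invertebrate mitochondrial: AGA/AGG→Ser, ATA→Met, TGA→Trp)."""
    return GeneticCode.from_table_id(5)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _is_gap_codon(codon: str) -> bool:
    return any(ch in GAP_CHARS for ch in codon)


def _is_plain_codon(codon: str) -> bool:
    return all(ch in NUCLEOTIDES for ch in codon)


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences plus the genetic code governing them.

    Codons containing gap characters are missing data; codons containing
    ambiguity codes (e.g. ``N``) are treated as missing by the likelihood
    machinery unless removed by :func:`filter_alignment_columns`.
    """

    taxa: list[str]
    sequences: list[str]
    code: GeneticCode
    gene_name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentShapeError("taxa and sequences count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise IdentifierError(f"duplicate taxa: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged alignment, lengths {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise FrameError(
                f"alignment length {next(iter(lengths))} not divisible by 3"
            )
        self.sequences = [_normalize_seq(s) for s in self.sequences]
        for taxon, seq in zip(self.taxa, self.sequences):
            for j in range(0, len(seq), 3):
                codon = seq[j : j + 3]
                if _is_plain_codon(codon) and self.code.is_stop(codon):
                    raise StopCodonError(
                        f"in-frame stop codon {codon} in taxon {taxon!r} "
                        f"at codon index {j // 3}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codon(self, taxon_index: int, codon_index: int) -> str:
        return self.sequences[taxon_index][3 * codon_index : 3 * codon_index + 3]

    def codon_column(self, codon_index: int) -> list[str]:
        return [self.codon(i, codon_index) for i in range(self.n_taxa)]

    def subset_taxa(self, names: list[str]) -> "CodonAlignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [n for n in names if n not in index]
        if missing:
            raise IdentifierError(f"taxa not in alignment: {missing}")
        return CodonAlignment(
            taxa=list(names),
            sequences=[self.sequences[index[n]] for n in names],
            code=self.code,
            gene_name=self.gene_name,
        )

    @staticmethod
    def concat(alignments: list["CodonAlignment"], gene_name: str = "concat") -> "CodonAlignment":
        """Concatenate alignments sharing the same taxon set and code."""
        first = alignments[0]
        taxa = first.taxa
        for aln in alignments[1:]:
            if set(aln.taxa) != set(taxa):
                raise IdentifierError("concat requires identical taxon sets")
            if aln.code.table_id != first.code.table_id:
                raise ParameterError("concat requires a shared genetic code")
        seqs = []
        for t in taxa:
            parts = [aln.sequences[aln.taxa.index(t)] for aln in alignments]
            seqs.append("".join(parts))
        return CodonAlignment(taxa=list(taxa), sequences=seqs, code=first.code,
                              gene_name=gene_name)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")


@dataclass
class NucleotideAlignment:
    """Plain aligned nucleotide sequences (no reading-frame semantics)."""

    taxa: list[str]
    sequences: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise IdentifierError("duplicate taxa in nucleotide alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError("ragged nucleotide alignment")
        self.sequences = [_normalize_seq(s) for s in self.sequences]

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")


def read_fasta(path, code: GeneticCode, gene_name: str = "") -> CodonAlignment:
    """Read and validate an in-frame codon alignment from FASTA.

    Case is normalized to upper, ``U`` to ``T``. Raises on ragged records,
    out-of-frame length, duplicate taxon names or in-frame stop codons.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return CodonAlignment(taxa=taxa, sequences=seqs, code=code, gene_name=gene_name)


def read_fasta_nucleotide(path, name: str = "") -> NucleotideAlignment:
    """Read an aligned nucleotide FASTA (no frame validation)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"no FASTA records in {path}")
    return NucleotideAlignment(
        taxa=[r.id for r in records], sequences=[str(r.seq) for r in records],
        name=name,
    )


def codon_alignment_as_nucleotide(aln: CodonAlignment) -> NucleotideAlignment:
    return NucleotideAlignment(taxa=list(aln.taxa), sequences=list(aln.sequences),
                               name=aln.gene_name)


@dataclass
class ColumnFilterReport:
    """Provenance record of a codon-column filtering pass."""

    removed_columns: list[int]           # 0-based codon column indices
    reasons: dict[int, str]              # column -> "gap_fraction" | "ambiguity"
    max_gap_fraction: float
    drop_ambiguous: bool
    n_columns_before: int
    n_columns_after: int

    def to_text(self) -> str:
        lines = [
            "codon column filter report",
            f"max_gap_fraction\t{self.max_gap_fraction}",
            f"drop_ambiguous\t{self.drop_ambiguous}",
            f"columns_before\t{self.n_columns_before}",
            f"columns_after\t{self.n_columns_after}",
            "removed_column\treason",
        ]
        lines += [f"{c}\t{self.reasons[c]}" for c in self.removed_columns]
        return "\n".join(lines) + "\n"


def filter_alignment_columns(
    aln: CodonAlignment,
    max_gap_fraction: float = 0.5,
    drop_ambiguous: bool = False,
) -> tuple[CodonAlignment, ColumnFilterReport]:
    """Remove gap-heavy (and optionally ambiguous) codon columns.

    A simplified, codon-granularity stand-in for block-based alignment
    trimming: a codon column is removed when the fraction of taxa whose
    codon contains a gap character exceeds ``max_gap_fraction``, or (with
    ``drop_ambiguous``) when any taxon's codon contains a non-ACGT,
    non-gap character. Removal is in whole codons, so the frame is kept.
    Column indices in the report are 0-based.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ParameterError("max_gap_fraction must be in [0, 1]")
    removed: list[int] = []
    reasons: dict[int, str] = {}
    kept: list[int] = []
    for j in range(aln.n_codons):
        col = aln.codon_column(j)
        gap_frac = sum(_is_gap_codon(c) for c in col) / len(col)
        ambiguous = any(
            not _is_plain_codon(c) and not _is_gap_codon(c) for c in col
        )
        if gap_frac > max_gap_fraction:
            removed.append(j)
            reasons[j] = "gap_fraction"
        elif drop_ambiguous and ambiguous:
            removed.append(j)
            reasons[j] = "ambiguity"
        else:
            kept.append(j)
    if not kept:
        raise FrameError("column filter removed every codon column")
    seqs = [
        "".join(s[3 * j : 3 * j + 3] for j in kept) for s in aln.sequences
    ]
    out = CodonAlignment(taxa=list(aln.taxa), sequences=seqs, code=aln.code,
                         gene_name=aln.gene_name)
    report = ColumnFilterReport(
        removed_columns=removed,
        reasons=reasons,
        max_gap_fraction=max_gap_fraction,
        drop_ambiguous=drop_ambiguous,
        n_columns_before=aln.n_codons,
        n_columns_after=out.n_codons,
    )
    return out, report


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree stored as parent-pointer arrays.

    ``parent[i]`` is the parent node index (-1 for the root); ``lengths[i]``
    is the length of the branch above node ``i`` (0 for the root);
    ``names[i]`` is the leaf name for leaves, an optional label for internal
    nodes; ``branch_class[i]`` is the ω-class of the branch above node ``i``
    or ``None``. Branches are identified by their child node index.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str | None]
    branch_class: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.branch_class is None:
            self.branch_class = [None] * self.n_nodes
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickParseError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.lengths < 0):
            raise ParameterError("negative branch length")
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self._children[p].append(i)

    # -- structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def is_leaf(self, node: int) -> bool:
        return not self._children[node]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]  # type: ignore[misc]

    @property
    def branches(self) -> list[int]:
        """All non-root nodes, i.e. branch identifiers."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self._children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def leaf_set(self, node: int) -> frozenset[str]:
        if self.is_leaf(node):
            return frozenset([self.names[node]])  # type: ignore[list-item]
        acc: dict[int, set[str]] = {}
        for n in self.postorder():
            if self.is_leaf(n):
                acc[n] = {self.names[n]}  # type: ignore[arg-type]
            else:
                s: set[str] = set()
                for c in self._children[n]:
                    s |= acc[c]
                acc[n] = s
        return frozenset(acc[node])

    def mrca(self, leaf_names: list[str]) -> int:
        """Most recent common ancestor node of the named leaves."""
        name_to_node = {self.names[i]: i for i in self.leaves}
        missing = [n for n in leaf_names if n not in name_to_node]
        if missing:
            raise IdentifierError(f"leaves not in tree: {missing}")
        paths = []
        for n in leaf_names:
            node = name_to_node[n]
            path = []
            while node >= 0:
                path.append(node)
                node = int(self.parent[node]) if self.parent[node] >= 0 else -1
            paths.append(path[::-1])
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            col = {p[depth] for p in paths}
            if len(col) == 1:
                mrca = paths[0][depth]
            else:
                break
        return mrca

    def is_monophyletic(self, leaf_names: list[str]) -> bool:
        return self.leaf_set(self.mrca(leaf_names)) == frozenset(leaf_names)

    def require_monophyletic(self, leaf_names: list[str], label: str = "clade") -> int:
        node = self.mrca(leaf_names)
        got = self.leaf_set(node)
        if got != frozenset(leaf_names):
            extra = sorted(got - set(leaf_names))
            raise CladeError(
                f"{label} is not monophyletic; MRCA also spans {extra}"
            )
        return node

    def clade_branches(self, node: int, include_stem: bool = False) -> list[int]:
        """Branch ids strictly inside the clade rooted at ``node``."""
        out: list[int] = []
        stack = list(self._children[node])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        if include_stem and self.parent[node] >= 0:
            out.append(node)
        return sorted(out)

    def with_branch_classes(self, class_map: dict[int, str]) -> "PhyloTree":
        classes = [class_map.get(i) for i in range(self.n_nodes)]
        return PhyloTree(parent=self.parent.copy(), lengths=self.lengths.copy(),
                         names=list(self.names), branch_class=classes)

    def copy(self) -> "PhyloTree":
        return PhyloTree(parent=self.parent.copy(), lengths=self.lengths.copy(),
                         names=list(self.names),
                         branch_class=list(self.branch_class))

    # -- dendropy bridge ------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        names: list[str | None] = [None] * len(nodes)
        classes: list[str | None] = [None] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                lengths[i] = n.edge.length if n.edge.length is not None else 0.0
            raw = n.taxon.label if n.taxon is not None else n.label
            if raw:
                if "#" in raw:
                    name_part, class_part = raw.split("#", 1)
                    names[i] = name_part or None
                    classes[i] = class_part or None
                else:
                    names[i] = raw
        return cls(parent=parent, lengths=lengths, names=names, branch_class=classes)

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: int) -> str:
            label = self.names[node] or ""
            if self.branch_class[node]:
                label = f"{label}#{self.branch_class[node]}"
            if self.is_leaf(node):
                body = label
            else:
                inner = ",".join(fmt(c) for c in self._children[node])
                body = f"({inner}){label}"
            if self.parent[node] >= 0:
                body += f":{self.lengths[node]:.{precision}g}"
            return body

        return fmt(self.root) + ";"

    def collapse_clade_to_leaf(self, leaf_names: list[str],
                               new_name: str) -> "PhyloTree":
        """Replace a monophyletic clade by a single leaf at its MRCA.

        The new leaf keeps the clade's stem branch length — the convention
        used to splice a reconstructed ancestral sequence into a dataset as
        an ordinary taxon.
        """
        node = self.require_monophyletic(leaf_names, label="collapsed clade")
        if self.parent[node] < 0:
            raise CladeError("cannot collapse the whole tree to a leaf")
        drop = set(self.clade_branches(node, include_stem=False))
        keep = [i for i in range(self.n_nodes) if i not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        parent = np.array(
            [remap[self.parent[i]] if self.parent[i] >= 0 else -1 for i in keep]
        )
        names = [new_name if i == node else self.names[i] for i in keep]
        classes = [self.branch_class[i] for i in keep]
        return PhyloTree(parent=parent, lengths=self.lengths[keep],
                         names=names, branch_class=classes)

    def extract_subtree(self, leaf_names: list[str]) -> "PhyloTree":
        """Prune to the given leaves, suppressing unifurcations (lengths summed)."""
        keep = set(leaf_names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise IdentifierError(f"leaves not in tree: {sorted(missing)}")
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                  preserve_underscores=True)
        taxa = [t for t in dtree.taxon_namespace
                if t.label.split("#", 1)[0] in keep]
        dtree.retain_taxa(taxa)
        dtree.suppress_unifurcations()
        return PhyloTree.from_dendropy(dtree)


def read_newick(source) -> PhyloTree:
    """Read a rooted Newick tree from a path or string.

    ``#class`` suffixes on node labels become branch-class labels (see module
    docstring). Missing branch lengths default to 0.
    """
    if isinstance(source, str) and (
        source.lstrip().startswith("(") or source.rstrip().endswith(";")
    ):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    if text.count("(") != text.count(")"):
        offset = _first_unbalanced(text)
        raise NewickParseError(f"unbalanced parentheses near character {offset}")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises its own hierarchy
        raise NewickParseError(str(exc)) from exc
    return PhyloTree.from_dendropy(dtree)


def _first_unbalanced(text: str) -> int:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Species metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesMetadata:
    """One species' locomotion group and optional habitat / clade labels."""

    species: str
    group: str
    habitat: str | None = None
    clade: str | None = None


def read_metadata(
    path,
    allowed_groups: tuple[str, ...] = DEFAULT_GROUPS,
    extra_groups: tuple[str, ...] = (),
) -> list[SpeciesMetadata]:
    """Read species metadata from a TSV with columns species, group[, habitat, clade]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "group"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing required columns: {sorted(missing)}")
    vocab = set(allowed_groups) | set(extra_groups)
    bad = sorted(set(df["group"]) - vocab)
    if bad:
        raise SchemaError(
            f"unknown group values {bad}; extend the vocabulary to accept them"
        )
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise IdentifierError(f"duplicate species in metadata: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpeciesMetadata(
                species=row["species"],
                group=row["group"],
                habitat=row.get("habitat") if "habitat" in df.columns else None,
                clade=row.get("clade") if "clade" in df.columns else None,
            )
        )
    return records


def write_metadata(records: list[SpeciesMetadata], path) -> None:
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "group": [r.group for r in records],
            "habitat": [r.habitat for r in records],
            "clade": [r.clade for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
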