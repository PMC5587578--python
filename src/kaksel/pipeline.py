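"""Config-driven end-to-end drivers.

Two analyses are packaged:

* :func:`run_group_analysis` — free-ratio codon fit → terminal-branch
  Ka/Ks → nonsynonymous-count filter → (outlier removal) → pairwise
  locomotion-group comparisons, for the pooled mitochondrial-like genes,
  optionally per gene, and for the nuclear-like control gene.
* :func:`run_atp8_analysis` — marginal ancestral reconstruction →
  assembly of ancestor-spliced datasets → nested branch-model LRT ladder
  localizing a relaxation of constraint to an ancestral branch.

Both consume an :class:`AnalysisConfig`, echo it (with a content hash)
into every output table, and are byte-reproducible given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import fit_nucleotide_model, marginal_ancestral_sequence
from .branch_metrics import branch_dn_ds, metrics_to_frame
from .codon_model import FitOptions, fit_model, free_ratio_spec
from .errors import KakselError
from .io_formats import (
    CodonAlignment,
    PhyloTree,
    codon_alignment_as_nucleotide,
    invertebrate_mito_code,
    read_fasta,
    read_metadata,
    read_newick,
    standard_code,
)
from .selection_tests import (
    BranchSelector,
    DatasetDef,
    LadderSpec,
    ModelDef,
    compare_groups,
    comparisons_to_frame,
    filter_branches,
    run_model_ladder,
)
from .synthetic_data import (
    CLASS_ANC_MARINE,
    CLASS_ANC_POOR,
    GROUP_POOR,
    SimulationSpec,
    SyntheticStudy,
    simulate_study,
)

logger = logging.getLogger("kaksel")


@dataclass
class AnalysisConfig:
    """Inputs and knobs of the end-to-end drivers.

    Either ``study_dir`` points at files on disk (per-gene FASTA, Newick
    tree, metadata TSV) or ``simulate=True`` generates a synthetic study
    from ``sim_spec`` at run time.
    """

    seed: int = 0
    out_dir: str | None = None
    simulate: bool = True
    sim_spec: SimulationSpec = field(default_factory=SimulationSpec)
    study_dir: str | None = None
    mito_genes: list[str] | None = None       # None = all mito-like genes
    control_gene: str | None = None
    atp8_gene: str | None = None
    min_nonsyn_subs: float = 20.0
    control_min_nonsyn_subs: float = 0.0
    outlier_removal: bool = True
    test: str = "mwu"
    per_gene: bool = False
    fix_branch_lengths: bool = True
    multistart: int = 3
    nucleotide_model: str = "HKY"
    nucleotide_gamma: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim_spec"]["control_gene"] = list(self.sim_spec.control_gene)
        d["sim_spec"]["atp8_gene"] = list(self.sim_spec.atp8_gene)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim_spec", None)
        cfg = cls(**raw)
        if sim_raw:
            if "control_gene" in sim_raw:
                sim_raw["control_gene"] = tuple(sim_raw["control_gene"])
            if "atp8_gene" in sim_raw:
                sim_raw["atp8_gene"] = tuple(sim_raw["atp8_gene"])
            cfg.sim_spec = SimulationSpec(**sim_raw)
        return cfg


def _fit_options(config: AnalysisConfig) -> FitOptions:
    return FitOptions(
        multistart=config.multistart,
        optimize_branch_lengths=not config.fix_branch_lengths,
    )


def load_or_simulate_study(config: AnalysisConfig) -> SyntheticStudy:
    if config.simulate:
        spec = dataclasses.replace(config.sim_spec, seed=config.seed)
        return simulate_study(spec, seed=config.seed)
    if not config.study_dir:
        raise KakselError("config needs study_dir when simulate is off")
    tree = read_newick(os.path.join(config.study_dir, "tree.nwk"))
    metadata = read_metadata(os.path.join(config.study_dir, "metadata.tsv"))
    alignments: dict[str, CodonAlignment] = {}
    mito = invertebrate_mito_code()
    nuc = standard_code()
    for fname in sorted(os.listdir(config.study_dir)):
        if not fname.endswith(".fasta"):
            continue
        gene = fname[: -len(".fasta")]
        code = nuc if gene == config.control_gene else mito
        alignments[gene] = read_fasta(
            os.path.join(config.study_dir, fname), code, gene_name=gene
        )
    return SyntheticStudy(tree=tree, alignments=alignments, metadata=metadata,
                          truth={})


@dataclass
class GroupAnalysisReport:
    comparisons: pd.DataFrame          # pooled mitochondrial genes
    group_summary: pd.DataFrame
    per_branch: pd.DataFrame
    per_gene: dict[str, pd.DataFrame]
    control_comparisons: pd.DataFrame | None
    provenance: dict

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        _write_table(self.comparisons, os.path.join(out_dir, "group_comparisons.tsv"),
                     self.provenance)
        _write_table(self.group_summary, os.path.join(out_dir, "group_summary.tsv"),
                     self.provenance)
        _write_table(self.per_branch, os.path.join(out_dir, "branch_metrics.tsv"),
                     self.provenance)
        for gene, df in self.per_gene.items():
            _write_table(df, os.path.join(out_dir, f"gene_{gene}_comparisons.tsv"),
                         self.provenance)
        if self.control_comparisons is not None:
            _write_table(self.control_comparisons,
                         os.path.join(out_dir, "control_comparisons.tsv"),
                         self.provenance)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)


def _write_table(df: pd.DataFrame, path, provenance: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kaksel {provenance['version']} config_hash={provenance['config_hash']} "
                 f"seed={provenance['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)


def _gene_group_tables(aln: CodonAlignment, tree: PhyloTree, metadata,
                       config: AnalysisConfig, threshold: float):
    """Free-ratio fit → metrics → filter → comparisons for one alignment."""
    options = _fit_options(config)
    spec = free_ratio_spec(tree, aln.code)
    fit = fit_model(aln, tree, spec, options)
    metrics = branch_dn_ds(fit)
    kept, report = filter_branches(metrics, min_nonsyn_subs=threshold)
    frames = []
    for metric in ("KaKs", "Ka", "Ks"):
        res = compare_groups(kept, metadata, metric=metric, test=config.test,
                             outlier_removal=config.outlier_removal)
        frames.append(comparisons_to_frame(res))
    comparisons = pd.concat(frames, ignore_index=True)
    logger.info("gene %s: %d/%d terminal branches retained (%s)",
                aln.gene_name, report.n_retained, report.n_input,
                report.discarded_by_reason)
    return fit, metrics, kept, comparisons


def _group_summary(kept, metadata, outlier_removal: bool) -> pd.DataFrame:
    from .selection_tests import remove_outliers

    meta = {r.species: r.group for r in metadata}
    rows = []
    groups: dict[str, list] = {}
    for m in kept:
        groups.setdefault(meta[m.species], []).append(m)
    for group, ms in sorted(groups.items()):
        for metric, getter in (("KaKs", lambda m: m.omega),
                               ("Ka", lambda m: m.dN), ("Ks", lambda m: m.dS)):
            raw = [getter(m) for m in ms]
            vals = remove_outliers(raw) if outlier_removal else raw
            rows.append({"group": group, "metric": metric, "n": len(vals),
                         "mean": float(np.mean(vals)),
                         "median": float(np.median(vals)),
                         "mean_raw": float(np.mean(raw))})
    return pd.DataFrame(rows)


def run_group_analysis(config: AnalysisConfig,
                       study: SyntheticStudy | None = None) -> GroupAnalysisReport:
    """The locomotion-group Ka/Ks comparison, end to end."""
    logging.basicConfig(level=config.log_level)
    study = study or load_or_simulate_study(config)
    tree = study.tree
    metadata = study.metadata

    control_name = config.control_gene
    atp8_name = config.atp8_gene
    if config.simulate:
        control_name = control_name or config.sim_spec.control_gene[0]
        atp8_name = atp8_name or config.sim_spec.atp8_gene[0]
    mito_names = config.mito_genes or [
        g for g in study.alignments if g not in (control_name, atp8_name)
    ]

    pooled = CodonAlignment.concat([study.alignments[g] for g in mito_names],
                                   gene_name="mito_pooled")
    fit, metrics, kept, comparisons = _gene_group_tables(
        pooled, tree, metadata, config, config.min_nonsyn_subs)
    summary = _group_summary(kept, metadata, config.outlier_removal)

    per_gene: dict[str, pd.DataFrame] = {}
    if config.per_gene:
        for gene in mito_names:
            _, _, _, table = _gene_group_tables(
                study.alignments[gene], tree, metadata, config,
                config.min_nonsyn_subs)
            per_gene[gene] = table

    control_table = None
    if control_name and control_name in study.alignments:
        _, _, _, control_table = _gene_group_tables(
            study.alignments[control_name], tree, metadata, config,
            config.control_min_nonsyn_subs)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "genes_pooled": mito_names,
    }
    report = GroupAnalysisReport(
        comparisons=comparisons,
        group_summary=summary,
        per_branch=metrics_to_frame(metrics),
        per_gene=per_gene,
        control_comparisons=control_table,
        provenance=provenance,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# Ancestral-relaxation (Atp8-style) analysis
# ---------------------------------------------------------------------------

@dataclass
class Atp8AnalysisReport:
    ladder_table: pd.DataFrame         # one row per LRT: comparison, lnLs, p
    omega_table: pd.DataFrame
    ancestors: dict[str, str]          # name -> reconstructed sequence
    mean_posteriors: dict[str, float]
    provenance: dict

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        _write_table(self.ladder_table, os.path.join(out_dir, "lrt_ladder.tsv"),
                     self.provenance)
        _write_table(self.omega_table, os.path.join(out_dir, "omega_estimates.tsv"),
                     self.provenance)
        with open(os.path.join(out_dir, "ancestors.fasta"), "w") as fh:
            for name, seq in self.ancestors.items():
                fh.write(f">{name}\n{seq}\n")
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)


def _mask_stop_codons(seq: str, code) -> tuple[str, int]:
    out = []
    masked = 0
    for j in range(0, len(seq), 3):
        codon = seq[j : j + 3]
        if all(c in "ACGT" for c in codon) and code.is_stop(codon):
            out.append("---")
            masked += 1
        else:
            out.append(codon)
    return "".join(out), masked


def splice_ancestor(aln: CodonAlignment, tree: PhyloTree,
                    clade_leaves: list[str], ancestor_name: str,
                    ancestor_seq: str) -> tuple[CodonAlignment, PhyloTree]:
    """Replace a clade by its reconstructed ancestor as an ordinary taxon.

    The ancestor leaf keeps the clade's stem branch length. In-frame stop
    codons in the reconstructed sequence (possible because reconstruction
    is nucleotide-level) are masked to gap codons.
    """
    new_tree = tree.collapse_clade_to_leaf(clade_leaves, ancestor_name)
    keep = [t for t in aln.taxa if t not in set(clade_leaves)]
    sub = aln.subset_taxa(keep)
    masked_seq, n_masked = _mask_stop_codons(ancestor_seq, aln.code)
    if n_masked:
        logger.warning("masked %d in-frame stop codon(s) in %s", n_masked,
                       ancestor_name)
    new_aln = CodonAlignment(
        taxa=sub.taxa + [ancestor_name],
        sequences=sub.sequences + [masked_seq],
        code=aln.code,
        gene_name=aln.gene_name,
    )
    return new_aln, new_tree


def build_relaxation_ladder(ancestor_i: str, ancestor_ii: str,
                            marine_leaves: list[str]) -> LadderSpec:
    """The three-dataset nested-model ladder.

    Dataset I: outgroup taxa + the clade ancestor as a leaf; uniform model
    A vs two-ratio model B singling out the ancestor's terminal branch.
    Dataset II: same construction one level deeper (marine subclade
    ancestor): C vs D. Dataset III: all extant taxa; E gives the marine
    stem plus the within-marine branches one shared foreground ω, F splits
    the stem (ω3) from the within-marine branches (ω2): F vs E.
    """
    model_a = ModelDef(name="A")
    model_b = ModelDef(name="B", foreground={
        "omega2": BranchSelector(kind="terminal", leaves=[ancestor_i])})
    model_c = ModelDef(name="C")
    model_d = ModelDef(name="D", foreground={
        "omega2": BranchSelector(kind="terminal", leaves=[ancestor_ii])})
    model_e = ModelDef(name="E", foreground={
        "omega2": BranchSelector(kind="stem_and_within", leaves=marine_leaves)})
    model_f = ModelDef(name="F", foreground={
        "omega2": BranchSelector(kind="within", leaves=marine_leaves),
        "omega3": BranchSelector(kind="stem", leaves=marine_leaves)})
    return LadderSpec(datasets=[
        DatasetDef(name="I", models=[model_a, model_b],
                   comparisons=[("B", "A")]),
        DatasetDef(name="II", models=[model_c, model_d],
                   comparisons=[("D", "C")]),
        DatasetDef(name="III", models=[model_e, model_f],
                   comparisons=[("F", "E")]),
    ])


ANC_BIVALVIA = "anc_bivalvia_seq"
ANC_MARINE = "anc_marine_seq"


def run_atp8_analysis(config: AnalysisConfig,
                      study: SyntheticStudy | None = None) -> Atp8AnalysisReport:
    """Ancestral reconstruction plus the LRT ladder, end to end."""
    logging.basicConfig(level=config.log_level)
    study = study or load_or_simulate_study(config)
    tree = study.tree
    atp8_name = config.atp8_gene or (
        config.sim_spec.atp8_gene[0] if config.simulate else None)
    if not atp8_name or atp8_name not in study.alignments:
        raise KakselError("no Atp8-like gene available for the ladder analysis")
    aln = study.alignments[atp8_name]

    meta = {r.species: r for r in study.metadata}
    poor_leaves = [t for t in aln.taxa if meta[t].group == GROUP_POOR]
    marine_leaves = [t for t in poor_leaves if meta[t].habitat == "marine"]
    if len(poor_leaves) < 2 or len(marine_leaves) < 2:
        raise KakselError("ladder needs a bivalve-like clade with a marine subclade")

    nuc_aln = codon_alignment_as_nucleotide(aln)
    nuc_fit = fit_nucleotide_model(
        nuc_aln, tree, model=config.nucleotide_model,
        gamma=config.nucleotide_gamma,
        optimize_branch_lengths=not config.fix_branch_lengths,
    )
    rec_biv = marginal_ancestral_sequence(nuc_fit, poor_leaves)
    rec_marine = marginal_ancestral_sequence(nuc_fit, marine_leaves)

    aln_i, tree_i = splice_ancestor(aln, tree, poor_leaves, ANC_BIVALVIA,
                                    rec_biv.sequence)
    aln_ii, tree_ii = splice_ancestor(aln, tree, marine_leaves, ANC_MARINE,
                                      rec_marine.sequence)

    ladder = build_relaxation_ladder(ANC_BIVALVIA, ANC_MARINE, marine_leaves)
    ladder_result = run_model_ladder(
        aln, tree, ladder, _fit_options(config),
        data_by_dataset={"I": (aln_i, tree_i), "II": (aln_ii, tree_ii),
                         "III": (aln, tree)},
    )
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "gene": atp8_name,
        "nucleotide_model": config.nucleotide_model,
    }
    report = Atp8AnalysisReport(
        ladder_table=ladder_result.to_frame(),
        omega_table=ladder_result.omega_table(),
        ancestors={ANC_BIVALVIA: rec_biv.sequence, ANC_MARINE: rec_marine.sequence},
        mean_posteriors={ANC_BIVALVIA: rec_biv.mean_posterior,
                         ANC_MARINE: rec_marine.mean_posterior},
        provenance=provenance,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
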