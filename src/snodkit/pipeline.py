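"""End-to-end orchestration of the synthetic-community analysis.

Runs the full chain — ortholog clustering, core-gene selection, trimming and
concatenation, tree inference with bootstrap and gene-jackknife support, ANI
species delimitation with dereplication, the specific-gene scan, and the HGT
screen — on a generated community, and scores every stage against the
community's planted truth. The same entry point backs the ``snodkit demo``
command and the acceptance script.

Each stage draws its randomness from a sub-seed derived from the global seed
and the stage name, so stages are individually reproducible and a rerun with
the same configuration is identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import ani as ani_mod
from . import phylo
from .msa import MultipleAlignment, align_og, concat_supermatrix, trim_alignment
from .pangenome import OrthologGroup, cluster_ogs, select_core
from .phylo import SupportedTree, bootstrap_support, gene_jackknife
from .simulate import Community, CommunityConfig, generate_community
from .specific import GroupSet, PresenceMatrix, scan_groups
from .hgt import cross_taxon_best_hits, match_specific_to_hgt

__all__ = ["PipelineResult", "run_pipeline", "stage_seed", "majority_family"]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage sub-seed: stable hash of the stage name mixed with the
    global seed, kept below 2^31."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def majority_family(og: OrthologGroup) -> str:
    """Planted family a clustered OG corresponds to (majority vote over
    member sequence ids of the form genome|family[|copy])."""
    fams = [r.id.split("|")[1] for _, r in og.sequences()]
    return max(set(fams), key=fams.count)


@dataclass
class PipelineResult:
    community: Community
    ogs: list[OrthologGroup]
    core: list[OrthologGroup]
    supermatrix: Any
    tree: SupportedTree
    rooted_tree: SupportedTree
    bootstrap: SupportedTree
    jackknife: SupportedTree
    ani: ani_mod.ANIMatrix
    partition: ani_mod.SpeciesPartition
    representatives: list[str]
    specific_report: Any
    hgt_candidates: list
    metrics: dict[str, float] = field(default_factory=dict)

    def checks(self) -> dict[str, bool]:
        m = self.metrics
        return {
            "species partition equals planted groups": m["ani_partition_exact"] == 1,
            "within-group ANI exceeds between-group ANI": m["ani_margin"] > 0,
            "rooted topology matches the generating tree": m["tree_rf_to_truth"] == 0,
            "all group clades at 100% bootstrap": m["bootstrap_min_group_support"] == 100,
            "all group clades at 100% jackknife": m["jackknife_min_group_support"] == 100,
            "topology unchanged without outgroup": m["rf_without_outgroup"] == 0,
            "topology preserved after dereplication": m["rf_after_derep"] == 0,
            "specific-gene recovery exact": m["specific_precision"] == 1
            and m["specific_recall"] == 1,
            "core selection equals planted clean core": m["core_exact"] == 1,
            "planted HGT all recovered": m["hgt_recall"] == 1,
            "no spurious HGT calls": m["hgt_false_positives"] == 0,
            "no specific gene among HGT candidates": m["specific_hgt_overlap"] == 0,
        }


def _canonical(bp: frozenset[str], all_taxa: frozenset[str]) -> frozenset[str]:
    ref = min(all_taxa)
    return bp if ref not in bp else frozenset(all_taxa - bp)


def _group_support(
    tree: SupportedTree, members: list[str], all_taxa: frozenset[str]
) -> float:
    if not 2 <= len(members) <= len(all_taxa) - 2:
        return 100.0  # trivial split: always present
    bp = _canonical(frozenset(members), all_taxa)
    return tree.supports.get(bp, 0.0)


def run_pipeline(
    config: CommunityConfig | None = None,
    community: Community | None = None,
    seed: int = 0,
    n_boot: int = 100,
    n_jack: int = 100,
    jackknife_fraction: float = 0.8,
    ani_threshold: float = 95.0,
    derep_threshold: float = 99.0,
    occupancy: float = 0.6,
    hgt_min_identity: float = 98.0,
    hgt_min_cov: float = 0.95,
) -> PipelineResult:
    """Generate (or accept) a community, run every stage, score vs truth."""
    if community is None:
        if config is None:
            config = CommunityConfig(seed=stage_seed(seed, "community"))
        community = generate_community(config)
    truth = community.truth
    metrics: dict[str, float] = {}

    # ---- pangenome ---------------------------------------------------
    clustering_input = community.clustering_proteomes()
    ogs = cluster_ogs(clustering_input)
    taxa = sorted(community.genomes)
    n_taxa = len(taxa)
    for og in ogs:
        full = len(og.genomes) == n_taxa
        unicopy = all(c == 1 for c in og.copy_count.values())
        if full and unicopy:
            og.alignment = align_og([r for _, r in og.sequences()])
    aligned = [og for og in ogs if og.alignment is not None]
    core = select_core(aligned, taxa)
    core_fams = sorted(majority_family(og) for og in core)
    truth_core = sorted(truth.core_families)
    metrics["core_n_selected"] = len(core_fams)
    metrics["core_exact"] = float(core_fams == truth_core)

    # ---- supermatrix + trees -----------------------------------------
    # re-key alignment rows from sequence ids to genome names
    def by_genome(og: OrthologGroup) -> MultipleAlignment:
        return MultipleAlignment(
            {g: og.alignment.rows[r.id] for g, r in og.sequences()},
            og.alignment.moltype,
        )

    trimmed = [(og.og_id, trim_alignment(by_genome(og))) for og in core]
    trimmed = [(og_id, a) for og_id, a in trimmed if a.length > 0]
    sm = concat_supermatrix(trimmed, taxa)
    metrics["supermatrix_length"] = sm.length
    metrics["supermatrix_missing_fraction"] = sm.missing_fraction

    tree = phylo.nj_tree(phylo.distance_matrix(sm))
    outgroup = next((g for g in taxa if truth.group_of[g] == "outgroup"), None)
    rooted = phylo.root_with_outgroup(tree, outgroup) if outgroup else tree
    # clones are grafted after tree generation, so compare on the
    # generating tree's own leaf set; polytomy resolutions score 0
    truth_tree = SupportedTree(truth.tree_newick)
    metrics["tree_rf_to_truth"] = phylo.resolution_distance(
        truth_tree, _restrict(tree, sorted(truth_tree.taxa))
    )

    boot = bootstrap_support(sm, n_reps=n_boot, seed=stage_seed(seed, "bootstrap"))
    total_len = sum(a.length for _, a in trimmed)
    target = int(jackknife_fraction * total_len)
    jack = gene_jackknife(
        trimmed, taxa, target_length=target, n_reps=n_jack,
        seed=stage_seed(seed, "jackknife"),
    )
    all_taxa = frozenset(taxa)
    groups = truth.groups
    boot_support = [
        _group_support(boot, truth.members(g), all_taxa) for g in groups
    ]
    jack_support = [
        _group_support(jack, truth.members(g), all_taxa) for g in groups
    ]
    metrics["bootstrap_min_group_support"] = min(boot_support)
    metrics["jackknife_min_group_support"] = min(jack_support)

    # outgroup-removal control: the supported (generating) structure of the
    # ingroup must be recovered identically without the outgroup; arbitrary
    # resolutions of within-group polytomies are allowed to differ
    if outgroup:
        ingroup = [t for t in taxa if t != outgroup]
        sm_in = concat_supermatrix(
            [(og_id, MultipleAlignment(
                {t: a.rows[t] for t in ingroup if t in a.rows}, a.moltype))
             for og_id, a in trimmed],
            ingroup,
        )
        tree_in = phylo.nj_tree(phylo.distance_matrix(sm_in))
        truth_in_taxa = sorted(truth_tree.taxa - {outgroup})
        metrics["rf_without_outgroup"] = phylo.resolution_distance(
            _restrict(truth_tree, truth_in_taxa),
            _restrict(tree_in, truth_in_taxa),
        )
    else:
        metrics["rf_without_outgroup"] = 0.0

    # ---- ANI + dereplication -----------------------------------------
    mat = ani_mod.ani_matrix(community.genome_seqs)
    part = ani_mod.species_partition(mat, threshold=ani_threshold)
    truth_blocks = {
        frozenset(truth.members(g)) for g in groups
    } | {frozenset([g for g in taxa if truth.group_of[g] == "outgroup"])}
    truth_blocks = {b for b in truth_blocks if b}
    metrics["ani_partition_exact"] = float(part.as_sets() == truth_blocks)
    within, between = [], []
    gidx = {g: i for i, g in enumerate(mat.genomes)}
    for i, a in enumerate(mat.genomes):
        for j in range(i + 1, len(mat.genomes)):
            b = mat.genomes[j]
            v = mat.ani[i, j]
            ga, gb = truth.group_of[a], truth.group_of[b]
            if "outgroup" in (ga, gb):
                continue
            (within if ga == gb else between).append(v)
    min_within = float(np.nanmin(within)) if within else 100.0
    max_between = float(np.nanmax(between)) if between else 0.0
    metrics["ani_min_within"] = min_within
    metrics["ani_max_between"] = max_between
    metrics["ani_margin"] = min_within - max_between

    reps = ani_mod.dereplicate(mat, community.metadata, threshold=derep_threshold)
    metrics["n_representatives"] = len(reps)
    sm_reps = concat_supermatrix(
        [(og_id, MultipleAlignment(
            {t: a.rows[t] for t in reps if t in a.rows}, a.moltype))
         for og_id, a in trimmed],
        reps,
    )
    tree_reps = phylo.nj_tree(phylo.distance_matrix(sm_reps))
    rep_truth_taxa = sorted(set(reps) & truth_tree.taxa)
    metrics["rf_after_derep"] = phylo.resolution_distance(
        _restrict(truth_tree, rep_truth_taxa),
        _restrict(tree_reps, rep_truth_taxa),
    )

    # ---- specific genes ----------------------------------------------
    pm = PresenceMatrix.from_ogs(ogs, taxa)
    group_sets = [
        GroupSet(g, frozenset(truth.members(g))) for g in groups
    ]
    report = scan_groups(
        pm, group_sets, rooted, community.proteomes, ogs=ogs,
        occupancy=occupancy, study_proteomes=clustering_input,
    )
    fam_by_og = {og.og_id: majority_family(og) for og in ogs}
    predicted: dict[frozenset[str], set[str]] = {}
    for name, res in report.results.items():
        if not res.confirmed:
            continue
        gs = res.group_set
        covered = frozenset(
            g for g in groups if set(truth.members(g)) <= gs.members
        )
        key = covered if covered else frozenset([name])
        predicted.setdefault(key, set()).update(
            fam_by_og[og_id] for og_id in res.confirmed
        )
    truth_map = {
        gs: set(fams) for gs, fams in truth.specific_genes.items()
    }
    tp = sum(
        len(predicted.get(gs, set()) & fams) for gs, fams in truth_map.items()
    )
    n_pred = sum(len(v) for v in predicted.values())
    n_true = sum(len(v) for v in truth_map.values())
    metrics["specific_precision"] = tp / n_pred if n_pred else 1.0
    metrics["specific_recall"] = tp / n_true if n_true else 1.0
    metrics["specific_n_confirmed"] = n_pred

    # ---- HGT screen ---------------------------------------------------
    taxon_of = dict(truth.group_of)
    cands = cross_taxon_best_hits(
        community.proteomes, taxon_of,
        min_identity=hgt_min_identity, min_cov=hgt_min_cov,
    )
    cand_pairs = {
        (c.source_genome, c.gene_id.split("|")[1]) for c in cands
    }
    recovered = sum(
        1 for _d, r, fam in truth.hgt_events if (r, fam) in cand_pairs
    )
    metrics["hgt_recall"] = (
        recovered / len(truth.hgt_events) if truth.hgt_events else 1.0
    )
    # every legitimate hit touches a transferred copy: either the recipient
    # reporting the donor taxon's gene, or a donor-taxon genome reporting
    # the copy now sitting in the recipient
    recipients = {(r, fam) for _d, r, fam in truth.hgt_events}
    fp = 0
    for c in cands:
        fam = c.gene_id.split("|")[1]
        if (c.source_genome, fam) in recipients:
            continue
        if (c.partner_genome, fam) in recipients:
            continue
        fp += 1
    metrics["hgt_false_positives"] = float(fp)
    specific_ogs = [
        og for og in ogs if og.og_id in report.all_confirmed()
    ]
    matched = match_specific_to_hgt(specific_ogs, cands)
    metrics["specific_hgt_overlap"] = float(len(matched))

    return PipelineResult(
        community=community,
        ogs=ogs,
        core=core,
        supermatrix=sm,
        tree=tree,
        rooted_tree=rooted,
        bootstrap=boot,
        jackknife=jack,
        ani=mat,
        partition=part,
        representatives=reps,
        specific_report=report,
        hgt_candidates=cands,
        metrics=metrics,
    )


def _restrict(tree: SupportedTree, keep: list[str]) -> SupportedTree:
    dtree = tree.to_dendropy()
    sub = dtree.extract_tree_with_taxa_labels(labels=set(keep))
    return SupportedTree(
        sub.as_string(schema="newick", suppress_rooting=True).strip()
    )
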