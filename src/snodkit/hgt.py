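"""Horizontal gene transfer screening.

The screen follows the best-hit logic of cross-taxon comparative genomics:
for every protein, the best hit in any genome of a *different* taxon is a
transfer candidate when identity and query coverage clear their thresholds
(defaults 98% / 0.95 — levels essentially impossible to sustain by vertical
descent between genomes whose background identity is far lower). Candidate
gene sets can be intersected with specific-gene families, and each
candidate family can be checked for phylogenetic incongruence: in the gene
tree, do the focal taxon's sequences nest inside another taxon's clade?
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io import SequenceRecord
from .pangenome import OrthologGroup, global_identity
from .phylo import SupportedTree

__all__ = [
    "HGTCandidate",
    "IncongruenceVerdict",
    "cross_taxon_best_hits",
    "match_specific_to_hgt",
    "tree_incongruence",
]


@dataclass(frozen=True)
class HGTCandidate:
    """A cross-taxon best hit above the identity/coverage thresholds."""

    gene_id: str
    source_genome: str
    partner_gene_id: str
    partner_genome: str
    identity: float  # percent
    coverage: float  # fraction of the shorter sequence
    gene_seq: str = ""
    direction: str = "unresolved"

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity out of [0, 100]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage out of [0, 1]")


@dataclass(frozen=True)
class IncongruenceVerdict:
    kind: str  # congruent | clusters_with_other_taxon | indeterminate
    partner_taxon: str | None = None


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(max(1, len(seq) - k + 1))}


def cross_taxon_best_hits(
    proteomes: dict[str, list[SequenceRecord]],
    taxon_of: dict[str, str],
    min_identity: float = 98.0,
    min_cov: float = 0.95,
    kmer: int = 5,
) -> list[HGTCandidate]:
    """Best cross-taxon hit per gene, filtered at the thresholds.

    ``min_identity`` is a percent; ``coverage`` is the length of the shorter
    sequence over the longer (global alignment end to end). A shared k-mer
    prefilter keeps the comparison set small; at the default 98% identity
    any true hit shares abundant k-mers.
    """
    taxa = {taxon_of[g] for g in proteomes}
    if len(taxa) < 2:
        raise ValueError("cross-taxon screen needs at least 2 taxa")
    entries = [
        (g, r) for g in sorted(proteomes) for r in proteomes[g]
    ]
    kmer_index: dict[str, list[int]] = defaultdict(list)
    for i, (_g, r) in enumerate(entries):
        for km in _kmer_set(r.seq, kmer):
            kmer_index[km].append(i)

    candidates: list[HGTCandidate] = []
    for i, (g, r) in enumerate(entries):
        partner_ids: set[int] = set()
        for p in range(0, max(1, len(r.seq) - kmer + 1), kmer):
            partner_ids.update(kmer_index.get(r.seq[p : p + kmer], ()))
        best: tuple[float, float, int] | None = None
        for j in sorted(partner_ids):
            g2, r2 = entries[j]
            if taxon_of[g2] == taxon_of[g]:
                continue
            ident = 100.0 * global_identity(r.seq, r2.seq)
            cov = min(len(r.seq), len(r2.seq)) / max(len(r.seq), len(r2.seq))
            if best is None or ident > best[0]:
                best = (ident, cov, j)
        if best is None:
            continue
        ident, cov, j = best
        if ident >= min_identity and cov >= min_cov:
            g2, r2 = entries[j]
            candidates.append(
                HGTCandidate(
                    gene_id=r.id,
                    source_genome=g,
                    partner_gene_id=r2.id,
                    partner_genome=g2,
                    identity=ident,
                    coverage=cov,
                    gene_seq=r.seq,
                )
            )
    return candidates


def match_specific_to_hgt(
    specific: list[OrthologGroup],
    candidates: list[HGTCandidate],
    min_identity: float = 98.0,
    min_cov: float = 0.95,
) -> list[str]:
    """Specific-gene families whose sequences match any HGT-candidate gene
    at >= ``min_identity`` percent over >= ``min_cov`` of the query."""
    matched: list[str] = []
    for og in specific:
        hit = False
        for _g, rec in og.sequences():
            for cand in candidates:
                if not cand.gene_seq:
                    continue
                ident = 100.0 * global_identity(rec.seq, cand.gene_seq)
                cov = min(len(rec.seq), len(cand.gene_seq)) / max(
                    len(rec.seq), len(cand.gene_seq)
                )
                if ident >= min_identity and cov >= min_cov:
                    hit = True
                    break
            if hit:
                break
        if hit:
            matched.append(og.og_id)
    return sorted(matched)


def tree_incongruence(
    gene_tree: SupportedTree,
    taxon_of: dict[str, str],
    focal_taxon: str,
) -> IncongruenceVerdict:
    """Phylogenetic placement of a focal taxon in a gene tree.

    Under midpoint rooting: ``congruent`` when the focal taxon's leaves are
    monophyletic; ``clusters_with_other_taxon(T)`` when the smallest clade
    containing all focal leaves admixes leaves of exactly one other taxon;
    ``indeterminate`` when the tree holds only two taxa (no meaningful
    comparison to a species tree) or when more than one other taxon
    intervenes.
    """
    dtree = gene_tree.to_dendropy()
    leaves = [l.taxon.label for l in dtree.leaf_node_iter()]
    if len(leaves) < 4:
        raise ValueError("gene tree needs at least 4 leaves")
    present_taxa = {taxon_of[l] for l in leaves if l in taxon_of}
    focal_leaves = {l for l in leaves if taxon_of.get(l) == focal_taxon}
    if not focal_leaves:
        raise ValueError(f"focal taxon {focal_taxon!r} absent from the tree")
    if len(present_taxa) < 2:
        raise ValueError("gene tree holds a single taxon")
    if len(present_taxa) == 2:
        return IncongruenceVerdict("indeterminate")

    dtree.reroot_at_midpoint()
    mrca = dtree.mrca(taxon_labels=sorted(focal_leaves))
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    if clade == focal_leaves:
        return IncongruenceVerdict("congruent")
    others = {taxon_of[l] for l in clade - focal_leaves if l in taxon_of}
    if len(others) == 1:
        return IncongruenceVerdict("clusters_with_other_taxon", next(iter(others)))
    return IncongruenceVerdict("indeterminate")
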