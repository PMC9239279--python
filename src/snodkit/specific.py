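"""Group-specific gene detection with orthologous enrichment.

A gene family is a candidate specific gene of a genome group when it occurs
in at least 60% of the group's members (ceiling) and in no study genome
outside the group. Candidates are then enriched from a sequence pool — any
pool protein whose best hit falls inside the family (and nowhere else in the
study proteome) is added, which recovers group members missed by annotation
and reveals occurrences in other taxa. A candidate is confirmed when, after
enrichment, every member of the group carries the family and still no study
genome outside the group does. The scan covers every single group, every
pair of groups, the union of all groups, and the leaf set of every internal
node of the species tree; a family confirmed for several nested sets is
reported for the smallest. Confirmed families are classified by taxonomic
breadth from their non-study (external) members.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord
from .pangenome import OrthologGroup, global_identity
from .phylo import SupportedTree

__all__ = [
    "PresenceMatrix",
    "GroupSet",
    "SpecificGeneReport",
    "candidate_specific",
    "enrich_og",
    "confirm_specific",
    "scan_groups",
    "classify_breadth",
]


@dataclass
class PresenceMatrix:
    """Copy counts of OGs (columns) across genomes (rows)."""

    genomes: list[str]
    ogs: list[str]
    count: np.ndarray

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count, dtype=int)
        if self.count.shape != (len(self.genomes), len(self.ogs)):
            raise ValueError("presence matrix shape mismatch")
        if np.any(self.count < 0):
            raise ValueError("negative copy counts")

    @classmethod
    def from_ogs(
        cls, ogs: list[OrthologGroup], genomes: list[str]
    ) -> "PresenceMatrix":
        count = np.zeros((len(genomes), len(ogs)), dtype=int)
        gi = {g: i for i, g in enumerate(genomes)}
        for j, og in enumerate(ogs):
            for g, c in og.copy_count.items():
                if g in gi:
                    count[gi[g], j] = c
        return cls(genomes=list(genomes), ogs=[og.og_id for og in ogs], count=count)


@dataclass(frozen=True)
class GroupSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group set {self.name!r} is empty")


@dataclass
class SetResult:
    group_set: GroupSet
    candidates: list[str]
    confirmed: list[str]
    breadth: dict[str, str] = field(default_factory=dict)


@dataclass
class SpecificGeneReport:
    """Scan outcome: per group-set candidates, confirmations, breadth."""

    results: dict[str, SetResult]

    def confirmed_by_set(self) -> dict[str, list[str]]:
        return {
            name: res.confirmed for name, res in self.results.items() if res.confirmed
        }

    def all_confirmed(self) -> set[str]:
        return {og for res in self.results.values() for og in res.confirmed}


def candidate_specific(
    pm: PresenceMatrix, gs: GroupSet, occupancy: float = 0.6
) -> list[str]:
    """OGs present in >= ceil(occupancy x group size) group members and in
    zero study genomes outside the group."""
    missing = gs.members - set(pm.genomes)
    if missing:
        raise ValueError(f"group members not in matrix: {sorted(missing)}")
    inside = np.array([g in gs.members for g in pm.genomes])
    need = math.ceil(occupancy * int(inside.sum()))
    present = pm.count > 0
    n_in = present[inside].sum(axis=0)
    n_out = present[~inside].sum(axis=0)
    keep = (n_in >= need) & (n_out == 0)
    return [og for og, k in zip(pm.ogs, keep) if k]


def _identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Global identity and length coverage of the shorter sequence."""
    ident = global_identity(a, b)
    cov = min(len(a), len(b)) / max(len(a), len(b))
    return ident, cov


def enrich_og(
    og: OrthologGroup,
    pool: dict[str, list[SequenceRecord]],
    min_identity: float = 0.4,
    min_cov: float = 0.5,
    study_proteomes: dict[str, list[SequenceRecord]] | None = None,
) -> OrthologGroup:
    """Add pool sequences orthologous to the group.

    A pool sequence joins the OG iff (i) its best hit among current members
    reaches ``min_identity`` over ``min_cov`` of the shorter sequence and
    (ii) when ``study_proteomes`` is given, its best hit across the whole
    study proteome set is itself an OG member (best-in-OG control, which
    stops paralogs from other families sneaking in). Existing members are
    never duplicated; added records keep their source genome key.
    """
    member_ids = {(g, r.id) for g, r in og.sequences()}
    member_seqs = [r.seq for _, r in og.sequences()]
    og_ids = {r.id for _, r in og.sequences()}

    study_index: list[tuple[str, SequenceRecord]] | None = None
    if study_proteomes is not None:
        study_index = [(g, r) for g, recs in study_proteomes.items() for r in recs]

    new_members: dict[str, list[SequenceRecord]] = {
        g: list(rs) for g, rs in og.members.items()
    }
    for genome in sorted(pool):
        for rec in pool[genome]:
            if (genome, rec.id) in member_ids:
                continue
            best = max(
                (_identity_coverage(rec.seq, ms) for ms in member_seqs),
                key=lambda t: t[0],
            )
            if best[0] < min_identity or best[1] < min_cov:
                continue
            if study_index is not None:
                top_id, top_rec = None, None
                for g2, r2 in study_index:
                    if g2 == genome and r2.id == rec.id:
                        continue
                    ident = global_identity(rec.seq, r2.seq)
                    if top_id is None or ident > top_id:
                        top_id, top_rec = ident, r2
                if top_rec is not None and top_rec.id not in og_ids:
                    continue
            new_members.setdefault(genome, []).append(rec)
    return OrthologGroup(og.og_id, new_members)


def confirm_specific(
    enriched: OrthologGroup, gs: GroupSet, all_study: set[str]
) -> bool:
    """True iff every group member carries the family and no study genome
    outside the group does; non-study genomes do not affect the verdict."""
    present = set(enriched.genomes)
    if not gs.members <= present:
        return False
    outsiders = (present & all_study) - gs.members
    return not outsiders


def classify_breadth(
    enriched: OrthologGroup,
    study: set[str],
    external_taxa: dict[str, str] | None = None,
) -> str:
    """Taxonomic breadth of a confirmed family: ``unique`` (no member
    outside the study genomes), ``shared_one_other`` (members from exactly
    one other genome) or ``shared_many``."""
    externals = {g for g in enriched.genomes if g not in study}
    if not externals:
        return "unique"
    if len(externals) == 1:
        return "shared_one_other"
    return "shared_many"


def _kmer_prefilter_pool(
    og: OrthologGroup, pool: dict[str, list[SequenceRecord]], k: int = 5
) -> dict[str, list[SequenceRecord]]:
    """Restrict the pool to sequences sharing >= 1 k-mer with the family."""
    fam_kmers: set[str] = set()
    for _g, r in og.sequences():
        s = r.seq
        for p in range(max(1, len(s) - k + 1)):
            fam_kmers.add(s[p : p + k])
    out: dict[str, list[SequenceRecord]] = {}
    for g, recs in pool.items():
        hits = []
        for r in recs:
            s = r.seq
            if any(s[p : p + k] in fam_kmers for p in range(0, max(1, len(s) - k + 1), k)):
                hits.append(r)
        if hits:
            out[g] = hits
    return out


def _outside_homolog(
    og: OrthologGroup,
    gs: GroupSet,
    study_proteomes: dict[str, list[SequenceRecord]],
    min_identity: float,
    min_cov: float,
) -> bool:
    """Cross-group homology control: does any annotated study sequence from
    a genome outside the group match the family at the enrichment gate?
    Such a hit shows the family is not truly exclusive even if the outside
    copies clustered separately (e.g. a fast-evolving family that fragmented
    into per-group clusters)."""
    outside = {g: recs for g, recs in study_proteomes.items() if g not in gs.members}
    hits = _kmer_prefilter_pool(og, outside, k=4)
    member_seqs = [r.seq for _, r in og.sequences()]
    for _genome, recs in hits.items():
        for rec in recs:
            for ms in member_seqs:
                ident, cov = _identity_coverage(rec.seq, ms)
                if ident >= min_identity and cov >= min_cov:
                    return True
    return False


def scan_groups(
    pm: PresenceMatrix,
    groups: list[GroupSet],
    tree: SupportedTree | None,
    pool: dict[str, list[SequenceRecord]],
    ogs: list[OrthologGroup] | None = None,
    occupancy: float = 0.6,
    min_identity: float = 0.4,
    min_cov: float = 0.5,
    study_proteomes: dict[str, list[SequenceRecord]] | None = None,
) -> SpecificGeneReport:
    """Run candidate -> enrich -> confirm over single groups, group pairs,
    the all-groups union, and every internal tree clade; each confirmed OG
    is reported only for the smallest set confirming it.

    ``ogs`` supplies member sequences for enrichment; without it (or
    without a pool) confirmation reduces to the presence-matrix criterion.
    """
    og_by_id = {og.og_id: og for og in ogs} if ogs else {}
    # exclusivity is judged against every study genome, outgroup included
    study = set(pm.genomes)
    ingroup = {g for gs in groups for g in gs.members}

    sets: list[GroupSet] = []
    seen: dict[frozenset[str], str] = {}

    def add_set(gs: GroupSet) -> None:
        if gs.members not in seen:
            seen[gs.members] = gs.name
            sets.append(gs)

    for gs in groups:
        add_set(gs)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            add_set(
                GroupSet(
                    "+".join(sorted([groups[i].name, groups[j].name])),
                    groups[i].members | groups[j].members,
                )
            )
    if len(groups) > 2:
        add_set(GroupSet("all_groups", frozenset(ingroup)))
    if tree is not None:
        dtree = tree.to_dendropy()
        for idx, node in enumerate(dtree.preorder_internal_node_iter()):
            leaves = frozenset(
                l.taxon.label for l in node.leaf_iter() if l.taxon.label in ingroup
            )
            if leaves and leaves != frozenset(ingroup):
                if leaves not in seen:
                    add_set(GroupSet(f"clade_{idx}", leaves))

    confirmed_sets: dict[str, list[tuple[GroupSet, OrthologGroup]]] = defaultdict(list)
    candidates_by_set: dict[str, list[str]] = {}
    for gs in sets:
        cands = candidate_specific(pm, gs, occupancy=occupancy)
        candidates_by_set[gs.name] = cands
        for og_id in cands:
            og = og_by_id.get(og_id)
            if og is None or not pool:
                enriched = og if og is not None else None
                ok = enriched is None or confirm_specific(enriched, gs, study)
                if ok:
                    confirmed_sets[og_id].append(
                        (gs, enriched if enriched is not None else None)
                    )
                continue
            sub_pool = _kmer_prefilter_pool(og, pool)
            enriched = enrich_og(
                og, sub_pool, min_identity=min_identity, min_cov=min_cov,
                study_proteomes=study_proteomes,
            )
            if not confirm_specific(enriched, gs, study):
                continue
            if study_proteomes is not None and _outside_homolog(
                og, gs, study_proteomes, min_identity, min_cov
            ):
                continue
            confirmed_sets[og_id].append((gs, enriched))

    results = {
        gs.name: SetResult(group_set=gs, candidates=candidates_by_set[gs.name],
                           confirmed=[])
        for gs in sets
    }
    for og_id, hits in confirmed_sets.items():
        gs, enriched = min(hits, key=lambda t: (len(t[0].members), t[0].name))
        results[gs.name].confirmed.append(og_id)
        if enriched is not None:
            results[gs.name].breadth[og_id] = classify_breadth(enriched, study)
    for res in results.values():
        res.confirmed.sort()
    return SpecificGeneReport(results=results)
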