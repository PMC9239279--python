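"""Orthologous-group construction and core-gene selection.

Proteins are clustered into orthologous groups (OGs) by single-linkage over
pairwise global identities, with a shared k-mer prefilter to keep the
candidate set near-linear. Core genes are then selected with the filters a
phylogenomic pipeline applies before concatenation: minimum occurrence,
occupancy across the taxon list, strict single-copy state, and two alignment
homogeneity indices — geometric (discordant gap placement) and functional
(cross-class residue substitutions) — both thresholded at 0.8 by default,
the regime in which an OG shows less than 20% discordant gap insertions and
less than 20% cross-class substitutions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from .io import MolType, SequenceRecord
from .msa import MultipleAlignment

__all__ = [
    "OrthologGroup",
    "HomogeneityScores",
    "global_identity",
    "cluster_ogs",
    "filter_min_occurrence",
    "geometric_homogeneity",
    "functional_homogeneity",
    "homogeneity_scores",
    "select_core",
    "select_unicopy_markers",
]


@dataclass
class OrthologGroup:
    """A set of putatively orthologous sequences keyed by genome."""

    og_id: str
    members: dict[str, list[SequenceRecord]]
    alignment: MultipleAlignment | None = None

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise ValueError(f"{self.og_id}: empty orthologous group")

    @property
    def copy_count(self) -> dict[str, int]:
        return {g: len(rs) for g, rs in self.members.items() if rs}

    @property
    def genomes(self) -> list[str]:
        return [g for g, rs in self.members.items() if rs]

    @property
    def n_sequences(self) -> int:
        return sum(len(rs) for rs in self.members.values())

    def sequences(self) -> list[tuple[str, SequenceRecord]]:
        return [(g, r) for g, rs in self.members.items() for r in rs]


@dataclass(frozen=True)
class HomogeneityScores:
    geometric: float
    functional: float


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) identity of two sequences as
    ``1 - edit_distance / max(len)``; 0 when either is empty."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_ogs(
    proteomes: dict[str, list[SequenceRecord]],
    min_identity: float = 0.6,
    kmer: int = 5,
) -> list[OrthologGroup]:
    """Single-linkage ortholog clustering over pairwise global identities.

    Two proteins land in one OG iff they are connected by a chain of
    pairwise identities >= ``min_identity``. Only pairs sharing at least one
    amino-acid k-mer are evaluated (the prefilter); every input protein is
    assigned to exactly one OG. OG ids are assigned in order of each
    cluster's first (genome, sequence) appearance, so the output is
    deterministic under input reordering of equal content.
    """
    if not proteomes or not any(proteomes.values()):
        raise ValueError("empty proteome set")
    entries: list[tuple[str, SequenceRecord]] = [
        (g, r) for g in sorted(proteomes) for r in proteomes[g]
    ]
    n = len(entries)
    kmer_index: dict[str, list[int]] = defaultdict(list)
    for i, (_g, rec) in enumerate(entries):
        seen: set[str] = set()
        s = rec.seq
        for p in range(max(1, len(s) - kmer + 1)):
            seen.add(s[p : p + kmer])
        for km in seen:
            kmer_index[km].append(i)

    uf = _UnionFind(n)
    checked: set[tuple[int, int]] = set()
    for ids in kmer_index.values():
        if len(ids) < 2:
            continue
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                if uf.find(i) == uf.find(j):
                    continue
                key = (i, j)
                if key in checked:
                    continue
                checked.add(key)
                if global_identity(entries[i][1].seq, entries[j][1].seq) >= min_identity:
                    uf.union(i, j)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[uf.find(i)].append(i)
    ogs: list[OrthologGroup] = []
    for k, root in enumerate(sorted(clusters, key=lambda r: min(clusters[r]))):
        members: dict[str, list[SequenceRecord]] = defaultdict(list)
        for i in sorted(clusters[root]):
            g, rec = entries[i]
            members[g].append(rec)
        ogs.append(OrthologGroup(f"OG{k + 1:05d}", dict(members)))
    return ogs


def filter_min_occurrence(
    ogs: list[OrthologGroup], min_occ: int = 2
) -> list[OrthologGroup]:
    """Keep OGs present in at least ``min_occ`` genomes (order preserved)."""
    return [og for og in ogs if len(og.genomes) >= min_occ]


def _alignment_arrays(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    arr = aln.as_array()
    gap = (arr == ord("-")) | (arr == ord("?"))
    return arr, gap


def geometric_homogeneity(aln: MultipleAlignment) -> float:
    """1 minus the fraction of (column, pair) incidences with a discordant
    gap — exactly one sequence of the pair gapped — over all columns and
    all sequence pairs. Concordant gaps do not count."""
    arr, gap = _alignment_arrays(aln)
    n_rows, n_cols = arr.shape
    if n_cols == 0:
        return 1.0
    k = gap.sum(axis=0)  # gaps per column
    discordant = (k * (n_rows - k)).sum()
    n_pairs = n_rows * (n_rows - 1) // 2
    return 1.0 - float(discordant) / (n_cols * n_pairs)


_RESIDUE_CLASSES = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "G", "P")
_CLASS_OF = np.full(128, -1, dtype=np.int8)
for _ci, _cls in enumerate(_RESIDUE_CLASSES):
    for _ch in _cls:
        _CLASS_OF[ord(_ch)] = _ci
# residues outside the seven classes each form their own singleton class
for _extra, _ch in enumerate("BZJUOX*"):
    _CLASS_OF[ord(_ch)] = len(_RESIDUE_CLASSES) + _extra


def functional_homogeneity(aln: MultipleAlignment) -> float:
    """Fraction of (column, pair) incidences, both residues non-gap, whose
    residues share a biochemical class: aliphatic/sulfur {AVLIMC}, aromatic
    {FWYH}, polar {STNQ}, basic {KR}, acidic {DE}, and the conformationally
    special singletons {G} and {P}."""
    if aln.moltype is not MolType.PROTEIN:
        raise ValueError("functional homogeneity is defined on protein alignments")
    arr, gap = _alignment_arrays(aln)
    n_rows, n_cols = arr.shape
    if n_cols == 0:
        return 1.0
    classes = _CLASS_OF[arr]
    classes[gap] = -1
    n_classes = int(classes.max()) + 1
    same = 0
    total = 0
    for c in range(n_cols):
        col = classes[:, c]
        col = col[col >= 0]
        m = col.size
        if m < 2:
            continue
        counts = np.bincount(col, minlength=n_classes)
        same += int((counts * (counts - 1)).sum()) // 2
        total += m * (m - 1) // 2
    return 1.0 if total == 0 else same / total


def homogeneity_scores(aln: MultipleAlignment) -> HomogeneityScores:
    return HomogeneityScores(
        geometric=geometric_homogeneity(aln),
        functional=functional_homogeneity(aln),
    )


def select_core(
    ogs: list[OrthologGroup],
    taxa: list[str],
    occupancy: float = 1.0,
    max_copy: int = 1,
    min_geometric: float = 0.8,
    min_functional: float = 0.8,
) -> list[OrthologGroup]:
    """Core-gene filter: occupancy across ``taxa``, copy-number ceiling, and
    both homogeneity indices at or above their thresholds.

    OGs must carry an alignment when the homogeneity filters are active.
    """
    need = occupancy * len(taxa)
    out: list[OrthologGroup] = []
    for og in ogs:
        present = [t for t in taxa if og.copy_count.get(t, 0) > 0]
        if len(present) < need:
            continue
        if any(c > max_copy for c in og.copy_count.values()):
            continue
        if min_geometric > 0 or min_functional > 0:
            if og.alignment is None:
                raise ValueError(
                    f"{og.og_id}: homogeneity filtering requires an alignment"
                )
            scores = homogeneity_scores(og.alignment)
            if scores.geometric < min_geometric or scores.functional < min_functional:
                continue
        out.append(og)
    return out


def select_unicopy_markers(
    marker_hits: dict[str, dict[str, int]], occupancy: float = 0.5
) -> list[str]:
    """Markers with exactly one copy in every genome where present, present
    in at least ``occupancy`` of genomes. ``marker_hits`` maps
    genome -> marker -> copy count."""
    genomes = list(marker_hits)
    markers = sorted({m for hits in marker_hits.values() for m in hits})
    out = []
    for m in markers:
        counts = [hits[m] for hits in marker_hits.values() if hits.get(m, 0) > 0]
        if counts and all(c == 1 for c in counts) and len(counts) >= occupancy * len(genomes):
            out.append(m)
    return out
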