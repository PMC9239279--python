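"""Distance-based tree inference with resampling support values.

Trees are inferred by neighbor joining on simple corrected distances
(Poisson for protein, Kimura two-parameter for DNA). Branch support comes
from two resampling schemes: the site bootstrap (columns resampled with
replacement, bipartition frequencies mapped onto the full-data tree) and the
gene jackknife (per replicate, whole genes are drawn without replacement
until a target concatenated length is reached; the replicate trees are
summarized by an extended majority-rule consensus). Rooting, monophyly and
Robinson-Foulds comparisons operate on the same bipartition encoding: each
internal edge is the frozenset of leaf labels on the side that excludes the
lexicographically smallest taxon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .msa import MultipleAlignment, Supermatrix, concat_supermatrix

__all__ = [
    "DistanceMatrix",
    "SupportedTree",
    "poisson_distance",
    "k2p_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "gene_jackknife",
    "majority_consensus",
    "root_with_outgroup",
    "is_monophyletic",
    "rf_distance",
    "resolution_distance",
    "splits_compatible",
    "bipartitions",
]

_MISSING = frozenset(b"-?X")
_MAX_P = 0.95


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


@dataclass
class SupportedTree:
    """A Newick topology with optional per-bipartition support percentages.

    Supports are keyed by the frozenset of leaf labels on the side of the
    bipartition that excludes the lexicographically smallest taxon.
    """

    newick: str
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    rooted: bool = False

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted" if self.rooted else "force-unrooted",
        )

    @property
    def taxa(self) -> frozenset[str]:
        t = self.to_dendropy()
        return frozenset(l.taxon.label for l in t.leaf_node_iter())

    def with_support_labels(self) -> str:
        """Newick with integer support percentages as internal node labels."""
        tree = self.to_dendropy()
        all_taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        ref = all_taxa[0]
        for node in tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if ref in leaves:
                leaves = frozenset(all_taxa) - leaves
            if leaves in self.supports:
                node.label = str(int(round(self.supports[leaves])))
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# distances


def _shared_mask(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError("rows of unequal length")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    bad = np.frombuffer(b"-?X", dtype=np.uint8)
    valid = ~np.isin(aa, bad) & ~np.isin(bb, bad)
    return aa, bb, valid


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance -ln(1 - p) over shared informative sites;
    p is clamped at 0.95 to keep saturated pairs finite."""
    aa, bb, valid = _shared_mask(a, b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no shared non-gap sites between rows")
    p = float(((aa != bb) & valid).sum()) / n
    p = min(p, _MAX_P)
    return -math.log(1.0 - p)


_PURINES = frozenset(b"AG")


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance from transition (P) and transversion
    (Q) fractions: -0.5 ln((1-2P-Q) sqrt(1-2Q)); non-positive log arguments
    are clamped with a warning."""
    aa, bb, valid = _shared_mask(a, b)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no shared non-gap sites between rows")
    diff = (aa != bb) & valid
    pur_a = np.isin(aa, np.frombuffer(b"AG", dtype=np.uint8))
    pur_b = np.isin(bb, np.frombuffer(b"AG", dtype=np.uint8))
    transitions = diff & (pur_a == pur_b)
    P = float(transitions.sum()) / n
    Q = float(diff.sum() - transitions.sum()) / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        warnings.warn("K2P distance saturated; clamping", stacklevel=2)
        arg1 = max(arg1, 1e-4)
        arg2 = max(arg2, 1e-4)
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def distance_matrix(sm: Supermatrix, dist: str = "poisson") -> DistanceMatrix:
    """Pairwise distances between supermatrix rows (taxa in sorted order).

    ``dist`` is ``poisson`` (protein) or ``k2p`` (DNA); both operate on
    shared non-gap, non-missing sites, vectorised over all pairs.
    """
    taxa = sorted(sm.taxa)
    n = len(taxa)
    L = sm.length
    arr = np.frombuffer("".join(sm.matrix[t] for t in taxa).encode(), dtype=np.uint8)
    arr = arr.reshape(n, L)
    bad = np.frombuffer(b"-?X", dtype=np.uint8)
    valid = ~np.isin(arr, bad)
    if dist == "k2p":
        purine = np.isin(arr, np.frombuffer(b"AG", dtype=np.uint8))
    d = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        shared = vi & valid[i + 1 :]
        nshared = shared.sum(axis=1)
        if np.any(nshared == 0):
            raise ValueError("a pair of rows shares no sites")
        diff = (arr[i] != arr[i + 1 :]) & shared
        if dist == "poisson":
            p = diff.sum(axis=1) / nshared
            p = np.minimum(p, _MAX_P)
            row = -np.log(1.0 - p)
        elif dist == "k2p":
            ti = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1) / nshared
            tv = diff.sum(axis=1) / nshared - ti
            arg1 = np.maximum(1.0 - 2.0 * ti - tv, 1e-4)
            arg2 = np.maximum(1.0 - 2.0 * tv, 1e-4)
            row = -0.5 * np.log(arg1 * np.sqrt(arg2))
        else:
            raise ValueError(f"unknown distance {dist!r}")
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> SupportedTree:
    """Saitou-Nei neighbor joining; ties in the Q criterion are broken by
    the lexicographically smallest (cluster, cluster) name pair, negative
    branch lengths are floored at zero. Returns an unrooted tree."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    # each active cluster: (sort key = smallest contained leaf, newick string)
    names = list(dm.taxa)
    keys = list(dm.taxa)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_newick = f"({names[ai]}:{li:.10g},{names[aj]}:{lj:.10g})"
        new_key = min(keys[ai], keys[aj])
        # distances from the new node
        dk = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = dk
        D[active, -1] = dk
        D[-1, -1] = 0.0
        names.append(new_newick)
        keys.append(new_key)
        active = [a for a in active if a not in (ai, aj)] + [len(names) - 1]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    order = sorted([(keys[a], a, la), (keys[b], b, lb), (keys[c], c, lc)])
    inner = ",".join(f"{names[i]}:{l:.10g}" for _, i, l in order)
    return SupportedTree(newick=f"({inner});", rooted=False)


# ---------------------------------------------------------------------------
# bipartitions and comparisons


def bipartitions(tree: SupportedTree | str) -> frozenset[frozenset[str]]:
    """Nontrivial bipartitions as canonical frozensets (the side excluding
    the lexicographically smallest taxon)."""
    t = tree if isinstance(tree, SupportedTree) else SupportedTree(tree)
    dtree = dendropy.Tree.get(
        data=t.newick, schema="newick", preserve_underscores=True
    )
    all_taxa = sorted(l.taxon.label for l in dtree.leaf_node_iter())
    ref = all_taxa[0]
    full = frozenset(all_taxa)
    out = set()
    for node in dtree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in leaves:
            leaves = full - leaves
        if 2 <= len(leaves) <= len(all_taxa) - 2:
            out.add(leaves)
    return frozenset(out)


def splits_compatible(b1: frozenset[str], b2: frozenset[str],
                      all_taxa: frozenset[str]) -> bool:
    """Whether two bipartitions (canonical sides) can coexist in one tree."""
    a, b = b1, all_taxa - b1
    c, d = b2, all_taxa - b2
    return not (a & c) or not (a & d) or not (b & c) or not (b & d)


def resolution_distance(reference: SupportedTree | str,
                        inferred: SupportedTree | str) -> int:
    """Topological disagreement tolerant of polytomy resolution.

    Counts reference bipartitions absent from the inferred tree plus
    inferred bipartitions incompatible with the reference tree. Equals the
    Robinson-Foulds distance when both trees are fully resolved; an inferred
    tree that merely resolves reference polytomies scores 0.
    """
    r = reference if isinstance(reference, SupportedTree) else SupportedTree(reference)
    i = inferred if isinstance(inferred, SupportedTree) else SupportedTree(inferred)
    if r.taxa != i.taxa:
        raise ValueError("trees are on different taxon sets")
    all_taxa = r.taxa
    ref_bps, inf_bps = bipartitions(r), bipartitions(i)
    missing = len(ref_bps - inf_bps)
    conflicting = sum(
        1
        for b in inf_bps - ref_bps
        if not all(splits_compatible(b, t, all_taxa) for t in ref_bps)
    )
    return missing + conflicting


def rf_distance(t1: SupportedTree | str, t2: SupportedTree | str) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    nontrivial bipartition sets."""
    n1 = t1 if isinstance(t1, SupportedTree) else SupportedTree(t1)
    n2 = t2 if isinstance(t2, SupportedTree) else SupportedTree(t2)
    if n1.taxa != n2.taxa:
        raise ValueError("trees are on different taxon sets")
    return len(bipartitions(n1) ^ bipartitions(n2))


def root_with_outgroup(t: SupportedTree, outgroup: str) -> SupportedTree:
    """Root on the outgroup's pendant edge (at its midpoint)."""
    tree = t.to_dendropy()
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    bl = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=bl / 2, length2=bl / 2)
    newick = tree.as_string(
        schema="newick", suppress_rooting=True
    ).strip()
    return SupportedTree(newick=newick, supports=dict(t.supports), rooted=True)


def is_monophyletic(t: SupportedTree, leaves: set[str]) -> bool:
    """True iff some clade of the rooted tree has exactly this leaf set."""
    if not t.rooted:
        raise ValueError("monophyly requires a rooted tree")
    query = frozenset(leaves)
    tree = t.to_dendropy()
    tree_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not query <= tree_taxa:
        raise ValueError("query leaves not all in tree")
    if len(query) == 1:
        return True
    for node in tree.preorder_node_iter():
        if frozenset(l.taxon.label for l in node.leaf_iter()) == query:
            return True
    return False


# ---------------------------------------------------------------------------
# support procedures


def _resample_supermatrix(sm: Supermatrix, rng: np.random.Generator) -> Supermatrix:
    taxa = list(sm.taxa)
    L = sm.length
    idx = rng.integers(0, L, size=L)
    arr = np.frombuffer("".join(sm.matrix[t] for t in taxa).encode(), dtype=np.uint8)
    arr = arr.reshape(len(taxa), L)[:, idx]
    matrix = {t: arr[i].tobytes().decode() for i, t in enumerate(taxa)}
    return Supermatrix(taxa=taxa, matrix=matrix, partitions=[("resampled", 0, L)])


def bootstrap_support(
    sm: Supermatrix,
    n_reps: int = 100,
    seed: int = 0,
    dist: str = "poisson",
) -> SupportedTree:
    """Site bootstrap: columns resampled with replacement to the original
    length; bipartition frequencies (percent) are mapped onto the full-data
    NJ tree."""
    if len(sm.taxa) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    full = nj_tree(distance_matrix(sm, dist))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(full)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = _resample_supermatrix(sm, rng)
        rep_bps = bipartitions(nj_tree(distance_matrix(rep, dist)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return SupportedTree(newick=full.newick, supports=supports, rooted=False)


def gene_jackknife(
    og_alns: list[tuple[str, MultipleAlignment]],
    taxa: list[str],
    target_length: int,
    n_reps: int = 100,
    seed: int = 0,
    dist: str = "poisson",
) -> SupportedTree:
    """Gene jackknife ("leave-one-out") support.

    Per replicate, genes are drawn uniformly without replacement from the
    canonically sorted gene list until the cumulative alignment length first
    reaches ``target_length``; a tree is inferred per replicate and the
    extended majority-rule consensus of all replicates is returned with
    bipartition percentages as supports.
    """
    if len(og_alns) < 2:
        raise ValueError("gene jackknife needs at least 2 genes")
    ordered = sorted(og_alns, key=lambda t: t[0])
    total = sum(a.length for _, a in ordered)
    if target_length > total:
        raise ValueError(
            f"target_length {target_length} exceeds total available {total}"
        )
    rng = np.random.default_rng(seed)
    trees: list[SupportedTree] = []
    for _ in range(n_reps):
        perm = rng.permutation(len(ordered))
        chosen: list[tuple[str, MultipleAlignment]] = []
        cum = 0
        for gi in perm:
            chosen.append(ordered[gi])
            cum += ordered[gi][1].length
            if cum >= target_length:
                break
        rep_sm = concat_supermatrix(chosen, taxa)
        trees.append(nj_tree(distance_matrix(rep_sm, dist)))
    return majority_consensus(trees, extended=True)


def majority_consensus(
    trees: list[SupportedTree], extended: bool = True
) -> SupportedTree:
    """Majority-rule consensus; in extended (greedy) mode, minority
    bipartitions compatible with the growing set are added in descending
    frequency order."""
    if not trees:
        raise ValueError("no trees to summarise")
    taxa_sets = {t.taxa for t in trees}
    if len(taxa_sets) != 1:
        raise ValueError("consensus requires identical taxon sets")
    all_taxa = sorted(next(iter(taxa_sets)))
    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    majority = [bp for bp, c in counts.items() if c / n > 0.5]
    rest = sorted(
        (bp for bp, c in counts.items() if c / n <= 0.5),
        key=lambda bp: (-counts[bp], sorted(bp)),
    )

    def compatible(bp: frozenset[str], accepted: list[frozenset[str]]) -> bool:
        return all(
            bp <= other or other <= bp or not (bp & other) for other in accepted
        )

    accepted = list(majority)
    if extended:
        for bp in rest:
            if compatible(bp, accepted):
                accepted.append(bp)
    supports = {bp: 100.0 * counts[bp] / n for bp in accepted}
    newick = _tree_from_clades(all_taxa, accepted)
    return SupportedTree(newick=newick, supports=supports, rooted=False)


def _tree_from_clades(all_taxa: list[str], clades: list[frozenset[str]]) -> str:
    """Assemble a Newick string from a laminar family of clades (each clade
    excludes the reference taxon ``all_taxa[0]``)."""
    # treat as rooted at the reference taxon: children nest inside parents
    ordered = sorted(clades, key=len)
    children: dict[frozenset[str] | None, list] = {None: []}
    parent_of: dict[frozenset[str], frozenset[str] | None] = {}
    by_size = sorted(clades, key=len, reverse=True)
    for c in by_size:
        parent = None
        best = None
        for cand in by_size:
            if cand is not c and c < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent_of[c] = best
    members: dict[frozenset[str] | None, list] = {c: [] for c in clades}
    members[None] = []
    for taxon in all_taxa:
        # smallest clade containing the taxon
        host = None
        for c in sorted(clades, key=len):
            if taxon in c:
                host = c
                break
        members[host].append(taxon)
    kids: dict[frozenset[str] | None, list[frozenset[str]]] = {c: [] for c in clades}
    kids[None] = []
    for c in clades:
        kids[parent_of[c]].append(c)

    def render(node: frozenset[str] | None) -> str:
        parts = [t for t in members[node]]
        parts += [render(k) for k in sorted(kids[node], key=lambda x: sorted(x))]
        parts.sort()
        return "(" + ",".join(parts) + ")"

    return render(None) + ";"
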