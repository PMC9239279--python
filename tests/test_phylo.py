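import itertools
import math

import numpy as np
import pytest

from snodkit.io import MolType
from snodkit.msa import MultipleAlignment, Supermatrix, concat_supermatrix
from snodkit.phylo import (
    DistanceMatrix,
    SupportedTree,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    gene_jackknife,
    is_monophyletic,
    k2p_distance,
    majority_consensus,
    nj_tree,
    poisson_distance,
    resolution_distance,
    rf_distance,
    root_with_outgroup,
)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        assert poisson_distance("MKVL", "MKVL") == 0.0
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_poisson_closed_form_at_ten_percent(self):
        a, b = "A" * 100, "A" * 90 + "C" * 10
        assert poisson_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_k2p_closed_form_pure_transitions(self):
        a, b = "A" * 100, "A" * 90 + "G" * 10  # A->G are transitions
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_gap_only_overlap_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance("MK--", "--VL")

    def test_saturated_k2p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            d = k2p_distance("A" * 50 + "C" * 50, "G" * 50 + "T" * 50)
        assert math.isfinite(d)


def additive_matrix_from_tree(newick: str, taxa: list[str]) -> DistanceMatrix:
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    n = len(taxa)
    d = np.zeros((n, n))
    tx = {x.label: x for x in t.taxon_namespace}
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tx[a], tx[taxa[j]])
    return DistanceMatrix(taxa, d)


def four_point_topology(dm: DistanceMatrix) -> set[frozenset]:
    """Oracle: the additive topology implied by the four-point condition.

    For every quartet the pairing with the smallest sum of distances is the
    quartet's split; a candidate topology (enumerated exhaustively) is
    consistent iff all its induced quartet splits agree.
    """
    taxa = dm.taxa
    idx = {t: i for i, t in enumerate(taxa)}

    def quartet_split(q):
        i, j, k, l = q
        sums = {
            frozenset([frozenset([i, j]), frozenset([k, l])]):
                dm.d[idx[i], idx[j]] + dm.d[idx[k], idx[l]],
            frozenset([frozenset([i, k]), frozenset([j, l])]):
                dm.d[idx[i], idx[k]] + dm.d[idx[j], idx[l]],
            frozenset([frozenset([i, l]), frozenset([j, k])]):
                dm.d[idx[i], idx[l]] + dm.d[idx[j], idx[k]],
        }
        return min(sums, key=sums.get)

    want = {frozenset(q): quartet_split(q)
            for q in itertools.combinations(taxa, 4)}

    best = None
    for topo in _enumerate_topologies(taxa):
        ok = True
        for q in itertools.combinations(taxa, 4):
            if _induced_split(topo, q) != want[frozenset(q)]:
                ok = False
                break
        if ok:
            best = topo
            break
    assert best is not None, "no additive-consistent topology found"
    return best


def _enumerate_topologies(taxa):
    """All unrooted binary topologies as sets of canonical bipartitions."""
    if len(taxa) == 3:
        yield frozenset()
        return
    first3, rest = list(taxa[:3]), taxa[3:]
    # edges represented by growing newick-like nested tuples
    def grow(tree, remaining):
        if not remaining:
            yield tree
            return
        leaf = remaining[0]
        for edited in _attach_everywhere(tree, leaf):
            yield from grow(edited, remaining[1:])

    base = (first3[0], first3[1], first3[2])
    for t in grow(base, rest):
        yield _splits_of(t, set(taxa))


def _attach_everywhere(tree, leaf):
    # attach at every edge: every element of every internal tuple
    def rec(node):
        # yields versions of `node` with leaf attached inside
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                for newchild in rec(child):
                    yield node[:i] + (newchild,) + node[i + 1 :]
        yield (node, leaf)

    if isinstance(tree, tuple):
        for i, child in enumerate(tree):
            for newchild in rec(child):
                yield tree[:i] + (newchild,) + tree[i + 1 :]


def _leaves_of(node):
    if isinstance(node, tuple):
        out = set()
        for c in node:
            out |= _leaves_of(c)
        return out
    return {node}


def _splits_of(tree, all_taxa):
    ref = min(all_taxa)
    splits = set()

    def rec(node):
        if not isinstance(node, tuple):
            return
        leaves = _leaves_of(node)
        side = frozenset(leaves if ref not in leaves else all_taxa - leaves)
        if 2 <= len(side) <= len(all_taxa) - 2:
            splits.add(side)
        for c in node:
            rec(c)

    rec(tree)
    return frozenset(splits)


def _induced_split(splits, quartet):
    qs = set(quartet)
    for side in splits:
        a = side & qs
        if len(a) == 2:
            return frozenset([frozenset(a), frozenset(qs - a)])
    # unresolved for this quartet under the enumerated splits: treat the
    # first pairing as undetermined (cannot happen for binary topologies)
    i, j, k, l = quartet
    return None


class TestNeighborJoining:
    def test_additive_four_taxon_hand_example(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        t = nj_tree(DistanceMatrix(taxa, d))
        assert bipartitions(t) == {frozenset({"C", "D"})}
        # branch lengths: pendant 1 each, internal 4
        assert ":1" in t.newick and ":4" in t.newick

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        assert bipartitions(t) == frozenset()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_taxon_order_invariance(self):
        newick = "((a:1,b:2):1,(c:1,d:3):2,(e:2,f:1):1);"
        taxa = ["a", "b", "c", "d", "e", "f"]
        t1 = nj_tree(additive_matrix_from_tree(newick, taxa))
        t2 = nj_tree(additive_matrix_from_tree(newick, taxa[::-1]))
        assert rf_distance(t1, t2) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_additive_topology_vs_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        taxa = ["a", "b", "c", "d", "e", "f"][: 5 + seed % 2]
        # random binary tree via random ordered pairs
        newick = _random_binary_newick(taxa, rng)
        dm = additive_matrix_from_tree(newick, taxa)
        oracle_splits = four_point_topology(dm)
        t = nj_tree(dm)
        assert bipartitions(t) == oracle_splits


def _random_binary_newick(taxa, rng):
    nodes = [f"{t}:{rng.uniform(0.5, 2):.3f}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.5, 2):.3f}")
    return "(" + ",".join(nodes) + ");"


class TestConsensus:
    def test_unanimous_trees(self):
        trees = [SupportedTree("((a,b),(c,d),e);")] * 10
        cons = majority_consensus(trees)
        assert rf_distance(cons, trees[0]) == 0
        assert all(v == 100.0 for v in cons.supports.values())

    def test_sixty_forty_majority(self):
        t1 = SupportedTree("((a,b),(c,d),e);")
        t2 = SupportedTree("((a,c),(b,d),e);")
        cons = majority_consensus([t1] * 6 + [t2] * 4)
        assert frozenset({"c", "d"}) in cons.supports
        assert cons.supports[frozenset({"c", "d"})] == pytest.approx(60.0)

    def test_greedy_mode_admits_plurality_resolution(self):
        t1 = SupportedTree("((((a,b),c),d),e);")
        t2 = SupportedTree("((((a,c),b),d),e);")
        t3 = SupportedTree("((((b,c),a),d),e);")
        cons = majority_consensus([t1] * 40 + [t2] * 35 + [t3] * 25, extended=True)
        # {a,b} (canonical side {c,d,e}... {a,b} excludes min taxon? min is a.
        # canonical side of the ab|cde split is the side without 'a': {c,d,e}
        assert frozenset({"c", "d", "e"}) in cons.supports
        assert cons.supports[frozenset({"c", "d", "e"})] == pytest.approx(40.0)
        assert frozenset({"b", "d", "e"}) not in cons.supports  # the 35% rival

    def test_mismatched_taxa_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(
                [SupportedTree("((a,b),c,d);"), SupportedTree("((a,b),c,e);")]
            )


class TestRootingMonophyly:
    TREE = SupportedTree("((a:1,b:1):1,(c:1,d:1):1,o:5);")

    def test_root_on_outgroup_and_monophyly(self):
        rooted = root_with_outgroup(self.TREE, "o")
        assert rooted.rooted
        assert is_monophyletic(rooted, {"a", "b"})
        assert is_monophyletic(rooted, {"a", "b", "c", "d"})
        assert not is_monophyletic(rooted, {"a", "c"})

    def test_single_leaf_and_full_set_trivially_monophyletic(self):
        rooted = root_with_outgroup(self.TREE, "o")
        assert is_monophyletic(rooted, {"a"})
        assert is_monophyletic(rooted, {"a", "b", "c", "d", "o"})

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError):
            root_with_outgroup(self.TREE, "zzz")

    def test_unrooted_monophyly_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(self.TREE, {"a", "b"})

    def test_rooting_preserves_unrooted_ingroup_topology(self):
        rooted = root_with_outgroup(self.TREE, "o")
        import dendropy

        t = rooted.to_dendropy()
        t.prune_taxa_with_labels(["o"])
        pruned = SupportedTree(
            t.as_string(schema="newick", suppress_rooting=True).strip()
        )
        ingroup = SupportedTree("((a:1,b:1):1,c:1,d:1);")
        assert rf_distance(pruned, ingroup) == 0


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = SupportedTree("((a,b),(c,d),e);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = SupportedTree("((a,b),c,d);")
        t2 = SupportedTree("((a,c),b,d);")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_resolution_distance_tolerates_polytomy_refinement(self):
        star = SupportedTree("((a,b,c),(d,e),f);")
        resolved = SupportedTree("(((a,b),c),(d,e),f);")
        conflicting = SupportedTree("((a,d),(b,c),(e,f));")
        assert resolution_distance(star, resolved) == 0
        assert resolution_distance(star, conflicting) > 0


def _signal_supermatrix(strength: int = 30) -> Supermatrix:
    """Four taxa with clean ab|cd signal."""
    rows = {
        "a": "A" * strength + "C" * strength,
        "b": "A" * strength + "C" * strength,
        "c": "C" * strength + "A" * strength,
        "d": "C" * strength + "A" * strength,
    }
    # add unique noise so pairwise distances are nonzero
    rows = {k: v + base for k, (v, base) in zip(rows, [
        (rows["a"], "GGGG"), (rows["b"], "GGGT"), (rows["c"], "GGTT"),
        (rows["d"], "GTTT")])}
    aln = MultipleAlignment(rows, MolType.DNA)
    return concat_supermatrix([("g", aln)], list(rows))


class TestResampling:
    def test_bootstrap_single_replicate_supports_are_binary(self):
        t = bootstrap_support(_signal_supermatrix(), n_reps=1, seed=0, dist="k2p")
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_bootstrap_deterministic_given_seed(self):
        t1 = bootstrap_support(_signal_supermatrix(), n_reps=20, seed=3, dist="k2p")
        t2 = bootstrap_support(_signal_supermatrix(), n_reps=20, seed=3, dist="k2p")
        assert t1.supports == t2.supports

    def test_unanimous_signal_gets_full_support(self):
        t = bootstrap_support(_signal_supermatrix(), n_reps=50, seed=1, dist="k2p")
        assert t.supports[frozenset({"c", "d"})] == 100.0

    def _conflicting_genes(self):
        rows_ab = {
            "a": "A" * 40 + "GGGG", "b": "A" * 40 + "GGGT",
            "c": "C" * 40 + "GGTT", "d": "C" * 40 + "GTTT",
        }
        rows_ac = {
            "a": "A" * 40 + "GGGG", "c": "A" * 40 + "GGGT",
            "b": "C" * 40 + "GGTT", "d": "C" * 40 + "GTTT",
        }
        return [
            ("gene_ab", MultipleAlignment(rows_ab, MolType.DNA)),
            ("gene_ac", MultipleAlignment(rows_ac, MolType.DNA)),
        ]

    def test_jackknife_full_target_equals_full_data_tree(self):
        genes = self._conflicting_genes()[:1] * 2
        genes = [("g1", genes[0][1]), ("g2", genes[1][1])]
        taxa = ["a", "b", "c", "d"]
        full = nj_tree(distance_matrix(concat_supermatrix(genes, taxa), "k2p"))
        jack = gene_jackknife(genes, taxa, target_length=88, n_reps=10, seed=0,
                              dist="k2p")
        assert rf_distance(jack, full) == 0
        assert all(v == 100.0 for v in jack.supports.values())

    def test_jackknife_conflicting_genes_split_support(self):
        genes = self._conflicting_genes()
        taxa = ["a", "b", "c", "d"]
        # target below one gene length forces single-gene replicates
        jack = gene_jackknife(genes, taxa, target_length=10, n_reps=100, seed=2,
                              dist="k2p")
        ab = jack.supports.get(frozenset({"c", "d"}), 0.0)
        assert 30.0 <= ab <= 70.0  # binomial around the 50% sampling ratio

    def test_jackknife_target_exceeding_total_rejected(self):
        genes = self._conflicting_genes()
        with pytest.raises(ValueError):
            gene_jackknife(genes, ["a", "b", "c", "d"], target_length=10_000)
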