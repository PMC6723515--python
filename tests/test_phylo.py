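"""Distances, neighbor joining, Fitch mapping, TSP assessment, Dxy, NW."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from stopswitch.phylo import (
    DistanceMatrix,
    MappingError,
    assess_tsp,
    distance_matrix,
    dxy,
    fitch_map,
    jc_distance,
    mean_within,
    nj_tree,
    nw_align,
    p_distance,
    root_on_outgroup,
    split_polymorphic_tips,
)
from stopswitch.scan import CharacterStateMap

S, L, SL = frozenset("S"), frozenset("L"), frozenset("SL")


# ---------------------------------------------------------------------------
# oracles


def random_tree(n, rng) -> dendropy.Tree:
    labels = [f"T{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    import random as _random

    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = 0.1
    return tree


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], d)


def unrooted_topology_equal(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


def brute_force_fitch(tree: dendropy.Tree, states: CharacterStateMap) -> int:
    """Exhaustive minimum over all internal assignments; leaves resolve
    freely within their state sets (ambiguity semantics)."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for combo in itertools.product("SL", repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            if node.is_leaf():
                cost += 0 if assign[parent] in states[node.taxon.label] else 1
            else:
                cost += assign[parent] != assign[node]
        best = min(best, cost)
    return best


def brute_force_tsp(tree: dendropy.Tree, states: CharacterStateMap):
    """Exhaustive allele-presence parsimony oracle over {S},{L},{S,L}
    internal assignments with a virtual root edge from {S}.

    Returns (min_cost, min_gains_at_min_cost, single_ancestral_origin_possible).
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    l_leaves = [n for n in leaves if "L" in states[n.taxon.label]]
    best_cost, best_gains, single_ok = math.inf, math.inf, False
    for combo in itertools.product((S, L, SL), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for leaf in leaves:
            assign[leaf] = frozenset(states[leaf.taxon.label])
        cost, gains = 0, 0
        gain_edges = []
        for node in tree.preorder_node_iter():
            parent_state = S if node.parent_node is None else assign[node.parent_node]
            st = assign[node]
            cost += len(parent_state ^ st)
            if "L" in st and "L" not in parent_state:
                gains += 1
                gain_edges.append(node)
        if cost < best_cost:
            best_cost, best_gains, single_ok = cost, gains, False
        if cost == best_cost:
            best_gains = min(best_gains, gains)
            if gains == 1:
                head = gain_edges[0]
                below = set(head.preorder_iter())
                if all(leaf in below for leaf in l_leaves):
                    single_ok = True
    return best_cost, best_gains, single_ok


def random_states(tree, rng) -> CharacterStateMap:
    choices = [S, L, SL]
    return CharacterStateMap(
        {l.taxon.label: choices[int(rng.integers(3))] for l in tree.leaf_node_iter()}
    )


# ---------------------------------------------------------------------------
# distances


class TestDistances:
    def test_p_distance_quarter(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_identical_zero_under_both_models(self):
        assert p_distance("ACGT", "ACGT") == 0
        assert jc_distance(0.0) == 0

    def test_jc_closed_form(self):
        assert jc_distance(0.25) == pytest.approx(-0.75 * math.log(1 - 1 / 3), rel=1e-12)
        assert jc_distance(0.25) == pytest.approx(0.30409883, abs=1e-7)

    def test_gap_and_n_sites_excluded_pairwise(self):
        assert p_distance("AC-TN", "ACGTA") == 0.0
        assert p_distance("ACNT", "AGNT") == pytest.approx(1 / 3)

    def test_saturation_flagged(self):
        dm = distance_matrix({"a": "AAAA", "b": "CCCC"}, model="jc")
        assert dm.saturated_pairs == [("a", "b")]

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestNeighborJoining:
    def test_recovers_fixed_additive_topology(self):
        gen = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:1):1);", schema="newick")
        dm = path_distance_matrix(gen)
        assert unrooted_topology_equal(nj_tree(dm), gen)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_recovers_random_additive_topologies(self, rng):
        for _ in range(40):
            gen = random_tree(int(rng.integers(5, 9)), rng)
            assert unrooted_topology_equal(nj_tree(path_distance_matrix(gen)), gen)

    def test_agrees_with_dendropy_nj_on_random_matrix(self, rng):
        # independent implementation cross-check
        gen = random_tree(7, rng)
        dm = path_distance_matrix(gen)
        csv = "," + ",".join(dm.taxa) + "\n"
        for t, row in zip(dm.taxa, dm.d):
            csv += t + "," + ",".join(str(x) for x in row) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(_io.StringIO(csv))
        ref = pdm.nj_tree()
        assert unrooted_topology_equal(nj_tree(dm), ref)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


# ---------------------------------------------------------------------------
# character mapping


def tree_of(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestFitch:
    def test_mixed_tip_sets_cost_one(self):
        tree = tree_of("((A,B),(C,D));")
        states = CharacterStateMap({"A": S, "B": L, "C": SL, "D": SL})
        assert fitch_map(tree, states).min_changes == 1

    def test_uniform_states_cost_zero(self):
        tree = tree_of("((A,B),(C,D));")
        states = CharacterStateMap({t: S for t in "ABCD"})
        assert fitch_map(tree, states).min_changes == 0

    def test_alternating_caterpillar_cost_two(self):
        tree = tree_of("(((A,B),C),D);")
        states = CharacterStateMap({"A": S, "B": L, "C": S, "D": L})
        assert fitch_map(tree, states).min_changes == 2

    def test_missing_leaf_state_raises(self):
        tree = tree_of("((A,B),C);")
        with pytest.raises(MappingError):
            fitch_map(tree, CharacterStateMap({"A": S, "B": L}))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            tree = random_tree(int(rng.integers(4, 9)), rng)
            states = random_states(tree, rng)
            assert fitch_map(tree, states).min_changes == brute_force_fitch(tree, states)

    def test_split_tip_encoding_costs_fitch_plus_polymorphic(self, rng):
        for _ in range(20):
            tree = random_tree(int(rng.integers(4, 8)), rng)
            states = random_states(tree, rng)
            split_tree, split_states = split_polymorphic_tips(tree, states)
            n_poly = sum(1 for st in states.states.values() if st == SL)
            assert (
                fitch_map(split_tree, split_states).min_changes
                == fitch_map(tree, states).min_changes + n_poly
            )


class TestAssessTsp:
    def test_sister_polymorphic_taxa_consistent(self):
        tree = tree_of("((A,B),(C,D));")
        states = CharacterStateMap({"A": SL, "B": SL, "C": S, "D": S})
        rep = assess_tsp(tree, states)
        assert rep.tsp_consistent
        assert rep.min_origins_of_L == 1

    def test_separated_polymorphic_taxa_convergent(self):
        tree = tree_of("((((A,B),C),D),E);")
        states = CharacterStateMap({"A": SL, "B": S, "C": S, "D": S, "E": SL})
        rep = assess_tsp(tree, states)
        assert not rep.tsp_consistent
        assert rep.min_origins_of_L == 2

    def test_single_polymorphic_taxon_never_consistent(self):
        tree = tree_of("((A,B),(C,D));")
        states = CharacterStateMap({"A": SL, "B": S, "C": S, "D": S})
        rep = assess_tsp(tree, states)
        assert not rep.tsp_consistent

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(40):
            tree = random_tree(int(rng.integers(4, 7)), rng)
            states = random_states(tree, rng)
            cost, gains, single_ok = brute_force_tsp(tree, states)
            rep = assess_tsp(tree, states)
            n_poly = sum(1 for st in states.states.values() if st == SL)
            assert rep.tsp_consistent == (single_ok and n_poly >= 2)
            if not single_ok:
                assert rep.min_origins_of_L == gains


class TestRooting:
    def test_outgroup_rooting(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,OUT:4):1);", schema="newick")
        rooted = root_on_outgroup(tree, "OUT")
        kids = rooted.seed_node.child_nodes()
        sides = [{l.taxon.label for l in k.leaf_iter()} for k in kids]
        assert {"OUT"} in sides

    def test_unknown_outgroup_raises(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(MappingError):
            root_on_outgroup(tree, "ZZZ")


# ---------------------------------------------------------------------------
# Dxy


class TestDxy:
    def test_identical_singletons(self):
        assert dxy(["AAAA"], ["AAAA"]) == (0.0, 0.0)

    def test_half_divergent_singletons(self):
        est, sd = dxy(["AAAA"], ["AATT"])
        assert est == 0.5
        assert sd == pytest.approx(math.sqrt(0.25 / 4))

    def test_symmetry(self):
        a, b = ["ACGTACGT", "ACGTACGA"], ["TCGTACGT"]
        assert dxy(a, b)[0] == dxy(b, a)[0]

    def test_self_comparison_equals_within_set_mean(self):
        seqs = ["ACGTACGT", "ACGAACGT", "TCGTACGT"]
        est, _ = dxy(seqs, seqs)
        assert est == pytest.approx(mean_within(seqs))

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            dxy([], ["AAAA"])

    def test_recovers_planted_divergence(self, rng):
        # two 2-sequence sets at planted divergence 0.01 over 5 kb,
        # repeated; the mean estimate must sit within 3 SD of truth
        n_sites, d_true, reps = 5000, 0.01, 200
        ests = []
        for _ in range(reps):
            anc = rng.integers(0, 4, size=n_sites)
            sets = []
            for _ in range(2):
                grp = []
                for _ in range(2):
                    seq = anc.copy()
                    flips = rng.random(n_sites) < d_true / 2
                    seq[flips] = (seq[flips] + rng.integers(1, 4, size=int(flips.sum()))) % 4
                    grp.append("".join("ACGT"[x] for x in seq))
                sets.append(grp)
            ests.append(dxy(sets[0], sets[1])[0])
        se = np.std(ests, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(ests) - d_true) < 3 * se + 5e-5


# ---------------------------------------------------------------------------
# alignment


class TestNwAlign:
    def test_identical(self):
        a, b, score = nw_align("ACGT", "ACGT", 1, -1, -2)
        assert (a, b, score) == ("ACGT", "ACGT", 4.0)

    def test_single_gap(self):
        a, b, score = nw_align("ACGT", "AGT", 1, -1, -2)
        assert score == 1.0  # 3 matches - one gap of 2
        assert a == "ACGT" and b.replace("-", "") == "AGT" and len(b) == 4

    def test_score_matches_brute_force_on_short_pairs(self, rng):
        def brute(a, b, match, mismatch, gap):
            best = -math.inf
            # enumerate all monotone alignments via pair recursion
            def rec(i, j, acc):
                nonlocal best
                if i == len(a) and j == len(b):
                    best = max(best, acc)
                    return
                if i < len(a) and j < len(b):
                    rec(i + 1, j + 1, acc + (match if a[i] == b[j] else mismatch))
                if i < len(a):
                    rec(i + 1, j, acc + gap)
                if j < len(b):
                    rec(i, j + 1, acc + gap)

            rec(0, 0, 0.0)
            return best

        bases = list("ACGT")
        for _ in range(30):
            a = "".join(rng.choice(bases, size=rng.integers(1, 6)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 6)))
            assert nw_align(a, b)[2] == brute(a, b, 1, -1, -2)

    def test_score_symmetry(self, rng):
        bases = list("ACGT")
        for _ in range(50):
            a = "".join(rng.choice(bases, size=rng.integers(1, 15)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 15)))
            assert nw_align(a, b)[2] == nw_align(b, a)[2]
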