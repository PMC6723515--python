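"""Distance-based trees, S/L character mapping, and the trans-species
polymorphism (TSP) assessment.

A trans-species polymorphism is a polymorphism whose allelic lineages
predate speciation: the same two alleles segregate in several descendant
species because they were inherited from a polymorphic ancestor (typically
maintained by balancing selection), not because the derived allele arose
independently in each species.  Given a species tree and per-taxon
character states over the alleles {S, L} (a taxon may be polymorphic,
{S, L}), this module asks whether a single ancestral origin of L can
explain the data as parsimoniously as independent origins can.

Two parsimony layers are used:

* :func:`fitch_map` — the classical Fitch intersection/union pass, with
  set-valued tips treated as ambiguity, giving the minimum number of
  character changes (``min_changes``).
* :func:`assess_tsp` — an allele-presence parsimony over node states
  {S}, {L}, {S, L} in which every allele gain or allele loss along an edge
  costs one event.  Under this model a polymorphic ancestor transmits both
  alleles at no cost, so ancestral persistence and convergent origins make
  distinct, comparable predictions: the scenario is TSP-consistent when at
  least two taxa are polymorphic and some minimum-cost reconstruction
  derives every L allele from one gain on an edge ancestral to all
  L-bearing taxa.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .scan import CharacterStateMap

logger = logging.getLogger(__name__)

#: documented stand-in for an inestimable (saturated) Jukes-Cantor distance
SATURATED_DISTANCE = 10.0

S = frozenset("S")
L = frozenset("L")
SL = frozenset("SL")
_LATTICE = (S, L, SL)


class MappingError(ValueError):
    """A leaf lacks a character state, or states do not match the tree."""


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal pairwise distance matrix over named taxa."""

    taxa: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")

    def to_phylip(self) -> str:
        lines = [f"{len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name.replace(" ", "_") + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def _compared_sites(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared) with gap/N sites excluded pairwise."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    mismatch = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    return mismatch, compared


def p_distance(a: str, b: str) -> float:
    mism, comp = _compared_sites(a, b)
    if comp == 0:
        raise ValueError("no comparable sites after gap/N exclusion")
    return mism / comp


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction -(3/4)ln(1 - 4p/3); saturated at p >= 0.75."""
    if p >= 0.75:
        return SATURATED_DISTANCE
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_distance(a: str, b: str, model: str = "p") -> float:
    p = p_distance(a, b)
    if model == "p":
        return p
    if model == "jc":
        return jc_distance(p)
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(seqs: Mapping[str, str], model: str = "p") -> DistanceMatrix:
    """All-pairs distance matrix from an aligned {name: sequence} map."""
    taxa = list(seqs)
    n = len(taxa)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        p = p_distance(seqs[taxa[i]], seqs[taxa[j]])
        if model == "jc" and p >= 0.75:
            saturated.append((taxa[i], taxa[j]))
        d[i, j] = d[j, i] = p if model == "p" else jc_distance(p)
    if saturated:
        logger.warning("saturated JC distances set to %s for pairs: %s", SATURATED_DISTANCE, saturated)
    return DistanceMatrix(taxa, d, saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def _quote(label: str) -> str:
    if any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Recovers the generating topology exactly on additive matrices.  Negative
    branch-length estimates are clamped to zero with the deficit logged.
    The returned tree is unrooted (trifurcating seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [_quote(t) for t in dm.taxa]
    active = list(range(n))

    def blen(x: float) -> str:
        if x < 0:
            logger.info("clamped negative NJ branch length %.6g to 0", x)
            x = 0.0
        return f"{x:.10g}"

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ia, ja in itertools.combinations(active, 2):
            q = (m - 2) * d[ia, ja] - r[ia] - r[ja]
            key = (q, ia, ja)  # deterministic tie-break on indices
            if best is None or key < best:
                best = key
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new_label = f"({nodes[i]}:{blen(li)},{nodes[j]}:{blen(lj)})"
        # reuse slot i for the merged node
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = new_label
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    newick = f"({nodes[a]}:{blen(la)},{nodes[b]}:{blen(lb)},{nodes[c]}:{blen(lc)});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _midpoint_edge(tree: dendropy.Tree) -> tuple[dendropy.Edge, float]:
    """The edge containing the midpoint of the longest leaf-to-leaf path,
    and the distance from that edge's child end to the midpoint."""
    leaves = tree.leaf_nodes()
    pdm = tree.phylogenetic_distance_matrix()
    best = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            d = pdm.patristic_distance(a.taxon, b.taxon)
            if best is None or d > best[0]:
                best = (d, a, b)
    diameter, a, b = best
    mrca = dendropy.Tree.mrca(tree, taxa=[a.taxon, b.taxon])

    def edges_up(node):
        out = []
        while node is not mrca:
            out.append(node.edge)
            node = node.parent_node
        return out

    path = edges_up(a) + list(reversed(edges_up(b)))
    walked = 0.0
    for edge in path:
        length = edge.length or 0.0
        if walked + length >= diameter / 2.0 - 1e-12:
            offset = diameter / 2.0 - walked
            # distance from the child (lower) end of the edge to the midpoint
            from_child = offset if edge in edges_up(a) else length - offset
            return edge, max(0.0, min(length, from_child))
        walked += length
    return path[-1], 0.0


def root_on_outgroup(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Root an (unrooted) tree on a named outgroup leaf, or at the midpoint
    of the longest leaf-to-leaf path when no outgroup is given; the choice
    is logged."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # treat the seed node as root during rerooting
    if outgroup is not None:
        taxon = tree.taxon_namespace.get_taxon(outgroup)
        if taxon is None:
            raise MappingError(f"outgroup {outgroup!r} is not a leaf of the tree")
        leaf = tree.find_node_with_taxon_label(outgroup)
        tree.reroot_at_edge(leaf.edge, update_bipartitions=True)
        logger.info("rooted tree on outgroup %s", outgroup)
    else:
        edge, from_child = _midpoint_edge(tree)
        length = edge.length or 0.0
        tree.reroot_at_edge(
            edge, length1=max(0.0, length - from_child), length2=from_child,
            update_bipartitions=True,
        )
        logger.info("no outgroup given; midpoint-rooted the tree")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# character mapping


@dataclass
class TspReport:
    """Outcome of mapping the S/L character on a tree."""

    min_changes: int
    min_origins_of_L: int
    polymorphic_taxa: list[str]
    tsp_consistent: bool
    narrative: str = ""


def _leaf_states(tree: dendropy.Tree, states: CharacterStateMap) -> dict:
    leaf_map = {}
    leaf_labels = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        leaf_labels.add(label)
        if label not in states.states:
            raise MappingError(f"leaf {label!r} has no S/L state")
        leaf_map[leaf] = frozenset(states[label])
    extra = set(states.states) - leaf_labels
    if extra:
        logger.info("states for taxa absent from the tree ignored: %s", sorted(extra))
    return leaf_map


def fitch_map(tree: dendropy.Tree, states: CharacterStateMap) -> TspReport:
    """Generalized Fitch parsimony with set-valued tips (treated as
    ambiguity), returning the minimum number of state changes."""
    leaf_map = _leaf_states(tree, states)
    changes = 0
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = leaf_map[node]
            continue
        children = [sets[c] for c in node.child_nodes()]
        inter = frozenset.intersection(*children)
        if inter:
            sets[node] = inter
        else:
            # Fitch on multifurcations: greedy pairwise fold, standard for
            # binary-after-NJ trees; exact for binary nodes
            acc = children[0]
            for ch in children[1:]:
                nxt = acc & ch
                if not nxt:
                    changes += 1
                    nxt = acc | ch
                acc = nxt
            sets[node] = acc
    poly = sorted(
        t for t, st in states.states.items()
        if st == SL and t in {lf.taxon.label for lf in tree.leaf_node_iter()}
    )
    return TspReport(
        min_changes=changes,
        min_origins_of_L=0,
        polymorphic_taxa=poly,
        tsp_consistent=False,
        narrative="Fitch cost only; run assess_tsp for the origin analysis.",
    )


def split_polymorphic_tips(
    tree: dendropy.Tree, states: CharacterStateMap
) -> tuple[dendropy.Tree, CharacterStateMap]:
    """Alternative encoding: each polymorphic taxon becomes a cherry of an
    S leaf and an L leaf.

    Under Fitch parsimony this encoding charges one extra change per
    polymorphic taxon relative to the set-valued encoding (each cherry
    forces one union), i.e. ``cost_split = cost_sets + n_polymorphic`` —
    the two encodings answer slightly different questions (allele presence
    vs ambiguity) and the identity is asserted in the test suite.
    """
    newick = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    new_states: dict[str, frozenset[str]] = {}
    for taxon, st in states.states.items():
        if st == SL:
            sub = f"({_quote(taxon + '__S')}:0.0,{_quote(taxon + '__L')}:0.0)"
            target = _quote(taxon)
            for pattern in (target + ":", target + ",", target + ")"):
                idx = newick.find(pattern)
                if idx >= 0:
                    newick = newick[:idx] + sub + newick[idx + len(target):]
                    break
            else:
                raise MappingError(f"could not split tip {taxon!r} in newick")
            new_states[taxon + "__S"] = S
            new_states[taxon + "__L"] = L
        else:
            new_states[taxon] = st
    out = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return out, CharacterStateMap(new_states)


def _edge_cost(parent: frozenset, child: frozenset) -> int:
    """Allele-presence parsimony: one event per allele gained or lost."""
    return len(parent ^ child)


def _gains_L(parent: frozenset, child: frozenset) -> int:
    return int("L" in child and "L" not in parent)


def _sankoff(
    tree: dendropy.Tree,
    leaf_map: dict,
    forbid_L_gain: bool = False,
    forced_gain_edge=None,
    root_state: frozenset = S,
) -> tuple[float, float]:
    """DP over the {S}/{L}/{S,L} lattice.

    Returns ``(min_cost, min_L_gains_among_min_cost)``; a virtual edge from
    ``root_state`` (the ancestral short variant) enters the root.  With
    ``forbid_L_gain`` every L gain is disallowed except on
    ``forced_gain_edge`` (child node), where the child state must contain L.
    """
    INF = float("inf")
    table: dict = {}  # node -> {state: (cost, gains)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            table[node] = {
                st: ((0.0, 0.0) if st == leaf_map[node] else (INF, INF)) for st in _LATTICE
            }
            continue
        entry = {}
        for st in _LATTICE:
            total_cost, total_gains = 0.0, 0.0
            for child in node.child_nodes():
                best = (INF, INF)
                for cst in _LATTICE:
                    ccost, cgains = table[child][cst]
                    if ccost == INF:
                        continue
                    g = _gains_L(st, cst)
                    if g and forbid_L_gain and child is not forced_gain_edge:
                        continue
                    if child is forced_gain_edge and "L" not in cst:
                        continue
                    cand = (ccost + _edge_cost(st, cst), cgains + g)
                    if cand < best:
                        best = cand
                total_cost += best[0]
                total_gains += best[1]
            entry[st] = (total_cost, total_gains)
        table[node] = entry

    root = tree.seed_node
    best = (INF, INF)
    for st in _LATTICE:
        cost, gains = table[root][st]
        if cost == INF:
            continue
        g = _gains_L(root_state, st)
        if g and forbid_L_gain and root is not forced_gain_edge:
            continue
        if root is forced_gain_edge and "L" not in st:
            continue
        cand = (cost + _edge_cost(root_state, st), gains + g)
        if cand < best:
            best = cand
    return best


def assess_tsp(
    tree: dendropy.Tree, states: CharacterStateMap
) -> TspReport:
    """Assess whether the S/L distribution is consistent with a trans-species
    polymorphism.

    Under allele-presence parsimony (see module docstring) the report is
    TSP-consistent iff at least two leaves are polymorphic and a
    minimum-cost reconstruction exists in which the single gain of L lies on
    an edge ancestral to every L-bearing leaf; otherwise the minimum number
    of independent L origins among minimum-cost reconstructions is reported
    (the convergence scenario).
    """
    leaf_map = _leaf_states(tree, states)
    fitch = fitch_map(tree, states)
    min_cost, min_gains = _sankoff(tree, leaf_map)
    l_leaves = [leaf for leaf, st in leaf_map.items() if "L" in st]
    poly = fitch.polymorphic_taxa

    single_origin = False
    if l_leaves:
        # candidate edges: the root's virtual edge and every edge on the
        # path from the root to the MRCA of all L-bearing leaves
        if len(l_leaves) == 1:
            mrca = l_leaves[0]
        else:
            mrca = tree.mrca(taxa=[leaf.taxon for leaf in l_leaves])
        candidates = []
        node = mrca
        while node is not None:
            candidates.append(node)
            node = node.parent_node
        for cand in candidates:
            cost, _ = _sankoff(tree, leaf_map, forbid_L_gain=True, forced_gain_edge=cand)
            if cost == min_cost:
                single_origin = True
                break

    consistent = single_origin and len(poly) >= 2
    if consistent:
        narrative = (
            f"{len(poly)} polymorphic taxa ({', '.join(poly)}); a single ancestral "
            f"origin of L explains the data at the minimum event count ({int(min_cost)}): "
            "consistent with a trans-species polymorphism maintained across speciation."
        )
    elif len(poly) < 2:
        narrative = (
            f"only {len(poly)} polymorphic taxon/taxa; shared ancestral polymorphism "
            "cannot be distinguished from a private one."
        )
    else:
        narrative = (
            f"minimum-cost reconstructions require {int(min_gains)} independent origins "
            "of L; the distribution favours convergent gains over a single maintained "
            "ancestral polymorphism."
        )
    return TspReport(
        min_changes=fitch.min_changes,
        min_origins_of_L=int(min_gains) if not single_origin else 1,
        polymorphic_taxa=poly,
        tsp_consistent=consistent,
        narrative=narrative,
    )


# ---------------------------------------------------------------------------
# Dxy


def dxy(
    seqs_a: Mapping[str, str] | Sequence[str],
    seqs_b: Mapping[str, str] | Sequence[str],
    correction: str = "none",
) -> tuple[float, float]:
    """Nei's between-group nucleotide divergence: the mean pairwise distance
    over all between-set pairs, with its standard deviation.

    With more than one cross pair the SD is the sample standard deviation
    over pairwise distances.  When each set holds a single sequence the SD
    degenerates to the per-site binomial SD sqrt(p(1-p)/m) over the m
    compared sites (delta-method scaled under the JC correction).
    """
    same_set = seqs_a is seqs_b
    a = list(seqs_a.values()) if isinstance(seqs_a, Mapping) else list(seqs_a)
    b = list(seqs_b.values()) if isinstance(seqs_b, Mapping) else list(seqs_b)
    if not a or not b:
        raise ValueError("both sequence sets must be non-empty")
    if correction not in ("none", "jc"):
        raise ValueError(f"unknown correction {correction!r}")
    dists = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if same_set and i == j:
                continue  # a set against itself: its within-set mean distance
            p = p_distance(x, y)
            dists.append(jc_distance(p) if correction == "jc" else p)
    if not dists:
        return 0.0, 0.0
    est = float(np.mean(dists))
    if len(dists) > 1:
        sd = float(np.std(dists, ddof=1))
    else:
        p = p_distance(a[0], b[0])
        _, m = _compared_sites(a[0], b[0])
        sd = math.sqrt(p * (1 - p) / m)
        if correction == "jc" and p < 0.75:
            sd /= 1.0 - 4.0 * p / 3.0
    return est, sd


def mean_within(seqs: Mapping[str, str] | Sequence[str], correction: str = "none") -> float:
    """Mean pairwise distance within one set (0 for a singleton)."""
    s = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    if len(s) < 2:
        return 0.0
    dists = [
        jc_distance(p_distance(x, y)) if correction == "jc" else p_distance(x, y)
        for x, y in itertools.combinations(s, 2)
    ]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# global alignment


def nw_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Tie-breaking in the traceback is deterministic: diagonal over up
    (gap in ``b``) over left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(
            score[i, j], score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and math.isclose(score[i, j], score[i - 1, j] + gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])
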