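"""Maximum-parsimony phylogenies from binary mutation-presence matrices.

Each patient's tree has one leaf per sampled tumor region plus a germline
outgroup fixed to the all-zero (no somatic mutation) state at the root. The
tree minimizes the total number of character state changes (Fitch parsimony),
and every edge length is the number of mutations assigned to that edge, so
trunks and branches are drawn proportional to detected mutation counts.

The search is exact: all rooted leaf-labeled topologies are explored by
stepwise leaf insertion, with branch-and-bound pruning (the parsimony score of
a leaf subset never exceeds that of a superset, so partial trees scoring
worse than the incumbent are discarded). Regions with identical mutation
profiles are collapsed before the search and re-attached afterwards as
zero-length cherries. Ties between equally parsimonious topologies are broken
deterministically by the lexicographically smallest canonical Newick string.

Somatic point mutations are treated as effectively irreversible: each
mutation is placed on the edges where its state changes, and for a
perfect-phylogeny-compatible character that is a single gain edge as close to
the root as the topology allows. Incompatible characters (homoplasy from
calling noise) additionally carry loss events, which count toward the
parsimony score and edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .ith import Clonality, PatientMutationMatrix

__all__ = [
    "EvolutionPattern",
    "TreeNode",
    "PhyloTree",
    "build_phylogenetic_tree",
    "classify_evolution_pattern",
    "trunk_fraction_from_tree",
    "MAX_REGIONS",
]

MAX_REGIONS = 10


class EvolutionPattern(str, Enum):
    LINEAR = "LINEAR"
    BRANCHED = "BRANCHED"


@dataclass
class TreeNode:
    """Node of a rooted phylogeny; edge attributes describe the edge above."""

    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    edge_length: int = 0
    gains: list[str] = field(default_factory=list)
    losses: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    root: TreeNode  # named "germline"
    parsimony_score: int
    pattern: EvolutionPattern
    patient_id: str = ""

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    @property
    def trunk_length(self) -> int:
        """Mutations on the single edge leaving the germline root."""
        (top,) = self.root.children
        return top.edge_length

    def edge_lengths(self) -> list[int]:
        return [n.edge_length for n in self.root.walk() if n is not self.root]

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.edge_length}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.name}:{node.edge_length}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner})germline;"


# ---------------------------------------------------------------------------
# topology search
#
# A topology over leaf indices is a nested structure: an int is a leaf, a
# 2-tuple an internal node. The germline root is implicit: every character is
# scored with the root state forced to 0. Character state sets are 2-bit
# masks (1 = absent, 2 = present).
# ---------------------------------------------------------------------------

def _fitch_score(tree, leaf_masks: list[list[int]], weights: list[int]) -> int:
    """Weighted Fitch parsimony score with the root state forced to absent."""
    n_chars = len(weights)
    changes = [0] * n_chars

    def post(node) -> list[int]:
        if isinstance(node, int):
            return leaf_masks[node]
        left, right = post(node[0]), post(node[1])
        out = [0] * n_chars
        for i in range(n_chars):
            inter = left[i] & right[i]
            if inter:
                out[i] = inter
            else:
                out[i] = left[i] | right[i]
                changes[i] += 1
        return out

    top = post(tree)
    score = 0
    for i in range(n_chars):
        if not top[i] & 1:  # absent-state unreachable at top: change on trunk edge
            changes[i] += 1
        score += changes[i] * weights[i]
    return score


def _insertions(tree, leaf: int):
    """All topologies obtained by inserting ``leaf`` on an edge (or above the top)."""
    yield (tree, leaf)
    if not isinstance(tree, int):
        left, right = tree
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def _canonical(tree, labels: list[str]) -> str:
    if isinstance(tree, int):
        return labels[tree]
    parts = sorted((_canonical(tree[0], labels), _canonical(tree[1], labels)))
    return f"({parts[0]},{parts[1]})"


def _search_topologies(n_leaves: int, leaf_masks, weights, labels) -> tuple:
    """Exact branch-and-bound over rooted leaf-labeled topologies.

    Returns (best_score, best_topology) with ties broken by canonical Newick.
    """
    if n_leaves == 1:
        return _fitch_score(0, leaf_masks, weights), 0

    best: dict = {"score": None, "tree": None, "key": None}

    def recurse(tree, next_leaf: int):
        score = _fitch_score(tree, leaf_masks, weights)
        if best["score"] is not None and score > best["score"]:
            return  # adding leaves never decreases the score
        if next_leaf == n_leaves:
            key = _canonical(tree, labels)
            if (best["score"] is None or score < best["score"]
                    or (score == best["score"] and key < best["key"])):
                best.update(score=score, tree=tree, key=key)
            return
        for candidate in _insertions(tree, next_leaf):
            recurse(candidate, next_leaf + 1)

    recurse((0, 1), 2)
    return best["score"], best["tree"]


_INF = (10 ** 9, 10 ** 9)


def _assign_mutations(topology, leaf_masks, char_keys, labels,
                      group_members: list[list[str]]) -> TreeNode:
    """Place each mutation on the edges where its state changes.

    Among assignments with the minimum number of changes (the parsimony
    score), the one with the fewest losses is chosen — somatic gains are
    preferred over back-mutations — with remaining ties resolved by keeping
    the parent's state. Compatible characters therefore get exactly one gain
    on the edge above their minimal clade, and the trunk edge carries a gain
    of a subclonal character only when homoplasy forces a loss.

    ``group_members[i]`` are the region ids collapsed into leaf ``i``; groups
    of size > 1 are re-expanded as zero-length cherries.
    """
    n_chars = len(char_keys)
    cost: dict = {}  # (node_id, char) -> {state: (changes, losses) below node}

    def _node_id(node):
        # leaf ints are unique by value; internal tuples by object identity
        return node if isinstance(node, int) else ("n", id(node))

    def post(node) -> None:
        nid = _node_id(node)
        if isinstance(node, int):
            for i in range(n_chars):
                present = leaf_masks[node][i] == 2
                cost[(nid, i)] = {0: _INF if present else (0, 0),
                                  1: (0, 0) if present else _INF}
            return
        post(node[0]), post(node[1])
        ids = [_node_id(node[0]), _node_id(node[1])]
        for i in range(n_chars):
            out = {}
            for s in (0, 1):
                ch = lo = 0
                for cid in ids:
                    best = min(_edge_cost(cost[(cid, i)][t], s, t)
                               for t in (0, 1))
                    ch += best[0]
                    lo += best[1]
                out[s] = (ch, lo)
            cost[(nid, i)] = out

    def _edge_cost(child_cost, s, t):
        return (child_cost[0] + (s != t), child_cost[1] + (s == 1 and t == 0))

    post(topology)

    top_states = []
    for i in range(n_chars):
        c = cost[(_node_id(topology), i)]
        # germline root is state 0; the trunk-edge change (if any) is a gain
        top_states.append(min((_edge_cost(c[s], 0, s), s) for s in (0, 1))[1])

    def expand_leaf(index: int, length: int, gains, losses) -> TreeNode:
        members = group_members[index]
        if len(members) == 1:
            return TreeNode(members[0], [], length, gains, losses)
        return TreeNode("", [TreeNode(m, [], 0, [], []) for m in sorted(members)],
                        length, gains, losses)

    def build(node, states: list[int], parent_states: list[int]) -> TreeNode:
        gains, losses = [], []
        for i in range(n_chars):
            if states[i] != parent_states[i]:
                (gains if states[i] == 1 else losses).extend(char_keys[i])
        length = len(gains) + len(losses)
        if isinstance(node, int):
            return expand_leaf(node, length, sorted(gains), sorted(losses))
        out = TreeNode("", [], length, sorted(gains), sorted(losses))
        kids = sorted(node, key=lambda sub: _canonical(sub, labels))
        for kid in kids:
            kid_states = []
            for i in range(n_chars):
                options = [(_edge_cost(cost[(_node_id(kid), i)][t], states[i], t),
                            t != states[i], t) for t in (0, 1)]
                kid_states.append(min(options)[2])  # tie keeps parent state
            out.children.append(build(kid, kid_states, states))
        return out

    return build(topology, top_states, [0] * n_chars)


def build_phylogenetic_tree(matrix: PatientMutationMatrix) -> PhyloTree:
    """Exact maximum-parsimony tree for one patient's presence matrix.

    The returned tree is rooted at a ``germline`` node whose single outgoing
    (trunk) edge carries every mutation shared by all regions; edge lengths
    count assigned mutations and sum to the parsimony score.
    """
    if not matrix.variant_keys:
        raise ValueError("cannot build a tree from an empty mutation matrix")
    n_regions = matrix.n_regions
    if n_regions > MAX_REGIONS:
        raise ValueError(
            f"{n_regions} regions exceeds the exact-search bound of "
            f"{MAX_REGIONS}; subsample regions before tree building")

    # collapse identical region profiles
    columns: dict[tuple, int] = {}
    group_members: list[list[str]] = []
    for j, region in enumerate(matrix.region_ids):
        profile = tuple(matrix.presence[:, j])
        if profile in columns:
            group_members[columns[profile]].append(region)
        else:
            columns[profile] = len(group_members)
            group_members.append([region])
    profiles = list(columns)  # column profile per collapsed leaf
    labels = [sorted(members)[0] for members in group_members]

    # collapse identical mutation rows into weighted characters
    char_index: dict[tuple, int] = {}
    char_keys: list[list[str]] = []
    for key, row in zip(matrix.variant_keys, matrix.presence):
        pattern = tuple(int(row[matrix.region_ids.index(m)])
                        for members in group_members for m in members[:1])
        if pattern not in char_index:
            char_index[pattern] = len(char_keys)
            char_keys.append([])
        char_keys[char_index[pattern]].append(key)
    patterns = list(char_index)
    weights = [len(keys) for keys in char_keys]
    for keys in char_keys:
        keys.sort()

    # per-leaf state masks: 1 = absent, 2 = present
    leaf_masks = [[2 if patterns[c][leaf] else 1 for c in range(len(patterns))]
                  for leaf in range(len(group_members))]

    score, topology = _search_topologies(len(group_members), leaf_masks,
                                         weights, labels)
    top = _assign_mutations(topology, leaf_masks, char_keys, labels, group_members)
    root = TreeNode("germline", [top], 0, [], [])
    pattern = classify_evolution_pattern(matrix)
    return PhyloTree(root, score, pattern, matrix.patient_id)


def classify_evolution_pattern(matrix: PatientMutationMatrix) -> EvolutionPattern:
    """LINEAR iff the distinct subclonal presence patterns form a nested chain.

    The all-ones (trunk) pattern is excluded; a patient with no branch
    mutations is LINEAR by convention (a single clonal expansion).
    """
    n = matrix.n_regions
    subclonal = {tuple(row) for row in matrix.presence if int(sum(row)) < n}
    patterns = [frozenset(i for i, bit in enumerate(p) if bit) for p in subclonal]
    for i, a in enumerate(patterns):
        for b in patterns[i + 1:]:
            if not (a <= b or b <= a):
                return EvolutionPattern.BRANCHED
    return EvolutionPattern.LINEAR


def trunk_fraction_from_tree(tree: PhyloTree) -> float:
    """Trunk edge length over total tree length; equals 1 - ITHi when the
    matrix is perfect-phylogeny compatible."""
    total = sum(tree.edge_lengths())
    if total == 0:
        raise ValueError("tree has zero total length")
    return tree.trunk_length / total


def trunk_branch_from_tree(tree: PhyloTree) -> dict[str, Clonality]:
    """Clonality labels implied by the tree: trunk-edge gains are TRUNK."""
    (top,) = tree.root.children
    trunk = set(top.gains)
    labels: dict[str, Clonality] = {}
    for node in tree.root.walk():
        for key in node.gains:
            labels.setdefault(key, Clonality.TRUNK if key in trunk
                              else Clonality.BRANCH)
    return labels
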