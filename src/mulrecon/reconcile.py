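"""LCA duplication-loss reconciliation against singly-labelled and MUL trees.

The classic least-common-ancestor (LCA) mapping embeds a rooted binary gene
tree into a rooted reference tree: each gene leaf maps to the reference
leaf of its species, each internal gene node to the LCA of its children's
images.  A gene node is a duplication iff it maps to the same reference
node as one of its children; losses are counted along each child edge as
the number of reference edges skipped (minus one for speciation nodes).
No losses are charged above the gene-tree root.  The reconciliation score
is duplications + losses.

Against a MUL reference the leaves of duplicated species are ambiguous:
each could descend from either subgenome copy (``*`` or ``+``).
Enumeration is made tractable by collapsing the gene tree into *polyploid
groups* -- maximal connected subtrees whose leaves all belong to
duplicated species with at most one leaf per species -- and assigning each
group en bloc to one copy, minimizing the total score over the 2^g
assignments.  A per-leaf brute-force oracle (:func:`brute_force_mul`)
bounds this heuristic from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .candidates import CandidatePlacement
from .treeio import Node, RootedTree, TreeError

__all__ = [
    "MappingError",
    "GroupCapExceeded",
    "OracleTooLarge",
    "PolyploidGroup",
    "ReconciliationResult",
    "RefIndex",
    "lca_map",
    "count_dup_loss",
    "find_polyploid_groups",
    "reconcile_single",
    "reconcile_mul",
    "brute_force_mul",
    "score_all",
    "GROUP_CAP_DEFAULT",
]

GROUP_CAP_DEFAULT = 8


class MappingError(TreeError):
    """A gene leaf's species is absent from the reference tree."""


class GroupCapExceeded(TreeError):
    """More polyploid groups than the configured cap; the tree is excluded."""


class OracleTooLarge(TreeError):
    """Brute-force enumeration would exceed its instance-size bound."""


@dataclass
class PolyploidGroup:
    """Leaves of duplicated species assigned en bloc to one subgenome copy."""

    root: Node
    leaves: list[Node]

    @property
    def species(self) -> frozenset:
        return frozenset(l.species_or_label() for l in self.leaves)


@dataclass
class ReconciliationResult:
    candidate_id: str
    duplications: int
    losses: int
    assignment: tuple | None = None  # per-group copy tags, MUL only
    node_map: dict = field(default_factory=dict, repr=False)

    @property
    def total(self) -> int:
        return self.duplications + self.losses


# ---------------------------------------------------------------------------
# Reference indexing
# ---------------------------------------------------------------------------


class RefIndex:
    """Array-based view of a reference tree for fast repeated LCA queries."""

    def __init__(self, tree: RootedTree):
        self.tree = tree
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = [
            self.index[id(n.parent)] if n.parent is not None else -1
            for n in self.nodes
        ]
        self.depth = [0] * len(self.nodes)
        for n in tree.preorder():
            i = self.index[id(n)]
            p = self.parent[i]
            self.depth[i] = 0 if p < 0 else self.depth[p] + 1
        # species -> {tag: leaf index}; singly-labelled leaves use tag None
        self.leaf_of: dict[str, dict[str | None, int]] = {}
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.leaf_of.setdefault(n.species_or_label(), {})[n.tag] = i
        self.duplicated_species = frozenset(
            sp for sp, tags in self.leaf_of.items() if len(tags) > 1
        )

    def lca(self, i: int, j: int) -> int:
        di, dj = self.depth[i], self.depth[j]
        while di > dj:
            i = self.parent[i]
            di -= 1
        while dj > di:
            j = self.parent[j]
            dj -= 1
        while i != j:
            i = self.parent[i]
            j = self.parent[j]
        return i

    def leaf_index(self, species: str, tag: str | None = None) -> int:
        try:
            tags = self.leaf_of[species]
        except KeyError:
            raise MappingError(f"species {species!r} absent from reference") from None
        if tag is None and len(tags) == 1:
            return next(iter(tags.values()))
        try:
            return tags[tag]
        except KeyError:
            raise MappingError(
                f"species {species!r} has no copy tagged {tag!r} in reference"
            ) from None


class _GeneIndex:
    """Postorder arrays for a binary gene tree, reusable across references."""

    def __init__(self, tree: RootedTree):
        if not tree.is_binary():
            raise TreeError("gene tree must be binary for reconciliation")
        self.tree = tree
        self.nodes = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.leaf_ids = [i for i, n in enumerate(self.nodes) if n.is_leaf]
        self.leaf_species = {i: self.nodes[i].species_or_label() for i in self.leaf_ids}


# ---------------------------------------------------------------------------
# Core mapping and counting
# ---------------------------------------------------------------------------


def lca_map(gene_tree: RootedTree, ref_tree: RootedTree, leaf_assignment: dict):
    """Map every gene-tree node to a reference node.

    ``leaf_assignment`` maps each gene leaf node to its reference leaf node.
    Returns a dict from gene node to reference node.
    """
    ref = ref_tree if isinstance(ref_tree, RefIndex) else RefIndex(ref_tree)
    gi = _GeneIndex(gene_tree)
    assign = {
        i: ref.index[id(leaf_assignment[gi.nodes[i]])] for i in gi.leaf_ids
    }
    m = _lca_map_arrays(gi, ref, assign)
    return {gi.nodes[i]: ref.nodes[m[i]] for i in range(len(gi.nodes))}


def _lca_map_arrays(gi: _GeneIndex, ref: RefIndex, leaf_assign: dict) -> list[int]:
    m = [0] * len(gi.nodes)
    for i in range(len(gi.nodes)):
        ch = gi.children[i]
        if not ch:
            m[i] = leaf_assign[i]
        else:
            m[i] = ref.lca(m[ch[0]], m[ch[1]])
    return m


def _count_arrays(gi: _GeneIndex, ref: RefIndex, m: list[int]) -> tuple[int, int]:
    dups = 0
    losses = 0
    depth = ref.depth
    for i in range(len(gi.nodes)):
        ch = gi.children[i]
        if not ch:
            continue
        c1, c2 = ch
        is_dup = m[i] == m[c1] or m[i] == m[c2]
        if is_dup:
            dups += 1
        for c in ch:
            d = depth[m[c]] - depth[m[i]]
            if d < 0:
                raise TreeError("inconsistent map: child image above parent image")
            losses += d if is_dup else d - 1
    return dups, losses


def count_dup_loss(gene_tree: RootedTree, ref_tree: RootedTree, node_map: dict):
    """Duplication and loss counts for an LCA map produced by :func:`lca_map`."""
    ref = ref_tree if isinstance(ref_tree, RefIndex) else RefIndex(ref_tree)
    gi = _GeneIndex(gene_tree)
    m = [ref.index[id(node_map[n])] for n in gi.nodes]
    return _count_arrays(gi, ref, m)


# ---------------------------------------------------------------------------
# Polyploid groups
# ---------------------------------------------------------------------------


def find_polyploid_groups(
    gene_tree: RootedTree, duplicated_species
) -> list[PolyploidGroup]:
    """Maximal single-copy subtrees of duplicated-species leaves, in preorder.

    A subtree qualifies when every leaf belongs to a duplicated species and
    no species occurs twice within it (two same-species leaves necessarily
    straddle distinct copies, so such a subtree cannot map en bloc).
    """
    duplicated_species = frozenset(duplicated_species)
    ok: dict[int, bool] = {}
    spset: dict[int, frozenset] = {}
    for n in gene_tree.postorder():
        if n.is_leaf:
            sp = n.species_or_label()
            ok[id(n)] = sp in duplicated_species
            spset[id(n)] = frozenset([sp])
        else:
            union: frozenset = frozenset()
            good = all(ok[id(c)] for c in n.children)
            disjoint = True
            for c in n.children:
                if union & spset[id(c)]:
                    disjoint = False
                union = union | spset[id(c)]
            spset[id(n)] = union
            ok[id(n)] = good and disjoint
    groups = []
    for n in gene_tree.preorder():
        if ok[id(n)] and (n.parent is None or not ok[id(n.parent)]):
            leaves = _subtree_leaves(n)
            groups.append(PolyploidGroup(root=n, leaves=leaves))
    return groups


def _subtree_leaves(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(reversed(n.children))
    return out


# ---------------------------------------------------------------------------
# Reconciliation entry points
# ---------------------------------------------------------------------------


def reconcile_single(
    gene_tree: RootedTree, species_tree, candidate_id: str = "SINGLE"
) -> ReconciliationResult:
    """Reconcile against the singly-labelled species tree (no ambiguity)."""
    ref = species_tree if isinstance(species_tree, RefIndex) else RefIndex(species_tree)
    gi = _GeneIndex(gene_tree)
    assign = {i: ref.leaf_index(gi.leaf_species[i]) for i in gi.leaf_ids}
    m = _lca_map_arrays(gi, ref, assign)
    dups, losses = _count_arrays(gi, ref, m)
    node_map = {gi.nodes[i]: ref.nodes[m[i]] for i in range(len(gi.nodes))}
    return ReconciliationResult(candidate_id, dups, losses, None, node_map)


_TAG_OF_BIT = ("*", "+")


def reconcile_mul(
    gene_tree: RootedTree,
    mul_candidate: CandidatePlacement,
    group_cap: int = GROUP_CAP_DEFAULT,
    ref: RefIndex | None = None,
    gi: _GeneIndex | None = None,
) -> ReconciliationResult:
    """Minimum-score reconciliation against a MUL candidate.

    All 2^g assignments of polyploid groups to copy tags are evaluated;
    ties prefer more ``*`` assignments, then lexicographic order (``*`` <
    ``+``), so results are reproducible.  Raises :class:`GroupCapExceeded`
    when the group count exceeds ``group_cap`` (the tree is then excluded,
    mirroring the preliminary filter).
    """
    if not mul_candidate.is_mul:
        return reconcile_single(gene_tree, mul_candidate, "SINGLE")
    if ref is None:
        ref = RefIndex(mul_candidate.mul_tree)
    if gi is None:
        gi = _GeneIndex(gene_tree)
    groups = find_polyploid_groups(gene_tree, ref.duplicated_species)
    if len(groups) > group_cap:
        raise GroupCapExceeded(
            f"{len(groups)} polyploid groups exceed cap {group_cap}"
        )
    gid = {id(n): i for i, n in enumerate(gi.nodes)}
    base_assign: dict[int, int] = {}
    group_leaf_ids: list[list[tuple[int, str]]] = []
    grouped = set()
    for g in groups:
        ids = [(gid[id(l)], l.species_or_label()) for l in g.leaves]
        group_leaf_ids.append(ids)
        grouped.update(i for i, _ in ids)
    for i in gi.leaf_ids:
        if i not in grouped:
            base_assign[i] = ref.leaf_index(gi.leaf_species[i])
    best = None
    for bits in product((0, 1), repeat=len(groups)):
        assign = dict(base_assign)
        for g_ids, bit in zip(group_leaf_ids, bits):
            tag = _TAG_OF_BIT[bit]
            for i, sp in g_ids:
                assign[i] = ref.leaf_index(sp, tag)
        m = _lca_map_arrays(gi, ref, assign)
        dups, losses = _count_arrays(gi, ref, m)
        key = (dups + losses, sum(bits), bits)
        if best is None or key < best[0]:
            best = (key, dups, losses, bits, m)
    _, dups, losses, bits, m = best
    node_map = {gi.nodes[i]: ref.nodes[m[i]] for i in range(len(gi.nodes))}
    return ReconciliationResult(
        mul_candidate.id,
        dups,
        losses,
        tuple(_TAG_OF_BIT[b] for b in bits),
        node_map,
    )


def brute_force_mul(
    gene_tree: RootedTree,
    mul_candidate: CandidatePlacement,
    max_dup_leaves: int = 12,
) -> ReconciliationResult:
    """Exhaustive per-leaf copy-assignment oracle (testing reference).

    Minimizes the score over all per-leaf assignments, a strict superset of
    the per-group search space.  Instances with more than
    ``max_dup_leaves`` duplicated-species leaves are refused.
    """
    ref = RefIndex(mul_candidate.mul_tree)
    gi = _GeneIndex(gene_tree)
    dup_leaves = [
        i for i in gi.leaf_ids if gi.leaf_species[i] in ref.duplicated_species
    ]
    if len(dup_leaves) > max_dup_leaves:
        raise OracleTooLarge(
            f"{len(dup_leaves)} duplicated-species leaves exceed {max_dup_leaves}"
        )
    base_assign = {
        i: ref.leaf_index(gi.leaf_species[i])
        for i in gi.leaf_ids
        if i not in set(dup_leaves)
    }
    best = None
    for bits in product((0, 1), repeat=len(dup_leaves)):
        assign = dict(base_assign)
        for i, bit in zip(dup_leaves, bits):
            assign[i] = ref.leaf_index(gi.leaf_species[i], _TAG_OF_BIT[bit])
        m = _lca_map_arrays(gi, ref, assign)
        dups, losses = _count_arrays(gi, ref, m)
        key = (dups + losses, sum(bits), bits)
        if best is None or key < best[0]:
            best = (key, dups, losses)
    _, dups, losses = best
    return ReconciliationResult(mul_candidate.id, dups, losses)


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------


def score_all(
    gene_trees,
    candidates,
    species_tree: RootedTree | None = None,
    group_cap: int = GROUP_CAP_DEFAULT,
):
    """Sum reconciliation scores of every gene tree over every candidate.

    Returns a pandas DataFrame with one row per candidate: number of trees
    reconciled, skipped-tree count, summed duplications/losses/total, and
    ascending rank by total (ties by enumeration order).  Per-tree failures
    (group cap, unmappable species) are tallied, not fatal.
    """
    import pandas as pd

    gene_indices = [_GeneIndex(t) for t in gene_trees]
    rows = []
    for order, cand in enumerate(candidates):
        if cand.is_mul:
            ref = RefIndex(cand.mul_tree)
        else:
            if species_tree is None:
                raise ValueError(
                    "species_tree required for the singly-labelled candidate"
                )
            ref = RefIndex(species_tree)
        n_ok = n_skip = sum_d = sum_l = 0
        for gi in gene_indices:
            try:
                if cand.is_mul:
                    res = reconcile_mul(gi.tree, cand, group_cap, ref=ref, gi=gi)
                else:
                    res = reconcile_single(gi.tree, ref)
                n_ok += 1
                sum_d += res.duplications
                sum_l += res.losses
            except (GroupCapExceeded, MappingError):
                n_skip += 1
        rows.append(
            {
                "candidate_id": cand.id,
                "order": order,
                "n_trees": n_ok,
                "n_skipped": n_skip,
                "sum_dups": sum_d,
                "sum_losses": sum_l,
                "total_score": sum_d + sum_l,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["total_score", "order"], kind="stable").reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df.drop(columns=["order"])
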