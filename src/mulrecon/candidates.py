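"""Enumeration of reconciliation references.

A candidate is either the singly-labelled species tree itself or a MUL
(multi-labelled) tree defined by a pair (H1, H2): H1 is the putative
polyploid clade, whose species appear twice in the MUL tree, and H2 marks
where the second subgenome copy attaches.  H2 = H1 encodes the
autopolyploid case (the copy becomes H1's sister); H2 = root attaches the
copy above the present root.

Copy tags: ``*`` marks the copy remaining at H1's original position, ``+``
the copy grafted at H2.  This orientation is fixed: the three canonical
retention/loss topologies are written in terms of it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .treeio import Node, RootedTree, TreeError, write_newick

__all__ = [
    "PlacementError",
    "CandidatePlacement",
    "build_mul_tree",
    "enumerate_candidates",
    "candidate_id",
    "write_candidates_tsv",
]

H2_SELF = "SELF"
H2_ROOT = "ROOT"


class PlacementError(TreeError):
    """Invalid (H1, H2) pair (H2 strictly inside the H1 subtree)."""


@dataclass
class CandidatePlacement:
    """One reconciliation reference.

    ``kind`` is ``"singly_labelled"`` or ``"mul"``.  For MUL candidates,
    ``h1`` holds the species of the duplicated clade and ``h2`` is either
    the species set of the attachment clade, or the sentinel strings
    ``"SELF"`` / ``"ROOT"``.  ``mul_tree`` is None for the singly-labelled
    candidate.
    """

    kind: str
    h1: frozenset | None = None
    h2: object = None  # frozenset | "SELF" | "ROOT"
    mul_tree: RootedTree | None = None

    @property
    def is_mul(self) -> bool:
        return self.kind == "mul"

    @property
    def duplicated_species(self) -> frozenset:
        return self.h1 if self.is_mul else frozenset()

    @property
    def id(self) -> str:
        return candidate_id(self)


def _tag_leaves(node: Node, tag: str) -> None:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            n.species = n.species_or_label()
            n.tag = tag
            n.label = n.species + tag
        stack.extend(n.children)


def build_mul_tree(species_tree: RootedTree, h1, h2) -> RootedTree:
    """Construct the MUL tree for placement (h1, h2).

    ``h1`` and ``h2`` may be given as nodes of ``species_tree`` or as leaf
    species sets; ``h2`` may also be the sentinels ``"SELF"`` or ``"ROOT"``.
    A deep copy of the H1 subtree, leaves tagged ``+``, is grafted onto the
    edge above H2 (a new node subdividing it); the original H1 leaves are
    tagged ``*``.  The result is binary when the input is.
    """
    t = species_tree.copy()

    def locate(spec) -> Node:
        if isinstance(spec, Node):
            return t.find_clade(
                [l.species_or_label() for l in RootedTree(spec.copy()).leaves()]
            )
        return t.find_clade(spec)

    h1_node = locate(h1)
    if h1_node.parent is None:
        raise PlacementError("H1 must not be the root")

    copy_sub = h1_node.copy()
    _tag_leaves(h1_node, "*")
    _tag_leaves(copy_sub, "+")

    if isinstance(h2, str) and h2 == H2_SELF:
        parent = h1_node.parent
        joint = Node("", [h1_node, copy_sub])
        parent.children[parent.children.index(h1_node)] = joint
        joint.parent = parent
        return t
    if isinstance(h2, str) and h2 == H2_ROOT:
        return RootedTree(Node("", [t.root, copy_sub]))

    h2_node = locate(h2)
    if h2_node is h1_node:
        return build_mul_tree(species_tree, h1, H2_SELF)
    if h2_node.parent is None:
        return RootedTree(Node("", [t.root, copy_sub]))
    # reject H2 strictly inside subtree(H1)
    anc = h2_node.parent
    while anc is not None:
        if anc is h1_node:
            raise PlacementError("H2 lies strictly inside the H1 subtree")
        anc = anc.parent
    parent = h2_node.parent
    joint = Node("", [h2_node, copy_sub])
    parent.children[parent.children.index(h2_node)] = joint
    joint.parent = parent
    return t


def enumerate_candidates(species_tree: RootedTree) -> list[CandidatePlacement]:
    """All reconciliation references for a binary species tree.

    Exactly one singly-labelled candidate, plus one MUL candidate for every
    pair (H1, H2) with H1 over all non-root nodes (preorder) and H2 over
    {H1} plus every node outside the subtree of H1, root included (preorder).
    Topologically identical placements are *not* deduplicated: the search
    space is counted in placements.
    """
    if not species_tree.is_binary():
        raise TreeError("species tree must be strictly bifurcating")
    pre = list(species_tree.preorder())
    species_sets: dict[int, frozenset] = {}
    for n in species_tree.postorder():
        if n.is_leaf:
            species_sets[id(n)] = frozenset([n.species_or_label()])
        else:
            species_sets[id(n)] = frozenset().union(
                *(species_sets[id(c)] for c in n.children)
            )
    subtree_nodes: dict[int, set] = {}
    for n in reversed(pre):
        s = {id(n)}
        for c in n.children:
            s |= subtree_nodes[id(c)]
        subtree_nodes[id(n)] = s

    out = [CandidatePlacement(kind="singly_labelled")]
    for h1 in pre[1:]:
        inside = subtree_nodes[id(h1)]
        for h2 in pre:
            if h2 is h1:
                h2_spec: object = H2_SELF
            elif id(h2) in inside:
                continue
            elif h2.parent is None:
                h2_spec = H2_ROOT
            else:
                h2_spec = species_sets[id(h2)]
            mul = build_mul_tree(species_tree, species_sets[id(h1)], h2_spec)
            out.append(
                CandidatePlacement(
                    kind="mul",
                    h1=species_sets[id(h1)],
                    h2=h2_spec,
                    mul_tree=mul,
                )
            )
    return out


def candidate_id(placement: CandidatePlacement) -> str:
    """Stable human-readable identifier, identical across runs."""
    if not placement.is_mul:
        return "SINGLE"
    h1 = ",".join(sorted(placement.h1))
    if isinstance(placement.h2, str):
        h2 = placement.h2
    else:
        h2 = ",".join(sorted(placement.h2))
    return f"H1={h1}|H2={h2}"


def write_candidates_tsv(candidates, path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tkind\tnewick\n")
        for c in candidates:
            nwk = write_newick(c.mul_tree) if c.is_mul else ""
            fh.write(f"{c.id}\t{c.kind}\t{nwk}\n")
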