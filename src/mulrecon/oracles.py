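"""Independent reconciliation oracles for testing.

Deliberately naive re-implementations that share no code with
:mod:`mulrecon.reconcile`: the duplication/loss counts of the fast path
must agree with these on random instances.
"""

from __future__ import annotations

from .treeio import Node, RootedTree

__all__ = ["naive_reconcile_single"]


def _root_path(node: Node) -> list[Node]:
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    return path


def naive_reconcile_single(gene_tree: RootedTree, species_tree: RootedTree):
    """Quadratic-time duplication/loss counter against a singly-labelled tree.

    Maps each gene node to the *smallest* species node covering its leaf
    species (found by scanning every species node), then walks explicit
    root paths to count losses.  Returns ``(duplications, losses)``.
    """
    sp_nodes = list(species_tree.postorder())
    below: dict[int, frozenset] = {}
    for n in sp_nodes:
        if n.is_leaf:
            below[id(n)] = frozenset([n.species_or_label()])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))

    def smallest_cover(species: frozenset) -> Node:
        best = None
        for n in sp_nodes:
            if species <= below[id(n)]:
                if best is None or len(below[id(n)]) < len(below[id(best)]):
                    best = n
        if best is None:
            raise ValueError(f"species {sorted(species)} not all in species tree")
        return best

    gene_species: dict[int, frozenset] = {}
    mapped: dict[int, Node] = {}
    for g in gene_tree.postorder():
        if g.is_leaf:
            gene_species[id(g)] = frozenset([g.species_or_label()])
        else:
            gene_species[id(g)] = frozenset().union(
                *(gene_species[id(c)] for c in g.children)
            )
        mapped[id(g)] = smallest_cover(gene_species[id(g)])

    dups = 0
    losses = 0
    for g in gene_tree.postorder():
        if g.is_leaf:
            continue
        images = [mapped[id(c)] for c in g.children]
        is_dup = any(img is mapped[id(g)] for img in images)
        if is_dup:
            dups += 1
        for img in images:
            path = _root_path(img)
            steps = path.index(mapped[id(g)])  # edges from child image up
            losses += steps if is_dup else steps - 1
    return dups, losses
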