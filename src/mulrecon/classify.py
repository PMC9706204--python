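"""Retention/loss scenario classification of gene trees.

After an allopolyploid origin of the focal clade, each gene family retains
or loses the two homeolog copies independently in the two descendant
clades ("other"-like cladeA and "core"-like cladeB).  Restricted to the
focal species, a rooted gene tree is matched to one of three canonical
topologies:

* ``T1`` -- one copy lost in cladeB: (cladeA, (cladeA, cladeB))
* ``T2`` -- one copy lost in cladeA: (cladeB, (cladeA, cladeB))
* ``T3`` -- both copies retained in both clades: ((cladeA, cladeB), (cladeA, cladeB))
* ``U``  -- anything else (reciprocal loss, topological error, degeneracy)

Matching keys on clade composition, not copy tags: ``strict`` mode demands
the literal patterns above on the induced subtree's first two levels,
``lenient`` mode only the A-only / B-only / mixed composition of the two
root children (useful for multi-copy families).
"""

from __future__ import annotations

from collections import Counter

from .treeio import Node, PruneError, RootedTree, SpeciesMap, TreeError, prune_to

__all__ = [
    "ClassifyError",
    "T1",
    "T2",
    "T3",
    "UNCLASSIFIED",
    "LABELS",
    "induced_subtree",
    "clade_composition",
    "classify_scenario",
    "tally_scenarios",
    "loss_vs_retention",
]

T1, T2, T3, UNCLASSIFIED = "T1", "T2", "T3", "U"
LABELS = (T1, T2, T3, UNCLASSIFIED)

A_ONLY, B_ONLY, MIXED = "A-only", "B-only", "mixed"


class ClassifyError(TreeError):
    pass


def induced_subtree(gene_tree: RootedTree, keep_species) -> RootedTree:
    """Subtree induced on ``keep_species``; rooting inherited, unary nodes
    suppressed. Fewer than two kept leaves is an error (label U upstream)."""
    try:
        sub = prune_to(gene_tree, keep_species)
    except PruneError as e:
        raise ClassifyError(str(e)) from None
    if sub.n_leaves < 2:
        raise ClassifyError("induced subtree has fewer than 2 leaves")
    return sub


def clade_composition(node: Node, speciesmap: SpeciesMap) -> str:
    """A-only / B-only / mixed composition of the leaves below ``node``."""
    roles = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            roles.add(speciesmap.role_of(n.species_or_label()))
        stack.extend(n.children)
    if roles == {"cladeA"}:
        return A_ONLY
    if roles == {"cladeB"}:
        return B_ONLY
    return MIXED


def _is_ab_binary(node: Node, smap: SpeciesMap) -> bool:
    """True when ``node`` has exactly two children, one A-only, one B-only."""
    if len(node.children) != 2:
        return False
    comps = sorted(clade_composition(c, smap) for c in node.children)
    return comps == sorted([A_ONLY, B_ONLY])


def classify_scenario(
    gene_tree: RootedTree, speciesmap: SpeciesMap, mode: str = "strict"
) -> str:
    """Assign T1/T2/T3/U to one gene tree. Symmetric in child order.

    Degenerate induced subtrees (fewer than two focal leaves, or a
    multifurcating root) are labelled U rather than raising.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    try:
        sub = induced_subtree(gene_tree, speciesmap.focal)
    except ClassifyError:
        return UNCLASSIFIED
    if len(sub.root.children) != 2:
        return UNCLASSIFIED
    x, y = sub.root.children
    cx, cy = clade_composition(x, speciesmap), clade_composition(y, speciesmap)
    if mode == "strict":
        for pure, other in ((x, y), (y, x)):
            comp = clade_composition(pure, speciesmap)
            if comp == A_ONLY and _is_ab_binary(other, speciesmap):
                return T1
            if comp == B_ONLY and _is_ab_binary(other, speciesmap):
                return T2
        if _is_ab_binary(x, speciesmap) and _is_ab_binary(y, speciesmap):
            return T3
        return UNCLASSIFIED
    # lenient: composition of the two root children only
    pair = {cx, cy}
    if pair == {A_ONLY, MIXED}:
        return T1
    if pair == {B_ONLY, MIXED}:
        return T2
    if cx == MIXED and cy == MIXED:
        return T3
    return UNCLASSIFIED


def tally_scenarios(labels):
    """Counts and fractions per label; fractions over the classified total."""
    labels = list(labels)
    counts = Counter(labels)
    total = len(labels)
    return {
        "counts": {lab: counts.get(lab, 0) for lab in LABELS},
        "fractions": {
            lab: (counts.get(lab, 0) / total if total else 0.0) for lab in LABELS
        },
        "total": total,
    }


def loss_vs_retention(results) -> float:
    """Fraction of reconciliation results with strictly more losses than
    duplications (ties count as not-greater)."""
    results = list(results)
    if not results:
        raise ValueError("no reconciliation results")
    n_more = sum(1 for r in results if r.losses > r.duplications)
    return n_more / len(results)
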