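"""Synthetic allopolyploid gene-family simulator.

Families descend from a hybridization of two diverged parental lineages:
the true history is a MUL tree in which every species of the polyploid
clade carries a ``*`` (original-position) and a ``+`` (grafted) homeolog.
Stochastic events, in order:

1. *Clade-level loss* -- four independent Bernoulli draws remove whole
   copy-clades: ``a`` = P(lose the ``+`` copy in cladeB), ``b`` = P(lose
   ``*`` in cladeB), ``c`` = P(lose ``+`` in cladeA), ``d`` = P(lose ``*``
   in cladeA).  These draws generate the T1/T2/T3/U scenario structure
   (with b = c = 0: T1 with probability a(1-d), T2 with d(1-a), T3 with
   (1-a)(1-d), U with ad).
2. *Per-leaf loss noise* -- each surviving leaf is deleted independently
   with probability ``eps``.
3. *Small-scale duplication* -- each branch duplicates its subtree with
   probability ``delta``.
4. *Gene-tree error* -- with probability ``eta`` one random
   nearest-neighbour-interchange is applied.

The true scenario label is recorded from the clade-level draws before
noise.  Loss events are recorded both as raw deleted leaves and as
maximal lost MUL subtrees (the parsimony count an LCA reconciliation
against the true MUL tree recovers, absent reciprocal whole-copy loss).
Families left with fewer than two leaves, or without their outgroup leaf
(needed for rooting), are resampled and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .candidates import H2_SELF, build_mul_tree
from .classify import classify_scenario
from .treeio import (
    LeafLabelScheme,
    Node,
    Role,
    RootedTree,
    RootingError,
    SpeciesMap,
    parse_newick,
    root_by_outgroup,
    write_newick,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_reference_fixture",
    "simulate_family",
    "simulate_dataset",
    "random_binary_tree",
]

REFERENCE_NEWICK = "(OUT,((a1,(a2,a3)),(b1,(b2,(b3,b4)))));"


def make_reference_fixture() -> tuple[RootedTree, SpeciesMap]:
    """The 8-leaf study species tree: one outgroup, a 3-taxon ladder
    (cladeA, "other"-like) and a 4-taxon ladder (cladeB, "core"-like)."""
    tree = parse_newick(REFERENCE_NEWICK, require_unique_leaves=True)
    roles = {"OUT": Role.OUTGROUP}
    roles.update({s: Role.CLADE_A for s in ("a1", "a2", "a3")})
    roles.update({s: Role.CLADE_B for s in ("b1", "b2", "b3", "b4")})
    return tree, SpeciesMap(roles)


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults are the moderate biased-loss regime used throughout the
    analysis: clade-level loss a = 0.4 (``+`` copy in cladeB) and d = 0.35
    (``*`` copy in cladeA), no cross losses (b = c = 0), 5% per-leaf loss
    noise, no small-scale duplication and no topological error.
    """

    species_tree: RootedTree | None = None
    species_map: SpeciesMap | None = None
    h1: frozenset | None = None  # default: the cladeA+cladeB ancestor
    h2: object = H2_SELF
    loss_plus_b: float = 0.4  # a
    loss_star_b: float = 0.0  # b
    loss_plus_a: float = 0.0  # c
    loss_star_a: float = 0.35  # d
    leaf_loss: float = 0.05  # eps
    dup_prob: float = 0.0  # delta
    nni_prob: float = 0.0  # eta
    n_families: int = 500
    seed: int = 0
    scheme: LeafLabelScheme = field(default_factory=LeafLabelScheme)

    def resolved(self) -> "SimConfig":
        cfg = self
        if cfg.species_tree is None or cfg.species_map is None:
            tree, smap = make_reference_fixture()
            cfg = replace(
                cfg,
                species_tree=cfg.species_tree or tree,
                species_map=cfg.species_map or smap,
            )
        if cfg.h1 is None:
            cfg = replace(cfg, h1=cfg.species_map.focal)
        for p in (
            cfg.loss_plus_b,
            cfg.loss_star_b,
            cfg.loss_plus_a,
            cfg.loss_star_a,
            cfg.leaf_loss,
            cfg.dup_prob,
            cfg.nni_prob,
        ):
            if not (0.0 <= p < 1.0):
                raise ValueError(f"probabilities must lie in [0, 1), got {p}")
        if cfg.n_families < 1:
            raise ValueError("n_families must be >= 1")
        return cfg


@dataclass
class SimTruth:
    """Ground truth for one simulated family."""

    family: str
    scenario: str  # strict label implied by the clade-level draws
    retained: frozenset  # surviving (species, copy-tag) pairs, after noise
    dup_events: int
    loss_events: int  # maximal lost MUL subtrees (parsimony count)
    leaf_losses: int  # raw deleted leaves
    nni_applied: bool


def _delete_leaves(tree: RootedTree, doomed: set) -> RootedTree | None:
    """Remove leaves whose id is in ``doomed``; suppress unary nodes."""

    def rec(n: Node) -> Node | None:
        if n.is_leaf:
            return None if id(n) in doomed else n
        kept = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        n.children = []
        for c in kept:
            n.add_child(c)
        return n

    root = rec(tree.root)
    return RootedTree(root) if root is not None else None


def _lost_subtree_events(mul: RootedTree, retained_keys: frozenset) -> int:
    """Number of maximal MUL subtrees with no surviving leaf."""
    lost: dict[int, bool] = {}
    for n in mul.postorder():
        if n.is_leaf:
            lost[id(n)] = (n.species_or_label(), n.tag) not in retained_keys
        else:
            lost[id(n)] = all(lost[id(c)] for c in n.children)
    events = 0
    for n in mul.preorder():
        if lost[id(n)] and (n.parent is None or not lost[id(n.parent)]):
            events += 1
    return events


def _apply_nni(tree: RootedTree, rng) -> bool:
    """One random NNI: swap a random child of an internal non-root node
    with that node's sibling."""
    internal = [
        n for n in tree.preorder() if not n.is_leaf and n.parent is not None
    ]
    if not internal:
        return False
    node = internal[int(rng.integers(len(internal)))]
    parent = node.parent
    sibling = next(c for c in parent.children if c is not node)
    child = node.children[int(rng.integers(len(node.children)))]
    pi = parent.children.index(sibling)
    ni = node.children.index(child)
    parent.children[pi], node.children[ni] = child, sibling
    child.parent, sibling.parent = parent, node
    return True


def simulate_family(cfg: SimConfig, rng, family_id: str = "fam0"):
    """Draw one gene family; returns ``(gene_tree, SimTruth)``.

    The gene tree is rooted by the outgroup and its leaves are labelled
    ``SPECIES@<family>_<j>``.
    """
    cfg = cfg.resolved()
    smap = cfg.species_map
    outgroup = smap.outgroup
    mul_template = build_mul_tree(cfg.species_tree, cfg.h1, cfg.h2)

    clade_probs = [
        (Role.CLADE_B, "+", cfg.loss_plus_b),
        (Role.CLADE_B, "*", cfg.loss_star_b),
        (Role.CLADE_A, "+", cfg.loss_plus_a),
        (Role.CLADE_A, "*", cfg.loss_star_a),
    ]

    for _attempt in range(1000):
        mul = mul_template.copy()
        # 1. clade-level copy loss
        doomed: set = set()
        for role, tag, p in clade_probs:
            hit = rng.random() < p
            if hit:
                for leaf in mul.leaves():
                    sp = leaf.species_or_label()
                    if leaf.tag == tag and smap.roles.get(sp) == role:
                        doomed.add(id(leaf))
        pre_noise = _delete_leaves(mul, doomed)
        if pre_noise is None:
            continue
        scenario = classify_scenario(pre_noise, smap, mode="strict")
        # 2. per-leaf loss noise
        leaves = pre_noise.leaves()
        noise_doomed = {
            id(l) for l in leaves if rng.random() < cfg.leaf_loss
        }
        tree = _delete_leaves(pre_noise, noise_doomed)
        if tree is None or tree.n_leaves < 2:
            continue
        retained = frozenset(
            (l.species_or_label(), l.tag) for l in tree.leaves()
        )
        if not any(sp == outgroup for sp, _ in retained):
            continue
        loss_events = _lost_subtree_events(mul_template, retained)
        leaf_losses = len(doomed) + len(noise_doomed)
        # 3. small-scale duplication
        dup_events = 0
        for n in list(tree.preorder()):
            if n.parent is None:
                continue
            if rng.random() < cfg.dup_prob:
                parent = n.parent
                twin = n.copy()
                joint = Node("", [n, twin])
                parent.children[parent.children.index(n)] = joint
                joint.parent = parent
                dup_events += 1
        # 4. topological error
        nni_applied = False
        if cfg.nni_prob > 0 and rng.random() < cfg.nni_prob:
            nni_applied = _apply_nni(tree, rng)
        # relabel leaves as SPECIES@family_j, drop copy tags
        for j, leaf in enumerate(tree.leaves()):
            sp = leaf.species_or_label()
            leaf.species = sp
            leaf.gene_id = f"{family_id}_{j}"
            leaf.tag = None
            leaf.label = cfg.scheme.join(sp, leaf.gene_id)
        try:
            tree = root_by_outgroup(tree, outgroup)
        except RootingError:
            # a duplication spanning the outgroup can break its monophyly;
            # such families are unrootable downstream, so redraw
            continue
        cfg.scheme.assign(tree)
        truth = SimTruth(
            family=family_id,
            scenario=scenario,
            retained=retained,
            dup_events=dup_events,
            loss_events=loss_events,
            leaf_losses=leaf_losses,
            nni_applied=nni_applied,
        )
        return tree, truth
    raise RuntimeError("family resampling failed 1000 times; check config")


def simulate_dataset(cfg: SimConfig, out_dir=None):
    """Simulate ``cfg.n_families`` families.

    Returns ``(trees, truths)``.  When ``out_dir`` is given, writes
    ``gene_trees.nwk`` (one Newick per line), ``truth.tsv``,
    ``speciesmap.tsv`` and ``config.txt``; outputs are byte-identical for
    identical seeds.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    trees, truths = [], []
    for i in range(cfg.n_families):
        tree, truth = simulate_family(cfg, rng, family_id=f"fam{i}")
        trees.append(tree)
        truths.append(truth)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "gene_trees.nwk"), "w") as fh:
            fh.write(f"# seed={cfg.seed}\n")
            for t in trees:
                fh.write(write_newick(t) + "\n")
        with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
            fh.write(
                "family\tscenario\tdup_events\tloss_events\tleaf_losses"
                "\tnni_applied\tretained\n"
            )
            for tr in truths:
                kept = ",".join(
                    f"{sp}{tag or ''}" for sp, tag in sorted(tr.retained, key=str)
                )
                fh.write(
                    f"{tr.family}\t{tr.scenario}\t{tr.dup_events}"
                    f"\t{tr.loss_events}\t{tr.leaf_losses}"
                    f"\t{int(tr.nni_applied)}\t{kept}\n"
                )
        cfg.species_map.write_tsv(os.path.join(out_dir, "speciesmap.tsv"))
        with open(os.path.join(out_dir, "config.txt"), "w") as fh:
            fh.write(f"seed\t{cfg.seed}\n")
            fh.write(f"species_tree\t{write_newick(cfg.species_tree)}\n")
            fh.write(f"h1\t{','.join(sorted(cfg.h1))}\n")
            h2 = cfg.h2 if isinstance(cfg.h2, str) else ",".join(sorted(cfg.h2))
            fh.write(f"h2\t{h2}\n")
            for k in (
                "loss_plus_b",
                "loss_star_b",
                "loss_plus_a",
                "loss_star_a",
                "leaf_loss",
                "dup_prob",
                "nni_prob",
                "n_families",
            ):
                fh.write(f"{k}\t{getattr(cfg, k)}\n")
    return trees, truths


def random_binary_tree(labels, rng) -> RootedTree:
    """Uniform-ish random rooted binary tree by sequential random joins."""
    nodes = [Node(lab) for lab in labels]
    if not nodes:
        raise ValueError("need at least one label")
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node("", [a, b]))
    return RootedTree(nodes[0])
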