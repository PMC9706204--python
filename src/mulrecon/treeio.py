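"""Rooted trees, Newick I/O, rooting and pruning.

Every other module works on :class:`RootedTree`: a minimal rooted, labeled,
multifurcation-tolerant tree.  Species trees and MUL (multi-labelled) trees
are required to be strictly bifurcating; gene trees are bifurcating by
default but polytomies can be randomly resolved on request.

Leaf labels in gene trees carry a species identifier and a gene identifier
joined by a delimiter (default ``SPECIES@gene``); species-tree leaves are
the species identifier itself, optionally suffixed by a subgenome copy tag
(``*`` or ``+``) in MUL trees.  Branch lengths and internal (support)
labels in input Newick are accepted and discarded: all downstream scoring
is topology-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

__all__ = [
    "TreeError",
    "NewickParseError",
    "RootingError",
    "PruneError",
    "Node",
    "RootedTree",
    "LeafLabelScheme",
    "Role",
    "SpeciesMap",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "root_by_outgroup",
    "prune_to",
    "resolve_polytomies",
    "canonical_form",
    "isomorphic",
]

COPY_TAGS = ("*", "+")


class TreeError(ValueError):
    """Base class for tree-structure errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; ``offset`` is the byte position of the error."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


class RootingError(TreeError):
    """Requested outgroup does not form a clade in the unrooted sense."""


class PruneError(TreeError):
    """Pruning would leave no leaves."""


class Node:
    """A tree node. Leaves carry a label and, once resolved, a species id,
    gene id and (for MUL trees) a subgenome copy tag."""

    __slots__ = ("label", "parent", "children", "species", "gene_id", "tag")

    def __init__(self, label: str = "", children: list["Node"] | None = None):
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.species: str | None = None
        self.gene_id: str | None = None
        self.tag: str | None = None
        for c in children or []:
            self.add_child(c)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def species_or_label(self) -> str:
        return self.species if self.species is not None else self.label

    def copy(self) -> "Node":
        """Deep copy of the subtree rooted here (parent left unset)."""
        n = Node(self.label)
        n.species, n.gene_id, n.tag = self.species, self.gene_id, self.tag
        for c in self.children:
            n.add_child(c.copy())
        return n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({_write_node(self)})"


class RootedTree:
    """A rooted tree with a distinguished root node."""

    def __init__(self, root: Node):
        if root is None:
            raise TreeError("empty tree")
        root.parent = None
        self.root = root

    # ---- traversal -------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def leaf_species(self) -> list[str]:
        return [n.species_or_label() for n in self.leaves()]

    # ---- structure -------------------------------------------------

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.preorder())

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy())

    def find_clade(self, leaf_set: Iterable[str], by_species: bool = True) -> Node:
        """Return the node whose descendant leaf set equals ``leaf_set``.

        Comparison is on species ids by default, raw labels otherwise.
        """
        want = frozenset(leaf_set)
        key: Callable[[Node], str] = (
            (lambda n: n.species_or_label()) if by_species else (lambda n: n.label)
        )
        sets: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[id(n)] = frozenset([key(n)])
            else:
                sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
            if sets[id(n)] == want:
                return n
        raise TreeError(f"no clade with leaf set {sorted(want)}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({write_newick(self)})"


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_RESERVED = set("(),;:")


def parse_newick(
    text: str,
    allow_multifurcations: bool = True,
    require_unique_leaves: bool = False,
) -> RootedTree:
    """Parse a single Newick tree.

    Branch lengths and internal-node labels are consumed and discarded.
    Errors report the byte offset of the offending character.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty input", 0)
    if not s.endswith(";"):
        raise NewickParseError("tree must end with ';'", len(s) - 1)
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _RESERVED and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def skip_branch_length() -> None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            if pos == start:
                raise NewickParseError("expected branch length after ':'", pos)

    def read_subtree() -> Node:
        nonlocal pos
        skip_ws()
        if pos >= len(s):
            raise NewickParseError("unexpected end of input", pos)
        if s[pos] == "(":
            open_at = pos
            pos += 1
            children = [read_subtree()]
            skip_ws()
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(read_subtree())
                skip_ws()
            if pos >= len(s) or s[pos] != ")":
                raise NewickParseError("unbalanced '('", open_at)
            pos += 1
            read_label()  # internal label: accepted, ignored
            skip_branch_length()
            node = Node("", children)
            return node
        label = read_label()
        if not label:
            raise NewickParseError("expected leaf label", pos)
        skip_branch_length()
        return Node(label)

    root = read_subtree()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise NewickParseError("trailing characters before ';'", pos)
    if root.is_leaf and not root.label:
        raise NewickParseError("empty tree", 0)
    tree = RootedTree(root)
    if not allow_multifurcations and not tree.is_binary():
        raise TreeError("tree contains multifurcations")
    if require_unique_leaves:
        labels = tree.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
    return tree


def _write_node(n: Node) -> str:
    if n.is_leaf:
        return n.label
    return "(" + ",".join(_write_node(c) for c in n.children) + ")"


def write_newick(tree: RootedTree) -> str:
    return _write_node(tree.root) + ";"


def read_newick_file(path, **kwargs) -> list[RootedTree]:
    """Read one tree per non-empty, non-comment line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                trees.append(parse_newick(line, **kwargs))
    return trees


# ---------------------------------------------------------------------------
# Leaf label scheme / species map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafLabelScheme:
    """How leaf labels encode species and gene ids (default ``SPECIES@gene``)."""

    delimiter: str = "@"
    species_first: bool = True

    def split(self, label: str) -> tuple[str, str]:
        if self.delimiter not in label:
            raise TreeError(f"leaf label {label!r} lacks delimiter {self.delimiter!r}")
        a, _, b = label.partition(self.delimiter)
        species, gene = (a, b) if self.species_first else (b, a)
        if not species or not gene:
            raise TreeError(f"leaf label {label!r} splits to empty species or gene id")
        return species, gene

    def join(self, species: str, gene: str) -> str:
        return (
            f"{species}{self.delimiter}{gene}"
            if self.species_first
            else f"{gene}{self.delimiter}{species}"
        )

    def assign(self, tree: RootedTree) -> RootedTree:
        """Set ``species``/``gene_id`` on every leaf of ``tree`` in place."""
        for leaf in tree.leaves():
            leaf.species, leaf.gene_id = self.split(leaf.label)
        return tree


class Role:
    OUTGROUP = "outgroup"
    CLADE_A = "cladeA"
    CLADE_B = "cladeB"
    OTHER = "other"
    ALL = (OUTGROUP, CLADE_A, CLADE_B, OTHER)


@dataclass
class SpeciesMap:
    """Species -> role assignment (outgroup / cladeA / cladeB / other)."""

    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, role in self.roles.items():
            if role not in Role.ALL:
                raise ValueError(f"unknown role {role!r} for species {sp!r}")

    def species_with(self, role: str) -> frozenset:
        return frozenset(sp for sp, r in self.roles.items() if r == role)

    @property
    def outgroup(self) -> str:
        og = self.species_with(Role.OUTGROUP)
        if len(og) != 1:
            raise ValueError(f"exactly one outgroup species required, got {sorted(og)}")
        return next(iter(og))

    @property
    def clade_a(self) -> frozenset:
        return self.species_with(Role.CLADE_A)

    @property
    def clade_b(self) -> frozenset:
        return self.species_with(Role.CLADE_B)

    @property
    def focal(self) -> frozenset:
        """Species of the putative polyploid clade (cladeA + cladeB)."""
        return self.clade_a | self.clade_b

    def role_of(self, species: str) -> str:
        return self.roles[species]

    @classmethod
    def read_tsv(cls, path) -> "SpeciesMap":
        roles = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated columns")
                roles[parts[0]] = parts[1]
        return cls(roles)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sp in sorted(self.roles):
                fh.write(f"{sp}\t{self.roles[sp]}\n")


# ---------------------------------------------------------------------------
# Rooting and pruning
# ---------------------------------------------------------------------------


def _leafsets(tree: RootedTree, key: Callable[[Node], str]) -> dict[int, frozenset]:
    sets: dict[int, frozenset] = {}
    for n in tree.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset([key(n)])
        else:
            sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
    return sets


def _reroot_above(tree: RootedTree, v: Node) -> RootedTree:
    """Re-root on the edge directly above ``v``; unary old root suppressed."""

    def lift(n: Node, exclude: Node) -> Node:
        rest = [c for c in n.children if c is not exclude]
        if n.parent is None:
            if len(rest) == 1:
                return rest[0]
            return Node("", rest)
        return Node("", rest + [lift(n.parent, n)])

    if v.parent is None:
        return tree
    new_root = Node("", [v, lift(v.parent, v)])
    return RootedTree(new_root)


def root_by_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Root ``tree`` so the leaves of species ``outgroup`` form one child clade.

    The input rooting is treated as arbitrary: the outgroup leaf set must be
    a clade in the *unrooted* sense, otherwise :class:`RootingError` is
    raised (callers typically log and skip such gene trees).
    """
    t = tree.copy()
    key = Node.species_or_label
    all_sp = frozenset(key(leaf) for leaf in t.leaves())
    if outgroup not in all_sp:
        raise RootingError(f"no leaf of outgroup species {outgroup!r}")
    og_leaves = frozenset(leaf.label for leaf in t.leaves() if key(leaf) == outgroup)
    rest = frozenset(leaf.label for leaf in t.leaves()) - og_leaves
    if not rest:
        raise RootingError("outgroup covers every leaf; nothing to root")
    sets = _leafsets(t, lambda n: n.label)
    pivot = None
    for n in t.preorder():
        if n.parent is None:
            continue
        if sets[id(n)] == og_leaves or sets[id(n)] == rest:
            pivot = n
            break
    if pivot is None:
        raise RootingError(
            f"outgroup species {outgroup!r} is not monophyletic in the unrooted tree"
        )
    return _reroot_above(t, pivot)


def prune_to(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Restrict ``tree`` to leaves whose species is in ``keep``.

    Unary internal nodes created by the pruning are suppressed.
    """
    keep = frozenset(keep)

    def rec(n: Node) -> Node | None:
        if n.is_leaf:
            return n.copy() if n.species_or_label() in keep else None
        kept = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(n.label, kept)

    root = rec(tree.root)
    if root is None:
        raise PruneError(f"no leaves left after pruning to {sorted(keep)}")
    return RootedTree(root)


def resolve_polytomies(tree: RootedTree, rng) -> RootedTree:
    """Arbitrarily binarize multifurcations using ``rng`` (numpy Generator)."""
    t = tree.copy()
    for n in list(t.preorder()):
        while len(n.children) > 2:
            i, j = sorted(rng.choice(len(n.children), size=2, replace=False))
            a, b = n.children[i], n.children[j]
            merged = Node("", [a, b])
            n.children = [c for c in n.children if c is not a and c is not b]
            n.add_child(merged)
    return t


# ---------------------------------------------------------------------------
# Comparison helpers
# ---------------------------------------------------------------------------


def canonical_form(tree: RootedTree):
    """Order-independent canonical representation of the labeled topology."""

    def rec(n: Node):
        if n.is_leaf:
            return n.label
        return tuple(sorted((rec(c) for c in n.children), key=repr))

    return rec(tree.root)


def isomorphic(a: RootedTree, b: RootedTree) -> bool:
    return canonical_form(a) == canonical_form(b)
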