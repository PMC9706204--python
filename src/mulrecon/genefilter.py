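"""Gene-tree filters applied before reconciliation.

Two filters are used.  The *preliminary* filter drops gene trees with more
than ``group_cap`` polyploid groups (default 8), which bounds the 2^g
assignment enumeration during MUL reconciliation.  The *deep* filter
additionally bounds the gene copy number per species (default: every
species present with 1-4 copies), which avoids overcounting reconciliation
scores in large families.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reconcile import GROUP_CAP_DEFAULT, find_polyploid_groups
from .treeio import RootedTree

__all__ = ["FilterConfig", "RejectionRecord", "preliminary_filter", "deep_filter", "filter_report"]


@dataclass(frozen=True)
class FilterConfig:
    group_cap: int = GROUP_CAP_DEFAULT
    min_copies_per_species: int = 1
    max_copies_per_species: int = 4
    require_all_species: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_copies_per_species <= self.max_copies_per_species):
            raise ValueError("require 1 <= min_copies <= max_copies")
        if self.group_cap < 1:
            raise ValueError("group_cap must be >= 1")


@dataclass(frozen=True)
class RejectionRecord:
    tree_index: int
    filter: str
    reason: str
    detail: str


def _as_indexed(gene_trees):
    items = list(gene_trees)
    if items and isinstance(items[0], tuple):
        return items
    return list(enumerate(items))


def preliminary_filter(gene_trees, duplicated_species, cfg: FilterConfig | None = None):
    """Keep trees whose polyploid-group count is within the cap.

    Accepts a plain list of trees or ``(index, tree)`` pairs; returns
    ``(kept, rejected)`` where kept preserves indexing and each rejection
    record carries the offending group count.
    """
    cfg = cfg or FilterConfig()
    kept: list[tuple[int, RootedTree]] = []
    rejected: list[RejectionRecord] = []
    for idx, tree in _as_indexed(gene_trees):
        n_groups = len(find_polyploid_groups(tree, duplicated_species))
        if n_groups <= cfg.group_cap:
            kept.append((idx, tree))
        else:
            rejected.append(
                RejectionRecord(
                    idx,
                    "preliminary",
                    "group_cap",
                    f"{n_groups} polyploid groups > cap {cfg.group_cap}",
                )
            )
    return kept, rejected


def deep_filter(gene_trees, species_universe, cfg: FilterConfig | None = None):
    """Keep trees whose per-species gene copy counts are within bounds."""
    cfg = cfg or FilterConfig()
    universe = sorted(species_universe)
    kept: list[tuple[int, RootedTree]] = []
    rejected: list[RejectionRecord] = []
    for idx, tree in _as_indexed(gene_trees):
        counts: dict[str, int] = {}
        for sp in tree.leaf_species():
            counts[sp] = counts.get(sp, 0) + 1
        offending = None
        for sp in universe:
            n = counts.get(sp, 0)
            if n == 0:
                if cfg.require_all_species:
                    offending = (sp, 0, "absent")
                    break
                continue
            if n < cfg.min_copies_per_species or n > cfg.max_copies_per_species:
                offending = (sp, n, "copy_number")
                break
        if offending is None:
            kept.append((idx, tree))
        else:
            sp, n, why = offending
            rejected.append(
                RejectionRecord(
                    idx,
                    "deep",
                    why,
                    f"species {sp} has {n} copies, allowed "
                    f"[{cfg.min_copies_per_species}, {cfg.max_copies_per_species}]",
                )
            )
    return kept, rejected


def filter_report(kept, rejected):
    """Summary DataFrame: kept count plus per-(filter, reason) rejection tallies."""
    import pandas as pd

    rows = [{"filter": "-", "reason": "kept", "n": len(kept)}]
    tally: dict[tuple[str, str], int] = {}
    for r in rejected:
        tally[(r.filter, r.reason)] = tally.get((r.filter, r.reason), 0) + 1
    for (flt, reason), n in sorted(tally.items()):
        rows.append({"filter": flt, "reason": reason, "n": n})
    return pd.DataFrame(rows)
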