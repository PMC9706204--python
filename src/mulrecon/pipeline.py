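"""Orchestration: simulate / filter / enumerate / score / classify / enrich.

``run_all`` chains the stages on a gene-tree file plus species tree and
species map, writing deterministic TSV reports to an output directory.
The two filter modes mirror the upstream workflow: the *preliminary*
dataset (group-cap filter only) and the *deep* dataset (additionally
copy-number-bounded) are scored separately and combined by summation;
scenario classification and enrichment run on the deep dataset.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from . import __version__
from .candidates import enumerate_candidates, write_candidates_tsv
from .classify import classify_scenario, loss_vs_retention, tally_scenarios
from .enrich import enrich_scenarios
from .genefilter import FilterConfig, deep_filter, filter_report, preliminary_filter
from .reconcile import (
    GroupCapExceeded,
    MappingError,
    RefIndex,
    reconcile_mul,
    reconcile_single,
    score_all,
)
from .treeio import (
    LeafLabelScheme,
    RootedTree,
    RootingError,
    SpeciesMap,
    parse_newick,
    read_newick_file,
    root_by_outgroup,
)

log = logging.getLogger("mulrecon")


@dataclass
class RunConfig:
    gene_trees: str = ""
    species_tree: str = ""
    species_map: str = ""
    categories: str | None = None
    out_dir: str = "mulrecon_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    classify_mode: str = "strict"
    candidate_ids: list[str] | None = None  # optional restriction
    enrich_universe: str = "all"  # "all" | "classified"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fc = raw.pop("filter", None)
        cfg = cls(**raw)
        if fc:
            cfg.filter = FilterConfig(**fc)
        return cfg


def _root_all(trees, outgroup):
    """Root every gene tree by the outgroup; failures are skipped and counted."""
    rooted, failed = [], []
    for i, t in enumerate(trees):
        try:
            rooted.append((i, root_by_outgroup(t, outgroup)))
        except RootingError as e:
            failed.append((i, str(e)))
    return rooted, failed


def _detail_table(indexed_trees, candidate, species_tree, group_cap):
    ref = RefIndex(candidate.mul_tree) if candidate.is_mul else RefIndex(species_tree)
    rows = []
    results = []
    for idx, tree in indexed_trees:
        try:
            if candidate.is_mul:
                res = reconcile_mul(tree, candidate, group_cap, ref=ref)
            else:
                res = reconcile_single(tree, ref)
        except (GroupCapExceeded, MappingError) as e:
            rows.append(
                {
                    "tree_index": idx,
                    "candidate_id": candidate.id,
                    "dups": "",
                    "losses": "",
                    "score": "",
                    "assignment": f"SKIPPED:{type(e).__name__}",
                }
            )
            continue
        results.append(res)
        rows.append(
            {
                "tree_index": idx,
                "candidate_id": res.candidate_id,
                "dups": res.duplications,
                "losses": res.losses,
                "score": res.total,
                "assignment": "" if res.assignment is None else "".join(res.assignment),
            }
        )
    return pd.DataFrame(rows), results


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of output paths.

    Any stage failure leaves partial outputs plus a MANIFEST naming the
    failed stage, then re-raises.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    manifest: list[str] = []
    scheme = LeafLabelScheme()

    def emit(name: str, writer) -> None:
        path = os.path.join(cfg.out_dir, name)
        writer(path)
        paths[name] = path
        manifest.append(f"OK\t{name}")

    stage = "setup"
    try:
        stage = "read-inputs"
        species_tree = parse_newick(
            open(cfg.species_tree).read(), require_unique_leaves=True
        )
        smap = SpeciesMap.read_tsv(cfg.species_map)
        raw_trees = read_newick_file(cfg.gene_trees)
        for t in raw_trees:
            scheme.assign(t)

        stage = "rooting"
        rooted, root_failed = _root_all(raw_trees, smap.outgroup)
        log.info("rooted %d/%d gene trees", len(rooted), len(raw_trees))
        # reconciliation semantics assume binary gene trees
        polytomic = [(i, t) for i, t in rooted if not t.is_binary()]
        rooted = [(i, t) for i, t in rooted if t.is_binary()]
        for i, _ in polytomic:
            log.warning("gene tree %d is multifurcating; excluded", i)

        stage = "candidates"
        cands = enumerate_candidates(species_tree)
        if cfg.candidate_ids is not None:
            want = set(cfg.candidate_ids)
            cands = [c for c in cands if c.id in want]
        emit("candidates.tsv", lambda p: write_candidates_tsv(cands, p))

        stage = "filtering"
        prelim, rej_pre = preliminary_filter(rooted, smap.focal, cfg.filter)
        deep, rej_deep = deep_filter(prelim, sorted(smap.roles), cfg.filter)
        report = filter_report(deep, rej_pre + rej_deep)
        report.loc[len(report)] = {"filter": "-", "reason": "rooting_failed",
                                   "n": len(root_failed)}
        report.loc[len(report)] = {"filter": "-", "reason": "multifurcating",
                                   "n": len(polytomic)}
        report.loc[len(report)] = {"filter": "-", "reason": "preliminary_kept",
                                   "n": len(prelim)}
        emit("filter_report.tsv", lambda p: report.to_csv(p, sep="\t", index=False))

        stage = "scoring"
        tables = {}
        for name, dataset in (("prelim", prelim), ("deep", deep)):
            df = score_all(
                [t for _, t in dataset], cands, species_tree, cfg.filter.group_cap
            )
            tables[name] = df
            emit(
                f"scores_{name}.tsv",
                lambda p, df=df: df.to_csv(p, sep="\t", index=False),
            )
        combined = (
            pd.concat(tables.values())
            .groupby("candidate_id", as_index=False, sort=False)[
                ["n_trees", "n_skipped", "sum_dups", "sum_losses", "total_score"]
            ]
            .sum()
            .sort_values("total_score", kind="stable")
            .reset_index(drop=True)
        )
        combined["rank"] = range(1, len(combined) + 1)
        emit(
            "scores_combined.tsv",
            lambda p: combined.to_csv(p, sep="\t", index=False),
        )
        best_id = combined.iloc[0]["candidate_id"]
        best = next(c for c in cands if c.id == best_id)

        stage = "best-detail"
        detail, best_results = _detail_table(
            deep, best, species_tree, cfg.filter.group_cap
        )
        emit("best_detail.tsv", lambda p: detail.to_csv(p, sep="\t", index=False))

        stage = "classification"
        labels = {
            f"tree{idx}": classify_scenario(tree, smap, cfg.classify_mode)
            for idx, tree in deep
        }
        tally = tally_scenarios(labels.values())
        tally_df = pd.DataFrame(
            {
                "label": list(tally["counts"]),
                "count": list(tally["counts"].values()),
                "fraction": list(tally["fractions"].values()),
            }
        )
        emit("scenario_tally.tsv", lambda p: tally_df.to_csv(p, sep="\t", index=False))
        frac = loss_vs_retention(best_results) if best_results else float("nan")
        emit(
            "loss_retention.txt",
            lambda p: open(p, "w").write(
                f"best_candidate\t{best_id}\nfraction_losses_gt_dups\t{frac:.6f}\n"
            ),
        )

        if cfg.categories:
            stage = "enrichment"
            fam_cats: dict[str, set] = {}
            with open(cfg.categories) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    fam, cat = line.split("\t")[:2]
                    fam_cats.setdefault(fam, set()).add(cat)
            universe = (
                [f for f, lab in labels.items() if lab != "U"]
                if cfg.enrich_universe == "classified"
                else list(labels)
            )
            enr = enrich_scenarios(labels, fam_cats, universe=universe)
            emit("enrichment.tsv", lambda p: enr.to_csv(p, sep="\t", index=False))

        stage = "log"
        emit(
            "run_log.txt",
            lambda p: open(p, "w").write(
                f"mulrecon {__version__}\nseed\t{cfg.seed}\n"
                f"n_gene_trees\t{len(raw_trees)}\n"
                f"n_rooted\t{len(rooted)}\n"
                f"n_rooting_failed\t{len(root_failed)}\n"
                f"n_preliminary\t{len(prelim)}\n"
                f"n_deep\t{len(deep)}\n"
                f"n_candidates\t{len(cands)}\n"
                f"best_candidate\t{best_id}\n"
            ),
        )
    except Exception:
        manifest.append(f"FAILED\t{stage}")
        with open(os.path.join(cfg.out_dir, "MANIFEST"), "w") as fh:
            fh.write("\n".join(manifest) + "\n")
        raise
    with open(os.path.join(cfg.out_dir, "MANIFEST"), "w") as fh:
        fh.write("\n".join(manifest) + "\n")
    paths["MANIFEST"] = os.path.join(cfg.out_dir, "MANIFEST")
    return paths


def subsample_designs(
    species_tree: RootedTree,
    speciesmap: SpeciesMap,
    k_range=(2, 6),
    n_designs: int = 16,
    seed: int = 0,
):
    """Random distinct taxon-subsampling designs of the focal clade.

    Each design keeps the outgroup and all non-focal species and restricts
    the focal (cladeA + cladeB) species to a random subset of size k with
    k in ``k_range`` (inclusive).  Deterministic given the seed; designs
    are distinct.  Returns a list of ``(kept_species, SpeciesMap)``.
    """
    import numpy as np

    focal = sorted(speciesmap.focal)
    kmin, kmax = k_range
    if not (2 <= kmin <= kmax <= len(focal) - 1):
        raise ValueError(
            f"k_range must lie within [2, {len(focal) - 1}] for {len(focal)} focal species"
        )
    tree_species = set(species_tree.leaf_species())
    pool = [
        frozenset(sub)
        for k in range(kmin, kmax + 1)
        for sub in combinations(focal, k)
    ]
    if n_designs > len(pool):
        raise ValueError(f"requested {n_designs} designs, only {len(pool)} distinct")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_designs, replace=False)
    non_focal = frozenset(speciesmap.roles) - speciesmap.focal
    designs = []
    for i in sorted(int(j) for j in chosen):
        kept = (pool[i] | non_focal) & tree_species
        roles = {sp: speciesmap.roles[sp] for sp in kept}
        designs.append((frozenset(kept), SpeciesMap(roles)))
    return designs
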