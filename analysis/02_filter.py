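"""Apply the two gene-tree filters to the simulated dataset.

Preliminary filter: at most 8 polyploid groups per gene tree (keeps the
2^g copy-assignment enumeration tractable).  Deep filter: every species
present with 1-4 gene copies (avoids overcounting reconciliation scores
in inflated families).  Writes the filter report to results/ and the
filtered tree files next to the input under scratch/sim/.

Run after 01_simulate.py:  python analysis/02_filter.py
"""

import os

from mulrecon.genefilter import FilterConfig, deep_filter, filter_report, preliminary_filter
from mulrecon.treeio import LeafLabelScheme, SpeciesMap, read_newick_file, write_newick

HERE = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(HERE, "scratch", "sim")
RESULTS = os.path.join(HERE, "results")


def main() -> None:
    smap = SpeciesMap.read_tsv(os.path.join(SCRATCH, "speciesmap.tsv"))
    scheme = LeafLabelScheme()
    trees = [
        scheme.assign(t)
        for t in read_newick_file(os.path.join(SCRATCH, "gene_trees.nwk"))
    ]
    cfg = FilterConfig()

    prelim, rej_pre = preliminary_filter(trees, smap.focal, cfg)
    deep, rej_deep = deep_filter(prelim, sorted(smap.roles), cfg)

    for name, dataset in (("prelim", prelim), ("deep", deep)):
        with open(os.path.join(SCRATCH, f"gene_trees_{name}.nwk"), "w") as fh:
            for idx, t in dataset:
                fh.write(write_newick(t) + "\n")

    report = filter_report(deep, rej_pre + rej_deep)
    os.makedirs(RESULTS, exist_ok=True)
    report.to_csv(os.path.join(RESULTS, "02_filter_report.tsv"), sep="\t", index=False)

    print(f"input trees:        {len(trees)}")
    print(f"preliminary kept:   {len(prelim)}  (rejected {len(rej_pre)})")
    print(f"deep kept:          {len(deep)}  (rejected {len(rej_deep)})")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
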