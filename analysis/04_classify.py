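"""Classify each deep-filtered gene family into a retention/loss scenario
and measure loss dominance against the best-fitting reference.

T1 = one homeolog lost in the core-like clade, T2 = one lost in the
other-like clade, T3 = both retained, U = unclassified (reciprocal loss,
noise).  Also reports the fraction of families with more losses than
duplications under the winning MUL tree.

Run after 03_score_candidates.py:  python analysis/04_classify.py
"""

import os

import pandas as pd

from mulrecon.candidates import enumerate_candidates
from mulrecon.classify import classify_scenario, loss_vs_retention, tally_scenarios
from mulrecon.reconcile import GroupCapExceeded, reconcile_mul, reconcile_single
from mulrecon.simulate import make_reference_fixture
from mulrecon.treeio import LeafLabelScheme, read_newick_file

HERE = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(HERE, "scratch", "sim")
RESULTS = os.path.join(HERE, "results")


def main() -> None:
    tree, smap = make_reference_fixture()
    scheme = LeafLabelScheme()
    trees = [
        scheme.assign(t)
        for t in read_newick_file(os.path.join(SCRATCH, "gene_trees_deep.nwk"))
    ]

    combined = pd.read_csv(os.path.join(RESULTS, "03_scores_combined.tsv"), sep="\t")
    best_id = combined.iloc[0]["candidate_id"]
    best = next(c for c in enumerate_candidates(tree) if c.id == best_id)

    labels = [classify_scenario(t, smap, "strict") for t in trees]
    tally = tally_scenarios(labels)
    df = pd.DataFrame(
        {
            "label": list(tally["counts"]),
            "count": list(tally["counts"].values()),
            "fraction": list(tally["fractions"].values()),
        }
    )
    df.to_csv(os.path.join(RESULTS, "04_scenario_tally.tsv"), sep="\t", index=False)

    results = []
    for t in trees:
        try:
            if best.is_mul:
                results.append(reconcile_mul(t, best))
            else:
                results.append(reconcile_single(t, tree))
        except GroupCapExceeded:
            continue
    frac = loss_vs_retention(results)
    with open(os.path.join(RESULTS, "04_loss_retention.txt"), "w") as fh:
        fh.write(f"best_candidate\t{best_id}\n")
        fh.write(f"fraction_losses_gt_dups\t{frac:.4f}\n")

    print(f"classified {tally['total']} deep-filtered families (strict mode):")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print(f"\nbest candidate: {best_id}")
    print(f"fraction of families with losses > duplications: {frac:.3f}")


if __name__ == "__main__":
    main()
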