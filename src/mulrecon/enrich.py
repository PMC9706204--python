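"""Per-scenario functional-category over-representation.

For each retention/loss scenario the families carrying a category are
tested for over-representation with the upper-tail hypergeometric
distribution (one-sided: the analysis asks which functions are *biased
toward* a scenario), followed by Benjamini-Hochberg false-discovery-rate
adjustment within each scenario.  Both statistics are implemented from
first principles and cross-checked against library implementations in the
test suite.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, exp, lgamma

__all__ = ["hypergeom_upper", "bh_adjust", "enrich_scenarios"]

_EXACT_N_MAX = 2000


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of marked items, n the draw size,
    k the observed number of marked draws.  Exact rational arithmetic is
    used for N <= 2000; larger instances fall back to stable log-binomials.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int,)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError("require K <= N and n <= N")
    if k > min(K, n):
        raise ValueError("require k <= min(K, n)")
    lo = max(k, n - (N - K))  # smallest feasible draw count
    hi = min(K, n)
    if k <= max(0, n - (N - K)):
        return 1.0
    if N <= _EXACT_N_MAX:
        num = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1))
        return float(Fraction(num, comb(N, n)))
    logc = lambda a, b: lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)
    log_den = logc(N, n)
    terms = [logc(K, i) + logc(N - K, n - i) - log_den for i in range(lo, hi + 1)]
    m = max(terms)
    return min(1.0, exp(m) * sum(exp(t - m) for t in terms))


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1.
    """
    ps = list(pvalues)
    m = len(ps)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: ps[i])
    qs = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, ps[i] * m / (pos + 1))
        qs[i] = running
    return qs


def enrich_scenarios(
    family_labels,
    family_categories,
    universe=None,
    scenarios=("T1", "T2", "T3"),
):
    """Per-scenario category enrichment table.

    Parameters
    ----------
    family_labels : mapping family id -> scenario label (T1/T2/T3/U)
    family_categories : mapping family id -> iterable of category ids
        (families may carry several categories or none; unannotated
        families stay in the universe but contribute to no category count)
    universe : iterable of family ids, default all labelled families
    scenarios : which labels get an enrichment panel

    Returns a pandas DataFrame with columns scenario, category, k, n, K, N,
    p, q; BH adjustment applied within each scenario; rows ordered by
    (scenario, ascending p, category id).
    """
    import pandas as pd

    if universe is None:
        universe = list(family_labels)
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    cats_of = {f: frozenset(family_categories.get(f, ())) for f in universe}
    all_cats = sorted(set().union(*cats_of.values()) if universe else ())
    K = {c: sum(1 for f in universe if c in cats_of[f]) for c in all_cats}

    rows = []
    for scen in scenarios:
        members = [f for f in universe if family_labels.get(f) == scen]
        n = len(members)
        if n == 0:
            continue
        scen_rows = []
        for c in all_cats:
            k = sum(1 for f in members if c in cats_of[f])
            p = hypergeom_upper(k, K[c], n, N)
            scen_rows.append(
                {"scenario": scen, "category": c, "k": k, "n": n, "K": K[c], "N": N, "p": p}
            )
        qs = bh_adjust([r["p"] for r in scen_rows])
        for r, q in zip(scen_rows, qs):
            r["q"] = q
        scen_rows.sort(key=lambda r: (r["p"], r["category"]))
        rows.extend(scen_rows)
    return pd.DataFrame(
        rows, columns=["scenario", "category", "k", "n", "K", "N", "p", "q"]
    )
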