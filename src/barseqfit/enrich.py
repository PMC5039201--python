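"""Term enrichment in hit lists and overlap significance between hit lists.

A local stand-in for database-backed GO enrichment: terms come from a flat
gene→term annotation table, each term is tested with an upper-tail
hypergeometric test against the analysis universe (the strains retained
after filtering), and p-values are Holm-adjusted across terms. Overlap
between two hit lists (the Venn analysis) is tested with a one-sided
Fisher's exact test for enrichment of co-membership.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from .core import OverlapResult
from .stats import adjust_bh, adjust_holm


def hypergeometric_enrichment(hit_set, universe, annotation: pd.DataFrame,
                              min_term_size: int = 3,
                              method: str = "holm") -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every annotated term.

    For a term with K genes in the universe, a hit list of size n out of N
    universe genes, and k hits in the term, p = P(X >= k) for
    X ~ Hypergeom(N, K, n). Terms with fewer than ``min_term_size`` universe
    genes are skipped. ``method`` selects the multiplicity adjustment
    ("holm" default, "bh" available); rows are sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_set) & universe
    N, n = len(universe), len(hits)
    ann = annotation[annotation["gene"].isin(universe)]
    rows = []
    for term, genes in ann.groupby("term")["gene"]:
        members = set(genes)
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "hits_in_term", "term_size",
                                      "hit_count", "universe_size", "p_value"])
    if len(out):
        adjust = {"holm": adjust_holm, "bh": adjust_bh}[method]
        out["p_holm"] = adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_holm"] = []
    return out


def overlap_test(list_a, list_b, universe) -> OverlapResult:
    """One-sided Fisher's exact test for overlap between two hit lists.

    Tests enrichment of co-membership in the 2x2 table
    (in A / not in A) x (in B / not in B) over the universe, and reports
    the four Venn region counts.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(list_a) & universe
    b = set(list_b) & universe
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ]
    _, p = fisher_exact(table, alternative="greater")
    return OverlapResult(n_a=len(a), n_b=len(b), n_intersection=k,
                         universe_size=len(universe), fisher_p=float(p))
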