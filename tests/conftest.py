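import numpy as np
import pandas as pd
import pytest

import barseqfit as bf


@pytest.fixture(scope="session")
def small_catalog():
    return bf.generate_catalog(30, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_catalog):
    return bf.generate_truth(small_catalog, seed=12)


@pytest.fixture(scope="session")
def samplesheet_hom():
    return bf.make_samplesheet("homozygous", seed=13)


@pytest.fixture(scope="session")
def small_tag_counts(small_catalog, small_truth):
    """Tag counts for all 12 homozygous samples of the small library."""
    cols = {}
    for c, cond in enumerate(["t0", "basal", "glucose", "sorbitol"]):
        sim = bf.simulate_competition(
            small_catalog, small_truth, cond, 0 if cond == "t0" else 10,
            depth=5000, seed=20 + c)
        for r in range(1, 4):
            cols[f"hom_{cond}_{r}"] = sim.tag_counts[f"rep{r}"]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def hamming_oracle(a: str, b: str) -> int:
    n = 0
    for i in range(len(a)):
        if a[i] != b[i]:
            n += 1
    return n


def assign_oracle(window: str, catalog: pd.DataFrame, max_mismatch: int = 2):
    """Brute-force nearest-tag scan over the catalog, pure python."""
    best = []
    best_d = None
    for row in catalog.itertuples(index=False):
        for kind, tag in (("up", row.up_tag), ("down", row.down_tag)):
            d = hamming_oracle(window, tag)
            if best_d is None or d < best_d:
                best, best_d = [(row.strain_id, kind)], d
            elif d == best_d:
                best.append((row.strain_id, kind))
    if best_d > max_mismatch:
        return "unassigned_tag"
    if len(best) > 1:
        return "ambiguous_tag"
    return best[0]


def qt_oracle(D, diameter, min_size):
    """Brute-force QT clustering: every seed, naive greedy growth."""
    n = len(D)
    active = set(range(n))
    clusters = []
    while len(active) >= min_size:
        best = None
        for seed in sorted(active):
            members = [seed]
            while True:
                cand_j, cand_d = None, None
                for j in sorted(active):
                    if j in members:
                        continue
                    dmax = max(D[j][m] for m in members)
                    pts = members + [j]
                    newdiam = max(D[a][b] for a in pts for b in pts)
                    if newdiam <= diameter and (cand_d is None or dmax < cand_d):
                        cand_j, cand_d = j, dmax
                if cand_j is None:
                    break
                members.append(cand_j)
            if best is None or len(members) > len(best):
                best = members
        if best is None or len(best) < min_size:
            break
        clusters.append(sorted(best))
        active -= set(best)
    return clusters, sorted(active)


def exact_test_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Conditional exact p by explicit scipy-pmf enumeration of all splits."""
    from scipy.stats import binom, nbinom

    total = sum_a + sum_b
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi == 0:
        pr = binom.pmf(s, total, n_a / (n_a + n_b))
    else:
        pr = nbinom.pmf(s, n_a / phi, 0.5) * nbinom.pmf(total - s, n_b / phi, 0.5)
    pr = pr / pr.sum()
    return float(pr[pr <= pr[sum_a] * (1 + 1e-12)].sum())


def bh_oracle(p):
    """Step-up BH adjusted values, recomputed from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.clip(adj, 0, 1)


def holm_oracle(p):
    """Step-down Holm adjusted values, recomputed from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, p[i] * (m - rank + 1))
        adj[i] = min(running, 1.0)
    return adj
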