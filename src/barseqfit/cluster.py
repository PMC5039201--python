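"""Quality-threshold (QT) clustering of strain abundance profiles.

Profiles are per-strain log2 abundance ratios of each competition sample
against the mean time-zero abundance, and distances are 1 - Pearson
correlation (a jackknifed variant is available). QT clustering grows a
candidate cluster around every possible seed under a hard diameter cap,
keeps the largest candidate, removes it, and repeats until no candidate
reaches the minimum population — no preset number of clusters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import ClusterAssignment


def pearson_distance(x, y) -> float:
    """1 - Pearson correlation; 0 for identical shapes, 2 for anticorrelated."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance profile")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pearson":
        D = 1.0 - np.corrcoef(X)
    elif metric == "jackknife":
        # leave-one-sample-out Pearson; keep the most pessimistic (lowest)
        # correlation, as in the jackknife-correlation option of MeV's QTC
        p = X.shape[1]
        corr_min = np.full((X.shape[0], X.shape[0]), np.inf)
        for drop in range(p):
            sub = np.delete(X, drop, axis=1)
            corr_min = np.minimum(corr_min, np.corrcoef(sub))
        corr_min = np.minimum(corr_min, np.corrcoef(X))
        D = 1.0 - corr_min
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def profile_matrix(counts: pd.DataFrame, samplesheet: pd.DataFrame,
                   prior: float = 0.5) -> pd.DataFrame:
    """Per-strain log2 CPM ratios of each competition sample vs mean t0 CPM.

    Entry (strain, sample) = log2((CPM + prior) / (mean t0 CPM + prior)).
    Columns are the non-t0 samples ordered basal, glucose, sorbitol and by
    replicate within each condition. Counts-per-million normalisation makes
    the matrix invariant under per-sample rescaling of counts.
    """
    sheet = samplesheet.set_index("sample_id")
    t0_samples = [s for s in counts.columns if s in sheet.index and sheet.loc[s, "condition"] == "t0"]
    if not t0_samples:
        raise ValueError("no t0 samples found")
    order = {"basal": 0, "glucose": 1, "sorbitol": 2}
    comp = [s for s in counts.columns if s in sheet.index and sheet.loc[s, "condition"] != "t0"]
    comp.sort(key=lambda s: (order.get(sheet.loc[s, "condition"], 99), sheet.loc[s, "replicate"]))
    cpm = counts.astype(float) / counts.sum(axis=0) * 1e6
    t0_mean = cpm[t0_samples].mean(axis=1)
    out = np.log2(cpm[comp].add(prior).div(t0_mean + prior, axis=0))
    return out


def qt_cluster(profiles: pd.DataFrame, diameter: float = 0.25,
               min_size: int = 25, metric: str = "pearson") -> ClusterAssignment:
    """Classic QT clustering under a maximum-diameter constraint.

    For every seed strain a candidate cluster grows greedily: at each step
    the strain whose addition least increases the cluster diameter (the max
    pairwise distance, tracked as max distance to current members) joins,
    as long as the diameter stays <= ``diameter``; ties break by ascending
    strain index. The largest candidate wins (ties by lowest seed index),
    its members are removed, and the search repeats until no candidate has
    >= ``min_size`` members. Zero-variance profiles are excluded up front
    with a warning. Fully deterministic.
    """
    X = profiles.to_numpy(dtype=float)
    ids = np.asarray(profiles.index)
    keep = X.std(axis=1) > 0
    dropped = [str(s) for s in ids[~keep]]
    if dropped:
        warnings.warn(f"excluding {len(dropped)} zero-variance profiles")
    X, ids = X[keep], ids[keep]
    n = len(ids)
    if n == 0:
        return ClusterAssignment(clusters=[], unclustered=dropped, diameters=[])
    D = _distance_matrix(X, metric)

    active = np.ones(n, dtype=bool)
    clusters: list[list[str]] = []
    diameters: list[float] = []
    INF = np.inf
    while active.sum() >= min_size:
        best_members: np.ndarray | None = None
        seeds = np.nonzero(active)[0]
        for seed in seeds:
            members = [seed]
            maxd = D[seed].copy()
            maxd[~active] = INF
            maxd[seed] = INF
            while True:
                j = int(np.argmin(maxd))
                if maxd[j] > diameter:
                    break
                members.append(j)
                np.maximum(maxd, D[j], out=maxd)
                maxd[j] = INF
            if best_members is None or len(members) > len(best_members):
                best_members = np.array(sorted(members))
        if best_members is None or len(best_members) < min_size:
            break
        sub = D[np.ix_(best_members, best_members)]
        clusters.append([str(s) for s in ids[best_members]])
        diameters.append(float(sub.max()))
        active[best_members] = False
    unclustered = [str(s) for s in ids[active]] + dropped
    return ClusterAssignment(clusters=clusters, unclustered=unclustered,
                             diameters=diameters)
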