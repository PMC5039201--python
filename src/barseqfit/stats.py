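"""Negative-binomial differential-fitness testing with a common dispersion.

The model: strain counts are negative-binomial with a single overdispersion
parameter phi shared by all strains (variance = mu + phi*mu^2; phi = 0 is
Poisson). After scaling every sample to a common library size, phi is
estimated by maximising the conditional log-likelihood of within-group
replicate counts given their group totals (conditioning removes the
per-strain mean parameter when library sizes are equal). A pairwise
contrast is then tested per strain with a conditional NB exact test: the
two group sums, given their total, follow a discrete law whose probabilities
are summed over all outcomes no more likely than the observed split —
the two-sided exact-test convention used for RNA-seq style count data.

logFC is the log2 ratio of mean counts-per-million between groups with a
0.5 pseudo-count (at the average library size) guarding against zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core import DispersionEstimate

DELTA_LO = 1e-6
DELTA_HI = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# library-size equalisation

def equalize_libraries(counts: pd.DataFrame,
                       library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size.

    Column j is multiplied by (geometric mean of library sizes) / (library
    size of j); adjusted values may be fractional. With equal library sizes
    this is the identity.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.astype(float)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"zero/negative library size for samples {bad}")
    geo = float(np.exp(np.mean(np.log(library_sizes))))
    return counts * (geo / library_sizes)


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)

def _group_matrix(counts: pd.DataFrame, groups) -> dict[str, np.ndarray]:
    groups = pd.Series(groups, index=counts.columns) if not isinstance(groups, pd.Series) else groups
    out = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        out[str(g)] = counts[cols].to_numpy(dtype=float)
    return out


def _conditional_loglik(delta: float, grouped: list[np.ndarray]) -> float:
    """Conditional NB log-likelihood at delta = phi/(1+phi), summed over strains."""
    r = (1.0 - delta) / delta  # 1/phi
    ll = 0.0
    for Y in grouped:
        n = Y.shape[1]
        z = Y.sum(axis=1)
        ll += float(
            gammaln(Y + r).sum()
            - Y.shape[0] * n * gammaln(r)
            - gammaln(Y + 1.0).sum()
            + gammaln(z + 1.0).sum()
            + Y.shape[0] * gammaln(n * r)
            - gammaln(z + n * r).sum()
        )
    return ll


def estimate_common_dispersion(counts: pd.DataFrame, groups,
                               tol: float = 1e-6) -> DispersionEstimate:
    """Estimate the common NB dispersion by conditional maximum likelihood.

    ``counts`` should be library-equalised and rounded to integers; ``groups``
    labels each column. Only groups with >= 2 replicates contribute. The
    conditional log-likelihood is maximised by golden-section search over
    delta = phi/(1+phi) in (1e-6, 1-1e-6).
    """
    grouped = [Y for Y in _group_matrix(counts, groups).values() if Y.shape[1] >= 2]
    if not grouped:
        raise ValueError("need at least one group with >= 2 replicate samples")
    if all((Y == 0).all() for Y in grouped):
        raise ValueError("all counts are zero")
    grouped = [np.round(Y) for Y in grouped]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = DELTA_LO, DELTA_HI
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _conditional_loglik(c, grouped)
    fd = _conditional_loglik(d, grouped)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _conditional_loglik(c, grouped)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _conditional_loglik(d, grouped)
    delta = (a + b) / 2.0
    phi = delta / (1.0 - delta)
    return DispersionEstimate(phi=phi, log_likelihood_at_max=_conditional_loglik(delta, grouped))


# ---------------------------------------------------------------------------
# conditional NB exact test

def _split_logpmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log-probabilities of every split (s, total-s) of the group-sum total.

    Group sums are NB with sizes n_a/phi and n_b/phi and means proportional
    to n_a, n_b; conditioning on the total cancels the shared success
    probability, leaving an integer law on s = 0..total. phi = 0 is the
    Poisson limit, Binomial(total, n_a/(n_a+n_b)).
    """
    s = np.arange(total + 1, dtype=float)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        lw = (
            gammaln(total + 1.0) - gammaln(s + 1.0) - gammaln(total - s + 1.0)
            + s * np.log(p) + (total - s) * np.log1p(-p)
        )
        return lw - logsumexp(lw)
    r_a, r_b = n_a / phi, n_b / phi
    lw = (
        gammaln(s + r_a) - gammaln(s + 1.0)
        + gammaln(total - s + r_b) - gammaln(total - s + 1.0)
    )
    return lw - logsumexp(lw)


def exact_test_sums(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float,
                    two_sided: str = "less-likely") -> float:
    """Conditional NB exact p-value for observed group sums.

    ``two_sided="less-likely"`` (default) sums P(s) over all splits with
    P(s) <= P(observed) (with a 1e-12 relative tolerance for ties);
    ``"doubled"`` doubles the smaller tail probability, capped at 1.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    sum_a, sum_b = int(round(sum_a)), int(round(sum_b))
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    logp = _split_logpmf(total, n_a, n_b, phi)
    p = np.exp(logp)
    if two_sided == "less-likely":
        obs = p[sum_a]
        return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))
    if two_sided == "doubled":
        lo = p[: sum_a + 1].sum()
        hi = p[sum_a:].sum()
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown two_sided rule {two_sided!r}")


def exact_test(strain_counts, groups, phi: float,
               two_sided: str = "less-likely") -> float:
    """Exact test for one strain's library-equalised counts.

    ``strain_counts`` is one row of the adjusted count matrix; ``groups``
    gives the two group labels in column order. Adjusted sums are rounded
    to the nearest integer (the conditional law lives on integers).
    """
    y = np.asarray(strain_counts, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exact_test requires exactly two groups")
    a, b = labels
    sa = y[groups == a].sum()
    sb = y[groups == b].sum()
    return exact_test_sums(int(round(sa)), int(round(sb)),
                           int((groups == a).sum()), int((groups == b).sum()),
                           phi, two_sided)


# ---------------------------------------------------------------------------
# effect size and multiplicity

def log_fold_change(strain_counts, groups, library_sizes, prior: float = 0.5) -> float:
    """log2 fold-change of normalised abundance, group B over group A.

    Counts are normalised to counts-per-million; the prior acts as ``prior``
    pseudo-counts at the average library size, keeping the ratio finite when
    one group is absent.
    """
    y = np.asarray(strain_counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("log_fold_change requires exactly two groups")
    a, b = labels
    cpm = y / lib * 1e6
    prior_cpm = prior / lib.mean() * 1e6
    mean_a = cpm[groups == a].mean()
    mean_b = cpm[groups == b].mean()
    return float(np.log2((mean_b + prior_cpm) / (mean_a + prior_cpm)))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR-adjusted values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_holm(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _check_p(p: np.ndarray) -> None:
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# per-contrast driver

def fitness_table(counts: pd.DataFrame, samples_a: list[str], samples_b: list[str],
                  phi: float | None = None, prior: float = 0.5,
                  lfc_threshold: float = 1.0, alpha: float = 0.05,
                  two_sided: str = "less-likely") -> pd.DataFrame:
    """Full per-strain fitness table for the contrast B vs A.

    Steps: equalise library sizes across the involved samples, round,
    estimate the common dispersion (unless ``phi`` is given), run the
    conditional exact test per strain, compute logFC from the raw counts,
    and attach BH-FDR and Holm adjustments plus an UP/DOWN/NS direction
    call at (``alpha``, ``lfc_threshold``). The dispersion used is stored
    in ``table.attrs["dispersion"]``.
    """
    cols = list(samples_a) + list(samples_b)
    sub = counts[cols]
    groups = np.array(["A"] * len(samples_a) + ["B"] * len(samples_b))
    lib = sub.sum(axis=0).astype(float)
    adj = np.round(equalize_libraries(sub, lib).to_numpy())
    if phi is None:
        phi = estimate_common_dispersion(
            pd.DataFrame(adj, index=sub.index, columns=cols), groups
        ).phi

    n_a, n_b = len(samples_a), len(samples_b)
    sums_a = adj[:, : n_a].sum(axis=1).round().astype(np.int64)
    sums_b = adj[:, n_a:].sum(axis=1).round().astype(np.int64)
    cache: dict[tuple[int, int], float] = {}
    pvals = np.empty(len(sub))
    for i, (sa, sb) in enumerate(zip(sums_a, sums_b)):
        key = (int(sa), int(sb))
        p = cache.get(key)
        if p is None:
            p = exact_test_sums(sa, sb, n_a, n_b, phi, two_sided)
            cache[key] = p
        pvals[i] = p

    raw = sub.to_numpy(dtype=float)
    cpm = raw / lib.to_numpy() * 1e6
    prior_cpm = prior / lib.mean() * 1e6
    mean_a = cpm[:, : n_a].mean(axis=1)
    mean_b = cpm[:, n_a:].mean(axis=1)
    lfc = np.log2((mean_b + prior_cpm) / (mean_a + prior_cpm))

    table = pd.DataFrame(
        {
            "strain_id": sub.index.to_numpy(),
            "logFC": lfc,
            "p_value": pvals,
            "fdr_bh": adjust_bh(pvals),
            "p_holm": adjust_holm(pvals),
        }
    ).set_index("strain_id")
    call_hits(table, lfc_threshold=lfc_threshold, alpha=alpha)
    table.attrs["dispersion"] = float(phi)
    return table


def call_hits(table: pd.DataFrame, lfc_threshold: float = 1.0,
              alpha: float = 0.05, method: str = "holm"):
    """Call UP/DOWN hits and set the table's ``direction`` column.

    DOWN: adjusted p < alpha and logFC < -lfc_threshold; UP: adjusted p <
    alpha and logFC > lfc_threshold; NS otherwise. ``method`` selects the
    Holm-adjusted p (default, the hit-calling rule) or the BH FDR. Returns
    ``(up_ids, down_ids)``.
    """
    col = {"holm": "p_holm", "bh": "fdr_bh"}[method]
    sig = table[col] < alpha
    up = sig & (table["logFC"] > lfc_threshold)
    down = sig & (table["logFC"] < -lfc_threshold)
    direction = np.where(up, "UP", np.where(down, "DOWN", "NS"))
    table["direction"] = direction
    return list(table.index[up]), list(table.index[down])
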