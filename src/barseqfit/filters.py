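"""Noise-reduction filters applied before the fitness analysis.

Two independent rules remove strains whose counts cannot support reliable
inference:

* the low-abundance rule drops strains represented by less than a fraction
  (default 10%) of the average per-strain counts across the reference
  samples (time zero plus basal-medium competitions);
* the reliability rule drops genes whose homozygous deletion looks neutral
  or better in basal medium (logFC > 0) while the heterozygote is strongly
  impaired there (logFC < -3 at FDR < 0.05) — the signature of extragenic
  suppressors accumulated in the homozygous collection, whose phenotype
  would not reflect the deleted gene.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .core import FilterReport


def low_abundance_filter(counts: pd.DataFrame, reference_samples: list[str],
                         threshold_frac: float = 0.10,
                         normalized: bool = False) -> set[str]:
    """Strains below ``threshold_frac`` of the mean per-strain total.

    The per-strain total T_i sums raw counts over the reference samples
    (time zero and basal competitions taken together); strain i is removed
    iff T_i < threshold_frac * mean(T). With ``normalized=True`` counts are
    first scaled to counts-per-million per sample.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    sub = counts[reference_samples].astype(float)
    if normalized:
        sub = sub / sub.sum(axis=0) * 1e6
    totals = sub.sum(axis=1)
    cutoff = threshold_frac * totals.mean()
    return set(totals.index[totals < cutoff])


def reliability_filter(hom_basal: pd.DataFrame, het_basal: pd.DataFrame,
                       hom_lfc_min: float = 0.0, het_lfc_max: float = -3.0,
                       het_fdr_max: float = 0.05) -> set[str]:
    """Genes with discordant homozygous/heterozygous basal fitness.

    Both tables are basal-vs-t0 fitness tables indexed by gene (columns
    logFC, fdr_bh). A gene is flagged unreliable iff its homozygous logFC >
    ``hom_lfc_min`` and its heterozygous logFC < ``het_lfc_max`` with FDR <
    ``het_fdr_max``. Genes present in only one collection are skipped with
    a warning.
    """
    common = hom_basal.index.intersection(het_basal.index)
    skipped = len(hom_basal.index.symmetric_difference(het_basal.index))
    if skipped:
        warnings.warn(f"{skipped} genes present in only one collection; skipped")
    hom = hom_basal.loc[common]
    het = het_basal.loc[common]
    flagged = (
        (hom["logFC"] > hom_lfc_min)
        & (het["logFC"] < het_lfc_max)
        & (het["fdr_bh"] < het_fdr_max)
    )
    return set(common[flagged])


def combine_filters(low_set: set[str], unreliable_set: set[str],
                    all_strains) -> FilterReport:
    """Union the two removal sets and report their overlap and the remainder."""
    all_strains = set(all_strains)
    if not low_set <= all_strains or not unreliable_set <= all_strains:
        raise ValueError("removal sets must be subsets of all_strains")
    low = set(low_set)
    unrel = set(unreliable_set)
    return FilterReport(
        removed_low_abundance=low,
        removed_unreliable=unrel,
        overlap=low & unrel,
        retained=all_strains - (low | unrel),
    )
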