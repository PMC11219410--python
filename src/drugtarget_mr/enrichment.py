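"""Tissue enrichment of a gene set: tissue-specific sets, fold change, hypergeometric p.

A gene is tissue-specific when its expression in a tissue is at least
``specificity_fold`` times its mean expression over the remaining tissues.  For
each tissue the drug-target set's overlap with the tissue-specific set is
scored by fold enrichment (k/n)/(K/N) and a hypergeometric upper-tail p,
Benjamini-Hochberg adjusted across tissues; the significance call combines a
fold-change cut of 2 with adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "tissue_specific_sets", "enrich", "hypergeom_upper_tail"]


@dataclass
class EnrichmentResult:
    tissue: str
    k: int       # target genes in the tissue set
    n: int       # target genes tested
    K: int       # tissue-set size
    N: int       # background size
    fold: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False


def tissue_specific_sets(
    expr: pd.DataFrame, specificity_fold: float = 5.0
) -> dict[str, set[str]]:
    """Tissue -> set of genes expressed >= specificity_fold x mean of other tissues.

    ``expr`` is a genes x tissues table of non-negative expression values.
    Genes with zero expression everywhere belong to no set; a gene whose other
    tissues are all zero belongs to any tissue where it is expressed at all.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two tissues to define specificity")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    sets: dict[str, set[str]] = {}
    total = expr.sum(axis=1)
    n_tissues = expr.shape[1]
    for tissue in expr.columns:
        other_mean = (total - expr[tissue]) / (n_tissues - 1)
        in_set = (expr[tissue] >= specificity_fold * other_mean) & (expr[tissue] > 0)
        sets[str(tissue)] = set(expr.index[in_set])
    return sets


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): chance of >= k tissue genes in a draw of n."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    targets: set[str],
    sets: dict[str, set[str]],
    background: set[str],
    fold_cut: float = 2.0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-tissue fold enrichment and hypergeometric significance of the target set."""
    if not targets:
        return []
    if not targets <= background:
        raise ValueError("targets must be a subset of the background")
    n = len(targets)
    n_bg = len(background)
    results = []
    for tissue in sorted(sets):
        tissue_set = sets[tissue] & background
        big_k = len(tissue_set)
        k = len(targets & tissue_set)
        fold = (k / n) / (big_k / n_bg) if big_k > 0 else 0.0
        p = hypergeom_upper_tail(k, n, big_k, n_bg)
        results.append(EnrichmentResult(tissue, k, n, big_k, n_bg, fold, p))
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
            r.significant = (r.fold >= fold_cut) and (r.p_adj < alpha)
    return results
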