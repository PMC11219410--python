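"""Summary-data Mendelian randomization: Wald ratio, SMR test, multi-SNP SMR.

The causal effect of gene expression x on outcome y is estimated from two sets
of summary statistics at a shared instrument g as the Wald ratio
b_xy = b_gy / b_gx.  The SMR test statistic combines the two Wald chi-squares,

    T_SMR = z_gx^2 * z_gy^2 / (z_gx^2 + z_gy^2),

referred to chi-square(1).  The multi-SNP extension sums per-SNP T_SMR over an
LD-pruned set of cis instruments; under the null the sum is distributed as an
eigenvalue-weighted combination of chi-square(1) variables, with weights from
the LD correlation matrix of the retained SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import Instrument
from .quadform import weighted_chi2_sf
from .sumstats import LDMatrix, SumstatsSet, harmonize

__all__ = [
    "SMRResult",
    "wald_ratio",
    "smr_test",
    "smr_multi",
    "to_odds_ratio",
    "prune_by_ld",
]


@dataclass
class SMRResult:
    """Per-gene SMR summary (one results-table row)."""

    gene_id: str
    top_rsid: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_smr_multi: Optional[float] = None
    n_multi_snps: int = 0


def wald_ratio(b_gx: float, se_gx: float, b_gy: float, se_gy: float) -> tuple[float, float]:
    """Single-instrument causal estimate b_gy/b_gx with its delta-method SE."""
    if b_gx == 0:
        raise ZeroDivisionError("exposure effect b_gx is zero")
    if se_gx <= 0 or se_gy <= 0:
        raise ValueError("standard errors must be > 0")
    b_xy = b_gy / b_gx
    var = se_gy**2 / b_gx**2 + b_gy**2 * se_gx**2 / b_gx**4
    return b_xy, math.sqrt(var)


def smr_test(b_gx: float, se_gx: float, b_gy: float, se_gy: float) -> tuple[float, float, float]:
    """SMR chi-square statistic, its p-value, and the SMR-implied SE of b_xy.

    The SE is defined through |b_xy| / sqrt(T_SMR) so that the two-sided normal
    p of b_xy/se equals the chi-square(1) p of T_SMR.
    """
    if se_gx <= 0 or se_gy <= 0:
        raise ValueError("standard errors must be > 0")
    z_gx = b_gx / se_gx
    z_gy = b_gy / se_gy
    denom = z_gx**2 + z_gy**2
    if denom == 0:
        return 0.0, 1.0, math.inf
    t_smr = (z_gx**2 * z_gy**2) / denom
    p_smr = float(stats.chi2.sf(t_smr, 1))
    if t_smr > 0 and b_gx != 0:
        se_xy = abs(b_gy / b_gx) / math.sqrt(t_smr)
    else:
        se_xy = math.inf
    return t_smr, p_smr, se_xy


def prune_by_ld(
    instruments: list[Instrument],
    ld: LDMatrix,
    r2_max: float = 0.1,
    max_snps: int = 20,
) -> list[Instrument]:
    """Greedy LD pruning seeded at the smallest eQTL p.

    Instruments are visited in ascending eQTL p; one is retained when its r^2
    with every already-retained SNP is below ``r2_max``, up to ``max_snps``.
    """
    ordered = sorted(instruments, key=lambda ins: (ins.record.p, -ins.f_stat, ins.rsid))
    kept: list[Instrument] = []
    for ins in ordered:
        if ins.rsid not in ld:
            continue
        if all(ld.corr(ins.rsid, k.rsid) ** 2 < r2_max for k in kept):
            kept.append(ins)
            if len(kept) >= max_snps:
                break
    return kept


def smr_multi(
    instruments: list[Instrument],
    gwas: SumstatsSet,
    ld: LDMatrix,
    r2_prune: float = 0.1,
    max_snps: int = 20,
    method: str = "imhof",
) -> Optional[float]:
    """Multi-SNP SMR p-value over an LD-pruned instrument set.

    Per retained SNP i, T_i is the SMR chi-square of the harmonized eQTL/GWAS
    pair; the combined statistic sum_i T_i is referred to the weighted
    chi-square null with weights the eigenvalues of the retained SNPs' LD
    correlation matrix.  Returns None when no instrument can be harmonized with
    the GWAS.
    """
    usable: list[tuple[Instrument, float]] = []
    for ins in prune_by_ld(instruments, ld, r2_prune, max_snps):
        gw = gwas.get(ins.rsid)
        if gw is None:
            continue
        verdict = harmonize(ins.record, gw)
        if not verdict.kept:
            continue
        t_i, _, _ = smr_test(ins.record.beta, ins.record.se,
                             verdict.record.beta, verdict.record.se)
        usable.append((ins, t_i))
    if not usable:
        return None
    rsids = [ins.rsid for ins, _ in usable]
    t_sum = sum(t for _, t in usable)
    if len(usable) == 1:
        return float(stats.chi2.sf(t_sum, 1))
    r_sub = ld.submatrix(rsids).r
    lam = np.linalg.eigvalsh(r_sub)
    lam = np.clip(lam, 0.0, None)
    return weighted_chi2_sf(t_sum, lam, method=method)


def to_odds_ratio(
    b_xy: float, se_xy: float, per_sd_decrease: bool = False
) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, 95% CI low, 95% CI high).

    ``per_sd_decrease`` negates the effect so the OR is per one SD *decrease*
    in expression, the reporting convention for drug-inhibited targets.
    """
    if se_xy <= 0:
        raise ValueError("se_xy must be > 0")
    b = -b_xy if per_sd_decrease else b_xy
    if math.isinf(se_xy):
        return math.exp(b), 0.0, math.inf
    return (
        math.exp(b),
        math.exp(b - 1.96 * se_xy),
        math.exp(b + 1.96 * se_xy),
    )
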