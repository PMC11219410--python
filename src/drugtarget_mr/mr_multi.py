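"""Multi-instrument MR of one trait on another: GSMR-style pooling, IVW, Egger.

Instruments are genome-wide-significant exposure SNPs pruned to near-linkage
equilibrium.  Per-SNP Wald ratios are pooled by generalized least squares with
a covariance built from the delta-method variances and residual LD; outlying
instruments (single-SNP heterogeneity p below a threshold) are removed first,
mirroring the HEIDI-outlier step of GSMR.  IVW and Egger regression serve as
consistency estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .quadform import weighted_chi2_sf  # noqa: F401  (re-exported for callers)
from .smr import prune_by_ld, wald_ratio
from .instruments import Instrument
from .sumstats import LDMatrix, SumstatsSet, f_statistic, harmonize

__all__ = [
    "MultiMRResult",
    "EstimationError",
    "heidi_outlier_filter",
    "gsmr_estimate",
    "ivw_egger",
    "ivw_pool",
]


class EstimationError(ValueError):
    """Too few usable instruments for the requested estimator."""


@dataclass
class MultiMRResult:
    estimator: str  # gsmr | ivw | egger
    b: float
    se: float
    p: float
    n_instruments_used: int
    outliers_removed: list[str] = field(default_factory=list)
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None


def ivw_pool(b: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Fixed-effect inverse-variance-weighted mean and its SE."""
    w = 1.0 / v
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return pooled, se


def heidi_outlier_filter(
    ratios: list[tuple[float, float]],
    p_thresh: float = 0.01,
    rsids: Optional[list[str]] = None,
) -> tuple[list[int], list[str]]:
    """Iteratively remove the most heterogeneous instrument while it is an outlier.

    ``ratios`` holds per-instrument (b_xy_i, se_xy_i).  At each round the pooled
    IVW estimate is formed from the surviving instruments, each instrument is
    tested for deviation from the pool (normal test of b_i - pooled with the
    delta-method SE of the difference), and the smallest-p instrument is removed
    while its p is below ``p_thresh``.  Returns retained indices and removed
    rsids (indices as strings when rsids are not given).
    """
    if len(ratios) < 3:
        raise EstimationError("outlier filtering needs at least 3 instruments")
    names = rsids if rsids is not None else [str(i) for i in range(len(ratios))]
    alive = list(range(len(ratios)))
    removed: list[str] = []
    while len(alive) > 2:
        b = np.array([ratios[i][0] for i in alive])
        v = np.array([ratios[i][1] ** 2 for i in alive])
        pooled, _ = ivw_pool(b, v)
        # var of (b_i - pooled) under the fixed-effect model
        w_sum = np.sum(1.0 / v)
        var_diff = v - 1.0 / w_sum
        var_diff = np.maximum(var_diff, 1e-300)
        z = (b - pooled) / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(np.abs(z))
        # smallest p first; ties (p underflows to 0) broken by largest |z|
        worst = int(np.lexsort((-np.abs(z), p))[0])
        if p[worst] >= p_thresh:
            break
        removed.append(names[alive[worst]])
        alive.pop(worst)
    if len(alive) < 2:
        raise EstimationError("fewer than 2 instruments survive outlier removal")
    return alive, removed


def _collect_ratios(
    exposure: SumstatsSet,
    outcome: SumstatsSet,
    ld: Optional[LDMatrix],
    p_sel: float,
    r2_prune: float,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Select, prune and harmonize instruments; return rsids, b_xy, se_xy, and LD."""
    candidates = [
        Instrument("", rec, f_statistic(rec))
        for rec in exposure.records.values()
        if rec.p < p_sel
    ]
    if ld is not None:
        kept = prune_by_ld(candidates, ld, r2_max=r2_prune, max_snps=10_000)
    else:
        kept = sorted(candidates, key=lambda i: (i.record.p, i.rsid))
    rsids, b_list, se_list = [], [], []
    for ins in kept:
        out_rec = outcome.get(ins.rsid)
        if out_rec is None:
            continue
        verdict = harmonize(ins.record, out_rec)
        if not verdict.kept:
            continue
        b_xy, se_xy = wald_ratio(
            ins.record.beta, ins.record.se, verdict.record.beta, verdict.record.se
        )
        rsids.append(ins.rsid)
        b_list.append(b_xy)
        se_list.append(se_xy)
    if ld is not None and rsids:
        r = ld.submatrix(rsids).r
    else:
        r = np.eye(len(rsids))
    return rsids, np.array(b_list), np.array(se_list), r


def gsmr_estimate(
    exposure: SumstatsSet,
    outcome: SumstatsSet,
    ld: Optional[LDMatrix] = None,
    p_sel: float = 5e-8,
    r2_prune: float = 0.05,
    heidi_p: float = 0.01,
    apply_outlier_filter: bool = True,
) -> MultiMRResult:
    """GLS-pooled multi-instrument causal estimate with HEIDI-outlier removal.

    Pooling solves b = (1' Omega^-1 b_vec) / (1' Omega^-1 1) with
    Omega_ij = r_ij * se_i * se_j (delta-method variances on the diagonal,
    residual LD off it).  With diagonal Omega this is exactly the IVW
    estimator.
    """
    rsids, b, se, r = _collect_ratios(exposure, outcome, ld, p_sel, r2_prune)
    if len(rsids) < 2:
        raise EstimationError(
            f"GSMR needs at least 2 harmonizable instruments, got {len(rsids)}"
        )
    removed: list[str] = []
    keep = list(range(len(rsids)))
    if apply_outlier_filter and len(rsids) >= 3:
        ratios = list(zip(b.tolist(), se.tolist()))
        keep, removed = heidi_outlier_filter(ratios, p_thresh=heidi_p, rsids=rsids)
    b_k = b[keep]
    se_k = se[keep]
    r_k = r[np.ix_(keep, keep)]
    omega = r_k * np.outer(se_k, se_k)
    try:
        omega_inv = np.linalg.inv(omega)
    except np.linalg.LinAlgError:
        omega = omega + 1e-8 * np.eye(len(keep))
        omega_inv = np.linalg.inv(omega)
    ones = np.ones(len(keep))
    denom = float(ones @ omega_inv @ ones)
    if denom <= 0:
        omega = omega + 1e-8 * np.eye(len(keep))
        omega_inv = np.linalg.inv(omega)
        denom = float(ones @ omega_inv @ ones)
    b_pool = float(ones @ omega_inv @ b_k) / denom
    se_pool = denom ** -0.5
    p = 2.0 * float(stats.norm.sf(abs(b_pool) / se_pool))
    return MultiMRResult(
        estimator="gsmr",
        b=b_pool,
        se=se_pool,
        p=max(p, 1e-300),
        n_instruments_used=len(keep),
        outliers_removed=removed,
    )


def ivw_egger(
    exposure: SumstatsSet,
    outcome: SumstatsSet,
    ld: Optional[LDMatrix] = None,
    p_sel: float = 5e-8,
    r2_prune: float = 0.05,
) -> tuple[MultiMRResult, Optional[MultiMRResult]]:
    """Fixed-effect IVW and Egger regression on the same instrument set.

    Egger regresses the outcome betas on the exposure betas (orientation:
    exposure beta positive) with an intercept, weighted by 1/se_gy^2; the
    intercept estimates directional pleiotropy.  Egger is omitted (None) with
    fewer than 3 instruments.
    """
    rsids, b, se, _ = _collect_ratios(exposure, outcome, ld, p_sel, r2_prune)
    if len(rsids) < 2:
        raise EstimationError(
            f"IVW needs at least 2 harmonizable instruments, got {len(rsids)}"
        )
    b_pool, se_pool = ivw_pool(b, se**2)
    p = 2.0 * float(stats.norm.sf(abs(b_pool) / se_pool))
    ivw = MultiMRResult(
        estimator="ivw",
        b=b_pool,
        se=se_pool,
        p=max(p, 1e-300),
        n_instruments_used=len(rsids),
    )
    if len(rsids) < 3:
        return ivw, None

    # Egger needs the per-SNP betas, not the ratios
    bx, by, sy = [], [], []
    for rsid in rsids:
        ex = exposure.get(rsid)
        out = harmonize(ex, outcome.get(rsid)).record
        sign = 1.0 if ex.beta >= 0 else -1.0
        bx.append(sign * ex.beta)
        by.append(sign * out.beta)
        sy.append(out.se)
    bx = np.array(bx)
    by = np.array(by)
    w = 1.0 / np.array(sy) ** 2
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=w).fit()
    slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    icept, icept_se = float(fit.params[0]), float(fit.bse[0])
    df = len(rsids) - 2
    p_slope = 2.0 * float(stats.t.sf(abs(slope / slope_se), df))
    p_icept = 2.0 * float(stats.t.sf(abs(icept / icept_se), df))
    egger = MultiMRResult(
        estimator="egger",
        b=slope,
        se=slope_se,
        p=max(p_slope, 1e-300),
        n_instruments_used=len(rsids),
        egger_intercept=icept,
        egger_intercept_p=max(p_icept, 1e-300),
    )
    return ivw, egger
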