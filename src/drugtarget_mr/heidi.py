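"""HEIDI: heterogeneity in dependent instruments.

Under a single shared causal variant, every cis-SNP in LD with the top eQTL
must yield the same Wald ratio b_xy up to sampling noise; systematic
heterogeneity indicates linkage of two distinct causal variants instead.  The
test contrasts each non-top SNP's ratio with the top SNP's ratio, accounting
for the LD-induced covariance of the differences, and refers the sum of
squared standardized differences to an eigenvalue-weighted chi-square null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instruments import Instrument
from .quadform import weighted_chi2_sf
from .sumstats import AssocRecord, LDMatrix, SumstatsSet

__all__ = ["HEIDIResult", "HEIDIConfigError", "select_heidi_snps", "heidi_test"]


class HEIDIConfigError(ValueError):
    """HEIDI cannot run with the provided configuration (e.g. top SNP not in LD)."""


@dataclass
class HEIDIResult:
    gene_id: str
    m: int                      # number of non-top SNPs entering the statistic
    stat: float
    p_heidi: float
    snps_used: list[str] = field(default_factory=list)


def select_heidi_snps(
    cis_eqtl: SumstatsSet,
    top: Instrument,
    ld: LDMatrix,
    r2_low: float = 0.05,
    r2_high: float = 0.9,
    p_eqtl_max: float = 1.6e-3,
    max_snps: int = 20,
    min_snps: int = 3,
) -> list[str]:
    """Candidate non-top SNPs for the heterogeneity test.

    A candidate must show an eQTL association (p < ``p_eqtl_max``) and sit in
    intermediate LD with the top SNP (r^2 in [``r2_low``, ``r2_high``]): too
    little LD carries no information about the shared signal, near-perfect LD
    makes the ratio difference ill-conditioned.  The ``max_snps`` smallest
    eQTL p are kept; fewer than ``min_snps`` survivors means the test cannot
    be run for this gene (empty list returned).
    """
    if top.rsid not in ld:
        raise HEIDIConfigError(f"top SNP {top.rsid} absent from the LD matrix")
    candidates = []
    for rec in cis_eqtl.records.values():
        if rec.rsid == top.rsid or rec.rsid not in ld:
            continue
        if rec.p >= p_eqtl_max:
            continue
        r2 = ld.corr(top.rsid, rec.rsid) ** 2
        if not (r2_low <= r2 <= r2_high):
            continue
        candidates.append(rec)
    candidates.sort(key=lambda r: (r.p, r.rsid))
    kept = [r.rsid for r in candidates[:max_snps]]
    if len(kept) < min_snps:
        return []
    return kept


def _ratio_cov(
    eqtl: list[AssocRecord], gwas: list[AssocRecord], r: np.ndarray
) -> np.ndarray:
    """Delta-method covariance of the per-SNP Wald ratios b_gy,i / b_gx,i."""
    bx = np.array([e.beta for e in eqtl])
    sx = np.array([e.se for e in eqtl])
    by = np.array([g.beta for g in gwas])
    sy = np.array([g.se for g in gwas])
    # Cov(b_i, b_j) = r_ij * [ sy_i sy_j / (bx_i bx_j) + by_i by_j sx_i sx_j / (bx_i^2 bx_j^2) ]
    term1 = np.outer(sy / bx, sy / bx)
    term2 = np.outer(by * sx / bx**2, by * sx / bx**2)
    return r * (term1 + term2)


def heidi_test(
    top_eqtl: AssocRecord,
    top_gwas: AssocRecord,
    other_eqtl: list[AssocRecord],
    other_gwas: list[AssocRecord],
    ld: LDMatrix,
    gene_id: str = "",
    method: str = "imhof",
) -> HEIDIResult:
    """Test homogeneity of Wald ratios across LD-linked cis SNPs.

    All records must already be harmonized to shared effect alleles.  The
    statistic is sum_i z_d,i^2 with d_i = b_xy(i) - b_xy(top) standardized by
    its delta-method SD; its null is sum_k lambda_k chi2_1 with lambda_k the
    eigenvalues of the correlation matrix of the d vector.  SNPs rendering the
    covariance singular are dropped (largest |r| with another retained SNP
    first).
    """
    if len(other_eqtl) != len(other_gwas):
        raise ValueError("eQTL and GWAS record lists differ in length")
    if not other_eqtl:
        raise ValueError("HEIDI needs at least one non-top SNP")

    order = [top_eqtl.rsid] + [e.rsid for e in other_eqtl]
    r_full = ld.submatrix(order).r
    eqtl_all = [top_eqtl] + list(other_eqtl)
    gwas_all = [top_gwas] + list(other_gwas)

    cov_b = _ratio_cov(eqtl_all, gwas_all, r_full)
    m = len(other_eqtl)

    # covariance of d_i = b_i - b_0 (i = 1..m)
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )

    b_all = np.array([g.beta / e.beta for e, g in zip(eqtl_all, gwas_all)])
    d = b_all[1:] - b_all[0]

    keep = list(range(m))
    while True:
        sub = cov_d[np.ix_(keep, keep)]
        sd = np.sqrt(np.diag(sub))
        corr = sub / np.outer(sd, sd)
        # near-singular correlation -> drop the SNP most collinear with the rest
        if np.linalg.matrix_rank(corr, tol=1e-8) == len(keep):
            break
        if len(keep) == 1:
            break
        off = np.abs(corr - np.eye(len(keep)))
        worst = int(np.argmax(off.max(axis=1)))
        keep.pop(worst)

    sub = cov_d[np.ix_(keep, keep)]
    sd = np.sqrt(np.diag(sub))
    z_d = d[keep] / sd
    stat = float(np.sum(z_d**2))
    corr = sub / np.outer(sd, sd)
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    p = weighted_chi2_sf(stat, lam, method=method)
    return HEIDIResult(
        gene_id=gene_id,
        m=len(keep),
        stat=stat,
        p_heidi=p,
        snps_used=[other_eqtl[i].rsid for i in keep],
    )
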