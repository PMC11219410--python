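"""Synthetic paired eQTL/GWAS summary statistics with known causal structure.

Summary statistics are drawn directly at the z-score level: in a cis region
with LD correlation matrix Lambda, the marginal GWAS/eQTL z-scores are
multivariate normal with mean Lambda @ zeta and covariance Lambda, where zeta
holds the standardized effects of the causal variants (zero elsewhere).  Betas
are recovered as z * se with the standard per-allele SE 1/sqrt(2*maf*(1-maf)*n)
(scaled by the case fraction variance phi*(1-phi) for case-control traits).
Three scenario kinds cover the analysis's hypotheses: ``null`` (eQTL signal,
no outcome effect), ``shared_causal`` (outcome effect mediated by expression at
the same variant) and ``linkage`` (distinct eQTL and outcome causal variants in
LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .sumstats import (
    AssocRecord,
    GeneModel,
    LDMatrix,
    SumstatsSet,
    TraitType,
    VariantKey,
)

__all__ = ["Scenario", "SyntheticBundle", "simulate_ld", "simulate_pair"]

# sample sizes of the source studies the generator emulates:
# whole-blood eQTL meta-analysis and the overall breast-cancer GWAS
DEFAULT_N_EQTL = 31_684
DEFAULT_N_GWAS = 214_675
DEFAULT_CASE_FRACTION = 118_474 / 214_675


@dataclass
class Scenario:
    """Generative configuration for one cis region.

    ``b_causal_expr`` is the expression change (in SD) per effect allele at the
    causal eQTL; ``b_xy_true`` the outcome effect per SD of expression (log
    odds for a case-control outcome); ``b_gwas_direct`` a direct,
    expression-independent outcome effect used by the linkage kind.
    """

    kind: str = "null"  # null | shared_causal | linkage
    n_snps: int = 100
    ld_blocks: Sequence[tuple[int, float]] = ((100, 0.8),)
    mafs: Optional[np.ndarray] = None
    causal_eqtl_idx: int = 50
    causal_gwas_idx: Union[int, str, None] = None  # int | "same" | None
    b_causal_expr: float = 0.3
    b_xy_true: float = 0.0
    b_gwas_direct: float = 0.08
    n_eqtl: int = DEFAULT_N_EQTL
    n_gwas: int = DEFAULT_N_GWAS
    trait_type: TraitType = TraitType.CASE_CONTROL
    case_fraction: float = DEFAULT_CASE_FRACTION
    seed: int = 0
    gene_id: str = "GENE1"

    def __post_init__(self) -> None:
        if self.kind not in ("null", "shared_causal", "linkage"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if sum(s for s, _ in self.ld_blocks) != self.n_snps:
            raise ValueError("ld_blocks sizes must sum to n_snps")
        if self.kind == "shared_causal":
            if self.causal_gwas_idx not in (None, "same"):
                raise ValueError("shared_causal requires causal_gwas_idx='same'")
            if self.b_xy_true == 0.0:
                raise ValueError("shared_causal requires a nonzero b_xy_true")
        if self.kind == "linkage":
            if not isinstance(self.causal_gwas_idx, int):
                raise ValueError("linkage requires an integer causal_gwas_idx")
            if self.causal_gwas_idx == self.causal_eqtl_idx:
                raise ValueError("linkage requires distinct causal indices")
        if self.kind == "null" and self.b_xy_true != 0.0:
            raise ValueError("null scenario must have b_xy_true = 0")


@dataclass
class SyntheticBundle:
    eqtl: SumstatsSet
    gwas: SumstatsSet
    ld: LDMatrix
    truth: Scenario
    gene: GeneModel = field(default=None)  # type: ignore[assignment]


def simulate_ld(ld_blocks: Sequence[tuple[int, float]], seed: int | None = None) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block r_ij = rho^|i-j|, zero across blocks.

    Construction is deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic generators and ignored.  Each AR(1) block is positive
    definite for |rho| < 1.
    """
    total = sum(s for s, _ in ld_blocks)
    r = np.zeros((total, total))
    offset = 0
    for size, rho in ld_blocks:
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"block rho must satisfy |rho| < 1, got {rho}")
        idx = np.arange(size)
        block = rho ** np.abs(np.subtract.outer(idx, idx))
        r[offset : offset + size, offset : offset + size] = block
        offset += size
    variants = [f"rs{i + 1}" for i in range(total)]
    return LDMatrix(variants, r)


def _se_per_allele(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    var_allele = 2.0 * maf * (1.0 - maf)
    if case_fraction is None:
        return 1.0 / np.sqrt(var_allele * n)
    phi = case_fraction
    return 1.0 / np.sqrt(var_allele * n * phi * (1.0 - phi))


def _records(
    z: np.ndarray,
    se: np.ndarray,
    maf: np.ndarray,
    positions: np.ndarray,
    n: int,
    trait_id: str,
    trait_type: TraitType,
    sdY: float | None,
) -> SumstatsSet:
    ss = SumstatsSet(trait_id, trait_type, sdY)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, 1e-300)
    for i in range(z.size):
        ss.add(
            AssocRecord(
                variant=VariantKey(f"rs{i + 1}", "1", int(positions[i])),
                effect_allele="A",
                other_allele="G",
                eaf=float(maf[i]),
                beta=float(z[i] * se[i]),
                se=float(se[i]),
                p=float(p[i]),
                n=n,
            )
        )
    return ss


def simulate_pair(sc: Scenario, rng: np.random.Generator | None = None) -> SyntheticBundle:
    """Draw one paired eQTL/GWAS summary-statistic bundle under a scenario.

    The eQTL and GWAS z-vectors are independent draws (two non-overlapping
    samples) around their respective LD-smeared means.  The same seed yields a
    bit-identical bundle.
    """
    rng = rng if rng is not None else np.random.default_rng(sc.seed)
    ld = simulate_ld(sc.ld_blocks)
    m = sc.n_snps

    if sc.mafs is not None:
        maf = np.asarray(sc.mafs, dtype=float)
        if maf.shape != (m,):
            raise ValueError("mafs length must equal n_snps")
    else:
        maf = rng.uniform(0.05, 0.5, size=m)
    if np.any((maf < 0.01) | (maf > 0.5)):
        raise ValueError("mafs must lie in [0.01, 0.5]")

    se_eqtl = _se_per_allele(maf, sc.n_eqtl, None)  # expression in SD units
    phi = sc.case_fraction if sc.trait_type == TraitType.CASE_CONTROL else None
    se_gwas = _se_per_allele(maf, sc.n_gwas, phi)

    zeta_eqtl = np.zeros(m)
    zeta_eqtl[sc.causal_eqtl_idx] = sc.b_causal_expr / se_eqtl[sc.causal_eqtl_idx]

    zeta_gwas = np.zeros(m)
    if sc.kind == "shared_causal":
        b_gy = sc.b_xy_true * sc.b_causal_expr  # mediated per-allele outcome effect
        zeta_gwas[sc.causal_eqtl_idx] = b_gy / se_gwas[sc.causal_eqtl_idx]
    elif sc.kind == "linkage":
        idx = int(sc.causal_gwas_idx)
        zeta_gwas[idx] = sc.b_gwas_direct / se_gwas[idx]

    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    z_eqtl = ld.r @ zeta_eqtl + chol @ rng.standard_normal(m)
    z_gwas = ld.r @ zeta_gwas + chol @ rng.standard_normal(m)

    positions = 5_000_000 + 10_000 * np.arange(m)
    eqtl = _records(z_eqtl, se_eqtl, maf, positions, sc.n_eqtl,
                    f"{sc.gene_id}_expression", TraitType.QUANTITATIVE, 1.0)
    gwas = _records(z_gwas, se_gwas, maf, positions, sc.n_gwas,
                    "outcome", sc.trait_type, None)

    mid = int(positions[m // 2])
    gene = GeneModel(sc.gene_id, "1", mid, mid - 5_000, mid + 5_000)
    return SyntheticBundle(eqtl=eqtl, gwas=gwas, ld=ld, truth=sc, gene=gene)
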