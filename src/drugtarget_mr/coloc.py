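"""Bayesian colocalization of two association signals under one causal variant.

Given per-SNP approximate Bayes factors (Wakefield's normal approximation) for
two traits over the same region, the posterior mass is split across five
hypotheses: H0 no association, H1/H2 association with one trait only, H3 two
distinct causal variants, H4 one shared causal variant.  PP4 above 0.8 is the
conventional support level for a shared variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumstatsSet, TraitType, harmonize

__all__ = ["ColocPriors", "ColocResult", "wakefield_labf", "coloc_abf", "prior_sd_for"]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causality (defaults of the standard method)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class ColocResult:
    pp: tuple[float, float, float, float, float]  # PP0..PP4
    n_snps: int
    snps: list[str] = field(default_factory=list)

    @property
    def pp4(self) -> float:
        return self.pp[4]

    @property
    def pp3(self) -> float:
        return self.pp[3]


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one SNP under a normal effect prior.

    With V = se^2, W = prior_sd^2 and r = W/(V+W):
    log ABF = 0.5*log(1 - r) + 0.5 * r * z^2.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * math.log(1.0 - r) + 0.5 * r * z * z


def prior_sd_for(trait_type: TraitType, sdY: float | None = None) -> float:
    """Default effect-size prior SD: 0.15 * sdY for a quantitative trait
    (0.15 when expression is already standardized), 0.2 on the log-odds scale
    for a case-control trait."""
    if trait_type == TraitType.CASE_CONTROL:
        return 0.2
    return 0.15 * (sdY if sdY is not None else 1.0)


def coloc_abf(
    trait1: SumstatsSet,
    trait2: SumstatsSet,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities PP0..PP4 over the shared variants of a region.

    Records of trait2 are harmonized to trait1's effect alleles (ABFs depend
    on z only through z^2, but harmonization also drops irreconcilable or
    strand-ambiguous variants).  All sums are done in log space.
    """
    shared: list[str] = []
    labf1: list[float] = []
    labf2: list[float] = []
    sd1 = prior_sd1 if prior_sd1 is not None else prior_sd_for(trait1.trait_type, trait1.sdY)
    sd2 = prior_sd2 if prior_sd2 is not None else prior_sd_for(trait2.trait_type, trait2.sdY)
    for rsid, rec1 in trait1.records.items():
        rec2 = trait2.get(rsid)
        if rec2 is None:
            continue
        verdict = harmonize(rec1, rec2)
        if not verdict.kept:
            continue
        shared.append(rsid)
        labf1.append(wakefield_labf(rec1.beta, rec1.se, sd1))
        labf2.append(wakefield_labf(verdict.record.beta, verdict.record.se, sd2))
    q = len(shared)
    if q == 0:
        raise ValueError("no shared harmonizable variants between the two traits")
    if q * (priors.p1 + priors.p2 + priors.p12) >= 1.0:
        import warnings

        warnings.warn("priors imply more than one causal variant per region on average")

    a1 = np.asarray(labf1)
    a2 = np.asarray(labf2)
    lse1 = float(logsumexp(a1))
    lse2 = float(logsumexp(a2))
    lse12 = float(logsumexp(a1 + a2))

    lh0 = 0.0
    lh1 = math.log(priors.p1) + lse1
    lh2 = math.log(priors.p2) + lse2
    # ordered pairs i != j: full cross product minus the diagonal, in log space
    if q > 1:
        lh3_sum = _log_diff(lse1 + lse2, lse12)
        lh3 = math.log(priors.p1) + math.log(priors.p2) + lh3_sum
    else:
        lh3 = -math.inf
    lh4 = math.log(priors.p12) + lse12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=tuple(float(x) for x in pp), n_snps=q, snps=shared)


def _log_diff(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)) for log_a >= log_b."""
    if log_b > log_a:
        # numerically the diagonal can exceed the product by rounding only
        if log_b - log_a < 1e-9:
            return -math.inf
        raise ValueError("log_diff requires log_a >= log_b")
    d = 1.0 - math.exp(log_b - log_a)
    if d <= 0.0:
        return -math.inf
    return log_a + math.log(d)
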