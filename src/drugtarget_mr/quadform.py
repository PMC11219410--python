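"""Upper-tail probabilities of positive linear combinations of chi-square(1) variables.

Statistics of the form Q = sum_k lambda_k * chi2_1 arise as the null distribution
of both the multi-SNP SMR statistic and the HEIDI heterogeneity statistic, with
lambda_k the eigenvalues of the LD (or ratio-difference) correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

__all__ = ["weighted_chi2_sf", "weighted_chi2_sf_mc"]


def _satterthwaite_sf(q: float, lam: np.ndarray) -> float:
    """Two-moment (scaled chi-square) approximation: Q ~ g * chi2_h."""
    s1 = lam.sum()
    s2 = (lam**2).sum()
    g = s2 / s1
    h = s1**2 / s2
    return float(stats.chi2.sf(q / g, h))


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """Imhof's exact inversion formula, evaluated by adaptive quadrature.

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du with
    theta(u) = sum_k atan(lam_k u)/2 - q u / 2 and
    rho(u) = prod_k (1 + lam_k^2 u^2)^(1/4).
    """

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        ln_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return float(np.sin(theta) * np.exp(-ln_rho) / u)

    with warnings.catch_warnings():
        # the integrand oscillates; quad converges but reports the subdivision cap
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
    p = 0.5 + val / np.pi
    return float(min(max(p, 0.0), 1.0))


def weighted_chi2_sf(q: float, weights, method: str = "imhof") -> float:
    """P(sum_k w_k chi2_1 > q) for non-negative weights.

    ``imhof`` evaluates the exact characteristic-function inversion;
    ``satterthwaite`` uses the closed-form two-moment chi-square match.
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if q <= 1e-12:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    if np.allclose(lam, lam[0], rtol=1e-9, atol=0.0):
        # equal weights: the quadratic form is an exact scaled chi-square
        return float(stats.chi2.sf(q / lam[0], lam.size))
    if method == "satterthwaite":
        return _satterthwaite_sf(q, lam)
    if method == "imhof":
        p = _imhof_sf(q, lam)
        # quadrature loses precision deep in the tail; fall back there
        if p < 1e-10:
            return _satterthwaite_sf(q, lam)
        return p
    raise ValueError(f"unknown method {method!r}")


def weighted_chi2_sf_mc(q: float, weights, n_draws: int = 100_000,
                        rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo estimate of the same tail probability (testing oracle)."""
    rng = rng or np.random.default_rng(0)
    lam = np.asarray(weights, dtype=float)
    draws = rng.chisquare(1, size=(n_draws, lam.size)) @ lam
    return float(np.mean(draws > q))
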