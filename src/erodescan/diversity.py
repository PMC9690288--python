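"""Genome-wide heterozygosity and a maximum-likelihood (theta, epsilon) fit.

``het_per_kb`` is the direct estimate: heterozygous calls per kilobase of
callable sequence.  ``estimate_theta`` fits a two-allele per-site mixture
to raw read profiles: each site is heterozygous with probability theta
(the population-scaled mutation rate, read as per-site heterozygosity under
the infinite-sites model) and homozygous otherwise, and each read misreports
its allele with probability epsilon.  This is a deliberately reduced version
of the classic read-profile likelihood (mlRho-style): two alleles per site
instead of four nucleotides, which preserves the (theta, epsilon)
identifiability structure — epsilon is pinned down by minor-allele reads at
homozygous sites, theta by the excess of balanced profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .matrix import HET, GenotypeMatrix

__all__ = ["HetResult", "ThetaEstimate", "het_per_kb", "site_log_likelihood",
           "estimate_theta"]


@dataclass(frozen=True)
class HetResult:
    individual: str
    n_het: int
    callable_bp: int
    het_per_kb: float


@dataclass(frozen=True)
class ThetaEstimate:
    theta: float
    epsilon: float
    log_likelihood: float
    n_sites: int


def het_per_kb(matrix: GenotypeMatrix, callable_bp: dict[str, int] | int) -> list[HetResult]:
    """Heterozygous calls per kb of callable sequence, per individual."""
    out = []
    for i, sample in enumerate(matrix.samples):
        cb = callable_bp[sample] if isinstance(callable_bp, dict) else callable_bp
        if cb <= 0:
            raise ValueError(f"callable length for {sample!r} must be positive")
        n_het = int((matrix.calls[i] == HET).sum())
        out.append(HetResult(sample, n_het, int(cb), 1000.0 * n_het / cb))
    return out


def site_log_likelihood(n_ref, n_alt, theta: float, epsilon: float) -> np.ndarray:
    """Log-likelihood of (theta, epsilon) for per-site (ref, alt) read counts.

    L = (1 - theta) P(profile | hom) + theta P(profile | het), where the
    homozygous term is maximized over which allele is the true one and the
    heterozygous term draws each read 50:50 (error then has no net effect
    on the allele balance).  Sites with zero depth contribute 0.
    Vectorized over sites.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_alt = np.asarray(n_alt, dtype=np.int64)
    if np.any(n_ref < 0) or np.any(n_alt < 0):
        raise ValueError("read counts must be non-negative")
    n = n_ref + n_alt
    k_min = np.minimum(n_ref, n_alt)
    k_max = np.maximum(n_ref, n_alt)
    log_choose = gammaln(n + 1) - gammaln(n_ref + 1) - gammaln(n_alt + 1)

    with np.errstate(divide="ignore"):
        log_eps = np.log(epsilon) if epsilon > 0 else -np.inf
        log_1m = np.log1p(-epsilon)
    # hom: minor reads are errors (epsilon < 0.5 makes this the better orientation)
    log_hom = np.where(k_min == 0, k_max * log_1m,
                       k_min * log_eps + k_max * log_1m) + log_choose
    log_het = n * np.log(0.5) + log_choose

    parts = []
    if theta < 1:
        parts.append(np.log1p(-theta) + log_hom)
    if theta > 0:
        parts.append(np.log(theta) + log_het)
    ll = parts[0] if len(parts) == 1 else logsumexp(np.stack(parts), axis=0)
    return np.where(n == 0, 0.0, ll)


def _total_ll(profiles_unique: np.ndarray, mult: np.ndarray,
              theta: float, epsilon: float) -> float:
    ll = site_log_likelihood(profiles_unique[:, 0], profiles_unique[:, 1],
                             theta, epsilon)
    return float(np.dot(ll, mult))


def estimate_theta(
    profiles: np.ndarray,
    theta_bounds: tuple[float, float] = (1e-6, 0.5),
    eps_bounds: tuple[float, float] = (1e-6, 0.45),
    grid: int = 50,
) -> ThetaEstimate:
    """Maximize the summed site log-likelihood over (theta, epsilon).

    A log-spaced coarse grid locates the basin; Nelder–Mead in log-parameter
    space refines it.  Fixed start, no randomness: deterministic given the
    profiles.  ``profiles`` is an ``(n_sites, 2)`` array of (ref, alt) counts.
    """
    profiles = np.asarray(profiles, dtype=np.int64).reshape(-1, 2)
    depth = profiles.sum(axis=1)
    if not np.any(depth > 0):
        raise ValueError("all profiles have zero depth; nothing to estimate")
    uniq, mult = np.unique(profiles[depth > 0], axis=0, return_counts=True)
    n_sites = int(mult.sum())

    thetas = np.geomspace(theta_bounds[0], theta_bounds[1], grid)
    epss = np.geomspace(eps_bounds[0], eps_bounds[1], grid)
    best = (-np.inf, thetas[0], epss[0])
    for th in thetas:
        for ep in epss:
            ll = _total_ll(uniq, mult, th, ep)
            if ll > best[0]:
                best = (ll, th, ep)

    def neg(x):
        th = float(np.exp(x[0]))
        ep = float(np.exp(x[1]))
        if not (theta_bounds[0] <= th <= theta_bounds[1]
                and eps_bounds[0] <= ep <= eps_bounds[1]):
            return 1e12
        return -_total_ll(uniq, mult, th, ep)

    res = minimize(neg, x0=np.log([best[1], best[2]]), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    theta_hat, eps_hat = np.exp(res.x)
    ll_hat = -res.fun if np.isfinite(res.fun) and res.fun < 1e11 else best[0]
    if -res.fun < best[0]:
        theta_hat, eps_hat, ll_hat = best[1], best[2], best[0]
    return ThetaEstimate(float(theta_hat), float(eps_hat), float(ll_hat), n_sites)


def het_table(results: list[HetResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
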