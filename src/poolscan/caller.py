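"""Bayesian SNP calling in pooled samples.

A pool of ``n`` chromosomes sequenced to read depth ``C`` yields ``n_A``
alternative-allele reads.  The likelihood marginalises the unknown number
``k`` of chromosomes in the pool carrying the alternative allele:

    P(n_A | f) = sum_k Binom(n_A; C, p_k) * Binom(k; n, f)

where ``p_k = (k/n)(1 - eps) + (1 - k/n) eps`` is the probability that a
single read shows the alternative allele given ``k`` carriers and a
per-read miscall probability ``eps`` derived from the geometric mean of
the Phred base qualities.  The prior over the population frequency ``f``
is a mixture of the two monomorphic classes (f = 0, weighted by the
residual mass, and f = 1, weighted by the prior divergence) and a
polymorphic class shaped like the standard neutral frequency spectrum
(density proportional to 1/f; symmetrised when the spectrum is folded)
scaled by the prior per-bp nucleotide diversity.  A site is called a SNP
when the posterior mass of 0 < f < 1 exceeds the threshold (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import binom as _binom

from poolscan.io_windows import AlleleCount


@dataclass
class PoolModelParams:
    """Model and filter settings for the pool caller."""

    n_chromosomes: int = 18
    prior_theta: float = 0.001
    prior_divergence: float = 0.01
    folded: bool = True
    posterior_threshold: float = 0.90
    min_depth: int = 3
    max_depth: int = 30
    frequency_grid_size: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.posterior_threshold < 1:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes in the pool")
        if self.frequency_grid_size < self.n_chromosomes:
            raise ValueError("frequency grid must resolve 1/n_chromosomes")


@dataclass
class SitePosterior:
    posterior_segregating: float
    map_frequency: float
    is_call: bool


@dataclass
class PoolCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    posterior: float
    map_frequency: float
    depth: int


def error_rate_from_quality(mean_phred: float) -> float:
    """Per-read miscall probability from a Phred-scale mean quality."""
    return float(10.0 ** (-mean_phred / 10.0))


def allele_read_prob(k: int, n: int, error_rate: float) -> float:
    """Probability that one read shows allele A given k of n carriers."""
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 <= error_rate < 0.75:
        raise ValueError("error_rate must be in [0, 0.75)")
    frac = k / n
    return frac * (1.0 - error_rate) + (1.0 - frac) * error_rate


class _GridCache:
    """Per-(params) cache of the frequency grid and pool-mixture weights."""

    def __init__(self, params: PoolModelParams):
        n = params.n_chromosomes
        G = params.frequency_grid_size
        self.params = params
        # interior grid at cell midpoints, spacing 1/G
        self.f = (np.arange(G) + 0.5) / G
        shape = 1.0 / self.f
        if params.folded:
            shape = shape + 1.0 / (1.0 - self.f)
        self.w_interior = params.prior_theta * shape / G
        self.w_fixed = params.prior_divergence
        self.w_ref = 1.0 - self.w_fixed - self.w_interior.sum()
        if self.w_ref <= 0:
            raise ValueError(
                "priors leave no mass for the monomorphic reference class"
            )
        k = np.arange(n + 1)
        # Binom(k; n, f) over the interior grid: shape (G, n+1)
        self.pool_weights = _binom.pmf(k[None, :], n, self.f[:, None])


_caches: dict[tuple, _GridCache] = {}


def _cache_for(params: PoolModelParams) -> _GridCache:
    key = (
        params.n_chromosomes,
        params.prior_theta,
        params.prior_divergence,
        params.folded,
        params.frequency_grid_size,
    )
    cache = _caches.get(key)
    if cache is None:
        cache = _GridCache(params)
        _caches[key] = cache
    return cache


def likelihood_counts(
    n_A: int, C: int, f: float, params: PoolModelParams, error_rate: float = 0.0
) -> float:
    """P(n_A | f): the k-marginalised binomial mixture at one frequency."""
    if not 0 <= n_A <= C:
        raise ValueError("n_A must be in [0, C]")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    n = params.n_chromosomes
    k = np.arange(n + 1)
    p = (k / n) * (1.0 - error_rate) + (1.0 - k / n) * error_rate
    read_lik = _binom.pmf(n_A, C, p)
    pool_w = _binom.pmf(k, n, f)
    return float(np.dot(read_lik, pool_w))


def posterior_batch(
    n_A: np.ndarray,
    C: np.ndarray,
    error_rate: np.ndarray,
    params: PoolModelParams,
    chunk: int = 8192,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised posterior for many sites.

    Returns ``(posterior_segregating, map_frequency)`` arrays.  Depth
    filtering is the caller's responsibility.
    """
    cache = _cache_for(params)
    n = params.n_chromosomes
    k = np.arange(n + 1)
    n_A = np.asarray(n_A, dtype=np.int64)
    C = np.asarray(C, dtype=np.int64)
    error_rate = np.broadcast_to(np.asarray(error_rate, dtype=float), n_A.shape)
    post = np.empty(n_A.shape, dtype=float)
    fmap = np.empty(n_A.shape, dtype=float)
    for lo in range(0, n_A.size, chunk):
        hi = min(lo + chunk, n_A.size)
        nA = n_A[lo:hi, None]
        Cc = C[lo:hi, None]
        eps = error_rate[lo:hi, None]
        p = (k[None, :] / n) * (1.0 - eps) + (1.0 - k[None, :] / n) * eps
        read_lik = _binom.pmf(nA, Cc, p)  # (s, n+1)
        lik_interior = read_lik @ cache.pool_weights.T  # (s, G)
        lik0 = read_lik[:, 0]
        lik1 = read_lik[:, n]
        num = lik_interior @ cache.w_interior
        m0 = cache.w_ref * lik0
        m1 = cache.w_fixed * lik1
        tot = num + m0 + m1
        post[lo:hi] = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 0.0)
        # MAP over {0, grid, 1} on the joint prior*likelihood scale
        joint = lik_interior * cache.w_interior[None, :]
        best = np.argmax(joint, axis=1)
        best_val = joint[np.arange(joint.shape[0]), best]
        f_best = cache.f[best]
        f_best = np.where(m0 >= best_val, 0.0, f_best)
        f_best = np.where((m1 > best_val) & (m1 > m0), 1.0, f_best)
        fmap[lo:hi] = f_best
    return post, fmap


def combined_error_rate(count: AlleleCount) -> float:
    """Depth-weighted mean Phred over both alleles, as a probability."""
    depth = count.depth
    if depth == 0:
        return 0.0
    q = (
        count.mean_quality_ref * count.ref_count
        + count.mean_quality_alt * count.alt_count
    ) / depth
    return error_rate_from_quality(q)


def site_posterior(count: AlleleCount, params: PoolModelParams) -> SitePosterior:
    """Posterior probability that one site segregates in the pool."""
    depth = count.depth
    if depth < params.min_depth or depth > params.max_depth:
        raise ValueError(
            f"depth {depth} outside callable bounds "
            f"[{params.min_depth}, {params.max_depth}]"
        )
    eps = combined_error_rate(count)
    post, fmap = posterior_batch(
        np.array([count.alt_count]), np.array([depth]), np.array([eps]), params
    )
    p = float(post[0])
    return SitePosterior(
        posterior_segregating=p,
        map_frequency=float(fmap[0]),
        is_call=p > params.posterior_threshold,
    )


def call_pool_sites(
    sites: Iterable[AlleleCount], params: PoolModelParams
) -> tuple[list[PoolCall], dict[str, int]]:
    """Call SNPs over a sorted site stream.

    Returns the calls and a summary of skipped (out-of-depth), fixed
    (MAP at f=1) and monomorphic sites.
    """
    batch: list[AlleleCount] = []
    summary = {"skipped_depth": 0, "fixed": 0, "monomorphic": 0, "called": 0}
    for site in sites:
        d = site.depth
        if d < params.min_depth or d > params.max_depth:
            summary["skipped_depth"] += 1
            continue
        batch.append(site)
    if not batch:
        return [], summary
    n_A = np.array([s.alt_count for s in batch])
    C = np.array([s.depth for s in batch])
    eps = np.array([combined_error_rate(s) for s in batch])
    post, fmap = posterior_batch(n_A, C, eps, params)
    calls: list[PoolCall] = []
    for site, p, f in zip(batch, post, fmap):
        if p > params.posterior_threshold and site.alt_base is not None:
            calls.append(
                PoolCall(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref_base=site.ref_base,
                    alt_base=site.alt_base,
                    posterior=float(p),
                    map_frequency=float(f),
                    depth=site.depth,
                )
            )
            summary["called"] += 1
        elif f == 1.0:
            summary["fixed"] += 1
        else:
            summary["monomorphic"] += 1
    return calls, summary
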