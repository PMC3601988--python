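"""Depth- and pool-corrected diversity estimators.

Pooled sequencing draws reads with replacement from the ``nc``
chromosomes of the pool, so the number of *distinct* chromosomes observed
at a site of depth ``nr`` is random.  Watterson's estimator for pools
divides the segregating-site count ``S`` by an effective number of
bp-equivalents::

    theta_w = S / sum_i L(i) * sum_{j=2}^{min(i, nc)} Pc(j | i, nc) * a_j

where ``L(i)`` is the covered length at depth ``i``, ``Pc`` the occupancy
probability that ``i`` reads hit exactly ``j`` distinct chromosomes and
``a_j = sum_{m<j} 1/m``.  The individual (diploid) analogue divides by
``sum_i L(i) * (1 - 2 * 0.5**i)``, the probability that both alleles of a
heterozygote appear among ``i`` reads.

theta-pi is the average pairwise diversity across reads corrected by
``nc/(nc-1)`` (i.e. ``2n/(2n-1)`` for ``n`` diploids); the Fay-Wu
estimator theta-H weights each site by ``k^2 / (r (r-1))`` for ``k``
derived alleles among ``r`` reads and is divided by a depth-dependent
factor that makes it unbiased under the standard neutral model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from poolscan.io_windows import AlleleCount, DepthSpectrum, GenomeWindow


def harmonic_constants(n: int) -> tuple[float, float]:
    """Watterson's constants ``a_n = sum 1/i`` and ``b_n = sum 1/i^2``.

    Sums run over ``i = 1 .. n-1``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


@lru_cache(maxsize=4096)
def _occupancy_row(nr: int, nc: int) -> tuple[float, ...]:
    """Occupancy pmf over j = 0..min(nr, nc) for nr reads on nc chromosomes.

    Computed by the stable all-positive recurrence over reads (each new
    read either hits an already-seen chromosome or a fresh one); equal to
    the inclusion-exclusion closed form C(nc,j) sum_m (-1)^m C(j,m)
    ((j-m)/nc)^nr, which cancels catastrophically for large nr, nc.
    """
    if nc < 1 or nr < 1:
        raise ValueError("nr and nc must be >= 1")
    jmax = min(nr, nc)
    cur = [0.0] * (jmax + 1)
    cur[1] = 1.0
    for _ in range(1, nr):
        nxt = [0.0] * (jmax + 1)
        for j in range(1, jmax + 1):
            nxt[j] = cur[j] * (j / nc)
            if j > 1:
                nxt[j] += cur[j - 1] * ((nc - j + 1) / nc)
        cur = nxt
    return tuple(cur)


def occupancy_prob(j: int, nr: int, nc: int) -> float:
    """P(exactly j distinct chromosomes among nr uniform draws of nc)."""
    if nc < 1 or nr < 1:
        raise ValueError("nr and nc must be >= 1")
    if j < 1 or j > min(nr, nc):
        return 0.0
    return _occupancy_row(nr, nc)[j]


def watterson_denominator(spectrum: DepthSpectrum, nc: int) -> float:
    """Effective bp-equivalents for the pooled Watterson estimator."""
    if nc < 2:
        raise ValueError("nc must be >= 2")
    a = [0.0, 0.0] + [harmonic_constants(j)[0] for j in range(2, nc + 1)]
    total = 0.0
    for depth, length in spectrum.items():
        row = _occupancy_row(depth, nc)
        jmax = min(depth, nc)
        total += length * sum(row[j] * a[j] for j in range(2, jmax + 1))
    return total


def theta_w_pool(S: int, spectrum: DepthSpectrum, nc: int) -> float:
    """Pooled Watterson's theta per bp."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return 0.0
    denom = watterson_denominator(spectrum, nc)
    if denom <= 0:
        raise ValueError("zero effective length with S > 0")
    return S / denom


def individual_denominator(spectrum: DepthSpectrum) -> float:
    """Sum of L(i) * P(both alleles read at depth i) for a diploid."""
    return sum(
        length * (1.0 - 2.0 * 0.5**depth) for depth, length in spectrum.items()
    )


def theta_w_individual(S: int, spectrum: DepthSpectrum) -> float:
    """Low-depth-corrected Watterson's theta per bp for one diploid."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return 0.0
    denom = individual_denominator(spectrum)
    if denom <= 0:
        raise ValueError("zero effective length with S > 0")
    return S / denom


def theta_pi_pool(
    sites: Iterable[AlleleCount], covered_bp: int, nc: int
) -> float:
    """Average pairwise diversity across reads, corrected by nc/(nc-1)."""
    if covered_bp <= 0:
        raise ValueError("covered_bp must be positive")
    total = 0.0
    for site in sites:
        r = site.depth
        if r < 2:
            continue
        total += 2.0 * site.ref_count * site.alt_count / (r * (r - 1))
    return (total / covered_bp) * nc / (nc - 1)


def derived_count(site: AlleleCount) -> int | None:
    """Derived-allele read count oriented by the outgroup base.

    Returns ``None`` when the outgroup base is unknown or matches neither
    allele (the site cannot be oriented).
    """
    og = site.outgroup_base
    if og is None:
        return None
    if og == site.ref_base:
        return site.alt_count if site.alt_base is not None else 0
    if site.alt_base is not None and og == site.alt_base:
        return site.ref_count
    return None


@lru_cache(maxsize=4096)
def _theta_h_depth_factor(r: int, nc: int) -> float:
    """E[k^2/(r(r-1)) summed over visible sites] per unit theta at depth r.

    Under the neutral model the expected number of sites per bp with ``j``
    derived copies among ``nc`` chromosomes is ``theta / j``; ``k`` reads
    of the derived allele among ``r`` follow Binom(r, j/nc).  Sites where
    every read is derived (k = r) are indistinguishable from fixed
    differences and never enter the segregating-site list, so the k = r
    term is removed from the expectation.
    """
    if r < 2:
        return 0.0
    total = 0.0
    for j in range(1, nc):
        p = j / nc
        ek2 = r * p * (1 - p) + (r * p) ** 2 - r**2 * p**r
        total += ek2 / (j * r * (r - 1))
    return total


def theta_h_denominator(spectrum: DepthSpectrum, nc: int) -> float:
    """Effective bp-equivalents for the pooled Fay-Wu estimator."""
    return sum(
        length * _theta_h_depth_factor(depth, nc)
        for depth, length in spectrum.items()
    )


def theta_h_pool(
    sites: Iterable[AlleleCount], spectrum: DepthSpectrum, nc: int
) -> float:
    """Fay-Wu theta-H per bp from outgroup-oriented derived counts.

    Sites without a usable outgroup base are skipped; the depth spectrum
    supplies the unbiasing denominator.
    """
    raw = 0.0
    for site in sites:
        r = site.depth
        if r < 2:
            continue
        k = derived_count(site)
        if k is None:
            continue
        raw += k * k / (r * (r - 1.0))
    if raw == 0.0:
        return 0.0
    denom = theta_h_denominator(spectrum, nc)
    if denom <= 0:
        raise ValueError("zero effective length with derived sites present")
    return raw / denom


def inbreeding_adjust(pi: float, F: float) -> float:
    """Rescale an observed diversity by 1/(1-F) for pedigree inbreeding F."""
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    return pi / (1.0 - F)


@dataclass
class ThetaEstimates:
    """Per-window diversity estimates (all per bp)."""

    theta_w: float
    theta_pi: float
    theta_h: float | None
    effective_denominator: float
    window: GenomeWindow


def estimate_window(window: GenomeWindow, nc: int) -> ThetaEstimates:
    """All pooled estimators for one window."""
    snps = [s for s in window.sites if s.segregating]
    denom = watterson_denominator(window.spectrum, nc)
    tw = window.S / denom if denom > 0 and window.S else 0.0
    tp = theta_pi_pool(snps, window.covered_bp, nc) if window.covered_bp else 0.0
    oriented = [s for s in snps if derived_count(s) is not None]
    th = theta_h_pool(oriented, window.spectrum, nc) if oriented else None
    return ThetaEstimates(
        theta_w=tw,
        theta_pi=tp,
        theta_h=th,
        effective_denominator=denom,
        window=window,
    )


@dataclass
class CompartmentSummary:
    """Ratios and reductions across genome compartments.

    ``pool`` / ``individual`` map compartment label -> mean per-bp theta.
    X/A is NPAR over autosome; reductions are ``1 - theta_ind /
    theta_pool``; ``individual_adjusted`` divides the individual estimates
    by ``1 - F`` for the matching compartment.
    """

    pool: dict[str, float]
    individual: dict[str, float]
    x_a_pool: float | None
    x_a_individual: float | None
    par_npar_pool: float | None
    par_npar_individual: float | None
    reduction: dict[str, float | None]
    individual_adjusted: dict[str, float]
    residual_deficit: dict[str, float | None]


def _ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or den == 0:
        return None
    return num / den


def summarize_compartments(
    pool_means: Mapping[str, float],
    individual_means: Mapping[str, float],
    F_auto: float,
    F_x: float,
) -> CompartmentSummary:
    """Derived ratios from per-compartment mean diversities.

    Compartment labels are ``autosome``, ``PAR`` and ``NPAR``.  ``F_auto``
    applies to autosomes and PAR, ``F_x`` to NPAR.
    """
    pool = dict(pool_means)
    ind = dict(individual_means)
    F_of = {"autosome": F_auto, "PAR": F_auto, "NPAR": F_x}
    adjusted = {
        c: inbreeding_adjust(v, F_of.get(c, F_auto)) for c, v in ind.items()
    }
    reduction = {
        c: (1.0 - ind[c] / pool[c]) if c in pool and pool.get(c) else None
        for c in ind
    }
    residual = {
        c: (1.0 - adjusted[c] / pool[c]) if c in pool and pool.get(c) else None
        for c in adjusted
    }
    return CompartmentSummary(
        pool=pool,
        individual=ind,
        x_a_pool=_ratio(pool.get("NPAR"), pool.get("autosome")),
        x_a_individual=_ratio(ind.get("NPAR"), ind.get("autosome")),
        par_npar_pool=_ratio(pool.get("PAR"), pool.get("NPAR")),
        par_npar_individual=_ratio(ind.get("PAR"), ind.get("NPAR")),
        reduction=reduction,
        individual_adjusted=adjusted,
        residual_deficit=residual,
    )


def _weighted_means(estimates: Sequence[ThetaEstimates]) -> dict[str, float]:
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for est in estimates:
        c = est.window.compartment
        w = est.window.covered_bp
        num[c] = num.get(c, 0.0) + est.theta_w * w
        den[c] = den.get(c, 0.0) + w
    return {c: num[c] / den[c] for c in num if den[c] > 0}


def compartment_summary(
    pool_estimates: Sequence[ThetaEstimates],
    individual_estimates: Sequence[ThetaEstimates],
    F_auto: float,
    F_x: float,
) -> CompartmentSummary:
    """Length-weighted compartment means and their derived ratios."""
    return summarize_compartments(
        _weighted_means(pool_estimates),
        _weighted_means(individual_estimates),
        F_auto,
        F_x,
    )
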