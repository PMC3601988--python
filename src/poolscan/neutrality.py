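"""Pool-adapted neutrality tests and extreme-window selection.

Tajima's D contrasts theta-pi against Watterson's theta; Fay-Wu's H
contrasts theta-pi against the high-frequency-derived estimator theta-H.
Both differences are standardised by their null standard deviation, which
is evaluated empirically by simulating neutral windows that match the
observed depth spectrum and pool size (coalescent haplotypes without
recombination, site-level read sampling).  The combined rank test
multiplies the per-statistic ranks (ascending, so the most negative D and
H and the lowest theta rank first) to flag jointly extreme windows; the
low/high-variability rules intersect individual and pool windows on the
same grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from poolscan.diversity import (
    ThetaEstimates,
    theta_h_pool,
    theta_pi_pool,
    theta_w_pool,
)
from poolscan.io_windows import DepthSpectrum, GenomeWindow
from poolscan import simulate as _sim


@dataclass
class NullCalibration:
    """Empirical null variances for the standardized D and H statistics.

    Variances are of the window-total (per-bp difference times covered
    bp) under the standard neutral model without recombination, matched
    to a depth spectrum, pool size and theta.
    """

    spectrum: DepthSpectrum
    nc: int
    theta: float
    replicates: int
    seed: int
    var_d: float
    var_h: float


def calibrate_null(
    spectrum: DepthSpectrum,
    nc: int,
    theta: float,
    replicates: int = 200,
    seed: int = 1,
) -> NullCalibration:
    """Simulate neutral windows matching the spectrum to estimate variances."""
    if replicates < 100:
        raise ValueError("need >= 100 replicates for a stable variance")
    if theta <= 0:
        raise ValueError("theta must be positive (null is uninformative)")
    if all(d < 2 for d, _ in spectrum.items()):
        raise ValueError("degenerate spectrum: no depth >= 2")
    L = spectrum.total_length
    rng = np.random.default_rng(seed)
    d_diffs = np.empty(replicates)
    h_diffs = np.empty(replicates)
    for rep in range(replicates):
        haps = _sim.sim_haplotypes(
            nc, theta, 0.0, L, int(rng.integers(1, 2**31 - 1))
        )
        sites = _sim.sample_pool_counts(
            haps, spectrum, int(rng.integers(1, 2**31 - 1))
        )
        S = len(sites)
        tw = theta_w_pool(S, spectrum, nc) if S else 0.0
        tp = theta_pi_pool(sites, L, nc)
        th = theta_h_pool(sites, spectrum, nc)
        d_diffs[rep] = (tp - tw) * L
        h_diffs[rep] = (tp - th) * L
    var_d = float(np.var(d_diffs, ddof=1))
    var_h = float(np.var(h_diffs, ddof=1))
    if var_d <= 0 or var_h <= 0:
        raise ValueError("uninformative null: zero variance")
    return NullCalibration(
        spectrum=spectrum.copy(),
        nc=nc,
        theta=theta,
        replicates=replicates,
        seed=seed,
        var_d=var_d,
        var_h=var_h,
    )


def tajima_d_pool(est: ThetaEstimates, calibration: NullCalibration) -> float:
    """Normalized Tajima's D for one window."""
    L = est.window.covered_bp
    return (est.theta_pi - est.theta_w) * L / math.sqrt(calibration.var_d)


def fay_wu_h_pool(
    est: ThetaEstimates, calibration: NullCalibration
) -> float | None:
    """Normalized Fay-Wu's H; None when no site could be oriented."""
    if est.theta_h is None:
        return None
    L = est.window.covered_bp
    return (est.theta_pi - est.theta_h) * L / math.sqrt(calibration.var_h)


@dataclass
class WindowTestResult:
    window: GenomeWindow
    D: float
    H: float
    theta_w: float
    r_d: float = 0.0
    r_h: float = 0.0
    r_t: float = 0.0
    score: float = 0.0
    outlier: bool = False


def combined_rank_test(
    results: Sequence[WindowTestResult], extreme_fraction: float = 0.01
) -> tuple[list[WindowTestResult], list[WindowTestResult]]:
    """Rank-product combination of D, H and theta_w.

    Each statistic is ranked ascending (ties mid-ranked); the combined
    score is the product of rank/M normalised to sum to one over windows.
    The lowest ``extreme_fraction`` of scores (at least one window) are
    flagged as outliers, ties broken by (D, H, theta, coordinates).
    Windows with undefined statistics must be filtered out beforehand.
    """
    M = len(results)
    if M < 3:
        raise ValueError("need at least 3 windows")
    D = np.array([r.D for r in results])
    H = np.array([r.H for r in results])
    T = np.array([r.theta_w for r in results])
    if np.isnan(D).any() or np.isnan(H).any():
        raise ValueError("undefined statistics present; exclude those windows")
    rd = rankdata(D)
    rh = rankdata(H)
    rt = rankdata(T)
    raw = (rd / M) * (rh / M) * (rt / M)
    norm = raw / raw.sum()
    for r, a, b, c, s in zip(results, rd, rh, rt, norm):
        r.r_d, r.r_h, r.r_t, r.score = float(a), float(b), float(c), float(s)
        r.outlier = False
    n_out = max(1, int(extreme_fraction * M))
    order = sorted(
        range(M),
        key=lambda i: (
            norm[i],
            D[i],
            H[i],
            T[i],
            results[i].window.chrom,
            results[i].window.start,
        ),
    )
    outliers = []
    for i in order[:n_out]:
        results[i].outlier = True
        outliers.append(results[i])
    return list(results), outliers


def _check_same_grid(
    a: Sequence[ThetaEstimates], b: Sequence[ThetaEstimates]
) -> None:
    keys_a = {e.window.key for e in a}
    keys_b = {e.window.key for e in b}
    if not keys_a & keys_b:
        raise ValueError("window grids are disjoint")


def _lowest_cutoff(values: np.ndarray, fraction: float) -> float:
    """Nearest-rank cutoff for the lowest `fraction`; boundary inclusive."""
    k = max(1, math.ceil(fraction * values.size))
    return float(np.sort(values)[k - 1])


def _highest_cutoff(values: np.ndarray, fraction: float) -> float:
    k = max(1, math.ceil(fraction * values.size))
    return float(np.sort(values)[-k])


def select_low_variability(
    individual: Sequence[ThetaEstimates],
    pool: Sequence[ThetaEstimates],
    pool_fraction: float = 0.05,
    min_individual_cov: int = 10_000,
    min_pool_cov: int = 3_000,
) -> list[GenomeWindow]:
    """Windows devoid of individual variability and in the pool's low tail.

    Selected when the individual window has S = 0 with more than
    ``min_individual_cov`` bp assembled and the same window falls in the
    lowest ``pool_fraction`` of pool theta with at least ``min_pool_cov``
    bp aligned.
    """
    _check_same_grid(individual, pool)
    eligible_pool = {
        e.window.key: e for e in pool if e.window.covered_bp >= min_pool_cov
    }
    if not eligible_pool:
        return []
    cutoff = _lowest_cutoff(
        np.array([e.theta_w for e in eligible_pool.values()]), pool_fraction
    )
    selected = []
    for e in individual:
        if e.window.S != 0 or e.window.covered_bp <= min_individual_cov:
            continue
        p = eligible_pool.get(e.window.key)
        if p is not None and p.theta_w <= cutoff:
            selected.append(e.window)
    return selected


def select_high_variability(
    individual: Sequence[ThetaEstimates],
    pool: Sequence[ThetaEstimates],
    fraction: float = 0.05,
    min_individual_cov: int = 10_000,
    min_pool_cov: int = 3_000,
) -> list[GenomeWindow]:
    """Windows in the top tail of both datasets with sufficient coverage."""
    _check_same_grid(individual, pool)
    elig_ind = [e for e in individual if e.window.covered_bp >= min_individual_cov]
    elig_pool = {
        e.window.key: e for e in pool if e.window.covered_bp >= min_pool_cov
    }
    if not elig_ind or not elig_pool:
        return []
    cut_ind = _highest_cutoff(
        np.array([e.theta_w for e in elig_ind]), fraction
    )
    cut_pool = _highest_cutoff(
        np.array([e.theta_w for e in elig_pool.values()]), fraction
    )
    selected = []
    for e in elig_ind:
        if e.theta_w < cut_ind:
            continue
        p = elig_pool.get(e.window.key)
        if p is not None and p.theta_w >= cut_pool:
            selected.append(e.window)
    return selected
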