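"""Multilocus Hudson-Kreitman-Aguade test adapted to pooled data.

Each 200-kb window contributes a segregating-site count ``S`` and a count
of fixed differences to the outgroup ``Dv`` over ``L`` compared bp.
Under the stationary neutral model::

    E[S_w]  = theta_w * L_w * a*_w
    E[Dv_w] = theta_w * L_w * (T + c_w)

where ``T`` is the species split time in units of 2Ne generations and
``a*_w`` the *effective* Watterson constant of the window: the pooled
Eq.-1 denominator divided by the compared length.  Because reads sample
pool chromosomes with replacement, the classical constants ``a_n``,
``b_n`` are unknown; ``a*`` is computed from the depth spectrum, and a
continuous effective sample size ``n*`` is recovered through the analytic
continuation ``a(n) = psi(n) + gamma``; then ``b* = pi^2/6 - psi'(n*)``
and the within-species contribution to divergence is evaluated at ``n*``
as ``c = (n* + 1) / (3 (n* - 1))``.

The M+1 moment equations (one per window plus the total-divergence
equation) are solved by bisection on ``T`` with the per-window thetas
eliminated in closed form.  Each window then yields a partial chi-square

    X_w = (S - E S)^2 / Var S + (Dv - E Dv)^2 / Var Dv

with ``Var S = E S + (theta L)^2 b*`` and ``Var Dv = E Dv +
(theta L c)^2``; the total sum is tested against chi-square with M - 1
degrees of freedom, and per-window p-values (1 d.f.) are screened by
Benjamini-Hochberg at a 5% false discovery rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from poolscan.diversity import watterson_denominator
from poolscan.io_windows import DepthSpectrum

_EULER_GAMMA = 0.5772156649015329
_PI2_6 = math.pi**2 / 6.0


def effective_constants(spectrum: DepthSpectrum, nc: int) -> tuple[float, float]:
    """Effective (a*, b*) Watterson constants from a pool depth spectrum."""
    L = spectrum.total_length
    if L == 0:
        raise ValueError("empty spectrum")
    a_star = watterson_denominator(spectrum, nc) / L
    if a_star <= 0:
        raise ValueError("a* must be positive (all depth-1 spectrum?)")
    n_star = effective_sample_size(a_star)
    b_star = _PI2_6 - float(polygamma(1, n_star))
    return a_star, b_star


def effective_sample_size(a_star: float) -> float:
    """Continuous n* with a(n*) = a_star via a(n) = psi(n) + gamma."""
    target = a_star - _EULER_GAMMA

    def f(n):
        return float(digamma(n)) - target

    return float(brentq(f, 1.0 + 1e-9, 1e9, xtol=1e-12, rtol=1e-14))


def divergence_coefficient(n_star: float) -> float:
    """Within-species coalescent contribution to divergence at n*."""
    if n_star <= 1.0:
        raise ValueError("n* must exceed 1")
    return (n_star + 1.0) / (3.0 * (n_star - 1.0))


@dataclass
class HKAWindowData:
    """Observed polymorphism and divergence for one window."""

    name: str
    S: int
    Dv: int
    L: int
    a_star: float
    b_star: float
    compartment: str = "autosome"

    def __post_init__(self) -> None:
        if self.S < 0 or self.Dv < 0:
            raise ValueError("counts must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.a_star <= 0:
            raise ValueError("a_star must be positive")

    @property
    def c(self) -> float:
        return divergence_coefficient(effective_sample_size(self.a_star))


def hka_window(
    name: str,
    S: int,
    Dv: int,
    spectrum: DepthSpectrum,
    nc: int,
    compartment: str = "autosome",
) -> HKAWindowData:
    """Build window data with effective constants from its depth spectrum."""
    a_star, b_star = effective_constants(spectrum, nc)
    return HKAWindowData(
        name=name,
        S=S,
        Dv=Dv,
        L=spectrum.total_length,
        a_star=a_star,
        b_star=b_star,
        compartment=compartment,
    )


@dataclass
class HKAFit:
    thetas: np.ndarray  # per-window theta per bp
    T: float
    converged: bool
    iterations: int
    residual: float


def _check_compartments(data: Sequence[HKAWindowData]) -> None:
    comps = {d.compartment for d in data}
    if "NPAR" in comps and len(comps) > 1:
        raise ValueError(
            "NPAR windows must be fitted separately from autosomes/PAR"
        )


def _thetas_at(data: Sequence[HKAWindowData], T: float, cs: np.ndarray) -> np.ndarray:
    tot = np.array([d.S + d.Dv for d in data], dtype=float)
    L = np.array([d.L for d in data], dtype=float)
    a = np.array([d.a_star for d in data], dtype=float)
    return tot / (L * (a + T + cs))


def hka_fit(
    data: Sequence[HKAWindowData],
    t_bracket: tuple[float, float] = (1e-6, 100.0),
    tol: float = 1e-12,
    max_iter: int = 500,
) -> HKAFit:
    """Solve the M+1 moment equations by bisection on the split time T.

    For each candidate T the per-window equations ``S + Dv = theta L (a*
    + T + c)`` give the thetas in closed form; T is then bisected on the
    residual of the total-divergence equation ``sum Dv = sum theta L (T +
    c)``.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 windows")
    _check_compartments(data)
    if not any(d.S > 0 for d in data) or not any(d.Dv > 0 for d in data):
        raise ValueError("need polymorphism and divergence somewhere")
    cs = np.array([d.c for d in data])
    L = np.array([d.L for d in data], dtype=float)
    Dv_tot = float(sum(d.Dv for d in data))

    def residual(T: float) -> float:
        th = _thetas_at(data, T, cs)
        return Dv_tot - float(np.sum(th * L * (T + cs)))

    lo, hi = t_bracket
    f_lo, f_hi = residual(lo), residual(hi)
    expand = 0
    while f_lo * f_hi > 0 and expand < 60:
        hi *= 2.0
        f_hi = residual(hi)
        expand += 1
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no sign change for T in [{lo}, {hi}]; residuals {f_lo}, {f_hi}"
        )
    it = 0
    while it < max_iter:
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        it += 1
        if hi - lo < tol * max(1.0, mid):
            break
    T = 0.5 * (lo + hi)
    thetas = _thetas_at(data, T, cs)
    scale = max(Dv_tot, 1.0)
    res = abs(residual(T)) / scale
    return HKAFit(
        thetas=thetas,
        T=T,
        converged=res < 1e-10,
        iterations=it,
        residual=res,
    )


@dataclass
class HKAWindowResult:
    name: str
    partial: float
    direction: str  # excess_differentiation | excess_polymorphism
    p_value: float


def hka_partials(
    data: Sequence[HKAWindowData], fit: HKAFit
) -> tuple[list[HKAWindowResult], float, float]:
    """Per-window partial chi-squares, the total statistic and its p-value."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    results: list[HKAWindowResult] = []
    total = 0.0
    m_used = 0
    for d, theta in zip(data, fit.thetas):
        tl = theta * d.L
        eS = tl * d.a_star
        eD = tl * (fit.T + d.c)
        vS = eS + tl**2 * d.b_star
        vD = eD + (tl * d.c) ** 2
        if vS <= 0 or vD <= 0:
            continue  # degenerate window (theta == 0): no information
        # The window moment equation S + Dv = theta L (a* + T + c) holds
        # exactly at the fit, so the S- and Dv-deviations are opposite:
        # one free residual per window.  Studentizing it by its null
        # variance keeps the per-window chi-square calibrated; when both
        # variances are Poisson-dominated (short loci) this equals the
        # classical (S - ES)^2/VarS + (Dv - EDv)^2/VarDv exactly.
        w = (fit.T + d.c) / (d.a_star + fit.T + d.c)
        resid = d.S - eS  # == -(Dv - EDv)
        var_resid = w**2 * vS + (1.0 - w) ** 2 * vD
        partial = resid**2 / var_resid
        direction = (
            "excess_differentiation" if resid < 0 else "excess_polymorphism"
        )
        results.append(
            HKAWindowResult(
                name=d.name,
                partial=partial,
                direction=direction,
                p_value=float(chi2.sf(partial, 1)),
            )
        )
        total += partial
        m_used += 1
    p_total = float(chi2.sf(total, max(m_used - 1, 1)))
    return results, total, p_total


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Step-up FDR control; returns a boolean flag per hypothesis."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def simulate_null_data(
    data: Sequence[HKAWindowData],
    fit: HKAFit,
    seed: int,
) -> list[HKAWindowData]:
    """Draw S and Dv from the fitted neutral model (moment-matched).

    Counts are generated as gamma-mixed Poissons whose mean and variance
    equal the model's ``E[S], Var[S]`` and ``E[Dv], Var[Dv]``, mimicking
    the coalescent (evolutionary) variance on top of mutational noise.
    """
    rng = np.random.default_rng(seed)
    out: list[HKAWindowData] = []
    for d, theta in zip(data, fit.thetas):
        tl = theta * d.L
        eS = tl * d.a_star
        eD = tl * (fit.T + d.c)
        exS = tl**2 * d.b_star  # extra-Poisson variance of S
        exD = (tl * d.c) ** 2

        def draw(mean: float, extra: float) -> int:
            if mean <= 0:
                return 0
            if extra <= 0:
                return int(rng.poisson(mean))
            shape = mean**2 / extra
            lam = rng.gamma(shape, extra / mean)
            return int(rng.poisson(lam))

        out.append(
            HKAWindowData(
                name=d.name,
                S=draw(eS, exS),
                Dv=draw(eD, exD),
                L=d.L,
                a_star=d.a_star,
                b_star=d.b_star,
                compartment=d.compartment,
            )
        )
    return out


def count_fixed_differences(
    sites: Sequence, min_depth: int = 3, max_depth: int = 30
) -> int:
    """Count sites where all reads carry a non-outgroup base.

    A fixed difference shows every read equal to one allele while the
    outgroup base differs; sites without outgroup information are
    ignored.
    """
    n = 0
    for s in sites:
        if s.outgroup_base is None:
            continue
        d = s.depth
        if d < min_depth or d > max_depth:
            continue
        if s.alt_count == 0 and s.ref_base != s.outgroup_base:
            n += 1
        elif s.ref_count == 0 and s.alt_base and s.alt_base != s.outgroup_base:
            n += 1
    return n
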