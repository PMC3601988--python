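"""Read-depth multicopy-region (MCR) detection.

Mean read depth in non-overlapping 1-kb bins is corrected for GC bias
against a copy-number-neutral baseline, converted to an integer copy
number against the diploid mean, and chained into MCR segments: runs of
bins with CN >= 3 spanning at least 4 kb, allowing single 1-kb gaps.
Only gains relative to the reference are considered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import trim_mean

from poolscan.diversity import theta_w_pool
from poolscan.io_windows import DepthSpectrum, GenomeWindow

BIN_SIZE = 1000
CN_CAP = 100


@dataclass
class DepthBin:
    """One 1-kb depth bin."""

    chrom: str
    start: int  # multiple of the bin size
    raw_depth: float  # mean reads per bp
    gc_fraction: float
    masked_fraction: float = 0.0
    corrected_depth: float | None = None
    cn: int | None = None


@dataclass
class MCRSegment:
    """A chained multicopy region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_cn: float
    n_bins: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _usable(b: DepthBin) -> bool:
    return b.masked_fraction <= 0.5


def gc_correct(
    bins: Sequence[DepthBin],
    baseline_bins: Sequence[DepthBin] | None = None,
    interval_width: float = 0.02,
    min_bins: int = 20,
    trim: float = 0.1,
) -> list[DepthBin]:
    """GC-bias correction against a copy-number-neutral baseline.

    The GC axis is partitioned into intervals of ``interval_width``; the
    correction factor of an interval is the overall baseline mean depth
    divided by the baseline mean in that interval.  When no explicit
    baseline is supplied, the genome-wide bins themselves serve as
    baseline with a 10%-per-tail trimmed mean per interval, which is
    robust to the multicopy minority.  Intervals with fewer than
    ``min_bins`` baseline bins borrow the nearest populated interval's
    factor.
    """
    base = [b for b in (baseline_bins if baseline_bins is not None else bins) if _usable(b)]
    if not base:
        raise ValueError("no baseline bins available")
    n_int = int(math.ceil(1.0 / interval_width))
    idx_of = lambda g: min(int(g / interval_width), n_int - 1)
    by_int: dict[int, list[float]] = {}
    for b in base:
        by_int.setdefault(idx_of(b.gc_fraction), []).append(b.raw_depth)
    overall = trim_mean([b.raw_depth for b in base], trim)
    factors: dict[int, float] = {}
    for i, depths in by_int.items():
        if len(depths) >= min_bins:
            m = trim_mean(depths, trim) if len(depths) >= 10 else float(np.mean(depths))
            if m > 0:
                factors[i] = overall / m
    if not factors:
        # too sparse for stratification: fall back to no correction
        factors = {0: 1.0}
    populated = sorted(factors)
    out: list[DepthBin] = []
    for b in bins:
        i = idx_of(b.gc_fraction)
        if i in factors:
            f = factors[i]
        else:
            nearest = min(populated, key=lambda j: abs(j - i))
            f = factors[nearest]
        out.append(
            DepthBin(
                chrom=b.chrom,
                start=b.start,
                raw_depth=b.raw_depth,
                gc_fraction=b.gc_fraction,
                masked_fraction=b.masked_fraction,
                corrected_depth=b.raw_depth * f,
                cn=b.cn,
            )
        )
    return out


def copy_number(
    bins: Sequence[DepthBin], diploid_mean_depth: float
) -> list[DepthBin]:
    """Integer copy number from corrected depth, rounded half-up."""
    if diploid_mean_depth <= 0:
        raise ValueError("diploid_mean_depth must be positive")
    out = []
    for b in bins:
        depth = b.corrected_depth if b.corrected_depth is not None else b.raw_depth
        cn = int(math.floor(2.0 * depth / diploid_mean_depth + 0.5))
        out.append(
            DepthBin(
                chrom=b.chrom,
                start=b.start,
                raw_depth=b.raw_depth,
                gc_fraction=b.gc_fraction,
                masked_fraction=b.masked_fraction,
                corrected_depth=depth,
                cn=min(cn, CN_CAP),
            )
        )
    return out


def chain_mcrs(
    bins: Sequence[DepthBin],
    min_len: int = 4000,
    min_cn: int = 3,
    max_gap: int = 1000,
    bin_size: int = BIN_SIZE,
) -> list[MCRSegment]:
    """Chain CN >= min_cn bins into segments.

    Qualifying bins may be separated by at most ``max_gap`` bp of
    sub-threshold or missing bins (single 1-kb gaps by default); chains
    spanning less than ``min_len`` are discarded.  Gap bins do not count
    toward the mean copy number.
    """
    qual = sorted(
        (b for b in bins if b.cn is not None and b.cn >= min_cn and _usable(b)),
        key=lambda b: (b.chrom, b.start),
    )
    segments: list[MCRSegment] = []
    run: list[DepthBin] = []

    def _flush() -> None:
        if not run:
            return
        start = run[0].start
        end = run[-1].start + bin_size
        if end - start >= min_len:
            segments.append(
                MCRSegment(
                    chrom=run[0].chrom,
                    start=start,
                    end=end,
                    mean_cn=float(np.mean([b.cn for b in run])),
                    n_bins=len(run),
                )
            )

    for b in qual:
        if run and (
            b.chrom != run[-1].chrom
            or b.start - (run[-1].start + bin_size) > max_gap
        ):
            _flush()
            run = []
        run.append(b)
    _flush()
    return segments


def _merged_coverage(
    intervals: Sequence[tuple[int, int]], start: int, end: int
) -> int:
    """bp of [start, end) covered by the union of intervals."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in intervals if e > start and s < end
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def gene_overlap(
    segments: Sequence[MCRSegment],
    genes: Sequence[tuple[str, int, int, str]],
) -> dict[str, tuple[str, float]]:
    """Classify each gene by MCR coverage of its length.

    Genes are ``(chrom, start, end, name)`` half-open intervals.  A gene
    is ``full`` when 100% of its length is covered by (merged) segments,
    ``partial`` when strictly more than half but not all is covered, and
    ``none`` otherwise.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    out: dict[str, tuple[str, float]] = {}
    for chrom, start, end, name in genes:
        if end <= start:
            raise ValueError(f"zero-length gene {name}")
        cov = _merged_coverage(by_chrom.get(chrom, []), start, end)
        frac = cov / (end - start)
        if frac >= 1.0:
            cls = "full"
        elif frac > 0.5:
            cls = "partial"
        else:
            cls = "none"
        out[name] = (cls, frac)
    return out


@dataclass
class WindowMCRSplit:
    """Per-window diversity split at MCR boundaries."""

    window: GenomeWindow
    mcr_bp: int
    stratum: str  # with_mcr | without_mcr
    theta_inside: float | None
    theta_outside: float | None


def mcr_window_overlap(
    segments: Sequence[MCRSegment],
    windows: Sequence[GenomeWindow],
    nc: int,
) -> tuple[list[WindowMCRSplit], dict[str, float]]:
    """Split window diversity inside vs. outside MCR boundaries.

    Each callable site of a window is classified by whether it falls in
    an MCR segment; Watterson's theta is recomputed per side from the
    side's own segregating sites and depth spectrum.  The summary maps
    the three strata (inside MCRs, outside-MCR parts of windows that
    contain MCRs, windows without MCRs) to mean theta over windows.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    for v in by_chrom.values():
        v.sort()
    splits: list[WindowMCRSplit] = []
    sums = {"inside_mcr": [], "outside_in_mcr_windows": [], "windows_without_mcr": []}
    for w in windows:
        ivs = by_chrom.get(w.chrom, [])
        starts = np.array([s for s, _ in ivs]) if ivs else np.empty(0)
        ends = np.array([e for _, e in ivs]) if ivs else np.empty(0)

        def inside(pos: int) -> bool:
            if starts.size == 0:
                return False
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            return i >= 0 and pos < ends[i]

        spec_in, spec_out = DepthSpectrum(), DepthSpectrum()
        s_in = s_out = 0
        for site in w.sites:
            if inside(site.pos):
                spec_in.add(site.depth)
                if site.segregating:
                    s_in += 1
            else:
                spec_out.add(site.depth)
                if site.segregating:
                    s_out += 1
        mcr_bp = _merged_coverage(ivs, w.start, w.end)
        if mcr_bp == 0:
            th_out = (
                theta_w_pool(s_out, spec_out, nc) if spec_out.total_length else None
            )
            splits.append(
                WindowMCRSplit(w, 0, "without_mcr", None, th_out)
            )
            if th_out is not None:
                sums["windows_without_mcr"].append(th_out)
            continue
        th_in = theta_w_pool(s_in, spec_in, nc) if spec_in.total_length else None
        th_out = theta_w_pool(s_out, spec_out, nc) if spec_out.total_length else None
        splits.append(WindowMCRSplit(w, mcr_bp, "with_mcr", th_in, th_out))
        if th_in is not None:
            sums["inside_mcr"].append(th_in)
        if th_out is not None:
            sums["outside_in_mcr_windows"].append(th_out)
    summary = {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in sums.items()
    }
    return splits, summary
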