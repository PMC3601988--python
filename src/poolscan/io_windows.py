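"""Per-site read evidence, genome windows and standard-format I/O.

Input dialects are samtools-pileup text (per-site read bases + qualities)
and sync-style tab-separated ``A:T:C:G:N:del`` allele counts.  Internally
all coordinates are 0-based half-open; pileup and VCF I/O are 1-based.

A :class:`GenomeWindow` aggregates the callable sites of a fixed-size,
non-overlapping genomic interval together with its *depth spectrum*
``L(i)`` -- the number of callable base pairs covered by exactly ``i``
reads -- which is the quantity the pooled diversity estimators correct by.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence, TextIO

NUCLEOTIDES = ("A", "C", "G", "T")

# column order of sync-style count fields
_SYNC_BASES = ("A", "T", "C", "G")


class PileupParseError(ValueError):
    """Raised when a pileup or count line cannot be decoded."""


@dataclass
class SiteRecord:
    """Read evidence at a single site.

    ``base_calls`` is a sequence of ``(base, phred_quality)`` tuples, one
    per read covering the site after quality filtering.
    """

    chrom: str
    pos: int  # 0-based
    ref_base: str
    base_calls: list[tuple[str, int]]
    outgroup_base: str | None = None

    @property
    def depth(self) -> int:
        return len(self.base_calls)


@dataclass
class AlleleCount:
    """Biallelic summary of a site: reference and alternative read counts.

    ``mean_quality_*`` are Phred-scale geometric means of the per-read
    error probabilities (equivalently, arithmetic means of the Phred
    scores) of the reads supporting each allele.
    """

    chrom: str
    pos: int  # 0-based
    ref_base: str
    ref_count: int
    alt_count: int
    alt_base: str | None = None
    mean_quality_ref: float = 0.0
    mean_quality_alt: float = 0.0
    outgroup_base: str | None = None
    segregating: bool | None = None

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class DepthSpectrum:
    """Mapping read depth ``i`` -> covered length ``L(i)`` in bp."""

    lengths: dict[int, int] = field(default_factory=dict)

    def add(self, depth: int, length: int = 1) -> None:
        if depth < 1:
            raise ValueError("depth classes start at 1")
        self.lengths[depth] = self.lengths.get(depth, 0) + length

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @property
    def mean_depth(self) -> float:
        tot = self.total_length
        if tot == 0:
            return 0.0
        return sum(i * l for i, l in self.lengths.items()) / tot

    def items(self):
        return sorted(self.lengths.items())

    def copy(self) -> "DepthSpectrum":
        return DepthSpectrum(dict(self.lengths))


@dataclass
class GenomeWindow:
    """Non-overlapping fixed-size window of callable sites.

    ``S`` counts the sites flagged segregating; ``spectrum`` tallies the
    callable bp of the window by exact read depth.  The compartment label
    distinguishes autosomes from the X pseudoautosomal (PAR) and
    non-pseudoautosomal (NPAR) regions.
    """

    chrom: str
    start: int
    end: int
    spectrum: DepthSpectrum = field(default_factory=DepthSpectrum)
    S: int = 0
    sites: list[AlleleCount] = field(default_factory=list)
    compartment: str = "autosome"

    @property
    def covered_bp(self) -> int:
        return self.spectrum.total_length

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _phred_mean(quals: Sequence[int]) -> float:
    # geometric mean of error probabilities == arithmetic mean of Phreds
    if not quals:
        return 0.0
    return float(sum(quals)) / len(quals)


def _decode_pileup_bases(bases: str, ref: str, lineno: int) -> list[str]:
    """Expand a pileup read-base string into one symbol per read."""
    out: list[str] = []
    i, n = 0, len(bases)
    ref = ref.upper()
    while i < n:
        c = bases[i]
        if c == "^":  # read start; next char is mapping quality
            i += 2
            continue
        if c == "$":  # read end marker
            i += 1
            continue
        if c in "+-":  # indel: +N<seq> / -N<seq>
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"line {lineno}: malformed indel token at column {i}"
                )
            indel_len = int(bases[i + 1 : j])
            i = j + indel_len
            continue
        if c in ".,":
            out.append(ref)
        elif c.upper() in NUCLEOTIDES:
            out.append(c.upper())
        elif c in "*><Nn":
            out.append("*")  # placeholder: consumes a quality, not a base
        else:
            raise PileupParseError(
                f"line {lineno}: unknown pileup symbol {c!r}"
            )
        i += 1
    return out


def read_pileup(
    stream: Iterable[str], min_base_quality: int = 0, quality_offset: int = 33
) -> Iterator[SiteRecord]:
    """Parse samtools-pileup text into :class:`SiteRecord` values.

    Positions are converted from the 1-based input convention to 0-based.
    Bases with Phred quality below ``min_base_quality`` are removed.
    Records with an ``N`` reference base are dropped.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 6:
            raise PileupParseError(
                f"line {lineno}: expected >= 6 columns, got {len(fields)}"
            )
        chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
        try:
            pos1 = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: {exc}") from None
        ref = ref.upper()
        if ref not in NUCLEOTIDES:
            continue
        decoded = _decode_pileup_bases(bases, ref, lineno)
        if len(decoded) != depth:
            raise PileupParseError(
                f"line {lineno}: depth field {depth} != {len(decoded)} decoded calls"
            )
        if len(quals) != len(decoded):
            raise PileupParseError(
                f"line {lineno}: quality string length {len(quals)} != depth {len(decoded)}"
            )
        calls = [
            (b, ord(q) - quality_offset)
            for b, q in zip(decoded, quals)
            if b != "*" and ord(q) - quality_offset >= min_base_quality
        ]
        yield SiteRecord(chrom=chrom, pos=pos1 - 1, ref_base=ref, base_calls=calls)


def collapse_site(site: SiteRecord) -> AlleleCount:
    """Summarise a :class:`SiteRecord` to its two most frequent alleles.

    The reference base is always retained; the alternative is the most
    frequent non-reference base (ties broken alphabetically).  Third and
    fourth alleles are dropped.
    """
    counts: Counter[str] = Counter(b for b, _ in site.base_calls)
    ref = site.ref_base
    non_ref = [
        (-(counts[b]), b) for b in NUCLEOTIDES if b != ref and counts[b] > 0
    ]
    alt = min(non_ref)[1] if non_ref else None
    ref_quals = [q for b, q in site.base_calls if b == ref]
    alt_quals = [q for b, q in site.base_calls if b == alt] if alt else []
    return AlleleCount(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=ref,
        ref_count=len(ref_quals),
        alt_count=len(alt_quals),
        alt_base=alt,
        mean_quality_ref=_phred_mean(ref_quals),
        mean_quality_alt=_phred_mean(alt_quals),
        outgroup_base=site.outgroup_base,
    )


def read_counts(stream: Iterable[str], default_quality: float = 30.0) -> Iterator[AlleleCount]:
    """Parse sync-style count lines (chrom, pos, ref, A:T:C:G:N:del).

    The two most frequent bases are retained as ref/alt (the reference
    base is kept as ref whenever observed; the alternative is the most
    frequent remaining base, rank then alphabetical on ties).
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise PileupParseError(
                f"line {lineno}: expected >= 4 columns, got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        parts = fields[3].split(":")
        if len(parts) < 4:
            raise PileupParseError(f"line {lineno}: malformed count field")
        try:
            pos1 = int(pos_s)
            counts = {b: int(c) for b, c in zip(_SYNC_BASES, parts)}
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: {exc}") from None
        if any(c < 0 for c in counts.values()):
            raise PileupParseError(f"line {lineno}: negative count")
        if ref not in NUCLEOTIDES:
            continue
        ref_count = counts.get(ref, 0)
        non_ref = [
            (-counts[b], b) for b in NUCLEOTIDES if b != ref and counts[b] > 0
        ]
        alt = min(non_ref)[1] if non_ref else None
        yield AlleleCount(
            chrom=chrom,
            pos=pos1 - 1,
            ref_base=ref,
            ref_count=ref_count,
            alt_count=counts[alt] if alt else 0,
            alt_base=alt,
            mean_quality_ref=default_quality if ref_count else 0.0,
            mean_quality_alt=default_quality if alt else 0.0,
        )


def _default_is_snp(site: AlleleCount) -> bool:
    return bool(site.segregating)


def build_windows(
    sites: Iterable[AlleleCount],
    window_size: int = 200_000,
    min_depth: int = 3,
    max_depth: int = 30,
    is_snp: Callable[[AlleleCount], bool] = _default_is_snp,
    compartment_of: Callable[[str, int], str] | None = None,
) -> list[GenomeWindow]:
    """Aggregate a sorted site stream into fixed-size genome windows.

    Sites with depth outside ``[min_depth, max_depth]`` are excluded from
    both the depth spectrum and the segregating-site count ``S``.  Window
    boundaries are multiples of ``window_size``; trailing windows keep the
    nominal ``end`` so that the grid is uniform across datasets.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    windows: dict[tuple[str, int], GenomeWindow] = {}
    last: tuple[str, int] | None = None
    for site in sites:
        key = (site.chrom, site.pos)
        if last is not None and key < last and site.chrom == last[0]:
            raise ValueError(f"unsorted input at {site.chrom}:{site.pos}")
        last = key
        depth = site.depth
        if depth < min_depth or depth > max_depth:
            continue
        start = (site.pos // window_size) * window_size
        wkey = (site.chrom, start)
        win = windows.get(wkey)
        if win is None:
            comp = (
                compartment_of(site.chrom, start) if compartment_of else "autosome"
            )
            win = GenomeWindow(
                chrom=site.chrom,
                start=start,
                end=start + window_size,
                compartment=comp,
            )
            windows[wkey] = win
        win.spectrum.add(depth)
        win.sites.append(site)
        if is_snp(site):
            win.S += 1
    return [windows[k] for k in sorted(windows)]


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=PP,Number=1,Type=Float,Description="Posterior probability of segregation">
##INFO=<ID=AF,Number=1,Type=Float,Description="MAP alternative allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants(calls: Iterable, destination: TextIO) -> None:
    """Write calls as VCF v4.2 text (positions converted to 1-based).

    Calls must expose ``chrom``, ``pos`` (0-based), ``ref_base``,
    ``alt_base``, ``posterior`` and optionally ``map_frequency`` and
    ``depth``.  QUAL is the Phred-scaled posterior ``-10 log10(1 - PP)``.
    """
    destination.write(_VCF_HEADER)
    last: tuple[str, int] | None = None
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and key[0] == last[0] and key[1] < last[1]:
            raise ValueError(f"unsorted calls at {call.chrom}:{call.pos}")
        last = key
        pp = min(max(float(call.posterior), 0.0), 1.0)
        qual = -10.0 * math.log10(max(1.0 - pp, 1e-10))
        info = [f"PP={pp:.6g}"]
        af = getattr(call, "map_frequency", None)
        if af is not None:
            info.append(f"AF={af:.6g}")
        dp = getattr(call, "depth", None)
        if dp is not None:
            info.append(f"DP={dp}")
        destination.write(
            f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref_base}\t{call.alt_base}"
            f"\t{qual:.2f}\t.\t{';'.join(info)}\n"
        )


def write_regions(segments: Iterable, destination: TextIO) -> None:
    """Write segments as BED (0-based half-open) text."""
    for seg in segments:
        if isinstance(seg, tuple):
            chrom, start, end = seg[:3]
            destination.write(f"{chrom}\t{start}\t{end}\n")
        else:
            destination.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\n")


def write_window_table(windows: Iterable[GenomeWindow], destination: TextIO) -> None:
    """Per-window TSV: chrom, start, end, S, covered bp, mean depth."""
    destination.write("chrom\tstart\tend\tS\tcovered_bp\tmean_depth\n")
    for w in windows:
        destination.write(
            f"{w.chrom}\t{w.start}\t{w.end}\t{w.S}\t{w.covered_bp}"
            f"\t{w.spectrum.mean_depth:.3f}\n"
        )
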