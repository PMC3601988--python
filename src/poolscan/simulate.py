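"""Coalescent simulation of the pooled sequencing process.

Generates every input the pipeline consumes: neutral coalescent
haplotypes (via msprime, with ms-format interop), pooled short reads with
per-base errors and Phred qualities, an outgroup sequence at a stated
divergence, read-depth bin tracks with planted multicopy segments, and
the pooling power / false-discovery-rate experiment.

Scaling: ``sim_haplotypes`` parameterises msprime so that the per-bp
pairwise diversity equals ``theta_per_bp`` and the ms-style scaled
recombination rate per bp equals ``rho_per_bp`` (haploid samples,
population size 1/2, per-generation rates equal to the scaled rates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, TextIO

import msprime
import numpy as np

from poolscan.caller import PoolModelParams, posterior_batch
from poolscan.io_windows import AlleleCount, DepthSpectrum
from poolscan.mcr import DepthBin

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class Haplotypes:
    """A sample of n haplotypes over L bp with biallelic segregating sites."""

    n: int
    L: int
    positions: np.ndarray  # bp, strictly increasing
    matrix: np.ndarray  # (n, S) 0 = ancestral, 1 = derived
    ancestral: np.ndarray  # base per site
    derived: np.ndarray  # base per site

    @property
    def S(self) -> int:
        return int(self.positions.size)

    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


@dataclass
class SimConfig:
    """Study conditions for the pooling simulation."""

    n_individuals: int = 9
    read_length: int = 75
    paired: bool = True
    mean_depth: float = 14.0
    error_rate: float = 1e-3
    phred_quality: int = 30
    outgroup_divergence: float = 0.01
    dropout: float = 0.05
    seed: int = 1
    replicates: int = 10
    length: int = 1_000_000
    theta_per_bp: float = 0.001
    rho_per_bp: float = 0.001
    min_depth: int = 3
    max_depth: int = 30
    insert_size: int = 300

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def sim_haplotypes(
    n: int, theta_per_bp: float, rho_per_bp: float, L: int, seed: int
) -> Haplotypes:
    """Standard neutral coalescent sample with recombination.

    ``theta_per_bp`` is the expected pairwise diversity per bp (ms-style
    4*N*mu) and ``rho_per_bp`` the scaled recombination rate per bp.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta_per_bp < 0 or rho_per_bp < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=0.5,
        sequence_length=L,
        recombination_rate=rho_per_bp,
        random_seed=_msprime_seed(rng),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=theta_per_bp,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=_msprime_seed(rng),
    )
    pos_f = np.array([s.position for s in mts.sites()])
    geno = mts.genotype_matrix()  # (S, n)
    if pos_f.size:
        keep = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < n)
        pos = np.floor(pos_f[keep]).astype(np.int64)
        geno = np.clip(geno[keep], 0, 1)
        # collapse the rare duplicate bp position
        uniq, idx = np.unique(pos, return_index=True)
        pos, geno = uniq, geno[idx]
    else:
        pos = np.empty(0, dtype=np.int64)
        geno = np.empty((0, n), dtype=np.int8)
    S = pos.size
    anc_idx = rng.integers(0, 4, size=S)
    der_idx = (anc_idx + rng.integers(1, 4, size=S)) % 4
    return Haplotypes(
        n=n,
        L=L,
        positions=pos,
        matrix=geno.T.astype(np.int8),
        ancestral=_BASES[anc_idx],
        derived=_BASES[der_idx],
    )


def write_ms(samples: Sequence[Haplotypes], destination: TextIO) -> None:
    """Serialise haplotype samples in ms output format."""
    if not samples:
        return
    destination.write(f"ms {samples[0].n} {len(samples)}\n0 0 0\n")
    for h in samples:
        destination.write("\n//\n")
        destination.write(f"segsites: {h.S}\n")
        pos = " ".join(f"{p / h.L:.6f}" for p in h.positions)
        destination.write(f"positions: {pos}\n")
        for row in h.matrix:
            destination.write("".join(str(int(v)) for v in row) + "\n")


def read_ms(stream: Iterable[str], L: int, seed: int = 1) -> list[Haplotypes]:
    """Parse ms-format text into :class:`Haplotypes` (positions scaled by L).

    Ancestral/derived bases are not part of the ms format and are drawn
    reproducibly from ``seed``.
    """
    rng = np.random.default_rng(seed)
    samples: list[Haplotypes] = []
    lines = iter(stream)
    rows: list[str] = []
    positions: np.ndarray | None = None

    def _flush():
        nonlocal rows, positions
        if positions is None:
            return
        mat = (
            np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
            if rows
            else np.empty((0, 0), dtype=np.int8)
        )
        S = positions.size
        anc_idx = rng.integers(0, 4, size=S)
        der_idx = (anc_idx + rng.integers(1, 4, size=S)) % 4
        samples.append(
            Haplotypes(
                n=mat.shape[0],
                L=L,
                positions=positions,
                matrix=mat,
                ancestral=_BASES[anc_idx],
                derived=_BASES[der_idx],
            )
        )
        rows, positions = [], None

    for line in lines:
        line = line.strip()
        if line == "//":
            _flush()
        elif line.startswith("positions:"):
            frac = np.array([float(x) for x in line.split()[1:]])
            positions = np.floor(frac * L).astype(np.int64)
        elif line and set(line) <= {"0", "1"}:
            rows.append(line)
    _flush()
    return samples


def sim_outgroup(
    ancestral: np.ndarray, divergence_rate: float, seed: int
) -> np.ndarray:
    """Jukes-Cantor-style outgroup bases at a stated divergence rate."""
    if not 0.0 <= divergence_rate < 0.75:
        raise ValueError("divergence_rate must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    anc = np.asarray(ancestral)
    out = anc.copy()
    flip = rng.random(anc.size) < divergence_rate
    if flip.any():
        idx = np.searchsorted(_BASES, anc[flip])
        new_idx = (idx + rng.integers(1, 4, size=int(flip.sum()))) % 4
        out[flip] = _BASES[new_idx]
    return out


def _read_chromosomes(n_reads: int, n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Equal-probability individual then chromosome within individual."""
    ind = rng.integers(0, n_ind, size=n_reads)
    within = rng.integers(0, 2, size=n_reads)
    return 2 * ind + within


def sim_pool_reads(
    haps: Haplotypes, config: SimConfig, seed: int | None = None
) -> tuple[list[AlleleCount], "np.recarray", DepthSpectrum]:
    """Pooled short-read sampling over a haplotype panel.

    Reads of ``read_length`` bp start uniformly along the sequence; each
    read (fragment, when paired) comes from a uniformly chosen individual
    and one of its two chromosomes, emulating equal pooling proportions.
    Per-base errors are injected at ``error_rate`` (uniform over the
    three other bases) with the matching Phred quality emitted, and a
    per-read dropout emulates residual mapping loss.

    Returns ``(counts, truth, spectrum)``: allele counts for every truly
    segregating covered site plus every monomorphic site with at least
    one error read (zero-alternative sites can never be called and are
    summarised by the returned genome-wide depth spectrum); a truth
    recarray with per-site derived copy number, pool MAF and sampled
    depth; and the depth spectrum of all covered positions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = haps.L
    n = haps.n
    if n != config.n_chromosomes:
        raise ValueError("haplotype count must equal 2 * n_individuals")
    rl = config.read_length
    n_reads = int(round(L * config.mean_depth / rl))
    if config.paired:
        n_frag = (n_reads + 1) // 2
        frag_start = rng.integers(0, max(L - config.insert_size, 1), size=n_frag)
        starts = np.concatenate(
            [frag_start, frag_start + config.insert_size - rl]
        )
        chroms = np.tile(_read_chromosomes(n_frag, config.n_individuals, rng), 2)
    else:
        starts = rng.integers(0, max(L - rl, 1), size=n_reads)
        chroms = _read_chromosomes(n_reads, config.n_individuals, rng)
    if config.dropout > 0:
        keep = rng.random(starts.size) >= config.dropout
        starts, chroms = starts[keep], chroms[keep]
    order = np.argsort(starts, kind="stable")
    starts, chroms = starts[order], chroms[order]

    # per-position coverage
    cov = np.zeros(L + 1, dtype=np.int32)
    np.add.at(cov, starts, 1)
    np.add.at(cov, np.minimum(starts + rl, L), -1)
    cov = np.cumsum(cov)[:L]

    spectrum = DepthSpectrum()
    depths, counts_per_depth = np.unique(cov[cov > 0], return_counts=True)
    for d, c in zip(depths, counts_per_depth):
        spectrum.add(int(d), int(c))

    eps = config.error_rate
    q = float(config.phred_quality)
    counts: list[AlleleCount] = []

    # --- truly segregating sites: reads drawn from their chromosomes ---
    pos = haps.positions
    lo = np.searchsorted(starts, pos - rl + 1, side="left")
    hi = np.searchsorted(starts, pos, side="right")
    truth = np.recarray(
        pos.size,
        dtype=[
            ("pos", np.int64),
            ("derived_copies", np.int32),
            ("maf", np.float64),
            ("depth", np.int32),
            ("n_alt", np.int32),
        ],
    )
    j_all = haps.derived_counts()
    seg_positions = set()
    for s in range(pos.size):
        p = int(pos[s])
        reads = chroms[lo[s] : hi[s]]
        r = reads.size
        j = int(j_all[s])
        truth[s] = (p, j, min(j, n - j) / n, r, 0)
        if r == 0:
            continue
        seg_positions.add(p)
        alleles = haps.matrix[reads, s].astype(np.int64)  # 1 = derived
        base_idx = np.where(
            alleles == 1,
            np.searchsorted(_BASES, haps.derived[s]),
            np.searchsorted(_BASES, haps.ancestral[s]),
        )
        err = rng.random(r) < eps
        if err.any():
            base_idx[err] = (
                base_idx[err] + rng.integers(1, 4, size=int(err.sum()))
            ) % 4
        tallies = np.bincount(base_idx, minlength=4)
        ref_base = str(haps.ancestral[s])
        ref_i = int(np.searchsorted(_BASES, ref_base))
        ref_count = int(tallies[ref_i])
        tallies[ref_i] = -1
        alt_i = int(np.argmax(tallies))
        alt_count = int(tallies[alt_i])
        if alt_count <= 0:
            alt_i = None
        truth["n_alt"][s] = alt_count if alt_count > 0 else 0
        counts.append(
            AlleleCount(
                chrom="sim",
                pos=p,
                ref_base=ref_base,
                ref_count=ref_count,
                alt_count=alt_count if alt_count > 0 else 0,
                alt_base=str(_BASES[alt_i]) if alt_i is not None else None,
                mean_quality_ref=q if ref_count else 0.0,
                mean_quality_alt=q if alt_count > 0 else 0.0,
            )
        )

    # --- monomorphic sites: only sequencing errors can create alt reads ---
    n_err = rng.binomial(cov, eps)
    err_pos = np.nonzero(n_err)[0]
    for p in err_pos:
        p = int(p)
        if p in seg_positions:
            continue
        ne = int(n_err[p])
        c = int(cov[p])
        # errors distribute uniformly over the three non-reference bases
        split = rng.multinomial(ne, [1 / 3] * 3)
        alt_count = int(split.max())
        alt_offset = int(np.argmax(split)) + 1
        ref_base = str(_BASES[rng.integers(0, 4)])
        ref_i = int(np.searchsorted(_BASES, ref_base))
        alt_base = str(_BASES[(ref_i + alt_offset) % 4])
        counts.append(
            AlleleCount(
                chrom="sim",
                pos=p,
                ref_base=ref_base,
                ref_count=c - ne,
                alt_count=alt_count,
                alt_base=alt_base,
                mean_quality_ref=q,
                mean_quality_alt=q,
            )
        )
    counts.sort(key=lambda s: s.pos)
    return counts, truth, spectrum


def sample_depths(
    spectrum: DepthSpectrum, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw site depths from the length-weighted spectrum distribution."""
    items = spectrum.items()
    depths = np.array([d for d, _ in items])
    weights = np.array([l for _, l in items], dtype=float)
    weights /= weights.sum()
    return rng.choice(depths, size=size, p=weights)


def sample_pool_counts(
    haps: Haplotypes,
    spectrum: DepthSpectrum,
    seed: int,
    error_rate: float = 0.0,
    phred_quality: int = 30,
) -> list[AlleleCount]:
    """Site-level pooled read sampling (short-read limit).

    Each segregating site independently receives a depth drawn from the
    spectrum and that many reads drawn uniformly with replacement from
    the pool chromosomes -- the limit in which a read covers a single
    site.  Sites where only one allele is read are invisible and are
    omitted; the outgroup base is set to the ancestral base so the
    derived allele is fully oriented.  Used for estimator calibration.
    """
    rng = np.random.default_rng(seed)
    S = haps.S
    out: list[AlleleCount] = []
    if S == 0:
        return out
    depths = sample_depths(spectrum, S, rng)
    j = haps.derived_counts()
    q = float(phred_quality)
    for s in range(S):
        r = int(depths[s])
        reads = rng.integers(0, haps.n, size=r)
        k = int(haps.matrix[reads, s].sum())
        if error_rate > 0:
            # a flipped base goes to one of the three other bases; only a
            # third of flips swap between the two focal alleles, the rest
            # create third alleles that the biallelic collapse drops
            flips = rng.random(r) < error_rate
            toward = rng.random(r) < (1.0 / 3.0)
            derived_mask = np.zeros(r, dtype=bool)
            derived_mask[:k] = True
            third = flips & ~toward
            swapped = np.where(flips & toward, ~derived_mask, derived_mask)
            k = int(swapped[~third].sum())
            r = int(r - third.sum())
        if k <= 0 or k >= r:
            continue
        out.append(
            AlleleCount(
                chrom="sim",
                pos=int(haps.positions[s]),
                ref_base=str(haps.ancestral[s]),
                ref_count=r - k,
                alt_count=k,
                alt_base=str(haps.derived[s]),
                mean_quality_ref=q,
                mean_quality_alt=q,
                outgroup_base=str(haps.ancestral[s]),
                segregating=True,
            )
        )
    return out


def sim_depth_track(
    L: int,
    diploid_depth: float,
    planted_segments: Sequence[tuple[int, int, int]],
    gc_bias_profile: Callable[[float], float] | None = None,
    seed: int = 1,
    bin_size: int = 1000,
) -> tuple[list[DepthBin], list[tuple[str, int, int, int]]]:
    """Per-bin read-depth track with planted multicopy segments.

    Bin depth is Poisson around ``diploid_depth * cn / 2`` scaled by the
    GC bias profile (a callable of the bin's GC fraction).  Returns the
    bins and a truth BED-like list ``(chrom, start, end, cn)``.
    """
    segs = sorted(planted_segments)
    for (s1, e1, c1), (s2, e2, c2) in zip(segs, segs[1:]):
        if s2 < e1:
            raise ValueError("overlapping planted segments")
    for s, e, c in segs:
        if not (0 <= s < e <= L):
            raise ValueError("planted segment outside [0, L)")
        if c < 3:
            raise ValueError("planted copy number must be >= 3")
    rng = np.random.default_rng(seed)
    n_bins = L // bin_size
    cn = np.full(n_bins, 2, dtype=int)
    for s, e, c in segs:
        cn[s // bin_size : -(-e // bin_size)] = c
    gc = rng.uniform(0.3, 0.6, size=n_bins)
    bias = (
        np.array([gc_bias_profile(g) for g in gc])
        if gc_bias_profile
        else np.ones(n_bins)
    )
    mean_reads = diploid_depth * (cn / 2.0) * bias * bin_size
    raw = rng.poisson(mean_reads) / bin_size
    bins = [
        DepthBin(
            chrom="sim",
            start=i * bin_size,
            raw_depth=float(raw[i]),
            gc_fraction=float(gc[i]),
        )
        for i in range(n_bins)
    ]
    truth = [("sim", s, e, c) for s, e, c in segs]
    return bins, truth


@dataclass
class PowerReport:
    """Power and FDR of pooled SNP calling, overall and stratified."""

    power: float
    fdr: float
    n_true: int
    n_called: int
    n_true_positive: int
    n_false_positive: int
    power_by_maf: dict[str, float]
    power_by_depth: dict[str, float]
    power_se: float
    fdr_se: float
    replicates: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _bin_label(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})"


def power_fdr_experiment(
    config: SimConfig,
    params: PoolModelParams | None = None,
    maf_edges: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    depth_edges: Sequence[int] = (3, 8, 15, 31),
) -> PowerReport:
    """Power / FDR of the pooled design, by simulation.

    Per replicate: coalescent haplotypes -> pooled reads -> posterior
    calling within the depth band.  Power is the fraction of truly
    segregating sites whose sampled depth lies within the callable band
    that are recovered; FDR is the fraction of calls that are not true
    segregating sites.  Reads carry their true coordinates (no alignment
    stage).
    """
    if params is None:
        params = PoolModelParams(
            n_chromosomes=config.n_chromosomes,
            min_depth=config.min_depth,
            max_depth=config.max_depth,
        )
    if config.replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(config.seed)
    maf_edges = list(maf_edges)
    n_true = n_tp = n_called = n_fp = 0
    maf_true = np.zeros(len(maf_edges) - 1, dtype=int)
    maf_tp = np.zeros(len(maf_edges) - 1, dtype=int)
    dep_true = np.zeros(len(depth_edges) - 1, dtype=int)
    dep_tp = np.zeros(len(depth_edges) - 1, dtype=int)
    rep_power: list[float] = []
    rep_fdr: list[float] = []
    for _ in range(config.replicates):
        hseed = int(rng.integers(1, 2**31 - 1))
        rseed = int(rng.integers(1, 2**31 - 1))
        haps = sim_haplotypes(
            config.n_chromosomes,
            config.theta_per_bp,
            config.rho_per_bp,
            config.length,
            hseed,
        )
        counts, truth, _spectrum = sim_pool_reads(haps, config, seed=rseed)
        in_band = [
            s
            for s in counts
            if config.min_depth <= s.depth <= config.max_depth
        ]
        if in_band:
            n_A = np.array([s.alt_count for s in in_band])
            C = np.array([s.depth for s in in_band])
            eps = np.full(
                n_A.shape, 10.0 ** (-config.phred_quality / 10.0)
            )
            post, _ = posterior_batch(n_A, C, eps, params)
            called_pos = {
                s.pos
                for s, p in zip(in_band, post)
                if p > params.posterior_threshold
            }
        else:
            called_pos = set()
        callable_truth = truth[
            (truth.depth >= config.min_depth) & (truth.depth <= config.max_depth)
        ]
        true_pos = set(int(p) for p in callable_truth.pos)
        tp = sum(1 for p in called_pos if p in true_pos)
        fp = len(called_pos) - tp
        n_true += len(true_pos)
        n_tp += tp
        n_called += len(called_pos)
        n_fp += fp
        rep_power.append(tp / len(true_pos) if true_pos else np.nan)
        rep_fdr.append(fp / len(called_pos) if called_pos else 0.0)
        mafs = np.asarray(callable_truth.maf)
        depths = np.asarray(callable_truth.depth)
        hit = np.array(
            [int(p) in called_pos for p in callable_truth.pos], dtype=bool
        )
        mi = np.digitize(mafs, maf_edges) - 1
        for b in range(len(maf_edges) - 1):
            sel = mi == b
            maf_true[b] += int(sel.sum())
            maf_tp[b] += int(hit[sel].sum())
        di = np.digitize(depths, depth_edges) - 1
        for b in range(len(depth_edges) - 1):
            sel = di == b
            dep_true[b] += int(sel.sum())
            dep_tp[b] += int(hit[sel].sum())
    if n_true == 0:
        raise ValueError("no true SNPs across replicates")
    rep_power_a = np.array(rep_power, dtype=float)
    rep_fdr_a = np.array(rep_fdr, dtype=float)
    power_by_maf = {
        _bin_label(maf_edges[b], maf_edges[b + 1]): (
            maf_tp[b] / maf_true[b] if maf_true[b] else float("nan")
        )
        for b in range(len(maf_edges) - 1)
    }
    power_by_depth = {
        _bin_label(depth_edges[b], depth_edges[b + 1]): (
            dep_tp[b] / dep_true[b] if dep_true[b] else float("nan")
        )
        for b in range(len(depth_edges) - 1)
    }
    nrep = config.replicates
    return PowerReport(
        power=n_tp / n_true,
        fdr=n_fp / n_called if n_called else 0.0,
        n_true=n_true,
        n_called=n_called,
        n_true_positive=n_tp,
        n_false_positive=n_fp,
        power_by_maf=power_by_maf,
        power_by_depth=power_by_depth,
        power_se=float(np.nanstd(rep_power_a, ddof=1) / math.sqrt(nrep))
        if nrep > 1
        else float("nan"),
        fdr_se=float(np.nanstd(rep_fdr_a, ddof=1) / math.sqrt(nrep))
        if nrep > 1
        else float("nan"),
        replicates=nrep,
    )
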