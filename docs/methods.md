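# Methods

This note documents the models behind `poolscan`, the parameters that
matter, the synthetic-data generator, and the numerical and design
choices made where the problem admitted more than one reasonable answer.

## The pooled sequencing model

A pool mixes DNA of `n/2` diploid individuals in equal proportions and
is sequenced as one library. A read at a site is a draw (with
replacement) from the `n` pool chromosomes, so two quantities that are
fixed in individual sequencing become random: the number of distinct
chromosomes observed at a site, and the read fraction of an allele given
its population frequency. Every estimator and test in the package
corrects for these two layers.

Throughout, `nc = n` is the number of pool chromosomes (default 18),
`C` or `r` the read depth at a site, `L(i)` the number of callable bp
covered at exactly depth `i` in a window (the *depth spectrum*), and
`θ` the per-bp population-scaled mutation rate.

## Pool SNP caller

The likelihood marginalises the unknown carrier count `k`:

    P(n_A | f) = Σ_{k=0}^{n} Binom(n_A; C, p_k) · Binom(k; n, f),
    p_k = (k/n)(1 − ε) + (1 − k/n) ε.

`ε` is the per-read miscall probability obtained from the geometric mean
of the per-read error probabilities (equivalently the arithmetic mean of
the Phred scores), pooled across both alleles with depth weights.
Miscalls are attributed entirely to the observed alternative allele
rather than split over three bases, consistent with the upstream
collapse of each site to its two most frequent alleles (ties broken
alphabetically; the handling of triallelic sites is our choice — the
data almost never exercise it at these depths).

The prior over the population frequency `f` is a three-class mixture:

- `f = 0` (monomorphic reference): the residual mass;
- `f = 1` (fixed difference): weight `prior_divergence` (default 0.01);
- `0 < f < 1` (polymorphic): density `θ · 1/f` (neutral spectrum),
  symmetrised to `θ (1/f + 1/(1−f))` when `folded=True`, discretised on
  a uniform midpoint grid (default 512 cells, configurable). The grid is
  the model: the polymorphic class lives on the open interval sampled at
  cell midpoints, so the improper `1/f` shape needs no ad-hoc cutoff.

Defaults (`θ = 0.001`, divergence `0.01`, folded, posterior threshold
strictly `> 0.90`, callable depths 3–30×) correspond to the run settings
of the study this package reimplements. A site exactly at the threshold
is not called. With these settings and Q30 data the threshold is crossed
at roughly three alternative reads (two below ~10×), which is what
shapes the power curve below.

The three prior classes are exhaustive, so the posterior masses sum to
one; the test suite asserts this to 1e-9 together with an independent
fine-grid quadrature oracle for the posterior and an exhaustive
read-outcome enumeration oracle for the likelihood at small `n, C`.

## Diversity estimators

**Occupancy.** `Pc(j | nr, nc)` is the probability that `nr` uniform
draws with replacement from `nc` chromosomes hit exactly `j` distinct
ones. It is computed by the all-positive one-read-at-a-time recurrence
rather than the inclusion–exclusion closed form, which cancels
catastrophically for `nr, nc ≳ 40`; the two agree exactly on exhaustive
enumeration for `nr, nc ≤ 6`.

**Pooled Watterson.** `θ_w = S / Σ_i L(i) Σ_{j=2}^{min(i,nc)}
Pc(j|i,nc) a_j` with `a_j = Σ_{m<j} 1/m`. The `j ≥ 2` cut encodes that a
site can only be seen segregating when at least two distinct chromosomes
are sampled; the denominator is the effective number of bp-equivalents.
For the diploid individual the analogue divides `S` by
`Σ_i L(i)(1 − 2·0.5^i)`, the probability that both alleles of a
heterozygote appear among `i` equally-sampled reads.

**θ_π.** Average pairwise diversity across reads,
`Σ_sites 2·n_ref·n_alt/(r(r−1))` per covered bp, multiplied by
`nc/(nc−1)` (the `2n/(2n−1)` correction for `n` diploids). We use
covered bp, not nominal window size, as the denominator.

**θ_H.** Sites are oriented by the outgroup base (sites whose outgroup
matches neither allele are skipped); each contributes `k²/(r(r−1))` for
`k` derived reads of `r`. The unbiasing denominator is
`Σ_i L(i) B(i, nc)` with

    B(r, nc) = Σ_{j=1}^{nc−1} (1/j) [ r p q + (r p)² − r² p^r ] / (r(r−1)),
    p = j/nc, q = 1 − p,

the neutral-model expectation of the per-site weight summed over the
`1/j` frequency spectrum and binomial read sampling. The `p^r` term
removes configurations in which every read is derived: such sites are
indistinguishable from fixed differences and never enter the
segregating-site list, so leaving the term in would bias θ_H down at low
depth. This construction is ours (the published account defers the
factor to an unpublished reference); simulation shows E[θ_H] within ~2%
of θ across mixed-depth spectra.

**Inbreeding.** Observed diversity of an inbred individual is rescaled
as `π* = π/(1−F)` with a pedigree-derived `F` supplied by the user. Note
the source study prints `F_X = 0.46` but divides by `1 − 0.49` in its
X-chromosome worked example; both numbers are inputs here, and the tests
use 0.49 to reproduce the printed arithmetic.

**Compartments.** Windows carry an `autosome`/`PAR`/`NPAR` label;
compartment means are covered-bp-weighted (the averaging rule is not
stated in the source; length weighting is the natural estimator-level
choice). Derived ratios: X/A = NPAR/autosome, PAR/NPAR, pool→individual
reductions `1 − θ_ind/θ_pool`, and the residual deficit after inbreeding
adjustment.

## Neutrality tests

**Normalisation.** `D = (θ_π − θ_w)·L / sd` and `H = (θ_π − θ_H)·L / sd`
where the null standard deviations come from `calibrate_null`: neutral
coalescent windows (no recombination) matched to the window's depth
spectrum, pool size and θ, pushed through site-level read sampling and
the same estimators. The exact short-read variance formulas exist only
in an unpublished reference, so an empirical null is the reproducible
substitute; calibrations are deterministic given a seed and should be
cached per (nc, depth-profile stratum, θ) — mean-depth deciles are an
adequate stratification, since per-window exact profiles would be noise
dominated.

**Combined rank test.** Windows are ranked ascending on each of D, H and
θ_w (mid-ranks on ties), so the most negative D and H and the lowest θ
rank first; the score is the product of the three `rank/M` factors,
normalised to sum to one. The lowest 1% (at least one window) are
flagged, ties broken by (D, H, θ, coordinate). Ranking ascending makes
the test one-sided toward the joint sweep signature by construction.
The score is invariant to any monotone transformation of each statistic.

**Extreme-variability windows.** Low: individual windows with `S = 0`
and > 10 kb assembled, intersected with the lowest 5% of pool θ among
windows with ≥ 3 kb aligned. High: top 5% in both datasets under the
same coverage floors. Percentiles use the nearest-rank definition with
the boundary value included on the extreme side.

## Multilocus HKA

Window `w` contributes polymorphism `S_w` and fixed differences to the
outgroup `Dv_w` over `L_w` bp. Moment equations:

    E[S_w]  = θ_w L_w a*_w,      E[Dv_w] = θ_w L_w (T + c_w)

with `T` the split time in 2Ne generations. Pooling makes the classical
`a_n, b_n` constants undefined, so `a*` is the pooled Eq.-1 denominator
per bp; a continuous effective sample size `n*` solves
`ψ(n*) + γ = a*`, giving `b* = π²/6 − ψ′(n*)` (the analytic continuation
of `Σ 1/i²`) and the within-species divergence contribution
`c = (n*+1)/(3(n*−1))`, which reduces to its classical value at
saturation. The `M+1` equations are solved by bisection on `T` with the
per-window θs eliminated in closed form; at the solution all residuals
are below 1e-10 relative.

**Partials.** Because the window equation is solved exactly, the S- and
Dv-deviations from their fitted expectations are equal and opposite —
each window carries one free residual. We studentise that residual by
its null variance `w² Var S + (1−w)² Var Dv`, where
`w = (T+c)/(a*+T+c)` and `Var S = E S + (θL)² b*`,
`Var Dv = E Dv + (θL c)²` are the classical HKA variance forms. When
both variances are Poisson-dominated (short loci, the regime the
classical test was built for) this is algebraically identical to the
textbook partial `(S−ES)²/VarS + (Dv−EDv)²/VarDv`; at 200-kb genomic
windows, where the coalescent variance term dominates `Var S`, the
textbook form is badly anticonservative (~27% of null windows flagged at
BH FDR 5% in our calibration runs) while the studentised form is
calibrated (≈0% flagged, total statistic ≈ its M−1 d.f. expectation).
Direction: a negative residual in S (equivalently positive in Dv) is
`excess_differentiation`, the opposite `excess_polymorphism`. Per-window
p-values use one d.f.; the total uses `M−1`. NPAR windows must be fitted
separately from autosomes+PAR (enforced). Windows are treated as
unlinked, which is conservative for nearby windows.

**Null generator.** `simulate_null_data` draws S and Dv as gamma-mixed
Poissons matched to the model's first two moments — mutational Poisson
noise with coalescent overdispersion on top. A literal coalescent of a
continuous-`n*` sample is not defined, so moment matching is the honest
stand-in; T is recovered within 10% over replicates from data generated
this way.

## Multicopy regions

Depth in non-overlapping 1-kb bins, repeat-masked bins (> 50% masked)
ignored. GC correction stratifies the GC axis into 0.02-wide intervals;
the factor is overall baseline mean over interval baseline mean, with
sparse intervals (< 20 bins) borrowing the nearest populated interval.
The baseline is a caller-supplied copy-number-neutral bin set when
available (the source study used 1:1 human/cow/pig orthologs, which
needs external data); otherwise the genome-wide bins themselves with a
10%-per-tail trimmed mean, robust to the multicopy minority. Copy number
is `round_half_up(2·depth/diploid_mean)`, capped at 100 to guard against
collapsed repeats; only gains are considered. Chaining: maximal runs of
CN ≥ 3 bins allowing single 1-kb gaps (any number of them, but never two
adjacent — the published rule is ambiguous on this point); runs spanning
< 4 kb are discarded; gap bins do not count toward the mean CN. Gene
overlap: `full` at 100% coverage, `partial` strictly above 50%, else
`none` (boundaries follow the printed "> 50%"). Window overlap splits
each window's sites at MCR boundaries and recomputes θ_w per side from
that side's own sites and depth spectrum.

## Synthetic data

`sim_haplotypes` wraps msprime with haploid samples, population size
1/2, and per-generation mutation/recombination rates equal to the target
per-bp `θ` and ms-style `ρ`; this makes E[pairwise diversity] = θ and
E[S] = θ L a_n exactly (verified to Monte-Carlo precision). Binary
mutations on a continuous genome are floored to integer bp and the rare
duplicate position dropped. ms-format text can be written and read for
interop with external simulators.

`sim_pool_reads` emulates the pooling protocol: reads (75 bp, paired
into 300-bp fragments by default) start uniformly; each fragment comes
from a uniformly chosen individual and one of its two chromosomes (equal
pool proportions in expectation); per-base errors at the configured rate
(default 1e-3) go to a uniformly chosen other base with the matching
Phred quality (Q30) emitted; a 5% per-read dropout emulates residual
mapping loss. There is no alignment stage — reads carry true
coordinates. Monomorphic sites with zero alternative reads cannot
produce calls and are summarised by the depth spectrum rather than
materialised; error-bearing monomorphic sites get their errors split
uniformly over the three non-reference bases.

What this generator deliberately does **not** reproduce: sequencing-
platform quality profiles (per-cycle quality decay, correlated errors),
alignment artefacts (mapping-quality filtering, paralogous mismapping,
indel realignment), library-preparation coverage biases, and demographic
structure in the sample. Consequences: false-positive rates are lower
than on real data (constant Q30 makes multi-error sites rare), and
detection power at intermediate allele frequencies is higher than the
published pipeline's, which pushed ART-profile reads through BWA. The
power/FDR experiment is therefore a scaled-down idealisation: its
overall power (~51% vs the published ~47%) and FDR (~0.004 vs 0.02)
land near the reported values, while its MAF ≈ 0.3 power (~89% vs 60%)
shows exactly the gap expected from idealised qualities — at 13.3×
effective depth a MAF-0.3 site almost always yields the ~3 alternative
reads a Q30 call needs. Passing tests validate the machinery and its
calibration, not platform-specific error behaviour.

`calibrate_null` and the estimator-recovery tests use `sample_pool_counts`,
the short-read limit of the read model: each site independently receives
a depth drawn from the target spectrum and that many chromosome draws.
This is the regime the estimators' corrections assume and is orders of
magnitude faster than laying down reads.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: 10 replicates
of 500 kb for the power/FDR experiment; 200 windows for estimator
recovery; 300–500 replicates for null calibrations; 20 fits for HKA
T-recovery. These sizes put Monte-Carlo error comfortably inside the
asserted tolerances. Every stochastic component takes an explicit seed
(msprime seeds are derived from a `numpy` generator seeded by it), and
all generators are bit-reproducible for a fixed seed and package
version.

## Known limitations

- The caller's MAP frequency is reported on the unfolded scale and is
  granular at the pool's `1/nc` resolution; the `1/f` prior shifts it
  downward at low depth.
- θ_H requires outgroup-oriented sites; windows without any are excluded
  from H (and the combined test) rather than imputed.
- The HKA variance forms inherit the classical independence assumptions;
  linked windows make the test conservative, not exact.
- GC correction with the self-baseline assumes multicopy bins are a
  minority within each GC interval.
- The depth-bin simulator draws GC uniformly and Poisson depth per bin;
  it is a fixture generator, not a platform model.
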