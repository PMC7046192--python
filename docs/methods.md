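# Methods

## The inheritance model

The simulator implements a single contact-zone deme of a ZW butterfly
embedded in a large panmictic species, with four interacting elements:

- **Sex determination and meiosis.**  Non-overlapping generations with
  fixed female and male census sizes.  Female meiosis is achiasmatic:
  a mother transmits each chromosome intact.  Offspring sex is decided by
  which maternal sex-chromosome side is inherited (probability ½ each).
- **The W–chr15 fusion.**  A fused chr15 haplotype is physically attached
  to the W: daughters of a carrier always receive it, sons never do.  The
  simulator asserts every generation that no male carries a fused
  haplotype.  Each transmission of the fused haplotype is recorded as a
  node in an explicit genealogy, so the true root age (time to the most
  recent common ancestor of any sampled set of fused copies) is known
  exactly.
- **Symbiont and mitochondrion.**  Both are maternal.  The symbiont is
  transmitted with fidelity τ; sons of infected mothers die with
  penetrance k (male-killing), implemented as sampling weights before
  density regulation.  Daughters of infected broods receive a fitness
  multiplier (1 + s), the compensation that makes a male-killer spread.
  When every mother is infected at k = 1, no local sons are produced and
  the deme persists on immigrant fathers — the heavily female-biased
  contact zone, not extinction.  True extinction is signalled (a state
  flag, not a crash) only when no father exists anywhere.
- **The supergene.**  chr15 carries a recombination-suppressed interval
  with three allele classes in a dominance series
  (dorippus > orientis > chrysippus).  Male crossovers (Poisson, uniform
  breakpoints) are suppressed inside the interval in heterokaryotypes,
  as for an inversion.  Phenotype scores at the B and C loci follow the
  dominance series; heterozygotes carrying the dominant allele are
  recognised (scored 0.5) with the *transiens* penetrance (default 0.5),
  otherwise mis-scored as the dominant homozygote.
- **Immigration.**  With probability m per mating, the father is drawn
  from a static, separately constructed pool fixed for the dorippus
  supergene allele — the "most males are immigrants" regime of the
  contact zone.

## Standing variation: coalescent import

Desk-scale census sizes cannot hold the two timescales of this system
apart: the sweep is decades old while the background coalescent of the
species is effectively millions of generations deep.  A pure forward
burn-in at census Ne would make the neo-W's diversity collapse only a few
fold rather than two orders of magnitude.  The simulator therefore
imports standing variation from a neutral coalescent (msprime) with an
*ancestral* effective size (default Ne = 5,000 at μ = 2 × 10⁻⁶/bp/gen,
i.e. per-site θ = 0.04, matching the observed scale of 4-fold-site
diversity) and runs only the recent generations forward.  A pure-forward
mode (`standing_variation="forward"`) is retained and validated against
Watterson's E[S] = θ·a_n.

Supergene allele classes are likewise stated, not evolved: each class
descends from one ancient inversion template (class-defining mutations,
default 7,000 over 300 kb ≈ 2.3% divergence, plus small per-haplotype
private sets giving within-class π ≈ 0.001).  This reproduces the
empirical geometry — three tight, well-separated haplotype clusters and
F<sub>ST</sub> islands over the supergene on a near-zero genome-wide
background.

Mutations are infinite-sites: integer positions drawn from a global
per-chromosome registry, haplotypes stored as sorted position arrays, so
emitted genotypes re-derive from truth exactly.

## Conditioning on establishment

A single foundress lineage with s ≈ 0.1 is usually lost by drift.
`run_simulation` re-introduces the fusion into a fresh female whenever
the lineage dies and restarts the post-fusion clock, so a completed run
is conditioned on establishment — the situation any observed sweep
implies — and ends a known number of generations after the successful
introduction.

## What the generator emulates, and what it does not

It emulates: co-transmission closure (with τ = 1 the infected are exactly
one matriline sharing one mitochondrial clade and the fused haplotype);
diversity collapse on the neo-W; the hitchhiking of the foundress's rare
deleterious alleles into the top frequency class; sequencing as phased,
error-free fragments (geometric lengths, mean 500 bp) standing in for
read pairs, which is what the diagnostic-site/linked-variant rescue
exercises.  It does not emulate: sequencing error, mapping artefacts,
real read-depth structure (depths are Poisson, qualities constant),
spatial structure beyond one deme plus static panels, overlapping
generations, or forward fitness selection on individual mutations.
Purifying selection on coding sites is represented by thinning standing
0-fold variants at import with retention probability (1 − x)^shape
(frequency x, default shape 0 = neutral; the load analyses use shape 12),
not by per-generation selection — adequate for frequency-class contrasts
over ~100 generations, not for long-term dynamics.  A green simulator
test therefore establishes the statistical machinery and its behaviour
under the stated world, not robustness to real-data artefacts.

Two desk-scale artefacts are worth naming.  First, drift in a small
focal deme pushes rare variants past the 20% female-frequency threshold
of the female-specific scan, creating a floor on control chromosomes
that the real system (enormous Ne) does not have; the scan therefore
offers an outgroup-polarised mode (allele also absent from allopatric
populations) which removes that floor.  Second, maternal lineages inside
a small matriline coalesce quickly, so the mean pairwise divergence of
neo-W copies undershoots the root age unless the root is much younger
than the female census; the dating validation uses that regime.

## Key parameters

| parameter | default | meaning / why |
|---|---|---|
| μ | 2 × 10⁻⁶ /bp/gen | scaled so that θ and the ~100-generation sweep both resolve on ≤1-Mb chromosomes |
| ancestral Ne | 5,000 | per-site θ = 4Neμ = 0.04, the observed diversity scale |
| N_f, N_m | 60, 60 | contact-zone census; large enough for 15 carrier females |
| τ | 1.0 | strict co-transmission (stated; the co-transmission checks assume it) |
| k (male-killing) | 1.0 | complete son loss in infected broods |
| s (daughter advantage) | 0.1 | compensation driving the sweep; a calibration choice, not a measured value |
| m (immigration) | 0.1 | fraction of immigrant fathers per mating |
| run length | 100 gen | post-fusion time: enough stem mutations for diagnostics, recent enough for the 100× diversity contrast |
| supergene | chr15:200–500 kb | suppressed-recombination interval; colinear region from 600 kb |
| fragment support | ≥ 3 | haploid call threshold, the ploidy-1 minimum-depth analogue |
| window / step | 100 kb / 20 kb | scan convention (20-kb windows for painting) |

## Numerical and procedural choices

- **Coordinates** are 0-based half-open everywhere; VCF/GFF conversion at
  the boundary.  Trailing partial windows are dropped.
- **Call filter** is asymmetric by design: depth applies to every call,
  quality only to heterozygous/alternate calls; absent DP/GQ tags pass by
  default (policy flag).
- **Missing data** is a first-class state, never imputed; π, d_XY and
  distances use pairwise-complete observations.
- **Per-base denominators.**  Variants-only matrices treat unrecorded
  positions as genotyped-invariant, so window denominators are spans;
  matrices flagged as containing invariant records use record counts.
- **Hudson F<sub>ST</sub>** is computed as a ratio of window sums
  (1 − Σπ_within/Σd_XY), robust to unbalanced samples.
- **The 80% painting rule** uses the mean of the two other group-mean
  distances and a strict inequality (an exact-boundary tie is
  unassigned); windows need ≥ 100 pairwise-complete sites.
- **Degeneracy classes** are conservative: 4-fold/0-fold only, and a
  position is classified only when the other two codon positions are
  invariant in the whole dataset.  The bootstrap resamples genes (not
  sites — linkage), one-sided p = 1 − (reproducing fraction), reported as
  the bound 1/n_boot rather than 0 when all replicates reproduce; a zero
  observed difference is scored against an arbitrary direction so the
  symmetric null yields p ≈ 0.5.
- **Wilcoxon** drops zero differences, mid-ranks ties, uses the exact
  null below n = 25 (no ties) and the normal approximation otherwise.
- **PCoA** applies the Cailliez additive constant when the Gower spectrum
  has an eigenvalue below −10⁻⁸ (mismatch matrices need not be
  Euclidean).  The Procrustes statistic is the normalised residual
  m² = 1 − (Σσᵢ)²/(tr X'X · tr Y'Y), invariant to rigid motion and
  rescaling of either configuration; permutation p uses the add-one
  convention, so perfect congruence reports 1/(n_perm + 1), never 0.
- **Dating.**  T̂ = π/(2μ) assumes a star genealogy and therefore dates
  the *root of the sampled neo-W genealogy*, not the mutational origin of
  the fusion; under slow establishment the two differ.  It replaces a
  Bayesian MCMC treatment and will not reproduce a posterior mean or SD;
  it is validated by recovery of the simulator's true root age in a
  rapid-sweep regime.
- **Copy-number depth calls** accept a median strictly within ±0.2 of
  {0, 0.5, 1}; anything else is a no-call.
- **Diagnostic sites** require, by default, every non-carrier genotyped
  and lacking the allele; a tolerance flag relaxes absence to "wherever
  genotyped".

## Known limitations

- Statistical phasing is out of scope: painting consumes phased
  haplotypes (simulator truth, or externally phased data).
- The moment dating estimator has heavy-tailed error at desk scale
  (occasional false diagnostic sites admit fragments from the non-fused
  haplotype and inflate π); accuracy is a factor-two statement in the
  aggregate, not per run.
- The CLI `paco` stage uses diploid chr15 genotype distances for the host
  side (conservative); the sharper neo-W-specific test — reconstructed or
  true fused-haplotype distances against symbiont mutation sets — is
  available through the library.
- Static immigrant pools and allopatric panels do not drift; their role
  is that of reference panels, not evolving demes.
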