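# Methods

## Data model and conventions

All statistics operate on phased chromosomes × biallelic sites with
0 = ancestral and 1 = derived at polarized sites (an indel is coded as
an ordinary biallelic site). Physical positions are 1-based; windows
are half-open `[start, start+len)`, matching VCF coordinates and
avoiding double counting. Genetic distances come from a monotone
piecewise-linear bp↔cM map; extrapolation beyond the anchors is an
error unless explicitly enabled. Sites with missing calls are excluded
pairwise per statistic; the EHH family requires complete data over the
analyzed span and raises otherwise — the simplest contract that is
correct for complete resequencing data and for simulated data.
Unpolarized sites are flagged on input (VCF `AA` tag absent or
mismatching both alleles) and excluded from unfolded statistics (DAF,
Fay & Wu's H, iHS).

## Neutrality-test conventions

Tajima's constants use n = number of chromosomes (a₁ sums to n−1).
Fay & Wu's H is reported unnormalized (k − θ_H). Fu & Li's D, D* and F
follow the original 1993 variance coefficients; F* uses the corrected
coefficients of Simonsen, Churchill & Aquadro (1995), the convention of
standard resequencing software — the original misprinted F* variance
does not reproduce published resequencing summaries, the corrected one
does exactly. Fu's Fs evaluates S′ = P(K ≥ K_obs) under the exact Ewens
sampling distribution with θ set to the mean pairwise difference, using
a log-space recurrence for unsigned Stirling numbers of the first kind
(stable to n of several hundred); S′ degenerating to 0 or 1 yields a
signed infinity rather than an exception.

Printed-table recovery: a frequency printed to two decimals at 2N = 40
maps back to a unique integer count via round-half-up of DAF × 2N; this
recovers every published S, D, H, Fu & Li and Fs value to printed
precision. Per-site π is recovered to within the published ±0.0001,
the residual being the information lost in two-decimal rounding.

Empirical critical values are two-sided by default (α/2 per tail, order
statistics taken conservatively outward: the lower tail rounds the
quantile index down, the upper tail up); one-sided bounds are available.
A null smaller than 1/α draws triggers a warning.

## AMOVA FST

Locus-by-locus F_ST uses one-way variance components on the haploid 0/1
allele indicator: MSA = Σnᵢ(pᵢ−p̄)²/(r−1), MSW = Σnᵢpᵢ(1−pᵢ)/(N−r),
n_c = (N−Σnᵢ²/N)/(r−1), σ²ₐ = (MSA−MSW)/n_c, F_ST = σ²ₐ/(σ²ₐ+MSW).
Negative estimates are reported as computed (they are informative small
or zero differentiation); the all-monomorphic case is NaN.

## EHH family

Core detection is a greedy left-to-right segmentation: a span extends
while every haplotype observed over it has frequency ≥ `min_core_freq`
(default 0.04) and the span stays within `max_snps` (default 20); each
distinct allele string over a closed span is one core. This rule is
deterministic and config-exposed; it is our fixed, documented choice
where historical core-finding software left the block rule unspecified.

EHH uses exact pair counting, Σ C(e_h,2)/C(m,2), computed incrementally
outward so a whole decay curve costs O(sites × chromosomes). REHH pools
all non-carrier chromosomes at the same span as the comparison set.
Distances are measured from the nearer core edge and reported in bp and
cM; logs are natural throughout.

The marker-H evaluation distance is defined here as the first outward
marker at which the mean per-marker EHH decay across all cores reaches
the threshold (presets 0.04 and 0.02); if the decay never reaches it
the region edge is returned with a warning. The historical definition
is ambiguous about how decay is aggregated; this mean-decay rule is a
documented interpretation, not a reimplementation of any specific
legacy binary.

LRH significance: background cores from independent regions are placed
in 5% frequency bins; a normal distribution is fitted to each bin's log
REHH; tested cores get upper-tail p (selection inflates REHH — a
deliberate one-sided choice) and Benjamini–Hochberg q over all testable
cores (Storey's π₀ correction optional). Cores in empty background bins
are flagged untestable rather than given a value.

iHH/iES integrate the EHH (EHHS) decay against genetic distance by
trapezoid, starting from (0 cM, EHH 1), stopping at the first crossing
of the cutoff (default 0.05) located by linear interpolation and
integrating down to the cutoff value there; curves that never reach the
cutoff are integrated to the region edge and flagged truncated. iHS
standardization uses 20 DAF bins of 5% with background moments; |iHS|
CLR windows are 31 SNPs, centered, sliding one SNP, with no partial
windows at region edges; |iHS| bins are 0.1 wide with a final open bin,
and empty genome bins receive 0.5/(count+bins) smoothing so the CLR
stays finite. Window p-values and XP-Rsb p-values are upper-tail
empirical ranks with a 1/N floor. XP-Rsb's reference is the unweighted
mean of the other populations' iES (2N-weighted optional), standardized
by genome-wide moments of the raw ln ratios; populations with 2N < 10
are refused as targets (small-sample iES is too noisy to rank).

## Frequency windows and geography

Sliding windows are 100 kb every 20 kb, fully contained in the region;
windows with no SNP are missing, and outliers are strictly above the
background 95th percentile. The candidate filter retains SNPs whose
MAF difference between groups is ≥ 0.2 (equality retained, with a 1e-12
float guard). Latitude correlations are Pearson r of per-population
allele frequency against |latitude| with two-sided p and Bonferroni
adjustment; the partial correlation controls great-circle distance to
East Africa (Nairobi, −1.2864°, 36.8172°) by the first-order formula,
with distances by haversine on a 6371-km sphere (direct distance — no
waypoint routing, a documented simplification). Where polarization is
unknown the globally minor allele's frequency is used; both
orientations only flip the sign of r.

## Coalescent simulator

`simulate_neutral` is a Hudson-style ancestral-recombination-graph
walk: lineages carry ancestral-material segments tagged with the sample
set they subtend (bitmasks); coalescence (rate k(k−1)/2/x per
population of relative size x), recombination (rate ρ/2 × breakable
extent per lineage) and island-model migration (total per-lineage rate
M/2) compete as exponentials, with scheduled size changes, pastward
splits and migration-rate changes. Time is in units of 2N₀ generations;
θ = 4N₀μ and ρ = 4N₀r per locus. Locally fixed segments are dropped, so
the walk terminates exactly at the positionwise MRCA.

Mutations follow the infinite-sites model, placed on branch "area"
(duration × segment length): Poisson(θ/2 × total area) in θ mode, or
exactly S draws in fixed-S mode — the conditioning used for the
empirical null of the neutrality tests (fixed placement, not rejection
sampling; the tree process itself is untouched by the conditioning).
Continuous positions map to unique, strictly increasing 1-based bp.
Calibration is tested against coalescent theory (E[k] = θ at n = 2,
E[S] = θa₁) and against msprime as an independent oracle (null mean of
Tajima's D at matched configuration).

Exponential growth is approximated by an internal piecewise-constant
staircase (`growth_staircase`, default 16 epochs). Recombination is
uniform along the region. The continental presets ("african":
recent two-fold growth; "european"/"asian": out-of-Africa bottleneck
then recovery) are deliberately simple, user-editable approximations of
published human demographic calibrations, not refits of any specific
model.

`inject_sweep` is a haplotype-copy emulator: round(f·n) chromosomes
become derived carriers at the focal SNP and copy one donor haplotype
out to independent exponential breakpoints (mean = extent in cM per
side). It reproduces the homozygosity tract of a recent sweep
deterministically and cheaply, which is what a power positive-control
needs; it is not a structured-coalescent simulation of selection, so
its frequency trajectories and tree shapes are not those of a real
sweep.

## What the synthetic data does and does not show

The generator emulates (a) 4-kb resequencing-style samples in small
populations, (b) multi-population phased panels over Mb-scale regions,
and (c) pools of independent regions standing in for a genome-wide
background. It does not emulate SNP ascertainment bias, genotyping
error, gene conversion, variable mutation/recombination landscapes, or
real population structure beyond the island/split models. Passing
calibration and power tests therefore demonstrates the statistics are
implemented correctly and behave as theory predicts under the stated
models — not that thresholds tuned here transfer to any real panel.

## Problem sizes in the test suite

The distributional checks run at sizes chosen to give binomially
meaningful error bars while staying desk-scale: 2,000 + 2,000 fixed-S
replicates (n = 40, S = 16, ρ = 2) for type-I error of Tajima's D and
Fay & Wu's H; 500 panmictic regions (48 chromosomes in 4 pseudo-
populations over 600 kb) for the XP-Rsb false-positive rate; 400
panmictic replicates (12 populations × 16 chromosomes) for the latitude
false-positive rate; and 100 paired sweep/neutral replicates (120
chromosomes, 1 Mb, focal frequency 0.6, extent 0.3 cM) for power.
Tolerances are 3σ binomial at those counts, fixed before running.

## Known limitations

- Fu & Li and Fs printed-value agreement is convention-dependent; the
  implemented conventions reproduce the published resequencing table
  but other software may differ in singleton handling.
- The LRH core rule and marker-H aggregation are documented choices
  where the original tooling is unspecified; results depend on them.
- XP-Rsb standardization uses genome-wide moments of raw ln ratios
  (not frequency-binned), a simplification of the companion-method
  definition.
- Hierarchical (multi-level) AMOVA, statistical phasing, imputation
  and map-driven variable recombination in the simulator are out of
  scope.
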