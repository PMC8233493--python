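# Methods

`bgsinfer` studies how purifying selection and background selection (BGS)
bias demographic inference, and implements a correction. This note records
the models, the numerical choices, and what the desk-scale experiments do
and do not establish.

## Model components

### Genome architecture

A simulated chromosome tiles genes between intergenic tracts, with a
leading intergenic tract. Each gene is `exons_per_gene` exons of fixed
length alternating with introns (defaults: eight 350-bp exons, seven
introns). The gene count for a target length L is
`round(L / (gene_bp + intergenic_bp))`, and the realized chromosome is one
base shorter than `leading + n_genes * unit`; with 150 Mb targets this
yields the three reference configurations with roughly 5%, 10% and 20% of
sites exonic (2,737 / 5,164 / 11,278 genes; 150,018,599 / 150,029,949 /
150,003,699 bp). Only exonic sites experience direct selection; introns
and intergenic sequence are neutral.

### Discrete DFE

New exonic mutations draw a selection coefficient from a four-class
distribution of fitness effects over bins of the scaled coefficient
`2*Nanc*s`: [0,1), [1,10), [10,100), [100, 2*Nanc), with class
proportions f0–f3 and s uniform within a bin. `s` is the homozygous
fitness reduction; all mutations are semidominant (h = 0.5) and fitness is
multiplicative across sites (1, 1−s/2, 1−s per site). `Nanc` is always the
ancestral (pre-size-change) population size. The named shapes DFE1–DFE6
put 70% of mass in one class (DFE1–3), spread mass evenly (DFE4), or mix
neutral with strongly deleterious mutations only (DFE5–6). The simplex
grid with spacing 0.05 contains 1,771 shapes and is the prior support of
the nuisance-DFE ABC method.

### Demography

A `Demography` is a piecewise size history, present first, ending in an
open-ended ancestral epoch; segments are constant or exponential. The
built-in presets are demographic equilibrium, recent ~30-fold exponential
growth, and a ~6-fold instantaneous decline. The exact human-calibrated
parameter values behind the growth/decline scenarios are not available in
the sources this package was built from, so the presets adopt
out-of-Africa-style round numbers — decline 12,300 → 2,100, growth
1,000 → 30,000, change time 1,000 generations — and every preset is
overridable; they are defaults, not ground truth.

### Rescaling

`rescale(params, Q)` applies the standard population-scaling trick:
N → N/Q, t → t/Q, and mu, r, s multiplied by Q, preserving 4Nμ, 4Nr and
2Ns. The DFE bins are defined on 2*Nanc*s and therefore survive rescaling
unchanged (the strongly deleterious bin's upper bound 2*Nanc keeps s < 1
at any Q). Scaled-down runs trade a modest violation of the weak-selection
assumption (s can approach 1) for large speedups; this is the same
trade-off made in the study design this package reproduces.

## Simulation engines

### Forward Wright–Fisher engine

Diploid, random mating (selfing permitted), fitness multiplicative across
sites, parents sampled proportionally to fitness, one crossover process
per locus (Poisson number of crossovers; loci assort freely), burn-in of
exactly `10*Nanc` generations before the demographic epochs play forward.
Mutation is finite-sites with at most one segregating mutation per site:
a mutation proposed at an occupied site is redrawn elsewhere; when an
allele fixes or is lost the site reopens; back mutation is not modeled.
At the mutation rates used here site collisions are rare and none of the
SFS-level statistics are sensitive to this choice. Fixations after the
burn-in are recorded with their generation for divergence estimates.
Samples are diploids drawn without replacement; the returned matrix keeps
only columns polymorphic in the sample. Every run is reproducible
bit-for-bit from its seed. No coalescent shortcut is used for the burn-in.

The per-generation update runs in a compiled (numba) kernel when rates
are uniform per locus — fitness, parent sampling, gamete formation,
mutation and loss/fixation bookkeeping in one pass, with the haplotype
matrix rebuilt position-sorted each generation; heterogeneous rate maps
take an equivalent vectorized numpy path (crossover and mutation
positions drawn from the step maps). Both paths implement the same
model; the engine-level validation tests (diversity, divergence,
coalescent agreement) exercise the kernel, and the rate-map path is
checked separately.

The engine is validated against the coalescent engine at neutral
equilibrium (two-sample Kolmogorov–Smirnov on replicate distributions of
S and pi), against 4Nμ for neutral diversity, and against the molecular
clock for neutral divergence.

### Neutral coalescent engine

msprime (binary mutation model) behind the same sample container. It is
used for every purely neutral computation — calibration targets, expected
SFS cross-checks, unlinked-LD baselines — because it is orders of
magnitude faster; the forward engine is authoritative whenever selection
is present. Regions beyond a chunk size (default 100 Mb) are simulated as
independent chunks, which bounds the ancestral recombination graph; for
segregating-site counts chunking is exact in expectation and its effect
on the replicate distribution is verified by a KS test.

### Rate maps and masks

Recombination maps follow the HapMap text convention (position, cM/Mb);
mutation maps are windowed per-site rates renormalized so the genome-wide
mean equals a target (default 1e-8). Windows with missing data inherit
the previous window's rate; centromeres get zero recombination, and a
fixed 4 Mb centromere mask (48.5–52.5 Mb of a 150 Mb chromosome) plus
random repeat-like masks (segments drawn from a length sampler until a
target fraction is covered, last segment truncated) emulate the masking
conventions of empirical pipelines.

## Analytic theory

### Equilibrium B

The classical deterministic prediction
`B = exp(-sum_j u*t_j / (t_j + r_j(1-t_j))^2)` over selected sites j,
with t = s/2, integrated over each DFE bin by Gauss–Legendre quadrature;
recombination fractions use the Haldane map. The formula assumes
`2*Nanc*s >> 1`; when more than 5% of DFE mass lies in the two weakest
bins the result is flagged unreliable (the deterministic theory
overpredicts BGS under weak selection) and simulation should be used
instead. This is why the package's transient-B experiments measure the
ancestral B from simulation rather than from this formula.

### Apparent B during transients

BGS is treated as a uniform rescaling of N(t) by B. The apparent
`B-hat(t) = pi_sel(t)/pi_neu(t)` uses the neutral pairwise-diversity
solution `pi(t) = 2*mu*E[T2]` with all sizes multiplied by B0 (selected
trajectory) or 1 (neutral trajectory); for a step change N0 → N1,
`pi(t) ∝ B*[N1 + (N0-N1)*exp(-t/(2*B*N1))]`. Both limits t → 0 and
t → ∞ return B0; in between, the faster response of the low-Ne region
makes B-hat sink below B0 throughout a decline transient and rise above
it during growth. Exponential segments are integrated by trapezoidal
quadrature on a fine grid; the trajectory is continuous across epoch
boundaries. The same construction, with the ancestral B measured from
forward simulation, predicts the post-change B values that the forward
engine produces (validated within Monte-Carlo error at reduced scale).

One direction subtlety is worth recording: the source material describes
the post-decline apparent B both as lower than the ancestral B (its
results/figures) and, in one discussion passage, as an "apparent
increase". The pairwise-rescaling mathematics gives the former — B-hat
below B0 after decline, above after growth — and this implementation
follows it; the contradictory sentence is noted, not resolved.

### Expected SFS (spectral representation)

For a piecewise-constant history the expected count of sites with b
derived copies in n haplotypes is `mu*L * sum_k k*E[S_k] * P(b|k)`,
where `E[S_k]`, the expected time the sample spends with k ancestral
lineages, is a signed combination (via the classical lineage-count
distribution) of the integrals
`lambda_j = ∫ exp(-C(j,2) * Λ(t)) dt`, `Λ(t) = ∫ dt'/(2N(t'))`, and
`P(b|k) = C(n-b-1,k-2)/C(n-1,k-1)`. B multiplies N(t) and cancels
entirely at constant size (the 1/b law). Exponential epochs are
discretized into ≥50 piecewise-constant steps, doubling until the
pairwise coalescence time changes by < 1e-4 relative. The alternating
signs limit double-precision accuracy to n ≲ 50; samples above that are
rejected, and the analyses here use n = 20 (ten diploids). Agreement
with coalescent simulation is verified for all presets with and without
B rescaling.

A genuine feature of the transient regime surfaced by this machinery:
after a decline, the singleton excess caused by BGS is *non-monotone* in
B. Mild BGS (B near 1) first depletes singletons relative to B = 1;
only sufficiently strong BGS (small B), which re-equilibrates the
population to its reduced size, produces the rare-variant excess
associated with BGS under decline. Direction tests therefore pin B in
the strong-BGS regime.

## SFS model fitting and model choice

Four single-population models are fitted: equilibrium (N),
instantaneous size change (Nanc, Ncur, T), exponential size change
(Nanc, Ncur, T), and an instantaneous bottleneck (Nanc, intensity I, T).
Search ranges: sizes uniform 100–500,000; times uniform 100–10,000
generations; intensity log-uniform 1e-5–2. The bottleneck is an
instantaneous coalescent-intensity pulse — pair coalescence probability
1 − e^(−I) at T — implemented exactly as a vanishing-duration epoch of
size eps/(2I), verified against the closed form for E[T2].

The likelihood is multinomial over SFS classes (composite: sites treated
as independent). Including the monomorphic class (with a known mutation
rate) anchors absolute sizes and is the default when fitting full or
thinned-and-rescaled spectra; the zero class of a thinned SFS is scaled
by the SNP survival fraction so both classes stay consistent. This
analytic likelihood replaces a simulation-based likelihood engine by
design: at the SFS level the two coincide, and the analytic route is
deterministic and fast. Optimization is bounded Nelder–Mead on
log-transformed parameters with seeded uniform multistart (default 50
restarts; best restart returned; ties broken by lowest AIC then model
order). Model choice uses `AIC = penalty*k − 2 lnL` with penalty 2
(standard) or 25 (a stricter variant that counteracts the
pseudo-replication of linked SNPs), and Akaike weights
`w_i = exp(-Δ_i/2)/Σ exp(-Δ_j/2)`. For replicate studies a pooling
helper takes the maximum of maximum likelihoods per model across
replicates before AIC.

## Nuisance-DFE ABC

The correction for selection bias: simulate the reference table *with*
purifying selection acting on the analyzed (exonic) sequence, drawing
(Nanc, Ncur) from uniform priors and the DFE proportions uniformly from
the 0.05 simplex grid, and estimate only the two sizes — the DFE is
marginalized out. The demographic model is a one-epoch exponential change
from Nanc to Ncur beginning at a fixed time in the past. Summary
statistics per exon: pi, Watterson's theta, Tajima's D, Fay & Wu's H
(absolute pi − theta_H, and the variance-normalized form), singleton
count, haplotype diversity, mean r², mean D, mean |D'| over SNP pairs,
and divergence (post-burn-in fixations per site per generation); the
final vector is the 22 between-exon means and variances, in that fixed
order. Windows where a statistic is undefined are excluded from that
statistic's mean/variance.

Rejection keeps the nearest `round(tolerance * table size)` rows
(default tolerance 0.1) by Euclidean distance on median/MAD-standardized
statistics (zero-MAD columns fall back to the SD; zero-spread columns are
dropped with a warning). Regression adjustment fits a small
single-hidden-layer network (width 5, averaged over 10 restarts; the
usual nonlinear ABC adjustment) of logit-transformed parameters on the
standardized statistics within the accepted set, shifts each draw by
`m(s_obs) − m(s_i)`, and weights draws by an Epanechnikov kernel in
distance; point estimates are weighted posterior medians. The logit
transform is anchored to the sampled parameter range, so adjusted draws
cannot leave the prior box — without it the network extrapolates freely
and produces estimates far outside the prior. Local-linear and
rejection-only adjustments are available both as explicit choices and as
automatic fallbacks on regression degeneracy (always logged, never
silent). The whole pipeline — priors, simulations, rejection, adjustment
— is reproducible bit-for-bit from a master seed, and reference tables
carry a configuration hash that inference validates before use.

The default configuration mirrors the full-scale study design
(94 single-exon genes of 1.5 kb, per-exon recombination rates, mu = 3e-9,
rescaling Q = 320, prior sizes 1e5–1e7, change time 1e6 generations,
50 diploids sampled); the exon panel is a synthetic stand-in with
log-uniform per-exon recombination rates, and a user-supplied exon/rate
table can be passed instead.

## Desk-scale study conditions

The full-scale experiments (3 Gb genomes, ten replicates, thousand-row
reference tables per parameter combination) are cluster-scale. The test
suite and examples run the same machinery at sizes chosen once for a
single CPU, as this package's own study conditions:

* Neutral calibrations: the printed-scale configurations themselves
  (N = 5,000, mu = r = 1e-8; 10 Mb–1 Gb), with Gb-scale regions chunked
  and replicate counts of 6–100 depending on the region size.
* False-growth experiment: mini genome20 chromosomes (1.5 Mb) at Q = 20
  (scaled N = 250), DFE2, linked-neutral SFS in 10 sampled diploids,
  ten seeds.
* Transient-B experiment: a 100 kb exon block under DFE5 with a 100 kb
  neutral flank at scaled N = 500, with the scaled mutation rate raised
  to 1e-6 so the equilibrium B (~0.75–0.8) is measurable above
  genealogical noise; 6-fold decline and 2-fold growth variants of the
  presets.
* ABC: a 48-exon panel of 600 bp single-exon genes, mu = 2e-6, sizes
  uniform 60–360, change time 200 generations (comparable to the typical
  prior N, the design regime in which both sizes are jointly
  identifiable), 30 diploids sampled, run at rescaling Q = 2; a 350-row
  nuisance-DFE reference table and a 100-row neutral-assumption table,
  acceptance tolerance 0.15 (about 52 accepted rows, matching the
  accepted-set size of the full-scale design rather than its acceptance
  fraction). The panel size matters: a single simulated observation of a
  16-exon panel carries ~20% noise in mean diversity alone, which no
  reference table can undo; 48 exons bring observation noise near 10%.
  The equal-size (equilibrium) history keeps a recent epoch of the same
  span so the divergence statistic is defined for every parameter
  combination. The weakest cell of the recovery grid is the ancestral
  size under recent growth (the ramp hides the ancestral epoch); its
  point estimates scatter more than the other cells even though the
  pooled medians meet the bound.

What passing at these scales shows: the analytic theory matches the
simulators where theory is exact; the engines agree with each other and
with closed forms under neutrality; the qualitative biases (diversity
loss, rare-variant skew, spurious growth, its ABC correction) are
reproduced with the correct directions and magnitudes at reduced scale.
What it does not show: effect sizes at 3 Gb / cluster scale, behavior of
empirical data with sequencing error, unphased genotypes, ancestral-state
misidentification, or gene conversion and crossover interference (none
of which are modeled). Positive selection is out of scope throughout.

## Known limitations

* The deterministic equilibrium-B formula is unreliable for weak
  selection (flagged, not fixed); transient-B predictions require an
  externally measured ancestral B.
* The expected-SFS machinery is limited to n ≤ 50 haplotypes by floating
  precision.
* The composite likelihood ignores linkage between SNPs, exactly like
  the methods whose biases are under study; AIC on linked data inherits
  the usual overconfidence (hence the 25x penalty variant).
* ABC accuracy at desk scale is limited by reference-table size; the
  point-estimate error bound checked in the acceptance suite (median
  relative error < 0.25) is a reduced-scale statement.
* The bottleneck "intensity" follows the coalescent-pulse definition;
  other tools may parameterize bottlenecks differently, so fitted
  intensities are comparable only through the implied pair-coalescence
  probability.
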