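# bgsinfer

Demographic inference from population-genomic data usually assumes that
the analyzed sites are neutral and unlinked. In real genomes, purifying
selection on functional sequence and background selection (BGS) at linked
sites depress diversity and skew the site frequency spectrum (SFS) toward
rare variants — the same signatures that demographic models attribute to
recent population growth. `bgsinfer` is a toolkit for quantifying that
bias and for correcting it, aimed at population geneticists who build or
evaluate demographic inference pipelines:

* **Simulators.** A forward Wright–Fisher engine with a discrete
  distribution of fitness effects (DFE) over bins of `2*Nanc*s`
  ([0,1), [1,10), [10,100), [100, 2*Nanc); semidominant, multiplicative
  fitness), human-like genome layouts (genes of eight 350-bp exons tiled
  at ~5/10/20% functional density), piecewise demographies, rescaling by
  `Q`, rate maps and masking; plus an msprime-backed neutral coalescent
  engine for calibration.
* **Theory.** Equilibrium `B = pi/pi0` around selected sites; the
  apparent B during size-change transients via uniform Ne rescaling of
  pairwise coalescence theory; expected SFS for arbitrary
  piecewise-constant histories (spectral representation of coalescence
  times) with BGS entering as a multiplier of N(t).
* **SFS model selection.** Composite (multinomial) likelihood fits of
  equilibrium, instantaneous and exponential size change, and
  instantaneous-bottleneck models; `AIC = penalty*k − 2 lnL` with the
  standard penalty 2 or a stricter 25x variant; Akaike weights
  `w_i = e^{−Δi/2}/Σ e^{−Δj/2}`; SNP thinning with consistent rescaling
  of the monomorphic class.
* **Nuisance-DFE ABC.** The correction: infer `(Nanc, Ncur)` from
  directly selected regions while drawing the DFE proportions
  `(f0..f3)` from the 1,771-point simplex grid and marginalizing them
  out — rejection on 22 summary statistics (between-exon means and
  variances of pi, Watterson's theta, Tajima's D, Fay & Wu's H, singleton
  count, haplotype diversity, r², D, D′, divergence), neural-net
  regression adjustment, weighted-median point estimates.

## Worked example: background selection mimics growth

`examples/04_false_growth_from_bgs.py` simulates a constant-size
population (N = 5,000, rescaled by Q = 20) whose genome — three pooled
1.5 Mb chromosomes — is 20% exonic under DFE2 (70% moderately
deleterious mutations), masks the exons, and fits the four demographic
models to the linked-neutral SFS:

```
true (scaled) population size: 250, constant
linked-neutral SNPs: 1890
selected model: instantaneous_bottleneck

  equilibrium                lnL= -20710.2  N=186
  instantaneous_change       lnL= -20702.3  Nanc=166, Ncur=228, T=100
  exponential_change         lnL= -20701.0  Nanc=168, Ncur=270, T=100
  instantaneous_bottleneck   lnL= -20696.4  Nanc=241, intensity=1, T=186

size-change fit: Ncur/Nanc = 1.4 (> 1: growth inferred under a constant-size truth)
```

Two biases are visible: the population size is underestimated (186 vs
250 — diversity lost to BGS) and the SFS skew is absorbed as spurious
recent growth / a bottleneck, exactly the mis-inference pattern this
package quantifies. `examples/07_nuisance_dfe_abc.py` runs the
correction on exonic data with the DFE treated as a nuisance parameter:

```
reference table: 250 rows (DFE drawn per row)
truth: {'Nanc': 200, 'Ncur': 200}
nuisance-DFE estimates: Nanc = 165, Ncur = 174 (method: nnet)
90% interval for Ncur: [128, 207]
```

Both sizes land within ~15% of the truth with no growth signal — the
bias is gone once DFE shape is averaged out (a larger reference table
tightens the estimates further).

The other examples walk the genome layouts and DFE grid (01), the
neutral segregating-site calibration (02), the SFS/diversity distortion
itself (03), the analytic apparent-B transient (05), and the expected
SFS under size change with BGS rescaling (06).

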