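# mdfluct

Statistical similarity between molecular-dynamics (MD) trajectories at
residue resolution.

A common way to compare two MD simulations of a protein — wild type
versus mutant, or the two halves of one run as a convergence check — is
to plot per-residue RMSF and eyeball the differences.  `mdfluct`
replaces the eyeball with distributions and p-values: it estimates the
full probability density of each residue's local fluctuations, computes
a panel of similarity measures between the two trajectories'
distributions, and turns Kolmogorov–Smirnov statistics into per-residue
significance profiles along the backbone.  It is aimed at structural
bioinformaticians and simulators who want a quantitative, per-residue
answer to "are these two trajectories sampling the same local dynamics?"

## Method

Two local descriptions of dynamics are supported, both built on Cα atoms:

* **1R (on-residue)** — the magnitude of a residue's displacement from
  its average position, `v_k(t) = |r_k(t) − μ_k|`, after rigid-body
  superposition of all frames onto a reference structure (the
  trajectory's own frame0, or a mean of several frame0 structures);
* **2R (residue-pair)** — the distance between two Cα atoms, which is
  rotationally invariant and needs no alignment.  Pairs are restricted
  to *nearest neighbors*: residues within a cutoff (default 12 Å) in at
  least one frame.  Optionally each distance distribution is *shifted*
  so its fitted mean is exactly zero, removing average-structure
  information and leaving pure fluctuations.

Each trajectory is split into two 1000-frame time blocks, giving samples
`A1, A2` (and `B1, B2` for a second trajectory).  For every scalar
sample the probability density is estimated nonparametrically in
maximum-entropy form

    p(v) = exp( λ₀ − 1 + Σ_{j=1..D} λ_j T_j(v) ),

with Chebyshev polynomials `T_j` as level functions.  The expansion
dimension `D` is selected automatically: the sample is mapped through
the trial CDF, which is uniform on [0, 1] exactly when the trial density
is right ("sampled uniform random data", SURD), and uniformity is scored
through the Beta-distributed single order statistics, standardized
against a Monte-Carlo null so the scale is sample-size invariant.  A
five-member ensemble of fits is generated and the median-scored member
is kept.

Between two samples `a, b` with fitted densities `p(z|a), p(z|b)` the
package computes eight non-negative measures: ΔRMSF; the Jensen–Shannon
divergence; the L1 distance Δp = ∫|p(z|a) − p(z|b)|dz; three weighted
integrals of |ln p(z|a)/p(z|b)| (weights min, geometric mean, max of the
densities — `KLmin ≤ KLave ≤ KLmax`, damping or emphasizing outliers);
the symmetrized one-sample KS statistic `KS1 = √(KS1(a|b)·KS1(b|a))`
against the fitted CDFs; and a "0-sample" statistic
`KS0 = sup|F(z|a) − F(z|b)|` between the two fitted CDFs.  KS statistics
are converted to p-values through the Kolmogorov distribution with the
standard finite-n correction; p-values are carried as `log10(pv)` down
to ~10⁻³⁰⁰ and beyond without underflow.

Residue-pair measures `M_kj` are collapsed onto residues by averaging
over each residue's neighbors (pairs must be neighbors in *both*
trajectories), and cross-trajectory comparisons average the four block
pairings {A1&B1, A2&B1, A1&B2, A2&B2}.  A built-in synthetic-data module
generates per-residue Gaussian mock trajectories (i.i.d. or AR(1)
time-correlated) with controlled mean/variance perturbations, plus
frame-shuffling controls, so the whole pipeline can be validated without
any MD data.

## Worked example

Generate a mock pair of "trajectories" (8 residues, 2000 frames) in
which trajectory B's per-axis Gaussians are perturbed by a 0.5·sd mean
shift and a 1.2× sd scale, then run the on-residue comparison:

```bash
mdfluct mock --n-residues 8 --n-frames 2000 --mean-shift 0.5 --sd-scale 1.2 \
        --seed 1 --out-dir example
mdfluct compare example/A.tsv example/B.tsv --mode 1R --seed 1 --out-dir example/out
```

`example/out/profiles.tsv` then contains (selected columns):

```
residue  delta_rmsf     js  kl_ave    ks1  log10_pv_ks1
      1      0.2001 0.0207  0.3203 0.1718      -25.6166
      2      0.2349 0.0254  0.3217 0.1783      -27.5455
      3      0.2297 0.0262  0.3457 0.1865      -30.2214
      4      0.2281 0.0194  0.2567 0.1378      -16.3493
      5      0.2396 0.0245  0.3284 0.1750      -26.6090
      6      0.1651 0.0157  0.2838 0.1436      -17.9208
      7      0.1932 0.0246  0.3241 0.1742      -26.3092
      8      0.1648 0.0167  0.2608 0.1462      -18.5918
```

Every column is the average over the four block pairings.  The RMSF
difference (~0.2 Å) and the divergences are modest, but the significance
column is decisive: log10 p-values of −16 to −30 mean the null
hypothesis of identical local dynamics is overwhelmingly rejected at
every residue — the characteristic outcome for any systematic
perturbation at this sample size.  For an unperturbed pair
(`--mean-shift 0 --sd-scale 1`) the same column sits in the ordinary
null regime (p-values spread over [0, 1]).

The same pipeline is available as a library (`mdfluct.run_pair`,
`mdfluct.run_group` with the standard comparison-group names such as
`1R-self-1` or `2R-mt-wt-2`), and `mdfluct mock --ar1 0.9 --shuffle`
produces the time-correlation / shuffling control datasets.

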