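# Methods

## Scope and model

`mdfluct` quantifies the statistical similarity of two molecular-dynamics
trajectories through the distributions of *local* fluctuation variables:
per-residue Cα displacement magnitudes (the 1R description) and Cα–Cα
distances of nearest-neighbor residue pairs (the 2R description).  The
underlying assumptions are:

* residues of the compared trajectories are in 1:1 correspondence
  (sequences perfectly aligned; point-mutation differences only);
* frames are treated as independent draws from a stationary per-variable
  distribution within each time block.  Real MD frames retain time
  correlations; the frame-shuffling control exists precisely to measure
  the effect of that assumption;
* coordinates are whole (no periodic-boundary artifacts) and in Å.

Each trajectory contributes two samples per variable — the first and
second half of its frames (1000 observations per block at the default
2000-frame, 50 ps/frame setup).  The reference structure `frame0` (the
last equilibration frame) is used only for alignment and is never an
observation.

## Density estimation

Densities are estimated in exponential (maximum-entropy) form,
`p(v) = exp(λ₀ − 1 + Σ λ_j T_j(t(v)))`, with Chebyshev polynomials of
the first kind on the support affinely mapped to [−1, 1].  The shape
multipliers are obtained by penalized maximum likelihood (a convex
problem solved with L-BFGS; ridge 10⁻⁶ for conditioning), with the
normalization recomputed by 256-node Gauss–Legendre quadrature at every
step and a final renormalization on a 32769-point grid so every returned
estimate integrates to 1 within 10⁻⁶ even when the data are nearly
degenerate.

**Support.**  `[min − 3·IQR/n^(1/3), max + 3·IQR/n^(1/3)]`, floored at 0
for nonnegative variables (magnitudes, distances).  The pad extends the
tails beyond the observed extremes so rare events carry density; the
n^(−1/3) scaling shrinks it as sampling improves.  The density is
defined as exactly 0 outside the support, which makes the divergence
integrals over support unions well defined.

**Goodness of fit (SURD scoring).**  The sample mapped through the trial
CDF is uniform on [0, 1] exactly when the trial density is correct.
Uniformity is scored as the log-likelihood of the sorted mapped values
under their Beta(k, n+1−k) order-statistic marginals, standardized by
the Monte-Carlo null mean and sd at the same sample size (10⁴ sorted
uniform replicates per size, cached under a fixed internal calibration
seed so thresholds never vary between runs).  Standardization makes the
score scale sample-size invariant, which is verified empirically in the
tests.

**Dimension selection.**  D grows from 1 and stops when the standardized
score reaches the *null median* — i.e. when the fitted model maps the
data to a sample at least as uniform as the typical genuine uniform
sample.  An earlier variant stopped at the 0.5% rejection quantile;
that leaves systematic misfit sitting just below the detection limit
(for example, skewed displacement-magnitude distributions accepted as
D = 2 quadratic exponentials), which we measured to roughly triple the
KL divergence to the true density (median 0.022 vs 0.008 nats on scaled
chi(3) samples at n = 1000) and to visibly bias every downstream
divergence and KS measure.  The 0.5% quantile is retained as the
*acceptance confidence*: an estimate is flagged `accept` when its score
exceeds it.  D is additionally capped at √n (constraints cannot exceed
the information in the sample) and the search stops early if the score
has not improved for 8 consecutive dimensions; if no dimension reaches
the target, the best-scoring fit is returned (with a warning if it is
not even accepted).

**Ensemble and representative.**  At the selected dimension, four refits
from randomly perturbed starting multipliers join the deterministic fit
(five members total).  Because the likelihood is convex the members
usually coincide; the median-scored accepted member is returned, a
robust reading of "most representative".  Degenerate samples (all values
identical) raise an explicit error; non-finite values are rejected.

## Similarity measures

For samples `a, b` with fitted densities `p(z|a), p(z|b)`:

| measure | definition | units/bounds |
|---|---|---|
| ΔRMSF | abs. difference of root-mean-square fluctuation | Å |
| JS | Jensen–Shannon divergence vs the mixture q = ½(pa+pb) | nats, ≤ ln 2 |
| Δp | ∫\|pa − pb\| dz | ≤ 2 |
| KLmin/ave/max | ∫ w·\|ln pa/pb\| dz, w ∈ {min, √(pa·pb), max} | nats, ordered |
| KS1 | √(KS1(a\|b)·KS1(b\|a)), one-sample sup-statistics vs fitted CDFs | ≤ 1 |
| KS0 | sup\|F(z\|a) − F(z\|b)\| between fitted CDFs | ≤ 1 |

The JS divergence is computed in its standard orientation
½KL(pa‖q) + ½KL(pb‖q).  The reverse orientation (mixture first) diverges
whenever the supports differ and is unbounded; the standard form is the
one that satisfies the ln 2 bound and the disjoint-support limit that
this panel relies on.

**RMSF convention.**  "RMSF" is the root of the mean *squared*
displacement magnitude (the conventional fluctuation amplitude).  The
sample standard deviation — a different quantity for non-zero-mean
variables such as magnitudes — is available via `convention="sd"`.

**Numerical choices.**  Divergence integrals use a dense composite
trapezoid (200 001 points over the union of supports, support endpoints
included as grid points).  Adaptive Gauss–Kronrod rules were rejected:
the integrands contain |·| kinks, min/max switches and floor
discontinuities that defeat adaptive subdivision, while the dense grid
is verified against 10⁶-point oracles to better than 10⁻⁴.  Densities
below the floor 10⁻¹² are treated as vanishing; where exactly one
density is below the floor the log-ratio is capped at the floor ratio
(the integrands are undefined at true zeros).  `KS0` maximizes over a
20 001-point grid with two local refinement passes.  KS statistics are
converted to p-values via the asymptotic Kolmogorov distribution with
the Stephens finite-n correction (√n + 0.12 + 0.11/√n); `log10(pv)` is
computed directly from the asymptotic series, reaching below −300
without underflow.  The `KS0`-derived p-value is descriptive only (the
null of a statistic between two estimated CDFs is not the one-sample
null).

## Comparison orchestration

Cross-trajectory comparisons evaluate all four block pairings
{A1&B1, A2&B1, A1&B2, A2&B2} and average them arithmetically;
self-comparisons use the single pairing A1&A2.  p-values are averaged on
the log10 scale (a geometric mean), matching how significance profiles
are plotted and preventing a single moderate p-value from masking
decisive ones.  2R pair measures are collapsed onto residues by an
arithmetic mean over each residue's nearest neighbors, using the
*intersection* of the two trajectories' neighbor sets; residues with no
neighbors are reported as missing, never as zero.  The default cutoff is
12 Å; values below 8 Å warn (sparse neighborhoods make the collapse
unreliable).  All fits are seeded deterministically from the master seed
and the (trajectory, block, variable) identity, so the entire pipeline
is reproducible bit-for-bit and independent of iteration order.

## Synthetic data

The mock generator draws each residue's position from three independent
Gaussians (x, y, z), i.i.d. across frames by default, for 263 residues
and 2000 frames — the structure of the real datasets it emulates.
Defaults chosen where nothing was prescribed: means on an ideal α-helix
(so alignment and neighbor machinery behave protein-like), per-axis sds
uniform in [0.3, 1.0] Å (a realistic range of Cα fluctuation
amplitudes), drawn once per spec seed.  The second trajectory of a pair
perturbs the Gaussians by a mean shift (in units of the local sd) and an
sd scale factor, either identically at every residue or randomly per
residue.  An AR(1) option (x_t = φx_{t−1} + √(1−φ²)ε_t, stationary)
emulates the residual time correlation of real MD data; uniform frame
shuffling destroys it, which is the control distinguishing
correlation-driven from distribution-driven significance.

What the mock data does *not* emulate: anharmonicity, multimodal
conformational substates, inter-residue coupling, and slow drift.
Passing the synthetic validations therefore demonstrates the statistical
machinery is calibrated and sensitive, not that any particular MD system
is converged.

Problem sizes in the test-suite validations are the package's own
choices: the perturbed-pair significance check runs 50 residues (each
residue is an independent replicate of the same claim, so the count only
sets how many times the claim is tested), while the shuffling control
and the null-calibration check run the full 263.

## Known limitations

* **Cross-sample KS1 p-values are conservative-to-liberal biased, not
  exactly uniform, under the null.**  KS1(a|b) tests sample `a` against
  a CDF *estimated* from sample `b`; the estimation error of F(·|b)
  inflates the statistic above the textbook one-sample null (the
  classical estimated-parameters effect, in the cross-sample direction).
  With the block-size conversion the per-residue null p-values have
  median ≈ 0.2–0.4 rather than 0.5, and a formal uniformity test across
  hundreds of residues rejects.  No fixed effective sample size repairs
  this (we checked n_eff from n down to 0.4n: the geometric-mean
  statistic's null is simply not a Kolmogorov distribution); exact
  calibration would require a parametric bootstrap per comparison.  The
  qualitative contrasts the p-values are used for — vanishing (10⁻²⁵⁰ to
  10⁻¹⁰) under real perturbations versus ordinary (majority > 0.05)
  under the shuffled null — are orders of magnitude larger than this
  bias and unaffected by it.
* The estimator targets smooth densities; discrete or near-degenerate
  samples yield a best-effort fit with a warning rather than a certified
  one.
* The 2R description scales quadratically with residue count through the
  neighbor set; beyond the 12 Å cutoff the cost grows while locality of
  the information is lost.
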