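"""Eight similarity measures between two fluctuation samples/densities.

Given samples ``a`` and ``b`` with fitted densities ``p(z|a)``, ``p(z|b)``:

* ``delta_rmsf`` — |RMSF(a) − RMSF(b)| (Å), from the raw samples;
* ``js`` — Jensen-Shannon divergence against the mixture
  q = ½[p(z|a)+p(z|b)] (nats, bounded by ln 2);
* ``delta_p`` — L1 distance ∫|p(z|a) − p(z|b)| dz (unitless, ≤ 2);
* ``kl_min/kl_ave/kl_max`` — integrals of the pointwise log-density ratio
  magnitude |ln p(z|a)/p(z|b)| weighted by min, geometric mean, and max of
  the two densities.  The weights order the three values pointwise, so
  kl_min ≤ kl_ave ≤ kl_max always; kl_min damps outlier regions while
  kl_max emphasizes them;
* ``ks1`` — symmetrized 1-sample Kolmogorov-Smirnov statistic: geometric
  mean of sup|F_n(a) − F(z|b)| and sup|F_n(b) − F(z|a)|;
* ``ks0`` — "0-sample" statistic sup|F(z|a) − F(z|b)| between the two
  estimated CDFs.

KS statistics are converted to p-values through the asymptotic Kolmogorov
distribution with the standard finite-n correction; log10 p-values are
computed directly from the asymptotic series so values down to ~1e-300
and beyond are representable without underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import kstwobign

from .maxent import DensityEstimate, FluctuationSample

__all__ = [
    "MeasurePanel",
    "delta_rmsf",
    "rmsf",
    "js_divergence",
    "delta_p",
    "kl_band",
    "overlap_integrals",
    "ks1_one_sided",
    "ks1_sym",
    "ks0",
    "ks_to_pvalue",
    "log10_ks_pvalue",
    "measure_panel",
]

# Densities below this are treated as vanishing; log-ratios are capped at
# the floor ratio (the divergence integrands are undefined at true zeros).
DENSITY_FLOOR = 1e-12
# Composite-trapezoid resolution for the divergence integrals.
GRID_POINTS = 200_001


def rmsf(sample: FluctuationSample, convention: str = "rms") -> float:
    """Root-mean-square of the displacement magnitudes (Å).

    ``convention="sd"`` gives the sample standard deviation instead; RMS
    is the default, the conventional fluctuation magnitude about a mean
    position (the two coincide for zero-mean variables).
    """
    v = np.asarray(sample.values if isinstance(sample, FluctuationSample) else sample, float)
    if v.size == 0:
        raise ValueError("empty sample")
    if convention == "rms":
        return float(np.sqrt(np.mean(v**2)))
    if convention == "sd":
        return float(np.std(v))
    raise ValueError(f"unknown RMSF convention {convention!r}")


def delta_rmsf(a: FluctuationSample, b: FluctuationSample, convention: str = "rms") -> float:
    """|RMSF(a) − RMSF(b)| in Å."""
    return abs(rmsf(a, convention) - rmsf(b, convention))


def _union_grid(pa: DensityEstimate, pb: DensityEstimate, n: int = GRID_POINTS) -> np.ndarray:
    pts = np.array([*pa.support, *pb.support], dtype=float)
    lo, hi = pts.min(), pts.max()
    grid = np.union1d(np.linspace(lo, hi, n), pts)
    return grid


def js_divergence(pa: DensityEstimate, pb: DensityEstimate) -> float:
    """Jensen-Shannon divergence (nats) between two estimates, in [0, ln 2].

    Computed as ½KL(pa‖q) + ½KL(pb‖q) with q the equal mixture; this is
    the symmetrized, bounded divergence that equals ln 2 for densities
    with disjoint supports.
    """
    z = _union_grid(pa, pb)
    fa, fb = pa.pdf(z), pb.pdf(z)
    q = 0.5 * (fa + fb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ia = np.where(fa > 0.0, fa * (np.log(np.maximum(fa, 1e-300)) - np.log(np.maximum(q, 1e-300))), 0.0)
        ib = np.where(fb > 0.0, fb * (np.log(np.maximum(fb, 1e-300)) - np.log(np.maximum(q, 1e-300))), 0.0)
    val = 0.5 * (np.trapezoid(ia, z) + np.trapezoid(ib, z))
    return float(min(max(val, 0.0), math.log(2.0)))


def delta_p(pa: DensityEstimate, pb: DensityEstimate) -> float:
    """L1 distance ∫|p(z|a) − p(z|b)| dz over the union of supports, ≤ 2."""
    z = _union_grid(pa, pb)
    val = np.trapezoid(np.abs(pa.pdf(z) - pb.pdf(z)), z)
    return float(min(max(val, 0.0), 2.0))


def _log_ratio(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    # |ln fa/fb| with both densities floored, capping the ratio wherever
    # one of them vanishes
    return np.abs(
        np.log(np.maximum(fa, DENSITY_FLOOR)) - np.log(np.maximum(fb, DENSITY_FLOOR))
    )


def kl_band(pa: DensityEstimate, pb: DensityEstimate) -> tuple[float, float, float]:
    """(kl_min, kl_ave, kl_max) in nats.

    All three share the integrand |ln p(z|a)/p(z|b)| and differ only in
    the weight: min, geometric mean, or max of the two densities.  The
    pointwise weight ordering guarantees kl_min ≤ kl_ave ≤ kl_max.
    """
    z = _union_grid(pa, pb)
    fa, fb = pa.pdf(z), pb.pdf(z)
    lr = _log_ratio(fa, fb)
    active = (fa > DENSITY_FLOOR) | (fb > DENSITY_FLOOR)
    lr = np.where(active, lr, 0.0)
    w_min = np.minimum(fa, fb)
    w_geo = np.sqrt(fa * fb)
    w_max = np.maximum(fa, fb)
    kmin = float(np.trapezoid(w_min * lr, z))
    kave = float(np.trapezoid(w_geo * lr, z))
    kmax = float(np.trapezoid(w_max * lr, z))
    return max(kmin, 0.0), max(kave, 0.0), max(kmax, 0.0)


def overlap_integrals(pa: DensityEstimate, pb: DensityEstimate) -> tuple[float, float, float]:
    """(∫min, ∫√(pa·pb), ∫max): the weight-normalization facts.

    For normalized densities ∫min ≤ 1 and ∫max ≥ 1 (their sum is 2), and
    the Bhattacharyya-type geometric-mean integral is ≤ 1 because a
    geometric mean never exceeds an arithmetic mean.
    """
    z = _union_grid(pa, pb)
    fa, fb = pa.pdf(z), pb.pdf(z)
    return (
        float(np.trapezoid(np.minimum(fa, fb), z)),
        float(np.trapezoid(np.sqrt(fa * fb), z)),
        float(np.trapezoid(np.maximum(fa, fb), z)),
    )


def ks1_one_sided(a: FluctuationSample, pb: DensityEstimate) -> float:
    """sup|F_n(a) − F(z|b)|, exact over the empirical-CDF step points."""
    v = np.sort(np.asarray(a.values if isinstance(a, FluctuationSample) else a, float))
    if v.size == 0:
        raise ValueError("empty sample")
    n = v.size
    f = pb.cdf(v)
    i = np.arange(1, n + 1)
    return float(max(np.max(np.abs(i / n - f)), np.max(np.abs((i - 1) / n - f))))


def ks1_sym(
    a: FluctuationSample,
    pa: DensityEstimate,
    b: FluctuationSample,
    pb: DensityEstimate,
) -> float:
    """Symmetrized 1-sample KS statistic: √(KS1(a|b)·KS1(b|a))."""
    return math.sqrt(ks1_one_sided(a, pb) * ks1_one_sided(b, pa))


def ks0(pa: DensityEstimate, pb: DensityEstimate, grid_points: int = 20_001) -> float:
    """sup|F(z|a) − F(z|b)| between the two estimated CDFs.

    A dense grid over the union support locates the maximum, which is
    then refined twice on shrinking brackets.
    """
    z = _union_grid(pa, pb, grid_points)
    diff = np.abs(pa.cdf(z) - pb.cdf(z))
    k = int(np.argmax(diff))
    best = float(diff[k])
    lo = z[max(k - 1, 0)]
    hi = z[min(k + 1, z.size - 1)]
    for _ in range(2):
        zz = np.linspace(lo, hi, 201)
        dd = np.abs(pa.cdf(zz) - pb.cdf(zz))
        j = int(np.argmax(dd))
        best = max(best, float(dd[j]))
        lo, hi = zz[max(j - 1, 0)], zz[min(j + 1, zz.size - 1)]
    return min(best, 1.0)


# ----------------------------------------------------------------------
# KS statistic -> p-value

def _kolmogorov_lambda(statistic: float, n_eff: int) -> float:
    rn = math.sqrt(n_eff)
    return statistic * (rn + 0.12 + 0.11 / rn)


def ks_to_pvalue(statistic: float, n_eff: int) -> float:
    """p-value of a KS statistic at effective sample size ``n_eff``.

    Uses the asymptotic Kolmogorov distribution of √n·D with the standard
    finite-n correction factor (√n + 0.12 + 0.11/√n).  Underflows to 0.0
    for extreme statistics; use :func:`log10_ks_pvalue` in that regime.
    """
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    if statistic <= 0.0:
        return 1.0
    lam = _kolmogorov_lambda(statistic, n_eff)
    return float(min(max(kstwobign.sf(lam), 0.0), 1.0))


def log10_ks_pvalue(statistic: float, n_eff: int) -> float:
    """log10 of the KS p-value, stable far below the float underflow limit.

    For moderate statistics this is log10 of :func:`ks_to_pvalue`; deep in
    the tail the asymptotic series Q(λ) = 2Σ(−1)^{j−1}exp(−2j²λ²) reduces
    to its leading term, whose log10 is evaluated directly.
    """
    if statistic <= 0.0:
        return 0.0
    lam = _kolmogorov_lambda(statistic, n_eff)
    pv = kstwobign.sf(lam)
    if pv > 1e-290:
        return float(math.log10(pv))
    # leading term 2 exp(-2 lam^2), next-order relative correction exp(-6 lam^2)
    ln_q = math.log(2.0) - 2.0 * lam * lam + math.log1p(-math.exp(max(-6.0 * lam * lam, -700.0)))
    return float(ln_q / math.log(10.0))


@dataclass
class MeasurePanel:
    """All eight similarity measures plus KS-derived p-values for one pair.

    ``pv_ks0`` is a descriptive device (the null of a statistic between
    two estimated CDFs is not the 1-sample KS null); it is flagged as
    non-calibrated wherever panels are written out.
    """

    delta_rmsf: float
    js: float
    delta_p: float
    kl_min: float
    kl_ave: float
    kl_max: float
    ks1: float
    ks0: float
    pv_ks1: float
    pv_ks0: float
    log10_pv_ks1: float
    log10_pv_ks0: float
    n_a: int
    n_b: int

    FIELDS = (
        "delta_rmsf", "js", "delta_p", "kl_min", "kl_ave", "kl_max",
        "ks1", "ks0", "pv_ks1", "pv_ks0", "log10_pv_ks1", "log10_pv_ks0",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS} | {"n_a": self.n_a, "n_b": self.n_b}


def measure_panel(
    a: FluctuationSample,
    pa: DensityEstimate,
    b: FluctuationSample,
    pb: DensityEstimate,
    rmsf_convention: str = "rms",
) -> MeasurePanel:
    """Compute the full eight-measure panel between two fitted samples."""
    kmin, kave, kmax = kl_band(pa, pb)
    d1 = ks1_sym(a, pa, b, pb)
    d0 = ks0(pa, pb)
    n_a, n_b = len(a.values), len(b.values)
    n_eff = min(n_a, n_b)
    return MeasurePanel(
        delta_rmsf=delta_rmsf(a, b, rmsf_convention),
        js=js_divergence(pa, pb),
        delta_p=delta_p(pa, pb),
        kl_min=kmin,
        kl_ave=kave,
        kl_max=kmax,
        ks1=d1,
        ks0=d0,
        pv_ks1=ks_to_pvalue(d1, n_eff),
        pv_ks0=ks_to_pvalue(d0, n_eff),
        log10_pv_ks1=log10_ks_pvalue(d1, n_eff),
        log10_pv_ks0=log10_ks_pvalue(d0, n_eff),
        n_a=n_a,
        n_b=n_b,
    )
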