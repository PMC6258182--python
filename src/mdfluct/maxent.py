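"""Nonparametric maximum-entropy density estimation for 1D fluctuation data.

The estimator represents a probability density on a closed support
``[lo, hi]`` as an exponential of a Chebyshev-polynomial expansion,

    P(v) = exp( lambda_0 - 1 + sum_{j=1..D} lambda_j T_j(t(v)) ),

where ``t`` maps the support affinely onto [-1, 1] and ``T_j`` are
Chebyshev polynomials of the first kind.  This is the maximum-entropy
density subject to D moment constraints on the level functions; the
multipliers are obtained by (convex) penalized maximum likelihood with
the normalization recomputed by Gauss-Legendre quadrature at every step.

Goodness of fit is judged without knowing the true density: the sample is
pushed through the trial CDF, which turns it into sampled uniform random
data (SURD) exactly when the trial density is correct.  Uniformity is
scored through single order statistics, whose marginals are Beta
distributions; the log-likelihood of the sorted mapped sample under those
Beta laws, standardized against a Monte-Carlo null at the same sample
size, gives a size-stable score and an acceptance decision at a fixed
confidence level.  The expansion dimension D grows from 1 until the score
reaches typical null quality, a small ensemble of refits from perturbed
starting points is generated at that dimension, and the median-scored
accepted member is returned as the representative estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "FluctuationSample",
    "DensityEstimate",
    "SurdScore",
    "EstimationConfig",
    "DegenerateSampleError",
    "estimate_density",
    "evaluate_pdf",
    "evaluate_cdf",
    "map_to_uniform",
    "score_surd",
    "select_representative",
]

# Seed for the SURD null-score calibration tables.  Fixed (not user
# controlled) so that acceptance thresholds are identical across runs and
# estimates stay reproducible under a given data seed.
_NULL_CALIBRATION_SEED = 19120646
_NULL_REPLICATES = 10_000
# Lower-tail probability of the null score distribution used for acceptance.
_ACCEPT_QUANTILE = 0.005


class DegenerateSampleError(ValueError):
    """Raised when a sample carries no usable spread (all values equal)."""


@dataclass
class FluctuationSample:
    """A 1D scalar sample for one local variable in one time block.

    Parameters
    ----------
    values:
        Observations in data units (Å for displacement magnitudes and
        residue-pair distances; unitless after mean-shifting).
    block_id:
        Which half-trajectory time block the sample came from (1 or 2).
    label:
        Identity of the variable: a residue index for on-residue
        displacements or an ``(i, j)`` tuple for a residue-pair distance.
    """

    values: np.ndarray
    block_id: int = 1
    label: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def validate(self, min_size: int = 2) -> None:
        if self.values.size < min_size:
            raise ValueError(
                f"sample needs at least {min_size} observations, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample contains non-finite values")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.values.size


@dataclass
class SurdScore:
    """Standardized order-statistic score of a uniform-mapped sample."""

    score: float  # standardized (null mean 0, null sd 1)
    accept: bool
    raw: float
    n: int
    threshold: float


@dataclass
class EstimationConfig:
    """Settings for :func:`estimate_density`.

    ``support`` fixes the estimation interval; when ``None`` it is derived
    from the sample as ``[min - 3*IQR/n**(1/3), max + 3*IQR/n**(1/3)]`` so
    the tails extend beyond the observed extremes.  ``nonnegative`` floors
    the lower bound at zero, appropriate for magnitudes and distances.
    """

    max_dimension: int = 40
    ensemble_size: int = 5
    quad_nodes: int = 256
    ridge: float = 1e-6
    support: tuple[float, float] | None = None
    nonnegative: bool = False
    cdf_grid: int = 4097


@dataclass
class DensityEstimate:
    """A fitted maximum-entropy density.

    ``lambdas[0]`` is the normalization multiplier lambda_0 (so that
    ``P = exp(lambdas[0] - 1 + sum_j lambdas[j] T_j)``); ``lambdas[1:]``
    are the D shape multipliers.  The density is defined to be exactly 0
    outside ``support``.
    """

    lambdas: np.ndarray
    support: tuple[float, float]
    basis: str = "chebyshev"
    seed: int | None = None
    surd: SurdScore | None = None
    _cdf_cache: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        lo, hi = self.support
        if not hi > lo:
            raise ValueError("support upper bound must exceed lower bound")
        self.support = (float(lo), float(hi))

    @property
    def dimension(self) -> int:
        return self.lambdas.size - 1

    def _to_unit(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.support
        return 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0

    def _log_pdf_inside(self, t: np.ndarray) -> np.ndarray:
        # log P on the affinely mapped coordinate, support points only
        coef = np.concatenate(([0.0], self.lambdas[1:]))
        return (self.lambdas[0] - 1.0) + _cheb.chebval(t, coef)

    def pdf(self, points) -> np.ndarray:
        """Density at ``points``; 0 outside the support by convention."""
        x = np.atleast_1d(np.asarray(points, dtype=float))
        lo, hi = self.support
        inside = (x >= lo) & (x <= hi)
        out = np.zeros_like(x)
        if np.any(inside):
            t = self._to_unit(x[inside])
            out[inside] = np.exp(self._log_pdf_inside(t))
        return out

    def _cdf_table(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cdf_cache is None:
            lo, hi = self.support
            grid = np.linspace(lo, hi, 4097)
            dens = self.pdf(grid)
            cum = np.concatenate(
                ([0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid)))
            )
            cum /= cum[-1]
            self._cdf_cache = (grid, cum)
        return self._cdf_cache

    def cdf(self, points) -> np.ndarray:
        """CDF at ``points``: 0 below the support, 1 above, monotone within."""
        x = np.atleast_1d(np.asarray(points, dtype=float))
        grid, cum = self._cdf_table()
        return np.clip(np.interp(x, grid, cum, left=0.0, right=1.0), 0.0, 1.0)

    def mean(self) -> float:
        """First moment of the density by quadrature."""
        lo, hi = self.support
        t, w = _leggauss(512)
        x = 0.5 * (hi - lo) * (t + 1.0) + lo
        dens = np.exp(self._log_pdf_inside(t))
        jac = 0.5 * (hi - lo)
        return float(np.sum(w * x * dens) * jac)

    def shifted(self, offset: float) -> "DensityEstimate":
        """The same density translated by ``offset`` (support moves, shape fixed)."""
        lo, hi = self.support
        return DensityEstimate(
            lambdas=self.lambdas.copy(),
            support=(lo + offset, hi + offset),
            basis=self.basis,
            seed=self.seed,
            surd=self.surd,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambdas": self.lambdas.tolist(),
                "dimension": self.dimension,
                "support": list(self.support),
                "basis": self.basis,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DensityEstimate":
        obj = json.loads(text)
        return cls(
            lambdas=np.asarray(obj["lambdas"], dtype=float),
            support=tuple(obj["support"]),
            basis=obj.get("basis", "chebyshev"),
            seed=obj.get("seed"),
        )


# ----------------------------------------------------------------------
# quadrature / basis helpers

_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _LEGGAUSS_CACHE[n]


def _chebvander(t: np.ndarray, deg: int) -> np.ndarray:
    """Columns T_1..T_deg evaluated at t (T_0 dropped: it is absorbed in lambda_0)."""
    return _cheb.chebvander(t, deg)[:, 1:]


def _default_support(values: np.ndarray, nonnegative: bool) -> tuple[float, float]:
    n = values.size
    q75, q25 = np.percentile(values, [75, 25])
    pad = 3.0 * (q75 - q25) / n ** (1.0 / 3.0)
    if pad <= 0.0:  # pathological but non-degenerate samples (two ties etc.)
        pad = 3.0 * values.std() if values.std() > 0 else 1.0
    lo = values.min() - pad
    hi = values.max() + pad
    if nonnegative:
        lo = max(lo, 0.0)
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# SURD scoring

_NULL_CACHE: dict[int, tuple[float, float, float]] = {}


def _beta_order_loglik(u_sorted: np.ndarray) -> float:
    """Sum over k of log Beta(k, n+1-k) density at the k-th order statistic."""
    u = np.clip(u_sorted, 1e-300, 1.0 - 1e-16)
    n = u.size
    k = np.arange(1, n + 1, dtype=float)
    log_b = gammaln(k) + gammaln(n + 1 - k) - gammaln(n + 1.0)
    return float(np.sum((k - 1.0) * np.log(u) + (n - k) * np.log1p(-u) - log_b))


def _null_score_stats(n: int) -> tuple[float, float, float, float]:
    """Null raw-score statistics at sample size n.

    Returns (mean, sd, standardized acceptance threshold, standardized
    median).  Computed once per sample size from sorted genuine-uniform
    samples and cached; the calibration seed is fixed so thresholds never
    vary between runs.
    """
    if n not in _NULL_CACHE:
        rng = np.random.default_rng(_NULL_CALIBRATION_SEED + n)
        scores = np.empty(_NULL_REPLICATES)
        chunk = max(1, int(2e6) // max(n, 1))
        k = np.arange(1, n + 1, dtype=float)
        log_b = gammaln(k) + gammaln(n + 1 - k) - gammaln(n + 1.0)
        done = 0
        while done < _NULL_REPLICATES:
            m = min(chunk, _NULL_REPLICATES - done)
            u = np.sort(rng.random((m, n)), axis=1)
            u = np.clip(u, 1e-300, 1.0 - 1e-16)
            scores[done : done + m] = (
                (k - 1.0) * np.log(u) + (n - k) * np.log1p(-u) - log_b
            ).sum(axis=1)
            done += m
        mean = float(scores.mean())
        sd = float(scores.std())
        q = float(np.quantile(scores, _ACCEPT_QUANTILE))
        q50 = float(np.quantile(scores, 0.5))
        _NULL_CACHE[n] = (mean, sd, (q - mean) / sd, (q50 - mean) / sd)
    return _NULL_CACHE[n]


def score_surd(uniform_sample: Sequence[float]) -> SurdScore:
    """Score a sorted [0,1] sample for uniformity via single order statistics.

    The raw score is the log-likelihood of the sorted values under their
    Beta order-statistic marginals; it is standardized by the Monte-Carlo
    null mean and sd at the same sample size, making the scale stable
    across sample sizes.  ``accept`` is true when the standardized score
    lies above the lower 0.5% quantile of the standardized null.
    """
    u = np.asarray(uniform_sample, dtype=float).ravel()
    if u.size == 0:
        raise ValueError("empty uniform sample")
    if np.any(np.diff(u) < 0):
        raise ValueError("uniform sample must be sorted ascending")
    if u.min() < 0.0 or u.max() > 1.0:
        raise ValueError("uniform sample must lie in [0, 1]")
    raw = _beta_order_loglik(u)
    mean, sd, thr, _ = _null_score_stats(u.size)
    z = (raw - mean) / sd
    return SurdScore(score=z, accept=bool(z >= thr), raw=raw, n=u.size, threshold=thr)


def map_to_uniform(estimate: DensityEstimate, sample: FluctuationSample) -> np.ndarray:
    """Push the sample through the estimated CDF and sort (the SURD candidate)."""
    return np.sort(estimate.cdf(sample.values))


# ----------------------------------------------------------------------
# fitting

def _fit_multipliers(
    g_data_mean: np.ndarray,
    g_quad: np.ndarray,
    quad_logw: np.ndarray,
    log_jac: float,
    init: np.ndarray,
    ridge: float,
) -> tuple[np.ndarray, float]:
    """Penalized ML for the shape multipliers at fixed dimension.

    Minimizes ``logZ(lam) - lam . mean g(data) + ridge * |lam|^2``; the
    problem is convex, so the optimum is unique up to solver tolerance.
    Returns the multipliers and log Z.
    """

    def negloglik(lam: np.ndarray):
        a = g_quad @ lam + quad_logw
        amax = a.max()
        ex = np.exp(a - amax)
        s = ex.sum()
        log_z = amax + np.log(s) + log_jac
        grad_z = (g_quad.T @ ex) / s
        f = log_z - g_data_mean @ lam + ridge * lam @ lam
        g = grad_z - g_data_mean + 2.0 * ridge * lam
        return f, g

    res = optimize.minimize(
        negloglik,
        init,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam = res.x
    a = g_quad @ lam + quad_logw
    amax = a.max()
    log_z = amax + np.log(np.exp(a - amax).sum()) + log_jac
    return lam, float(log_z)


def _build_estimate(
    lam: np.ndarray, log_z: float, support: tuple[float, float], seed: int | None
) -> DensityEstimate:
    # Recompute the normalization on a dense grid: for ill-conditioned fits
    # (sharp spikes from near-degenerate data) the fitting quadrature can be
    # off, and the returned estimate must integrate to 1 regardless.
    t = np.linspace(-1.0, 1.0, 32769)
    coef = np.concatenate(([0.0], lam))
    log_u = _cheb.chebval(t, coef)
    umax = log_u.max()
    z = np.trapezoid(np.exp(log_u - umax), t) * 0.5 * (support[1] - support[0])
    log_z = umax + np.log(z)
    lambdas = np.concatenate(([1.0 - log_z], lam))
    return DensityEstimate(lambdas=lambdas, support=support, seed=seed)


def estimate_density(
    sample: FluctuationSample,
    config: EstimationConfig | None = None,
    seed: int = 0,
) -> DensityEstimate:
    """Fit the maximum-entropy density to a 1D sample.

    The expansion dimension is grown from 1 until the SURD score reaches
    typical (null-median) uniformity quality or the dimension cap is
    reached; at the selected dimension an ensemble of refits from
    randomly perturbed starting multipliers is generated and the
    median-scored accepted member is returned.  Deterministic for a
    given ``(sample, config, seed)``.
    """
    config = config or EstimationConfig()
    if isinstance(sample, np.ndarray) or not isinstance(sample, FluctuationSample):
        sample = FluctuationSample(np.asarray(sample, dtype=float))
    sample.validate()
    x = sample.values
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("all sample values identical; no density to fit")

    support = config.support or _default_support(x, config.nonnegative)
    lo, hi = support
    if x.min() < lo or x.max() > hi:
        raise ValueError("sample values fall outside the fixed support")

    t_data = 2.0 * (x - lo) / (hi - lo) - 1.0
    t_quad, w_quad = _leggauss(config.quad_nodes)
    log_w = np.log(w_quad)
    log_jac = np.log(0.5 * (hi - lo))

    vander_data = _chebvander(t_data, config.max_dimension)
    vander_quad = _chebvander(t_quad, config.max_dimension)
    data_mean_full = vander_data.mean(axis=0)

    # Growth target: the fitted model should map the data to a sample whose
    # uniformity score is at least that of the *typical* genuine uniform
    # sample (the null median), not merely above the 0.5% rejection
    # threshold.  Stopping at the bare rejection threshold leaves
    # systematic misfit right at the detection limit (e.g. skewed
    # magnitude distributions accepted as quadratic-exponential fits),
    # which measurably biases downstream divergence and KS measures.
    _, _, _, target = _null_score_stats(x.size)

    # constraint count is capped by the information in the sample (~sqrt n)
    max_dim = min(config.max_dimension, max(4, int(np.sqrt(x.size))))
    best: DensityEstimate | None = None
    best_score = -np.inf
    best_dim = 0
    lam_prev = np.zeros(0)
    selected_dim = None
    for dim in range(1, max_dim + 1):
        init = np.concatenate((lam_prev, [0.0]))
        lam, log_z = _fit_multipliers(
            data_mean_full[:dim],
            vander_quad[:, :dim],
            log_w,
            log_jac,
            init,
            config.ridge,
        )
        lam_prev = lam
        est = _build_estimate(lam, log_z, support, seed)
        est.surd = score_surd(map_to_uniform(est, sample))
        if est.surd.score > best_score:
            best, best_score, best_dim = est, est.surd.score, dim
        if est.surd.score >= target:
            selected_dim = dim
            break
        if dim - best_dim >= 8:
            break  # score has plateaued; more constraints will not help

    if selected_dim is None:
        if not best.surd.accept:
            warnings.warn(
                "no expansion dimension up to "
                f"{max_dim} passed the SURD acceptance; "
                "returning the best-scoring fit",
                RuntimeWarning,
            )
            return best
        est = best
        selected_dim = best.dimension
        lam_prev = best.lambdas[1:]
    accepted_dim = selected_dim

    # ensemble of refits at the accepted dimension from perturbed starts
    rng = np.random.default_rng(seed)
    candidates = [est]
    base_lam = est.lambdas[1:]
    for _ in range(config.ensemble_size - 1):
        init = base_lam + rng.normal(0.0, 0.5, accepted_dim)
        lam, log_z = _fit_multipliers(
            data_mean_full[:accepted_dim],
            vander_quad[:, :accepted_dim],
            log_w,
            log_jac,
            init,
            config.ridge,
        )
        cand = _build_estimate(lam, log_z, support, seed)
        cand.surd = score_surd(map_to_uniform(cand, sample))
        candidates.append(cand)
    accepted = [c for c in candidates if c.surd.accept]
    return select_representative(accepted or candidates, sample)


def select_representative(
    candidates: Sequence[DensityEstimate], sample: FluctuationSample
) -> DensityEstimate:
    """Pick the median-scored candidate from an ensemble of fits.

    Candidates missing a cached SURD score are scored against ``sample``.
    With an even count the lower median is used; five candidates give the
    rank-3 member.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    scored = []
    for c in candidates:
        if c.surd is None:
            c.surd = score_surd(map_to_uniform(c, sample))
        scored.append((c.surd.score, c))
    scored.sort(key=lambda pair: pair[0])
    return scored[(len(scored) - 1) // 2][1]


def evaluate_pdf(estimate: DensityEstimate, points) -> np.ndarray:
    """Density values at ``points`` (0 outside the support)."""
    return estimate.pdf(points)


def evaluate_cdf(estimate: DensityEstimate, points) -> np.ndarray:
    """CDF values at ``points``, clipped to [0, 1]."""
    return estimate.cdf(points)
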