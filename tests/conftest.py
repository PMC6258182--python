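"""Shared fixtures and analytic density helpers for the test suite."""

import numpy as np
import pytest

from mdfluct import DensityEstimate


def gaussian_estimate(mu: float, sigma: float, support: tuple[float, float]) -> DensityEstimate:
    """Exact truncated-Gaussian density in the Chebyshev-exponential form.

    log p is quadratic in the mapped coordinate, so T1/T2 represent it
    exactly; the normalization multiplier is computed by quadrature.
    """
    lo, hi = support
    m = 0.5 * (hi - lo)
    c0 = 0.5 * (hi + lo)
    # -(m t + c0 - mu)^2 / (2 sigma^2) = a2 t^2 + a1 t + const
    a2 = -(m * m) / (2.0 * sigma * sigma)
    a1 = -m * (c0 - mu) / (sigma * sigma)
    lam1 = a1
    lam2 = a2 / 2.0  # t^2 = (T2 + 1) / 2
    t, w = np.polynomial.legendre.leggauss(512)
    log_u = lam1 * t + lam2 * (2.0 * t * t - 1.0)
    z = np.sum(w * np.exp(log_u)) * m
    return DensityEstimate(lambdas=np.array([1.0 - np.log(z), lam1, lam2]), support=support)


def uniform_estimate(lo: float, hi: float) -> DensityEstimate:
    return DensityEstimate(lambdas=np.array([1.0 - np.log(hi - lo)]), support=(lo, hi))


class StubDensity:
    """Duck-typed density (pdf + support) for closed-form oracle tests."""

    def __init__(self, pdf_fn, support):
        self._pdf = pdf_fn
        self.support = support

    def pdf(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        lo, hi = self.support
        out = np.where((x >= lo) & (x <= hi), self._pdf(x), 0.0)
        return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20171129)


@pytest.fixture(scope="session")
def std_normal_estimate():
    return gaussian_estimate(0.0, 1.0, (-6.0, 7.0))


@pytest.fixture(scope="session")
def shifted_normal_estimate():
    return gaussian_estimate(1.0, 1.0, (-6.0, 7.0))
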