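"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chromaflim._core import decay_shape
from chromaflim.flimio import TimeAxis
from chromaflim.irf_tools import IRFCurve, gaussian_irf
from chromaflim.synthgen import default_axis


@pytest.fixture
def small_axis() -> TimeAxis:
    """64 bins of 100 ps on a 50 ns (20 MHz) period."""
    return TimeAxis(n_bins=64, bin_width=100.0, rep_period=50000.0)


@pytest.fixture
def fit_axis() -> TimeAxis:
    """The post-binning fitting grid: 401 bins of ~122 ps on a 50 ns period."""
    return default_axis()


@pytest.fixture
def std_irf(fit_axis) -> IRFCurve:
    """A realistic instrument response: Gaussian at 1 ns, 300 ps FWHM."""
    return gaussian_irf(1000.0, 300.0, fit_axis)


def brute_force_periodic_conv(
    tau: float, response: np.ndarray, bin_width: float, rep_period: float
) -> np.ndarray:
    """O(n^2) mod-P convolution of the incomplete decay with the IRF.

    Independent of the recursive-filter implementation: evaluates the
    wrap-around sum term by term from its closed form.
    """
    n = len(response)
    t = (np.arange(n) + 0.5) * bin_width
    out = np.zeros(n)
    denom = 1.0 - np.exp(-rep_period / tau)
    for k in range(n):
        delta = np.mod(t[k] - t, rep_period)
        out[k] = np.sum(response * np.exp(-delta / tau)) / denom
    return out


def oracle_profile_em(y: np.ndarray, s: np.ndarray, n_iter: int = 300) -> tuple[float, float, float]:
    """Reference amplitude/offset profiling via plain EM, written standalone.

    Returns ``(A, b, loglik)`` for the model ``lam = A*s + b`` with ``s``
    summing to one.
    """
    n = y.size
    A = 0.9 * y.sum()
    b = max(0.1 * y.sum() / n, 1e-12)
    for _ in range(n_iter):
        lam = A * s + b
        A_new = A * float(np.sum(y * s / lam))
        b_new = b * float(np.mean(y / lam))
        if abs(A_new - A) < 1e-11 * A + 1e-14 and abs(b_new - b) < 1e-11 * b + 1e-14:
            A, b = A_new, b_new
            break
        A, b = A_new, b_new
    lam = A * s + b
    ll = float(np.sum(y * np.log(lam)) - lam.sum())
    return A, b, ll


def oracle_grid_tau(
    y: np.ndarray,
    response: np.ndarray,
    axis: TimeAxis,
    taus: np.ndarray,
) -> float:
    """Brute-force profile-likelihood grid search over tau.

    For each candidate lifetime the amplitude and offset are profiled out by
    the standalone EM above; returns the grid tau with the highest profiled
    log-likelihood.  Warm-starts (A, b) along the grid for speed only — the
    final inner solve at each tau is run to convergence.
    """
    n = y.size
    best_ll, best_tau = -np.inf, float(taus[0])
    A = 0.9 * y.sum()
    b = max(0.1 * y.sum() / n, 1e-12)
    for tau in taus:
        s = decay_shape(tau, response, axis.bin_width, axis.rep_period)
        for _ in range(200):
            lam = A * s + b
            A_new = A * float(np.sum(y * s / lam))
            b_new = b * float(np.mean(y / lam))
            moved = abs(A_new - A) > 1e-10 * A + 1e-13 or abs(b_new - b) > 1e-10 * b + 1e-13
            A, b = A_new, b_new
            if not moved:
                break
        lam = A * s + b
        ll = float(np.sum(y * np.log(lam)) - lam.sum())
        if ll > best_ll:
            best_ll, best_tau = ll, float(tau)
    return best_tau
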