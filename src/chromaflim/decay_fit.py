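"""Pixelwise mono-exponential lifetime fitting by Poisson maximum likelihood.

Model per pixel: ``lambda_k = A * s_k(tau) + b`` where ``s(tau)`` is the
incomplete (wrap-around) exponential decay under periodic excitation,
convolved with the IRF and normalized to sum 1 over the acquisition window
(:mod:`chromaflim._core`).  The estimator is Poisson maximum likelihood, not
weighted least squares: at the few hundred photons per (pooled) pixel typical
of chromatin FLIM, Gaussian weights are biased in the low-count tail bins.

The likelihood is maximized by profiling: amplitude and offset are
concentrated out with monotone EM updates at each candidate lifetime, leaving
a one-dimensional profiled likelihood in ``tau`` that is scanned coarsely and
then refined with bounded Brent minimization.  Goodness of fit is reported as
the reduced Pearson chi-squared with ``nu = n_bins - 3`` degrees of freedom
and an expected-count floor to keep empty tail bins from dividing by ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from chromaflim._core import decay_shape, profile_amplitude_offset
from chromaflim.flimio import DecayStack, TimeAxis
from chromaflim.irf_tools import IRFCurve

__all__ = [
    "DecayModelParams",
    "PixelFit",
    "LifetimeMap",
    "model_decay",
    "fit_pixel",
    "fit_image",
    "CHI2_FLOOR",
]

#: expected-count floor used in the Pearson chi-squared denominator
CHI2_FLOOR = 0.1


@dataclass(frozen=True)
class DecayModelParams:
    """Mono-exponential decay parameters.

    ``tau`` in ps; ``amplitude`` is the expected number of decay photons in
    the acquisition window; ``offset`` the expected flat background photons
    per bin.
    """

    tau: float
    amplitude: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.amplitude < 0 or self.offset < 0:
            raise ValueError("amplitude and offset must be >= 0")


class PixelFit(NamedTuple):
    params: DecayModelParams
    chi2_reduced: float
    converged: bool


@dataclass
class LifetimeMap:
    """Fitted per-pixel lifetime map (the tau_0 image) with QC planes.

    ``tau`` holds the fitted lifetime in ps (NaN outside ``mask``), ``chi2``
    the reduced Pearson statistic, ``intensity`` the integrated pre-smoothing
    photon counts used for display and thresholding.  The intensity-weighted
    "merged" rendering is produced by :func:`chromaflim.chromatin_maps.merged_map`.
    """

    tau: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    chi2: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    axis: TimeAxis
    irf_description: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.tau, self.amplitude, self.offset, self.chi2, self.intensity, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all LifetimeMap planes must share one shape")
        inside = self.mask & np.isfinite(self.tau)
        if np.any(self.tau[inside] <= 0):
            raise ValueError("tau must be > 0 inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.shape

    def masked_tau(self) -> np.ndarray:
        """Fitted lifetimes of masked pixels as a flat array."""
        return self.tau[self.mask & np.isfinite(self.tau)]


def _axis_check(irf: IRFCurve, axis: TimeAxis) -> None:
    if irf.axis.n_bins != axis.n_bins or not np.isclose(irf.axis.bin_width, axis.bin_width):
        raise ValueError("IRF and decay must share the same time axis")
    if axis.window > axis.rep_period * (1 + 1e-9):
        raise ValueError("acquisition window may not exceed the repetition period")


def model_decay(params: DecayModelParams, irf: IRFCurve, axis: TimeAxis) -> np.ndarray:
    """Expected counts per bin for the periodic-excitation model.

    ``sum_k (lambda_k - offset) == amplitude`` holds exactly by the shape
    normalization.
    """
    _axis_check(irf, axis)
    shape = decay_shape(params.tau, irf.effective_response(), axis.bin_width, axis.rep_period)
    return params.amplitude * shape + params.offset


class _ProfiledObjective:
    """Profiled negative log-likelihood in tau with warm-started EM."""

    def __init__(self, y: np.ndarray, response: np.ndarray, axis: TimeAxis):
        self.y = y
        self.response = response
        self.axis = axis
        self.amp = None
        self.off = None
        self.best: tuple[float, float, float, float] = (np.inf, np.nan, np.nan, np.nan)

    def __call__(self, tau: float) -> float:
        shape = decay_shape(tau, self.response, self.axis.bin_width, self.axis.rep_period)
        amp, off, ll, _ = profile_amplitude_offset(self.y, shape, amp0=self.amp, off0=self.off)
        self.amp, self.off = amp, off
        nll = -ll
        if nll < self.best[0]:
            self.best = (nll, tau, amp, off)
        return nll


def _pearson_chi2(y: np.ndarray, lam: np.ndarray, n_params: int = 3) -> float:
    nu = y.size - n_params
    resid = (y - lam) ** 2 / np.maximum(lam, CHI2_FLOOR)
    return float(resid.sum() / nu)


def fit_pixel(
    decay: np.ndarray,
    irf: IRFCurve,
    axis: TimeAxis,
    init: DecayModelParams | None = None,
    tau_bounds: tuple[float, float] | None = None,
    xatol: float = 0.05,
) -> PixelFit:
    """Fit one decay histogram; returns parameters, reduced chi2, convergence.

    A coarse logarithmic scan of the profiled likelihood brackets the
    optimum, which bounded Brent minimization then refines to ``xatol`` ps.
    When ``init`` is given (e.g. the neighboring pixel's solution) the scan
    is narrowed around it.  Non-convergence or a solution pinned at the tau
    bounds is flagged via ``converged=False`` rather than raised, so image
    fits can mask such pixels and continue.
    """
    y = np.asarray(decay, dtype=np.float64)
    if y.ndim != 1 or y.size != axis.n_bins:
        raise ValueError("decay must be 1-D with length axis.n_bins")
    if y.sum() <= 0:
        raise ValueError("cannot fit an all-zero decay")
    _axis_check(irf, axis)

    lo, hi = tau_bounds if tau_bounds is not None else (axis.bin_width, 5.0 * axis.rep_period)
    obj = _ProfiledObjective(y, irf.effective_response(), axis)

    if init is not None:
        grid = np.geomspace(max(lo, init.tau / 3.0), min(hi, init.tau * 3.0), 12)
        obj.amp, obj.off = init.amplitude, max(init.offset, 1e-12)
    else:
        grid = np.geomspace(lo, hi, 60)
    vals = np.array([obj(t) for t in grid])
    i = int(np.argmin(vals))
    # restart the EM warm start from the best scan point: the scan ends at
    # extreme tau, a poor starting point for the refinement bracket
    obj.amp, obj.off = obj.best[2], max(obj.best[3], 1e-12)
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    if b_lo >= b_hi:  # degenerate bracket at a boundary
        b_lo, b_hi = max(lo, b_lo * 0.5), min(hi, b_hi * 2.0)
    result = minimize_scalar(obj, bounds=(b_lo, b_hi), method="bounded", options={"xatol": xatol})

    # obj.best tracks the lowest profiled NLL over every evaluation,
    # including Brent's, with its matching profiled amplitude/offset
    _, tau_hat, amp_hat, off_hat = obj.best
    converged = bool(result.success) and (tau_hat > lo * 1.001) and (tau_hat < hi * 0.999)
    params = DecayModelParams(tau=tau_hat, amplitude=max(amp_hat, 0.0), offset=max(off_hat, 0.0))
    lam = model_decay(params, irf, axis)
    return PixelFit(params=params, chi2_reduced=_pearson_chi2(y, lam), converged=converged)


def fit_image(
    stack: DecayStack,
    mask: np.ndarray,
    irf: IRFCurve,
    intensity: np.ndarray | None = None,
) -> LifetimeMap:
    """Fit every masked pixel of a preprocessed stack.

    ``intensity`` should carry the unsmoothed per-pixel totals (from
    :func:`chromaflim.preprocess.smooth_and_mask`'s input); when omitted the
    stack's own totals are used.  Pixels whose fit does not converge are
    removed from the output mask rather than aborting the image.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.counts.shape[:2]:
        raise ValueError("mask shape must match the stack's spatial shape")
    if not mask.any():
        raise ValueError("empty mask: no pixels to fit")
    axis = stack.axis
    shape2d = mask.shape
    tau = np.full(shape2d, np.nan)
    amp = np.full(shape2d, np.nan)
    off = np.full(shape2d, np.nan)
    chi2 = np.full(shape2d, np.nan)
    out_mask = np.zeros(shape2d, dtype=bool)
    if intensity is None:
        intensity = stack.intensity_image().astype(np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.shape != shape2d:
        raise ValueError("intensity shape must match the stack's spatial shape")

    prev: DecayModelParams | None = None
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        y = stack.counts[r, c].astype(np.float64)
        if y.sum() <= 0:
            prev = None
            continue
        fit = fit_pixel(y, irf, axis, init=prev)
        if not fit.converged:
            # one restart from scratch before masking the pixel out
            fit = fit_pixel(y, irf, axis, init=None)
        if fit.converged:
            tau[r, c] = fit.params.tau
            amp[r, c] = fit.params.amplitude
            off[r, c] = fit.params.offset
            chi2[r, c] = fit.chi2_reduced
            out_mask[r, c] = True
            prev = fit.params
        else:
            prev = None

    irf_description = {
        "is_delta": irf.is_delta,
        "center": irf.center,
        "fwhm": irf.fwhm,
        "shift": irf.shift,
    }
    return LifetimeMap(
        tau=tau,
        amplitude=amp,
        offset=off,
        chi2=chi2,
        intensity=intensity,
        mask=out_mask,
        axis=axis,
        irf_description=irf_description,
    )
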