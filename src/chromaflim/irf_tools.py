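"""Instrument response function (IRF) representation and estimation.

The measured TCSPC decay is the true decay convolved with the instrument
response.  Here the IRF is either an idealized delta (single unit bin) or a
parametric Gaussian.  The estimator recovers the Gaussian's center and width
from a reference measurement of a mono-exponential dye of known lifetime
(e.g. rhodamine 6G imaged under acquisition settings), by maximizing the
Poisson likelihood of the spatially pooled decay with the lifetime held
fixed.  A parametric fit is preferred over non-parametric deconvolution,
which is ill-posed at typical photon counts; two parameters suffice for
single-exponential work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from chromaflim._core import decay_shape, profile_amplitude_offset
from chromaflim.flimio import DecayStack, TimeAxis

__all__ = [
    "IRFCurve",
    "gaussian_irf",
    "delta_irf",
    "estimate_irf",
    "write_irf",
    "read_irf",
    "InsufficientSignalError",
    "IRFEstimationError",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InsufficientSignalError(ValueError):
    """The pooled reference decay carries too few photons to estimate an IRF."""


class IRFEstimationError(RuntimeError):
    """The IRF optimizer failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: dict):
        super().__init__(f"{message}; last iterate: {last_iterate}")
        self.last_iterate = last_iterate


@dataclass
class IRFCurve:
    """Normalized instrument response on a time axis.

    ``shift`` is a global temporal offset (ps) applied when the IRF is used
    in fitting; it is never fitted per pixel.  ``center``/``fwhm`` record the
    Gaussian parameters when the curve is parametric.
    """

    response: np.ndarray
    axis: TimeAxis
    shift: float = 0.0
    is_delta: bool = False
    center: float | None = field(default=None)
    fwhm: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=np.float64)
        if self.response.ndim != 1 or self.response.size != self.axis.n_bins:
            raise ValueError("response must be 1-D with length axis.n_bins")
        if np.any(self.response < 0):
            raise ValueError("response entries must be >= 0")
        total = self.response.sum()
        if total <= 0:
            raise ValueError("response must have positive mass")
        self.response = self.response / total
        if self.is_delta and np.count_nonzero(self.response) != 1:
            raise ValueError("a delta IRF must occupy exactly one bin")

    def effective_response(self) -> np.ndarray:
        """Response with the global shift applied (linear interpolation)."""
        if self.shift == 0.0:
            return self.response
        t = self.axis.bin_centers
        shifted = np.interp(t - self.shift, t, self.response, left=0.0, right=0.0)
        total = shifted.sum()
        if total <= 0:
            raise ValueError("shift moved the IRF entirely out of the window")
        return shifted / total

    def centroid(self) -> float:
        """First temporal moment of the (shifted) response, in ps."""
        r = self.effective_response()
        return float(r @ self.axis.bin_centers)


def delta_irf(axis: TimeAxis) -> IRFCurve:
    """Idealized instantaneous IRF: all mass in the first time bin."""
    response = np.zeros(axis.n_bins)
    response[0] = 1.0
    return IRFCurve(response=response, axis=axis, is_delta=True)


def gaussian_irf(center: float, fwhm: float, axis: TimeAxis) -> IRFCurve:
    """Discretized Gaussian IRF, renormalized to sum 1.

    ``center`` must lie inside the acquisition window and ``fwhm`` must be
    positive; a Gaussian narrower than a bin simply concentrates in one bin.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    if not (0 <= center <= axis.window):
        raise ValueError(f"center {center} outside the acquisition window [0, {axis.window}]")
    t = axis.bin_centers
    sigma = fwhm * _FWHM_TO_SIGMA
    response = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    if response.sum() <= 0 or not np.all(np.isfinite(response)):
        # kernel far narrower than a bin: all samples underflow; put the
        # mass in the nearest bin instead
        response = np.zeros(axis.n_bins)
        response[np.argmin(np.abs(t - center))] = 1.0
    return IRFCurve(response=response, axis=axis, center=center, fwhm=fwhm)


def estimate_irf(
    reference: DecayStack,
    reference_tau: float,
    min_photons: int = 1000,
) -> IRFCurve:
    """Estimate a Gaussian IRF from a reference-dye measurement.

    The stack is pooled over all pixels (the estimate depends only on the
    pooled histogram) and the Gaussian center and FWHM are found by
    maximizing the Poisson likelihood of the pooled decay under the periodic
    mono-exponential model with the dye lifetime ``reference_tau`` held
    fixed; amplitude and flat background are profiled out.

    The dye lifetime is a required input: it must come from the caller's
    calibration, not from this package.
    """
    if reference_tau <= 0:
        raise ValueError("reference_tau must be > 0")
    axis = reference.axis
    pooled = reference.counts.sum(axis=(0, 1)).astype(np.float64)
    total = pooled.sum()
    if total < min_photons:
        raise InsufficientSignalError(
            f"pooled reference decay has {int(total)} photons; need >= {min_photons}"
        )

    t = axis.bin_centers
    center0 = float(t[int(np.argmax(pooled))])
    fwhm0 = max(3.0 * axis.bin_width, 1e-3)
    min_fwhm = axis.bin_width / 100.0
    warm = {"amp": None, "off": None}

    def neg_profiled_loglik(x: np.ndarray) -> float:
        center, log_fwhm = x
        fwhm = float(np.exp(log_fwhm))
        if not (0 <= center <= axis.window):
            return 1e30
        try:
            irf = gaussian_irf(center, max(fwhm, min_fwhm), axis)
            shape = decay_shape(reference_tau, irf.response, axis.bin_width, axis.rep_period)
            amp, off, ll, _ = profile_amplitude_offset(
                pooled, shape, amp0=warm["amp"], off0=warm["off"]
            )
        except (ValueError, FloatingPointError):
            return 1e30
        warm["amp"], warm["off"] = amp, off
        return -ll

    x0 = np.array([center0, np.log(fwhm0)])
    result = minimize(
        neg_profiled_loglik,
        x0,
        method="Nelder-Mead",
        bounds=[(0.0, axis.window), (np.log(min_fwhm), np.log(axis.window))],
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 600, "maxfev": 1200},
    )
    if not result.success or not np.isfinite(result.fun) or result.fun >= 1e29:
        raise IRFEstimationError(
            "IRF estimation did not converge",
            {"center": float(result.x[0]), "fwhm": float(np.exp(result.x[1])), "neg_loglik": float(result.fun)},
        )
    center_hat = float(result.x[0])
    fwhm_hat = max(float(np.exp(result.x[1])), min_fwhm)
    return gaussian_irf(center_hat, fwhm_hat, axis)


def write_irf(irf: IRFCurve, csv_path: str | Path) -> Path:
    """Store an IRF as a two-column CSV plus a JSON parameter sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_ps": irf.axis.bin_centers, "response": irf.response}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "center": irf.center,
        "fwhm": irf.fwhm,
        "shift": irf.shift,
        "is_delta": irf.is_delta,
        "bin_width_ps": irf.axis.bin_width,
        "rep_period_ps": irf.axis.rep_period,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_irf(csv_path: str | Path) -> IRFCurve:
    """Read an IRF written by :func:`write_irf`."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    n_bins = len(table)
    axis = TimeAxis(
        n_bins=n_bins,
        bin_width=float(meta["bin_width_ps"]),
        rep_period=float(meta["rep_period_ps"]),
    )
    return IRFCurve(
        response=table["response"].to_numpy(),
        axis=axis,
        shift=float(meta.get("shift", 0.0)),
        is_delta=bool(meta.get("is_delta", False)),
        center=meta.get("center"),
        fwhm=meta.get("fwhm"),
    )
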