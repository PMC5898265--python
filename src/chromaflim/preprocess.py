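"""Data conditioning applied before lifetime fitting.

The chain is fixed: temporal binning (4096 → 401 bins by summing groups of
10), 4×4 spatial binning so enough photons land in each pixel, then a 5×5
neighborhood pooling ("smoothing") with a photon threshold of 200 applied to
the *unsmoothed* per-pixel totals.  Photons are conserved at every stage over
the retained ranges; each stage stamps the stack's processing record and
smoothing refuses to run twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from chromaflim.flimio import DecayStack, TimeAxis

__all__ = [
    "PreprocessConfig",
    "temporal_bin",
    "spatial_bin",
    "smooth_and_mask",
    "preprocess_stack",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Default conditioning parameters of the pipeline.

    ``temporal_target_bins=401``, ``spatial_bin=4``, ``smooth_kernel=5`` and
    ``intensity_threshold=200`` photons are the standard settings; the
    threshold applies strictly ("above ... photons").
    """

    temporal_target_bins: int = 401
    spatial_bin: int = 4
    smooth_kernel: int = 5
    intensity_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.spatial_bin < 1:
            raise ValueError("spatial_bin must be >= 1")
        if self.smooth_kernel < 1 or self.smooth_kernel % 2 == 0:
            raise ValueError("smooth_kernel must be an odd integer >= 1")
        if self.temporal_target_bins < 1:
            raise ValueError("temporal_target_bins must be >= 1")
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")


def _check_not_smoothed(stack: DecayStack, op: str) -> None:
    if any(step.startswith("smooth") for step in stack.processing):
        raise ValueError(f"{op} may not run after smoothing (processing: {stack.processing})")


def temporal_bin(stack: DecayStack, target_bins: int) -> DecayStack:
    """Sum consecutive groups of time bins down to ``target_bins``.

    The binning factor is ``f = floor(n_bins / target_bins)``; the first
    ``target_bins * f`` bins are summed in groups of ``f`` and any trailing
    bins are discarded (with 4096 input bins and the default target of 401,
    ``f = 10`` and bins 4010–4095 are dropped).  Photons are conserved over
    the retained range.
    """
    _check_not_smoothed(stack, "temporal_bin")
    n = stack.axis.n_bins
    if target_bins > n:
        raise ValueError(f"target_bins {target_bins} exceeds n_bins {n}")
    f = n // target_bins
    retained = target_bins * f
    counts = stack.counts[:, :, :retained]
    binned = counts.reshape(counts.shape[0], counts.shape[1], target_bins, f).sum(axis=3)
    axis = TimeAxis(
        n_bins=target_bins,
        bin_width=stack.axis.bin_width * f,
        rep_period=stack.axis.rep_period,
    )
    return DecayStack(
        counts=binned,
        axis=axis,
        z_index=stack.z_index,
        channel_label=stack.channel_label,
        metadata=stack.metadata,
        processing=stack.processing + [f"temporal_bin:{f}"],
    )


def spatial_bin(stack: DecayStack, factor: int) -> DecayStack:
    """Sum non-overlapping ``factor x factor`` pixel blocks per time bin.

    512×512 → 128×128 at the default factor 4.  Dimensions not divisible by
    the factor are cropped at the bottom/right with a warning.
    """
    _check_not_smoothed(stack, "spatial_bin")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rows, cols, nt = stack.counts.shape
    r_keep = (rows // factor) * factor
    c_keep = (cols // factor) * factor
    if r_keep == 0 or c_keep == 0:
        raise ValueError(f"image {rows}x{cols} smaller than binning factor {factor}")
    if (r_keep, c_keep) != (rows, cols):
        warnings.warn(
            f"image {rows}x{cols} not divisible by {factor}; cropping to {r_keep}x{c_keep}",
            stacklevel=2,
        )
    counts = stack.counts[:r_keep, :c_keep]
    binned = counts.reshape(r_keep // factor, factor, c_keep // factor, factor, nt).sum(axis=(1, 3))
    return DecayStack(
        counts=binned,
        axis=stack.axis,
        z_index=stack.z_index,
        channel_label=stack.channel_label,
        metadata=stack.metadata,
        processing=stack.processing + [f"spatial_bin:{factor}"],
    )


def smooth_and_mask(
    stack: DecayStack, config: PreprocessConfig | None = None
) -> tuple[DecayStack, np.ndarray]:
    """Neighborhood photon pooling plus the intensity-threshold fit mask.

    The mask is ``True`` where the *unsmoothed* per-pixel photon total
    strictly exceeds the threshold.  The smoothed stack holds, per time bin,
    the kernel-neighborhood photon sum (boxcar mean × kernel area), with
    reflective edge padding, and is what the fitter consumes; the mask decides
    which pixels get fitted.
    """
    config = config or PreprocessConfig()
    if any(step.startswith("smooth") for step in stack.processing):
        raise ValueError("stack is already smoothed; smoothing may not be applied twice")
    k = config.smooth_kernel
    totals = stack.counts.sum(axis=2)
    mask = totals > config.intensity_threshold
    if k == 1:
        smoothed = stack.counts
    else:
        pooled = uniform_filter(
            stack.counts.astype(np.float64), size=k, axes=(0, 1), mode="reflect"
        ) * (k * k)
        smoothed = np.rint(pooled).astype(np.int64)
    out = DecayStack(
        counts=smoothed,
        axis=stack.axis,
        z_index=stack.z_index,
        channel_label=stack.channel_label,
        metadata=stack.metadata,
        processing=stack.processing + [f"smooth:{k}"],
    )
    return out, mask


def preprocess_stack(
    stack: DecayStack, config: PreprocessConfig | None = None
) -> tuple[DecayStack, np.ndarray, np.ndarray]:
    """Full conditioning chain: temporal bin → spatial bin → smooth + mask.

    Returns ``(smoothed stack, mask, unsmoothed binned intensity)``; the
    intensity plane feeds the lifetime map's display/threshold channel.
    """
    config = config or PreprocessConfig()
    target = min(config.temporal_target_bins, stack.axis.n_bins)
    stack = temporal_bin(stack, target)
    stack = spatial_bin(stack, config.spatial_bin)
    intensity = stack.counts.sum(axis=2).astype(np.float64)
    smoothed, mask = smooth_and_mask(stack, config)
    return smoothed, mask, intensity
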