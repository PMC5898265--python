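"""Persistent data model and I/O for time-resolved image stacks and maps.

The on-disk container is deliberately instrument-agnostic: a multi-page TIFF
(one page per TCSPC time bin, ``uint32`` photon counts) accompanied by a JSON
sidecar holding the time-axis metadata (``n_bins``, ``bin_width_ps``,
``rep_period_ps``, ...).  Vendor TCSPC formats (e.g. PicoQuant ``.ptu``) are
out of scope; converting them to this container is the caller's job.

Conventions: row-major arrays, 0-based indices, pixel ``(0, 0)`` at the
top-left; time bin ``k`` covers ``[k * bin_width, (k + 1) * bin_width)`` so
bin centers are ``(k + 0.5) * bin_width``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "TimeAxis",
    "DecayStack",
    "StackMetadata",
    "read_decay_stack",
    "write_decay_stack",
    "export_map",
    "import_map",
    "MetadataError",
    "DimensionMismatchError",
]


class MetadataError(ValueError):
    """A required sidecar or metadata field is missing or inconsistent."""


class DimensionMismatchError(ValueError):
    """Array dimensions disagree with the declared metadata."""


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC time axis.

    Parameters
    ----------
    n_bins
        Number of time bins (≥ 2).
    bin_width
        Bin width in picoseconds.
    rep_period
        Laser repetition period in picoseconds (20 MHz → 50,000 ps).  The
        acquisition window ``n_bins * bin_width`` may cover only part of the
        period.
    """

    n_bins: int
    bin_width: float
    rep_period: float

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if self.rep_period <= 0:
            raise ValueError(f"rep_period must be > 0, got {self.rep_period}")

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times ``(k + 0.5) * bin_width`` in ps."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def window(self) -> float:
        """Total acquisition window ``n_bins * bin_width`` in ps."""
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class StackMetadata:
    """Optional acquisition metadata carried alongside a stack."""

    pixel_size: float | None = None  # micrometres
    excitation_wavelength: float | None = None  # nanometres
    acquisition_notes: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 when present")


@dataclass
class DecayStack:
    """Per-pixel photon-count histograms over TCSPC time bins.

    ``counts`` is indexed ``(row, col, time_bin)`` and holds non-negative
    integer photon counts.
    """

    counts: np.ndarray
    axis: TimeAxis
    z_index: int | None = None
    channel_label: str = ""
    metadata: StackMetadata = field(default_factory=StackMetadata)
    processing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise DimensionMismatchError(
                f"counts must be 3-D (row, col, time_bin), got ndim={self.counts.ndim}"
            )
        if self.counts.shape[2] != self.axis.n_bins:
            raise DimensionMismatchError(
                f"time dimension {self.counts.shape[2]} != axis.n_bins {self.axis.n_bins}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integer photon counts")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def total_counts(self) -> int:
        """Total photons in the stack."""
        return int(self.counts.sum())

    def intensity_image(self) -> np.ndarray:
        """Per-pixel integrated photon counts (sum over time bins)."""
        return self.counts.sum(axis=2)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_decay_stack(stack: DecayStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (pages = time bins) + JSON sidecar.

    Returns the TIFF path; the sidecar lives next to it with a ``.json``
    suffix.
    """
    path = Path(path)
    pages = np.moveaxis(stack.counts.astype(np.uint32), 2, 0)  # (t, row, col)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "n_bins": stack.axis.n_bins,
        "bin_width_ps": stack.axis.bin_width,
        "rep_period_ps": stack.axis.rep_period,
        "pixel_size_um": stack.metadata.pixel_size,
        "excitation_wavelength_nm": stack.metadata.excitation_wavelength,
        "acquisition_notes": stack.metadata.acquisition_notes,
        "channel_label": stack.channel_label,
        "z_index": stack.z_index,
        "processing": stack.processing,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_decay_stack(path: str | Path) -> DecayStack:
    """Read a stack written by :func:`write_decay_stack`.

    Raises
    ------
    MetadataError
        If the JSON sidecar is missing, naming the expected file.
    DimensionMismatchError
        If the TIFF page count disagrees with the sidecar's ``n_bins``.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise MetadataError(f"missing JSON sidecar: expected {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("n_bins", "bin_width_ps", "rep_period_ps"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar_path} lacks required key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    if pages.shape[0] != meta["n_bins"]:
        raise DimensionMismatchError(
            f"TIFF has {pages.shape[0]} pages but sidecar declares n_bins={meta['n_bins']}"
        )
    axis = TimeAxis(
        n_bins=int(meta["n_bins"]),
        bin_width=float(meta["bin_width_ps"]),
        rep_period=float(meta["rep_period_ps"]),
    )
    metadata = StackMetadata(
        pixel_size=meta.get("pixel_size_um"),
        excitation_wavelength=meta.get("excitation_wavelength_nm"),
        acquisition_notes=meta.get("acquisition_notes", ""),
    )
    return DecayStack(
        counts=np.moveaxis(pages, 0, 2).astype(np.int64),
        axis=axis,
        z_index=meta.get("z_index"),
        channel_label=meta.get("channel_label", ""),
        metadata=metadata,
        processing=list(meta.get("processing", [])),
    )


def export_map(map_array: np.ndarray, path: str | Path, mask: np.ndarray | None = None) -> Path:
    """Export a 2-D map as 32-bit float TIFF; masked-out pixels become NaN."""
    map_array = np.asarray(map_array, dtype=np.float32)
    if map_array.ndim != 2:
        raise DimensionMismatchError("export_map expects a 2-D array")
    out = map_array.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != out.shape:
            raise DimensionMismatchError("mask shape must match map shape")
        out[~mask] = np.nan
    path = Path(path)
    tifffile.imwrite(path, out)
    return path


def import_map(path: str | Path) -> np.ndarray:
    """Read back a float map written by :func:`export_map`."""
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float32)
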