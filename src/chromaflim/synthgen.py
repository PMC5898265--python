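"""Synthetic nuclei phantoms and TCSPC stacks with known ground truth.

The phantom emulates a fluorescently tagged histone (H2B-GFP-like) nucleus:
a bright disc of open chromatin ("euchromatin", long donor lifetime) dotted
with compact foci ("heterochromatin", shortened lifetime).  Compaction brings
nucleosome-bound donors and acceptors closer, raising FRET and lowering the
donor lifetime — so in the phantom every focus pixel has ``tau_compact <=
tau_open``.  FRET is modeled phenomenologically as that shortened single
lifetime per pixel (not a two-component decay): ground truth then lives in
the same model family the fitter uses, so recovery is well-posed.

Photon noise is Poisson on the periodic-excitation model curve; background
is flat over time bins (dark counts / afterpulsing — no scattered-laser peak
is simulated).  Geometry and photon noise draw from independent seeded
sub-streams so one phantom can be reused across noise realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from chromaflim._core import decay_shape
from chromaflim.flimio import DecayStack, TimeAxis
from chromaflim.irf_tools import IRFCurve, delta_irf

__all__ = [
    "SimConfig",
    "ChromatinPhantom",
    "make_phantom",
    "simulate_decay_stack",
    "simulate_pixels",
    "simulate_reference_stack",
    "simulate_if_image",
    "default_axis",
    "GeometryError",
]

BACKGROUND = 0
EUCHROMATIN = 1
HETEROCHROMATIN = 2


class GeometryError(ValueError):
    """Requested phantom geometry cannot be placed inside the image."""


def default_axis(n_bins: int = 401) -> TimeAxis:
    """Time axis matching the fitted-grid resolution of a 20 MHz acquisition.

    4096 raw bins over a 50 ns period give a 12.207 ps raw bin; after 10×
    temporal binning the fitted grid has 401 bins of 122.07 ps.  Smaller
    ``n_bins`` keep the same bin width (shorter window) for fast tests.
    """
    return TimeAxis(n_bins=n_bins, bin_width=10 * 50000.0 / 4096.0, rep_period=50000.0)


@dataclass
class SimConfig:
    """Ground-truth study conditions for the synthetic pipeline.

    Lifetimes default to the donor-only vs donor+acceptor contrast typical of
    the chromatin assay (open ≈ 2600 ps, compact ≈ 2100 ps).
    ``photons_per_pixel`` is the expected decay-photon count of a lit pixel
    on the simulated grid; ``background_rate`` the expected flat background
    photons per pixel spread uniformly over the time bins.
    """

    image_size: int = 128
    n_nuclei: int = 1
    nucleus_radius: float = 40.0
    n_foci: int = 8
    focus_radius: float = 4.0
    tau_open: float = 2600.0
    tau_compact: float = 2100.0
    photons_per_pixel: float = 10_000.0
    background_rate: float = 200.0
    irf: IRFCurve | None = None
    axis: TimeAxis = field(default_factory=default_axis)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_compact > self.tau_open:
            raise ValueError("tau_compact must be <= tau_open (FRET shortens the donor lifetime)")
        if self.photons_per_pixel < 0 or self.background_rate < 0:
            raise ValueError("photon rates must be >= 0")
        if self.nucleus_radius < 1 or self.focus_radius < 1:
            raise ValueError("radii must be >= 1 pixel")

    def get_irf(self) -> IRFCurve:
        return self.irf if self.irf is not None else delta_irf(self.axis)


@dataclass
class ChromatinPhantom:
    """Ground-truth maps: state (0 bg / 1 open / 2 compact), tau, brightness."""

    state_map: np.ndarray
    tau_map: np.ndarray
    brightness_map: np.ndarray
    nucleus_centers: list[tuple[float, float]]
    focus_centers: list[tuple[float, float]]

    def __post_init__(self) -> None:
        lit = self.state_map > 0
        if np.any(self.tau_map[lit] <= 0):
            raise ValueError("tau_map must be > 0 wherever state_map > 0")


def _disc_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_phantom(config: SimConfig) -> ChromatinPhantom:
    """Place nuclei discs with interior compact foci; deterministic per seed."""
    size = config.image_size
    r = config.nucleus_radius
    if 2 * r + 2 > size:
        raise GeometryError(f"nucleus radius {r} does not fit in a {size}px image")
    rng = np.random.default_rng([config.seed, 0])

    state = np.zeros((size, size), dtype=np.int8)
    centers: list[tuple[float, float]] = []
    for _ in range(config.n_nuclei):
        placed = False
        for _attempt in range(500):
            c = tuple(rng.uniform(r + 1, size - r - 1, size=2))
            if all((c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2 > (2 * r + 2) ** 2 for p in centers):
                placed = True
                break
        if not placed:
            raise GeometryError(
                f"could not place {config.n_nuclei} non-overlapping nuclei of radius {r} "
                f"in a {size}px image"
            )
        centers.append(c)
        state[_disc_mask(size, c, r)] = EUCHROMATIN

    focus_centers: list[tuple[float, float]] = []
    for c in centers:
        for _ in range(config.n_foci):
            # uniform inside the disc that keeps the focus wholly in the nucleus
            rho = (r - config.focus_radius) * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            fc = (c[0] + rho * np.sin(theta), c[1] + rho * np.cos(theta))
            focus_centers.append(fc)
            state[_disc_mask(size, fc, config.focus_radius)] = HETEROCHROMATIN

    tau_map = np.zeros((size, size))
    tau_map[state == EUCHROMATIN] = config.tau_open
    tau_map[state == HETEROCHROMATIN] = config.tau_compact
    brightness = np.zeros((size, size))
    brightness[state > 0] = config.photons_per_pixel
    return ChromatinPhantom(
        state_map=state,
        tau_map=tau_map,
        brightness_map=brightness,
        nucleus_centers=centers,
        focus_centers=focus_centers,
    )


def _expected_rates(phantom: ChromatinPhantom, config: SimConfig) -> np.ndarray:
    """Per-pixel expected counts per bin, shape (rows, cols, n_bins)."""
    axis = config.axis
    irf = config.get_irf()
    lam = np.full(
        phantom.state_map.shape + (axis.n_bins,),
        config.background_rate / axis.n_bins,
    )
    response = irf.effective_response()
    for tau in np.unique(phantom.tau_map[phantom.state_map > 0]):
        shape = decay_shape(tau, response, axis.bin_width, axis.rep_period)
        sel = (phantom.tau_map == tau) & (phantom.state_map > 0)
        lam[sel] += phantom.brightness_map[sel][:, None] * shape[None, :]
    if np.any(lam < 0):
        raise AssertionError("negative expected rates — internal error")
    return lam


def simulate_decay_stack(phantom: ChromatinPhantom, config: SimConfig) -> DecayStack:
    """Poisson-sample a TCSPC stack from the phantom's ground truth.

    Per pixel, ``counts[k] ~ Poisson(brightness * p_k(tau) +
    background_rate / n_bins)`` where ``p_k`` is the periodic-excitation
    model shape (IRF included) normalized over the acquisition window.
    Reproducible: the photon stream is seeded independently of geometry.
    """
    lam = _expected_rates(phantom, config)
    rng = np.random.default_rng([config.seed, 1])
    counts = rng.poisson(lam).astype(np.int64)
    return DecayStack(counts=counts, axis=config.axis, channel_label="donor")


def simulate_pixels(
    tau: float,
    n_pixels: int,
    photons: float,
    background: float,
    irf: IRFCurve,
    axis: TimeAxis,
    seed: int,
) -> np.ndarray:
    """Independent single-pixel decays, shape (n_pixels, n_bins).

    Convenience generator for estimator studies: every pixel shares the same
    ground truth (``tau``, expected ``photons`` in the decay, flat
    ``background`` photons over the window).
    """
    shape = decay_shape(tau, irf.effective_response(), axis.bin_width, axis.rep_period)
    lam = photons * shape + background / axis.n_bins
    rng = np.random.default_rng([seed, 2])
    return rng.poisson(lam, size=(n_pixels, axis.n_bins)).astype(np.int64)


def simulate_reference_stack(
    tau_ref: float,
    irf: IRFCurve,
    axis: TimeAxis,
    photons_per_pixel: float,
    image_size: int = 8,
    background_per_pixel: float = 0.0,
    seed: int = 0,
) -> DecayStack:
    """Uniform mono-exponential dye measurement for IRF estimation.

    Emulates imaging a reference dye solution (e.g. rhodamine 6G) under
    acquisition settings: every pixel shares the dye lifetime ``tau_ref``.
    """
    decays = simulate_pixels(
        tau_ref, image_size * image_size, photons_per_pixel, background_per_pixel, irf, axis, seed
    )
    counts = decays.reshape(image_size, image_size, axis.n_bins)
    return DecayStack(counts=counts, axis=axis, channel_label="reference_dye")


def focus_profile_endpoints(
    phantom: ChromatinPhantom, length: float = 20.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Horizontal line through a compact focus, kept inside its nucleus.

    Picks the focus nearest its nucleus center and clips the endpoints so the
    whole profile crosses chromatin (never background) — the synthetic
    analogue of drawing a line through a bright heterochromatin focus.
    """
    if not phantom.focus_centers:
        raise ValueError("phantom has no compact foci")
    best, best_center, best_d = None, None, np.inf
    for fc in phantom.focus_centers:
        for c in phantom.nucleus_centers:
            d = np.hypot(fc[0] - c[0], fc[1] - c[1])
            if d < best_d:
                best, best_center, best_d = fc, c, d
    r, c = best
    cr, cc = best_center
    # estimate the nucleus radius from the chromatin footprint per nucleus
    radius = np.sqrt((phantom.state_map > 0).sum() / (np.pi * len(phantom.nucleus_centers)))
    dy = r - cr
    across = np.sqrt(max((radius - 2.0) ** 2 - dy**2, 1.0))
    half = length / 2.0
    left = min(half, across + (c - cc))
    right = min(half, across - (c - cc))
    return ((r, c - left), (r, c + right))


def simulate_if_image(
    phantom: ChromatinPhantom,
    peak_intensity: float = 1000.0,
    euchromatin_level: float = 0.25,
    blur_sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Immunofluorescence co-stain channel (heterochromatin-mark-like).

    The stain is bright at compact foci and dim over open chromatin, matching
    an H3K9me3-style heterochromatin mark; optical blur is a small Gaussian
    and counting noise is Poisson.  Returned on the phantom's grid as floats.
    """
    expected = np.zeros_like(phantom.tau_map)
    expected[phantom.state_map == EUCHROMATIN] = euchromatin_level * peak_intensity
    expected[phantom.state_map == HETEROCHROMATIN] = peak_intensity
    expected = gaussian_filter(expected, sigma=blur_sigma)
    rng = np.random.default_rng([seed, 3])
    return rng.poisson(expected).astype(np.float64)
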