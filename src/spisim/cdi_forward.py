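"""Far-field diffraction of a voxelized particle with photon-counting noise.

The expected photon count in a detector pixel is

    I(q) = Phi * r_e^2 * dOmega * P * |F(q)|^2

with Phi the fluence (photons/area, top-hat focus), r_e the classical
electron radius, dOmega the pixel solid angle (oblique-incidence
cos^3(2theta) correction), P the polarization factor (~1 at water-window
angles) and F the Fourier transform of the electron density sampled at the
pixel's scattering vector.  By default the Ewald sphere is flattened
(small-angle mode): F is the 2D FFT of the beam-axis projection of the
density, which is accurate for 2theta up to a few tenths of a radian.  An
optional curved mode samples the 3D FFT on the Ewald sphere.  Measured
counts are Poisson draws from the expected plane, which is always kept for
statistics and tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._elements import R_E_NM
from .synthetic_structures import VoxelDensity
from .xray_optics import FELPulse, peak_fluence

__all__ = [
    "DetectorGeometry",
    "DiffractionPattern",
    "q_map",
    "edge_resolution",
    "diffract",
    "radial_average",
    "RESOLUTION_CONVENTION",
]

logger = logging.getLogger(__name__)

RESOLUTION_CONVENTION = (
    "full-period resolution d = lambda / (2 sin theta) at the detector "
    "half-width (edge mid-point)"
)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat pixel-array detector normal to the beam.

    ``beam_center`` is in 0-based fractional pixel coordinates and defaults
    to (n_x / 2, n_y / 2).
    """

    n_x: int = 1024
    n_y: int = 1024
    pixel_size_um: float = 75.0
    distance_cm: float = 15.0
    beam_center: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y) < 1 or self.pixel_size_um <= 0 or self.distance_cm <= 0:
            raise ValueError("detector parameters must be positive")
        center = self.beam_center
        if center is None:
            center = (self.n_x / 2.0, self.n_y / 2.0)
        if not (0 <= center[0] <= self.n_x and 0 <= center[1] <= self.n_y):
            raise ValueError("beam center outside the array")
        object.__setattr__(self, "beam_center", tuple(float(c) for c in center))

    @property
    def pixel_size_nm(self) -> float:
        return self.pixel_size_um * 1e3

    @property
    def distance_nm(self) -> float:
        return self.distance_cm * 1e7

    def pixel_offsets_nm(self) -> tuple:
        """In-plane (x, y) offsets of pixel centers from the beam axis."""
        x = (np.arange(self.n_x) - self.beam_center[0]) * self.pixel_size_nm
        y = (np.arange(self.n_y) - self.beam_center[1]) * self.pixel_size_nm
        return np.meshgrid(x, y, indexing="ij")

    def two_theta(self) -> np.ndarray:
        x, y = self.pixel_offsets_nm()
        return np.arctan2(np.hypot(x, y), self.distance_nm)

    def solid_angles(self) -> np.ndarray:
        """Per-pixel solid angle with the cos^3 oblique-incidence factor."""
        return (
            self.pixel_size_nm**2 / self.distance_nm**2 * np.cos(self.two_theta()) ** 3
        )


@dataclass
class DiffractionPattern:
    """Expected and sampled photon counts plus geometry bookkeeping."""

    expected: np.ndarray
    counts: np.ndarray
    q_map: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.expected < 0):
            raise ValueError("expected counts must be >= 0")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")


def q_map(detector: DetectorGeometry, wavelength_nm: float) -> np.ndarray:
    """Per-pixel scattering-vector magnitude q = (4 pi / lambda) sin(theta), 1/nm."""
    return 4.0 * math.pi / wavelength_nm * np.sin(detector.two_theta() / 2.0)


def edge_resolution(detector: DetectorGeometry, wavelength_nm: float) -> float:
    """Full-period resolution d = lambda / (2 sin theta) at the edge mid-point."""
    half_width = min(detector.n_x, detector.n_y) / 2.0 * detector.pixel_size_nm
    theta = math.atan2(half_width, detector.distance_nm) / 2.0
    return wavelength_nm / (2.0 * math.sin(theta))


def diffract(
    density: VoxelDensity,
    pulse: FELPulse,
    detector: DetectorGeometry,
    seed: int = 0,
    mode: str = "flat",
    polarization: float = 1.0,
    noise: bool = True,
    fft_size: int | None = None,
) -> DiffractionPattern:
    """Simulate the expected and Poisson-sampled diffraction pattern.

    The voxel grid must oversample the particle: the occupied bounding box
    must fit in half the grid per axis (pad with zeros before calling).
    """
    grid = density.grid
    occupied = np.nonzero(grid > 0)
    if len(occupied[0]) == 0:
        raise ValueError("empty density grid")
    for ax in range(3):
        extent = occupied[ax].max() - occupied[ax].min() + 1
        if 2 * extent > grid.shape[ax]:
            raise ValueError(
                f"particle extent {extent} voxels on axis {ax} needs a padded box of "
                f">= {2 * extent} voxels (grid has {grid.shape[ax]})"
            )

    lam = pulse.wavelength_nm
    fluence_nm2 = peak_fluence(pulse) * 1e-14  # photons / nm^2
    qmap = q_map(detector, lam)
    xs, ys = detector.pixel_offsets_nm()
    r_pix = np.sqrt(xs**2 + ys**2 + detector.distance_nm**2)

    # the particle is re-centered before the FFT so that the complex
    # amplitude carries no fast phase ramp and interpolates accurately
    com = [int(round(np.average(occ, weights=grid[occupied]))) for occ in occupied]

    if mode == "flat":
        projection = grid.sum(axis=2)
        n0, n1 = projection.shape
        # zero-pad so the FFT q grid is fine enough to resolve the speckle
        # oscillations (period ~ 2 pi / particle size) before interpolation
        if fft_size is None:
            fft_size = 1 << (4 * max(n0, n1) - 1).bit_length()
            fft_size = min(max(fft_size, 512), 4096)
        if fft_size < max(n0, n1):
            raise ValueError("fft_size smaller than the density grid")
        embedded = np.zeros((fft_size, fft_size))
        off0 = min(max(fft_size // 2 - com[0], 0), fft_size - n0)
        off1 = min(max(fft_size // 2 - com[1], 0), fft_size - n1)
        embedded[off0 : off0 + n0, off1 : off1 + n1] = projection
        f2d = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(embedded)))
        dq = 2.0 * math.pi / (fft_size * density.voxel_size)
        q_axis = (np.arange(fft_size) - fft_size // 2) * dq
        # interpolate the complex amplitude, not |F|^2: F is smooth through
        # its zero rings, so bilinear interpolation does not fill the minima
        interp = RegularGridInterpolator(
            (q_axis, q_axis), f2d, bounds_error=False, fill_value=0.0
        )
        # sample the qz = 0 plane at the exact scattering magnitude
        # |q| = (4 pi / lambda) sin(theta); only the O(theta^2) direction
        # error of the flattened Ewald sphere remains
        rho = np.hypot(xs, ys)
        with np.errstate(invalid="ignore"):
            dir_x = np.where(rho > 0, xs / np.maximum(rho, 1e-300), 0.0)
            dir_y = np.where(rho > 0, ys / np.maximum(rho, 1e-300), 0.0)
        qx = qmap * dir_x
        qy = qmap * dir_y
        f_sq = np.abs(interp(np.stack([qx, qy], axis=-1))) ** 2
    elif mode == "curved":
        n0, n1, n2 = grid.shape
        # cyclic shift to the origin removes the phase ramp; |F| is unchanged
        centered = np.roll(grid, [-c for c in com], axis=(0, 1, 2))
        f3d = np.fft.fftshift(np.fft.fftn(centered))
        axes = [
            (np.arange(n) - n // 2) * 2.0 * math.pi / (n * density.voxel_size)
            for n in (n0, n1, n2)
        ]
        interp = RegularGridInterpolator(
            tuple(axes), f3d, bounds_error=False, fill_value=0.0
        )
        k = 2.0 * math.pi / lam
        qx = k * xs / r_pix
        qy = k * ys / r_pix
        qz = k * (detector.distance_nm / r_pix - 1.0)
        f_sq = np.abs(interp(np.stack([qx, qy, qz], axis=-1))) ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")

    expected = fluence_nm2 * R_E_NM**2 * detector.solid_angles() * polarization * f_sq
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected) if noise else np.rint(expected).astype(np.int64)
    metadata = {
        "wavelength_nm": lam,
        "photons_per_pulse": pulse.photons_per_pulse,
        "focus_diameter_nm": pulse.focus_diameter_nm,
        "detector": (detector.n_x, detector.n_y, detector.pixel_size_um, detector.distance_cm),
        "mode": mode,
        "seed": seed,
        "edge_resolution_nm": edge_resolution(detector, lam),
        "resolution_convention": RESOLUTION_CONVENTION,
    }
    return DiffractionPattern(
        expected, counts.astype(np.int64), qmap, np.ones_like(counts, dtype=bool), metadata
    )


def radial_average(values: np.ndarray, qmap: np.ndarray, n_bins: int = 200):
    """Mean of ``values`` in equal-width q bins; returns (q_centers, means)."""
    q = qmap.ravel()
    v = values.ravel()
    edges = np.linspace(0.0, q.max() * (1 + 1e-12), n_bins + 1)
    idx = np.digitize(q, edges) - 1
    sums = np.bincount(idx, weights=v, minlength=n_bins)[:n_bins]
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return centers, means
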