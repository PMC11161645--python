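"""Scalar Fourier-optics forward model.

A phase element placed in the back focal plane (BFP) of an infinity-corrected
objective modulates the wavefront shift-invariantly, so the camera image of a
point emitter is

    PSF(x, y; M, Θ) = | FT{ A(ρ) · exp(i [M(ρ) + φ_z(ρ; z0) + φ_xy(ρ; x0, y0)]) } |²

where ``A`` is the (uniform-amplitude) pupil aperture, ``M`` the designed
phase mask, ``φ_z`` the defocus phase of an emitter at axial position ``z0``
and ``φ_xy`` the linear tilt encoding the lateral position ``(x0, y0)``.
All lateral quantities live in sample-plane micrometres (camera lengths
divided by the magnification); ``z`` is positive toward the objective.

PSFs are stored unit-normalized: the full (padded) transform plane sums to 1
at every axial position (Parseval), so photon scaling is applied downstream
by the noise model and the renderer, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalConfig",
    "PupilGrid",
    "PhaseMask",
    "EmitterState",
    "PSFStack",
    "make_pupil_grid",
    "defocus_phase",
    "shift_phase",
    "psf_at",
    "psf_stack",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Physical and numerical parameters of the imaging system.

    Defaults describe a 10x / NA 0.3 high-throughput objective imaging the
    green emission channel (504-544 nm band, centre 0.524 um).

    Parameters
    ----------
    na : numerical aperture (dimensionless), 0 < na < medium_index.
    wavelength : emission wavelength, um.
    magnification : lateral magnification.
    pupil_diameter : BFP aperture diameter, mm (used by multizone designs).
    medium_index : refractive index of object space.
    grid_n : pupil grid side length in pixels (even, >= 32).
    pad_factor : zero-padding multiplier applied before the FFT.
    pixel_pitch_sample : optional user-supplied sample-plane pixel pitch, um.
        The simulation itself samples the image plane at the FFT-determined
        pitch lambda / (2 * na * pad_factor); a supplied value that disagrees
        by more than 5% triggers a warning (see :meth:`pixel_pitch`).
    """

    na: float = 0.3
    wavelength: float = 0.524
    magnification: float = 10.0
    pupil_diameter: float = 12.0
    medium_index: float = 1.0
    grid_n: int = 128
    pad_factor: int = 2
    pixel_pitch_sample: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.na < self.medium_index):
            raise ValueError(
                f"need 0 < na < medium_index, got na={self.na}, "
                f"medium_index={self.medium_index}"
            )
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.grid_n < 32 or self.grid_n % 2 != 0:
            raise ValueError(f"grid_n must be even and >= 32, got {self.grid_n}")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    @property
    def fft_pixel_pitch(self) -> float:
        """Image-plane sampling pitch implied by the Fourier relation, um.

        The pupil radius spans the spatial-frequency band na/lambda over
        grid_n/2 samples; an FFT over grid_n*pad_factor points therefore
        samples the image plane at lambda / (2 * na * pad_factor).
        """
        return self.wavelength / (2.0 * self.na * self.pad_factor)

    @property
    def pixel_pitch(self) -> float:
        """Effective sample-plane pixel pitch (um), with consistency check."""
        fft_pitch = self.fft_pixel_pitch
        if self.pixel_pitch_sample is not None:
            rel = abs(self.pixel_pitch_sample - fft_pitch) / fft_pitch
            if rel > 0.05:
                warnings.warn(
                    f"supplied pixel_pitch_sample={self.pixel_pitch_sample:.4g} um "
                    f"differs from the FFT sampling pitch {fft_pitch:.4g} um by "
                    f"{100 * rel:.1f}%; the simulation uses the FFT pitch",
                    stacklevel=2,
                )
        return fft_pitch

    @property
    def pad_n(self) -> int:
        return self.grid_n * self.pad_factor


@dataclass(frozen=True)
class PupilGrid:
    """Discretized BFP: normalized radius, binary aperture, frequency axes.

    ``rho`` is the radial pupil coordinate with the aperture rim at rho = 1;
    ``kx``/``ky`` are transverse spatial frequencies in 1/um, reaching
    na/wavelength at the rim.
    """

    rho: np.ndarray
    aperture: np.ndarray
    kx: np.ndarray
    ky: np.ndarray


@dataclass
class PhaseMask:
    """Pupil-plane phase design variable M, radians, on the pupil grid.

    Stored wrapped to [0, 2pi); wrapping is a no-op inside the complex
    exponential of the forward model.
    """

    phase: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2 or self.phase.shape[0] != self.phase.shape[1]:
            raise ValueError("phase must be a square 2D array")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase values must be finite")
        self.phase = np.mod(self.phase, TWO_PI)

    @classmethod
    def zero(cls, config: OpticalConfig, label: str = "clear aperture") -> "PhaseMask":
        return cls(np.zeros((config.grid_n, config.grid_n)), label=label)


@dataclass(frozen=True)
class EmitterState:
    """Emitter parameters Theta = (x0, y0, z0) plus photometry.

    Positions in sample-plane um (z relative to the nominal focal plane);
    ``photons`` is the expected signal count per frame and ``background``
    the expected background photons per pixel.
    """

    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    photons: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be >= 0")


@dataclass
class PSFStack:
    """Unit-normalized PSF images across an axial grid (z, y, x order)."""

    values: np.ndarray
    z_grid: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.z_grid = np.asarray(self.z_grid, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D (z, y, x) array")
        if len(self.z_grid) != self.values.shape[0]:
            raise ValueError("z_grid length must match the number of planes")


# ---------------------------------------------------------------------------
# pupil grids and phases
# ---------------------------------------------------------------------------


def make_pupil_grid(config: OpticalConfig) -> PupilGrid:
    """Build the normalized pupil coordinate grids for ``config``.

    The grid is centred on the pixel at index grid_n // 2 so that the
    optical axis coincides with the FFT origin after an ifftshift.
    """
    n = config.grid_n
    coord = (np.arange(n) - n // 2) / (n // 2)
    x, y = np.meshgrid(coord, coord)
    rho = np.hypot(x, y)
    aperture = rho <= 1.0
    k_max = config.na / config.wavelength
    return PupilGrid(rho=rho, aperture=aperture, kx=x * k_max, ky=y * k_max)


def defocus_phase(grid: PupilGrid, config: OpticalConfig, z: float) -> np.ndarray:
    """Defocus phase (radians) of an emitter at axial position ``z`` um.

    Exact scalar form (2pi/lambda) * z * sqrt(n^2 - NA^2 rho^2); odd in z.
    Zero outside the aperture.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    arg = config.medium_index**2 - (config.na * grid.rho) ** 2
    phase = (TWO_PI / config.wavelength) * z * np.sqrt(np.clip(arg, 0.0, None))
    return np.where(grid.aperture, phase, 0.0)


def shift_phase(grid: PupilGrid, x0: float, y0: float) -> np.ndarray:
    """Linear pupil phase translating the PSF by (x0, y0) um in the image."""
    return TWO_PI * (grid.kx * x0 + grid.ky * y0)


# ---------------------------------------------------------------------------
# PSF computation
# ---------------------------------------------------------------------------


def _pad_centered(arr: np.ndarray, pad_n: int) -> np.ndarray:
    """Embed a centred grid_n array in a centred pad_n array (zeros around)."""
    n = arr.shape[0]
    out = np.zeros((pad_n, pad_n), dtype=arr.dtype)
    lo = (pad_n - n) // 2
    out[lo : lo + n, lo : lo + n] = arr
    return out


def _crop_centered(arr: np.ndarray, n: int) -> np.ndarray:
    lo = (arr.shape[0] - n) // 2
    return arr[lo : lo + n, lo : lo + n]


def pupil_field(
    mask: PhaseMask, config: OpticalConfig, theta: EmitterState
) -> np.ndarray:
    """Complex pupil field A * exp(i psi), centred layout, padded."""
    grid = make_pupil_grid(config)
    if mask.phase.shape != grid.rho.shape:
        raise ValueError(
            f"mask grid {mask.phase.shape} does not match config grid_n="
            f"{config.grid_n}"
        )
    psi = (
        mask.phase
        + defocus_phase(grid, config, theta.z0)
        + shift_phase(grid, theta.x0, theta.y0)
    )
    field_c = np.where(grid.aperture, np.exp(1j * psi), 0.0)
    return _pad_centered(field_c, config.pad_n)


def psf_full_plane(
    mask: PhaseMask, config: OpticalConfig, theta: EmitterState
) -> np.ndarray:
    """Unit-sum PSF over the full padded transform plane (centred layout)."""
    pupil = pupil_field(mask, config, theta)
    u = np.fft.fft2(np.fft.ifftshift(pupil))
    energy = config.pad_n**2 * np.count_nonzero(make_pupil_grid(config).aperture)
    return np.fft.fftshift(np.abs(u) ** 2) / energy


def psf_at(mask: PhaseMask, config: OpticalConfig, theta: EmitterState) -> np.ndarray:
    """Unit-normalized PSF image of an emitter, cropped to the FOV.

    The full transform plane sums to exactly 1 (Parseval); the returned
    grid_n x grid_n field-of-view crop can only lose energy at the edges.
    """
    return _crop_centered(psf_full_plane(mask, config, theta), config.grid_n)


def psf_stack(
    mask: PhaseMask, config: OpticalConfig, z_grid: np.ndarray
) -> PSFStack:
    """On-axis PSF images across an axial grid (strictly increasing z)."""
    z_grid = np.asarray(z_grid, dtype=np.float64)
    if z_grid.size == 0:
        raise ValueError("z_grid must be nonempty")
    if z_grid.size > 1 and not np.all(np.diff(z_grid) > 0):
        raise ValueError("z_grid must be strictly increasing")
    planes = [psf_at(mask, config, EmitterState(z0=z)) for z in z_grid]
    return PSFStack(np.stack(planes), z_grid, config.pixel_pitch)
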