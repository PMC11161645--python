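"""Synthetic scenes and forward imaging.

Generates the inputs every evaluation needs without any experimental data:
volumetric bead scenes at a stated density, nuclei on a spheroid-like
spherical shell, and Brownian 3D tracks.  Rendering composes the scalar
forward model of :mod:`psfdesign.pupil_optics` — each emitter contributes
``photons * PSF`` at its sub-pixel position (placed exactly via the pupil
shift phase, the same mechanism the Fisher analysis differentiates), on a
uniform expected background, optionally Poisson-sampled (pure shot noise; no
read noise).  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pupil_optics import (
    EmitterState,
    OpticalConfig,
    PhaseMask,
    _crop_centered,
    psf_full_plane,
)

__all__ = [
    "Scene",
    "TrackSimSettings",
    "Track",
    "random_bead_scene",
    "spheroid_shell_scene",
    "render_snapshot",
    "render_zstack",
    "simulate_brownian_tracks",
    "frame_period",
]


def frame_period(exposure_s: float, delay_s: float) -> float:
    """Temporal resolution of a time-lapse: exposure plus inter-frame delay, s.

    A 400 ms exposure with a 2000 ms delay between images gives the 2.4 s
    frame period of a typical tracking acquisition.
    """
    if exposure_s < 0 or delay_s < 0:
        raise ValueError("exposure and delay must be >= 0")
    return exposure_s + delay_s


@dataclass
class Scene:
    """Emitters (x, y, z um, photons) in a lateral FOV with background."""

    emitters: np.ndarray  # (n, 4): x, y, z, photons
    fov: tuple[float, float]  # lateral extent (x, y), um
    background: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.emitters = np.atleast_2d(np.asarray(self.emitters, dtype=np.float64))
        if self.emitters.size == 0:
            self.emitters = np.empty((0, 4))
        if self.emitters.shape[1] != 4:
            raise ValueError("emitters must be rows of (x, y, z, photons)")
        if np.any(self.emitters[:, 3] < 0):
            raise ValueError("photons must be >= 0")
        half = np.asarray(self.fov) / 2.0
        if self.emitters.size and np.any(np.abs(self.emitters[:, :2]) > half):
            raise ValueError("emitters must lie within the lateral FOV")

    @property
    def n_emitters(self) -> int:
        return self.emitters.shape[0]


@dataclass(frozen=True)
class TrackSimSettings:
    """Brownian track simulation: isotropic diffusion plus localization noise.

    diffusion_coeff in um^2/s, dt the frame interval in s, loc_noise_sigma
    the per-axis localization error in um added independently per frame.
    """

    n_particles: int = 100
    diffusion_coeff: float = 0.05
    dt: float = 2.4
    n_frames: int = 100
    loc_noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles <= 0 or self.n_frames <= 0 or self.dt <= 0:
            raise ValueError("n_particles, n_frames and dt must be positive")
        if self.diffusion_coeff < 0 or self.loc_noise_sigma < 0:
            raise ValueError("diffusion_coeff and loc_noise_sigma must be >= 0")


@dataclass
class Track:
    """Time-indexed 3D trajectory of one particle."""

    times: np.ndarray
    positions: np.ndarray  # (n, 3) um
    id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------


def random_bead_scene(
    density: float,
    volume: tuple[float, float, float],
    photons_mean: float = 5000.0,
    seed: int = 0,
    background: float = 10.0,
) -> Scene:
    """Beads uniformly scattered in a volume at a given density per mm^3.

    The emitter count is Poisson with mean density * volume; positions are
    uniform, lateral coordinates centred on the optical axis, z centred on
    the focal plane.  The default density regime mirrors dense gel-embedded
    bead samples (~22,000 beads per mm^3).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    vx, vy, vz = volume
    mean = density * (vx * vy * vz) * 1e-9  # um^3 -> mm^3
    n = rng.poisson(mean)
    xyz = rng.uniform(-0.5, 0.5, size=(n, 3)) * np.array([vx, vy, vz])
    photons = np.full((n, 1), float(photons_mean))
    return Scene(
        emitters=np.hstack([xyz, photons]) if n else np.empty((0, 4)),
        fov=(vx, vy),
        background=background,
        label=f"beads density={density}/mm^3",
    )


def spheroid_shell_scene(
    radius: float = 100.0,
    n_nuclei: int = 200,
    photons_mean: float = 5000.0,
    seed: int = 0,
    background: float = 10.0,
) -> Scene:
    """Nuclei scattered on a spherical shell — a qualitative spheroid stand-in.

    Emitters sit at uniformly random directions at the given radius (um),
    mimicking outer-shell nuclear staining of a cell spheroid.  Intended for
    demos; no biological realism is claimed.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_nuclei, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    xyz = v * radius
    photons = np.full((n_nuclei, 1), float(photons_mean))
    return Scene(
        emitters=np.hstack([xyz, photons]),
        fov=(2.5 * radius, 2.5 * radius),
        background=background,
        label="spheroid shell",
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_snapshot(
    scene: Scene,
    mask: PhaseMask,
    config: OpticalConfig,
    focal_offset: float = 0.0,
    noise: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Expected (or Poisson-sampled) photon-count image of a scene.

    Each emitter is rendered with the full forward model at axial position
    z - focal_offset; sub-pixel lateral placement goes through the pupil
    shift phase, so positions are exact to machine precision.  The image
    grid is the scene FOV sampled at the config's FFT pixel pitch.
    """
    pitch = config.fft_pixel_pitch
    nx = max(int(round(scene.fov[0] / pitch)), 1)
    ny = max(int(round(scene.fov[1] / pitch)), 1)
    image = np.full((ny, nx), float(scene.background))
    half_fov = config.pad_n // 2  # PSF canvas half-size, pixels
    for x, y, z, photons in scene.emitters:
        # nearest-pixel anchor plus exact sub-pixel remainder via the pupil;
        # the optical axis maps to pixel index n // 2, matching the PSF grids
        col = x / pitch + nx // 2
        row = y / pitch + ny // 2
        ic, ir = int(round(col)), int(round(row))
        dx, dy = (col - ic) * pitch, (row - ir) * pitch
        theta = EmitterState(x0=dx, y0=dy, z0=z - focal_offset)
        psf = psf_full_plane(mask, config, theta)
        # paste the full padded PSF plane centred on the anchor pixel
        r0, c0 = ir - half_fov, ic - half_fov
        rs, cs = max(r0, 0), max(c0, 0)
        re = min(r0 + config.pad_n, ny)
        ce = min(c0 + config.pad_n, nx)
        if rs >= re or cs >= ce:
            continue
        image[rs:re, cs:ce] += photons * psf[rs - r0 : re - r0, cs - c0 : ce - c0]
    if noise:
        rng = np.random.default_rng(seed)
        image = rng.poisson(image).astype(np.float64)
    return image


def render_zstack(
    scene: Scene,
    mask: PhaseMask,
    config: OpticalConfig,
    z_positions: np.ndarray,
    noise: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """One snapshot per focal offset (a simulated z-stack acquisition)."""
    z_positions = np.asarray(z_positions, dtype=np.float64)
    if z_positions.size == 0:
        raise ValueError("z_positions must be nonempty")
    frames = [
        render_snapshot(scene, mask, config, focal_offset=z, noise=noise,
                        seed=seed + i)
        for i, z in enumerate(z_positions)
    ]
    return np.stack(frames)


# ---------------------------------------------------------------------------
# Brownian tracks
# ---------------------------------------------------------------------------


def simulate_brownian_tracks(settings: TrackSimSettings) -> list[Track]:
    """Isotropic Brownian 3D tracks with additive localization noise.

    Per-axis increments are N(0, 2 D dt); each recorded position further
    carries independent N(0, s^2) localization error per axis.
    """
    rng = np.random.default_rng(settings.seed)
    sigma_step = np.sqrt(2.0 * settings.diffusion_coeff * settings.dt)
    times = np.arange(settings.n_frames) * settings.dt
    tracks = []
    for pid in range(settings.n_particles):
        steps = rng.normal(0.0, sigma_step, size=(settings.n_frames - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(0.0, settings.loc_noise_sigma, size=pos.shape)
        tracks.append(Track(times=times.copy(), positions=pos, id=pid))
    return tracks
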