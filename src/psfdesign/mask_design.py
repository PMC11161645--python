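"""Phase-mask designers and fabrication conversions.

Three design routes produce pupil-plane elements:

* :func:`optimize_tetrapod` — per-pixel gradient descent on the summed-CRLB
  axial-range cost of :func:`psfdesign.fisher_crlb.design_cost`.  The
  resulting "Tetrapod" PSF trades a compact in-focus spot for lobes whose
  geometry encodes emitter depth, making 3D localization precise across the
  whole design range.  The phase is optimized pixel by pixel rather than in
  a Zernike subspace, which admits the full variety of solutions.
* :func:`optimize_edof` — phase retrieval toward an extended-depth-of-field
  PSF: minimize the mean square difference between the PSF and a fixed
  narrow 2D Gaussian target at equal axial intervals across the design
  range, keeping photons in a tight single spot throughout.
* :func:`multizone_diameters` / :func:`multizone_psf` — an incoherence-based
  EDOF element built from stacked glass layers.  Each layer adds an optical
  path difference far beyond the fluorescence coherence length, so the
  annular pupil zones between layer edges do not interfere: the PSF is the
  incoherent (area-weighted) sum of the per-zone PSFs.  Zone diameters are
  chosen so every zone spans an equal defocus-phase range ("same DOF").

:func:`phase_to_depth` converts a designed phase profile to an etch depth
map for photolithographic fabrication in a substrate such as quartz.

Both gradient-based designers share one analytic adjoint through the
|FT{A e^{i phi}}|^2 chain, so a 128x128-padded design iteration costs a
handful of FFTs per axial sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fisher_crlb import SINGULARITY_CONDITION, NoiseModel
from .pupil_optics import (
    TWO_PI,
    OpticalConfig,
    PhaseMask,
    PSFStack,
    _crop_centered,
    _pad_centered,
    defocus_phase,
    make_pupil_grid,
)

__all__ = [
    "OptimizeSettings",
    "MultizoneDesign",
    "DepthMap",
    "optimize_tetrapod",
    "optimize_edof",
    "multizone_diameters",
    "multizone_psf",
    "path_difference",
    "coherence_length",
    "phase_to_depth",
    "depth_to_phase",
]


@dataclass(frozen=True)
class OptimizeSettings:
    """Knobs of the gradient-descent mask designers.

    step_size is the per-iteration phase step in radians applied along the
    max-normalized gradient; z_range is the axial design span in um sampled
    at n_z midpoints; init is one of {"zeros", "random-small"} or a supplied
    :class:`PhaseMask`.  Small random initial phases (seeded) break the
    focal symmetry that makes the zero mask a stationary point.
    """

    iterations: int = 300
    step_size: float = 0.05
    seed: int = 0
    z_range: tuple[float, float] = (-20.0, 20.0)
    n_z: int = 20
    init: str | PhaseMask = "random-small"
    record_every: int = 10

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.n_z < 2:
            raise ValueError("n_z must be >= 2")
        if not self.z_range[0] < self.z_range[1]:
            raise ValueError("z_range must satisfy zmin < zmax")


@dataclass(frozen=True)
class MultizoneDesign:
    """Stacked-glass incoherent EDOF element geometry.

    n_layers glass layers of thickness layer_thickness (mm) and index
    contrast delta_n to air partition the BFP into n_layers + 1 mutually
    incoherent annular zones; ``diameters`` are the layer diameters in mm.
    """

    aperture_diameter: float
    n_layers: int
    diameters: tuple[float, ...]
    layer_thickness: float = 0.17
    delta_n: float = 0.5

    def __post_init__(self) -> None:
        if self.n_layers != len(self.diameters):
            raise ValueError("need one diameter per layer")
        d = np.asarray(self.diameters)
        if d.size and (np.any(np.diff(d) <= 0) or np.any(d >= self.aperture_diameter)):
            raise ValueError(
                "diameters must be strictly increasing and smaller than the aperture"
            )

    @property
    def n_zones(self) -> int:
        return self.n_layers + 1

    @property
    def diameters_rounded(self) -> tuple[float, ...]:
        """Diameters rounded to 0.1 mm, as quoted for fabrication."""
        return tuple(round(d, 1) for d in self.diameters)

    @property
    def layer_path_difference(self) -> float:
        """Per-layer optical path difference, um."""
        return path_difference(self.layer_thickness, self.delta_n)


@dataclass
class DepthMap:
    """Etch depth profile (nm) realizing a phase mask in a substrate."""

    depth: np.ndarray
    wavelength: float
    material_index: float


# ---------------------------------------------------------------------------
# shared adjoint engine for the gradient designers
# ---------------------------------------------------------------------------


class _DesignEngine:
    """Precomputed FFT-layout grids for per-pixel phase optimization.

    All arrays live in unshifted (FFT) layout on the padded grid; the public
    entry points convert the optimized phase back to the centred pupil grid.
    """

    def __init__(self, config: OpticalConfig, z_grid: np.ndarray):
        self.config = config
        grid = make_pupil_grid(config)
        self.aperture = grid.aperture
        self.ap_f = np.fft.ifftshift(_pad_centered(grid.aperture.astype(float), config.pad_n))
        self.energy = config.pad_n**2 * np.count_nonzero(grid.aperture)
        self.z_grid = np.asarray(z_grid, dtype=np.float64)
        # per-z defocus phase, and the three Theta-derivative grids
        self.defocus_f = [
            np.fft.ifftshift(_pad_centered(defocus_phase(grid, config, z), config.pad_n))
            for z in self.z_grid
        ]
        d_x = np.where(grid.aperture, TWO_PI * grid.kx, 0.0)
        d_y = np.where(grid.aperture, TWO_PI * grid.ky, 0.0)
        arg = config.medium_index**2 - (config.na * grid.rho) ** 2
        d_z = np.where(
            grid.aperture,
            (TWO_PI / config.wavelength) * np.sqrt(np.clip(arg, 0.0, None)),
            0.0,
        )
        self.derivs_f = [
            np.fft.ifftshift(_pad_centered(d, config.pad_n)) for d in (d_x, d_y, d_z)
        ]
        fov = np.zeros((config.pad_n, config.pad_n), dtype=bool)
        lo = (config.pad_n - config.grid_n) // 2
        fov[lo : lo + config.grid_n, lo : lo + config.grid_n] = True
        self.fov_f = np.fft.ifftshift(fov)

    def pad_phase(self, phase: np.ndarray) -> np.ndarray:
        return np.fft.ifftshift(_pad_centered(phase, self.config.pad_n))

    def unpad_grad(self, grad_f: np.ndarray) -> np.ndarray:
        g = _crop_centered(np.fft.fftshift(grad_f), self.config.grid_n)
        return np.where(self.aperture, g, 0.0)

    # -- CRLB (Tetrapod) cost -------------------------------------------------

    def crlb_cost_grad(self, phase: np.ndarray, noise: NoiseModel, cap: float):
        """Summed-CRLB cost over the axial grid and its per-pixel gradient."""
        mf = self.pad_phase(phase)
        n_ph, bg = noise.photons, noise.background
        total_cost = 0.0
        grad_f = np.zeros_like(mf)
        for phi_z in self.defocus_f:
            p = self.ap_f * np.exp(1j * (mf + phi_z))
            u = np.fft.fft2(p)
            cu = np.conj(u)
            psf = (u.real**2 + u.imag**2) / self.energy
            v = [np.fft.fft2(1j * d * p) for d in self.derivs_f]
            g = [2.0 * np.real(cu * vi) / self.energy for vi in v]
            mu = n_ph * psf + bg
            w = np.where(self.fov_f, n_ph**2 / mu, 0.0)
            q = np.array(
                [[np.sum(w * g[i] * g[j]) for j in range(3)] for i in range(3)]
            )
            q = 0.5 * (q + q.T)
            vals, vecs = np.linalg.eigh(q)
            thresh = max(vals.max(), 0.0) / SINGULARITY_CONDITION
            keep = vals > thresh
            inv_part = (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T
            diag = np.diag(inv_part).copy()
            if not np.all(keep):
                # null-space components contribute the constant cap (zero grad)
                null_w = np.sum(vecs[:, ~keep] ** 2, axis=1)
                diag[null_w > 1e-9] = cap
            total_cost += float(np.sum(diag))
            # d(sum diag inv)/dQ = -(inv_part @ inv_part); capped parts constant
            b_mat = -inv_part @ inv_part
            # adjoints on image pixels
            gsum = b_mat[0, 0] * g[0] * g[0]
            for i in range(3):
                for j in range(3):
                    if i == 0 and j == 0:
                        continue
                    gsum = gsum + b_mat[i, j] * g[i] * g[j]
            gpsf = np.where(self.fov_f, -(n_ph**3) / mu**2, 0.0) * gsum
            grad_f += self._backprop(p, u, cu, v, gpsf, b_mat, g, w)
        return total_cost, self.unpad_grad(grad_f)

    # -- EDOF (Gaussian-target) cost -------------------------------------------

    def edof_cost_grad(self, phase: np.ndarray, target_f: np.ndarray):
        """Mean-square PSF-to-Gaussian cost over z and its gradient."""
        mf = self.pad_phase(phase)
        total_cost = 0.0
        grad_f = np.zeros_like(mf)
        for phi_z in self.defocus_f:
            p = self.ap_f * np.exp(1j * (mf + phi_z))
            u = np.fft.fft2(p)
            cu = np.conj(u)
            psf = (u.real**2 + u.imag**2) / self.energy
            resid = np.where(self.fov_f, psf - target_f, 0.0)
            total_cost += float(np.sum(resid**2))
            gpsf = 2.0 * resid
            grad_f += (2.0 / self.energy) * np.real(
                1j * p * np.fft.fft2(gpsf * cu)
            )
        return total_cost, self.unpad_grad(grad_f)

    def _backprop(self, p, u, cu, v, gpsf, b_mat, g, w):
        """Adjoint of (PSF, G_i) -> cost through the |FT|^2 chain."""
        e = self.energy
        grad = (2.0 / e) * np.real(1j * p * np.fft.fft2(gpsf * cu))
        cp = np.conj(p)
        npad2 = self.config.pad_n**2
        for i in range(3):
            gg = 2.0 * w * (b_mat[i, 0] * g[0] + b_mat[i, 1] * g[1] + b_mat[i, 2] * g[2])
            t1 = (2.0 / e) * np.real(-1j * cp * (npad2 * np.fft.ifft2(gg * v[i])))
            t2 = (2.0 / e) * np.real(-self.derivs_f[i] * p * np.fft.fft2(gg * cu))
            grad += t1 + t2
        return grad


def _midpoint_z_grid(z_range: tuple[float, float], n_z: int) -> np.ndarray:
    zmin, zmax = z_range
    step = (zmax - zmin) / n_z
    return zmin + step * (np.arange(n_z) + 0.5)


def _initial_phase(
    config: OpticalConfig, settings: OptimizeSettings
) -> np.ndarray:
    if isinstance(settings.init, PhaseMask):
        if settings.init.phase.shape != (config.grid_n, config.grid_n):
            raise ValueError("supplied init mask does not match config grid_n")
        return settings.init.phase.copy()
    if settings.init == "zeros":
        return np.zeros((config.grid_n, config.grid_n))
    if settings.init == "random-small":
        rng = np.random.default_rng(settings.seed)
        return rng.uniform(-0.1, 0.1, size=(config.grid_n, config.grid_n))
    raise ValueError(f"unknown init {settings.init!r}")


def _descend(cost_grad, phase0, settings: OptimizeSettings, label: str):
    """Max-normalized gradient descent; returns the best-seen mask."""
    phase = phase0.copy()
    best_phase = phase.copy()
    cost, grad = cost_grad(phase)
    if not np.isfinite(cost):
        raise RuntimeError(f"{label}: non-finite initial cost")
    best_cost = cost
    history = [cost]
    for it in range(1, settings.iterations + 1):
        gmax = np.max(np.abs(grad))
        if gmax == 0:
            break
        phase = phase - settings.step_size * grad / gmax
        cost, grad = cost_grad(phase)
        if not np.isfinite(cost):
            raise RuntimeError(
                f"{label}: non-finite cost at iteration {it}; reduce step_size"
            )
        if cost < best_cost:
            best_cost = cost
            best_phase = phase.copy()
        if it % settings.record_every == 0 or it == settings.iterations:
            history.append(cost)
    return best_phase, best_cost, history


def optimize_tetrapod(
    config: OpticalConfig,
    settings: OptimizeSettings | None = None,
    noise: NoiseModel | None = None,
) -> tuple[PhaseMask, list[float]]:
    """Design a Tetrapod-style mask by per-pixel CRLB descent.

    Minimizes the summed (x, y, z) CRLB over the axial design range.
    Deterministic given ``settings.seed``; the returned mask is the best
    iterate seen, so its cost never exceeds the initial cost.
    """
    settings = settings or OptimizeSettings()
    noise = noise or NoiseModel()
    z_grid = _midpoint_z_grid(settings.z_range, settings.n_z)
    engine = _DesignEngine(config, z_grid)
    cap = (settings.z_range[1] - settings.z_range[0]) ** 2
    phase0 = _initial_phase(config, settings)
    best, _, history = _descend(
        lambda ph: engine.crlb_cost_grad(ph, noise, cap),
        phase0,
        settings,
        "tetrapod",
    )
    return PhaseMask(best, label="tetrapod"), history


def gaussian_target(config: OpticalConfig, sigma: float) -> np.ndarray:
    """Unit-sum isotropic Gaussian on the FOV grid (sigma in um)."""
    n = config.grid_n
    pitch = config.fft_pixel_pitch
    coord = (np.arange(n) - n // 2) * pitch
    x, y = np.meshgrid(coord, coord)
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return g / g.sum()


def optimize_edof(
    config: OpticalConfig,
    settings: OptimizeSettings | None = None,
    target_sigma: float | None = None,
) -> tuple[PhaseMask, list[float]]:
    """Design an EDOF mask by phase retrieval toward a fixed Gaussian PSF.

    The cost is the mean square difference between the PSF and a
    non-changing narrow Gaussian target, summed over equal axial intervals
    spanning ``settings.z_range`` (default 60 um total).  The default target
    width is the diffraction-limited sigma ~ 0.21 * lambda / NA; the design
    is robust to the exact choice.
    """
    settings = settings or OptimizeSettings(z_range=(-30.0, 30.0))
    if target_sigma is None:
        target_sigma = 0.21 * config.wavelength / config.na
    if target_sigma <= 0:
        raise ValueError("target_sigma must be > 0")
    z_grid = _midpoint_z_grid(settings.z_range, settings.n_z)
    engine = _DesignEngine(config, z_grid)
    target = gaussian_target(config, target_sigma)
    target_f = np.where(
        engine.fov_f,
        np.fft.ifftshift(_pad_centered(target, config.pad_n)),
        0.0,
    )
    phase0 = _initial_phase(config, settings)
    best, _, history = _descend(
        lambda ph: engine.edof_cost_grad(ph, target_f),
        phase0,
        settings,
        "edof",
    )
    return PhaseMask(best, label="edof"), history


# ---------------------------------------------------------------------------
# incoherence-based multizone EDOF element
# ---------------------------------------------------------------------------


def multizone_diameters(
    aperture_diameter: float,
    n_layers: int,
    layer_thickness: float = 0.17,
    delta_n: float = 0.5,
) -> MultizoneDesign:
    """Equal-DOF partition of the BFP into n_layers + 1 incoherent zones.

    Defocus phase grows as rho^2 to leading order, so zones of equal
    rho^2 increment span equal defocus ranges: layer radii sit at
    r_k = (D/2) * sqrt(k / (n_layers + 1)).  For a 12 mm aperture and three
    layers this gives diameters [6.0, 8.5, 10.4] mm (rounded to 0.1 mm).
    """
    if aperture_diameter <= 0:
        raise ValueError("aperture_diameter must be > 0")
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    n_zones = n_layers + 1
    radii = (aperture_diameter / 2.0) * np.sqrt(np.arange(1, n_layers + 1) / n_zones)
    return MultizoneDesign(
        aperture_diameter=aperture_diameter,
        n_layers=n_layers,
        diameters=tuple(2.0 * radii),
        layer_thickness=layer_thickness,
        delta_n=delta_n,
    )


def multizone_psf(
    design: MultizoneDesign,
    config: OpticalConfig,
    z_grid: np.ndarray,
    crop: bool = True,
) -> PSFStack:
    """Incoherent-sum PSF stack of a multizone element.

    Each annular zone images independently (path differences between zones
    exceed the fluorescence coherence length), so per z the PSF is the sum
    of per-zone intensities; uniform transmission weights each zone by its
    area fraction, and the total stays unit-normalized.  With ``crop=False``
    the full padded transform plane is returned (sums to exactly 1 per z).
    """
    z_grid = np.asarray(z_grid, dtype=np.float64)
    if np.any(np.asarray(design.diameters) > design.aperture_diameter):
        raise ValueError("zone diameter exceeds the aperture")
    grid = make_pupil_grid(config)
    # normalized radii of the zone boundaries; outer boundary is the rim
    bounds = [d / design.aperture_diameter for d in design.diameters] + [1.0]
    lowers = [-1.0] + bounds[:-1]  # first zone includes the rho = 0 pixel
    zones = [
        grid.aperture & (grid.rho > lo) & (grid.rho <= hi)
        for lo, hi in zip(lowers, bounds)
    ]
    energy = config.pad_n**2 * np.count_nonzero(grid.aperture)
    planes = []
    for z in z_grid:
        phi = defocus_phase(grid, config, z)
        total = np.zeros((config.pad_n, config.pad_n))
        for zone in zones:
            p = np.where(zone, np.exp(1j * phi), 0.0)
            u = np.fft.fft2(np.fft.ifftshift(_pad_centered(p, config.pad_n)))
            total += np.abs(u) ** 2
        plane = np.fft.fftshift(total) / energy
        planes.append(_crop_centered(plane, config.grid_n) if crop else plane)
    return PSFStack(np.stack(planes), z_grid, config.pixel_pitch)


def path_difference(layer_thickness: float, delta_n: float) -> float:
    """Optical path difference of one glass layer, um (thickness in mm)."""
    if layer_thickness < 0 or delta_n < 0:
        raise ValueError("inputs must be >= 0")
    return layer_thickness * 1000.0 * delta_n


def coherence_length(center_wavelength: float, bandwidth: float) -> float:
    """Temporal coherence length lambda^2 / delta-lambda, um."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    return center_wavelength**2 / bandwidth


# ---------------------------------------------------------------------------
# fabrication conversion
# ---------------------------------------------------------------------------


def phase_to_depth(
    mask: PhaseMask, wavelength: float, material_index: float
) -> DepthMap:
    """Convert a phase profile to the etch depth map realizing it.

    A relief of depth d in a substrate of index n imparts phase
    2 pi (n - 1) d / lambda, so the wrapped phase maps to
    d = phase * lambda / (2 pi (n - 1)), in [0, lambda / (n - 1)).
    Depths are returned in nm.
    """
    if material_index <= 1.0:
        raise ValueError("material_index must exceed 1")
    depth_um = mask.phase * wavelength / (TWO_PI * (material_index - 1.0))
    return DepthMap(
        depth=depth_um * 1000.0,
        wavelength=wavelength,
        material_index=material_index,
    )


def depth_to_phase(depth_map: DepthMap) -> PhaseMask:
    """Inverse of :func:`phase_to_depth` (recovers the wrapped mask)."""
    phase = (
        (depth_map.depth / 1000.0)
        * TWO_PI
        * (depth_map.material_index - 1.0)
        / depth_map.wavelength
    )
    return PhaseMask(phase, label="from depth map")
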