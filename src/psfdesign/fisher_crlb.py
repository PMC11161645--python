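"""Poisson likelihood, Fisher information, and the CRLB design cost.

Under shot-noise-limited detection, each camera pixel measures

    I(x, y) ~ Poisson( N * PSF(x, y; M, Theta) + B )

with expected signal photons ``N``, a scalar background ``B`` per pixel, and
the unit-normalized PSF of :mod:`psfdesign.pupil_optics`.  The Fisher
information matrix for Theta = (x0, y0, z0) is

    Q_ij = sum_pixels  (N dPSF/dTheta_i)(N dPSF/dTheta_j) / (N PSF + B)

and the Cramer-Rao lower bound on the variance of any unbiased estimator of
Theta_i is the i-th diagonal entry of Q^-1.  The mask-design cost sums the
three CRLB components over an axial grid: a mask with a low cost encodes
emitter depth precisely across the whole design range.

The data-only additive term of the Poisson log-likelihood (a function of the
measurements alone) is dropped throughout: it is constant in Theta and
cancels in every gradient and information quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pupil_optics import (
    EmitterState,
    OpticalConfig,
    PhaseMask,
    _crop_centered,
    defocus_phase,
    make_pupil_grid,
    pupil_field,
    shift_phase,
)

__all__ = [
    "NoiseModel",
    "FisherResult",
    "CRLBProfile",
    "log_likelihood",
    "psf_gradient",
    "fisher_matrix",
    "crlb",
    "design_cost",
]

#: Condition-number threshold above which the Fisher matrix is treated as
#: singular and affected CRLB components are capped.
SINGULARITY_CONDITION = 1e12


@dataclass(frozen=True)
class NoiseModel:
    """Photometry of a frame: expected signal photons and scalar background.

    Defaults are typical single-molecule-scale signal counts: 5000 signal
    photons against 10 background photons per pixel.
    """

    photons: float = 5000.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class FisherResult:
    """3x3 Fisher information and CRLB variances at one axial position.

    ``q`` has units photons/um^2; ``crlb_diag`` holds (x, y, z) variances in
    um^2, with components that sit in the null space of ``q`` set to the cap
    (or inf) and flagged in ``capped``.
    """

    q: np.ndarray
    crlb_diag: np.ndarray
    z: float
    capped: np.ndarray

    @property
    def singular(self) -> bool:
        return bool(np.any(self.capped))

    @property
    def precision(self) -> np.ndarray:
        """Root-CRLB localization precision per axis, um."""
        return np.sqrt(self.crlb_diag)


@dataclass
class CRLBProfile:
    """CRLB variances across an axial grid and the summed design cost."""

    z_grid: np.ndarray
    crlb: np.ndarray  # (n_z, 3) um^2
    cost: float
    saturated: bool

    def to_records(self) -> list[dict]:
        return [
            {
                "z": float(z),
                "crlb_x": float(c[0]),
                "crlb_y": float(c[1]),
                "crlb_z": float(c[2]),
            }
            for z, c in zip(self.z_grid, self.crlb)
        ]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def expected_image(
    mask: PhaseMask, config: OpticalConfig, theta: EmitterState, noise: NoiseModel
) -> np.ndarray:
    """Expected photon counts mu = N * PSF + B on the FOV."""
    from .pupil_optics import psf_at

    return noise.photons * psf_at(mask, config, theta) + noise.background


def log_likelihood(
    image: np.ndarray,
    mask: PhaseMask,
    config: OpticalConfig,
    theta: EmitterState,
    noise: NoiseModel,
) -> float:
    """Poisson log-likelihood L(Theta) = sum I*log(mu) - mu (data term dropped)."""
    image = np.asarray(image, dtype=np.float64)
    mu = expected_image(mask, config, theta, noise)
    if image.shape != mu.shape:
        raise ValueError(f"image shape {image.shape} does not match FOV {mu.shape}")
    # PSF nulls make mu underflow toward 0 at zero background; log(mu) is
    # then meaningless, so treat anything below a photon-scale floor as the
    # zero-background degenerate case
    if np.any(mu < 1e-6):
        raise ValueError(
            "expected image has (near-)zero pixels: zero background with "
            "zero-PSF pixels; use a positive background"
        )
    return float(np.sum(image * np.log(mu) - mu))


# ---------------------------------------------------------------------------
# analytic PSF gradients
# ---------------------------------------------------------------------------


def _forward_fields(mask: PhaseMask, config: OpticalConfig, theta: EmitterState):
    """Image field U and phase-derivative grids, FFT (unshifted) layout."""
    grid = make_pupil_grid(config)
    pupil = np.fft.ifftshift(pupil_field(mask, config, theta))
    u = np.fft.fft2(pupil)
    energy = config.pad_n**2 * np.count_nonzero(grid.aperture)

    # d(psi)/dTheta_i on the pupil, padded to the FFT layout
    from .pupil_optics import _pad_centered, TWO_PI

    d_x = np.where(grid.aperture, TWO_PI * grid.kx, 0.0)
    d_y = np.where(grid.aperture, TWO_PI * grid.ky, 0.0)
    arg = config.medium_index**2 - (config.na * grid.rho) ** 2
    d_z = np.where(
        grid.aperture,
        (TWO_PI / config.wavelength) * np.sqrt(np.clip(arg, 0.0, None)),
        0.0,
    )
    derivs = [
        np.fft.ifftshift(_pad_centered(d, config.pad_n)) for d in (d_x, d_y, d_z)
    ]
    return pupil, u, energy, derivs


def psf_gradient(
    mask: PhaseMask, config: OpticalConfig, theta: EmitterState, crop: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (dPSF/dx0, dPSF/dy0, dPSF/dz0) on the FOV, plus the PSF.

    Each derivative follows from the chain rule through the coherent image
    field: with U = FT{A e^{i psi}} and V_i = FT{i (dpsi/dTheta_i) A e^{i psi}},

        dPSF/dTheta_i = 2 Re(conj(U) V_i) / E.

    Returns ``(grads, psf)`` with ``grads`` shaped (3, grid_n, grid_n), or
    the full padded planes with ``crop=False`` — there every gradient plane
    sums to ~0, since the normalized PSF's total energy does not depend on
    Theta.
    """
    pupil, u, energy, derivs = _forward_fields(mask, config, theta)
    n = config.grid_n
    grads = []
    for d in derivs:
        v = np.fft.fft2(1j * d * pupil)
        g_full = np.fft.fftshift(2.0 * np.real(np.conj(u) * v) / energy)
        grads.append(_crop_centered(g_full, n) if crop else g_full)
    psf = np.fft.fftshift(np.abs(u) ** 2) / energy
    if crop:
        psf = _crop_centered(psf, n)
    return np.stack(grads), psf


# ---------------------------------------------------------------------------
# Fisher information and CRLB
# ---------------------------------------------------------------------------


def fisher_from_gradients(
    grads: np.ndarray, psf: np.ndarray, noise: NoiseModel
) -> np.ndarray:
    """Fisher matrix from PSF-derivative planes under the Poisson model.

    Q_ij = sum (N g_i)(N g_j) / (N PSF + B).  Pixels with exactly zero
    expected count (possible only at zero background) carry no information
    and are excluded; there the PSF gradient vanishes as well, so the 0/0
    limit is 0.
    """
    mu = noise.photons * psf + noise.background
    valid = mu > 0
    w = np.zeros_like(mu)
    w[valid] = noise.photons**2 / mu[valid]
    q = np.einsum("iyx,jyx,yx->ij", grads, grads, w)
    return 0.5 * (q + q.T)


def fisher_matrix(
    mask: PhaseMask,
    config: OpticalConfig,
    theta: EmitterState,
    noise: NoiseModel,
) -> FisherResult:
    """Fisher information of (x0, y0, z0) from the Poisson pixel model."""
    grads, psf = psf_gradient(mask, config, theta)
    q = fisher_from_gradients(grads, psf, noise)
    diag, capped = _invert_diag(q, cap=np.inf)
    return FisherResult(q=q, crlb_diag=diag, z=theta.z0, capped=capped)


def _invert_diag(q: np.ndarray, cap: float) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal of Q^-1 with a null-space policy.

    Eigen-components below max(eigval)/SINGULARITY_CONDITION are treated as
    uninformative; parameters with weight in that null space get the cap
    value (interpreted as "no better than the prior range") and a flag.
    """
    vals, vecs = np.linalg.eigh(q)
    vmax = float(np.max(vals)) if np.max(vals) > 0 else 0.0
    thresh = vmax / SINGULARITY_CONDITION
    informative = vals > thresh
    diag = np.zeros(q.shape[0])
    capped = np.zeros(q.shape[0], dtype=bool)
    if np.any(informative):
        inv_part = (vecs[:, informative] / vals[informative]) @ vecs[:, informative].T
        diag = np.diag(inv_part).copy()
    if not np.all(informative):
        null_weight = np.sum(vecs[:, ~informative] ** 2, axis=1)
        capped = null_weight > 1e-9
        diag[capped] = cap
    return diag, capped


def crlb(fisher: FisherResult, cap: float = np.inf) -> np.ndarray:
    """CRLB variances (um^2) for (x0, y0, z0) from a Fisher result.

    Singular directions of Q are returned as ``cap`` (default inf) and
    flagged on the result.
    """
    diag, capped = _invert_diag(fisher.q, cap=cap)
    fisher.crlb_diag = diag
    fisher.capped = capped
    return diag


def design_cost(
    mask: PhaseMask,
    config: OpticalConfig,
    z_range: tuple[float, float],
    n_samples: int = 100,
    noise: NoiseModel | None = None,
) -> CRLBProfile:
    """Axial-range design cost: sum of all three CRLB components over z.

    The axial range is split into ``n_samples`` equal intervals and the CRLB
    evaluated at each interval midpoint (on-axis emitter, x0 = y0 = 0).
    Midpoint placement avoids evaluating exactly at the symmetric focus
    where a clear aperture's Fisher matrix is singular in z; components that
    are singular anyway are capped at (z-range span)^2 and flagged.
    """
    zmin, zmax = z_range
    if not zmin < zmax:
        raise ValueError("z_range must satisfy zmin < zmax")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    noise = noise or NoiseModel()
    span = zmax - zmin
    step = span / n_samples
    z_grid = zmin + step * (np.arange(n_samples) + 0.5)
    cap = span**2
    rows = []
    saturated = False
    for z in z_grid:
        fr = fisher_matrix(mask, config, EmitterState(z0=z), noise)
        diag, capped = _invert_diag(fr.q, cap=cap)
        saturated = saturated or bool(np.any(capped))
        rows.append(diag)
    crlb_arr = np.asarray(rows)
    return CRLBProfile(
        z_grid=z_grid,
        crlb=crlb_arr,
        cost=float(np.sum(crlb_arr)),
        saturated=saturated,
    )
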