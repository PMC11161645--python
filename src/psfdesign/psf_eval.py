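"""Quantitative PSF and tracking evaluation.

Measures what a designed PSF actually buys: Gaussian width versus defocus
and the depth-of-field factor it implies, spot detection plus localization
(least-squares Gaussian and maximum-likelihood against the full forward
model), Richardson-Lucy deconvolution for EDOF post-processing, and
ensemble mean-square-displacement fitting for diffusion estimation from 3D
tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage.feature import peak_local_max

from .fisher_crlb import NoiseModel, log_likelihood
from .image_sim import Track
from .pupil_optics import EmitterState, OpticalConfig, PhaseMask, PSFStack

__all__ = [
    "GaussianFit",
    "WidthCurve",
    "LocalizationRecord",
    "MSDResult",
    "fit_gaussian_width",
    "width_vs_defocus",
    "dof_factor",
    "detect_and_localize",
    "mle_localize",
    "richardson_lucy",
    "ensemble_msd_fit",
]

#: FWHM of an isotropic Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class GaussianFit:
    """Isotropic 2D Gaussian fit of an image patch (pixel units)."""

    x: float
    y: float
    sigma: float
    amplitude: float
    offset: float
    ok: bool

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma


@dataclass
class WidthCurve:
    """Fitted PSF width (um) as a function of defocus."""

    z: np.ndarray
    sigma: np.ndarray
    fit_ok: np.ndarray


@dataclass
class LocalizationRecord:
    """One detected emitter: position (um), width, photometry."""

    x: float
    y: float
    sigma: float
    photons: float
    frame: int = 0


@dataclass
class MSDResult:
    """Per-axis ensemble MSD and the (D, s) fit MSD(tau) = 2 D tau + 2 s^2."""

    lag: np.ndarray
    msd_per_axis: np.ndarray  # (n_lags, 3)
    d_est: np.ndarray  # (3,) um^2/s
    s_est: np.ndarray  # (3,) um
    intercept_floored: np.ndarray  # (3,) bool


# ---------------------------------------------------------------------------
# Gaussian width fitting
# ---------------------------------------------------------------------------


def _gauss2d(params, xg, yg):
    x0, y0, sigma, amp, off = params
    return amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * sigma**2)) + off


def fit_gaussian_width(
    patch: np.ndarray,
    center: tuple[float, float] | None = None,
    center_bound: float = 2.0,
) -> GaussianFit:
    """Least-squares isotropic Gaussian fit; never raises on bad data.

    Returns pixel-unit parameters; a flat or non-converging patch comes
    back with ``ok=False``.  FWHM is 2 sqrt(2 ln 2) * sigma (~2.355 sigma).
    When ``center`` (x, y in pixels) is given the fitted centre is
    constrained to within ``center_bound`` pixels of it, which measures the
    width of the central spot rather than locking onto a bright side lobe
    of a structured PSF.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) <= 5:
        raise ValueError("patch must be 2D and larger than 5x5")
    ny, nx = patch.shape
    yg, xg = np.mgrid[0:ny, 0:nx]
    off0 = float(np.percentile(patch, 10))
    amp0 = float(patch.max() - off0)
    if amp0 <= 0 or not np.isfinite(amp0):
        return GaussianFit(0.0, 0.0, 0.0, 0.0, off0, ok=False)
    iy, ix = np.unravel_index(np.argmax(patch), patch.shape)
    if center is not None:
        ix, iy = center
        amp0 = max(
            float(patch[int(round(iy)), int(round(ix))] - off0), amp0 * 1e-3
        )
    # second-moment width seed from above-offset signal
    sig = np.clip(patch - off0, 0.0, None)
    tot = sig.sum()
    if tot <= 0:
        return GaussianFit(0.0, 0.0, 0.0, 0.0, off0, ok=False)
    cx, cy = float((sig * xg).sum() / tot), float((sig * yg).sum() / tot)
    var = float((sig * ((xg - cx) ** 2 + (yg - cy) ** 2)).sum() / tot) / 2.0
    sigma0 = float(np.clip(np.sqrt(max(var, 1e-6)), 0.5, max(nx, ny)))
    p0 = [float(ix), float(iy), sigma0, amp0, off0]
    if center is None:
        lo_xy = [-float(nx), -float(ny)]
        hi_xy = [2.0 * nx, 2.0 * ny]
    else:
        lo_xy = [ix - center_bound, iy - center_bound]
        hi_xy = [ix + center_bound, iy + center_bound]
    try:
        res = optimize.least_squares(
            lambda p: (_gauss2d(p, xg, yg) - patch).ravel(),
            p0,
            bounds=(
                lo_xy + [0.05, 0.0, -np.inf],
                hi_xy + [4.0 * max(nx, ny), np.inf, np.inf],
            ),
            max_nfev=400,
        )
    except Exception:
        return GaussianFit(0.0, 0.0, 0.0, 0.0, off0, ok=False)
    x0, y0, sigma, amp, off = res.x
    ok = bool(
        res.success
        and amp > 0
        and 0 < sigma < 2.0 * max(nx, ny)
        and 0 <= x0 < nx
        and 0 <= y0 < ny
    )
    return GaussianFit(float(x0), float(y0), float(sigma), float(amp), float(off), ok)


def width_vs_defocus(stack: PSFStack) -> WidthCurve:
    """Per-plane Gaussian width of an on-axis PSF stack, in um."""
    sigmas = np.full(len(stack.z_grid), np.nan)
    oks = np.zeros(len(stack.z_grid), dtype=bool)
    ny, nx = stack.values.shape[1:]
    for i, plane in enumerate(stack.values):
        fit = fit_gaussian_width(plane, center=(nx // 2, ny // 2))
        if fit.ok:
            sigmas[i] = fit.sigma * stack.pixel_pitch
            oks[i] = True
    return WidthCurve(z=stack.z_grid.copy(), sigma=sigmas, fit_ok=oks)


def _dof_span(curve: WidthCurve, threshold_ratio: float) -> float:
    """Contiguous z-span around focus where sigma stays acceptably compact.

    The reference width is the fitted sigma at the plane nearest z = 0 (the
    in-focus width), and the span is the contiguous region containing that
    plane with sigma <= threshold_ratio * reference.  Anchoring at focus
    keeps the measure meaningful for structured PSFs whose width curve has
    spurious narrow fits away from focus.
    """
    valid = curve.fit_ok & np.isfinite(curve.sigma)
    if not np.any(valid):
        return 0.0
    sig = np.where(valid, curve.sigma, np.inf)
    ifocus = int(np.argmin(np.abs(curve.z)))
    if not np.isfinite(sig[ifocus]):
        return 0.0
    limit = threshold_ratio * sig[ifocus]
    lo = hi = ifocus
    while lo > 0 and sig[lo - 1] <= limit:
        lo -= 1
    while hi < len(sig) - 1 and sig[hi + 1] <= limit:
        hi += 1
    if hi == lo:
        return 0.0
    return float(curve.z[hi] - curve.z[lo])


def dof_factor(
    curve_a: WidthCurve, curve_b: WidthCurve, threshold_ratio: float = 1.5
) -> float:
    """Ratio of depth-of-field spans DOF(a) / DOF(b).

    DOF is the contiguous axial span around focus where the fitted width
    stays within threshold_ratio of the in-focus width.  Returns inf
    (flagged by value) when curve_b never satisfies the threshold.
    """
    if not np.array_equal(curve_a.z, curve_b.z):
        raise ValueError("curves must share a z grid")
    span_a = _dof_span(curve_a, threshold_ratio)
    span_b = _dof_span(curve_b, threshold_ratio)
    if span_b == 0.0:
        return np.inf if span_a > 0 else np.nan
    return span_a / span_b


# ---------------------------------------------------------------------------
# detection and localization
# ---------------------------------------------------------------------------


def detect_and_localize(
    image: np.ndarray,
    min_separation: int = 5,
    intensity_threshold: float = 0.0,
    patch_half: int = 6,
    frame: int = 0,
    pixel_pitch: float = 1.0,
) -> list[LocalizationRecord]:
    """Local-maxima detection with suppression, then per-spot Gaussian fits.

    Positions are reported in um relative to the image centre (pixel index
    n // 2, the renderer's optical-axis convention); an empty list is a
    valid result.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    peaks = peak_local_max(
        image,
        min_distance=int(min_separation),
        threshold_abs=intensity_threshold,
        exclude_border=False,
    )
    ny, nx = image.shape
    records = []
    for ir, ic in peaks:
        r0, r1 = max(ir - patch_half, 0), min(ir + patch_half + 1, ny)
        c0, c1 = max(ic - patch_half, 0), min(ic + patch_half + 1, nx)
        patch = image[r0:r1, c0:c1]
        if min(patch.shape) <= 5:
            continue
        fit = fit_gaussian_width(patch)
        if not fit.ok:
            continue
        col = c0 + fit.x
        row = r0 + fit.y
        records.append(
            LocalizationRecord(
                x=(col - nx // 2) * pixel_pitch,
                y=(row - ny // 2) * pixel_pitch,
                sigma=fit.sigma * pixel_pitch,
                photons=float(2.0 * np.pi * fit.amplitude * fit.sigma**2),
                frame=frame,
            )
        )
    return records


@dataclass
class MLEResult:
    """Converged maximum-likelihood emitter estimate."""

    theta: EmitterState
    log_likelihood: float
    converged: bool


def mle_localize(
    image: np.ndarray,
    mask: PhaseMask,
    config: OpticalConfig,
    noise: NoiseModel,
    init: EmitterState,
    z_multistart: tuple[float, ...] = (0.0,),
) -> MLEResult:
    """Maximum-likelihood (x0, y0, z0) from a single image.

    Runs a derivative-free simplex on the negative Poisson log-likelihood of
    the full forward model, optionally from several axial starting offsets
    (the Tetrapod likelihood can be multimodal in z), and keeps the best
    converged iterate.  Photometry is taken from ``noise``, not fitted.
    """
    image = np.asarray(image, dtype=np.float64)

    def negloglik(p):
        theta = EmitterState(
            x0=p[0], y0=p[1], z0=p[2],
            photons=noise.photons, background=noise.background,
        )
        return -log_likelihood(image, mask, config, theta, noise)

    best = None
    for dz in z_multistart:
        x0 = [init.x0, init.y0, init.z0 + dz]
        res = optimize.minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = EmitterState(
        x0=float(best.x[0]), y0=float(best.x[1]), z0=float(best.x[2]),
        photons=noise.photons, background=noise.background,
    )
    return MLEResult(
        theta=theta, log_likelihood=-float(best.fun), converged=bool(best.success)
    )


# ---------------------------------------------------------------------------
# Richardson-Lucy deconvolution
# ---------------------------------------------------------------------------


def richardson_lucy(
    image: np.ndarray, psf_kernel: np.ndarray, iterations: int
) -> np.ndarray:
    """Multiplicative Richardson-Lucy deconvolution.

    The image is zero-padded by the kernel extent internally so the
    convolutions never clip, which makes every iterate conserve total flux
    exactly under a unit-sum kernel; ``iterations=0`` returns the input.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(psf_kernel, dtype=np.float64)
    if np.any(image < 0) or np.any(kernel < 0):
        raise ValueError("image and kernel must be nonnegative")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return image.copy()
    ksum = kernel.sum()
    if ksum <= 0:
        raise ValueError("kernel must have positive total")
    kernel = kernel / ksum
    pad = [(s // 2 + 1, s // 2 + 1) for s in kernel.shape]
    padded = np.pad(image, pad)
    # circular convolution on the padded domain: with the kernel centred at
    # the origin every RL iterate conserves total flux exactly
    kpad = np.zeros_like(padded)
    kh, kw = kernel.shape
    kpad[:kh, :kw] = kernel
    kpad = np.roll(kpad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    kf = np.fft.rfft2(kpad)
    # standard initialization with the observed image: the zero-padded
    # border stays exactly zero under the multiplicative update, so the
    # cropped result loses no flux
    est = padded.copy()
    eps = 1e-12
    shape = padded.shape
    for _ in range(iterations):
        conv = np.fft.irfft2(np.fft.rfft2(est) * kf, s=shape)
        ratio = padded / np.clip(conv, eps, None)
        est = est * np.fft.irfft2(np.fft.rfft2(ratio) * np.conj(kf), s=shape)
    return est[pad[0][0] : shape[0] - pad[0][1],
               pad[1][0] : shape[1] - pad[1][1]]


# ---------------------------------------------------------------------------
# MSD / diffusion analysis
# ---------------------------------------------------------------------------


def ensemble_msd_fit(
    tracks: list[Track], max_lag: float | None = None, max_lag_frames: int = 10
) -> MSDResult:
    """Per-axis ensemble MSD and inverse-variance linear fit MSD = 2 D tau + 2 s^2.

    Lags run from one frame up to ``max_lag_frames`` (or the given time
    ``max_lag``).  The line is fitted by generalized least squares using
    the empirical covariance of the per-track MSD curves across tracks
    (overlapping-window MSD values at different lags are strongly
    correlated, so plain per-lag weights misallocate the intercept error);
    with fewer than five tracks a per-lag inverse-variance fit is used
    instead.  The slope gives the per-axis diffusion coefficient D and the
    intercept the localization precision s; a negative intercept is floored
    at s = 0 and flagged.
    """
    if not tracks:
        raise ValueError("need at least one track")
    dt = float(tracks[0].times[1] - tracks[0].times[0])
    shortest = min(len(t.times) for t in tracks)
    n_lags = min(max_lag_frames, shortest - 1)
    if max_lag is not None:
        n_lags = min(n_lags, int(max_lag / dt))
    if n_lags < 2:
        raise ValueError("tracks too short for an MSD fit")
    lags = np.arange(1, n_lags + 1) * dt
    n_tracks = len(tracks)
    per_track = np.zeros((n_tracks, n_lags, 3))
    for i, tr in enumerate(tracks):
        pos = tr.positions
        for j in range(1, n_lags + 1):
            disp = pos[j:] - pos[:-j]
            per_track[i, j - 1] = np.mean(disp**2, axis=0)
    msd = per_track.mean(axis=0)
    design = np.column_stack([lags, np.ones(n_lags)])
    d_est = np.zeros(3)
    s_est = np.zeros(3)
    floored = np.zeros(3, dtype=bool)
    for ax in range(3):
        y = msd[:, ax]
        if n_tracks >= 5:
            cov = np.cov(per_track[:, :, ax].T) / n_tracks
            cov = cov + 1e-12 * max(np.trace(cov), 1e-30) * np.eye(n_lags)
            ci = np.linalg.pinv(cov)
        else:
            ci = np.diag(1.0 / np.clip(y, 1e-30, None) ** 2)
        beta = np.linalg.lstsq(
            design.T @ ci @ design, design.T @ ci @ y, rcond=None
        )[0]
        slope, intercept = beta
        d_est[ax] = max(slope, 0.0) / 2.0
        if intercept < 0:
            floored[ax] = True
            intercept = 0.0
        s_est[ax] = np.sqrt(intercept / 2.0)
    return MSDResult(
        lag=lags, msd_per_axis=msd, d_est=d_est, s_est=s_est,
        intercept_floored=floored,
    )
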