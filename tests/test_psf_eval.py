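"""Evaluation tests: width fitting, DOF, localization, RL, MSD."""

import numpy as np
import pytest

from psfdesign import (
    EmitterState,
    NoiseModel,
    PhaseMask,
    Scene,
    Track,
    TrackSimSettings,
    detect_and_localize,
    dof_factor,
    ensemble_msd_fit,
    fit_gaussian_width,
    mle_localize,
    psf_at,
    psf_stack,
    render_snapshot,
    richardson_lucy,
    simulate_brownian_tracks,
    width_vs_defocus,
)
from psfdesign.psf_eval import FWHM_PER_SIGMA, WidthCurve


def synthetic_gaussian(n, sigma_px, x0=None, y0=None, amp=100.0, offset=5.0):
    x0 = (n - 1) / 2 if x0 is None else x0
    y0 = (n - 1) / 2 if y0 is None else y0
    yg, xg = np.mgrid[0:n, 0:n]
    return amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2 * sigma_px**2)) + offset


class TestGaussianFit:
    @pytest.mark.parametrize("sigma_um", [0.5, 1.39, 3.0, 5.0])
    def test_unbiased_on_noiseless_gaussians(self, sigma_um):
        pitch = 0.437
        patch = synthetic_gaussian(41, sigma_um / pitch)
        fit = fit_gaussian_width(patch)
        assert fit.ok
        assert fit.sigma * pitch == pytest.approx(sigma_um, rel=0.01)

    def test_fwhm_sigma_ratio(self):
        fit = fit_gaussian_width(synthetic_gaussian(31, 3.0))
        assert fit.ok
        assert fit.fwhm / fit.sigma == pytest.approx(2.3548, abs=1e-4)
        assert FWHM_PER_SIGMA == pytest.approx(2.3548, abs=1e-4)

    def test_flat_patch_flagged(self):
        fit = fit_gaussian_width(np.full((15, 15), 7.0))
        assert not fit.ok

    def test_small_patch_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_width(np.zeros((5, 5)))

    def test_center_constraint_ignores_bright_side_lobe(self):
        patch = synthetic_gaussian(41, 2.0) + synthetic_gaussian(
            41, 1.0, x0=35.0, y0=35.0, amp=300.0, offset=0.0
        )
        fit = fit_gaussian_width(patch, center=(20.0, 20.0))
        assert fit.ok
        assert abs(fit.x - 20.0) <= 2.0 and abs(fit.y - 20.0) <= 2.0


class TestWidthCurve:
    def test_clear_aperture_symmetric_and_broadening(self, cfg64, zero_mask64):
        z = np.linspace(-20.0, 20.0, 21)
        curve = width_vs_defocus(psf_stack(zero_mask64, cfg64, z))
        assert curve.fit_ok.all()
        np.testing.assert_allclose(curve.sigma, curve.sigma[::-1], rtol=0.02)
        assert curve.sigma[0] > curve.sigma[10]
        assert curve.sigma[-1] > curve.sigma[10]

    def test_edof_stays_narrower_than_defocused_clear_aperture(
        self, cfg64, zero_mask64, edof64
    ):
        mask, _, settings = edof64
        z = np.linspace(*settings.z_range, 31)
        edof_curve = width_vs_defocus(psf_stack(mask, cfg64, z))
        zero_curve = width_vs_defocus(psf_stack(zero_mask64, cfg64, z))
        assert np.nanmax(edof_curve.sigma) < zero_curve.sigma[0]
        assert np.nanmax(edof_curve.sigma) < zero_curve.sigma[-1]


class TestDofFactor:
    def _curve(self, z, sigma):
        return WidthCurve(
            z=np.asarray(z, float),
            sigma=np.asarray(sigma, float),
            fit_ok=np.ones(len(z), dtype=bool),
        )

    def test_identical_curves_unity(self):
        z = np.linspace(-10, 10, 11)
        c = self._curve(z, 1 + 0.05 * z**2)
        assert dof_factor(c, c) == 1.0

    def test_infinite_threshold_full_range(self):
        z = np.linspace(-10, 10, 11)
        a = self._curve(z, 1 + 0.05 * z**2)
        b = self._curve(z, 1 + 0.2 * z**2)
        assert dof_factor(a, b, threshold_ratio=np.inf) == 1.0

    def test_symmetric_inverse(self):
        z = np.linspace(-10, 10, 21)
        a = self._curve(z, 1 + 0.02 * z**2)
        b = self._curve(z, 1 + 0.2 * z**2)
        f = dof_factor(a, b)
        assert f > 1.0
        assert dof_factor(b, a) == pytest.approx(1.0 / f)

    def test_mismatched_grids_rejected(self):
        a = self._curve([0, 1], [1, 1])
        b = self._curve([0, 2], [1, 1])
        with pytest.raises(ValueError):
            dof_factor(a, b)


class TestDetectAndLocalize:
    def test_blank_image_empty(self):
        assert detect_and_localize(np.zeros((50, 50))) == []

    def test_ten_separated_beads_recovered(self, cfg64, zero_mask64):
        rng = np.random.default_rng(2)
        xs = (np.arange(10) % 5 - 2) * 9.0 + rng.uniform(-1, 1, 10)
        ys = (np.arange(10) // 5 - 0.5) * 18.0 + rng.uniform(-1, 1, 10)
        emitters = np.column_stack(
            [xs, ys, np.zeros(10), np.full(10, 5000.0)]
        )
        scene = Scene(emitters=emitters, fov=(60.0, 60.0), background=1.0)
        image = render_snapshot(scene, zero_mask64, cfg64)
        pitch = cfg64.fft_pixel_pitch
        records = detect_and_localize(
            image, min_separation=5, intensity_threshold=50.0, pixel_pitch=pitch
        )
        assert len(records) == 10
        for x, y in zip(xs, ys):
            err = min(np.hypot(r.x - x, r.y - y) for r in records)
            assert err < 0.25 * pitch

    def test_close_pair_suppressed_to_one(self, cfg64, zero_mask64):
        scene = Scene(
            emitters=[[-0.4, 0.0, 0.0, 3000.0], [0.4, 0.0, 0.0, 3000.0]],
            fov=(30.0, 30.0),
            background=0.5,
        )
        image = render_snapshot(scene, zero_mask64, cfg64)
        records = detect_and_localize(
            image, min_separation=8, intensity_threshold=50.0
        )
        assert len(records) == 1

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            detect_and_localize(np.full((20, 20), -1.0))


class TestMleLocalize:
    def test_noiseless_recovery(self, cfg64, tetrapod64):
        """The likelihood peak of a noise-free image is the true position."""
        mask, _, _ = tetrapod64
        noise = NoiseModel(photons=5000.0, background=10.0)
        truth = EmitterState(x0=0.3, y0=-0.2, z0=5.0, photons=5000.0,
                             background=10.0)
        image = 5000.0 * psf_at(mask, cfg64, truth) + 10.0
        res = mle_localize(
            image, mask, cfg64, noise,
            EmitterState(x0=0.1, y0=0.0, z0=4.0),
        )
        assert abs(res.theta.x0 - 0.3) < 1e-3
        assert abs(res.theta.y0 + 0.2) < 1e-3
        assert abs(res.theta.z0 - 5.0) < 1e-2

    def test_clear_aperture_focus_depth_unidentifiable(self, cfg64, zero_mask64):
        """At focus the clear aperture carries no axial information: the
        CRLB z-component is capped/huge, honoring the instability contract."""
        from psfdesign import crlb, fisher_matrix

        noise = NoiseModel(photons=5000.0, background=10.0)
        fr = fisher_matrix(zero_mask64, cfg64, EmitterState(), noise)
        diag = crlb(fr, cap=1600.0)
        assert diag[2] > 1e4 * diag[0]


class TestRichardsonLucy:
    def test_delta_kernel_identity(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0.5, 2.0, (40, 40))
        delta = np.zeros((21, 21))
        delta[10, 10] = 1.0
        for it in (0, 1, 7):
            np.testing.assert_allclose(
                richardson_lucy(image, delta, it), image, atol=1e-10
            )

    def test_flux_conserved_every_iteration(self, cfg64, zero_mask64):
        kernel = psf_at(zero_mask64, cfg64, EmitterState(z0=8.0))
        kernel /= kernel.sum()
        scene = Scene(emitters=[[0.0, 0.0, 8.0, 5000.0]], fov=(30.0, 30.0),
                      background=0.1)
        blurred = render_snapshot(scene, zero_mask64, cfg64)
        total = blurred.sum()
        for it in (1, 5, 20):
            out = richardson_lucy(blurred, kernel, it)
            assert out.sum() == pytest.approx(total, rel=1e-6)

    def test_deblurring_sharpens_noiseless_bead(self, cfg64, zero_mask64):
        kernel = psf_at(zero_mask64, cfg64, EmitterState(z0=8.0))
        kernel /= kernel.sum()
        scene = Scene(emitters=[[0.0, 0.0, 8.0, 5000.0]], fov=(30.0, 30.0),
                      background=0.1)
        blurred = render_snapshot(scene, zero_mask64, cfg64)
        out = richardson_lucy(blurred, kernel, 50)
        assert out.max() > blurred.max()
        # the half-maximum footprint of the spot shrinks
        def halfmax_area(im):
            return int(np.count_nonzero(im > 0.5 * im.max()))

        assert halfmax_area(out) < halfmax_area(blurred)

    def test_poisson_likelihood_nondecreasing_on_noiseless_data(
        self, cfg64, zero_mask64
    ):
        kernel = psf_at(zero_mask64, cfg64, EmitterState(z0=8.0))
        kernel /= kernel.sum()
        scene = Scene(emitters=[[0.0, 0.0, 8.0, 5000.0]], fov=(30.0, 30.0),
                      background=0.1)
        data = render_snapshot(scene, zero_mask64, cfg64)
        from scipy.signal import fftconvolve

        prev = -np.inf
        for it in (1, 3, 10, 30):
            est = richardson_lucy(data, kernel, it)
            model = np.clip(fftconvolve(est, kernel, mode="same"), 1e-12, None)
            ll = float(np.sum(data * np.log(model) - model))
            assert ll >= prev - 1e-6 * abs(prev)
            prev = ll

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            richardson_lucy(np.full((10, 10), -1.0), np.ones((3, 3)) / 9, 1)


class TestEnsembleMsd:
    def test_parameter_recovery(self):
        """D and s from 100 tracks x 100 frames at the tracking frame rate."""
        settings = TrackSimSettings(
            n_particles=100, diffusion_coeff=0.05, dt=2.4, n_frames=100,
            loc_noise_sigma=0.1, seed=0,
        )
        result = ensemble_msd_fit(simulate_brownian_tracks(settings))
        for ax in range(3):
            assert result.d_est[ax] == pytest.approx(0.05, rel=0.10)
            assert result.s_est[ax] == pytest.approx(0.1, rel=0.25)

    def test_static_tracks_zero_everything(self):
        settings = TrackSimSettings(
            n_particles=5, diffusion_coeff=0.0, dt=1.0, n_frames=30,
            loc_noise_sigma=0.0, seed=2,
        )
        result = ensemble_msd_fit(simulate_brownian_tracks(settings))
        np.testing.assert_array_equal(result.msd_per_axis, 0.0)
        np.testing.assert_array_equal(result.d_est, 0.0)
        np.testing.assert_array_equal(result.s_est, 0.0)

    def test_coordinate_scaling_quadruples_msd(self):
        settings = TrackSimSettings(
            n_particles=10, diffusion_coeff=0.05, dt=1.0, n_frames=50, seed=4
        )
        tracks = simulate_brownian_tracks(settings)
        doubled = [
            Track(times=t.times, positions=2.0 * t.positions, id=t.id)
            for t in tracks
        ]
        r1 = ensemble_msd_fit(tracks)
        r2 = ensemble_msd_fit(doubled)
        np.testing.assert_allclose(r2.msd_per_axis, 4.0 * r1.msd_per_axis,
                                   rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd_fit([])
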