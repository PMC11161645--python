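# Methods

This note records the models, parameter choices and numerical decisions
behind `psfdesign`, and what the synthetic studies do and do not establish.

## Scalar forward model

The imaging model is scalar Fourier optics: the field in the back focal
plane (BFP) is a uniform-amplitude disk (normalized radius ρ ≤ 1) carrying
the designed mask phase, an emitter-dependent defocus phase, and a linear
tilt for lateral position; the camera intensity is the squared magnitude of
its Fourier transform. Assumptions and consequences:

* **Exact scalar defocus.** φ_z = (2π/λ) z √(n² − NA²ρ²) rather than the
  paraxial ρ² form. At NA 0.3 the two differ by well under a percent, but
  the exact form is correct at higher NA and costs nothing.
* **No vectorial effects, no index mismatch, no field dependence.** At
  NA ≤ 0.45 polarization mixing is small; depth-dependent spherical
  aberration from refractive-index mismatch and off-axis aberrations are
  out of scope. PSFs here are shift-invariant by construction.
* **Uniform pupil amplitude.** No apodization; transparent phase-only
  masks preserve all photons.
* **Sampling.** The pupil is a `grid_n × grid_n` disk (default 128, tests
  and design runs use 64), zero-padded by `pad_factor` (default 2) before
  the FFT. The image-plane pitch is then fixed by λ/(2·NA·pad_factor)
  (0.437 µm at NA 0.3, λ 0.524 µm) — exactly Nyquist for the intensity.
  A user-supplied camera pitch that disagrees with this by more than 5%
  triggers a warning; the simulation always uses the FFT pitch.
* **Normalization.** PSFs are stored unit-normalized: the full padded
  transform plane sums to 1 at every z (Parseval), so cropping to the
  field of view can only lose energy, and photon scaling happens solely in
  the noise model and renderer. Phases are stored wrapped to [0, 2π),
  which is a no-op inside the complex exponential.
* **Grid conventions.** The optical axis sits at pixel index `n // 2`
  (the FFT origin after an ifftshift); z is positive toward the objective;
  all lateral quantities are sample-plane micrometres (camera lengths
  divided by the magnification). On an even-sized grid the ±z mirror
  symmetry of an aberration-free PSF holds only up to the half-pixel
  asymmetry of the grid (relative deviations ~10⁻³), which the tests
  allow for.

## Statistics: Poisson likelihood, Fisher information, CRLB

Detection is pure shot noise: I(x,y) ~ Poisson(N·PSF + B) with scalar
background B (no read noise, gain, or EMCCD excess noise). The data-only
term of the log-likelihood is dropped everywhere — it is constant in Θ and
cancels in gradients and information quantities.

PSF derivatives with respect to Θ are analytic: each parameter enters only
through a pupil phase, so ∂PSF/∂Θᵢ = 2 Re(conj(U)·Vᵢ)/E with one extra FFT
per parameter. Finite-difference cross-checks hold to <1% (tests) and the
per-pixel mask-gradient adjoint agrees with finite differences to ~10⁻⁷
relative.

**Singular Fisher policy.** The clear aperture at focus carries no axial
information (Q_zz → 0), so Q is inverted by eigendecomposition with a
condition threshold of 10¹²; parameters with weight in the null space are
reported as a cap value and flagged. Inside the axial-range design cost the
cap is (z-range span)² — "no better than already knowing the prior range".
The design cost samples CRLB at the midpoints of 100 equal intervals
(`n_samples=100` default); midpoint placement also avoids evaluating the
symmetric-focus singularity exactly.

**Design photometry.** Defaults are 5000 expected signal photons against a
background of 10 per pixel — typical single-molecule-scale counts — and are
configurable everywhere; no claim is made that these match any specific
instrument.

## Mask design

* **Tetrapod.** Per-pixel gradient descent on the summed CRLB over the
  axial range, with the full analytic adjoint through Q⁻¹ and the |FT|²
  chain (a handful of FFTs per axial sample per iteration). Steps are
  max-normalized so `step_size` is in radians; the returned mask is the
  best-seen iterate, making the final cost ≤ the initial cost by
  construction, and runs are bitwise-deterministic given the seed.
  Initialization is small seeded random phase: zero phase is a stationary
  point of the symmetric problem. At the reduced study scale (64 × 64
  pupil, ±20 µm, 20 design samples, 300 iterations) the optimized mask
  reaches ≈ 0.34× the clear-aperture cost at the 100-interval evaluation
  and holds the axial CRLB finite (≈ (106 nm)² worst case) across the
  range, while breaking the ±z symmetry (mirror-plane correlation ≈ 0.15).
* **EDOF.** The same descent machinery with the mean-square difference
  from a fixed unit-sum Gaussian target, summed over equal axial intervals
  across the design range (default total 60 µm). The default target width
  is the diffraction-limited σ ≈ 0.21 λ/NA; the design is insensitive to
  the exact value within a factor of ~2. The resulting phase-only masks
  trade a compact in-focus spot for width uniformity: at ±30 µm they hold
  the fitted width within 1.5× the in-focus width over ≈ 3× the
  clear-aperture span. The cost landscape is nearly flat across a family
  of local minima (parallel/sequential Gerchberg–Saxton projections and
  Adam all land at the same cost level as plain descent), so no global
  optimality is claimed.
* **Multizone element.** The equal-DOF rule is implemented as equal ρ²
  increments (defocus phase ∝ ρ² to leading order): layer radii
  r_k = (D/2)√(k/K) for K zones, reproducing the fabricated
  [6.0, 8.5, 10.4] mm set for a 12 mm aperture. Zones are weighted by
  geometric area fraction (uniform transmission); per-zone coherence is
  justified when the per-layer optical path difference (85 µm for a
  0.17 mm coverslip at Δn 0.5) far exceeds the emission coherence length
  λ²/Δλ (≈ 7 µm for the 40 nm green band).
* **Fabrication conversion.** Phase → etch depth as
  d = φ·λ/(2π(n−1)) on the wrapped phase, with the exact inverse as a
  round-trip check; depths are reported in nm for a quartz-like substrate.

## Synthetic data

The generators define the study conditions:

* **Bead scenes** — Poisson-distributed counts at 22,000 beads/mm³
  (dense gel-sample regime), uniform positions, 5000 photons per bead.
* **Spheroid shells** — nuclei at random directions on a sphere; a purely
  qualitative stand-in for outer-shell-stained spheroids, with no claim of
  biological realism.
* **Brownian tracks** — per-axis Gaussian increments of variance 2·D·dt
  plus independent per-frame localization noise; defaults D = 0.05 µm²/s,
  dt = 2.4 s (a 400 ms exposure + 2000 ms delay acquisition), 100 frames,
  s = 0.1 µm.

Rendering places emitters at exact sub-pixel positions through the pupil
tilt — the same mechanism the Fisher analysis differentiates — so
localization tests are free of interpolation bias. What these fixtures do
not exercise: real cameras (gain, read noise, saturation), aberrated or
depth-varying PSFs, photobleaching, and dense-emitter overlap; passing
tests show internal consistency of model + estimator, not instrument-level
accuracy.

## Evaluation choices

* **Width fitting.** Isotropic 2D Gaussian least squares with a
  moment-based seed; FWHM = 2√(2 ln 2)·σ ≈ 2.355σ. For on-axis PSF stacks
  the fit centre is constrained to within 2 pixels of the optical axis —
  structured PSFs (Tetrapod lobes, EDOF halos) otherwise capture the fit
  on a bright side lobe. Fits that fail or leave the patch are flagged,
  not raised.
* **DOF factor.** DOF(curve) is the contiguous axial span containing the
  focal plane over which σ ≤ threshold·σ(focus) (threshold default 1.5),
  and the factor is the ratio of spans. The reference is the in-focus
  width — the classical DOF convention — rather than the global minimum of
  the curve, which for structured EDOF PSFs can be a degenerate
  sub-diffraction Gaussian fit to a narrow needle on a broad pedestal far
  from focus; anchoring at focus keeps the measure monotone and
  symmetric-inverse (DOF(a,b) = 1/DOF(b,a)).
* **MLE.** Nelder–Mead on the negative Poisson log-likelihood of the full
  forward model, with optional multi-start in z (the Tetrapod likelihood
  can be multimodal); photometry is taken as known. Monte Carlo scatter
  matches √CRLB within a few percent at 5000 photons — the bound is tight
  in the shot-noise regime.
* **Richardson–Lucy.** Multiplicative updates with FFT circular
  convolution on a zero-padded copy, initialized with the observed image:
  the padding border stays exactly zero under the update, so every iterate
  conserves total flux to machine precision, and a delta kernel is an
  exact identity. No regularization; iteration count is the only control.
* **MSD fitting.** Ensemble per-axis MSD over lags 1–10 frames, line fit
  MSD = 2Dτ + 2s² by generalized least squares using the empirical
  covariance of per-track MSD curves (overlapping-lag estimates are
  strongly correlated; diagonal weights alone leave the small intercept
  with errors up to ~100% at the 100-track study size). Below 5 tracks the
  fit falls back to diagonal inverse-variance weights. Negative intercepts
  floor s at 0 with a flag. At the default study size D is recovered to a
  few percent and s to within ~25% per axis.

## Known limitations

* The EDOF phase-retrieval optimizer finds local minima of a nearly flat
  cost; different initializations give masks of equivalent cost but
  different fine structure. The reported DOF gains are properties of the
  found minima, not of a global optimum.
* CRLB statements are local (they do not capture the clear aperture's ±z
  sign ambiguity beyond the vanishing of Q_zz at focus).
* All acceptance-scale studies run at a 64 × 64 pupil with a ±20–30 µm
  axial range; fabricated designs for hundreds of micrometres of range are
  a configuration choice (`z_range`, `grid_n`) but are not exercised by
  the test suite.
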