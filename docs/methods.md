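# Methods

## Physical model

The package models a lensless in-line (Gabor) digital holographic
microscope. A monochromatic unit-amplitude plane wave (λ = 525 nm by
default, the green LED band of a typical tabletop setup) illuminates a
thin pure-phase specimen with transmission `t(x, y) = exp(i φ(x, y))`,
`φ ≥ 0`. The transmitted field propagates a distance `z` (default 1 mm,
detector-plane holography) to a sensor with pixel pitch 1.55 µm that
records intensity only:

    I_H = |P_z[exp(iφ)]|²,

where `P_z` is the angular-spectrum propagator — the exact scalar
free-space solution, applied as a diagonal operator in the Fourier
domain with kernel `exp(i·(2π/λ)·z·√(1 − (λf_x)² − (λf_y)²))`.

Assumptions: ideal spatial and temporal coherence (the physical LED +
pinhole source is partially coherent; this is not modelled), thin-object
(multiplicative) specimen, no multiple scattering, square pixels with
100 % fill factor, and unit magnification.

### Numerical conventions

- FFT pair: negative-exponent forward transform, unnormalised; inverse
  carries 1/N (numpy's convention). Stated so tests are bit-reproducible.
- Evanescent band `(λf_x)² + (λf_y)² > 1`: kernel hard-zeroed. Backward
  propagation would otherwise amplify these components exponentially. At
  the default pitch the Nyquist frequency is far inside the propagating
  band, so the simulator loses no energy and the propagator is exactly
  unitary (checked to 1e−6 relative in tests).
- No zero-padding by default; `pad_factor` is available for large-`z`
  work. At z = 1 mm the kernel's spatial support (~110 px) is small
  against the 1024-px default frame and wrap-around is negligible.
- Reconstruction-side propagations multiply out the on-axis carrier
  `exp(i·2πz/λ)`, i.e. phases are referenced to the illuminating plane
  wave. Without this a featureless hologram would reconstruct to the
  meaningless piston `2πz/λ mod 2π` (~1.5 rad at the defaults) instead
  of zero.
- Zero-modulus pixels get phase 0 (no NaNs); a phase-only projection of
  a zero pixel is defined as 1 + 0j.

## The PCOF reconstruction

Single pass, three FFT-pair propagations, no iteration:

1. **Back-propagate** the preprocessed hologram (linear rescale to unit
   mean — nothing nonlinear, so phase structure cannot be distorted) and
   take the four-quadrant phase `φ_o ∈ (−π, π]`.
2. **Segment the support.** Per-pixel statistic over a sliding m×m window
   (m = 5): `V = mean[(φ_o² − μ)²]` with `μ = mean(φ_o)`. Note the first
   term is the *squared* phase; this makes V large wherever phase is
   large **or** locally varying, so it acts as a support detector rather
   than a pure edge detector. The textbook local variance
   (`variance_mode="standard"`) is available but responds only to edges.
   The mask keeps pixels with `V > τ`, `τ` = 50 % of max(V) by default
   (`threshold_mode="variance-max"`); `"phase-max"` takes τ from the
   phase maximum instead. Ties (`V = τ`) are excluded. The masked phase
   is smoothed with a normalised Gaussian blur (σ = 1 px, reflective
   boundary, sum-preserving).
3. **Phase-only constraint.** `exp(i·φ_masked)` — unit modulus
   everywhere — is propagated forward to the detector.
4. **Re-synthesis.** The recorded hologram is divided by the squared
   reference modulus (DC suppression; `U_r ≡ 1` for simulations, or a
   Gaussian low-pass of √I with σ = 20 px floored at 1e−6 of its maximum
   for experimental frames), given the phase of the forward-propagated
   field, and back-propagated. The result's phase, unwrapped, is the
   output. The recombination uses the hologram *intensity* as the field
   modulus, as the method prescribes; since I ≈ 1 + fringes this differs
   from the physical amplitude √I only at second order in the fringe
   contrast, but the difference is measurable for strong scatterers (see
   Limitations).

Phase unwrapping is reliability-sorted 2D unwrapping
(scikit-image); the only contract the pipeline relies on — and the one
tests assert — is `output − input ∈ 2πZ` pixelwise, which any correct
unwrapper satisfies.

## Baselines

- **ASM**: a single back-propagation of the hologram intensity. The
  out-of-focus conjugate (twin) term, defocused by 2z, remains as
  ringing around every object.
- **ItPR**: Gerchberg–Saxton-type alternating projections, 30 iterations
  by default. Detector plane: amplitude replaced by √I. Object plane:
  unit amplitude, non-negative phase. The positivity clamp is applied to
  the *unwrapped* object phase: clamping the wrapped phase would destroy
  any object whose true phase crosses π (the 2π-peak beads do). The
  per-iteration detector-amplitude RMS residual is recorded; it is
  non-increasing on noise-free phantoms (alternating-projection
  monotonicity), and non-convergence is reported via the history, never
  raised.

## Synthetic specimens

- **Beads**: by default 150 discs of 30 µm diameter (19–20 px) with a
  spherical-cap phase profile peaking at 2π, placed uniformly at random
  with ≥ 1 diameter center separation (plus a one-pixel guard so
  rasterised discs never merge) by seeded rejection sampling. A top-hat
  profile exists but a uniform 2π step has transmission exp(2πi) = 1 and
  produces no hologram — the continuous cap is the physically meaningful
  default.
- **Spiral**: an Archimedean ribbon (3 turns, 8-px arm) of constant
  phase π — an extended, non-centrosymmetric object.
- **Ψ glyph**: a built-in binary trident stencil at a π step; the exact
  letterform is irrelevant, only its binarity and area fraction matter.
- Optional detector noise: additive Gaussian (σ in intensity units) or
  scaled Poisson (photons per unit intensity), seeded, clipped at zero.

What the generator does **not** emulate: partial coherence, sensor
nonlinearity/quantisation (except when explicitly writing 16-bit files),
dark current, or thick-specimen diffraction. A green test on these
phantoms therefore establishes algorithmic correctness of the pipeline,
not end-to-end performance on real detector frames.

## Evaluation

Reconstructed and ground-truth phase maps are mapped linearly from
[0, max(ground truth)] radians to [0, 255] gray levels (clipped) before
computing MSE, PSNR = 10·log₁₀(255²/MSE) (+∞ sentinel at MSE = 0), and
MSSIM with an 11×11 Gaussian window (σ = 1.5, K₁ = 0.01, K₂ = 0.03,
dynamic range 255). The 255-gray-level convention is the one under which
published (MSE, PSNR) pairs for this problem are internally consistent;
no radian-scale convention reproduces them. Thickness maps follow
`t = φλ / (2π(n_obj − n_med))`.

## Known limitations

- A single in-line intensity hologram does not determine a strong phase
  object uniquely. At the default geometry the 30 µm / 2π beads produce
  order-unity fringe contrast, and all three methods retain errors of
  several gray levels RMS on the 255 scale. The support mask reliably
  lowers off-object ringing (asserted in tests), but the re-synthesis
  step reinjects part of the twin energy through the measured amplitude:
  with an oracle-perfect mask the pipeline's MSSIM ceiling is ≈ 0.77 at
  this geometry (≈ 0.96 if the amplitude were taken as √I instead of I).
  Published near-unity similarity scores for this class of method are
  only reachable in much weaker-scattering regimes.
- The ItPR baseline's positivity clamp half-wave-rectifies background
  ringing; its structural-similarity score *decreases* with iterations on
  strong-phase scenes even as its amplitude residual decreases.
- Smooth, laterally extended phase (low spatial frequencies) barely
  diffracts over 1 mm and is under-recovered by every single-shot method;
  peak-phase estimates are reliable for objects a few tens of pixels
  across, not for wide plateaus.
- The variance threshold is global (fraction of the map maximum); a
  field of view containing one dominant scatterer can mask out weaker
  ones. No z-dependent threshold is implemented.
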