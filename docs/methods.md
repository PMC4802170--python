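# Methods

This note documents the model behind `simsir`, the conventions the modules
share, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Image-formation model

A structured-illumination acquisition multiplies the fluorophore density
`O(r) ≥ 0` by a sinusoidal intensity pattern before diffraction-limited
detection.  With `B` bands (two-beam: `B = 2`, one harmonic; three-beam:
`B = 3`, harmonics at `k/2` and `k`), frame `p` of one orientation is

    D_p(r) = PSF ⊛ [ O(r) · I_p(r) ],
    I_p(r) = 1 + Σ_{m>0} m_m cos( 2π m k₁·(r − r₀)/N + m θ_p ),

where `k₁` is the per-order step frequency (cycles/image), `θ_p` the
first-harmonic phase of that frame and `r₀ = (N/2, N/2)` the field centre.
In frequency space

    D̃_p(k) = Σ_{m=−(B−1)}^{B−1} C_m(k) e^{i m θ_p},
    C_m(k) = (m_|m|/2) e^{i m φ} Õ(k − m k₁) · OTF(k)      (C_0: coefficient 1),

with `φ` the orientation's global pattern phase.  All processing operates
on this linear model.

### Conventions

* Forward DFT unnormalized, inverse carries `1/N²`; spectra stored with
  zero frequency at the array centre; frequency pixel `u` ↔ `u − N/2`
  cycles/image.
* Spectrum translations are implemented as origin-indexed phase ramps
  `exp(+2πi s·r/N)`, `r ∈ {0..N−1}` (integer shifts are then exact
  circular rolls).
* Pattern **phases are referenced to the field centre**, in the simulator,
  the estimator and the reconstruction alike.  With an origin reference, a
  k-vector error `δk` contaminates the measured phase by `2π δk·r̄/N ≈ π δk`
  for a centred object — centre referencing removes that coupling, so the
  phase estimate degrades gracefully with k error.  The conversion constant
  `π m (k₁ₓ + k₁ᵧ)` is applied where the two conventions meet
  (`phase_and_modulation`, `place_bands`).

## Optical transfer function

Without a measured OTF the in-focus incoherent 2-D OTF of a circular pupil
is used: the normalized pupil autocorrelation
`OTF(ν) = (2/π)(arccos ν − ν√(1−ν²))`, `ν = k/kc`, `kc = 2·NA/λ_em`
(cycles/µm; `λ_em` is the *emission* wavelength).  Measured OTFs are read
from two-column text or a small JSON dialect, clamped to [0, 1],
renormalized to 1 at DC and interpolated with a monotone cubic (PCHIP).

The attenuation used for optical sectioning is an inverted Gaussian notch
`att(k) = 1 − a·exp(−k²/2σ²)`, `σ = FWHM/(2√(2 ln 2))`, defaults `a = 0.99`
and `FWHM = 1.2 cycles/µm`.  Shape and defaults are heuristic (the
technique, not the parameterization, is standard); both are configuration.
Wherever a spectrum is divided by the OTF a floor of `1e−4` caps the
amplification.

## Band separation

The mixing matrix `M[p, m] = exp(i m θ_p)` (columns `m = −(B−1)…B−1`) is
inverted with the Moore–Penrose pseudo-inverse, so `P > 2B−1` phases are
combined as least squares and `P = 2B−1` is the exact inverse.  The
pseudo-inverse contains the `1/P` scale: component 0 equals the mean
(widefield) spectrum.  Phases default to `P` equidistant steps; the global
offset stays attached to the components and is measured afterwards.

Per-frame exposure normalization (rescaling each frame's mean to the stack
median, for bleaching drift) exists but is **off by default**: the frame
mean legitimately varies with the pattern phase (by the object's spectral
amplitude at the pattern frequency), so the rescale injects crosstalk
through the mixing matrix — measured as a 10× increase of flat-field
print-through.  Enable it only for visibly bleaching acquisitions.

Frames are edge-windowed (raised-cosine apron, default width `N/16`)
before transforming; fractional-frequency patterns are not grid-periodic
and would otherwise leak across the whole spectrum.

## Parameter estimation

Band `m` carries `Õ(k − m k₁)`, so correlating it against band 0 over
relative shifts peaks at `m k₁`:

1. **Coarse stage** — the full integer-shift correlation map comes from a
   single FFT of the product of the (OTF-support-masked) bands in real
   space.  A disk `|k| ≤ 0.4·kc` is excluded: the low-frequency overlap
   dominates regardless of the pattern and would always win.  A peak on the
   search-region boundary, or with a normalized height below 0.45, triggers
   a likely-failure warning.
2. **Sub-pixel refinement** — an 11 × 11 candidate grid of spacing
   `zoom⁻ⁱ` px around the current best, for `i = 1…3` with `zoom = 10`
   (resolution 10⁻³ px).  Fractional-shift correlations are evaluated
   exactly through closed-form fractional-frequency DFT sums (two thin
   matrix products), never by interpolating maps.

**Weighting and objective.**  The overlap weight is
`w_s(k) = OTF(k)·OTF(k+s)`; under it the OTF compensation (division with
the 1e−4 floor) cancels algebraically and the correlation is computed on
the raw masked bands — exact for every fractional shift and free of noise
amplification at the support edge.  The fit maximizes the Cauchy–Schwarz
normalized coefficient `|c(s)|/√(e₀(s)·e_m(s))`: the raw magnitude is
biased (measured ≈ 0.05 px on bead fields) because the object's spectral
energy drifts under the moving weight, and the normalization removes that
bias (< 0.005 px).  The energy surfaces are smooth OTF-geometry sums and
are evaluated analytically through a dense radial OTF table; the flat
out-of-support noise power (median beyond the cutoff) is subtracted from
the band power densities so the energies — and hence the modulation
normalization — are unbiased under shot/read noise.

At the optimum, `phase = arg c` (re-referenced to the field centre) and
`modulation = 2|c|/e₀`; the factor 2 reflects the `m/2` carried by the
separated component, so a perfect forward model with modulation `m`
returns `m`.  Values outside (0, 1.5] are clamped and flagged, values
outside (0.3, 1.1) flagged as suspicious.  Three-beam data anchor the k
fit on band 2 (double lever arm), then fit band 1 at `k̂` for its own
phase and modulation.

Measured accuracy on 128² bead fields (12-configuration grids): noiseless
≤ 0.004 px / 0.01 rad / 0.002; at 500 photons peak (SNR ≈ 22) ≤ 0.025 px /
0.02 rad / 0.05.

### Per-frame (non-equidistant) phase estimation

The optional per-frame phase mode correlates each frame (widefield
removed) against the widefield at the fitted shift.  With the minimal
phase count `P = 2B−1` individual frame phases are *exactly* unidentifiable
from the data alone — any phase guess reproduces the frames through the
pseudo-inverse, and the Hermitian-mirror constraint is automatically
satisfied — so every estimator of this class carries an object-dependent
bias from the spectral self-overlap of the remaining orders (chiefly the
mirror order).  On sparse 128² bead fields this is of order 0.1 rad,
shrinking for denser samples and larger fields.  The implementation
therefore reports phases at that accuracy and falls back to equidistant
stepping (with a warning) when the per-frame correlation quality drops
below 0.1, e.g. at zero modulation.

## Reconstruction

Each component is zero-pasted into the doubled grid (field of view
unchanged, pixel size halved), rotated by `e^{−iφ̂_m}`, rescaled by
`2/max(m̂, 0.15)` (the clamp prevents noise blow-up at tiny modulation
estimates), translated by `−m k̂₁`, and multiplied by the (optionally
attenuated) OTF re-centred at its shift.  Orders `m > 0` contribute their
Hermitian mirrors explicitly, which makes the assembled spectrum exactly
Hermitian and the output real (imaginary residue checked against 1e−6 of
the RMS and discarded).  Recombination uses one global Wiener denominator
`Σ|OTF_am|² + w²` across all orientations and bands, default `w = 0.05`
on the OTF-normalized scale, then a radial cosine bell falling to zero at
`kc + max_a |m_max·k̂_a|` (multiplier configurable).

Attenuation, when enabled, multiplies the notch into both the numerator
OTFs and the denominator weights, each at its band's own centre; since the
out-of-focus haze is unmodulated it enters only band 0, whose low
frequencies the notch suppresses — the other bands keep supplying in-focus
low-frequency content.  It is off by default (two-beam data rarely needs
it).

The widefield comparator is the mean of all raw frames; the filtered
widefield applies the single-band Wiener filter `OTF/(OTF² + w²)` — same
regularization, no extended support — for fair visual comparison.

## Synthetic data

The generator emulates the standard validation samples: seeded
non-overlapping anti-aliased bead disks (default 200 nm on 80 nm pixels),
a deterministic two-point scene for resolution tests, and uniform fields.
Acquisition defaults mirror common platforms: 3 orientations at
0°/60°/120°, 3 phases (two-beam) or 5 (three-beam), pattern frequency
0.9·kc, modulations 0.8 (two-beam) or (1.0, 0.5) (three-beam harmonic
amplitudes), peak photon budget 500 with Poisson shot noise, 2 e⁻ Gaussian
read noise and 16-bit quantization.  Noise-free runs (`photons=None`) skip
quantization so exact-linearity properties hold to numerical precision.
A single configurable defocus term — the object blurred by a wide Gaussian
and added unmodulated to every frame — exercises the attenuation path.

Not emulated: 3-D defocus structure, aberrations, sCMOS fixed-pattern
noise, pattern distortion, stage drift.  Passing tests therefore
demonstrate correctness of the demodulation and recombination machinery
under the stated model, not robustness to instrument non-idealities beyond
shot/read noise and uneven phase stepping.

## Numerical choices and degenerate inputs

* Tie-breaks in correlation argmax: smallest `|k|`, then lexicographic.
* Non-improving refinement iterations warn and return the best-so-far.
* Duplicate phases make the mixing matrix rank-deficient → error naming
  the colliding frames; fewer than `2B−1` phases → error.
* Non-square TIFF pages are centre-cropped (logged); page counts must be
  a multiple of `angles × phases` (time series are split sequentially and
  reconstructed with shared parameters by default).
* Uniform (pattern-free) input separates into an empty first order; the
  estimator flags the failed modulation fit rather than guessing.

## Problem sizes

The validation experiments use 128² fields for parameter-recovery grids,
256² for resolution and two-point measurements, and one 512² 15-frame
three-beam run for the sizing/timing contract (estimation plus
reconstruction completes in well under a minute on a single CPU; the
512×512 stack reconstructs to 1024×1024).

## Known limitations

* Single-slice (2-D) only: no axial resolution improvement; the OTF model
  is the in-focus 2-D autocorrelation (no refractive-index or depth
  dependence).
* Per-frame phase estimation accuracy is object-dependent (see above).
* The rotational-equivariance property of the linear pipeline is exact
  only for integer-cycle patterns under the periodic quarter-turn about
  the FFT centre; fractional patterns break grid periodicity at the wrap
  seam (the edge window exists for exactly that reason).
* Linear SIM only — no nonlinear/saturated extensions, no iterative or
  regularized reconstruction variants.
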