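# simsir

Single-slice super-resolved structured illumination microscopy (SR-SIM)
reconstruction: a Python library and command-line tool that turns a stack of
raw, sinusoidally illuminated wide-field frames into an image with twice the
lateral resolution and twice the pixel count.

## Who it is for

SR-SIM microscopes — commercial three-beam systems (3 orientations × 5
phases, 15 frames) as well as home-built two-beam / TIRF set-ups (3 × 3, 9
frames) — acquire raw data that must be demodulated numerically.  `simsir`
provides that reconstruction independently of vendor software: automatic
estimation of the illumination parameters from the data itself, band
separation, and generalized Wiener recombination, plus a forward simulator
with known ground truth so the whole pipeline can be validated without
instrument data.

## The method

Sinusoidal illumination `I(r) = 1 + m cos(2π k·r + φ)` mixes the sample
spectrum with the pattern frequency: each raw frame's spectrum is a phase
weighted sum of components `C_m(k) ∝ Õ(k − m·k₁) · OTF(k)` — copies of the
object spectrum `Õ` shifted by multiples of the pattern step `k₁`, all seen
through the detection OTF.  The pipeline:

1. **Band separation** — invert the per-frame phase mixing with the
   Moore–Penrose pseudo-inverse of `M[p,m] = exp(i m φ_p)`; any number of
   phases `P ≥ 2B−1` is accepted.
2. **Parameter estimation** — recover `k₁` to sub-pixel precision, the
   global pattern phase and the modulation depth by weighted cross
   correlation of band `m` against band 0 over the spectral overlap:
   a coarse FFT correlation map (with a low-frequency exclusion disk),
   then iterative 11×11 sub-pixel grid refinement (3 iterations × zoom 10
   → 10⁻³ px), maximizing the normalized correlation coefficient.
   Phase = arg of the correlation at the optimum; modulation = its
   magnitude over the band-0 overlap energy.
3. **Recombination** — each band is pasted into a doubled grid, moved to
   its true frequency position, phase-rotated and rescaled by the measured
   modulation, and all bands (plus Hermitian mirrors) are combined with a
   single generalized Wiener filter

        S(k) = Σ conj(OTF_am)·B_am / (Σ |OTF_am|² + w²),

   followed by a cosine-bell apodization out to the extended support
   `kc + max|m·k₁|`.  Optional OTF attenuation (an inverted Gaussian notch
   at low frequencies) restores optical sectioning for three-beam data.

The OTF is either read from a measured two-column table / JSON file or
modelled in closed form as the incoherent 2-D pupil autocorrelation with
cutoff `kc = 2·NA/λ_em`.

## Worked example

Simulate a 9-frame two-beam acquisition of a fluorescent-bead field,
estimate the pattern parameters from the raw frames, and reconstruct:

```sh
simsir simulate  --preset twobeam-generic --seed 7 --size 128 \
                 --n-beads 40 --bead-diameter-nm 120 --photons 800 --out sim
simsir estimate  --preset twobeam-generic sim/raw.tif --out recon
simsir reconstruct --preset twobeam-generic sim/raw.tif \
                 --params recon/params.json --out recon
```

The estimate step logs, per pattern orientation (this run's actual output):

```
INFO simsir: orientation 0: k = (32.519, -0.007) px, phase = -0.000 rad, modulation = 0.788, quality = 0.923
INFO simsir: orientation 1: k = (16.255, 28.168) px, phase = 0.006 rad, modulation = 0.784, quality = 0.935
INFO simsir: orientation 2: k = (-16.258, 28.162) px, phase = -0.015 rad, modulation = 0.791, quality = 0.920
```

`k` is the pattern frequency in cycles/image (here 0.9× the OTF cutoff at
each of the three orientations 0°/60°/120°), `phase` the global pattern
phase referenced to the field centre, `modulation` the recovered pattern
contrast (the stack was generated with m = 0.8), and `quality` the
normalized correlation peak height (1 = perfect fit).  The reconstruct step
writes `sr.tif` (256×256, 40 nm pixels — double the 128×128 input),
`widefield.tif` and `widefield_filtered.tif` comparators, the log-scaled
`sr_power_spectrum.tif`, and the effective `config.yaml` for provenance.
Because estimation and reconstruction are separate commands, the Wiener
weight, attenuation and apodization can be retuned (`--wiener`,
`--attenuation A,FWHM`, `--apodization`) without re-estimating.

The same pipeline is available as library calls
(`simulate_stack → estimate_parameters → reconstruct`); see the test suite
for worked library-level experiments.

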