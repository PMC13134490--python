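# Methods

## CTF model

The transfer function is modelled without amplitude contrast:

```
CTF(k) = -s_eff · exp(-B_eff k²/4) · sin(χ(k) + φ_eff(k)),
χ(k)   =  π λ Δf k² - (π/2) λ³ C_s k⁴,
```

with λ the relativistic electron wavelength, Δf the defocus (positive =
underfocus) and C_s the spherical aberration. The sign convention
(leading minus, positive-underfocus χ) is fixed and documented; band
densities use |CTF|, so the sign is observable only in simulated
images. The envelope is the standard Gaussian amplitude envelope
`exp(-B k²/4)` with B in Å² — the simplest isotropic form consistent
with the B factors the package fits.

Interfaces use field-conventional units (kV, mm, nm, pm, Å, degrees);
all quantities are converted to Å and radians once, at construction.

### Volta phase plate terms

* **Cut-on frequency** `k_h = r_h/(f λ)`: below k_h the plate imposes no
  phase shift; at and above it the full phase shift applies (closed
  lower boundary — the boundary bin belongs to the shifted region). The
  step is hard (no smoothing) and there is no high-frequency cut-off.
  Defaults r_h = 275 nm, f = 3.5 mm give k_h ≈ 0.004 Å⁻¹ at 300 kV.
* **Transmission** s = 0.88, from a ~12% beam-intensity drop measured
  without a specimen. By default the factor is applied directly to the
  CTF amplitude, matching its use as a single damping factor elsewhere
  in the analysis (dose matching); `sqrt_transmission=True` applies
  √0.88 instead for the strict amplitude reading of an intensity
  measurement. Band-density argmax results are invariant to this
  choice, which only rescales matrices.
* **Extra envelope** ΔB = 33.2 Å² = 100.8 − 67.6, the difference of
  cumulative B factors measured with and without the plate on the same
  specimen and pipeline; added to the baseline B (default 67.6 Å²) only
  when attenuation is enabled. Both numbers are configurable because
  the split between baseline and plate-specific damping is a modelling
  choice, not a measurement.

## Band densities and sweeps

Band density is the mean of |CTF| over 2D reciprocal-space grid pixels
with `k_lo ≤ |k| < k_hi` (half-open, so adjacent bands never double
count a pixel, and densities on a partition recombine exactly when
reweighted by bin counts). Using 2D pixels as bins means higher-|k|
annuli carry more bins — the weighting of a 2D spectral integral. A
`radial=True` option averages per annulus first, for users who want
1D-radial weighting; it is not the default.

The default sweep covers defocus 0–2.5 µm in 0.1 µm steps × phase shift
0–90° in 5° steps (26 × 19 = 494 conditions) on a 512² grid at
1.51 Å/px, whose Nyquist (0.331 Å⁻¹) just accommodates the R4 upper
bound. The φ = 0 column of a sweep reproduces the no-phase-shift
condition; with attenuation disabled it is the conventional (no plate)
case. Sweeps with attenuation enabled apply s and ΔB uniformly at all
phase shifts, including φ = 0, so each heatmap varies only through the
phase term; whether a "no plate" display row should also drop the
attenuation is a presentation choice left to the caller
(`attenuation_enabled` is recorded in the result).

Defocus enters χ linearly in k², so the sweep precomputes the constant
C_s term and envelope once per grid; the full default sweep takes a few
seconds on one CPU.

## Rosenthal–Henderson fitting

The fit is ordinary least squares of ln N on 1/d² with B = 2 × slope,
the orientation in which the B factor is defined; it requires ≥ 3
entries with distinct particle counts and non-degenerate 1/d² spread.
R² is reported as goodness of fit. FSC resolution is read at the 0.143
threshold as the first downward crossing, linearly interpolated in
(k, FSC) between the bracketing samples; a curve that never crosses
returns the last-sample limit flagged `at_limit`, and a curve starting
at or below threshold has no defined resolution and raises.

## Synthetic data

* **FSC generator**: FSC(k) = S/(S+1) with SSNR
  S = N·α·exp(−B k²/2). This form is chosen because its threshold-t
  crossing satisfies `ln N = ln(t/((1−t)α)) + (B/2)(1/d²)` exactly —
  the linear law the Rosenthal–Henderson fit assumes — so generator and
  fitter form a closed loop and parameter recovery is a meaningful
  test. The per-particle scale α is a free parameter (recovery of B is
  invariant to it); the default 1e-4 puts the 0.143 crossing of a
  3×10⁵-particle series near 2 Å, a realistic single-particle regime.
  Resolution series use subsets of 10%…100% in 10% increments; optional
  multiplicative log-normal noise perturbs resolutions.
* **Phantom micrographs**: Gaussian-blob phase maps pushed through the
  weak-phase forward model (multiply the spectrum by the 2D CTF), scaled
  by dose, plus Gaussian noise of variance equal to the dose — the
  Poisson limit, adequate at ≥ 1 e/Å² and linear. The generator
  emulates contrast and band-power behaviour, not real specimens: no 3D
  geometry, solvent scattering, motion or detector effects, so passing
  tests demonstrate the transfer-function algebra, not image realism.
* **Alignment tables**: per-tomogram tilt axis ~ Normal(calibrated axis,
  sd), flagged local-alignment patches ~ Binomial(16, p), thickness ~
  Normal truncated at 0, zero-tilt post-specimen dose ~ Uniform. These
  are the simplest distributions matching the summary statistics the
  analysis reports; defaults reflect a measured phase-plate dataset
  (n = 110, axis sd 9.18° about −96.06°, thickness 2627 ± 536 Å,
  p = 0.0304 so that (1−p)¹⁶ ≈ 0.61 of tomograms carry no flag). The
  default dose window (40–70 e/Å²) is a plausible zero-tilt
  post-specimen range for a ~120 e/Å² vacuum dose; it is a free
  generator parameter, and the dose-matching filter is tested against a
  brute-force scan rather than any particular window.

All generators consume `numpy.random.default_rng(seed)`; identical spec
and seed give bit-identical output.

## Alignment statistics

A tilt axis is an orientation, defined modulo 180°, so each measured
angle is unwrapped into (calibrated − 90°, calibrated + 90°] before
linear statistics; median and sample (n−1) standard deviation are then
taken directly. Circular statistics are unnecessary at the observed
dispersions (≤ ~23°). The problematic-shift fraction is
flagged/total per tomogram, averaged unweighted. Dose matching scales
the reference dataset's [min, max] zero-tilt dose by 1/0.88 and retains
records in the closed interval; closure at the ends is a convention
("within the range" read inclusively).

## Numerical choices and degenerate inputs

* Band membership and radial-profile binning are half-open; empty
  radial bins hold NaN, empty bands raise naming the band and grid.
* `normalize_sweep` rejects all-zero matrices; `compare_conditions`
  rejects a zero denominator; the sd ratio of two summaries is NaN when
  the reference sd is 0.
* Brute-force oracle comparisons (scalar-loop CTF, per-bin averaging,
  per-record dose scan) are exact to 1e-12 on ≤ 16² instances; identity
  comparisons that reassociate floating-point sums use 1e-12 relative
  tolerance.
* Acceptance-scale computations use the full 512² sweep (494
  conditions, seconds); statistical recovery tests use 100–200 seeds at
  the generative sample sizes above, keeping the suite under a minute.

## Known limitations

No astigmatism, amplitude contrast, chromatic envelope, beam tilt or
per-tilt dose weighting; no CTF estimation from images; no modelling of
phase-shift evolution as the plate charges during acquisition; no 3D
tilt-series geometry in the simulator. The package quantifies
analytical band signal — it does not predict absolute alignment success
rates on real data.
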