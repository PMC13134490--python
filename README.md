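# voltactf

Analytical modelling of the Volta phase plate (VPP) contrast transfer
function for cryo-EM and cryo-electron tomography, with the quantitative
analyses built on it: band-integrated |CTF| signal density over defocus
and phase-shift grids, Rosenthal–Henderson B-factor fitting,
dose-matched dataset filtering, and tilt-series alignment-quality
statistics. Seed-deterministic synthetic-data generators make every
stage runnable and testable with no external data.

## Who it is for

Cryo-ET practitioners deciding whether (and at which defocus and phase
shift) a VPP helps a given processing stage, and developers who need a
small, tested CTF/FSC/B-factor toolkit with clean file interfaces.

## The model

The CTF is a pure phase-contrast transfer function with an isotropic
Gaussian envelope:

```
CTF(k) = -s · exp(-B k² / 4) · sin(χ(k) + φ(k))
χ(k)   =  π λ Δf k² - (π/2) λ³ C_s k⁴
```

with electron wavelength λ (1.97 pm at 300 kV), defocus Δf (positive =
underfocus), spherical aberration C_s (2.7 mm default), and cumulative
envelope B factor B (Å²). A VPP adds:

* a phase shift φ applied only at and above the cut-on frequency
  `k_h = r_h / (f λ)` (≈ 0.004 Å⁻¹ for patch radius r_h = 275 nm and
  focal length f = 3.5 mm), as a hard step with no high-frequency
  cut-off;
* a transmission factor s = 0.88 (from a measured ~12% beam-intensity
  drop);
* an extra envelope ΔB = 33.2 Å², the difference between B factors
  measured with (100.8 Å²) and without (67.6 Å²) the plate on the same
  specimen and pipeline.

Band signal is the mean of |CTF| over all 2D reciprocal-space pixels in
a frequency band; the standard bands R1 (0.002–0.03 Å⁻¹) through R4
(0.17–0.33 Å⁻¹) correspond to tilt-series alignment, particle
localization, intermediate refinement and high-resolution averaging.
The Rosenthal–Henderson fit regresses ln N on 1/d² over a series of
(particle count N, FSC-0.143 resolution d) pairs; B = 2 × slope.

## Worked example

```python
import numpy as np
from voltactf import (
    PhasePlateModel, ImagingCondition, FrequencyGrid, FrequencyBand,
    electron_wavelength, cut_on_frequency, compare_conditions,
    SyntheticFscModel, generate_resolution_series, fit_rosenthal_henderson,
)

print(f"wavelength at 300 kV: {electron_wavelength(300):.3g} pm")
print(f"VPP cut-on:           {cut_on_frequency(275, 3.5, 1.97):.4f} 1/A")

grid = FrequencyGrid(side_length=512, pixel_size_A=1.51)
vpp = ImagingCondition(defocus_A=7800, base_B_A2=67.6,
                       phase_plate=PhasePlateModel(phase_shift_deg=72.0),
                       attenuation_enabled=True)
plain = ImagingCondition(defocus_A=19700, base_B_A2=67.6)
for label, lo, hi in [("R1", 0.002, 0.03), ("R4", 0.17, 0.33)]:
    r = compare_conditions(FrequencyBand(label, lo, hi), vpp, plain, grid)
    print(f"{label} density ratio (VPP / conventional): {r:.2f}")

series = generate_resolution_series(SyntheticFscModel(alpha=1e-4, b_A2=100.8),
                                    n_total=300702)
fit = fit_rosenthal_henderson(series)
print(f"fitted B factor: {fit.b_A2:.1f} A^2 (R^2 = {fit.r_squared:.6f})")
```

prints

```
wavelength at 300 kV: 1.97 pm
VPP cut-on:           0.0040 1/A
R1 density ratio (VPP / conventional): 1.73
R4 density ratio (VPP / conventional): 0.53
fitted B factor: 100.8 A^2 (R^2 = 1.000000)
```

The ratios quantify the VPP trade-off: at the median experimental
condition (0.78 µm defocus, 72° phase shift) the plate carries ~73%
more signal than conventional ~2 µm defocus imaging in the
alignment-critical R1 band, but only about half the signal in the
high-resolution R4 band. The B-factor fit closes the loop on the
synthetic FSC generator: a noiseless series generated at B = 100.8 Å²
fits back to exactly that value.

## Command line

`voltactf` exposes `ctf-profile`, `sweep`, `rh-fit`, `simulate` and
`align-summary` subcommands over YAML configs and CSV tables; every run
writes a JSON manifest (config echo, seed, version) sufficient to
replay it. See `voltactf --help`.

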