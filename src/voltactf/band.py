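"""Band-integrated |CTF| density and defocus x phase-shift sweeps.

The signal carried by a spatial-frequency band is quantified as the mean
of |CTF| over all 2D reciprocal-space grid pixels whose |k| falls in the
band (half-open interval [k_lo, k_hi)).  Because the bins are 2D pixels,
higher-frequency annuli contribute more bins, which is the natural
weighting of a 2D power integral; a 1D-radial weighting (each annulus
counted once) is available as an option.

Four standard bands cover the regimes of cryo-ET processing:

* R1 (0.002-0.03 A^-1): patch-based tilt-series alignment / motion
  correction scales,
* R2 (0.005-0.05 A^-1): particle localization at heavy binning,
* R3 (0.05-0.17 A^-1): intermediate subtomogram-averaging refinement,
* R4 (0.17-0.33 A^-1): the high-resolution regime.

Sweeping the density over a defocus x phase-shift grid maps where a
Volta phase plate adds or removes band signal relative to conventional
defocus-based contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from voltactf.optics import (
    FrequencyGrid,
    ImagingCondition,
    PhasePlateModel,
    aberration_phase,
    ctf_field,
    effective_phase_shift,
)

__all__ = [
    "FrequencyBand",
    "DensitySweep",
    "STANDARD_BANDS",
    "DEFAULT_DEFOCUS_VALUES_A",
    "DEFAULT_PHASE_SHIFT_VALUES_DEG",
    "band_density",
    "sweep_density",
    "normalize_sweep",
    "compare_conditions",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Labelled half-open spatial-frequency interval [k_lo, k_hi) in A^-1."""

    label: str
    k_lo_A_inv: float
    k_hi_A_inv: float

    def __post_init__(self) -> None:
        if self.k_lo_A_inv < 0:
            raise ValueError(f"k_lo_A_inv must be >= 0, got {self.k_lo_A_inv}")
        if self.k_hi_A_inv <= self.k_lo_A_inv:
            raise ValueError(
                f"band {self.label!r}: k_hi ({self.k_hi_A_inv}) must exceed "
                f"k_lo ({self.k_lo_A_inv})"
            )

    def mask(self, magnitudes: np.ndarray) -> np.ndarray:
        return (magnitudes >= self.k_lo_A_inv) & (magnitudes < self.k_hi_A_inv)


STANDARD_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("R1", 0.002, 0.03),
    FrequencyBand("R2", 0.005, 0.05),
    FrequencyBand("R3", 0.05, 0.17),
    FrequencyBand("R4", 0.17, 0.33),
)

# default sweep grid: defocus 0-2.5 um in 0.1 um steps, phase shift 0-90 deg
# in 5 deg steps
DEFAULT_DEFOCUS_VALUES_A = tuple(float(x) for x in np.arange(0.0, 25001.0, 1000.0))
DEFAULT_PHASE_SHIFT_VALUES_DEG = tuple(float(x) for x in np.arange(0.0, 91.0, 5.0))


@dataclass(frozen=True)
class DensitySweep:
    """Band density matrix over a (phase shift, defocus) grid.

    ``matrix[i, j]`` is the band density at phase shift
    ``phase_shift_values_deg[i]`` and defocus ``defocus_values_A[j]``.
    """

    band: FrequencyBand
    defocus_values_A: np.ndarray
    phase_shift_values_deg: np.ndarray
    matrix: np.ndarray
    attenuation_enabled: bool

    def __post_init__(self) -> None:
        if self.matrix.shape != (
            len(self.phase_shift_values_deg),
            len(self.defocus_values_A),
        ):
            raise ValueError(
                "matrix shape must be (n_phase_shifts, n_defoci); got "
                f"{self.matrix.shape}"
            )
        if np.any(self.matrix < 0):
            raise ValueError("band densities must be non-negative")

    def argmax(self) -> tuple[float, float]:
        """(phase_shift_deg, defocus_A) of the matrix maximum."""
        i, j = np.unravel_index(np.argmax(self.matrix), self.matrix.shape)
        return float(self.phase_shift_values_deg[i]), float(self.defocus_values_A[j])


def band_density(
    field: np.ndarray,
    grid: FrequencyGrid,
    band: FrequencyBand,
    radial: bool = False,
) -> float:
    """Mean |field| over grid bins with k_lo <= |k| < k_hi.

    With ``radial=True`` the |field| values are first averaged within thin
    annuli so each radius contributes equally, removing the 2D bin-count
    weighting.
    """
    if band.k_hi_A_inv > grid.nyquist_A_inv * (1 + 1e-12):
        raise ValueError(
            f"band {band.label!r} upper bound {band.k_hi_A_inv} exceeds grid "
            f"Nyquist {grid.nyquist_A_inv:.6g}"
        )
    mask = band.mask(grid.magnitudes)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"band {band.label!r} [{band.k_lo_A_inv}, {band.k_hi_A_inv}) contains "
            f"no bins of a {grid.side_length}x{grid.side_length} grid at "
            f"{grid.pixel_size_A} A/px"
        )
    vals = np.abs(np.asarray(field))[mask]
    if not radial:
        return float(vals.sum() / n)
    # annulus-equalized variant: average per unique radius, then over radii
    mags = grid.magnitudes[mask]
    order = np.argsort(mags)
    mags_s, vals_s = mags[order], vals[order]
    uniq, start = np.unique(mags_s, return_index=True)
    sums = np.add.reduceat(vals_s, start)
    counts = np.diff(np.append(start, len(vals_s)))
    return float(np.mean(sums / counts))


def sweep_density(
    base_condition: ImagingCondition,
    defocus_values_A: Sequence[float],
    phase_shift_values_deg: Sequence[float],
    bands: Sequence[FrequencyBand] = STANDARD_BANDS,
    attenuation_enabled: bool = True,
    grid: FrequencyGrid | None = None,
) -> list[DensitySweep]:
    """Band densities over every (phase shift, defocus) combination.

    The base condition supplies the optics, baseline envelope and phase
    plate template; its defocus and phase shift are replaced by the sweep
    values.  Phase shift 0 with attenuation disabled reproduces the
    conventional (no phase plate) condition.
    """
    defoci = np.asarray(list(defocus_values_A), dtype=float)
    phases = np.asarray(list(phase_shift_values_deg), dtype=float)
    if defoci.size == 0 or phases.size == 0:
        raise ValueError("defocus and phase-shift value lists must be non-empty")
    if grid is None:
        grid = FrequencyGrid()
    bands = list(bands)

    plate_template = base_condition.phase_plate or PhasePlateModel()
    mags = grid.magnitudes.ravel()
    masks = []
    for band in bands:
        m = band.mask(grid.magnitudes).ravel()
        if band.k_hi_A_inv > grid.nyquist_A_inv * (1 + 1e-12) or not m.any():
            raise ValueError(
                f"band {band.label!r} is empty or exceeds Nyquist on this grid"
            )
        masks.append(m)

    matrices = [np.empty((phases.size, defoci.size)) for _ in bands]
    lam = base_condition.optics.wavelength_A
    cs = base_condition.optics.cs_A
    k2 = mags**2
    # chi = pi*lam*df*k^2 - (pi/2)*lam^3*cs*k^4; defocus enters linearly
    chi_cs = -0.5 * np.pi * lam**3 * cs * k2**2
    if attenuation_enabled:
        b_eff = base_condition.base_B_A2 + plate_template.delta_B_A2
        s_eff = plate_template.amplitude_factor
    else:
        b_eff = base_condition.base_B_A2
        s_eff = 1.0
    envelope = s_eff * np.exp(-b_eff * k2 / 4.0)
    above_cut = mags >= plate_template.cut_on
    for i, phi_deg in enumerate(phases):
        phi = np.where(above_cut, np.deg2rad(phi_deg), 0.0)
        for j, df in enumerate(defoci):
            chi = np.pi * lam * df * k2 + chi_cs
            absctf = envelope * np.abs(np.sin(chi + phi))
            for b, mask in enumerate(masks):
                matrices[b][i, j] = absctf[mask].mean()

    return [
        DensitySweep(
            band=band,
            defocus_values_A=defoci,
            phase_shift_values_deg=phases,
            matrix=matrices[b],
            attenuation_enabled=attenuation_enabled,
        )
        for b, band in enumerate(bands)
    ]


def normalize_sweep(sweep: DensitySweep) -> DensitySweep:
    """Scale a sweep matrix to [0, 1] by its maximum (argmax preserved)."""
    peak = float(sweep.matrix.max())
    if peak <= 0:
        raise ValueError(
            f"sweep for band {sweep.band.label!r} has no positive density; "
            "cannot normalize"
        )
    return replace(sweep, matrix=sweep.matrix / peak)


def compare_conditions(
    band: FrequencyBand,
    condition_a: ImagingCondition,
    condition_b: ImagingCondition,
    grid: FrequencyGrid | None = None,
) -> float:
    """Ratio of band densities a/b; > 1 means condition a carries more signal."""
    if grid is None:
        grid = FrequencyGrid()
    da = band_density(ctf_field(grid, condition_a), grid, band)
    db = band_density(ctf_field(grid, condition_b), grid, band)
    if db == 0:
        raise ZeroDivisionError(
            f"band {band.label!r} density is zero for the reference condition"
        )
    return da / db
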