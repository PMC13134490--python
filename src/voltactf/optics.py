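"""Electron optics and the phase-contrast transfer function (CTF).

The CTF is modelled as a pure phase-contrast transfer function (no
amplitude contrast)::

    CTF(k) = -s_eff * exp(-B_eff k^2 / 4) * sin(chi(k) + phi_eff(k))

with the aberration phase ``chi(k) = pi lambda dF k^2 - (pi/2) lambda^3
C_s k^4`` (positive defocus = underfocus) and an isotropic Gaussian
amplitude envelope ``exp(-B k^2 / 4)`` parameterized by a B factor in A^2.

A Volta phase plate (VPP) adds a frequency-dependent phase shift
``phi_eff``: zero below the cut-on frequency ``k_h = r_h / (f lambda)``
(set by the phase-shift patch radius r_h and the effective focal length f)
and a constant phase shift phi at and above it, as a hard step with no
high-frequency cut-off.  VPP signal attenuation is modelled by a scalar
transmission factor s (default 0.88, from a ~12% beam-intensity drop) and
an extra envelope term delta_B added to the baseline B factor.

Units at the interfaces follow microscopy convention: kV, mm, nm, pm,
Angstrom and degrees.  Everything is converted to Angstrom and radians at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import constants

__all__ = [
    "ElectronOptics",
    "PhasePlateModel",
    "ImagingCondition",
    "FrequencyGrid",
    "electron_wavelength",
    "cut_on_frequency",
    "transmission_from_intensity_drop",
    "aberration_phase",
    "effective_phase_shift",
    "ctf_value",
    "ctf_field",
    "radial_profile",
]

PM_PER_A = 100.0  # picometres per Angstrom
A_PER_MM = 1.0e7
A_PER_NM = 10.0
A_PER_UM = 1.0e4


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic electron wavelength in picometres.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))

    Parameters
    ----------
    voltage_kV : accelerating voltage in kilovolts (> 0).

    Returns
    -------
    Wavelength in pm; 1.97 pm at 300 kV.
    """
    if voltage_kV <= 0:
        raise ValueError(f"voltage_kV must be > 0, got {voltage_kV}")
    V = voltage_kV * 1e3
    h = constants.h
    m0 = constants.m_e
    e = constants.e
    c = constants.c
    lam_m = h / np.sqrt(2.0 * m0 * e * V * (1.0 + e * V / (2.0 * m0 * c**2)))
    return lam_m * 1e12


def cut_on_frequency(
    patch_radius_nm: float, focal_length_mm: float, wavelength_pm: float
) -> float:
    """VPP cut-on frequency k_h = r_h / (f lambda), in inverse Angstrom.

    Below k_h the phase plate imposes no phase shift.  With the typical
    r_h ~ 275 nm, f = 3.5 mm and lambda = 1.97 pm the cut-on is
    ~0.004 A^-1.
    """
    for name, val in (
        ("patch_radius_nm", patch_radius_nm),
        ("focal_length_mm", focal_length_mm),
        ("wavelength_pm", wavelength_pm),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    r_h_A = patch_radius_nm * A_PER_NM
    f_A = focal_length_mm * A_PER_MM
    lam_A = wavelength_pm / PM_PER_A
    return r_h_A / (f_A * lam_A)


def transmission_from_intensity_drop(intensity_drop: float) -> float:
    """Signal transmission factor from a fractional beam-intensity drop.

    A ~12% intensity reduction measured without a specimen gives the
    default VPP transmission (and dose-matching damping) factor
    1 - 0.12 = 0.88.
    """
    if not 0.0 <= intensity_drop < 1.0:
        raise ValueError(f"intensity_drop must be in [0, 1), got {intensity_drop}")
    return 1.0 - intensity_drop


@dataclass(frozen=True)
class ElectronOptics:
    """Accelerating voltage, spherical aberration and derived wavelength."""

    voltage_kV: float = 300.0
    cs_mm: float = 2.7

    def __post_init__(self) -> None:
        if self.voltage_kV <= 0:
            raise ValueError(f"voltage_kV must be > 0, got {self.voltage_kV}")
        if self.cs_mm < 0:
            raise ValueError(f"cs_mm must be >= 0, got {self.cs_mm}")

    @property
    def wavelength_pm(self) -> float:
        return electron_wavelength(self.voltage_kV)

    @property
    def wavelength_A(self) -> float:
        return self.wavelength_pm / PM_PER_A

    @property
    def cs_A(self) -> float:
        return self.cs_mm * A_PER_MM


@dataclass(frozen=True)
class PhasePlateModel:
    """Volta phase plate: phase shift, cut-on frequency and attenuation.

    Parameters
    ----------
    phase_shift_deg : VPP phase shift phi in degrees, in [0, 180).
    patch_radius_nm : effective phase-shift patch radius r_h (nm).
    focal_length_mm : effective focal length f (mm).
    cut_on_A_inv : optional override for k_h; when None it is derived as
        r_h / (f lambda) using ``wavelength_pm``.
    signal_transmission : scalar signal factor s in (0, 1], applied to
        the CTF amplitude by default (``sqrt_transmission=True`` applies
        sqrt(s) instead, the strict amplitude reading of an intensity
        measurement).
    delta_B_A2 : VPP-specific extra envelope B factor (A^2), the
        difference of cumulative B factors measured with and without the
        plate (100.8 - 67.6 = 33.2 A^2 by default).
    wavelength_pm : wavelength used to derive the cut-on when not
        overridden.
    """

    phase_shift_deg: float = 72.0
    patch_radius_nm: float = 275.0
    focal_length_mm: float = 3.5
    cut_on_A_inv: Optional[float] = None
    signal_transmission: float = 0.88
    delta_B_A2: float = 33.2
    sqrt_transmission: bool = False
    wavelength_pm: float = field(default_factory=lambda: electron_wavelength(300.0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_shift_deg < 180.0:
            raise ValueError(
                f"phase_shift_deg must be in [0, 180), got {self.phase_shift_deg}"
            )
        if self.patch_radius_nm <= 0:
            raise ValueError("patch_radius_nm must be > 0")
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be > 0")
        if not 0.0 < self.signal_transmission <= 1.0:
            raise ValueError("signal_transmission must be in (0, 1]")
        if self.delta_B_A2 < 0:
            raise ValueError("delta_B_A2 must be >= 0")
        if self.cut_on_A_inv is not None and self.cut_on_A_inv <= 0:
            raise ValueError("cut_on_A_inv must be > 0")

    @property
    def cut_on(self) -> float:
        """Cut-on frequency k_h in A^-1 (derived unless overridden)."""
        if self.cut_on_A_inv is not None:
            return self.cut_on_A_inv
        return cut_on_frequency(
            self.patch_radius_nm, self.focal_length_mm, self.wavelength_pm
        )

    @property
    def phase_shift_rad(self) -> float:
        return np.deg2rad(self.phase_shift_deg)

    @property
    def amplitude_factor(self) -> float:
        """Transmission as applied to the CTF amplitude."""
        if self.sqrt_transmission:
            return float(np.sqrt(self.signal_transmission))
        return self.signal_transmission


@dataclass(frozen=True)
class ImagingCondition:
    """Defocus, optics, baseline envelope and optional phase plate."""

    defocus_A: float = 7800.0
    optics: ElectronOptics = field(default_factory=ElectronOptics)
    base_B_A2: float = 67.6
    phase_plate: Optional[PhasePlateModel] = None
    attenuation_enabled: bool = True

    def __post_init__(self) -> None:
        if self.defocus_A < 0:
            raise ValueError(f"defocus_A must be >= 0, got {self.defocus_A}")
        if self.base_B_A2 < 0:
            raise ValueError(f"base_B_A2 must be >= 0, got {self.base_B_A2}")

    @property
    def effective_B_A2(self) -> float:
        if self.phase_plate is not None and self.attenuation_enabled:
            return self.base_B_A2 + self.phase_plate.delta_B_A2
        return self.base_B_A2

    @property
    def effective_transmission(self) -> float:
        if self.phase_plate is not None and self.attenuation_enabled:
            return self.phase_plate.amplitude_factor
        return 1.0


class FrequencyGrid:
    """Square 2D reciprocal-space grid in FFT layout.

    Bin (i, j) holds frequency (f[i], f[j]) with f = fftfreq(n, pixel_size),
    so the zero-frequency bin is at (0, 0) and Nyquist is 1/(2 pixel_size).
    """

    def __init__(self, side_length: int = 512, pixel_size_A: float = 1.51):
        if side_length < 8 or side_length % 2 != 0:
            raise ValueError(
                f"side_length must be an even integer >= 8, got {side_length}"
            )
        if pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be > 0, got {pixel_size_A}")
        self.side_length = int(side_length)
        self.pixel_size_A = float(pixel_size_A)
        f = np.fft.fftfreq(self.side_length, d=self.pixel_size_A)
        kx, ky = np.meshgrid(f, f, indexing="ij")
        self._magnitudes = np.sqrt(kx**2 + ky**2)
        self._magnitudes.setflags(write=False)

    @property
    def magnitudes(self) -> np.ndarray:
        """Per-bin |k| in A^-1 (read-only array)."""
        return self._magnitudes

    @property
    def nyquist_A_inv(self) -> float:
        return 1.0 / (2.0 * self.pixel_size_A)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FrequencyGrid(side_length={self.side_length}, "
            f"pixel_size_A={self.pixel_size_A})"
        )


def aberration_phase(k, defocus_A: float, optics: ElectronOptics):
    """Aberration phase chi(k) = pi lam dF k^2 - (pi/2) lam^3 Cs k^4 (rad).

    Accepts scalar or array k in A^-1; positive defocus means underfocus.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("spatial frequency k must be >= 0")
    lam = optics.wavelength_A
    chi = np.pi * lam * defocus_A * k**2 - 0.5 * np.pi * lam**3 * optics.cs_A * k**4
    return chi if chi.ndim else float(chi)


def effective_phase_shift(k, plate: Optional[PhasePlateModel]):
    """Frequency-dependent VPP phase shift in radians.

    Zero when no plate is present or below the cut-on frequency; the full
    phase shift at and above the cut-on (closed lower boundary, hard step,
    no high-frequency cut-off).
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("spatial frequency k must be >= 0")
    if plate is None:
        out = np.zeros_like(k)
    else:
        out = np.where(k >= plate.cut_on, plate.phase_shift_rad, 0.0)
    return out if out.ndim else float(out)


def ctf_value(k, condition: ImagingCondition):
    """Evaluate the CTF amplitude at frequency k (scalar or array, A^-1).

    Returns s_eff * exp(-B_eff k^2 / 4) * (-sin(chi + phi_eff)); the
    magnitude never exceeds 1.
    """
    k = np.asarray(k, dtype=float)
    chi = aberration_phase(k, condition.defocus_A, condition.optics)
    phi = effective_phase_shift(k, condition.phase_plate)
    envelope = np.exp(-condition.effective_B_A2 * k**2 / 4.0)
    out = -condition.effective_transmission * envelope * np.sin(np.asarray(chi) + phi)
    return out if out.ndim else float(out)


def ctf_field(grid: FrequencyGrid, condition: ImagingCondition) -> np.ndarray:
    """CTF amplitude on every bin of a 2D reciprocal-space grid.

    The field depends only on |k| (no astigmatism), so it is exactly
    invariant under rotation of the frequency axes.
    """
    return ctf_value(grid.magnitudes, condition)


def radial_profile(
    field: np.ndarray,
    grid: FrequencyGrid,
    n_bins: int = 128,
    absolute: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial average of |field| over uniform |k| bins of [0, Nyquist).

    Returns ``(k_centers, profile)``; bins containing no grid pixels hold
    NaN.  Pixels at or beyond Nyquist (grid corners) are excluded.  With
    ``absolute=False`` the signed field is averaged instead.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mags = grid.magnitudes.ravel()
    vals = np.asarray(field).ravel()
    if absolute:
        vals = np.abs(vals)
    nyq = grid.nyquist_A_inv
    edges = np.linspace(0.0, nyq, n_bins + 1)
    idx = np.digitize(mags, edges) - 1
    inside = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins)
    sums = np.bincount(idx[inside], weights=vals[inside], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, profile
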