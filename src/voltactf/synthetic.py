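"""Seed-deterministic generators emulating the data the analyses consume.

Four generators cover the package's inputs end to end:

* **FSC curves** from a spectral signal-to-noise (SSNR) model,
  FSC(k) = S/(S+1) with S = N * alpha * exp(-B k^2 / 2).  This form is
  chosen so that the FSC = t crossing obeys
  ln N = ln(t / ((1-t) alpha)) + (B/2) (1/d^2) exactly — i.e. the series
  it produces satisfy the Rosenthal-Henderson law with slope B/2, making
  parameter recovery a closed-loop test.
* **Resolution-vs-N series** from subsets in 10% increments of a total
  particle count, with optional multiplicative log-normal noise on the
  resolutions.
* **Phantom micrographs** under the weak-phase forward model: a phase map
  of Gaussian blobs, CTF-filtered in reciprocal space, scaled by dose,
  with Gaussian shot noise of variance proportional to dose.
* **Alignment tables** with Gaussian tilt-axis error, Binomial
  problematic-patch flags per 4x4 local-alignment grid, truncated-Gaussian
  thickness and Uniform zero-tilt dose.

Every generator draws from ``numpy.random.default_rng(seed)``: identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from voltactf.alignment import AlignmentRecord
from voltactf.bfactor import FscCurve, ResolutionSeries
from voltactf.optics import FrequencyGrid, ImagingCondition, ctf_field

__all__ = [
    "SyntheticFscModel",
    "PhantomSpec",
    "AlignmentTableSpec",
    "fsc_from_model",
    "fsc_crossing_closed_form",
    "generate_resolution_series",
    "simulate_micrograph",
    "generate_alignment_table",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass(frozen=True)
class SyntheticFscModel:
    """SSNR-model parameters: per-particle signal scale alpha and decay B."""

    alpha: float = 1e-4
    b_A2: float = 100.0
    threshold: float = 0.143

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.b_A2 < 0:
            raise ValueError(f"b_A2 must be >= 0, got {self.b_A2}")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class PhantomSpec:
    """Blob phantom for weak-phase micrograph simulation.

    ``blobs`` is a list of ((row, col) centre in pixels, radius in A,
    amplitude) Gaussian blobs; radius is the Gaussian sigma.
    """

    image_side: int = 256
    pixel_size_A: float = 1.51
    blobs: tuple = (((128.0, 128.0), 60.0, 1.0),)
    dose_e_per_A2: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")
        if self.pixel_size_A <= 0:
            raise ValueError("pixel_size_A must be > 0")
        if self.dose_e_per_A2 < 0:
            raise ValueError("dose must be >= 0")
        fov_A = self.image_side * self.pixel_size_A
        for _, radius_A, _ in self.blobs:
            if radius_A >= fov_A:
                raise ValueError(
                    f"blob radius {radius_A} A exceeds the field of view {fov_A} A"
                )


@dataclass(frozen=True)
class AlignmentTableSpec:
    """Generative parameters of a per-tomogram alignment table."""

    n_tomograms: int = 110
    calibrated_axis_deg: float = -96.06
    axis_error_sd_deg: float = 9.18
    # (1 - p)^16 = 0.61 -> ~61% of tomograms carry no flagged patch
    problematic_patch_prob: float = 0.0304
    n_patches: int = 16
    thickness_mean_A: float = 2627.0
    thickness_sd_A: float = 536.0
    dose_range: tuple[float, float] = (40.0, 70.0)
    condition_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tomograms <= 0 or self.n_patches <= 0:
            raise ValueError("counts must be > 0")
        if not 0.0 <= self.problematic_patch_prob <= 1.0:
            raise ValueError("problematic_patch_prob must be in [0, 1]")
        if self.axis_error_sd_deg < 0 or self.thickness_sd_A < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.dose_range[1] < self.dose_range[0]:
            raise ValueError("dose_range must be (lo, hi) with hi >= lo")


def fsc_from_model(
    model: SyntheticFscModel, n_particles: int, k_values
) -> FscCurve:
    """FSC curve FSC(k) = S/(S+1), S = N alpha exp(-B k^2 / 2).

    Monotone decreasing in k for B > 0 and pointwise increasing in N.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    k = np.asarray(k_values, dtype=float)
    s = n_particles * model.alpha * np.exp(-model.b_A2 * k**2 / 2.0)
    fsc = s / (s + 1.0)
    return FscCurve(k_values=tuple(k.tolist()), correlations=tuple(fsc.tolist()))


def fsc_crossing_closed_form(model: SyntheticFscModel, n_particles: int) -> float:
    """Analytic FSC = threshold crossing frequency of the SSNR model.

    Solving S/(S+1) = t for k gives
    k* = sqrt((2/B) ln(N alpha (1-t)/t)).  Requires the argument of the
    log to exceed 1 (the curve starts above threshold) and B > 0.
    """
    t = model.threshold
    arg = n_particles * model.alpha * (1.0 - t) / t
    if arg <= 1.0:
        raise ValueError(
            f"N={n_particles} is too small: the model FSC never exceeds the "
            f"threshold {t} above k=0 crossing (N alpha (1-t)/t = {arg:.4g} <= 1)"
        )
    if model.b_A2 == 0:
        raise ValueError("B = 0 gives a flat FSC with no threshold crossing")
    return math.sqrt(2.0 / model.b_A2 * math.log(arg))


def generate_resolution_series(
    model: SyntheticFscModel,
    n_total: int,
    fractions=DEFAULT_FRACTIONS,
    noise_sd_log: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ResolutionSeries:
    """Resolution-vs-N series from subsets of ``n_total`` particles.

    Each subset size is round(fraction * n_total); its resolution is the
    closed-form FSC-threshold crossing of the model, optionally multiplied
    by exp(Normal(0, noise_sd_log)) noise.  Deterministic when
    ``noise_sd_log`` is 0.
    """
    if n_total < 10:
        raise ValueError("n_total must be >= 10")
    fractions = tuple(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    counts, resolutions = [], []
    for f in fractions:
        n = int(round(f * n_total))
        if n == 0:
            raise ValueError(f"fraction {f} of n_total {n_total} gives 0 particles")
        d = 1.0 / fsc_crossing_closed_form(model, n)
        if noise_sd_log > 0:
            d *= math.exp(rng.normal(0.0, noise_sd_log))
        counts.append(n)
        resolutions.append(d)
    return ResolutionSeries(
        n_particles=tuple(counts), resolution_A=tuple(resolutions), label=label
    )


def _render_phase_map(spec: PhantomSpec) -> np.ndarray:
    side = spec.image_side
    rows, cols = np.mgrid[0:side, 0:side].astype(float)
    phase = np.zeros((side, side))
    for (r0, c0), radius_A, amp in spec.blobs:
        sigma_px = radius_A / spec.pixel_size_A
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        phase += amp * np.exp(-d2 / (2.0 * sigma_px**2))
    return phase


def simulate_micrograph(
    spec: PhantomSpec,
    condition: ImagingCondition,
    transfer: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weak-phase micrograph of a blob phantom under an imaging condition.

    Forward model: render the phantom phase map, filter its spectrum by
    the 2D CTF, return to real space, scale by dose, and add Gaussian
    shot noise with variance equal to the dose (the Poisson limit).
    Returns ``(noisy, noise_free)`` images; both are all-zero at zero
    dose.  ``transfer`` replaces the CTF field with an arbitrary
    reciprocal-space filter (e.g. all-ones for an unfiltered reference).
    """
    grid = FrequencyGrid(side_length=spec.image_side, pixel_size_A=spec.pixel_size_A)
    phase = _render_phase_map(spec)
    ctf = ctf_field(grid, condition) if transfer is None else np.asarray(transfer)
    filtered = np.fft.ifft2(np.fft.fft2(phase) * ctf).real
    noise_free = spec.dose_e_per_A2 * filtered
    rng = np.random.default_rng(spec.seed)
    if spec.dose_e_per_A2 > 0:
        noise = rng.normal(0.0, math.sqrt(spec.dose_e_per_A2), size=phase.shape)
    else:
        noise = np.zeros_like(phase)
    return noise_free + noise, noise_free


def generate_alignment_table(spec: AlignmentTableSpec) -> list[AlignmentRecord]:
    """Synthetic per-tomogram alignment records.

    Tilt axis ~ Normal(calibrated, sd); flagged patches ~ Binomial(n_patches,
    p); thickness ~ Normal truncated at 0 (redraw); dose ~ Uniform(range).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_tomograms):
        axis = rng.normal(spec.calibrated_axis_deg, spec.axis_error_sd_deg)
        flagged = int(rng.binomial(spec.n_patches, spec.problematic_patch_prob))
        thickness = rng.normal(spec.thickness_mean_A, spec.thickness_sd_A)
        while thickness <= 0:
            thickness = rng.normal(spec.thickness_mean_A, spec.thickness_sd_A)
        dose = rng.uniform(spec.dose_range[0], spec.dose_range[1])
        records.append(
            AlignmentRecord(
                tomogram_id=f"{spec.condition_label}_{i:04d}",
                condition_label=spec.condition_label,
                tilt_axis_deg=float(axis),
                flagged_patches=flagged,
                total_patches=spec.n_patches,
                zero_tilt_dose=float(dose),
                thickness_A=float(thickness),
            )
        )
    return records
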