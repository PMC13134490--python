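"""Summary statistics over per-tomogram tilt-series alignment tables.

Global alignment quality is measured by the dispersion of the
per-tomogram tilt-axis orientation around the instrument-calibrated axis;
local quality by the fraction of patch-based local alignments flagged as
problematic.  A tilt axis is an orientation (defined modulo 180 deg), so
each measured angle is first unwrapped into the half-turn window
(calibrated - 90, calibrated + 90] before linear statistics are taken.

``dose_match_filter`` reproduces dose-matched dataset comparison: the
reference (phase plate) dataset's zero-tilt post-specimen dose range,
divided by a damping factor (0.88, the measured beam transmission of the
plate), defines the closed interval of pre-specimen-equivalent doses a
conventional tomogram must fall in to be retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentRecord",
    "AlignmentSummary",
    "DoseMatchReport",
    "summarize_alignment",
    "dose_match_filter",
    "compare_summaries",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One tomogram's alignment metrics."""

    tomogram_id: str
    condition_label: str
    tilt_axis_deg: float
    flagged_patches: int
    total_patches: int
    zero_tilt_dose: float
    thickness_A: float

    def __post_init__(self) -> None:
        if self.total_patches <= 0:
            raise ValueError("total_patches must be > 0")
        if not 0 <= self.flagged_patches <= self.total_patches:
            raise ValueError(
                f"flagged_patches ({self.flagged_patches}) must lie in "
                f"[0, total_patches={self.total_patches}]"
            )
        if self.zero_tilt_dose < 0:
            raise ValueError("zero_tilt_dose must be >= 0")
        if self.thickness_A <= 0:
            raise ValueError("thickness_A must be > 0")


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-dataset summary of tilt-axis, local-shift and thickness metrics."""

    n_total: int
    axis_median_deg: float
    axis_sd_deg: float
    axis_offset_deg: float
    frac_zero_problematic: float
    mean_problematic_fraction: float
    thickness_mean_A: float
    thickness_median_A: float
    thickness_sd_A: float


@dataclass(frozen=True)
class DoseMatchReport:
    """Bounds and counts of a dose-matching filter run."""

    dose_min: float
    dose_max: float
    damping_factor: float
    n_before: int
    n_after: int


def unwrap_axis(angle_deg, calibrated_axis_deg: float):
    """Map orientation angles into (calibrated - 90, calibrated + 90].

    Adds the multiple of 180 deg that brings each angle within a half
    turn of the calibrated axis (orientations are defined modulo 180).
    """
    a = np.asarray(angle_deg, dtype=float)
    out = a - 180.0 * np.ceil((a - calibrated_axis_deg - 90.0) / 180.0)
    return out if out.ndim else float(out)


def summarize_alignment(
    records: Sequence[AlignmentRecord], calibrated_axis_deg: float
) -> AlignmentSummary:
    """Median/sd of unwrapped tilt axes, flagged-patch fractions, thickness.

    Standard deviations use the sample (n-1) convention; a single record
    reports sd 0.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    axes = unwrap_axis([r.tilt_axis_deg for r in records], calibrated_axis_deg)
    axes = np.atleast_1d(axes)
    fracs = np.array([r.flagged_patches / r.total_patches for r in records])
    thick = np.array([r.thickness_A for r in records])
    n = len(records)
    sd = float(np.std(axes, ddof=1)) if n > 1 else 0.0
    thick_sd = float(np.std(thick, ddof=1)) if n > 1 else 0.0
    median = float(np.median(axes))
    return AlignmentSummary(
        n_total=n,
        axis_median_deg=median,
        axis_sd_deg=sd,
        axis_offset_deg=abs(median - calibrated_axis_deg),
        frac_zero_problematic=float(np.mean(fracs == 0.0)),
        mean_problematic_fraction=float(np.mean(fracs)),
        thickness_mean_A=float(np.mean(thick)),
        thickness_median_A=float(np.median(thick)),
        thickness_sd_A=thick_sd,
    )


def dose_match_filter(
    records: Sequence[AlignmentRecord],
    reference_records: Sequence[AlignmentRecord],
    damping_factor: float = 0.88,
) -> tuple[list[AlignmentRecord], DoseMatchReport]:
    """Retain records whose zero-tilt dose falls in the scaled reference range.

    Bounds are [min, max] of the reference doses, each divided by the
    damping factor; the retention interval is closed at both ends.
    """
    if not reference_records:
        raise ValueError("reference record list is empty; no dose bounds defined")
    if not 0.0 < damping_factor <= 1.0:
        raise ValueError(f"damping_factor must be in (0, 1], got {damping_factor}")
    ref = [r.zero_tilt_dose for r in reference_records]
    lo = min(ref) / damping_factor
    hi = max(ref) / damping_factor
    retained = [r for r in records if lo <= r.zero_tilt_dose <= hi]
    report = DoseMatchReport(
        dose_min=lo,
        dose_max=hi,
        damping_factor=damping_factor,
        n_before=len(records),
        n_after=len(retained),
    )
    return retained, report


def compare_summaries(a: AlignmentSummary, b: AlignmentSummary) -> dict:
    """Pure-arithmetic comparison of two alignment summaries.

    ``sd_ratio_b_over_a`` > 1 means dataset b's tilt axes are more
    dispersed than a's (NaN when a's sd is zero).
    """
    sd_ratio = b.axis_sd_deg / a.axis_sd_deg if a.axis_sd_deg > 0 else float("nan")
    return {
        "sd_ratio_b_over_a": sd_ratio,
        "median_diff_deg": b.axis_median_deg - a.axis_median_deg,
        "offset_diff_deg": b.axis_offset_deg - a.axis_offset_deg,
        "frac_zero_problematic_diff": b.frac_zero_problematic
        - a.frac_zero_problematic,
        "mean_problematic_fraction_diff": b.mean_problematic_fraction
        - a.mean_problematic_fraction,
        "thickness_mean_diff_A": b.thickness_mean_A - a.thickness_mean_A,
    }
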