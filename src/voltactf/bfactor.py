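"""Rosenthal-Henderson B-factor fitting and FSC threshold resolution.

The Rosenthal-Henderson relation links the particle count N needed to
reach resolution d to a single cumulative B factor::

    ln N = const + (B / 2) * (1 / d^2)

so an ordinary least-squares fit of ln N against 1/d^2 over a series of
subset reconstructions yields B = 2 * slope.  B aggregates every source
of coherent signal loss in the pipeline (specimen, imaging, processing);
comparing B between two acquisition conditions isolates the condition's
own damping when the rest of the pipeline is shared.

Resolution itself is read off a Fourier shell correlation (FSC) curve at
the gold-standard 0.143 threshold, using linear interpolation between the
samples that bracket the first downward crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResolutionSeries",
    "BFactorFit",
    "FscCurve",
    "ThresholdCrossing",
    "fit_rosenthal_henderson",
    "resolution_at_threshold",
    "rh_plot_table",
]


@dataclass(frozen=True)
class ResolutionSeries:
    """Ordered (particle count, FSC-threshold resolution) pairs."""

    n_particles: tuple[int, ...]
    resolution_A: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.n_particles) != len(self.resolution_A):
            raise ValueError("n_particles and resolution_A lengths differ")
        if any(n <= 0 for n in self.n_particles):
            raise ValueError("particle counts must be > 0")
        if any(d <= 0 for d in self.resolution_A):
            raise ValueError("resolutions must be > 0 A")

    def __len__(self) -> int:
        return len(self.n_particles)


@dataclass(frozen=True)
class BFactorFit:
    """Result of a Rosenthal-Henderson regression."""

    b_A2: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class FscCurve:
    """FSC values sampled on strictly increasing spatial frequencies."""

    k_values: tuple[float, ...]
    correlations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.correlations):
            raise ValueError("k_values and correlations lengths differ")
        k = np.asarray(self.k_values)
        if len(k) < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("k_values must be strictly increasing (>= 2 samples)")
        if np.any(np.asarray(self.correlations) > 1.0 + 1e-12):
            raise ValueError("FSC values cannot exceed 1")


@dataclass(frozen=True)
class ThresholdCrossing:
    """Resolution at an FSC threshold; ``at_limit`` flags a curve that
    never crossed, in which case the resolution is the Nyquist/last-sample
    limit rather than a measured crossing."""

    resolution_A: float
    k_cross_A_inv: float
    at_limit: bool = False


def fit_rosenthal_henderson(series: ResolutionSeries) -> BFactorFit:
    """OLS of ln N on 1/d^2; B = 2 * slope.

    Requires at least three entries with distinct particle counts and
    non-degenerate 1/d^2 spread.
    """
    if len(set(series.n_particles)) < 3:
        raise ValueError(
            "Rosenthal-Henderson fit needs >= 3 entries with distinct "
            f"particle counts (got {len(set(series.n_particles))})"
        )
    x = 1.0 / np.asarray(series.resolution_A, dtype=float) ** 2
    y = np.log(np.asarray(series.n_particles, dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("all resolutions identical; 1/d^2 has zero variance")
    res = stats.linregress(x, y)
    return BFactorFit(
        b_A2=2.0 * res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        n_points=len(series),
    )


def resolution_at_threshold(
    curve: FscCurve, threshold: float = 0.143
) -> ThresholdCrossing:
    """Resolution 1/k* at the first downward crossing of the threshold.

    The crossing frequency k* is located by linear interpolation between
    the last sample above the threshold and the first at/below it.  A
    curve that stays above the threshold returns the last-sample limit
    with ``at_limit=True``; a curve starting at/below the threshold has no
    defined resolution and raises.
    """
    k = np.asarray(curve.k_values, dtype=float)
    fsc = np.asarray(curve.correlations, dtype=float)
    if fsc[0] <= threshold:
        raise ValueError(
            f"FSC curve starts at {fsc[0]:.4g} <= threshold {threshold}; "
            "no resolution defined"
        )
    below = np.nonzero(fsc <= threshold)[0]
    if below.size == 0:
        return ThresholdCrossing(
            resolution_A=1.0 / k[-1], k_cross_A_inv=float(k[-1]), at_limit=True
        )
    j = int(below[0])
    i = j - 1
    # linear interpolation in (k, FSC) between the bracketing samples
    frac = (fsc[i] - threshold) / (fsc[i] - fsc[j])
    k_star = k[i] + frac * (k[j] - k[i])
    return ThresholdCrossing(
        resolution_A=float(1.0 / k_star), k_cross_A_inv=float(k_star)
    )


def rh_plot_table(series_list: list[ResolutionSeries]) -> pd.DataFrame:
    """Plot-ready table of (label, n_particles, resolution_A, inv_d2, ln_n).

    A pure coordinate transform of the input series; no fitting.
    """
    rows = []
    for s in series_list:
        for n, d in zip(s.n_particles, s.resolution_A):
            rows.append(
                {
                    "label": s.label,
                    "n_particles": n,
                    "resolution_A": d,
                    "inv_d2_A_inv2": 1.0 / d**2,
                    "ln_n": float(np.log(n)),
                }
            )
    return pd.DataFrame(
        rows, columns=["label", "n_particles", "resolution_A", "inv_d2_A_inv2", "ln_n"]
    )
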