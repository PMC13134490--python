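"""File interfaces: YAML configs, CSV tables, MRC2014 images, manifests.

All delimited text is comma-separated UTF-8 with a mandatory header row
and "." decimals; angles are degrees and lengths Angstrom at every file
boundary.  Simulated micrographs are written as MRC2014 mode-2 (float32)
maps with the pixel size carried in the cell header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from voltactf.alignment import AlignmentRecord
from voltactf.band import DensitySweep, FrequencyBand
from voltactf.bfactor import ResolutionSeries
from voltactf.optics import ElectronOptics, ImagingCondition, PhasePlateModel

ALIGNMENT_COLUMNS = [
    "tomogram_id",
    "condition_label",
    "tilt_axis_deg",
    "flagged_patches",
    "total_patches",
    "zero_tilt_dose",
    "thickness_A",
]


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def condition_from_config(block: dict) -> ImagingCondition:
    """Build an ImagingCondition from a config mapping.

    Recognized keys: defocus_A, base_B_A2, attenuation_enabled,
    optics: {voltage_kV, cs_mm}, phase_plate: {phase_shift_deg,
    patch_radius_nm, focal_length_mm, cut_on_A_inv, signal_transmission,
    delta_B_A2, sqrt_transmission} or phase_plate: null.
    """
    optics = ElectronOptics(**block.get("optics", {}))
    plate_block = block.get("phase_plate")
    plate = None
    if plate_block is not None:
        plate = PhasePlateModel(
            wavelength_pm=optics.wavelength_pm, **plate_block
        )
    return ImagingCondition(
        defocus_A=block.get("defocus_A", 7800.0),
        optics=optics,
        base_B_A2=block.get("base_B_A2", 67.6),
        phase_plate=plate,
        attenuation_enabled=block.get("attenuation_enabled", True),
    )


def parse_band(spec: str | dict) -> FrequencyBand:
    """Band from 'label:k_lo:k_hi' string or a mapping."""
    if isinstance(spec, dict):
        return FrequencyBand(
            label=spec["label"],
            k_lo_A_inv=float(spec["k_lo_A_inv"]),
            k_hi_A_inv=float(spec["k_hi_A_inv"]),
        )
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"band spec {spec!r} is not 'label:k_lo:k_hi'")
    return FrequencyBand(parts[0], float(parts[1]), float(parts[2]))


def write_profile_csv(
    path: str | Path, k: np.ndarray, ctf: np.ndarray, abs_ctf: np.ndarray
) -> None:
    pd.DataFrame({"k_A_inv": k, "ctf": ctf, "abs_ctf": abs_ctf}).to_csv(
        path, index=False
    )


def write_sweep_csv(path: str | Path, sweep: DensitySweep) -> None:
    """Matrix as CSV: first row defocus values, first column phase shifts."""
    df = pd.DataFrame(
        sweep.matrix,
        index=pd.Index(sweep.phase_shift_values_deg, name="phase_shift_deg"),
        columns=[f"{d:g}" for d in sweep.defocus_values_A],
    )
    df.to_csv(path)


def read_sweep_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (phase_shifts_deg, defocus_values_A, matrix)."""
    df = pd.read_csv(path, index_col=0)
    return (
        df.index.to_numpy(dtype=float),
        np.array([float(c) for c in df.columns]),
        df.to_numpy(dtype=float),
    )


def write_resolution_series_csv(
    path: str | Path, series_list: Sequence[ResolutionSeries]
) -> None:
    rows = [
        {"label": s.label, "n_particles": n, "resolution_A": d}
        for s in series_list
        for n, d in zip(s.n_particles, s.resolution_A)
    ]
    pd.DataFrame(rows, columns=["label", "n_particles", "resolution_A"]).to_csv(
        path, index=False
    )


def read_resolution_series_csv(path: str | Path) -> list[ResolutionSeries]:
    df = pd.read_csv(path)
    for col in ("n_particles", "resolution_A"):
        if col not in df.columns:
            raise ValueError(f"resolution series table {path} lacks column {col!r}")
    if "label" not in df.columns:
        df["label"] = ""
    df["label"] = df["label"].fillna("")
    out = []
    for label, grp in df.groupby("label", sort=False):
        out.append(
            ResolutionSeries(
                n_particles=tuple(int(n) for n in grp["n_particles"]),
                resolution_A=tuple(float(d) for d in grp["resolution_A"]),
                label=str(label),
            )
        )
    return out


def write_alignment_csv(
    path: str | Path, records: Sequence[AlignmentRecord]
) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=ALIGNMENT_COLUMNS)
    df.to_csv(path, index=False)


def read_alignment_csv(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path)
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"alignment table {path} lacks required column(s): {', '.join(missing)}"
        )
    return [
        AlignmentRecord(
            tomogram_id=str(row.tomogram_id),
            condition_label=str(row.condition_label),
            tilt_axis_deg=float(row.tilt_axis_deg),
            flagged_patches=int(row.flagged_patches),
            total_patches=int(row.total_patches),
            zero_tilt_dose=float(row.zero_tilt_dose),
            thickness_A=float(row.thickness_A),
        )
        for row in df.itertuples(index=False)
    ]


def write_mrc(path: str | Path, image: np.ndarray, pixel_size_A: float) -> None:
    """Write a 2D image as an MRC2014 mode-2 (float32) map."""
    arr = np.ascontiguousarray(np.asarray(image, dtype=np.float32))
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(arr)
    # gemmi maps numpy axis 0 to grid axis u, so cell edges follow arr.shape
    du, dv, dw = arr.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        du * pixel_size_A, dv * pixel_size_A, dw * pixel_size_A, 90, 90, 90
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2)
    ccp4.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns (array, pixel_size_A along x)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid, copy=True)
    pixel = ccp4.grid.unit_cell.a / ccp4.grid.nu
    return np.squeeze(arr), float(pixel)


def write_manifest(
    path: str | Path, config: dict, seed: int | None, outputs: Sequence[str]
) -> None:
    """Run manifest: config echo, seed and produced files; enough to replay."""
    from voltactf import __version__

    manifest = {
        "package": "voltactf",
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": list(outputs),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
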