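"""File interfaces: TIFF frames/maps, text geometry configs, profile tables."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import DetectorFrame, DetectorGeometry, Profile1D
from .mapping import ParameterMap


def geometry_hash(geometry: DetectorGeometry) -> str:
    """Short stable digest of a geometry, recorded in profile headers."""
    key = (f"{geometry.distance:.9g}|{geometry.pixel_size:.9g}|"
           f"{geometry.beam_center}|{geometry.energy:.9g}|{geometry.frame_shape}")
    return hashlib.md5(key.encode()).hexdigest()[:10]


def save_geometry(path, geometry: DetectorGeometry) -> None:
    data = {
        "distance_m": geometry.distance,
        "pixel_size_um": geometry.pixel_size,
        "beam_center_row": geometry.beam_center[0],
        "beam_center_col": geometry.beam_center[1],
        "energy_keV": geometry.energy,
        "frame_rows": geometry.frame_shape[0],
        "frame_cols": geometry.frame_shape[1],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_geometry(path) -> DetectorGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return DetectorGeometry(
        distance=float(data["distance_m"]),
        pixel_size=float(data["pixel_size_um"]),
        beam_center=(float(data["beam_center_row"]), float(data["beam_center_col"])),
        energy=float(data["energy_keV"]),
        frame_shape=(int(data["frame_rows"]), int(data["frame_cols"])),
    )


def write_frame(path, frame: DetectorFrame, mask_path=None) -> None:
    """Frame counts as 32-bit float TIFF, optional companion mask TIFF."""
    tifffile.imwrite(path, frame.counts.astype(np.float32))
    if mask_path is not None:
        tifffile.imwrite(mask_path, frame.mask.astype(np.uint8))


def read_frame(path, mask_path=None) -> DetectorFrame:
    counts = tifffile.imread(path).astype(float)
    mask = None
    if mask_path is not None:
        mask = tifffile.imread(mask_path).astype(bool)
    return DetectorFrame(counts=counts, mask=mask)


def write_profile(path, profile: Profile1D, geometry: DetectorGeometry | None = None) -> None:
    """Two-column text profile with a comment header."""
    lines = [f"# axis_kind: {profile.axis_kind}"]
    for key, value in profile.meta.items():
        lines.append(f"# {key}: {value}")
    if geometry is not None:
        lines.append(f"# geometry_hash: {geometry_hash(geometry)}")
    lines.append("# columns: grid intensity counts_per_bin")
    for g, inten, n in zip(profile.grid, profile.intensity, profile.counts_per_bin):
        lines.append(f"{g:.8g}\t{inten:.8g}\t{n:d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> Profile1D:
    axis_kind = None
    grid, intensity, counts = [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "axis_kind:" in line:
                axis_kind = line.split("axis_kind:")[1].strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        grid.append(float(parts[0]))
        intensity.append(float(parts[1]))
        counts.append(int(parts[2]) if len(parts) > 2 else 1)
    if axis_kind is None:
        raise ValueError("profile header missing axis_kind")
    return Profile1D(axis_kind, np.array(grid), np.array(intensity), np.array(counts))


def write_map(values_path, mask_path, pmap: ParameterMap) -> None:
    tifffile.imwrite(values_path, np.nan_to_num(pmap.values).astype(np.float32))
    tifffile.imwrite(mask_path, pmap.valid_mask.astype(np.uint8))


def read_map(values_path, mask_path, parameter_name: str = "", units: str = "") -> ParameterMap:
    values = tifffile.imread(values_path).astype(float)
    valid = tifffile.imread(mask_path).astype(bool)
    values[~valid] = np.nan
    return ParameterMap(values, valid, parameter_name=parameter_name, units=units)


def write_fit_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
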