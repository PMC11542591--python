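"""Readers, writers, and run configuration.

Volumes and frame stacks travel as CCP4/MRC maps (via gemmi) with the voxel
size in the header; single images may also be written as TIFF.  Curves travel
as CSV with a commented provenance header.  All writers are deterministic
byte-for-byte given identical inputs.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from .curves import FrequencyCurve
from .errors import DataError

__all__ = [
    "read_volume",
    "write_volume",
    "read_tiff",
    "write_tiff",
    "read_curve",
    "write_curve",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# Volumes (MRC / CCP4)
# ---------------------------------------------------------------------------

def write_volume(path: str | os.PathLike, volume: np.ndarray, voxel_size: float) -> None:
    """Write a 2D/3D array as an MRC (mode 2, float32) map with its voxel size."""
    vol = np.asarray(volume)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise DataError("write_volume expects a 2D or 3D array")
    if not (voxel_size > 0):
        raise DataError("voxel_size must be > 0")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        vol.shape[0] * voxel_size,
        vol.shape[1] * voxel_size,
        vol.shape[2] * voxel_size,
        90.0,
        90.0,
        90.0,
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map (modes 0/1/2) into an array plus voxel size (A).

    The array follows the on-disk axis order of our writer (axis 0 slowest);
    non-cubic volumes are returned as stored — downstream FSC operations
    reject them with their own message.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad files
        size = path.stat().st_size if path.exists() else 0
        raise DataError(
            f"failed to parse MRC file {path} (file is {size} bytes): {exc}"
        ) from exc
    arr = np.array(m.grid, copy=True)
    sp = m.grid.spacing
    voxel = float(sp[0]) if sp[0] > 0 else 1.0
    return arr, voxel


def write_tiff(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a single 2D image as TIFF (counts kept as integers when integral)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise DataError("write_tiff expects a 2D image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.int32)
    tifffile.imwrite(str(path), img)


def read_tiff(path: str | os.PathLike) -> np.ndarray:
    try:
        return tifffile.imread(str(path))
    except Exception as exc:
        raise DataError(f"failed to parse TIFF file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Curve tables (CSV with commented provenance header)
# ---------------------------------------------------------------------------

_FMT = "%.9g"  # printed precision of the curve tables


def write_curve(
    path: str | os.PathLike,
    curve: FrequencyCurve,
    pixel_size: float | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a curve as CSV with '# key = value' provenance lines.

    Columns: frequency (unit recorded in the header), fraction_nyquist, value,
    and spread when present.  Numbers are printed to 9 significant digits, so
    the table round-trips bit-identically at that precision.
    """
    df = curve.to_dataframe(pixel_size=pixel_size)
    fcol = df.columns[0]
    header = {
        "kind": curve.kind,
        "frequency_unit": curve.frequency_unit,
        "frequency_column": fcol,
    }
    for k, v in {**curve.metadata, **(provenance or {})}.items():
        if isinstance(v, (str, int, float, bool)):
            header[k] = v
    lines = [f"# {k} = {v}" for k, v in header.items()]
    body = df.to_csv(index=False, float_format=_FMT, lineterminator="\n")
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_curve(path: str | os.PathLike) -> FrequencyCurve:
    """Read a curve table written by :func:`write_curve` (locale-independent)."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    fcol = meta.get("frequency_column", df.columns[0])
    if fcol not in df.columns or "value" not in df.columns:
        raise DataError(
            f"curve table {path} must have columns [{fcol}, value]; got {list(df.columns)}"
        )
    kind = meta.pop("kind", "MTF")
    unit = meta.pop("frequency_unit", "cycles/pixel")
    meta.pop("frequency_column", None)
    spread = df["spread"].to_numpy(float) if "spread" in df.columns else None
    for k, v in list(meta.items()):
        try:
            meta[k] = json.loads(v)
        except (ValueError, TypeError):
            pass
    return FrequencyCurve(
        df[fcol].to_numpy(float),
        df["value"].to_numpy(float),
        kind,
        spread=spread,
        frequency_unit=unit,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Flat, validated document of all pipeline defaults.

    Unknown keys are rejected; the effective configuration is echoed into
    every run's output manifest.
    """

    model_config = ConfigDict(extra="forbid")

    bin_factor: int = 4
    window: Literal["hann", "none"] = "hann"
    esf_smoothing: int = 0
    tile: int = 128
    detrend: Literal["mean", "plane"] = "mean"
    fsc_threshold: float = 0.143
    q_slope: float = -0.1775
    q_intercept: float = 1.1192
    dose_rate: float = 7.5  # e-/pixel/s, default flat/edge measurement rate
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        try:
            return cls(**(data or {}))
        except Exception as exc:
            raise DataError(f"invalid config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        return self.model_dump()
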