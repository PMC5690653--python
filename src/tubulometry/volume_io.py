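"""Volume, label-map and measurement-table I/O with explicit conventions.

Conventions used package-wide:

* axis order is ``zyx`` — ``data[page, row, col]``; page 0 is the first TIFF
  page;
* all physical quantities are in μm; voxel indices are 0-based; the physical
  coordinate of voxel ``(i, j, k)`` center is ``index * spacing + origin``;
* intensity volumes are written as 16-bit unsigned multi-page TIFF, label
  volumes as 32-bit unsigned, each with a JSON sidecar recording the voxel
  spacing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_SPACING_UM = 5.0

__all__ = [
    "VoxelVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_measurements",
    "read_measurements",
]


@dataclass
class VoxelVolume:
    """A 3-D scalar intensity grid with physical voxel spacing.

    ``spacing_um`` is per-axis ``(z, y, x)`` voxel size in μm; ``origin_um``
    is the physical coordinate of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("volume needs at least one voxel per axis")
        if np.isscalar(self.spacing_um):
            self.spacing_um = (float(self.spacing_um),) * 3
        else:
            self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("all spacing values must be positive")
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis (n_voxels × spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_um))


@dataclass
class LabelVolume:
    """Integer tubule-instance labels over a voxel grid; 0 is background."""

    labels: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if np.isscalar(self.spacing_um):
            self.spacing_um = (float(self.spacing_um),) * 3
        else:
            self.spacing_um = tuple(float(s) for s in self.spacing_um)
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _read_sidecar(sidecar_path) -> tuple[float, float, float]:
    if sidecar_path is not None and Path(sidecar_path).exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        spacing = meta["spacing_um"]
        if np.isscalar(spacing):
            spacing = (spacing,) * 3
        return tuple(float(s) for s in spacing)
    logger.warning(
        "no spacing sidecar found (%s); defaulting to %.1f um isotropic",
        sidecar_path,
        DEFAULT_SPACING_UM,
    )
    return (DEFAULT_SPACING_UM,) * 3


def _write_sidecar(sidecar_path, spacing_um, grid_shape) -> None:
    meta = {
        "spacing_um": list(spacing_um),
        "axis_order": "zyx",
        "grid_shape": list(int(n) for n in grid_shape),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def _default_sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def read_volume(path, sidecar_path=None) -> VoxelVolume:
    """Read a multi-page TIFF stack into a :class:`VoxelVolume`.

    The resulting shape is ``(n_pages, rows, cols)``.  A missing sidecar
    falls back to 5 μm isotropic spacing with a logged warning.
    """
    if sidecar_path is None:
        sidecar_path = _default_sidecar(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"could not read TIFF volume {path!r}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise OSError(f"{path!r}: expected 2-D or 3-D TIFF, got ndim={data.ndim}")
    return VoxelVolume(data=data, spacing_um=_read_sidecar(sidecar_path))


def write_volume(vol: VoxelVolume, path, sidecar_path=None) -> None:
    """Write a volume as 16-bit unsigned multi-page TIFF + JSON sidecar."""
    if sidecar_path is None:
        sidecar_path = _default_sidecar(path)
    data = np.clip(np.rint(vol.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    _write_sidecar(sidecar_path, vol.spacing_um, vol.data.shape)


def read_labels(path, sidecar_path=None) -> LabelVolume:
    """Read a label volume (any integer TIFF) with its spacing sidecar."""
    if sidecar_path is None:
        sidecar_path = _default_sidecar(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    return LabelVolume(labels=data.astype(np.uint32), spacing_um=_read_sidecar(sidecar_path))


def write_labels(labels: LabelVolume, path, sidecar_path=None) -> None:
    """Write labels as 32-bit unsigned multi-page TIFF + JSON sidecar."""
    if sidecar_path is None:
        sidecar_path = _default_sidecar(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint32), photometric="minisblack")
    _write_sidecar(sidecar_path, labels.spacing_um, labels.labels.shape)


#: stable column order of the per-tubule measurement table
MEASUREMENT_COLUMNS = [
    "tubule_id",
    "summary_diameter_um",
    "n_slices_used",
    "tilt_deg",
    "axis_z",
    "axis_y",
    "axis_x",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "zone",
    "colocalized",
]


def write_measurements(records, path) -> None:
    """Serialize per-tubule measurements to CSV (RFC-4180, header row, UTF-8).

    ``records`` may be a DataFrame or a list of dicts/dataclass-like rows.
    Diameters are written in μm with 4 decimals; one row per tubule.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "to_row"):
                rows.append(r.to_row())
            elif isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(vars(r))
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS if not rows else None)
    if df.empty and not list(df.columns):
        df = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")


def read_measurements(path) -> pd.DataFrame:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path)
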