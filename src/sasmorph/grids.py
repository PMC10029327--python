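"""Voxel containers shared by every pipeline stage.

All volumes are axis-ordered ``(z, y, x)`` with a single isotropic voxel
spacing in micrometres and an integer origin offset (voxels) that places a
tile or crop inside a larger frame. Grayscale data is float32 or float64;
masks are boolean arrays on the same geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class VoxelGrid:
    """A 3D scalar intensity field with isotropic voxel spacing.

    Parameters
    ----------
    data
        3D array, axis order ``(z, y, x)``.
    voxel_size_um
        Edge length of one voxel in micrometres (isotropic).
    origin
        Integer voxel offset of ``data[0, 0, 0]`` in a global frame.
    """

    data: np.ndarray
    voxel_size_um: float = 1.0
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin = tuple(int(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def copy_with(self, data: np.ndarray) -> "VoxelGrid":
        """New grid with the same geometry but different data."""
        return replace(self, data=data)

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            np.asarray(self.data),
            metadata={"voxel_size_um": self.voxel_size_um, "origin": list(self.origin)},
        )

    @classmethod
    def read_tiff(cls, path, voxel_size_um: float | None = None) -> "VoxelGrid":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        vs = voxel_size_um if voxel_size_um is not None else float(meta.get("voxel_size_um", 1.0))
        origin = tuple(meta.get("origin", (0, 0, 0)))
        return cls(data=data, voxel_size_um=vs, origin=origin)

    def write_zarr(self, path, chunks: tuple[int, int, int] | None = None) -> None:
        """Chunked-array store for volumes that stream poorly as TIFF."""
        import zarr

        arr = zarr.create_array(
            store=str(path), shape=self.data.shape, dtype=self.data.dtype,
            chunks=chunks or tuple(min(64, s) for s in self.data.shape),
            overwrite=True,
            attributes={"voxel_size_um": self.voxel_size_um,
                        "origin": list(self.origin)},
        )
        arr[:] = self.data

    @classmethod
    def read_zarr(cls, path) -> "VoxelGrid":
        import zarr

        arr = zarr.open_array(str(path), mode="r")
        return cls(data=arr[:],
                   voxel_size_um=float(arr.attrs.get("voxel_size_um", 1.0)),
                   origin=tuple(arr.attrs.get("origin", (0, 0, 0))))


@dataclass
class BinaryMask:
    """Boolean foreground on a :class:`VoxelGrid` geometry."""

    data: np.ndarray
    voxel_size_um: float = 1.0
    origin: tuple[int, int, int] = (0, 0, 0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin = tuple(int(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def volume_um3(self) -> float:
        """Voxel-count volume (no sub-voxel correction)."""
        return self.voxel_count() * self.voxel_volume_um3

    def copy_with(self, data: np.ndarray, label: str | None = None) -> "BinaryMask":
        return BinaryMask(
            data=np.asarray(data, dtype=bool),
            voxel_size_um=self.voxel_size_um,
            origin=self.origin,
            label=self.label if label is None else label,
        )

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.data.astype(np.uint8) * 255,
            metadata={"voxel_size_um": self.voxel_size_um, "origin": list(self.origin)},
        )

    @classmethod
    def read_tiff(cls, path, voxel_size_um: float | None = None, label: str = "") -> "BinaryMask":
        grid = VoxelGrid.read_tiff(path, voxel_size_um=voxel_size_um)
        return cls(grid.data > 0, voxel_size_um=grid.voxel_size_um, origin=grid.origin, label=label)


def write_json(path, payload: dict) -> None:
    """JSON writer that copes with numpy scalars and arrays."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
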