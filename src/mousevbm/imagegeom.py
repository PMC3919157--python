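"""Volume data model, NIfTI-1 I/O and stereotaxic (bregma) coordinates.

World coordinates follow the Franklin–Paxinos reading convention used in
mouse stereotaxic surgery: millimetres relative to bregma with +x running
left→right (lateral), +y posterior→anterior and +z inferior→superior.
Voxel indices are 0-based.  On disk the voxel-to-world matrix is stored in
the NIfTI sform (code "aligned"), mirrored into the qform when it is
rigid-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "StereotaxicCoordinate",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
]


class VolumeFormatError(ValueError):
    """Raised for files or headers that do not describe a valid 3-D volume."""


@dataclass(frozen=True)
class StereotaxicCoordinate:
    """Bregma-relative position in mm: x lateral, y anterior(+), z superior(+)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Volume3D:
    """A 3-D scalar grid with voxel size (mm) and a voxel→world matrix.

    ``vox2world`` maps homogeneous 0-based voxel indices (i, j, k, 1) to
    Paxinos millimetre coordinates.  ``voxel_size`` must agree with the
    column norms of the matrix's 3×3 block.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    vox2world: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected 3-D data, got {self.data.ndim}-D")
        self.vox2world = np.asarray(self.vox2world, dtype=np.float64)
        if self.vox2world.shape != (4, 4):
            raise VolumeFormatError("vox2world must be 4x4")
        rzs = self.vox2world[:3, :3]
        if abs(np.linalg.det(rzs)) < 1e-12:
            raise VolumeFormatError("vox2world 3x3 block is singular")
        vs = np.asarray(self.voxel_size, dtype=float)
        if np.any(vs <= 0):
            raise VolumeFormatError("voxel sizes must be strictly positive")
        col_norms = np.linalg.norm(rzs, axis=0)
        if np.any(np.abs(col_norms - vs) > 1e-6 * np.maximum(vs, 1.0)):
            raise VolumeFormatError(
                f"voxel_size {tuple(vs)} inconsistent with matrix column norms {tuple(col_norms)}"
            )
        self.voxel_size = (float(vs[0]), float(vs[1]), float(vs[2]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, new data array."""
        return Volume3D(data=data, voxel_size=self.voxel_size,
                        vox2world=self.vox2world.copy(), units=self.units)

    def same_geometry(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.vox2world, other.vox2world, atol=atol))


def default_vox2world(shape: tuple[int, int, int],
                      voxel_size: tuple[float, float, float],
                      bregma_voxel: tuple[float, float, float] | None = None) -> np.ndarray:
    """Diagonal voxel→world matrix placing bregma at ``bregma_voxel`` (default: grid centre)."""
    if bregma_voxel is None:
        bregma_voxel = tuple((n - 1) / 2.0 for n in shape)  # type: ignore[assignment]
    m = np.eye(4)
    for a in range(3):
        m[a, a] = voxel_size[a]
        m[a, 3] = -voxel_size[a] * bregma_voxel[a]
    return m


def read_volume(path) -> Volume3D:
    """Load a single-file NIfTI-1 volume.

    Raises :class:`VolumeFormatError` for non-3-D images or degenerate
    geometry.  Data are returned as float64 regardless of on-disk dtype.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path!r} as NIfTI-1: {exc}") from exc
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # tolerate a singleton 4th dimension
    elif len(shape) != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got {len(shape)} dimensions {shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeFormatError("header voxel-to-world matrix has zero determinant")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data[..., 0]
    voxel_size = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return Volume3D(data=data, voxel_size=voxel_size, vox2world=affine)  # type: ignore[arg-type]


def write_volume(vol: Volume3D, path, dtype=np.float32) -> None:
    """Write ``vol`` as a single-file NIfTI-1 image (sform code 'aligned')."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.vox2world)
    img.header.set_zooms(vol.voxel_size)
    img.set_sform(vol.vox2world, code="aligned")
    img.set_qform(vol.vox2world, code="aligned")
    nib.save(img, str(path))


def voxel_to_world(vol: Volume3D, ijk) -> StereotaxicCoordinate:
    """Map a 0-based voxel index triple to bregma-relative mm."""
    ijk = np.asarray(ijk, dtype=float)
    if np.any(ijk < 0) or np.any(ijk > np.asarray(vol.shape) - 1):
        raise IndexError(f"voxel index {tuple(ijk)} outside grid {vol.shape}")
    xyz = vol.vox2world @ np.append(ijk, 1.0)
    return StereotaxicCoordinate(*xyz[:3])


def world_to_voxel(vol: Volume3D, coord: StereotaxicCoordinate | np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns fractional voxel indices."""
    xyz = coord.as_array() if isinstance(coord, StereotaxicCoordinate) else np.asarray(coord, float)
    inv = np.linalg.inv(vol.vox2world)
    return (inv @ np.append(xyz, 1.0))[:3]
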