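"""Volume containers, NIfTI I/O, coordinate conventions and fixed-grid resampling.

All world coordinates are in millimetres in a right-handed RAS anatomical
frame (+x left->right, +y posterior->anterior, +z inferior->superior).
Voxel indices are 0-based and refer to voxel centres.  Images are
reoriented to the closest canonical (RAS) frame on read so that biometry
downstream is orientation-stable; the sagittal plane is the plane
orthogonal to the x (left-right) axis of this frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Fixed parcellation label dictionary.  The readers accept a JSON sidecar
#: to remap nonstandard on-disk codes onto these.
LABELS: dict[int, str] = {
    0: "background",
    1: "endocervical_canal",
    2: "inner_stroma",
    3: "outer_stroma",
    4: "cyst",
    5: "bladder",
}

BACKGROUND, CANAL, INNER_STROMA, OUTER_STROMA, CYST, BLADDER = range(6)

DEFAULT_SPACING_MM = 0.8  # isotropic resolution of motion-corrected reconstructions


class VolumeError(ValueError):
    """Raised for invalid volumes, geometries or label maps."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel grid geometry: spacing (mm/axis), world origin (mm) and axis directions.

    ``axes`` is an orthonormal 3x3 matrix whose columns map voxel index axes
    to anatomical (world) axes.  The world position of voxel centre ``idx``
    is ``origin + axes @ (idx * spacing)``.
    """

    spacing: np.ndarray = field(default_factory=lambda: np.full(3, DEFAULT_SPACING_MM))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.all(spacing > 0):
            raise VolumeError(f"spacing must be positive on all axes, got {spacing}")
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-6):
            raise VolumeError("direction matrix is not orthonormal within 1e-6")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel-centre convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.axes * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_origin(self, origin: np.ndarray) -> "VoxelGeometry":
        return VoxelGeometry(self.spacing, np.asarray(origin, float), self.axes)

    def close_to(self, other: "VoxelGeometry", atol: float = 1e-5) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )


@dataclass
class IntensityVolume:
    """3D non-negative scalar T2w image with voxel geometry."""

    data: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeError(f"intensity data must be 3D, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3D integer parcellation map; one label code per voxel."""

    data: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"label data must be 3D, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise VolumeError("label data contains non-integer values")
            data = rounded
        self.data = data.astype(np.int16, copy=False)
        self.validate_codes()

    def validate_codes(self) -> None:
        present = np.unique(self.data)
        bad = [int(c) for c in present if int(c) not in self.label_map]
        if bad:
            raise VolumeError(
                f"label value(s) {bad} outside label dictionary {sorted(self.label_map)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given codes."""
        return np.isin(self.data, codes)


Volume = IntensityVolume | LabelVolume


# ---------------------------------------------------------------------------
# coordinates


def voxel_to_world(idx, geom: VoxelGeometry, shape=None) -> np.ndarray:
    """World-mm position of voxel-centre index ``idx`` (0-based).

    ``idx`` may be a single triple or an (N, 3) array.  If ``shape`` is given,
    out-of-bounds indices raise.
    """
    idx = np.asarray(idx, dtype=float)
    if shape is not None:
        shp = np.asarray(shape)
        if np.any(idx < 0) or np.any(idx >= shp):
            raise IndexError(f"voxel index {idx} out of bounds for shape {tuple(shape)}")
    return geom.origin + (idx * geom.spacing) @ geom.axes.T


def world_to_voxel(point, geom: VoxelGeometry) -> np.ndarray:
    """Continuous voxel index of a world-mm point (inverse of voxel_to_world)."""
    point = np.asarray(point, dtype=float)
    return ((point - geom.origin) @ geom.axes) / geom.spacing


# ---------------------------------------------------------------------------
# NIfTI I/O


def _geometry_from_affine(affine: np.ndarray) -> VoxelGeometry:
    rzs = affine[:3, :3]
    spacing = np.linalg.norm(rzs, axis=0)
    if np.any(spacing <= 0):
        raise VolumeError("degenerate NIfTI affine: zero-length axis")
    axes = rzs / spacing[np.newaxis, :]
    return VoxelGeometry(spacing=spacing, origin=affine[:3, 3], axes=axes)


def read_volume(
    path,
    kind: str = "auto",
    label_sidecar=None,
) -> Volume:
    """Read a NIfTI volume, reoriented to the canonical RAS frame.

    Parameters
    ----------
    path : str or Path
        ``.nii``/``.nii.gz`` file.
    kind : {"auto", "intensity", "labels"}
        ``auto`` treats integer-typed data whose values are all label codes
        as a :class:`LabelVolume` and everything else as an
        :class:`IntensityVolume`.
    label_sidecar : str, Path or dict, optional
        JSON sidecar (or mapping) remapping nonstandard on-disk codes to the
        standard dictionary, e.g. ``{"7": 1}`` maps code 7 to the canal.
        If omitted and ``<path>.labels.json`` exists it is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path.name}: expected 3D data, got shape {data.shape}")
    geom = _geometry_from_affine(img.affine)

    looks_integral = np.issubdtype(data.dtype, np.integer) or np.allclose(
        data, np.rint(data), atol=1e-6
    )
    if kind == "auto":
        kind = (
            "labels"
            if looks_integral and set(np.unique(np.rint(data)).astype(int)) <= set(LABELS)
            else "intensity"
        )
    if kind == "labels":
        data = np.rint(data).astype(np.int16)
        remap = _load_sidecar(path, label_sidecar)
        if remap:
            data = _apply_remap(data, remap)
        return LabelVolume(data=data, geometry=geom)
    if kind == "intensity":
        return IntensityVolume(data=data.astype(np.float32), geometry=geom)
    raise ValueError(f"unknown kind {kind!r}")


def _load_sidecar(path: Path, sidecar) -> dict[int, int] | None:
    if isinstance(sidecar, dict):
        return {int(k): int(v) for k, v in sidecar.items()}
    if sidecar is not None:
        return {int(k): int(v) for k, v in json.loads(Path(sidecar).read_text()).items()}
    default = path.with_name(path.name.split(".")[0] + ".labels.json")
    if default.exists():
        return {int(k): int(v) for k, v in json.loads(default.read_text()).items()}
    return None


def _apply_remap(data: np.ndarray, remap: dict[int, int]) -> np.ndarray:
    out = data.copy()
    for src, dst in remap.items():
        out[data == src] = dst
    return out


def write_volume(vol: Volume, path) -> Path:
    """Write a volume to NIfTI; geometry goes into the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        arr = vol.data.astype(np.int16)
    else:
        arr = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, vol.geometry.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# volumetry


def label_volumes_mm3(lab: LabelVolume) -> dict[str, float]:
    """Per-label volume in mm^3 (voxel count x voxel volume).

    Also reports ``total_canal`` = canal + cyst, the aggregate used for the
    normative charts (fluid-filled cysts sit inside the canal lumen).
    """
    vv = lab.geometry.voxel_volume_mm3
    counts = np.bincount(lab.data.ravel(), minlength=max(lab.label_map) + 1)
    out = {name: float(counts[code] * vv) for code, name in sorted(lab.label_map.items())}
    out["total_canal"] = out.get("endocervical_canal", 0.0) + out.get("cyst", 0.0)
    return out


# ---------------------------------------------------------------------------
# fixed-grid resampling


def resample_pad(
    vol: Volume,
    grid: int,
    spacing: float | None = None,
    center_voxel=None,
    guard_codes=None,
):
    """Resample onto an isotropic grid^3 array with zero padding, content centred.

    Intensity volumes are interpolated trilinearly, label volumes
    nearest-neighbour.  If ``spacing`` is given the volume is first resampled
    to that isotropic spacing; otherwise the input spacing is kept (it must
    then be isotropic).  ``center_voxel`` optionally fixes the (input-grid)
    voxel index placed at the output centre — used to keep an image/label
    pair aligned; by default label volumes centre their nonzero bounding box
    and intensity volumes their full extent.

    The anatomy is never silently cropped: if its bounding box does not fit
    in ``grid^3`` after resampling, an error is raised.  ``guard_codes``
    restricts that guarantee to a subset of label codes — e.g. a
    cervix-focused field of view may legitimately truncate the bladder at
    the edge, exactly as a cropped reconstruction would.
    """
    if grid < 1:
        raise VolumeError("grid must be a positive integer")
    is_labels = isinstance(vol, LabelVolume)
    data = vol.data
    geom = vol.geometry
    if spacing is not None:
        factors = geom.spacing / float(spacing)
        data = _rescale(data, factors, order=0 if is_labels else 1)
        geom = VoxelGeometry(np.full(3, float(spacing)), geom.origin, geom.axes)
    elif not np.allclose(geom.spacing, geom.spacing[0]):
        raise VolumeError("anisotropic input: pass an explicit target spacing")

    if center_voxel is None:
        nz = np.nonzero(data)
        if is_labels and nz[0].size:
            center = np.array([(a.min() + a.max()) / 2.0 for a in nz])
        else:
            center = (np.asarray(data.shape) - 1) / 2.0
    else:
        center = np.asarray(center_voxel, dtype=float)

    if is_labels:
        # the anatomy itself is never silently cropped; surrounding FOV of an
        # intensity image may be (the window is centred on the anatomy)
        guarded = np.isin(data, guard_codes) if guard_codes is not None else data != 0
        nz = np.nonzero(guarded)
        if nz[0].size:
            extent = np.array([a.max() - a.min() + 1 for a in nz])
            if np.any(extent > grid):
                raise VolumeError(
                    f"anatomy bounding box {tuple(int(e) for e in extent)} exceeds grid "
                    f"{grid}; refusing to crop"
                )

    out = np.zeros((grid,) * 3, dtype=data.dtype)
    # output voxel o maps to input voxel o + start
    start = np.rint(center - (grid - 1) / 2.0).astype(int)
    in_lo = np.maximum(start, 0)
    in_hi = np.minimum(start + grid, data.shape)
    if np.any(in_lo >= in_hi):
        raise VolumeError("resample window does not overlap the input volume")
    out_lo = in_lo - start
    out_hi = out_lo + (in_hi - in_lo)
    out[out_lo[0]:out_hi[0], out_lo[1]:out_hi[1], out_lo[2]:out_hi[2]] = data[
        in_lo[0]:in_hi[0], in_lo[1]:in_hi[1], in_lo[2]:in_hi[2]
    ]
    new_origin = voxel_to_world(start, geom)
    new_geom = geom.with_origin(new_origin)
    if is_labels:
        return LabelVolume(out, new_geom, dict(vol.label_map))
    return IntensityVolume(out, new_geom)


def _rescale(data: np.ndarray, factors: np.ndarray, order: int) -> np.ndarray:
    """Resample by axis scale factors, voxel-centre convention sharing voxel (0,0,0)."""
    new_shape = np.maximum(1, np.rint(np.asarray(data.shape) * factors)).astype(int)
    coords = np.meshgrid(
        *[np.arange(n) / f for n, f in zip(new_shape, factors)], indexing="ij"
    )
    out = ndimage.map_coordinates(
        data.astype(np.float32), np.stack(coords), order=order, mode="nearest"
    )
    if order == 0:
        out = np.rint(out).astype(data.dtype)
    return out
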