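"""Volumes on regular grids: NIfTI I/O, resampling, masks, coordinates.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)``; world coordinates are RAS mm
  obtained through the NIfTI affine.  Template-space coordinates are
  reported as MNI mm.
* The canonical template grid is 91 x 109 x 91 voxels, 2 mm isotropic,
  origin (-90, -126, -72) -- the standard MNI 2 mm bounding box.
* Out-of-field resampling values: 0 for dose/stat maps, -1024 for CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "MaskVolume",
    "AtlasVolume",
    "GridSpec",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "resample_to",
    "make_brain_mask",
    "voxel_to_world",
    "world_to_voxel",
    "AIR_HU",
]

#: CT padding value for out-of-field voxels (air).
AIR_HU = -1024.0


@dataclass
class GridSpec:
    """Regular-grid geometry: shape, isotropic-or-not spacing and origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @classmethod
    def mni_2mm(cls) -> "GridSpec":
        """Standard MNI 2 mm bounding box used for template-space output."""
        return cls(shape=(91, 109, 91), spacing=(2.0, 2.0, 2.0),
                   origin=(-90.0, -126.0, -72.0))

    @classmethod
    def centered(cls, shape, spacing) -> "GridSpec":
        """Grid of ``shape`` voxels at ``spacing`` mm centred on world 0."""
        shape = tuple(int(s) for s in np.broadcast_to(shape, 3))
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, 3))
        origin = tuple(-(n - 1) * d / 2.0 for n, d in zip(shape, spacing))
        return cls(shape=shape, spacing=spacing, origin=origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size along each axis in mm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid centre."""
        return (np.asarray(self.origin)
                + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) for every voxel."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                for a in range(3)]
        return (axes[0][:, None, None], axes[1][None, :, None],
                axes[2][None, None, :])


@dataclass
class Volume:
    """A 3D scalar grid plus its voxel-index -> world-mm affine.

    ``data`` carries HU for CT, Gy for dose, or unitless statistic values.
    ``space`` tags whether the volume lives in subject or template space.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"grid dimensions must be positive: {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return type(self)(data=self.data.copy() if data is None else data,
                          affine=self.affine.copy(), space=self.space)

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=atol))


@dataclass
class MaskVolume(Volume):
    """Binary mask on the same grid as its parent volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be strictly binary {0, 1}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclass
class AtlasVolume(Volume):
    """Integer label volume plus a label -> (region, lobe) table.

    Label 0 is background and must not appear in the table.
    """

    label_table: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.rint(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels missing from label_table: {sorted(missing)}")

    def region_name(self, label: int) -> str:
        return self.label_table[label][0]

    def lobe_name(self, label: int) -> str:
        return self.label_table[label][1]

    def labels_for_lobe(self, lobe: str) -> list[int]:
        out = [lab for lab, (_, lo) in self.label_table.items() if lo == lobe]
        if not out:
            known = sorted({lo for _, lo in self.label_table.values()})
            raise KeyError(f"lobe {lobe!r} not in atlas table (known: {known})")
        return out


def read_volume(path: str | Path, space: str = "subject") -> Volume:
    """Read a 3D NIfTI-1/2 image, applying scl_slope/scl_inter scaling.

    Raises on missing files, non-3D images and singular affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises various subclasses
        raise ValueError(f"{path} is not a readable NIfTI image: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise ValueError(f"{path} is not NIfTI-1/2 (got {type(img).__name__})")
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # tolerate trailing singleton
    elif len(shape) != 3:
        raise ValueError(f"{path} is not a 3D image (shape {shape})")
    data = np.asarray(img.get_fdata(dtype=np.float64))  # applies scaling
    if data.ndim == 4:
        data = data[..., 0]
    if np.iscomplexobj(data):
        raise ValueError("complex-valued images are not supported")
    return Volume(data=data, affine=np.asarray(img.affine), space=space)


def write_volume(vol: Volume, path: str | Path, dtype=None) -> None:
    """Write ``vol`` as NIfTI; dtype defaults to float32 (uint8 for masks)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if dtype is None:
        dtype = np.uint8 if isinstance(vol, MaskVolume) else np.float32
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_atlas(path: str | Path, table_path: str | Path,
               space: str = "template") -> AtlasVolume:
    """Read an atlas NIfTI and its TSV table (columns label, region[, lobe])."""
    vol = read_volume(path, space=space)
    table: dict[int, tuple[str, str]] = {}
    for line in Path(table_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label\t"):
            continue
        parts = line.split("\t")
        label = int(parts[0])
        region = parts[1]
        lobe = parts[2] if len(parts) > 2 else region
        table[label] = (region, lobe)
    return AtlasVolume(data=vol.data, affine=vol.affine, space=space,
                       label_table=table)


def write_atlas(atlas: AtlasVolume, path: str | Path,
                table_path: str | Path) -> None:
    write_volume(atlas, path, dtype=np.int16)
    lines = ["label\tregion\tlobe"]
    for lab in sorted(atlas.label_table):
        region, lobe = atlas.label_table[lab]
        lines.append(f"{lab}\t{region}\t{lobe}")
    Path(table_path).write_text("\n".join(lines) + "\n")


_INTERP_ORDER = {"linear": 1, "nearest": 0}


def resample_to(vol: Volume, reference: Volume | GridSpec,
                interpolation: str = "linear", cval: float = 0.0) -> Volume:
    """Resample ``vol`` onto the grid of ``reference``.

    Values are sampled at the world points of the reference grid; points
    outside the input field of view get ``cval`` (0 for dose, use
    :data:`AIR_HU` for CT).  Use ``nearest`` for masks and atlases.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    ref_affine = reference.affine
    ref_shape = reference.shape
    # output voxel -> input voxel map
    M = np.linalg.inv(vol.affine) @ ref_affine
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), M[:3, :3], offset=M[:3, 3],
        output_shape=tuple(ref_shape), order=_INTERP_ORDER[interpolation],
        mode="constant", cval=cval, prefilter=False)
    space = reference.space if isinstance(reference, Volume) else vol.space
    if isinstance(vol, MaskVolume):
        return MaskVolume(data=(out > 0.5).astype(np.uint8),
                          affine=ref_affine.copy(), space=space)
    if isinstance(vol, AtlasVolume):
        return AtlasVolume(data=out, affine=ref_affine.copy(), space=space,
                           label_table=dict(vol.label_table))
    return Volume(data=out, affine=ref_affine.copy(), space=space)


def make_brain_mask(template: Volume, hu_threshold: float = -500.0) -> MaskVolume:
    """Binarize a CT-like template into a brain/head mask.

    Threshold, keep the largest 26-connected component, fill holes.  The
    default threshold of -500 HU separates tissue from air.
    """
    raw = template.data > hu_threshold
    if not raw.any():
        raise ValueError(
            f"empty mask: no voxels above {hu_threshold} HU "
            f"(max {template.data.max():.1f})")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        raw = labels == counts.argmax()
    filled = ndimage.binary_fill_holes(raw)
    return MaskVolume(data=filled.astype(np.uint8), affine=template.affine.copy(),
                      space=template.space)


def voxel_to_world(index, affine) -> np.ndarray:
    """Map 0-based voxel indices to world mm: ``affine @ (i, j, k, 1)``."""
    index = np.atleast_2d(np.asarray(index, dtype=float))
    pts = index @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return pts[0] if pts.shape[0] == 1 else pts


def world_to_voxel(point, affine) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (continuous voxel coordinates)."""
    inv = np.linalg.inv(np.asarray(affine))
    point = np.atleast_2d(np.asarray(point, dtype=float))
    vox = point @ inv[:3, :3].T + inv[:3, 3]
    return vox[0] if vox.shape[0] == 1 else vox
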