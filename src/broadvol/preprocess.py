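"""Volume preprocessing for the ensemble classifier.

Heterogeneous NIfTI scans are brought onto a common footing in three steps,
applied in this order:

1. resample to isotropic voxels (default 1.5 mm),
2. rescale intensities to a fixed range (default (0, 1)),
3. crop (or zero-pad) to a fixed grid centred on the volume centre
   (default 224 x 224 x 128 voxels, i.e. 336 x 336 x 192 mm at 1.5 mm).

All operations are total and deterministic; smaller-than-target inputs are
symmetrically zero-padded so the pipeline also accepts small synthetic
phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._exceptions import DimensionalityError

log = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "PreprocessConfig",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "scale_intensity",
    "center_crop",
    "preprocess_volume",
]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and world-affine metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in native voxel order.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-coordinate transform.
    id : str
        Subject/scan identifier.
    """

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume {self.id!r}: expected 3 axes, got {self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class PreprocessConfig:
    """Configuration of the three-step preprocessing chain.

    ``clip_percentiles`` optionally winsorizes intensities (e.g. ``(1, 99)``)
    before min-max scaling; off by default.  ``interpolation_order`` 1 is
    trilinear; 0 (nearest) is appropriate for label maps.  ``to_ras``
    reorients to closest-canonical RAS before anything else; off by default
    because volumes are used in native voxel order.
    """

    target_spacing_mm: float = 1.5
    intensity_range: tuple = (0.0, 1.0)
    crop_shape: tuple = (224, 224, 128)
    interpolation_order: int = 1
    clip_percentiles: tuple | None = None
    to_ras: bool = False

    def __post_init__(self):
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be > 0")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError(f"intensity_range must satisfy lo < hi, got {self.intensity_range}")
        self.crop_shape = tuple(int(c) for c in self.crop_shape)
        if len(self.crop_shape) != 3 or any(c <= 0 for c in self.crop_shape):
            raise ValueError(f"crop_shape must be three positive integers, got {self.crop_shape}")

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def load_volume(path) -> Volume:
    """Load a 3D NIfTI-1/NIfTI-2 file as a :class:`Volume`.

    Trailing singleton axes (a common NIfTI quirk) are squeezed; a genuine
    4D time series raises :class:`DimensionalityError`.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except DimensionalityError:
        raise
    except Exception as exc:  # corrupt/unreadable file
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {data.ndim} axes {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol_id = path.name
    for suffix in (".nii.gz", ".nii"):
        if vol_id.endswith(suffix):
            vol_id = vol_id[: -len(suffix)]
            break
    return Volume(data=data, spacing=spacing, affine=img.affine, id=vol_id)


def save_volume(v: Volume, path) -> None:
    """Write a :class:`Volume` to a NIfTI-1 file, preserving spacing."""
    img = nib.Nifti1Image(v.data, v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def resample_isotropic(v: Volume, target_spacing_mm: float, order: int = 1) -> Volume:
    """Resample onto an isotropic grid of ``target_spacing_mm`` voxels.

    The output grid has ``round(shape * spacing / target)`` voxels per axis,
    preserving the physical extent to within one voxel.  Interpolation is
    spline of the given ``order`` (1 = trilinear; 0 = nearest for labels).
    """
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be > 0")
    t = float(target_spacing_mm)
    in_shape = np.array(v.shape)
    out_shape = np.rint(in_shape * np.array(v.spacing) / t).astype(int)
    if np.any(out_shape < 1):
        raise ValueError(
            f"resampling {v.shape} at spacing {v.spacing} to {t} mm yields "
            f"degenerate shape {tuple(out_shape)}"
        )
    scale = in_shape / out_shape  # input voxels per output voxel
    new_affine = v.affine.copy()
    new_affine[:, :3] = new_affine[:, :3] * scale
    if tuple(out_shape) == tuple(in_shape) and np.allclose(v.spacing, t):
        data = v.data.copy()
    else:
        data = ndimage.zoom(
            np.asarray(v.data, dtype=float),
            zoom=out_shape / in_shape,  # guarantees the computed output shape
            order=order,
            mode="nearest",
            grid_mode=True,
        )
    return Volume(data=data, spacing=(t, t, t), affine=new_affine, id=v.id)


def scale_intensity(v: Volume, lo: float = 0.0, hi: float = 1.0) -> Volume:
    """Affinely map intensities so min -> ``lo`` and max -> ``hi``.

    A constant-valued volume cannot be min-max scaled; it maps to all-``lo``
    with a logged warning rather than producing NaN.
    """
    x = np.asarray(v.data, dtype=float)
    xmin, xmax = float(x.min()), float(x.max())
    if xmax == xmin:
        log.warning("volume %r is constant-valued; intensity scaling maps it to %g", v.id, lo)
        data = np.full_like(x, lo)
    else:
        data = (x - xmin) / (xmax - xmin) * (hi - lo) + lo
    return replace(v, data=data)


def center_crop(v: Volume, crop_shape: tuple) -> Volume:
    """Crop (or zero-pad) to ``crop_shape``, centred on the grid centre.

    Crop offsets are ``floor((in - out) / 2)`` per axis; axes smaller than
    the target are symmetrically zero-padded (left pad ``floor((out-in)/2)``).
    Total on inputs of any size.
    """
    crop_shape = tuple(int(c) for c in crop_shape)
    data = v.data
    offsets = []  # voxel-index shift of the new origin in the old grid
    for ax, (n, m) in enumerate(zip(data.shape, crop_shape)):
        if n >= m:
            start = (n - m) // 2
            data = data[(slice(None),) * ax + (slice(start, start + m),)]
            offsets.append(start)
        else:
            left = (m - n) // 2
            right = m - n - left
            pad = [(0, 0)] * data.ndim
            pad[ax] = (left, right)
            data = np.pad(data, pad, mode="constant")
            offsets.append(-left)
    new_affine = v.affine.copy()
    new_affine[:3, 3] = (v.affine @ np.array([*offsets, 1.0]))[:3]
    return Volume(data=data, spacing=v.spacing, affine=new_affine, id=v.id)


def preprocess_volume(source, cfg: PreprocessConfig | None = None) -> Volume:
    """Run the full chain (resample -> scale -> crop) on a path or Volume."""
    cfg = cfg or PreprocessConfig()
    v = source if isinstance(source, Volume) else load_volume(source)
    if cfg.to_ras:
        img = nib.Nifti1Image(v.data, v.affine)
        img = nib.as_closest_canonical(img)
        v = Volume(
            data=np.asanyarray(img.dataobj),
            spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
            affine=img.affine,
            id=v.id,
        )
    v = resample_isotropic(v, cfg.target_spacing_mm, order=cfg.interpolation_order)
    if cfg.clip_percentiles is not None:
        plo, phi = np.percentile(v.data, cfg.clip_percentiles)
        v = replace(v, data=np.clip(v.data, plo, phi))
    v = scale_intensity(v, *cfg.intensity_range)
    return center_crop(v, cfg.crop_shape)
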