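"""Volume preprocessing and peritumoral ring construction.

Images are plain 3-D scalar grids with physical voxel spacing (mm) and an
origin: ``values[i, j, k]`` sits at world coordinate
``origin + (i, j, k) * spacing``, with the first index the fastest-varying
(x) axis — the same convention nibabel uses for a diagonal-affine NIfTI.

The preprocessing chain mirrors standard chest-CT radiomics practice:
resample to 1 mm isotropic with B-spline interpolation, window the HU range
to the lung setting (-1200 to 600 HU) and rescale to 0-255, then build
peritumoral shells by physical-unit Euclidean dilation clipped to the lung.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "RingSpec",
    "resample_isotropic",
    "window_scale",
    "dilate_ring",
    "read_nifti",
    "write_nifti",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar image with physical spacing and origin (both in mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return dataclasses.replace(self, values=values)


@dataclass(frozen=True)
class MaskVolume:
    """A binary label grid on the same lattice as a companion ImageVolume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={values.ndim}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be binary, found {uniq[:10]}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "MaskVolume":
        return dataclasses.replace(self, values=values)


@dataclass(frozen=True)
class RingSpec:
    """Peritumoral shell definition: thickness in mm plus optional exclusion."""

    thickness_mm: float = 5.0
    exclusion: MaskVolume | None = None

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError(f"ring thickness must be > 0 mm, got {self.thickness_mm}")


def _grids_aligned(a, b, atol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def resample_isotropic(
    image: ImageVolume | MaskVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "bspline",
) -> ImageVolume | MaskVolume:
    """Resample a volume onto a new (typically 1 mm isotropic) grid.

    ``mode="bspline"`` uses cubic B-spline interpolation for intensity
    images; ``mode="nearest"`` must be used for masks so they stay binary.
    The output grid has ``ceil(extent / target)`` voxels per axis, so the
    physical extent is preserved to within one voxel per axis.
    """
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be 3 positive numbers, got {target_spacing}")
    if mode not in ("bspline", "nearest"):
        raise ValueError(f"mode must be 'bspline' or 'nearest', got {mode!r}")
    if isinstance(image, MaskVolume) and mode != "nearest":
        raise ValueError("masks must be resampled with mode='nearest'")

    spacing = image.spacing
    if np.allclose(spacing, target):
        return image

    values = image.values.astype(np.float64)
    old_shape = values.shape
    new_shape = tuple(
        int(np.ceil(n * s / t)) for n, s, t in zip(old_shape, spacing, target)
    )
    # Voxel-centre alignment: new centre j*t + t/2 maps to old index
    # (j*t + t/2 - s/2) / s, keeping the first voxel corner fixed.
    coords = np.meshgrid(
        *[
            (np.arange(m) * t + t / 2 - s / 2) / s
            for m, s, t in zip(new_shape, spacing, target)
        ],
        indexing="ij",
    )
    order = 3 if mode == "bspline" else 0
    out = ndimage.map_coordinates(
        values, np.stack(coords), order=order, mode="nearest"
    )
    if isinstance(image, MaskVolume):
        return MaskVolume(out > 0.5, spacing=target, origin=image.origin)
    return ImageVolume(out, spacing=target, origin=image.origin)


def window_scale(
    image: ImageVolume,
    lo: float = -1200.0,
    hi: float = 600.0,
    out_max: float = 255.0,
) -> ImageVolume:
    """Clamp HU to [lo, hi] and linearly rescale to [0, out_max].

    Defaults match the lung window used for ablation CT review: -1200 to
    600 HU mapped onto 0-255.
    """
    if lo >= hi:
        raise ValueError(f"window lower bound must be < upper bound, got [{lo}, {hi}]")
    scaled = (np.clip(image.values, lo, hi) - lo) / (hi - lo) * out_max
    return image.with_values(scaled)


def dilate_ring(
    mask: MaskVolume,
    spec: RingSpec,
    lung: MaskVolume | None = None,
) -> MaskVolume:
    """Construct the peritumoral shell around a mask.

    The ring is the set of voxels whose Euclidean distance to the mask —
    computed in physical mm, honouring anisotropic spacing — lies in
    ``(0, thickness]``, intersected with the lung mask and with any
    exclusion mask removed. The ring is always disjoint from the input.
    """
    if mask.voxel_count() == 0:
        raise ValueError("cannot dilate an empty mask")
    if lung is not None and not _grids_aligned(mask, lung):
        raise ValueError("lung mask grid is not aligned with the target mask")
    if spec.exclusion is not None and not _grids_aligned(mask, spec.exclusion):
        raise ValueError("exclusion mask grid is not aligned with the target mask")

    # distance transform restricted to a padded bounding box: the ring lies
    # within thickness of the mask, so the crop is exact
    idx = np.argwhere(mask.values)
    pad = [int(np.ceil(spec.thickness_mm / s)) + 1 for s in mask.spacing]
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    dist = ndimage.distance_transform_edt(~mask.values[sl], sampling=mask.spacing)
    ring = np.zeros(mask.shape, dtype=bool)
    ring[sl] = (dist > 0) & (dist <= spec.thickness_mm)
    if lung is not None:
        ring &= lung.values
    if spec.exclusion is not None:
        ring &= ~spec.exclusion.values
    return mask.with_values(ring)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_nifti(volume: ImageVolume | MaskVolume, path) -> None:
    data = volume.values
    if isinstance(volume, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_nifti(path, as_mask: bool = False) -> ImageVolume | MaskVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    if as_mask:
        return MaskVolume(data > 0.5, spacing=spacing, origin=origin)
    return ImageVolume(data.astype(np.float64), spacing=spacing, origin=origin)
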