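"""CT volume I/O and the nodule-centred preprocessing chain.

The pipeline mirrors standard LUNA16-style preparation: HU clipping to
[-1000, 600], lung-field restriction, resampling to 1 mm isotropic voxels,
window normalisation with per-volume de-averaging, and cropping of
11x64x64 regions of interest centred on each annotated nodule.  Arrays are
indexed (z, y, x); world coordinates follow the annotations.csv convention
(x, y, z) in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "CTVolume", "NoduleAnnotation", "ROISample", "load_volume",
    "load_annotations", "clip_hu", "extract_lung_mask", "apply_lung_mask",
    "resample_isotropic", "normalize_volume", "world_to_voxel", "crop_roi",
    "sphere_mask_from_annotation", "preprocess_case",
    "HU_LO", "HU_HI", "ROI_SIZE", "DIAMETER_RANGE_MM",
]

HU_LO, HU_HI = -1000.0, 600.0
ROI_SIZE = (11, 64, 64)
DIAMETER_RANGE_MM = (3.170, 27.442)
LUNG_AIR_THRESHOLD_HU = -320.0
ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar volume with physical geometry, indexed (z, y, x)."""

    voxels: np.ndarray
    spacing: tuple          # mm per axis, (z, y, x)
    origin: tuple           # world mm of voxel (0,0,0), (z, y, x)
    intensity_domain: str = "HU"

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {self.voxels.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass(frozen=True)
class NoduleAnnotation:
    """One nodule record: world-mm centre (x, y, z) and diameter."""

    series_id: str
    center_world: tuple
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError(
                f"diameter must be positive, got {self.diameter_mm} "
                f"for series {self.series_id}")


@dataclass(frozen=True)
class ROISample:
    """A nodule-centred 11x64x64 image/mask pair, the network's input unit."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str
    center_voxel: tuple

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shapes differ: {self.image.shape} vs {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


# ------------------------------------------------------------------------ I/O

def load_volume(path) -> CTVolume:
    """Read a MetaImage (.mhd/.raw) or NIfTI volume with its geometry."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path!s}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path!s}: expected a 3D volume, got {img.GetDimension()}D")
    vox = sitk.GetArrayFromImage(img).astype(np.float32)   # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))            # -> (z, y, x)
    origin = tuple(reversed(img.GetOrigin()))
    return CTVolume(vox, spacing, origin, intensity_domain="HU")


def save_volume(vol: CTVolume, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels))
    img.SetSpacing(tuple(reversed([float(s) for s in vol.spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in vol.origin])))
    sitk.WriteImage(img, str(path))


def load_annotations(path) -> list:
    """Parse a LUNA16-dialect annotations CSV into NoduleAnnotation records."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path!s}: missing columns {missing}; expected header "
            f"{','.join(ANNOTATION_COLUMNS)}")
    anns = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        if row.diameter_mm <= 0:
            raise ValueError(
                f"{path!s} row {row_number}: non-positive diameter "
                f"{row.diameter_mm}")
        anns.append(NoduleAnnotation(
            series_id=str(row.seriesuid),
            center_world=(float(row.coordX), float(row.coordY), float(row.coordZ)),
            diameter_mm=float(row.diameter_mm)))
    out_of_range = [a for a in anns
                    if not DIAMETER_RANGE_MM[0] <= a.diameter_mm <= DIAMETER_RANGE_MM[1]]
    if out_of_range:
        warnings.warn(
            f"{len(out_of_range)} annotation(s) outside the expected diameter "
            f"range {DIAMETER_RANGE_MM} mm", stacklevel=2)
    return anns


def save_annotations(anns, path) -> None:
    rows = [{"seriesuid": a.series_id, "coordX": a.center_world[0],
             "coordY": a.center_world[1], "coordZ": a.center_world[2],
             "diameter_mm": a.diameter_mm} for a in anns]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------- HU handling

def clip_hu(vol: CTVolume, lo: float = HU_LO, hi: float = HU_HI) -> CTVolume:
    """Clamp intensities to the retained HU window."""
    if lo >= hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    if vol.intensity_domain != "HU":
        raise ValueError("clip_hu expects a volume in Hounsfield units")
    return replace(vol, voxels=np.clip(vol.voxels, lo, hi))


def extract_lung_mask(vol: CTVolume) -> np.ndarray:
    """Segment the lung fields of a clipped HU volume.

    Air-like voxels (< -320 HU) are labelled; components touching the
    volume border (outside air) are discarded; the two largest remaining
    components are kept as the lungs and closed with a radius-2 ball.
    Degenerate inputs without an interior air component fail open to an
    all-true mask with a warning so synthetic slabs pass through unharmed.
    """
    air = vol.voxels < LUNG_AIR_THRESHOLD_HU
    labels, n = ndimage.label(air)
    if n:
        border = np.zeros(vol.shape, bool)
        border[0], border[-1] = True, True
        border[:, 0], border[:, -1] = True, True
        border[:, :, 0], border[:, :, -1] = True, True
        touching = np.unique(labels[border & air])
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        sizes[touching] = 0
        keep = np.argsort(sizes)[::-1][:2]
        keep = keep[sizes[keep] > 0]
    else:
        keep = []
    if len(keep) == 0:
        warnings.warn("no interior air component found; returning all-true "
                      "lung mask", stacklevel=2)
        return np.ones(vol.shape, bool)
    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=_ball(2))
    # dense structures inside the parenchyma (nodules, vessels) are not
    # air-like; fill them back in so masking never erases the target
    return ndimage.binary_fill_holes(mask)


def _ball(radius):
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return zz * zz + yy * yy + xx * xx <= r * r


def apply_lung_mask(vol: CTVolume, mask: np.ndarray, fill: float = HU_LO) -> CTVolume:
    """Restrict the volume to the lung fields, filling elsewhere with `fill`."""
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    return replace(vol, voxels=np.where(mask, vol.voxels, np.float32(fill)))


# ----------------------------------------------------------------- geometry

def resample_isotropic(vol: CTVolume, target_spacing: float = 1.0,
                       is_mask: bool = False) -> CTVolume:
    """Resample to isotropic voxels (trilinear; nearest-neighbour for masks)."""
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        vol.voxels.astype(np.uint8 if is_mask else np.float32)))
    img.SetSpacing(tuple(reversed([float(s) for s in vol.spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in vol.origin])))
    new_size = [int(round(n * s / target_spacing))
                for n, s in zip(reversed(vol.shape), reversed(vol.spacing))]
    res = sitk.Resample(
        img, new_size, sitk.Transform(),
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        img.GetOrigin(), (target_spacing,) * 3, img.GetDirection(),
        0 if is_mask else float(vol.voxels.min()),
        sitk.sitkUInt8 if is_mask else sitk.sitkFloat32)
    out = sitk.GetArrayFromImage(res)
    return CTVolume(out.astype(np.float32), (target_spacing,) * 3, vol.origin,
                    intensity_domain=vol.intensity_domain)


def normalize_volume(vol: CTVolume) -> CTVolume:
    """Map the retained HU window linearly to [0,1], then subtract the mean."""
    if vol.intensity_domain == "normalized":
        raise ValueError("volume is already normalized")
    scaled = (vol.voxels - HU_LO) / (HU_HI - HU_LO)
    scaled -= scaled.mean()
    return CTVolume(scaled.astype(np.float32), vol.spacing, vol.origin,
                    intensity_domain="normalized")


def world_to_voxel(ann: NoduleAnnotation, vol: CTVolume) -> tuple:
    """Round the annotation's world-mm (x,y,z) centre to a (z,y,x) index."""
    wx, wy, wz = ann.center_world
    oz, oy, ox = vol.origin
    sz, sy, sx = vol.spacing
    idx = (int(round((wz - oz) / sz)), int(round((wy - oy) / sy)),
           int(round((wx - ox) / sx)))
    if any(i < 0 or i >= n for i, n in zip(idx, vol.shape)):
        raise ValueError(
            f"annotation {ann.series_id} at world {ann.center_world} maps to "
            f"voxel {idx}, outside volume of shape {vol.shape}")
    return idx


def crop_roi(vol: CTVolume, mask: np.ndarray, center: tuple,
             size: tuple = ROI_SIZE, source_id: str = "") -> ROISample:
    """Extract a zero-padded patch with `center` at the patch midpoint.

    The centre voxel lands at patch index (size//2) per axis, i.e. (5,32,32)
    for the default 11x64x64 window; out-of-volume regions are zero-filled.
    """
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    img = np.zeros(size, np.float32)
    msk = np.zeros(size, np.uint8)
    halves = tuple(s // 2 for s in size)
    starts = [c - h for c, h in zip(center, halves)]
    src, dst = [], []
    for st, sz, n in zip(starts, size, vol.shape):
        lo, hi = max(st, 0), min(st + sz, n)
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    if all(s.stop > s.start for s in src):
        img[tuple(dst)] = vol.voxels[tuple(src)]
        msk[tuple(dst)] = mask[tuple(src)]
    filled = np.prod([d.stop - d.start for d in dst])
    if filled < 0.5 * np.prod(size):
        warnings.warn(f"ROI at {center} is more than half padding", stacklevel=2)
    return ROISample(img, msk, source_id, tuple(center))


def sphere_mask_from_annotation(ann: NoduleAnnotation, vol: CTVolume) -> np.ndarray:
    """Diameter-sphere proxy ground truth around the annotated centre.

    At least the centre voxel is set even for sub-voxel diameters.
    """
    zz, yy, xx = np.meshgrid(
        *[o + s * np.arange(n) for o, s, n in zip(vol.origin, vol.spacing, vol.shape)],
        indexing="ij")
    wx, wy, wz = ann.center_world
    d2 = (zz - wz) ** 2 + (yy - wy) ** 2 + (xx - wx) ** 2
    mask = d2 <= (ann.diameter_mm / 2.0) ** 2
    if not mask.any():
        mask[world_to_voxel(ann, vol)] = True
    return mask


# ------------------------------------------------------------------ pipeline

def preprocess_case(vol: CTVolume, annotations, gt_mask: np.ndarray = None,
                    hu_lo: float = HU_LO, hu_hi: float = HU_HI,
                    target_spacing: float = 1.0) -> list:
    """Run the full chain and crop one ROISample per annotation.

    Order is fixed: clip -> lung-mask -> resample -> normalize -> crop.
    When no ground-truth mask volume is supplied, the diameter-sphere proxy
    is rendered on the resampled grid.
    """
    clipped = clip_hu(vol, hu_lo, hu_hi)
    lung = extract_lung_mask(clipped)
    masked = apply_lung_mask(clipped, lung, fill=hu_lo)
    iso = resample_isotropic(masked, target_spacing)
    if gt_mask is not None:
        gt_iso = resample_isotropic(
            CTVolume(gt_mask.astype(np.float32), vol.spacing, vol.origin),
            target_spacing, is_mask=True).voxels.astype(np.uint8)
    norm = normalize_volume(iso)
    samples = []
    for ann in annotations:
        center = world_to_voxel(ann, norm)
        gm = gt_iso if gt_mask is not None else sphere_mask_from_annotation(ann, norm)
        samples.append(crop_roi(norm, np.asarray(gm).astype(np.uint8), center,
                                source_id=ann.series_id))
    return samples
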