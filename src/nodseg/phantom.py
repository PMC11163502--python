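"""Synthetic LUNA16-format phantom cases.

Each case is a CT-like volume (body ellipse of soft tissue containing two
air-density lung fields) with one nodule of a chosen archetype, an exact
binary ground-truth mask, a lung-field label, and a LUNA16-dialect
annotation row.  Realism is deliberately minimal -- ellipsoids, tubes and
Gaussian noise -- because the phantoms exist to exercise the preprocessing
chain and the learning dynamics, not to imitate radiology.

Archetypes:

* ``solid_isolated``  -- well-circumscribed nodule inside the lung field;
* ``wall_adherent``   -- nodule centred on the lung boundary so it merges
  with the chest wall;
* ``ggo``             -- ground-glass opacity: reduced contrast and a wide
  smoothed edge;
* ``vessel_adherent`` -- a 1-2 mm soft-tissue tube pierces the nodule
  surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import (CTVolume, NoduleAnnotation, DIAMETER_RANGE_MM,
                         save_annotations, save_volume)

__all__ = ["PhantomSpec", "PhantomCase", "ARCHETYPES", "generate_phantom",
           "write_case", "generate_dataset"]

ARCHETYPES = ("solid_isolated", "wall_adherent", "ggo", "vessel_adherent")

HU_AIR = -1000.0
HU_LUNG = -850.0
HU_SOFT = 40.0
HU_SOLID_NODULE = 20.0
HU_GGO_NODULE = -550.0
HU_BONE = 1200.0


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity recipe for one phantom case."""

    archetype: str = "solid_isolated"
    volume_shape: tuple = (40, 96, 96)          # (z, y, x) voxels
    spacing: tuple = (1.0, 1.0, 1.0)            # mm, (z, y, x)
    nodule_center: tuple = None                 # world mm (x, y, z); default: in-lung
    radii: tuple = (4.0, 4.0, 4.0)              # mm, (z, y, x) semi-axes
    nodule_hu: float = None                     # default per archetype
    lung_hu: float = HU_LUNG
    edge_sigma_mm: float = None                 # default per archetype
    vessel_radius_mm: float = 1.5
    noise_sd: float = 12.0                      # HU
    seed: int = 0
    series_id: str = "phantom-0"

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise PhantomSpecError(
                f"unknown archetype {self.archetype!r}; valid: {ARCHETYPES}")
        d = 2.0 * max(self.radii)
        if not DIAMETER_RANGE_MM[0] <= d <= DIAMETER_RANGE_MM[1]:
            raise PhantomSpecError(
                f"nodule diameter {d:.2f} mm outside the emulated range "
                f"{DIAMETER_RANGE_MM}")


@dataclass(frozen=True)
class PhantomCase:
    volume: CTVolume
    mask: np.ndarray
    lung_label: np.ndarray
    annotation: NoduleAnnotation


def _world_grids(shape, spacing):
    axes = [s * np.arange(n, dtype=np.float64) for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")       # zz, yy, xx in world mm


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.volume_shape, spec.spacing
    zz, yy, xx = _world_grids(shape, spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    cz, cy, cx = [e / 2.0 for e in extent]

    vol = np.full(shape, HU_AIR, np.float64)
    body = (((yy - cy) / (0.46 * extent[1])) ** 2
            + ((xx - cx) / (0.48 * extent[2])) ** 2) <= 1.0
    vol[body] = HU_SOFT

    lungs = np.zeros(shape, bool)
    lung_geom = []
    for side in (-1.0, +1.0):
        lcx = cx + side * 0.22 * extent[2]
        rz, ry, rx = 0.42 * extent[0], 0.30 * extent[1], 0.18 * extent[2]
        ell = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
               + ((xx - lcx) / rx) ** 2) <= 1.0
        lungs |= ell
        lung_geom.append((lcx, rz, ry, rx))
    vol[lungs] = spec.lung_hu

    # nodule placement: default inside the right lung field
    lcx, rz, ry, rx = lung_geom[1]
    if spec.nodule_center is None:
        if spec.archetype == "wall_adherent":
            center = (lcx + 0.95 * rx, cy, cz)           # world (x, y, z)
        else:
            center = (lcx + 0.25 * rx, cy - 0.1 * ry, cz)
    else:
        center = tuple(float(c) for c in spec.nodule_center)
    wx, wy, wz = center
    in_lung = (((wz - cz) / rz) ** 2 + ((wy - cy) / ry) ** 2) + \
        min(((wx - lung_geom[0][0]) / lung_geom[0][3]) ** 2,
            ((wx - lcx) / rx) ** 2)
    if in_lung > 1.0 and spec.archetype != "wall_adherent":
        raise PhantomSpecError(
            f"nodule centre {center} lies outside the lung fields")

    nod_hu = spec.nodule_hu
    if nod_hu is None:
        nod_hu = HU_GGO_NODULE if spec.archetype == "ggo" else HU_SOLID_NODULE
    sigma_mm = spec.edge_sigma_mm
    if sigma_mm is None:
        sigma_mm = 1.5 if spec.archetype == "ggo" else 0.6

    nrz, nry, nrx = spec.radii
    mask = (((zz - wz) / nrz) ** 2 + ((yy - wy) / nry) ** 2
            + ((xx - wx) / nrx) ** 2) <= 1.0

    if spec.archetype == "vessel_adherent":
        # soft-tissue tube along y through a point on the nodule surface
        tube = ((zz - wz) ** 2 + (xx - (wx + nrx)) ** 2) \
            <= spec.vessel_radius_mm ** 2
        vol[tube & lungs] = HU_SOFT

    alpha = ndimage.gaussian_filter(
        mask.astype(np.float64), sigma=[sigma_mm / s for s in spacing])
    vol = vol * (1.0 - alpha) + nod_hu * alpha

    # sparse bone/air speckles exercise the HU clipping stage
    n_speck = max(4, int(vol.size * 1e-5))
    idx = tuple(rng.integers(0, s, n_speck) for s in shape)
    vol[idx] = np.where(rng.random(n_speck) < 0.5, HU_BONE, -1024.0)

    vol += rng.normal(0.0, spec.noise_sd, shape)

    ann = NoduleAnnotation(series_id=spec.series_id, center_world=(wx, wy, wz),
                           diameter_mm=2.0 * max(spec.radii))
    ct = CTVolume(vol.astype(np.float32), spacing, (0.0, 0.0, 0.0), "HU")
    return PhantomCase(ct, mask.astype(np.uint8), lungs.astype(np.uint8), ann)


def write_case(case: PhantomCase, out_dir) -> dict:
    """Write MetaImage volume + mask and append the annotations.csv row."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    sid = case.annotation.series_id
    vol_path = out / f"{sid}.mhd"
    mask_path = out / "masks" / f"{sid}.mhd"
    save_volume(case.volume, vol_path)
    save_volume(CTVolume(case.mask.astype(np.float32), case.volume.spacing,
                         case.volume.origin, "HU"), mask_path)
    csv_path = out / "annotations.csv"
    existing = []
    if csv_path.exists():
        from .preprocess import load_annotations
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            existing = load_annotations(csv_path)
    save_annotations(existing + [case.annotation], csv_path)
    return {"volume": vol_path, "mask": mask_path, "annotations": csv_path}


def generate_dataset(n: int, seed: int, out_dir, mix: dict = None,
                     anisotropic: bool = False) -> list:
    """Generate n phantom cases with archetypes drawn per `mix`.

    Archetype counts follow a deterministic largest-remainder allocation of
    the mix proportions; the master seed fans out one child seed per case.
    With ``anisotropic=True`` the slice spacing is drawn uniformly from
    [0.45, 3.0] mm to exercise isotropic resampling.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    mix = dict(mix) if mix else {a: 0.25 for a in ARCHETYPES}
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"mix proportions must sum to 1, got {sum(mix.values())}")
    counts = {a: int(np.floor(mix.get(a, 0.0) * n)) for a in ARCHETYPES}
    rema = sorted(ARCHETYPES,
                  key=lambda a: (mix.get(a, 0.0) * n) % 1.0, reverse=True)
    i = 0
    while sum(counts.values()) < n:
        counts[rema[i % len(rema)]] += 1
        i += 1
    order = [a for a in ARCHETYPES for _ in range(counts[a])]

    master = np.random.default_rng(seed)
    cases = []
    for k, arch in enumerate(order):
        case_rng = np.random.default_rng(master.integers(0, 2 ** 31))
        sz = float(case_rng.uniform(0.45, 3.0)) if anisotropic else 1.0
        nz = max(12, int(round(40 / sz)))
        radii = tuple(case_rng.uniform(2.2, 6.5, 3).round(2))
        spec = PhantomSpec(
            archetype=arch,
            volume_shape=(nz, 96, 96),
            spacing=(sz, 1.0, 1.0),
            radii=radii,
            noise_sd=12.0,
            seed=int(case_rng.integers(0, 2 ** 31)),
            series_id=f"phantom-{seed}-{k:03d}-{arch}")
        case = generate_phantom(spec)
        write_case(case, out_dir)
        cases.append(case)
    return cases
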