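"""Generate a synthetic chest phantom and run the preprocessing chain.

The phantom is written in the LUNA16 layout (MetaImage volume + one
annotations.csv row + mask volume), read back, clipped to [-1000, 600] HU,
lung-masked, resampled to 1 mm, normalised, and cropped to the 11x64x64
nodule-centred region of interest the network consumes.
"""

import tempfile
from pathlib import Path

import numpy as np

from nodseg.phantom import PhantomSpec, generate_phantom, write_case
from nodseg.preprocess import load_annotations, load_volume, preprocess_case

case = generate_phantom(PhantomSpec(archetype="vessel_adherent",
                                    radii=(5.0, 4.0, 4.0), seed=42,
                                    series_id="demo"))
with tempfile.TemporaryDirectory() as d:
    write_case(case, d)
    vol = load_volume(Path(d) / "demo.mhd")
    (ann,) = load_annotations(Path(d) / "annotations.csv")

print(f"volume {vol.shape} at spacing {vol.spacing} mm, "
      f"HU range [{vol.voxels.min():.0f}, {vol.voxels.max():.0f}]")
print(f"annotation: centre {ann.center_world} mm, diameter {ann.diameter_mm} mm")

(roi,) = preprocess_case(vol, [ann], gt_mask=case.mask)
print(f"ROI image {roi.image.shape}, intensity mean {roi.image.mean():+.4f} "
      f"(de-averaged), mask voxels {roi.mask.sum()} "
      f"(~{4 / 3 * np.pi * 5 * 4 * 4:.0f} expected for the ellipsoid)")
print("mask present at the centre voxel:", bool(roi.mask[5, 32, 32]))
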