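"""Generate one synthetic head phantom and look at what it contains.

The phantom is a parametric head-and-neck CT: an ellipsoidal head with
skull, brain, eyes (with lenses and bony orbital rims), C1-C3 vertebrae
and a neck, plus exact reference apertures for each beam side and caudal
extent. Every case is fully determined by its seed.
"""

import numpy as np

from autowbrt import PhantomSpec, generate_phantom

case = generate_phantom(PhantomSpec(seed=42))

print(f"case id:            {case.case_id}")
print(f"CT grid (z, y, x):  {case.ct.shape} voxels at {case.ct.spacing_mm} mm")
print(f"clinical extent:    {case.clinical_extent}  (caudal field border target)")
print(f"structures:         {', '.join(case.structures.names())}")

iso = np.asarray(case.isocenter_mm)
print(f"isocenter (mm):     {np.round(iso, 1)}  -- the brain centroid; "
      "dose is normalized to 100% here")

hu = case.ct.hu
print(f"HU range:           {hu.min():.0f} (air) .. {hu.max():.0f} (bone)")

brain = case.masks["brain"]
vox_cc = np.prod(case.ct.spacing_mm) / 1000.0
print(f"brain volume:       {brain.sum() * vox_cc:.0f} cm^3")

for (side, extent), ap in sorted(case.reference_apertures.items()):
    area = ap.mask.pixels.sum() * ap.mask.grid.pixel_spacing_mm ** 2 / 100.0
    print(f"reference aperture  {side:14s} {extent}: {area:6.1f} cm^2 open")
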