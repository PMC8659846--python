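#!/usr/bin/env python
"""Generate the synthetic bone phantom and the six resection scenarios.

Builds the parametric hemipelvis stand-in (broad homogeneous crest band =
C region, narrow high-curvature notch = S region), verifies the regional
curvature contrast, places the six paired guide scenarios, and exports
everything (STL + JSON) so later stages and external tools can ingest the
same geometry.
"""

from pathlib import Path
import json

import numpy as np
import trimesh

from psiplace import PhantomSpec, make_cases, make_phantom_mesh, save_mesh
from psiplace.synthetic_data import _S_CENTER_UV

OUT = Path(__file__).resolve().parent.parent / "results" / "phantom"
OUT.mkdir(parents=True, exist_ok=True)

spec = PhantomSpec(seed=0)
mesh = make_phantom_mesh(spec)
print(f"phantom: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces, "
      f"extents {np.round(mesh.extents, 1)} mm")

# regional curvature contrast (angle defects, radians)
defects = np.abs(trimesh.curvature.vertex_defects(mesh))
uu, vv = np.meshgrid(np.linspace(0, 1, spec.n_u), np.linspace(0, 1, spec.n_v),
                     indexing="ij")
u, v = uu.ravel(), vv.ravel()
c_band = (v > 0.02) & (v < 0.25) & (u > 0.08) & (u < 0.92)
u0, v0 = _S_CENTER_UV
s_area = (np.abs(u - u0) < 0.08) & (np.abs(v - v0) < 0.10)
print(f"max |angle defect|  crest band: {defects[c_band].max():.4f} rad, "
      f"supra-acetabular notch: {defects[s_area].max():.4f} rad")

cases = make_cases(mesh, seed=0)
print("cases (footprints, mm):")
for s_case, c_case in cases:
    print(f"  case {s_case.case_id}: S {s_case.footprint_size_mm:.0f}  "
          f"C {c_case.footprint_size_mm:.0f}  C plane origin "
          f"{np.round(c_case.plane.origin, 1)}")

save_mesh(mesh, OUT / "phantom.stl")
(OUT / "cases.json").write_text(
    json.dumps([[c.to_dict() for c in pair] for pair in cases], indent=2)
)
print(f"written: {OUT / 'phantom.stl'}, {OUT / 'cases.json'}")
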