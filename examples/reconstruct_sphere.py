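"""Reconstruct a sphere isosurface with both edge-interpolation modes.

Builds a signed-distance sphere volume (positive inside), runs marching
cubes with classic linear interpolation and with the value-independent
midpoint rule, and prints mesh size, topology and geometric accuracy.
The two meshes always share triangle/vertex counts and connectivity;
only the vertex positions along the crossed edges differ.
"""

import numpy as np

from dermamesh import (
    FieldSpec,
    IsosurfaceSpec,
    deduplicate,
    extract_isosurface,
    generate_volume,
    mesh_report,
)

center, radius, h = (3.1, 3.1, 3.1), 2.05, 0.2
volume = generate_volume(
    FieldSpec(kind="sphere", center=center, radius=radius),
    dims=(32, 32, 32),
    spacing=(h, h, h),
)

for mode in ("linear", "midpoint"):
    soup = extract_isosurface(volume, IsosurfaceSpec(isovalue=0.0, mode=mode))
    mesh = deduplicate(soup)
    report = mesh_report(mesh)
    radii = np.linalg.norm(mesh.vertices - np.asarray(center), axis=1)
    err = np.abs(radii - radius)
    print(
        f"{mode:>8}: {report.triangle_count} triangles, {report.vertex_count} vertices, "
        f"watertight={report.watertight}, Euler={report.euler_characteristic}, "
        f"radial error mean={err.mean():.4f} max={err.max():.4f} (bound sqrt(3)h={np.sqrt(3)*h:.4f}), "
        f"divisions={soup.interpolator_divisions}"
    )

# Equal counts confirm the interpolation choice only moves vertices along
# edges; the radial-error columns quantify the accuracy the midpoint rule
# trades away (still within one cell diagonal of the true sphere).
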