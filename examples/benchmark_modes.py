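"""Benchmark linear vs midpoint extraction on a torus volume.

Prints triangle/vertex counts (always equal across modes), the per-vertex
displacement statistics between the two meshes, the interpolator division
counters, and wall-clock times.  Times depend entirely on the machine and
are shown for orientation only.
"""

from dermamesh import FieldSpec, compare_modes, generate_volume

volume = generate_volume(
    FieldSpec(kind="torus", center=(19.5, 19.5, 11.5), ring_radius=9.0, tube_radius=4.2),
    dims=(40, 40, 24),
)
cmp = compare_modes(volume, isovalue=0.0)

print(f"triangles: linear {cmp.triangle_count_linear}, midpoint {cmp.triangle_count_midpoint}")
print(f"vertices:  linear {cmp.vertex_count_linear}, midpoint {cmp.vertex_count_midpoint}")
print(f"divisions: linear {cmp.divisions_linear}, midpoint {cmp.divisions_midpoint}")
print(f"vertex displacement between modes: max {cmp.max_vertex_displacement:.4f}, "
      f"mean {cmp.mean_vertex_displacement:.4f} (edge length 1.0)")
print(f"wall clock (this machine only): linear {cmp.seconds_linear:.3f}s, "
      f"midpoint {cmp.seconds_midpoint:.3f}s, saved {cmp.speedup_percent:.1f}%")

# The midpoint rule removes the per-vertex division entirely; identical
# counts show the topology is untouched, and the displacement statistics
# bound how far any vertex moved (never more than half an edge).
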