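"""Side-by-side comparison of the linear and midpoint extraction modes.

Both modes march the same cells and look up the same case table, so the
triangle count, vertex count and connectivity are identical; the i-th
triangle corner of one soup corresponds to the i-th of the other, which
makes per-vertex displacement between modes well defined.  Wall-clock
times are measured and reported for orientation only — they depend on
the machine and are never asserted anywhere.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .marching import IsosurfaceSpec, extract_isosurface
from .mesh import deduplicate
from .volume import ScalarVolume


@dataclass(frozen=True)
class ModeComparison:
    isovalue: float
    triangle_count_linear: int
    triangle_count_midpoint: int
    vertex_count_linear: int
    vertex_count_midpoint: int
    seconds_linear: float
    seconds_midpoint: float
    max_vertex_displacement: float
    mean_vertex_displacement: float
    divisions_linear: int
    divisions_midpoint: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    @property
    def speedup_percent(self) -> float:
        """Relative time saved by the midpoint mode (informational only)."""
        if self.seconds_linear == 0:
            return 0.0
        return 100.0 * (self.seconds_linear - self.seconds_midpoint) / self.seconds_linear


def compare_modes(volume: ScalarVolume, isovalue: float, inside_rule: str = ">=") -> ModeComparison:
    """Extract with both interpolation modes and compare the results."""
    soups = {}
    seconds = {}
    for mode in ("linear", "midpoint"):
        spec = IsosurfaceSpec(isovalue=isovalue, inside_rule=inside_rule, mode=mode)
        t0 = time.perf_counter()
        soups[mode] = extract_isosurface(volume, spec)
        seconds[mode] = time.perf_counter() - t0
    lin, mid = soups["linear"], soups["midpoint"]
    if lin.n_triangles and lin.n_triangles == mid.n_triangles:
        disp = np.linalg.norm(lin.triangles - mid.triangles, axis=-1)
        max_disp, mean_disp = float(disp.max()), float(disp.mean())
    else:
        max_disp = mean_disp = 0.0
    return ModeComparison(
        isovalue=isovalue,
        triangle_count_linear=lin.n_triangles,
        triangle_count_midpoint=mid.n_triangles,
        vertex_count_linear=deduplicate(lin).n_vertices,
        vertex_count_midpoint=deduplicate(mid).n_vertices,
        seconds_linear=seconds["linear"],
        seconds_midpoint=seconds["midpoint"],
        max_vertex_displacement=max_disp,
        mean_vertex_displacement=mean_disp,
        divisions_linear=lin.interpolator_divisions,
        divisions_midpoint=mid.interpolator_divisions,
    )
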