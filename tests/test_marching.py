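"""Marching-cubes extraction: sampling, case indexing, edge intersections,
gradients, and whole-volume properties on analytic fixtures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dermamesh import (
    Cell,
    FieldSpec,
    IsosurfaceSpec,
    ScalarVolume,
    cell_case_index,
    deduplicate,
    edge_intersection_linear,
    edge_intersection_midpoint,
    extract_isosurface,
    generate_volume,
    gradient_central_difference,
    trilinear_sample,
)
from dermamesh.marching import trilinear_coefficients
from dermamesh.tables import CORNER_OFFSETS
from dermamesh.volume import VolumeError

from conftest import SPHERE_CENTER, SPHERE_RADIUS


def reference_trilinear(corners, u, v, w):
    """Independent 8-term blend, written out term by term."""
    weights = {}
    for k, (ox, oy, oz) in enumerate(CORNER_OFFSETS):
        wx = u if ox == 1 else (1.0 - u)
        wy = v if oy == 1 else (1.0 - v)
        wz = w if oz == 1 else (1.0 - w)
        weights[k] = wx * wy * wz
    return sum(weights[k] * corners[k] for k in range(8))


class TestTrilinearSampling:
    def test_corner_and_constant_values(self):
        cell = Cell(base=(0, 0, 0), corners=tuple(float(k) for k in range(8)))
        for k, off in enumerate(CORNER_OFFSETS):
            assert trilinear_sample(cell, off) == pytest.approx(float(k))
        const = Cell(base=(0, 0, 0), corners=(5.0,) * 8)
        assert trilinear_sample(const, (0.5, 0.5, 0.5)) == 5.0

    def test_outside_point_rejected(self):
        cell = Cell(base=(0, 0, 0), corners=(0.0,) * 8)
        with pytest.raises(ValueError):
            trilinear_sample(cell, (1.2, 0.0, 0.0))

    @given(
        st.lists(st.floats(-100, 100), min_size=8, max_size=8),
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
    )
    def test_blend_matches_reference_and_polynomial_form(self, corners, u, v, w):
        """The blend, the independent term-by-term sum, and the 8-coefficient
        polynomial expansion agree to 1e-12 on random cells."""
        cell = Cell(base=(0, 0, 0), corners=tuple(corners))
        direct = trilinear_sample(cell, (u, v, w))
        assert direct == pytest.approx(reference_trilinear(corners, u, v, w), abs=1e-9)
        b = trilinear_coefficients(cell)
        poly = (
            b[0] + b[1] * u + b[2] * v + b[3] * w
            + b[4] * u * v + b[5] * v * w + b[6] * w * u + b[7] * u * v * w
        )
        assert abs(direct - poly) <= 1e-9 * max(1.0, max(abs(c) for c in corners))

    def test_coefficients_reproduce_corners_exactly(self):
        rng = np.random.default_rng(11)
        corners = tuple(rng.uniform(-10, 10, 8))
        cell = Cell(base=(0, 0, 0), corners=corners)
        b = trilinear_coefficients(cell)
        for k, (u, v, w) in enumerate(CORNER_OFFSETS):
            poly = (
                b[0] + b[1] * u + b[2] * v + b[3] * w
                + b[4] * u * v + b[5] * v * w + b[6] * w * u + b[7] * u * v * w
            )
            assert poly == pytest.approx(corners[k], abs=1e-12)


class TestCaseIndex:
    def test_all_below_and_all_above(self):
        spec = IsosurfaceSpec(isovalue=5.0)
        assert cell_case_index(Cell(base=(0, 0, 0), corners=(1.0,) * 8), spec) == 0
        assert cell_case_index(Cell(base=(0, 0, 0), corners=(9.0,) * 8), spec) == 255

    def test_single_corner_inside_sets_single_bit(self):
        for k in range(8):
            corners = [0.0] * 8
            corners[k] = 9.0
            idx = cell_case_index(Cell(base=(0, 0, 0), corners=tuple(corners)), IsosurfaceSpec(5.0))
            assert idx == 1 << k

    def test_inside_rule_controls_ties(self):
        cell = Cell(base=(0, 0, 0), corners=(5.0,) * 8)
        assert cell_case_index(cell, IsosurfaceSpec(5.0, inside_rule=">=")) == 255
        assert cell_case_index(cell, IsosurfaceSpec(5.0, inside_rule=">")) == 0


class TestEdgeIntersections:
    def test_linear_crossing_parameter(self):
        p = edge_intersection_linear((0, 0, 0), (1, 0, 0), 0.0, 10.0, 5.0)
        np.testing.assert_allclose(p, [0.5, 0, 0])
        p = edge_intersection_linear((0, 0, 0), (1, 0, 0), 0.0, 10.0, 2.5)
        np.testing.assert_allclose(p, [0.25, 0, 0])

    def test_uncrossed_edge_rejected(self):
        with pytest.raises(ValueError):
            edge_intersection_linear((0, 0, 0), (1, 0, 0), 1.0, 2.0, 5.0)

    def test_midpoint_coordinates_are_half_offsets(self):
        """An x-edge at (x, y, z) intersects at (x + 1/2, y, z); likewise
        for the y and z axes — independent of the sample values."""
        np.testing.assert_array_equal(
            edge_intersection_midpoint((1, 2, 3), (2, 2, 3)), [1.5, 2, 3]
        )
        np.testing.assert_array_equal(
            edge_intersection_midpoint((4, 0, 7), (4, 1, 7)), [4, 0.5, 7]
        )
        np.testing.assert_array_equal(
            edge_intersection_midpoint((0, 0, 0), (0, 0, 1)), [0, 0, 0.5]
        )

    def test_midpoint_requires_axis_aligned_edge(self):
        with pytest.raises(ValueError):
            edge_intersection_midpoint((0, 0, 0), (1, 1, 0))

    def test_modes_coincide_when_isovalue_is_the_endpoint_mean(self):
        p_lin = edge_intersection_linear((0, 0, 0), (1, 0, 0), 2.0, 8.0, 5.0)
        p_mid = edge_intersection_midpoint((0, 0, 0), (1, 0, 0))
        np.testing.assert_allclose(p_lin, p_mid)


class TestGradients:
    def test_exact_on_linear_fields(self):
        vol = generate_volume(
            FieldSpec(kind="linear_ramp", gradient=(2.0, -3.0, 0.5)),
            (6, 6, 6),
            spacing=(0.5, 1.0, 2.0),
        )
        for idx in [(2, 3, 1), (1, 1, 1), (4, 4, 4)]:
            np.testing.assert_allclose(
                gradient_central_difference(vol, idx), [2.0, -3.0, 0.5], atol=1e-12
            )

    def test_zero_on_constant_volume(self):
        vol = ScalarVolume(np.full((4, 4, 4), 3.0))
        np.testing.assert_array_equal(gradient_central_difference(vol, (2, 2, 2)), [0, 0, 0])

    def test_quadratic_field_gives_exact_centered_derivative(self):
        """For f = x^2 on a unit grid the centered stencil gives exactly 2x."""
        x = np.arange(7, dtype=float)
        samples = np.broadcast_to((x**2)[:, None, None], (7, 7, 7)).copy()
        vol = ScalarVolume(samples)
        for xi in range(1, 6):
            g = gradient_central_difference(vol, (xi, 3, 3))
            assert g[0] == pytest.approx(2.0 * xi)

    def test_boundary_uses_one_sided_difference(self):
        x = np.arange(5, dtype=float)
        vol = ScalarVolume(np.broadcast_to((x**2)[:, None, None], (5, 5, 5)).copy())
        assert gradient_central_difference(vol, (0, 2, 2))[0] == pytest.approx(1.0)  # f(1)-f(0)
        assert gradient_central_difference(vol, (4, 2, 2))[0] == pytest.approx(7.0)  # f(4)-f(3)


class TestExtraction:
    def test_constant_volume_yields_empty_soup(self):
        vol = ScalarVolume(np.full((5, 5, 5), 2.0))
        soup = extract_isosurface(vol, IsosurfaceSpec(isovalue=7.0))
        assert soup.n_triangles == 0

    def test_nan_volume_rejected(self):
        samples = np.zeros((4, 4, 4))
        vol = ScalarVolume(samples)
        vol.samples[0, 0, 0] = np.nan  # corrupt after validation
        with pytest.raises(VolumeError):
            extract_isosurface(vol, IsosurfaceSpec(isovalue=0.5))

    def test_single_inside_corner_yields_one_triangle_on_incident_edges(self):
        samples = np.zeros((2, 2, 2))
        samples[0, 1, 0] = 1.0  # corner D0 of the only cell
        vol = ScalarVolume(samples)
        soup = extract_isosurface(vol, IsosurfaceSpec(isovalue=0.5, mode="linear"))
        assert soup.n_triangles == 1
        # each vertex lies on one of the three edges incident to (0, 1, 0)
        for v in soup.triangles[0]:
            assert sorted(np.abs(v - np.array([0, 1, 0]))) == pytest.approx([0, 0, 0.5])

    @pytest.mark.parametrize("fixture", ["sphere_volume", "torus_volume", "noise_volume"])
    def test_mode_equivalence_of_topology(self, fixture, request):
        """Linear and midpoint extraction agree on triangle count, vertex
        count and face connectivity; vertices move along edges only, by at
        most half an edge length."""
        vol = request.getfixturevalue(fixture)
        lin = extract_isosurface(vol, IsosurfaceSpec(0.0, mode="linear"))
        mid = extract_isosurface(vol, IsosurfaceSpec(0.0, mode="midpoint"))
        assert lin.n_triangles == mid.n_triangles > 0
        mesh_lin, mesh_mid = deduplicate(lin), deduplicate(mid)
        assert mesh_lin.n_vertices == mesh_mid.n_vertices
        np.testing.assert_array_equal(mesh_lin.faces, mesh_mid.faces)
        displacement = np.linalg.norm(lin.triangles - mid.triangles, axis=-1)
        assert displacement.max() <= 0.5 * max(vol.spacing) + 1e-12

    def test_median_is_an_alias_for_midpoint(self, sphere_volume):
        a = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="midpoint"))
        b = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="median"))
        np.testing.assert_array_equal(a.triangles, b.triangles)

    @pytest.mark.parametrize("mode", ["linear", "midpoint"])
    def test_sphere_vertices_within_one_cell_diagonal_of_surface(self, sphere_volume, mode):
        """Every emitted vertex lies on a crossed edge, hence within
        sqrt(3) * h of the true sphere."""
        soup = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode=mode))
        verts = soup.triangles.reshape(-1, 3)
        radii = np.linalg.norm(verts - np.asarray(SPHERE_CENTER), axis=1)
        h = max(sphere_volume.spacing)
        assert np.abs(radii - SPHERE_RADIUS).max() <= np.sqrt(3) * h

    def test_linear_mode_is_closer_to_the_true_sphere_on_average(self, sphere_volume):
        lin = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="linear"))
        mid = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="midpoint"))
        center = np.asarray(SPHERE_CENTER)

        def mean_err(soup):
            radii = np.linalg.norm(soup.triangles.reshape(-1, 3) - center, axis=1)
            return np.abs(radii - SPHERE_RADIUS).mean()

        assert mean_err(lin) < mean_err(mid)

    def test_normals_point_outward_on_positive_inside_sphere(self, sphere_volume):
        soup = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="linear"))
        mesh = deduplicate(soup)
        radial = mesh.vertices - np.asarray(SPHERE_CENTER)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert (np.einsum("ij,ij->i", mesh.normals, radial) > 0).all()

    def test_triangle_winding_matches_outward_normals(self, sphere_volume):
        """Vertex order is counter-clockwise seen from the normal side:
        geometric triangle normals also point outward."""
        soup = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="linear"))
        tri = soup.triangles
        geo = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centers = tri.mean(axis=1) - np.asarray(SPHERE_CENTER)
        assert (np.einsum("ij,ij->i", geo, centers) > 0).all()

    def test_division_counter_zero_in_midpoint_mode(self, sphere_volume):
        """The midpoint interpolator performs no per-vertex division; the
        linear one performs exactly one per unique crossed edge."""
        mid = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="midpoint"))
        lin = extract_isosurface(sphere_volume, IsosurfaceSpec(0.0, mode="linear"))
        assert mid.interpolator_divisions == 0
        assert lin.interpolator_divisions == deduplicate(lin).n_vertices

    def test_anisotropic_spacing_lands_vertices_in_physical_space(self):
        vol = generate_volume(
            FieldSpec(kind="sphere", center=(4.0, 4.0, 4.0), radius=2.5),
            (9, 9, 5),
            spacing=(1.0, 1.0, 2.0),
        )
        soup = extract_isosurface(vol, IsosurfaceSpec(0.0, mode="linear"))
        verts = soup.triangles.reshape(-1, 3)
        radii = np.linalg.norm(verts - 4.0, axis=1)
        assert np.abs(radii - 2.5).max() <= np.sqrt(3) * 2.0


class TestReferenceOracle:
    @pytest.mark.parametrize("fixture,iso", [("sphere_volume", 0.0), ("torus_volume", 0.0)])
    def test_counts_and_vertices_match_reference_implementation(self, fixture, iso, request):
        from scipy.spatial import cKDTree
        from skimage.measure import marching_cubes

        vol = request.getfixturevalue(fixture)
        mesh = deduplicate(extract_isosurface(vol, IsosurfaceSpec(iso, mode="linear")))
        verts, faces, _, _ = marching_cubes(
            vol.samples, level=iso, method="lorensen", spacing=vol.spacing
        )
        assert mesh.n_vertices == len(verts)
        assert mesh.n_triangles == len(faces)
        d, _ = cKDTree(np.asarray(verts, dtype=np.float64)).query(mesh.vertices - np.asarray(vol.origin))
        assert d.max() <= 1e-6
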