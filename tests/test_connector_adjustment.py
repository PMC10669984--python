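"""The displacement law, its invariants, and the area-matching solver."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpdremodel.connector_adjustment import (
    AdjustmentSpec,
    ConnectorPointSet,
    adjust_connector,
    apply_displacement,
    bezier_weight,
    max_safe_k,
    select_points,
    solve_k,
)
from fpdremodel.connector_detection import LocalFrame
from fpdremodel.errors import InputError, ParameterError, SolverError
from fpdremodel.mesh_io import TriangleMesh


class TestBezierWeight:
    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_endpoints(self, w):
        assert bezier_weight(0.0, w) == w**4
        assert bezier_weight(w, w) == 0.0

    def test_halfway_hand_evaluation(self):
        # (0.5)^3*1 + 3*0.5*(0.5)^2*0.9 + 3*0.25*0.5*0.1 = 0.125+0.3375+0.0375
        assert bezier_weight(0.5, 1.0) == pytest.approx(0.5, abs=1e-15)

    def test_strictly_decreasing(self):
        t = np.linspace(0.0, 1.0, 1000)
        b = bezier_weight(t, 1.0)
        assert np.all(np.diff(b) < 0)

    def test_clamped_outside_domain(self):
        assert bezier_weight(-0.5, 1.0) == 1.0
        assert bezier_weight(1.5, 1.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        w=st.floats(min_value=0.05, max_value=10.0),
        s=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_bernstein_form(self, w, s):
        """B(t) = w^4 * Bernstein cubic with control values (1, .9, .1, 0)."""
        t = s * w
        bern = (
            (1 - s) ** 3 * 1.0
            + 3 * s * (1 - s) ** 2 * 0.9
            + 3 * s**2 * (1 - s) * 0.1
        )
        assert bezier_weight(t, w) == pytest.approx(w**4 * bern, rel=1e-9)


def _manual_points(local, w=1.0):
    local = np.asarray(local, float)
    return ConnectorPointSet(indices=np.arange(len(local)), local=local, w=w)


class TestSelectPoints:
    def test_matches_direct_distance_scan(self, dumbbell, dumbbell_detection):
        """Selection equals an independent |distance to plane| < w scan."""
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        site = sites[0]
        pts = select_points(mesh, site, w=1.0)
        d = np.abs((mesh.vertices - site.frame.origin) @ site.frame.z_axis)
        assert np.array_equal(pts.indices, np.flatnonzero(d < 1.0))
        assert np.all(pts.d_xy < 1.0)

    def test_strict_boundary_exclusion(self):
        frame = LocalFrame(
            origin=np.zeros(3),
            x_axis=np.array([1.0, 0, 0]),
            y_axis=np.array([0, 1.0, 0]),
            z_axis=np.array([0, 0, 1.0]),
        )

        class Site:
            pass

        site = Site()
        site.frame = frame
        v = np.array(
            [[1, 0, 0.0], [1, 0, 0.5], [1, 0, 1.0], [1, 0, 1.5]], dtype=float
        )
        mesh = TriangleMesh(v, np.array([[0, 1, 2], [1, 2, 3]]))
        pts = select_points(mesh, site, w=1.0)
        assert list(pts.indices) == [0, 1]  # z = 1.0 (== w) excluded

    def test_w_larger_than_mesh(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        pts = select_points(mesh, sites[0], w=1e3)
        assert len(pts.indices) == mesh.n_vertices

    def test_empty_selection_raises(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        with pytest.raises(InputError):
            select_points(mesh, sites[0], w=1e-9)

    def test_subsets_disjoint_by_sign(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        pts = select_points(mesh, sites[0], w=1.0)
        assert not np.any(pts.subset("occlusal") & pts.subset("gingival"))
        assert not np.any(pts.subset("buccal") & pts.subset("lingual"))


class TestApplyDisplacement:
    def test_k_zero_identity_bitexact(self):
        rng = np.random.default_rng(1)
        pts = _manual_points(rng.uniform(-0.9, 0.9, (50, 3)))
        out = apply_displacement(pts, 0.0, 1.0, "iso")
        assert np.array_equal(out, pts.local)

    def test_single_vertex_hand_computation(self):
        # x = 2, d_xy = 0 => B = w^4 = 1; x_new = 2 - 0.1*2*1*2 = 1.6
        pts = _manual_points([[2.0, 0.0, 0.0]])
        out = apply_displacement(pts, 0.1, 1.0, "occlusal")
        assert out[0, 0] == pytest.approx(1.6, abs=1e-15)

    def test_x_zero_plane_fixed(self):
        pts = _manual_points([[0.0, 0.4, 0.2], [0.0, -1.0, -0.5]])
        out = apply_displacement(pts, 0.3, 1.0, "iso")
        assert np.array_equal(out[:, 0], pts.local[:, 0])

    def test_continuity_at_selection_boundary(self):
        pts = _manual_points([[1.0, 0.0, 1.0 - 1e-9]])
        out = apply_displacement(pts, 0.5, 1.0, "occlusal")
        assert abs(out[0, 0] - 1.0) < 1e-6

    def test_untouched_coordinates_bitexact(self):
        rng = np.random.default_rng(2)
        local = rng.uniform(-0.9, 0.9, (100, 3))
        pts = _manual_points(local)
        out = apply_displacement(pts, 0.05, 1.0, "occlusal")
        assert np.array_equal(out[:, 1:], local[:, 1:])  # y, z untouched
        gin = pts.subset("gingival")
        assert np.array_equal(out[gin, 0], local[gin, 0])

    def test_gingival_mirror_of_occlusal(self):
        """Mirroring x and swapping occ/gin gives mirrored displacements."""
        rng = np.random.default_rng(3)
        local = rng.uniform(-0.9, 0.9, (200, 3))
        mirrored = local * np.array([-1.0, 1.0, 1.0])
        k = 0.2
        out_occ = apply_displacement(_manual_points(local), k, 1.0, "occlusal")
        out_gin = apply_displacement(_manual_points(mirrored), k, 1.0, "gingival")
        assert np.allclose(out_gin[:, 0], -out_occ[:, 0], atol=1e-6)
        # iso preserves the mirror symmetry as well
        out_iso_a = apply_displacement(_manual_points(local), k, 1.0, "iso")
        out_iso_b = apply_displacement(_manual_points(mirrored), k, 1.0, "iso")
        assert np.allclose(out_iso_b[:, 0], -out_iso_a[:, 0], atol=1e-6)
        assert np.allclose(out_iso_b[:, 1], out_iso_a[:, 1], atol=1e-6)

    def test_foldover_guard(self):
        pts = _manual_points([[2.0, 0.0, 0.0]])
        kmax = max_safe_k(pts, "occlusal")
        with pytest.raises(ParameterError):
            apply_displacement(pts, kmax * 1.5, 1.0, "occlusal")

    def test_negative_k_rejected(self):
        pts = _manual_points([[1.0, 0.0, 0.0]])
        with pytest.raises(ParameterError):
            apply_displacement(pts, -0.1, 1.0, "occlusal")


class TestSpecValidation:
    def test_exactly_one_target_form(self):
        with pytest.raises(ParameterError):
            AdjustmentSpec(0, "iso")
        with pytest.raises(ParameterError):
            AdjustmentSpec(0, "iso", target_area=10.0, reduction=0.1)

    def test_direction_checked(self):
        with pytest.raises(ParameterError):
            AdjustmentSpec(0, "sideways", reduction=0.1)

    def test_target_above_a0_rejected(self):
        spec = AdjustmentSpec(0, "iso", target_area=20.0)
        with pytest.raises(ParameterError):
            spec.resolve_target(10.0)


class TestSolver:
    def test_identity_target_returns_k_zero(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        spec = AdjustmentSpec(0, "gingival", target_area=sites[0].a0)
        adjusted, res = adjust_connector(mesh, sites[0], spec)
        assert res.k == 0.0
        assert res.iterations == 0
        assert np.array_equal(adjusted.vertices, mesh.vertices)

    def test_iso_reduction_meets_tolerance(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        spec = AdjustmentSpec(0, "iso", reduction=0.2)
        _, res = adjust_connector(mesh, sites[0], spec)
        assert res.achieved <= 1e-3
        assert res.a_final < res.a_initial

    def test_monotone_area_in_k(self, dumbbell, dumbbell_detection):
        """Section area is non-increasing in k over [0, k_max]."""
        from fpdremodel.connector_adjustment import _measure_area

        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        site = sites[0]
        pts = select_points(mesh, site, 1.0)
        kmax = max_safe_k(pts, "iso")
        areas = []
        for k in np.linspace(0, kmax, 50):
            v = mesh.vertices.copy()
            v[pts.indices] = site.frame.to_world(
                apply_displacement(pts, k, 1.0, "iso")
            )
            areas.append(_measure_area(mesh, site, v))
        assert np.all(np.diff(areas) <= 1e-9)

    def test_locality_beyond_w(self, dumbbell, dumbbell_detection):
        """Vertices outside the falloff band never move (bit-exact)."""
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        site = sites[0]
        spec = AdjustmentSpec(0, "occlusal", reduction=0.1)
        adjusted, _ = adjust_connector(mesh, site, spec)
        d = np.abs((mesh.vertices - site.frame.origin) @ site.frame.z_axis)
        outside = d >= 1.0
        assert np.array_equal(adjusted.vertices[outside], mesh.vertices[outside])
        # for occ/gin directions, world displacement is along the x axis only
        delta = adjusted.vertices - mesh.vertices
        perp = delta - (delta @ site.frame.x_axis)[:, None] * site.frame.x_axis
        assert np.abs(perp).max() < 1e-12

    def test_faces_shared_and_input_unmodified(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        before = mesh.vertices.copy()
        spec = AdjustmentSpec(0, "buccal", reduction=0.1)
        adjusted, res = adjust_connector(mesh, sites[0], spec)
        assert np.array_equal(adjusted.faces, mesh.faces)
        assert np.array_equal(mesh.vertices, before)
        assert adjusted.provenance == "adjusted"
        assert res.displaced_count > 0

    def test_unreachable_target(self, dumbbell, dumbbell_detection):
        mesh, _ = dumbbell
        _, _, sites = dumbbell_detection
        spec = AdjustmentSpec(0, "occlusal", target_area=0.05 * sites[0].a0)
        with pytest.raises(SolverError, match="achievable"):
            solve_k(mesh, sites[0], spec)

    def test_sequential_sites_do_not_interfere(self, fpd_fast, fpd_fast_detection):
        """Adjusting distal then mesial leaves each within tolerance and
        perturbs the other's section by < 0.1% of A0 (sites >> 2w apart)."""
        from fpdremodel.connector_adjustment import _measure_area

        mesh, _ = fpd_fast
        _, _, sites = fpd_fast_detection
        distal, mesial = sites[0], sites[2]
        m1, r1 = adjust_connector(
            mesh, distal, AdjustmentSpec(0, "gingival", reduction=0.1)
        )
        m2, r2 = adjust_connector(
            m1, mesial, AdjustmentSpec(2, "gingival", reduction=0.1)
        )
        assert r1.achieved <= 1e-3 and r2.achieved <= 1e-3
        a_distal_after = _measure_area(m2, distal, m2.vertices)
        assert abs(a_distal_after - r1.a_final) < 1e-3 * distal.a0
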