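import numpy as np
import pytest

from brainmbm.dynamics import SimulationConfig, SimulationResult
from brainmbm.geometry import Node, PlanarMesh, PlaneSpec, Spring, TriangleElement
from brainmbm.strain import (
    StrainError,
    StrainField,
    deformation_gradient,
    green_from_deformation_gradient,
    green_strain,
    hencky_from_green,
    mps_field,
    percentile_mps,
    principal_mps,
    relative_error,
    resultant_mps,
)

REF_TRI = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def _apply(F, verts, t=np.zeros(2)):
    return verts @ F.T + t


def _random_triangle(rng):
    while True:
        tri = rng.uniform(-1, 1, size=(3, 2))
        d1, d2 = tri[1] - tri[0], tri[2] - tri[0]
        area = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
        if area > 0.05:
            return tri


def _random_F(rng):
    while True:
        F = np.eye(2) + rng.uniform(-0.4, 0.4, size=(2, 2))
        if np.linalg.det(F) > 0.2:
            return F


class TestGreenStrain:
    def test_identity_map_zero(self):
        E = green_strain(REF_TRI, REF_TRI)
        np.testing.assert_allclose(E, 0.0, atol=1e-14)

    def test_uniaxial_stretch_closed_form(self):
        lam = 1.2
        F = np.diag([lam, 1.0])
        E = green_strain(REF_TRI, _apply(F, REF_TRI))
        assert E[0, 0] == pytest.approx((lam**2 - 1) / 2)  # 0.22
        assert E[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert E[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_invariant(self):
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        E = green_strain(REF_TRI, _apply(R, REF_TRI))
        np.testing.assert_allclose(E, 0.0, atol=1e-12)

    def test_side_length_route_equals_deformation_gradient_route(self):
        # The two formulations are algebraically identical for an affine
        # map; check on 100 random triangle/deformation pairs.
        rng = np.random.default_rng(42)
        for _ in range(100):
            tri = _random_triangle(rng)
            F = _random_F(rng)
            E_sides = green_strain(tri, _apply(F, tri, t=rng.uniform(-1, 1, 2)))
            E_grad = green_from_deformation_gradient(F)
            np.testing.assert_allclose(E_sides, E_grad, atol=1e-10)

    def test_degenerate_triangle_rejected(self):
        bad = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(StrainError):
            green_strain(bad, bad)


class TestHencky:
    def test_zero_green_zero_hencky(self):
        np.testing.assert_allclose(hencky_from_green(np.zeros((2, 2))), 0.0)

    def test_uniaxial_log_stretch(self):
        EH = hencky_from_green(np.diag([0.22, 0.0]))
        assert EH[0, 0] == pytest.approx(np.log(1.2))  # 0.18232
        assert EH[1, 1] == pytest.approx(0.0, abs=1e-14)

    def test_eigenvalues_are_log_principal_stretches(self):
        # Independent oracle: principal stretches are the singular values
        # of F; Hencky principal strains must equal their logs.
        rng = np.random.default_rng(7)
        for _ in range(20):
            F = _random_F(rng)
            EG = green_from_deformation_gradient(F)
            EH = hencky_from_green(EG)
            sv = np.linalg.svd(F, compute_uv=False)
            np.testing.assert_allclose(
                np.sort(np.linalg.eigvalsh(EH)), np.sort(np.log(sv)), atol=1e-10
            )

    def test_invalid_deformation_rejected(self):
        with pytest.raises(StrainError):
            hencky_from_green(np.diag([-0.6, 0.0]))  # I + 2EG not PD


class TestPrincipalMPS:
    def test_diagonal(self):
        assert principal_mps(np.diag([0.18232, 0.0])) == pytest.approx(0.18232)

    def test_pure_shear(self):
        s = 0.07
        assert principal_mps(np.array([[0.0, s], [s, 0.0]])) == pytest.approx(s)

    def test_isotropic(self):
        assert principal_mps(np.diag([0.3, 0.3])) == pytest.approx(0.3)


class TestObjectivity:
    def test_rigid_rotation_composition_leaves_mps_unchanged(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            tri = _random_triangle(rng)
            F = _random_F(rng)
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            m1 = principal_mps(hencky_from_green(green_strain(tri, _apply(F, tri))))
            m2 = principal_mps(hencky_from_green(green_strain(tri, _apply(R @ F, tri))))
            assert abs(m1 - m2) < 1e-10

    def test_small_strain_limit_hencky_matches_green(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            F = np.eye(2) + rng.uniform(-1e-3, 1e-3, size=(2, 2))
            EG = green_from_deformation_gradient(F)
            EH = hencky_from_green(EG)
            assert abs(principal_mps(EH) - principal_mps(EG)) < 1e-5


def _toy_mesh_and_result(stretch_history):
    """Two-triangle square mesh whose right edge is stretched in x."""
    spec = PlaneSpec("coronal", total_mass=0.4)
    L = 0.02
    pos = np.array([[0, 0], [L, 0], [L, L], [0, L]], dtype=float)
    nodes = [Node(i, "brain", pos[i], 0.1) for i in range(4)]
    tris = []
    for tid, v in enumerate([(0, 1, 2), (0, 2, 3)]):
        p = [pos[i] for i in v]
        sides = np.array(
            [np.linalg.norm(p[1] - p[0]), np.linalg.norm(p[2] - p[1]), np.linalg.norm(p[0] - p[2])]
        )
        e1, e2 = p[1] - p[0], p[2] - p[0]
        area = 0.5 * (e1[0] * e2[1] - e1[1] * e2[0])
        tris.append(TriangleElement(tid, v, sides, float(area)))
    mesh = PlanarMesh(spec=spec, nodes=nodes, springs=[], triangles=tris)
    T = len(stretch_history)
    hist = np.repeat(pos[None], T, axis=0)
    for t, lam in enumerate(stretch_history):
        hist[t, :, 0] = pos[:, 0] * lam
    cfg = SimulationConfig()
    res = SimulationResult(
        time=np.arange(T) * cfg.output_dt,
        brain_positions=hist,
        brain_velocities=np.zeros_like(hist),
        skull_positions=np.zeros((T, 0, 2)),
        config=cfg,
        trace=None,
    )
    return mesh, res


class TestMPSField:
    def test_zero_amplitude_all_peaks_zero(self):
        mesh, res = _toy_mesh_and_result([1.0, 1.0, 1.0])
        fld = mps_field(res, mesh)
        np.testing.assert_allclose(fld.peak_mps, 0.0, atol=1e-14)

    def test_rigid_rotation_history_below_1e8(self):
        mesh, res = _toy_mesh_and_result([1.0] * 5)
        pos0 = res.brain_positions[0]
        for t, th in enumerate(np.linspace(0, 1.0, 5)):
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            res.brain_positions[t] = pos0 @ R.T
        fld = mps_field(res, mesh)
        assert np.all(fld.peak_mps < 1e-8)

    def test_prescribed_stretch_matches_log_lambda(self):
        lams = [1.0, 1.05, 1.18, 1.11]
        mesh, res = _toy_mesh_and_result(lams)
        fld = mps_field(res, mesh)
        np.testing.assert_allclose(fld.peak_mps, np.log(max(lams)), rtol=1e-10)
        assert np.all(fld.time_of_peak == res.time[2])


class TestPercentile:
    def _field(self, peaks):
        peaks = np.asarray(peaks, dtype=float)
        return StrainField(
            element_ids=np.arange(len(peaks)),
            time=np.zeros(1),
            mps_history=peaks[None],
            peak_mps=peaks,
            time_of_peak=np.zeros(len(peaks)),
        )

    def test_constant_field(self):
        assert percentile_mps(self._field([0.3] * 12)) == pytest.approx(0.3)

    def test_outlier_robustness(self):
        peaks = [0.1] * 99 + [1.0]
        assert percentile_mps(self._field(peaks), 95) < 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        peaks = rng.uniform(0, 0.5, 40)
        a = percentile_mps(self._field(peaks))
        b = percentile_mps(self._field(rng.permutation(peaks)))
        assert a == pytest.approx(b)

    def test_empty_field_rejected(self):
        with pytest.raises(StrainError):
            percentile_mps(self._field([]))


class TestResultantAndError:
    def test_single_plane(self):
        assert resultant_mps(0.1, 0.0, 0.0) == pytest.approx(0.1)

    def test_pythagorean(self):
        assert resultant_mps(0.3, 0.4, 0.0) == pytest.approx(0.5)

    def test_dominates_components(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.uniform(0, 1, 3)
            assert resultant_mps(*v) >= v.max() - 1e-15

    def test_negative_rejected(self):
        with pytest.raises(StrainError):
            resultant_mps(-0.1, 0.0, 0.0)

    def test_relative_error_examples(self):
        assert relative_error(0.25, 0.25) == pytest.approx(0.0)
        assert relative_error(0.2, 0.25) == pytest.approx(20.0)
        assert relative_error(0.3, 0.25) == pytest.approx(relative_error(0.2, 0.25))

    def test_relative_error_zero_reference_rejected(self):
        with pytest.raises(StrainError):
            relative_error(0.2, 0.0)


# ---------------------------------------------------------------------------
# Property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def _deformations(draw):
    tri = np.array(
        [
            [draw(st.floats(-1, 1)), draw(st.floats(-1, 1))],
            [draw(st.floats(-1, 1)), draw(st.floats(-1, 1))],
            [draw(st.floats(-1, 1)), draw(st.floats(-1, 1))],
        ]
    )
    d1, d2 = tri[1] - tri[0], tri[2] - tri[0]
    area = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
    if area < 0.05:
        tri = REF_TRI
    F = np.eye(2) + np.array(
        [
            [draw(st.floats(-0.3, 0.3)), draw(st.floats(-0.3, 0.3))],
            [draw(st.floats(-0.3, 0.3)), draw(st.floats(-0.3, 0.3))],
        ]
    )
    if np.linalg.det(F) < 0.2:
        F = np.eye(2)
    return tri, F


@settings(max_examples=50, derandomize=True)
@given(_deformations(), st.floats(0, 2 * np.pi))
def test_mps_objective_under_superposed_rotation(deformation, theta):
    """Hencky MPS is invariant to rigid rotations composed with any
    admissible deformation (material objectivity)."""
    tri, F = deformation
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    m1 = principal_mps(hencky_from_green(green_strain(tri, _apply(F, tri))))
    m2 = principal_mps(hencky_from_green(green_strain(tri, _apply(R @ F, tri))))
    assert abs(m1 - m2) < 1e-9


@settings(max_examples=50, derandomize=True)
@given(_deformations())
def test_hencky_mps_equals_log_largest_singular_value(deformation):
    _, F = deformation
    mps = principal_mps(hencky_from_green(green_from_deformation_gradient(F)))
    assert mps == pytest.approx(np.log(np.linalg.svd(F, compute_uv=False).max()), abs=1e-10)
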