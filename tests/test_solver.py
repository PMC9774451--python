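"""Conduction solver: boundary conditions, conservation, linearity and
superposition semantics."""

import numpy as np
import pytest

from ocustim.phantom import TissuePhantom, place_electrode
from ocustim.solver import (ConductivityMap, SolverError, element_field,
                            solve_pair, superpose)


@pytest.fixture(scope="module")
def pair_solution(coarse_phantom, coarse_operator):
    anode = place_electrode(coarse_phantom, "right_temporal_lower")
    cathode = place_electrode(coarse_phantom, "right_cheek_medial_low")
    sol = coarse_operator.solve_dirichlet_pair(anode, cathode, 1.0)
    return anode, cathode, sol


class TestConductivityMap:
    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            ConductivityMap(values={"skin": -1.0})

    def test_rejects_missing_tissue(self):
        cmap = ConductivityMap(values={"skin": 0.1})
        with pytest.raises(ValueError):
            cmap.for_labels(np.array(["skin", "bone"]))


class TestPairSolve:
    def test_zero_current_gives_zero_field(self, coarse_phantom,
                                           coarse_operator):
        anode = place_electrode(coarse_phantom, "right_temporal_lower")
        cathode = place_electrode(coarse_phantom, "right_cheek_medial_low")
        sol = coarse_operator.solve_dirichlet_pair(anode, cathode, 0.0)
        assert np.all(sol.element_field_magnitude == 0)

    def test_linearity_in_drive_current(self, coarse_phantom,
                                        coarse_operator, pair_solution):
        anode, cathode, sol1 = pair_solution
        sol2 = coarse_operator.solve_dirichlet_pair(anode, cathode, 2.0)
        assert np.allclose(sol2.element_field_magnitude,
                           2.0 * sol1.element_field_magnitude,
                           rtol=1e-9, atol=1e-12)

    def test_current_conservation(self, pair_solution):
        _, _, sol = pair_solution
        assert np.isclose(sol.drive["anode_current_a"], 1e-3)
        assert abs(sol.drive["cathode_current_a"] + 1e-3) < 1e-6 * 1e-3
        assert sol.residual < 1e-8

    def test_magnitude_is_norm_of_vector(self, pair_solution):
        _, _, sol = pair_solution
        assert np.allclose(sol.element_field_magnitude,
                           np.linalg.norm(sol.element_field, axis=1))
        assert sol.element_field_magnitude.min() >= 0

    def test_shared_patch_nodes_rejected(self, coarse_phantom,
                                         coarse_operator):
        a = place_electrode(coarse_phantom, "left_cheek_crossed_a")
        b = place_electrode(coarse_phantom, "left_cheek_crossed_b")
        with pytest.raises(SolverError):
            coarse_operator.solve_dirichlet_pair(a, b, 1.0)

    def test_unknown_model_rejected(self, coarse_phantom):
        a = place_electrode(coarse_phantom, "right_temporal_lower")
        c = place_electrode(coarse_phantom, "right_cheek_medial_low")
        with pytest.raises(ValueError):
            solve_pair(coarse_phantom, a, c, model="spectral")


def two_tet_fixture():
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0],
                      [0, 0, 10.0], [10.0, 10.0, 10.0]])
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    labels = np.array(["skin", "skin"])
    return TissuePhantom(nodes=nodes, tets=tets, tet_labels=labels,
                         tri_nodes=np.empty((0, 3), int),
                         tri_labels=np.empty(0, "U12"),
                         tri_tets=np.empty(0, int), eye_centers=None,
                         eye_radius=None, plane_nodes=np.empty(0, int),
                         provenance={"tri_boundary": np.empty(0, bool)})


class TestElementField:
    def test_constant_potential_gives_zero_field(self, coarse_phantom):
        v = np.full(len(coarse_phantom.nodes), 3.7)
        E, mag = element_field(coarse_phantom, v)
        # rounding in the per-element gradients leaves O(1e-8 V/m) noise
        assert np.abs(E).max() < 1e-6 and mag.max() < 1e-6

    def test_linear_ramp_gives_uniform_gradient(self, coarse_phantom):
        a = 0.25    # volts per mm of x
        v = a * coarse_phantom.nodes[:, 0]
        E, _ = element_field(coarse_phantom, v)
        # coordinates are mm, fields V/m
        assert np.allclose(E, [[-a * 1e3, 0.0, 0.0]], rtol=1e-9, atol=1e-6)

    def test_matches_brute_force_shape_gradients(self, rng):
        phantom = two_tet_fixture()
        v = rng.normal(size=5)
        E, mag = element_field(phantom, v)
        for k, tet in enumerate(phantom.tets):
            # brute force: fit V = c0 + c.x exactly on the 4 vertices
            A = np.column_stack([np.ones(4), phantom.nodes[tet] * 1e-3])
            coef = np.linalg.solve(A, v[tet])
            assert np.allclose(E[k], -coef[1:], rtol=1e-10)
        assert np.allclose(mag, np.linalg.norm(E, axis=1))


class TestSuperposition:
    def test_identity_and_self_cancellation(self, pair_solution):
        _, _, sol = pair_solution
        same = superpose([sol], [1.0])
        assert np.array_equal(same.element_field, sol.element_field)
        null = superpose([sol, sol], [1.0, -1.0])
        assert np.all(null.element_field_magnitude == 0)

    def test_global_phase_flip_preserves_magnitudes(
            self, coarse_phantom, coarse_operator, pair_solution):
        anode, cathode, sol1 = pair_solution
        a2 = place_electrode(coarse_phantom, "right_central_lower")
        c2 = place_electrode(coarse_phantom, "right_cheek_medial_low2")
        sol2 = coarse_operator.solve_dirichlet_pair(a2, c2, 1.0)
        anti = superpose([sol1, sol2], [1.0, -1.0])
        flipped = superpose([sol1, sol2], [-1.0, 1.0])
        assert np.allclose(anti.element_field_magnitude,
                           flipped.element_field_magnitude)

    def test_mesh_mismatch_rejected(self, pair_solution):
        _, _, sol = pair_solution
        other = superpose([sol], [1.0])
        other.n_elements += 1
        with pytest.raises(ValueError):
            superpose([sol, other], [1.0, 1.0])


class TestInjectionModel:
    def test_unbalanced_currents_rejected(self, coarse_phantom,
                                          coarse_operator):
        a = place_electrode(coarse_phantom, "right_temporal_lower")
        c = place_electrode(coarse_phantom, "right_cheek_medial_low")
        with pytest.raises(SolverError):
            coarse_operator.solve_injection([a, c], [1.0, -0.5])

    def test_joint_solve_equals_signed_superposition(self, small_sphere):
        """Two pairs solved separately and superposed with phase signs must
        reproduce the joint four-patch solve (same current-injection
        operator, so agreement is limited only by solver error)."""
        from ocustim.solver import ConductionOperator
        op = ConductionOperator(
            small_sphere, ConductivityMap(values={"gray_matter": 0.3}))
        pads = [place_electrode(small_sphere, (az, el), edge_length=18.0)
                for az, el in ((20, 10), (150, -20), (-60, 30), (-130, -40))]
        s1 = op.solve_injection(pads[:2], [1.0, -1.0])
        s2 = op.solve_injection(pads[2:], [1.5, -1.5])
        combined = superpose([s1, s2], [1.0, -1.0])
        joint = op.solve_injection(pads, [1.0, -1.0, -1.5, 1.5])
        scale = np.abs(joint.element_field_magnitude).max()
        diff = np.abs(combined.element_field_magnitude
                      - joint.element_field_magnitude).max()
        assert diff / scale < 1e-6
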