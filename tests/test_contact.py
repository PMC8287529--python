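"""Elastic-foundation contact: penetration, force law, pressure module."""

import numpy as np
import pytest

from atsasim.contact import (ContactParams, contact_force, pressure_module,
                             translation_pose, vertex_penetration)
from atsasim.mesh import icosphere_cap


@pytest.fixture(scope="module")
def cup28():
    """28 mm concave cup, pole toward -ML, moderate resolution."""
    return icosphere_cap(0.028, 60.0, subdivisions=5, concave=True)


@pytest.fixture(scope="module")
def head24():
    return icosphere_cap(0.024, 120.0, subdivisions=3, concave=False)


@pytest.fixture(scope="module")
def conforming_pair():
    """Concentric 24 mm cup against an inflated 24.5 mm head: exactly
    0.5 mm of uniform penetration over the whole cap."""
    cup = icosphere_cap(0.024, 60.0, subdivisions=5, concave=True)
    head = icosphere_cap(0.0245, 120.0, subdivisions=2, concave=False)
    return cup, head


class TestVertexPenetration:
    def test_tangent_surfaces_zero_depth(self, cup28, head24):
        # head center 4 mm from cup center toward the pole: exact tangency
        pose = translation_pose((0, 0, -4e-3))
        d = vertex_penetration(cup28, head24, pose)
        assert np.all(d <= 1e-12)

    def test_sphere_in_cup_translated_depth(self, cup28, head24):
        # concentric then translated 4.5 mm toward the pole: uniform gap
        # 4 mm shrinks to -0.5 mm at the pole
        pose = translation_pose((0, 0, -4.5e-3))
        d = vertex_penetration(cup28, head24, pose)
        assert d.max() == pytest.approx(0.5e-3, rel=1e-9)
        pole_idx = np.argmin(cup28.vertices[:, 2])
        assert d[pole_idx] == pytest.approx(d.max(), rel=1e-9)

    def test_separated_surfaces_zero_depth(self, cup28, head24):
        pose = translation_pose((0, 0, -3e-3))  # 1 mm gap at the pole
        assert np.all(vertex_penetration(cup28, head24, pose) == 0.0)

    def test_non_rigid_pose_rejected(self, cup28, head24):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError, match="rigid"):
            vertex_penetration(cup28, head24, bad)

    def test_mesh_master_fallback_matches_analytic(self, cup28):
        """Nearest-point projection agrees with the analytic sphere."""
        head = icosphere_cap(0.024, 120.0, subdivisions=4)
        pose = translation_pose((0, 0, -4.3e-3))
        exact = vertex_penetration(cup28, head, pose)
        head_mesh_only = type(head)(head.vertices.copy(), head.faces.copy())
        approx = vertex_penetration(cup28, head_mesh_only, pose)
        mask = exact > 1e-5
        assert mask.any()
        # the faceted master under-reports depth by up to about twice
        # the chord sag, edge^2 / 8R ~ 1.4e-5 m at this resolution
        assert np.allclose(approx[mask], exact[mask], atol=4e-5)


class TestContactForce:
    def test_no_interpenetration_zero_result(self, cup28, head24):
        res = contact_force(cup28, head24, translation_pose((0, 0, -3e-3)))
        assert np.allclose(res.resultant_force, 0.0)
        assert res.contact_area == 0.0 and not res.in_contact

    def test_uniform_depth_total_load_vs_overlap_volume(self,
                                                        conforming_pair):
        cup, head = conforming_pair
        params = ContactParams()
        res = contact_force(cup, head, params=params)
        d = 0.5e-3
        analytic_volume = d * 2 * np.pi * 0.024 ** 2 * (1 - np.cos(
            np.radians(60.0)))
        assert res.total_load == pytest.approx(
            params.pressure_module * analytic_volume, rel=0.02)

    def test_linearity_in_pressure_module(self, conforming_pair):
        cup, head = conforming_pair
        res1 = contact_force(cup, head, params=ContactParams())
        res2 = contact_force(
            cup, head, params=ContactParams(pressure_module=2 * 2.74e11))
        assert np.allclose(res2.resultant_force, 2 * res1.resultant_force,
                           rtol=1e-12)

    def test_force_volume_identity(self, conforming_pair):
        cup, head = conforming_pair
        params = ContactParams()
        res = contact_force(cup, head, params=params)
        assert np.allclose(res.force, params.pressure_module * res.volume,
                           rtol=1e-12)
        assert np.allclose(res.volume, res.depth * cup.vertex_areas,
                           rtol=1e-12)

    def test_force_vanishes_with_penetration(self, cup28, head24):
        """Continuity: resultant magnitude -> 0 as penetration -> 0."""
        mags = []
        for dz in (0.2e-3, 0.1e-3, 0.05e-3, 0.01e-3, 0.0):
            pose = translation_pose((0, 0, -4e-3 - dz))
            res = contact_force(cup28, head24, pose)
            mags.append(np.linalg.norm(res.resultant_force))
        assert all(a >= b for a, b in zip(mags, mags[1:]))
        assert mags[-1] == 0.0

    def test_refinement_converges_to_analytic(self):
        """Quadrature error shrinks monotonically with triangle count."""
        head = icosphere_cap(0.0245, 120.0, subdivisions=2)
        params = ContactParams()
        oracle = params.pressure_module * 0.5e-3 * 2 * np.pi * 0.024 ** 2 \
            * (1 - np.cos(np.radians(60.0)))
        errs = []
        for sub in (4, 5, 6):
            cup = icosphere_cap(0.024, 60.0, subdivisions=sub, concave=True)
            res = contact_force(cup, head, params=params)
            errs.append(abs(res.total_load - oracle) / oracle)
        assert errs[0] > errs[1] > errs[2]

    def test_newtons_third_law_on_resultants(self, cup28):
        """Swapping slave/master flips the resultant within quadrature
        tolerance."""
        head = icosphere_cap(0.024, 120.0, subdivisions=5)
        pose = translation_pose((0, 0, -4.3e-3))
        res_a = contact_force(cup28, head, pose)
        # swapped roles: head is slave, so move it and hold the cup
        head_moved = icosphere_cap(0.024, 120.0, center=(0, 0, -4.3e-3),
                                   subdivisions=5)
        res_b = contact_force(head_moved, cup28)
        fa, fb = res_a.resultant_force, res_b.resultant_force
        assert np.linalg.norm(fa + fb) <= 0.05 * np.linalg.norm(fa)


class TestPressureModule:
    def test_bracket_is_two_for_linear_material(self):
        params = ContactParams(n=1.0, poisson=0.3, thickness=5e-3)
        v, h = 0.3, 5e-3
        elastic = (1 - v) / ((1 + v) * (1 - 2 * v))
        expected = elastic / h * 2 * params.p_o / params.eps_o * 2.0
        for p_i in (1e6, 18.4e6, 40e6):
            assert pressure_module(params, p_i) == pytest.approx(
                expected, rel=1e-12)

    def test_direct_formula_evaluation(self):
        params = ContactParams(poisson=0.46, thickness=5e-3)
        v, h, p_i, p_o, eps_o, n = 0.46, 5e-3, 18.4e6, 18.4e6, 0.0597, 3.0
        expected = ((1 - v) / ((1 + v) * (1 - 2 * v)) / h
                    * 2 * p_o / eps_o * (1 + n * (p_i / p_o) ** (n - 1)))
        assert pressure_module(params, p_i) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            ContactParams(poisson=0.5)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            ContactParams(thickness=0.0)

    def test_nonpositive_reference_pressure_rejected(self):
        with pytest.raises(ValueError):
            pressure_module(ContactParams(), 0.0)

    def test_default_model_ships_the_constant(self, default_model):
        assert default_model.contact.pressure_module == 2.74e11
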