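"""Recruitment: moment arms and the polynomial-criterion solver."""

import numpy as np
import pytest

import atsasim
from atsasim import EquilibriumSystem, GHState, solve_recruitment
from atsasim.core import (BodySegment, Frame, MuscleUnit, ShoulderModel,
                          SpringRestraint, muscle_strength)
from atsasim.contact import ContactParams
from atsasim.recruitment import moment_arms
from conftest import brute_force_recruitment, random_recruitment_instance


def _one_muscle_model(path):
    mus = MuscleUnit("m", path, pcsa=10.0, strength=muscle_strength(10.0))
    return ShoulderModel(gh_frame=Frame(), arm=BodySegment("arm", 4.0,
                                                           [0, -0.3, 0]),
                         muscles=[mus], head_mesh=None, insert_mesh=None,
                         contact=ContactParams(), spring=SpringRestraint())


class TestMomentArms:
    def test_line_through_center_gives_zero_column(self):
        # pulls straight from the humeral point through the joint center
        model = _one_muscle_model([("ground", [0, 0.04, 0]),
                                   ("humerus", [0, 0.02, 0])])
        R = moment_arms(model, GHState(0.0))
        assert np.allclose(R[:, 0], 0.0, atol=1e-15)

    def test_planar_muscle_after_rotation(self):
        """Attachment 20 mm off-axis on the rotated humerus pulling along
        +SI: the moment arm about the AP axis is exactly 20 mm."""
        # at 90° the local +SI offset maps to -ML: humeral point lands at
        # (0, 0, -0.02); the ground anchor straight above gives a pure
        # +SI pull, hence the hand-computed column (0.02, 0, 0)
        model = _one_muscle_model([("ground", [0, 1.0, -0.02]),
                                   ("humerus", [0, 0.02, 0])])
        R = moment_arms(model, GHState(90.0))
        col = R[:, 0]
        assert col == pytest.approx([0.02, 0.0, 0.0], abs=1e-12)

    def test_translation_shifts_arms_consistently(self, default_model):
        from atsasim.recruitment import muscle_geometry
        u = np.array([1e-3, -2e-3, 0.5e-3])
        state = GHState(40.0, u)
        R = moment_arms(default_model, state)
        attach, dirs = muscle_geometry(default_model, state)
        manual = np.cross(attach - u, dirs).T
        assert np.allclose(R, manual, atol=1e-15)

    def test_zero_length_segment_names_muscle(self):
        model = _one_muscle_model([("ground", [0, 0.02, 0]),
                                   ("humerus", [0, 0.02, 0])])
        with pytest.raises(ValueError, match="'m'"):
            moment_arms(model, GHState(0.0))


class TestSolveRecruitment:
    def test_single_muscle_unique_point(self):
        sys = EquilibriumSystem([[0.02]], [-10.0], [1000.0])
        sol = solve_recruitment(sys)
        assert sol.optimal
        assert sol.forces[0] == pytest.approx(500.0, rel=1e-6)

    def test_identical_pair_splits_equally(self):
        sys = EquilibriumSystem([[0.02, 0.02]], [-10.0], [1000.0, 1000.0])
        sol = solve_recruitment(sys)
        assert sol.forces == pytest.approx([250.0, 250.0], rel=1e-6)

    def test_two_muscle_closed_form(self):
        """Lagrange solution f_i = M r_i N_i^2 / sum(r_j^2 N_j^2)."""
        sys = EquilibriumSystem([[0.02, 0.01]], [-10.0], [1000.0, 1000.0])
        sol = solve_recruitment(sys)
        assert sol.forces == pytest.approx([400.0, 200.0], rel=1e-6)

    def test_infeasible_reported_not_raised(self):
        # demanded moment beyond the single muscle's capacity
        sys = EquilibriumSystem([[0.02]], [-100.0], [1000.0])
        sol = solve_recruitment(sys)
        assert sol.status == "infeasible"

    def test_deficient_muscle_stays_at_zero(self):
        sys = EquilibriumSystem([[0.02, 0.02]], [-10.0], [1000.0, 1000.0],
                                bounds=[0.0, 1000.0])
        sol = solve_recruitment(sys)
        assert sol.optimal
        assert sol.forces[0] == 0.0
        assert sol.forces[1] == pytest.approx(500.0, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumSystem([[0.02, 0.01]], [-10.0, 0.0, 0.0],
                              [1000.0, 1000.0])

    def test_criterion_order_below_two_rejected(self):
        sys = EquilibriumSystem([[0.02]], [-10.0], [1000.0])
        with pytest.raises(ValueError):
            solve_recruitment(sys, criterion_order=1)


class TestSolverProperties:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(25):
            sys = random_recruitment_instance(rng)
            sol = solve_recruitment(sys)
            oracle = brute_force_recruitment(
                sys.moment_arms, sys.external_moment, sys.strengths)
            if not np.isfinite(oracle):
                continue
            assert sol.optimal
            assert sol.objective == pytest.approx(
                oracle, rel=1e-4, abs=1e-10)
            checked += 1
        assert checked >= 15

    def test_deficiency_never_decreases_objective(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            sys = random_recruitment_instance(rng)
            base = solve_recruitment(sys)
            if not base.optimal:
                continue
            n = len(sys.strengths)
            for k in range(n):
                bounds = sys.bounds.copy()
                bounds[k] = 0.0
                restricted = EquilibriumSystem(sys.moment_arms,
                                               sys.external_moment,
                                               sys.strengths, bounds)
                sol = solve_recruitment(restricted)
                if sol.optimal:
                    assert sol.objective >= base.objective - 1e-8

    def test_activation_scale_invariance(self):
        """Scaling all strengths by c scales interior activations by 1/c."""
        sys = EquilibriumSystem([[0.02, 0.01]], [-10.0], [1000.0, 800.0])
        base = solve_recruitment(sys)
        c = 3.0
        scaled = EquilibriumSystem([[0.02, 0.01]], [-10.0],
                                   [c * 1000.0, c * 800.0])
        sol = solve_recruitment(scaled)
        assert sol.activations == pytest.approx(base.activations / c,
                                                rel=1e-5)
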