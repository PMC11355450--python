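import math

import numpy as np
import pytest

from sim2sr.flow import (
    Covector,
    ExtremalState,
    abnormal_trajectory,
    chart_momentum,
    exponential_map,
    fiber_geodesic,
    first_identity_return,
    first_integrals,
    frame_momentum,
    maxwell_pair,
    normal_rhs,
    poisson_matrix,
    pontryagin_value,
    random_unit_covectors,
    vertical_tail,
)
from sim2sr.group import GroupElement, multiply


class TestPontryaginFunction:
    def test_linear_pairing_examples(self):
        assert pontryagin_value(Covector(1, 0, 0, 0), (1, 0, 0)) == 1.0
        assert pontryagin_value(Covector(0, 0, 1, 0), (0, 1, 0)) == 1.0

    def test_maximizing_control_saturates_cauchy_schwarz(self, rng):
        for _ in range(20):
            h = random_unit_covectors(1, rng)[0]
            u_star = np.array([h.h1, h.h3, h.h4])
            assert pontryagin_value(h, u_star) == pytest.approx(1.0, abs=1e-12)
            u_other = rng.normal(size=3)
            u_other /= np.linalg.norm(u_other)
            assert pontryagin_value(h, u_other) <= 1.0 + 1e-12


class TestNormalField:
    def test_pure_fiber_velocity(self):
        s = ExtremalState(GroupElement.identity(), Covector(0, 0, 0.3, 0.9))
        d = normal_rhs(s)
        assert d == pytest.approx([0, 0, 0.3, 0.9, 0, 0, 0, 0], abs=1e-15)

    def test_straight_ray_initial_derivative(self):
        s = ExtremalState(GroupElement.identity(), Covector(1, 0, 0, 0))
        d = normal_rhs(s)
        assert d == pytest.approx([1, 0, 0, 0, 0, 0, 0, -1], abs=1e-15)

    def test_hamiltonian_is_stationary_along_field(self, rng):
        # directional derivative of h1^2 + h3^2 + h4^2 along the flow
        for h in random_unit_covectors(20, rng):
            s = ExtremalState(GroupElement.identity(), h)
            d = normal_rhs(s)[4:]
            dH = 2 * (h.h1 * d[0] + h.h3 * d[2] + h.h4 * d[3])
            assert abs(dH) < 1e-14


class TestExponentialMap:
    def test_requires_unit_level_set(self):
        with pytest.raises(ValueError):
            exponential_map(Covector(0.5, 0, 0, 0), 1.0)
        traj = exponential_map(Covector(0.5, 0, 0, 0), 1.0, renormalize=True)
        assert traj.conserved[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_fiber_rotation_returns_to_identity_at_2pi(self):
        t = first_identity_return(Covector(0, 0, 1, 0))
        assert t == pytest.approx(2 * math.pi, abs=1e-9)

    def test_fiber_trajectory_matches_linear_closed_form(self):
        traj = exponential_map(Covector(0, 0, 0.6, 0.8), 3.0, n_samples=100)
        assert traj.q[:, 2] == pytest.approx(0.6 * traj.times, abs=1e-10)
        assert traj.q[:, 3] == pytest.approx(0.8 * traj.times, abs=1e-10)
        assert np.abs(traj.q[:, :2]).max() < 1e-10

    def test_h4_non_increasing_along_extremals(self, rng):
        for h0 in random_unit_covectors(100, rng):
            traj = exponential_map(h0, 5.0, n_samples=100)
            assert np.all(np.diff(traj.h[:, 3]) <= 1e-10)

    def test_unit_speed_and_horizontality(self, rng):
        for h0 in random_unit_covectors(5, rng):
            traj = exponential_map(h0, 4.0, n_samples=80)
            assert traj.max_speed_deviation() < 1e-6
            assert traj.max_contact_violation() < 1e-6

    def test_left_invariance_of_the_flow(self, rng):
        h0 = random_unit_covectors(1, rng)[0]
        q0 = GroupElement(0.5, -0.3, 1.1, 0.4)
        at_base = exponential_map(h0, 2.0, n_samples=40, base=q0)
        at_id = exponential_map(h0, 2.0, n_samples=40)
        for i in range(40):
            expected = multiply(q0, at_id.state_at(i).q)
            got = at_base.state_at(i).q
            assert got.as_array() == pytest.approx(expected.as_array(), abs=1e-8)

    def test_spatial_projection_bounded_for_negative_h4(self, rng):
        # contracting scale freezes spatial motion: the planar radius
        # stabilizes (late increments vanish)
        for h0 in [Covector(0.8, 0.0, 0.0, -0.6), Covector(0.6, 0.3, 0.519615242270663, -0.6)]:
            h0 = Covector(*(h0.as_array() / math.sqrt(h0.hamiltonian) * np.array([1, 0, 1, 1]).clip(1, 1)))
            traj = exponential_map(Covector(*h0.as_array()), 50.0, n_samples=500, renormalize=True)
            r = np.hypot(traj.q[:, 0], traj.q[:, 1])
            assert np.isfinite(r).all()
            assert r[-1] - r[-100] < 1e-6


class TestClosedForms:
    def test_abnormal_examples(self):
        up = abnormal_trajectory(1.0, +1)
        assert up.endpoint().as_array() == pytest.approx([0, 0, 0, 1], abs=1e-15)
        assert abnormal_trajectory(0.0).endpoint() == GroupElement.identity()

    def test_abnormal_is_not_strictly_abnormal(self):
        closed = abnormal_trajectory(2.0, -1, n_samples=50)
        integ = exponential_map(Covector(0, 0, 0, -1), 2.0, n_samples=50)
        assert np.abs(closed.q - integ.q).max() < 1e-9

    @pytest.mark.parametrize(
        "h30, h40, cut",
        [(0.6, 0.8, math.pi / 0.6), (0.0, 1.0, math.inf), (1.0, 0.0, math.pi)],
    )
    def test_fiber_cut_times(self, h30, h40, cut):
        _, got = fiber_geodesic(h30, h40, 1.0)
        assert got == cut

    def test_fiber_endpoint(self):
        traj, _ = fiber_geodesic(1.0, 0.0, math.pi / 2)
        assert traj.endpoint().as_array() == pytest.approx([0, 0, math.pi / 2, 0], abs=1e-12)

    def test_exp_matches_closed_forms_on_long_interval(self):
        for h30, h40 in [(0.6, 0.8), (1.0, 0.0), (0.0, -1.0)]:
            closed, _ = fiber_geodesic(h30, h40, 5.0, n_samples=100)
            integ = exponential_map(Covector(0, 0, h30, h40), 5.0, n_samples=100)
            assert np.abs(closed.q - integ.q).max() < 1e-9
            assert np.abs(closed.h - integ.h).max() < 1e-9


class TestMaxwellPoints:
    def test_meeting_time_and_angle(self):
        t, q = maxwell_pair(0.6, 0.8)
        assert t == pytest.approx(math.pi / 0.6, abs=1e-6)
        assert abs(q.theta) == pytest.approx(math.pi, abs=1e-6)
        assert q.sigma == pytest.approx(0.8 / 0.6 * math.pi, abs=1e-6)

    def test_pure_rotation_meets_at_pi(self):
        t, q = maxwell_pair(1.0, 0.0)
        assert t == pytest.approx(math.pi, abs=1e-8)
        assert q.as_array() == pytest.approx([0, 0, math.pi, 0], abs=1e-8)

    def test_h30_zero_has_no_maxwell_point(self):
        with pytest.raises(ValueError):
            maxwell_pair(0.0, 1.0)


class TestFirstIntegrals:
    def test_values_at_identity(self):
        h = Covector(0.3, -0.7, 0.2, 0.1)
        H, g1, g2 = first_integrals(ExtremalState(GroupElement.identity(), h))
        assert g1 == pytest.approx(h.h1)
        assert g2 == pytest.approx(h.h2)
        assert H == pytest.approx(h.hamiltonian)

    def test_conservation_along_flow(self, rng):
        worst = 0.0
        for h0 in random_unit_covectors(30, rng):
            traj = exponential_map(h0, 10.0, n_samples=50)
            worst = max(worst, traj.conservation_drift().max())
        assert worst < 1e-8


class TestMomentumCharts:
    def test_identity_chart_is_trivial(self):
        h = Covector(0.1, 0.2, 0.3, 0.4)
        p = chart_momentum(h, GroupElement.identity())
        assert p == pytest.approx([0.1, 0.2, 0.3, 0.4])

    def test_quarter_turn_swaps_components(self):
        # at theta = pi/2 the frame vector X2 points along -dx, so the
        # chart momentum dx pairs to h2 = -1
        h = frame_momentum(np.array([1.0, 0, 0, 0]), GroupElement(0.3, 9.0, math.pi / 2, 0))
        assert h.as_array() == pytest.approx([0, -1, 0, 0], abs=1e-12)

    def test_round_trip(self, rng):
        for _ in range(50):
            q = GroupElement(*rng.uniform(-2, 2, 2), rng.uniform(-4, 4), rng.uniform(-2, 2))
            h = Covector(*rng.normal(size=4))
            back = frame_momentum(chart_momentum(h, q), q)
            assert back.as_array() == pytest.approx(h.as_array(), abs=1e-12)


class TestPoissonStructure:
    def test_rank_degenerate_on_fiber_axis(self):
        P, det, rank = poisson_matrix(Covector(0, 0, 1, 0))
        assert rank == 0 and det == pytest.approx(0.0)

    def test_rank_full_off_axis(self):
        P, det, rank = poisson_matrix(Covector(1, 1, 0.5, 0.3))
        assert rank == 4
        assert det == pytest.approx(4.0)  # (h1^2 + h2^2)^2

    def test_antisymmetry_and_determinant_formula(self, rng):
        for _ in range(20):
            h = Covector(*rng.normal(size=4))
            P, det, _ = poisson_matrix(h)
            assert np.abs(P + P.T).max() == 0.0
            assert det == pytest.approx((h.h1**2 + h.h2**2) ** 2, rel=1e-9)


class TestVerticalAsymptotics:
    def test_decay_for_negative_initial_h4(self):
        rep = vertical_tail(Covector(0.6, 0, 0, -0.8), 50.0)
        assert rep.abs_h1 < 1e-6 and rep.abs_h2 < 1e-6
        assert rep.h3sq_plus_h4sq == pytest.approx(1.0, abs=1e-6)
        assert rep.h4_nonincreasing

    def test_fiber_orbit_is_stationary(self):
        rep = vertical_tail(Covector(0, 0, 0.6, 0.8), 20.0)
        assert rep.h_final == pytest.approx([0, 0, 0.6, 0.8], abs=1e-10)

    def test_h4_zero_start_observed_decay(self):
        # conjectured regime (h4(0) = 0): reported numerics, not a theorem
        rep = vertical_tail(Covector(1, 0, 0, 0), 50.0)
        assert rep.abs_h1 < 1e-3
        assert rep.h_final[3] < 0
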