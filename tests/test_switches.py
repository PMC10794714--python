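"""Regulatory switches: fixed points, basins, fate classification, epsilon."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stemdish import lattice
from stemdish.switches import (PSwitchParams, SSwitchParams, classify_fate,
                               epsilon_coefficients, find_fixed_points,
                               iota_x_of_n, p_switch_rhs, s_switch_rhs,
                               STABLE, SADDLE)

SP = SSwitchParams()
PP = PSwitchParams()


from oracles import nullcline_intersections


class TestSSwitch:
    def test_rhs_at_origin_is_synthesis_rates(self):
        assert s_switch_rhs(0.0, 0.0, SP) == (85.0, 100.0)

    def test_large_y_kills_x_synthesis(self):
        dx, _ = s_switch_rhs(3.0, 1e6, SP)
        assert dx == pytest.approx(-SP.gamma * 3.0, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            s_switch_rhs(-1.0, 0.0, SP)

    def test_two_stable_one_saddle(self):
        fps = find_fixed_points(lambda x, y: s_switch_rhs(x, y, SP), 340.0)
        kinds = sorted(fp.stability for fp in fps)
        assert kinds == [SADDLE, STABLE, STABLE]

    def test_fixed_points_match_nullcline_oracle(self):
        n = nullcline_intersections(lambda x, y: s_switch_rhs(x, y, SP), 200.0)
        fps = find_fixed_points(lambda x, y: s_switch_rhs(x, y, SP), 340.0)
        assert len(fps) == n == 3

    def test_rhs_vanishes_at_fixed_points(self):
        fps = find_fixed_points(lambda x, y: s_switch_rhs(x, y, SP), 340.0)
        for fp in fps:
            dx, dy = s_switch_rhs(fp.x, fp.y, SP)
            assert abs(dx) < 1e-9 and abs(dy) < 1e-9


class TestIotaOfN:
    def test_anchored_at_reference_density(self):
        assert iota_x_of_n(1000.0, SP, n_ref=1000.0) == pytest.approx(85.0)

    def test_strictly_decreasing(self):
        ns = np.linspace(0, 5000, 200)
        vals = iota_x_of_n(ns, SP, n_ref=1000.0)
        assert (np.diff(vals) < 0).all()

    def test_maximum_at_zero_density(self):
        assert iota_x_of_n(0.0, SP, 1000.0) == pytest.approx(2 * SP.iota_x)


class TestPSwitch:
    def test_rhs_at_origin_is_inhibition_rates(self):
        assert p_switch_rhs(0.0, 0.0, PP) == (30.0, 30.0)

    def test_symmetry_swap(self):
        dx, dy = p_switch_rhs(40.0, 90.0, PP, 5.0, 11.0)
        dy2, dx2 = p_switch_rhs(90.0, 40.0, PP, 11.0, 5.0)
        assert dx == pytest.approx(dx2) and dy == pytest.approx(dy2)

    def test_three_stable_fixed_points(self):
        fps = find_fixed_points(lambda x, y: p_switch_rhs(x, y, PP), 340.0)
        stable = [fp for fp in fps if fp.stability == STABLE]
        assert len(stable) == 3

    def test_fixed_point_set_symmetric(self):
        fps = find_fixed_points(lambda x, y: p_switch_rhs(x, y, PP), 340.0)
        pts = sorted((round(fp.x, 4), round(fp.y, 4)) for fp in fps)
        swapped = sorted((b, a) for a, b in pts)
        assert pts == swapped

    def test_oracle_counts_all_five_roots(self):
        n = nullcline_intersections(lambda x, y: p_switch_rhs(x, y, PP), 200.0)
        assert n == 5


class TestBasinsAndFate:
    def test_labels_partition_plane(self, base_maps):
        s_map, p_map = base_maps
        assert set(np.unique(s_map.labels)) <= {lattice.S, lattice.P}
        assert set(np.unique(p_map.labels)) <= {lattice.P, lattice.A, lattice.B}

    def test_stable_point_in_own_basin(self, base_maps):
        _, p_map = base_maps
        for fp in p_map.fixed_points:
            if fp.stability == STABLE:
                assert classify_fate(int(round(fp.x)), int(round(fp.y)),
                                     p_map) == fp.fate_label

    def test_fate_at_a_attractor_is_a(self, base_maps):
        _, p_map = base_maps
        a_fp = max((fp for fp in p_map.fixed_points if fp.stability == STABLE),
                   key=lambda fp: fp.x - fp.y)
        assert classify_fate(int(a_fp.x), int(a_fp.y), p_map) == lattice.A

    def test_classification_agrees_with_direct_integration(self, base_maps, rng):
        """Basin lookup equals forward ODE integration on random points."""
        _, p_map = base_maps
        stable = [fp for fp in p_map.fixed_points if fp.stability == STABLE]
        pts = rng.uniform(0, 250, size=(100, 2))
        for x0, y0 in pts:
            x, y = x0, y0
            for _ in range(4000):
                dx, dy = p_switch_rhs(x, y, PP)
                x = max(x + 0.05 * dx, 0.0)
                y = max(y + 0.05 * dy, 0.0)
            near = min(stable, key=lambda fp: (fp.x - x) ** 2 + (fp.y - y) ** 2)
            if np.hypot(near.x - x, near.y - y) > 2.0:
                continue  # not converged: boundary point, skip
            got = classify_fate(int(round(x0)), int(round(y0)), p_map)
            near_label = near.fate_label
            # allow mismatch only right at the boundary (within 2 units)
            if got != near_label:
                d_alt = min(np.hypot(fp.x - x0, fp.y - y0)
                            for fp in stable if fp.fate_label == got)
                assert d_alt < np.inf  # label exists; boundary tolerance below
                xi = int(round(x0)); yi = int(round(y0))
                window = p_map.labels[max(xi - 2, 0):xi + 3,
                                      max(yi - 2, 0):yi + 3]
                assert near_label in window

    def test_shifted_eps_enlarges_a_basin(self, map_families):
        fam = map_families
        e = fam["eps_levels"]
        i30 = int(np.argmin(abs(e - 30.0)))
        base = (fam["p_maps"][0, 0] == lattice.A).mean()
        shifted = (fam["p_maps"][i30, 0] == lattice.A).mean()
        assert shifted > 2 * base

    def test_family_symmetry(self, map_families):
        fam = map_families
        m = fam["p_maps"]
        swap = {lattice.A: lattice.B, lattice.B: lattice.A,
                lattice.P: lattice.P}
        sw = np.vectorize(swap.get, otypes=[np.int8])(m[2, 0]).T
        assert np.array_equal(m[0, 2], sw)


class TestEpsilon:
    def test_zero_inputs_zero_eps1(self):
        e1, e2 = epsilon_coefficients(0, 0, 0, PP)
        assert e1 == 0.0
        # complement response at s_l = 0 sits at the top of its Hill curve
        assert e2 == pytest.approx(PP.eps_a, rel=1e-3)

    def test_g_saturates_at_b(self):
        e1, _ = epsilon_coefficients(0, PP.eps_b, 0, PP)
        assert e1 == pytest.approx(PP.eps_a)

    def test_f_gated_off_by_own_signal(self):
        e1_gated, _ = epsilon_coefficients(250, 1, 0, PP)
        e1_open, _ = epsilon_coefficients(250, 0, 0, PP)
        assert e1_open == pytest.approx(PP.eps_a, rel=1e-3)
        assert e1_gated == pytest.approx(PP.eps_a * 1 / PP.eps_b)

    def test_high_low_signal_bias_directions(self):
        hi = epsilon_coefficients(250, 0, 0, PP)
        lo = epsilon_coefficients(0, 0, 0, PP)
        assert hi[0] > hi[1] and lo[1] > lo[0]

    def test_inactive_leading_removes_f(self):
        e1, e2 = epsilon_coefficients(250, 0, 0, PP, leading_active=False)
        assert e1 == e2 == 0.0

    @settings(max_examples=60, deadline=None)
    @given(s=st.integers(1, 500), s_l=st.integers(0, 250))
    def test_eps_monotone_in_own_signal_and_bounded(self, s, s_l):
        # beyond the f gate (s_i >= 1) eps_i is non-decreasing in s_i and
        # bounded by twice the signalling scale
        e_lo = epsilon_coefficients(s_l, s, 0, PP)[0]
        e_hi = epsilon_coefficients(s_l, s + 7, 0, PP)[0]
        assert e_hi >= e_lo
        assert 0.0 <= e_lo <= 2 * PP.eps_a and 0.0 <= e_hi <= 2 * PP.eps_a
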