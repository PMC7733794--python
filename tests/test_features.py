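"""Landmark-cell, BVC and place-cell feature populations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualsys.environments import build_arena
from dualsys.features import (
    BVCParams,
    LandmarkCellParams,
    PlaceCellParams,
    build_lc_bank,
    build_place_cell_bank,
    bvc_activation,
    feature_table_pc,
    lc_activation,
    lc_population,
    one_hot,
    place_cell_rates,
)

LC = LandmarkCellParams(d_pref=3.0, theta_pref=0.5, sigma_d=1.0, sigma_theta=0.4, identity="L")


class TestLandmarkCells:
    def test_peak_at_preferred_tuning(self):
        peak = lc_activation(3.0, 0.5, LC)
        assert peak == pytest.approx(1.0)
        for d, th in [(2.0, 0.5), (3.0, 1.2), (5.0, -1.0)]:
            assert lc_activation(d, th, LC) < peak

    def test_one_sigma_distance_gives_exp_half(self):
        assert lc_activation(4.0, 0.5, LC) == pytest.approx(np.exp(-0.5))

    def test_angle_wrapping(self):
        assert lc_activation(3.0, 0.5 + 2 * np.pi, LC) == pytest.approx(1.0)

    def test_invalid_widths_rejected(self):
        with pytest.raises(ValueError):
            LandmarkCellParams(1.0, 0.0, -1.0, 0.3, "L")
        with pytest.raises(ValueError):
            lc_activation(-0.1, 0.0, LC)

    def test_absent_landmark_silences_its_cells(self):
        bank = build_lc_bank(["A", "B"], radii=(1.0, 2.0), n_angles=4)
        rates = lc_population((0.0, 0.0, 0.0), [((1.5, 0.0), "A")], bank)
        a_cells = np.array([c.identity == "A" for c in bank.cells])
        assert rates[a_cells].max() > 0
        assert np.all(rates[~a_cells] == 0)

    def test_rotation_in_place_permutes_angular_cells(self):
        bank = build_lc_bank(["A"], radii=(2.0,), n_angles=8)
        lm = [((2.0, 0.0), "A")]
        r0 = lc_population((0.0, 0.0, 0.0), lm, bank)
        r90 = lc_population((0.0, 0.0, np.pi / 2), lm, bank)
        # rotating the agent by one angular step shifts the active cell ring
        assert np.allclose(np.roll(r0.reshape(1, 8), -2, axis=1).ravel(), r90, atol=1e-12)

    def test_dead_ahead_landmark_maximizes_straight_ahead_cell(self):
        bank = build_lc_bank(["A"], radii=(1.0, 2.0, 3.0), n_angles=8)
        rates = lc_population((0.0, 0.0, 0.0), [((2.0, 0.0), "A")], bank)
        best = bank.cells[int(np.argmax(rates))]
        assert best.d_pref == 2.0 and best.theta_pref == pytest.approx(0.0)

    def test_identical_scenes_identical_vectors(self):
        bank = build_lc_bank(["A"])
        lm = [((3.0, 1.0), "A")]
        a = lc_population((1.0, -2.0, 0.7), lm, bank)
        b = lc_population((1.0, -2.0, 0.7), lm, bank)
        assert np.array_equal(a, b)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x=st.floats(-5, 5),
        y=st.floats(-5, 5),
        h=st.floats(-3, 3),
        dx=st.floats(-10, 10),
        dy=st.floats(-10, 10),
        rot=st.floats(-3, 3),
    )
    def test_egocentric_invariance_under_joint_rigid_motion(self, x, y, h, dx, dy, rot):
        """LC vectors depend only on the agent-relative scene geometry."""
        bank = build_lc_bank(["A"], radii=(1.0, 3.0), n_angles=4)
        lx, ly = x + 2.0, y + 1.0
        base = lc_population((x, y, h), [((lx, ly), "A")], bank)
        c, s = np.cos(rot), np.sin(rot)
        R = np.array([[c, -s], [s, c]])
        ax, ay = R @ (x, y) + (dx, dy)
        gx, gy = R @ (lx, ly) + (dx, dy)
        moved = lc_population((ax, ay, h + rot), [((gx, gy), "A")], bank)
        assert np.allclose(base, moved, atol=1e-9)


class TestBVCs:
    WALL = ((0.0, -4.0), (0.0, 4.0))

    def test_no_boundaries_zero_rate(self):
        p = BVCParams(np.pi, 2.0)
        assert bvc_activation((0.0, 0.0), [], p) == 0.0

    def test_additive_over_disjoint_segments(self):
        p = BVCParams(np.pi, 3.0)
        top = ((-3.0, 2.0), (-3.0, 4.0))
        bottom = ((-3.0, -4.0), (-3.0, -2.0))
        both = bvc_activation((0.0, 0.0), [top, bottom], p, ds=0.25)
        split = bvc_activation((0.0, 0.0), [top], p, ds=0.25) + bvc_activation(
            (0.0, 0.0), [bottom], p, ds=0.25
        )
        assert both == pytest.approx(split, rel=1e-9)

    def test_nearer_wall_subtends_larger_angle(self):
        # same wall length at the preferred distance versus twice as far
        p = BVCParams(0.0, 2.0, sigma0=1.0, beta=100.0, sigma_ang=2.0)
        near = bvc_activation((0.0, 0.0), [((2.0, -1.0), (2.0, 1.0))], p, ds=0.05)
        p_far = BVCParams(0.0, 4.0, sigma0=1.0, beta=100.0, sigma_ang=2.0)
        far = bvc_activation((0.0, 0.0), [((4.0, -1.0), (4.0, 1.0))], p_far, ds=0.05)
        assert near > far

    def test_radial_width_grows_with_preferred_distance(self):
        assert BVCParams(0.0, 8.0).sigma_rad > BVCParams(0.0, 1.0).sigma_rad

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            BVCParams(0.0, 1.0, sigma0=-1.0)


class TestPlaceCells:
    def test_threshold_above_drive_silences_map(self):
        cell = PlaceCellParams([BVCParams(np.pi, 2.0)], threshold=1e9)
        rates = place_cell_rates((0.0, 0.0), [TestBVCs.WALL], [cell])
        assert np.all(rates == 0)

    def test_place_cell_needs_bvcs(self):
        with pytest.raises(ValueError):
            PlaceCellParams([], 0.0)

    def test_square_box_fields_are_localized(self):
        """In an enclosed box, conjunctive cells fire in one compact field."""
        arena = build_arena("open_field", size=12)
        walls = [
            ((-6, -6), (6, -6)),
            ((6, -6), (6, 6)),
            ((6, 6), (-6, 6)),
            ((-6, 6), (-6, -6)),
        ]
        bank = build_place_cell_bank(
            arena, spacing=3, mode="conjunctive", threshold_frac=0.75, walls=walls
        )
        F = feature_table_pc(arena, bank, walls=walls)
        n_local = 0
        for k in range(bank.n_features):
            field = (F[:, k] > 0).reshape(arena.grid_shape)
            if not field.any():
                continue
            assert field.mean() < 0.35  # compact support
            n_local += _n_components(field) == 1
        assert n_local >= 0.8 * bank.n_features

    def test_removing_wall_weakens_dependent_fields(self):
        arena = build_arena("open_field", size=12)
        walls = [((-6, -6), (-6, 6)), ((6, -6), (6, 6))]
        bank = build_place_cell_bank(
            arena, spacing=3, mode="per_wall", walls=walls
        )
        full = feature_table_pc(arena, bank, walls=walls)
        no_left = feature_table_pc(arena, bank, walls=walls[1:])
        left_cells = [k for k, c in enumerate(bank.cells) if c.label.endswith("w0")]
        assert full[:, left_cells].max() > 0
        assert np.all(no_left[:, left_cells] == 0)
        right_cells = [k for k, c in enumerate(bank.cells) if c.label.endswith("w1")]
        # right-wall cells barely change (only far Gaussian tails touched)
        assert np.allclose(no_left[:, right_cells], full[:, right_cells], atol=0.02)

    def test_rates_heading_free_and_nonnegative(self):
        arena = build_arena("open_field", size=10)
        walls = [((-5, -5), (-5, 5))]
        bank = build_place_cell_bank(arena, spacing=2, mode="per_wall", walls=walls)
        F = feature_table_pc(arena, bank, walls=walls)
        assert np.all(F >= 0)  # place-cell rates are rates
        # allocentric: the API takes positions only, no heading enters
        assert bank.rates((1.0, 1.0), walls).shape == (bank.n_features,)


def _n_components(mask):
    """4-connected component count on a boolean grid (test helper)."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    nx, ny = mask.shape
    for i in range(nx):
        for j in range(ny):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                while stack:
                    a, b = stack.pop()
                    if not (0 <= a < nx and 0 <= b < ny) or seen[a, b] or not mask[a, b]:
                        continue
                    seen[a, b] = True
                    stack += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
    return n


class TestOneHot:
    @pytest.mark.parametrize("i,n", [(0, 1), (2, 5), (4, 5)])
    def test_unit_vector(self, i, n):
        v = one_hot(i, n)
        assert v.sum() == 1.0 and v[i] == 1.0

    def test_distinct_states_orthogonal(self):
        assert one_hot(1, 4) @ one_hot(2, 4) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            one_hot(5, 5)
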