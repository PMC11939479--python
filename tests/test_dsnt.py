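"""DSNT core: grids, softmax normalization, expectation, regularizer,
target heatmaps and argmax decoding."""

import numpy as np
import pytest

from carapace_landmarks.dsnt import (build_grids, decode_argmax,
                                     dsnt_expectation, dsnt_regularizer,
                                     normalize_heatmaps,
                                     render_target_heatmaps,
                                     target_distribution)

RNG = np.random.default_rng(11)


class TestCoordinateGrids:
    def test_single_cell_is_origin(self):
        g = build_grids(1, 1)
        assert g.X[0, 0] == 0.0 and g.Y[0, 0] == 0.0

    def test_two_columns(self):
        g = build_grids(1, 2)
        assert np.allclose(g.X[0], [-0.5, 0.5])

    def test_32_grid_boundary_values(self):
        g = build_grids(32, 32)
        assert g.X[0, 0] == pytest.approx(-31 / 32, abs=1e-15)
        assert g.X[0, 31] == pytest.approx(31 / 32, abs=1e-15)
        assert g.Y[0, 0] == pytest.approx(-31 / 32, abs=1e-15)
        assert g.Y[31, 0] == pytest.approx(31 / 32, abs=1e-15)

    def test_axis_structure_and_antisymmetry(self):
        g = build_grids(5, 7)
        assert np.allclose(g.X, g.X[0])               # varies with j only
        assert np.allclose(g.Y, g.Y[:, :1])           # varies with i only
        assert np.allclose(g.X, -g.X[:, ::-1])
        assert np.allclose(g.Y, -g.Y[::-1, :])

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            build_grids(0, 4)


class TestNormalizeHeatmaps:
    def test_constant_channel_uniform(self):
        Z = np.full((2, 4, 6), 3.7)
        out = normalize_heatmaps(Z)
        assert np.allclose(out, 1.0 / 24)

    def test_hand_computed_softmax(self):
        Z = np.array([[np.log(3.0), 0.0], [0.0, 0.0]])
        out = normalize_heatmaps(Z)
        assert np.allclose(out, [[0.5, 1 / 6], [1 / 6, 1 / 6]], atol=1e-12)

    def test_channels_sum_to_one_extreme_logits(self):
        Z = RNG.uniform(-50, 50, size=(8, 16, 16))
        out = normalize_heatmaps(Z)
        assert np.allclose(out.sum(axis=(-2, -1)), 1.0, atol=1e-6)
        assert (out > 0).all()

    def test_shift_invariance_exact(self):
        Z = RNG.normal(size=(3, 5, 5))
        out1 = normalize_heatmaps(Z)
        out2 = normalize_heatmaps(Z + 11.3)
        assert np.allclose(out1, out2, atol=1e-12)


class TestDSNTExpectation:
    def test_uniform_gives_origin(self):
        g = build_grids(32, 32)
        Zn = np.full((1, 32, 32), 1.0 / 1024)
        xy = dsnt_expectation(Zn, g)
        assert np.allclose(xy, 0.0, atol=1e-12)

    def test_one_hot_reads_grid_value(self):
        g = build_grids(32, 32)
        Zn = np.zeros((1, 32, 32))
        Zn[0, 0, 31] = 1.0                    # i=1, j=32 (1-based)
        xy = dsnt_expectation(Zn, g)
        assert xy[0, 0] == pytest.approx(31 / 32)
        assert xy[0, 1] == pytest.approx(-31 / 32)

    def test_hand_computed_2x2(self):
        g = build_grids(2, 2)
        Zn = np.array([[[0.5, 1 / 6], [1 / 6, 1 / 6]]])
        xy = dsnt_expectation(Zn, g)
        assert np.allclose(xy, [[-1 / 6, -1 / 6]], atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        g = build_grids(5, 7)
        Zn = normalize_heatmaps(RNG.normal(size=(4, 5, 7)))
        got = dsnt_expectation(Zn, g)
        for k in range(4):
            x = sum(Zn[k, i, j] * g.X[i, j]
                    for i in range(5) for j in range(7))
            y = sum(Zn[k, i, j] * g.Y[i, j]
                    for i in range(5) for j in range(7))
            assert abs(got[k, 0] - x) < 1e-12
            assert abs(got[k, 1] - y) < 1e-12

    def test_outputs_strictly_inside_unit_box(self):
        g = build_grids(9, 9)
        Zn = normalize_heatmaps(RNG.uniform(-30, 30, size=(50, 9, 9)))
        xy = dsnt_expectation(Zn, g)
        assert np.all(np.abs(xy) < 1.0)

    def test_low_temperature_limit_agrees_with_argmax(self):
        """Sharpening the softmax drives the expectation to the argmax cell."""
        g = build_grids(6, 8)
        # distinct values with a guaranteed margin so the max is unique
        raw = np.stack([RNG.permutation(np.linspace(0.0, 1.0, 48)).reshape(6, 8)
                        for _ in range(3)])
        hard = decode_argmax(raw)
        gaps = []
        for temp in (0.1, 0.01, 0.001):
            soft = dsnt_expectation(normalize_heatmaps(raw / temp), g)
            err = 0.0
            for k in range(3):
                j, i = int(hard[k, 0]), int(hard[k, 1])
                err = max(err, abs(soft[k, 0] - g.X[i, j]),
                          abs(soft[k, 1] - g.Y[i, j]))
            gaps.append(err)
        assert gaps[0] >= gaps[1] >= gaps[2]
        assert gaps[-1] < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsnt_expectation(np.zeros((1, 4, 4)), build_grids(5, 5))


class TestRegularizer:
    def test_zero_when_heatmap_equals_target(self):
        g = build_grids(8, 8)
        tgt = np.array([[0.1, -0.2]])
        Q = target_distribution(tgt, g, sigma_t=1.0)
        assert dsnt_regularizer(Q, tgt, g, sigma_t=1.0) <= 1e-9

    def test_bounded_by_ln2(self):
        g = build_grids(6, 6)
        tgt = RNG.uniform(-0.8, 0.8, size=(10, 2))
        Zn = normalize_heatmaps(RNG.uniform(-40, 40, size=(10, 6, 6)))
        val = dsnt_regularizer(Zn, tgt, g)
        assert 0.0 <= val <= np.log(2.0) + 1e-12

    def test_decreases_along_interpolation_to_target(self):
        g = build_grids(8, 8)
        tgt = np.array([[0.3, 0.1]])
        Q = target_distribution(tgt, g, sigma_t=1.0)
        P = normalize_heatmaps(RNG.normal(size=(1, 8, 8)))
        vals = [dsnt_regularizer((1 - a) * P + a * Q, tgt, g)
                for a in np.linspace(0, 1, 8)]
        assert all(v1 >= v2 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_invalid_sigma_rejected(self):
        g = build_grids(4, 4)
        with pytest.raises(ValueError):
            dsnt_regularizer(np.full((1, 4, 4), 1 / 16.0),
                             np.zeros((1, 2)), g, sigma_t=0.0)


class TestTargetHeatmaps:
    def test_peak_value_one_at_integer_landmark(self):
        hm = render_target_heatmaps(np.array([[[17.0, 5.0]]]), 3.0, 32, 32)
        assert hm[0, 0].max() == pytest.approx(1.0)
        assert hm[0, 0, 5, 17] == pytest.approx(1.0)

    def test_out_of_frame_landmark_zero_channel(self):
        hm = render_target_heatmaps(np.array([[[-4.0, 10.0]]]), 3.0, 32, 32)
        assert np.all(hm[0, 0] == 0.0)

    def test_wider_sigma_more_mass_outside_radius(self):
        p = np.array([[[16.0, 16.0]]])
        narrow = render_target_heatmaps(p, 2.0, 32, 32)[0, 0]
        wide = render_target_heatmaps(p, 4.0, 32, 32)[0, 0]
        yy, xx = np.mgrid[0:32, 0:32]
        outside = np.hypot(xx - 16, yy - 16) > 2.0
        assert (wide[outside].sum() / wide.sum()
                > narrow[outside].sum() / narrow.sum())

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            render_target_heatmaps(np.zeros((1, 1, 2)), 0.0, 8, 8)


class TestDecodeArgmax:
    def test_round_trip_with_rendered_gaussian(self):
        hm = render_target_heatmaps(np.array([[[100.0, 37.0]]]), 5.0,
                                    128, 128)
        assert np.array_equal(decode_argmax(hm)[0, 0], [100.0, 37.0])

    def test_constant_channel_ties_to_origin(self):
        out = decode_argmax(np.ones((2, 8, 8)))
        assert np.array_equal(out, np.zeros((2, 2)))

    def test_decode_render_equals_round_on_grid(self):
        xs = np.linspace(2.3, 28.7, 6)
        ys = np.linspace(3.1, 27.9, 6)
        pts = np.array([[x, y] for x in xs for y in ys])[None]
        hm = render_target_heatmaps(pts, 2.5, 32, 32)
        decoded = decode_argmax(hm)
        assert np.array_equal(decoded[0], np.round(pts[0]))

    def test_empty_heatmap_rejected(self):
        with pytest.raises(ValueError):
            decode_argmax(np.zeros((1, 0, 4)))
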