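"""Procedural carapace generator: geometry, rendering, datasets."""

import json

import numpy as np
import pytest
from scipy import ndimage

from carapace_landmarks.schema import build_schema
from carapace_landmarks.synthetic import (CarapaceParams, JitterConfig,
                                          default_test_size, generate_dataset,
                                          landmarks_from_params, make_dataset,
                                          outline_polygon, render,
                                          sample_params)


@pytest.fixture(scope="module")
def params():
    return sample_params(7, image_size=128)


@pytest.fixture(scope="module")
def sample(params):
    return render(params)


class TestSampleParams:
    def test_deterministic(self):
        a = sample_params(42, image_size=128)
        b = sample_params(42, image_size=128)
        assert a.center == b.center
        assert np.array_equal(a.tooth_amplitudes, b.tooth_amplitudes)
        assert a.texture_seed == b.texture_seed

    def test_zero_jitter_gives_template(self):
        p = sample_params(5, jitter=JitterConfig.zero(), image_size=128)
        q = sample_params(99, jitter=JitterConfig.zero(), image_size=128)
        assert p.center == q.center == (64.0, 64.0)
        assert p.semi_axes == q.semi_axes
        assert np.array_equal(p.tooth_amplitudes, q.tooth_amplitudes)

    def test_ranges_respected_over_many_seeds(self):
        jitter = JitterConfig()
        lo, hi = jitter.scale_range
        for seed in range(300):
            p = sample_params(seed, jitter=jitter, image_size=128)
            assert lo * 0.33 * 128 <= p.semi_axes[0] <= hi * 0.33 * 128
            assert lo * 0.29 * 128 <= p.semi_axes[1] <= hi * 0.29 * 128
            p.validate()

    def test_off_image_carapace_rejected(self):
        p = sample_params(0, image_size=128)
        p.semi_axes = (120.0, 120.0)
        with pytest.raises(ValueError, match="fit"):
            p.validate()


class TestLandmarksFromParams:
    def test_37_carapace_points_plus_bbox(self, params):
        lm = landmarks_from_params(params)
        assert lm.n_points == 39
        assert np.isfinite(lm.coords).all()

    def test_schema_validates(self, params):
        lm = landmarks_from_params(params)
        lm.schema.validate()
        assert lm.schema is not None and lm.n_points == 39

    def test_shared_tooth_points_exactly_equal(self, params):
        lm = landmarks_from_params(params)
        for _, s, _, e in lm.schema.teeth:
            assert np.isfinite(lm.coords[s - 1]).all()
        by_group = {}
        for g, s, p, e in lm.schema.teeth:
            by_group.setdefault(g, []).append((s, p, e))
        for teeth in by_group.values():
            for (_, _, e0), (s1, _, _) in zip(teeth, teeth[1:]):
                assert np.array_equal(lm.coords[e0 - 1], lm.coords[s1 - 1])

    def test_zero_amplitude_peak_on_base_outline(self, params):
        import copy
        p = copy.deepcopy(params)
        p.tooth_amplitudes = np.zeros(12)
        lm = landmarks_from_params(p)
        center = np.asarray(p.center)
        # peak points (ids 2,4,6,8 within each tooth group) sit at the
        # base super-ellipse radius when the amplitude is zero
        for _, s, peak, e in lm.schema.teeth:
            pk = lm.coords[peak - 1] - center
            chord_mid = (lm.coords[s - 1] + lm.coords[e - 1]) / 2 - center
            assert np.linalg.norm(pk) <= np.linalg.norm(chord_mid) * 1.05

    def test_rotation_rotates_all_landmarks(self, params):
        import copy
        p0 = copy.deepcopy(params)
        p0.orientation = 0.0
        theta = 0.37
        p1 = copy.deepcopy(params)
        p1.orientation = theta
        l0 = landmarks_from_params(p0).coords[:37]
        l1 = landmarks_from_params(p1).coords[:37]
        c = np.asarray(params.center)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert np.allclose((l0 - c) @ R.T + c, l1, atol=1e-6)

    def test_groove_is_m_shaped(self, params):
        """Interior groove vertices alternate down-up-down-up."""
        import copy
        p = copy.deepcopy(params)
        p.orientation = 0.0
        groove = landmarks_from_params(p).coords[30:37]
        dy = np.diff(groove[:, 1])
        signs = np.sign(dy)
        assert all(signs[i] != signs[i + 1] for i in range(len(signs) - 1))

    def test_groove_ordered_left_to_right(self, params):
        import copy
        p = copy.deepcopy(params)
        p.orientation = 0.0
        groove = landmarks_from_params(p).coords[30:37]
        assert np.all(np.diff(groove[:, 0]) > 0)


class TestRender:
    def test_deterministic_bit_identical(self, params):
        a = render(params)
        b = render(params)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.landmarks.coords, b.landmarks.coords)

    def test_shape_and_dtype(self, sample):
        assert sample.image.shape == (128, 128, 3)
        assert sample.image.dtype == np.uint8

    def test_512_resolution_supported(self):
        p = sample_params(3, image_size=512)
        s = render(p)
        assert s.image.shape == (512, 512, 3)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            p = CarapaceParams(image_size=32, center=(16, 16),
                               semi_axes=(8, 7),
                               tooth_amplitudes=np.full(12, 1.0),
                               groove_halfwidth=3.0)
            render(p)

    def test_interior_background_contrast(self, params, sample):
        poly = outline_polygon(params)
        from skimage.draw import polygon
        rr, cc = polygon(poly[:, 1], poly[:, 0], shape=(128, 128))
        mask = np.zeros((128, 128), bool)
        mask[rr, cc] = True
        diff = sample.image[mask].mean() - sample.image[~mask].mean()
        assert abs(diff) >= 20.0

    def test_outline_passes_through_tooth_landmarks(self, params, sample):
        from skimage.draw import polygon
        poly = outline_polygon(params)
        rr, cc = polygon(poly[:, 1], poly[:, 0], shape=(128, 128))
        mask = np.zeros((128, 128), bool)
        mask[rr, cc] = True
        edge = mask ^ ndimage.binary_erosion(mask)
        dist = ndimage.distance_transform_edt(~edge)
        lm = sample.landmarks.coords[:27]           # the three tooth groups
        for x, y in lm:
            assert dist[int(round(y)), int(round(x))] <= 1.5


class TestDatasets:
    def test_default_test_size_one_tenth(self):
        assert default_test_size(4600) == 460
        assert default_test_size(100) == 10

    def test_make_dataset_deterministic(self):
        a = make_dataset(3, seed=1, image_size=64)
        b = make_dataset(3, seed=1, image_size=64)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_generate_dataset_files_and_manifest(self, tmp_path):
        manifest = generate_dataset(4, 2, seed=3, out_dir=tmp_path,
                                    image_size=64)
        assert len(manifest) == 6
        splits = [rec["split"] for rec in manifest]
        assert splits.count("train") == 4 and splits.count("test") == 2
        for rec in manifest:
            assert (tmp_path / rec["image"]).exists()
            assert (tmp_path / rec["annotation"]).exists()
        lines = (tmp_path / "manifest.jsonl").read_text().splitlines()
        assert len(lines) == 6 and json.loads(lines[0])["split"] == "train"

    def test_generate_dataset_reproducible(self, tmp_path):
        m1 = generate_dataset(2, 1, seed=9, out_dir=tmp_path / "a",
                              image_size=64)
        m2 = generate_dataset(2, 1, seed=9, out_dir=tmp_path / "b",
                              image_size=64)
        assert [r["seed"] for r in m1] == [r["seed"] for r in m2]
        img1 = (tmp_path / "a" / m1[0]["image"]).read_bytes()
        img2 = (tmp_path / "b" / m2[0]["image"]).read_bytes()
        assert img1 == img2

    def test_invalid_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, 1, seed=0, out_dir=tmp_path)

    def test_generated_landmarks_validate_against_schema(self):
        schema = build_schema()
        for s in make_dataset(3, seed=2, image_size=64):
            assert s.landmarks.n_points == 39
            assert s.landmarks.schema.n_total == schema.n_total
            assert np.isfinite(s.landmarks.coords).all()
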