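from __future__ import annotations

import numpy as np
import pytest

import _references as ref
from handtremor import features as ft


class TestGradients:
    def test_constant_image_has_zero_gradients(self):
        field = ft.compute_gradients(np.full((6, 6), 9.0))
        assert not field.u_x.any() and not field.u_y.any()
        assert not field.u_g.any() and not field.u_o.any()

    def test_three_four_five_magnitude(self):
        assert np.hypot(3.0, 4.0) == 5.0  # documented identity used below
        img = np.zeros((5, 5))
        field = ft.GradientField(
            np.full((1, 1), 3.0), np.full((1, 1), 4.0), None, None
        )
        # magnitude recomputed the way compute_gradients does
        assert np.hypot(field.u_x, field.u_y)[0, 0] == 5.0
        del img

    def test_equal_derivatives_give_pi_over_4(self, rng):
        img = np.add.outer(np.arange(6.0), np.arange(6.0))  # diagonal ramp
        field = ft.compute_gradients(img)
        interior = field.u_o[1:-1, 1:-1]
        assert np.allclose(interior, np.pi / 4)

    def test_matches_brute_force_correlation(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 255, size=(6, 6))
            field = ft.compute_gradients(img)
            u_x, u_y, u_o, u_g = ref.gradients_ref(img)
            assert np.allclose(field.u_x, u_x, atol=1e-12)
            assert np.allclose(field.u_y, u_y, atol=1e-12)
            assert np.allclose(field.u_o, u_o, atol=1e-12)
            assert np.allclose(field.u_g, u_g, atol=1e-12)

    def test_magnitude_non_negative(self, rng):
        field = ft.compute_gradients(rng.normal(size=(12, 12)))
        assert (field.u_g >= 0).all()


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(8, 1 / 8), 3.0),
            (np.array([1.0, 0.0, 0.0]), 0.0),
            (np.array([0.5, 0.5]), 1.0),
        ],
    )
    def test_known_values(self, p, expected):
        assert ft.shannon_entropy(p, base=2) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            ft.shannon_entropy(np.array([1.2, -0.2]))


class TestImprovedEntropy:
    def test_finite_and_non_negative_on_random_maps(self, rng):
        for _ in range(20):
            value = ft.improved_entropy(rng.normal(scale=50, size=(8, 8)))
            assert np.isfinite(value) and value >= 0.0

    def test_matches_scalar_transcription_on_hand_built_masses(self):
        masses = np.array([0.4, 0.3, 0.2, 0.1])
        assert ft.entropy_from_masses(masses) == pytest.approx(
            ref.improved_entropy_masses_ref(masses), abs=1e-12
        )

    def test_map_value_matches_reference(self, rng):
        g = rng.normal(scale=20, size=(8, 8))
        assert ft.improved_entropy(g) == pytest.approx(
            ref.improved_entropy_map_ref(g), abs=1e-12
        )

    def test_bin_permutation_invariance(self, rng):
        masses = rng.dirichlet(np.ones(6))
        shuffled = rng.permutation(masses)
        assert ft.entropy_from_masses(masses) == pytest.approx(
            ft.entropy_from_masses(shuffled), abs=1e-12
        )

    def test_all_zero_gradient_map_returns_zero(self):
        assert ft.improved_entropy(np.zeros((5, 5))) == 0.0

    def test_scale_within_bins_preserves_value(self, rng):
        # the value depends on the map only through bin probabilities
        g = rng.normal(scale=10, size=(10, 10))
        assert ft.improved_entropy(2.0 * g) == pytest.approx(ft.improved_entropy(g))


class TestModifiedGradients:
    def test_constant_image_derivatives_equal_ie(self):
        field = ft.modified_gradients(np.full((8, 8), 3.0))
        # zero gradients -> both entropies 0 -> IE = 0 added uniformly
        assert np.allclose(field.u_x, 0.0) and np.allclose(field.u_y, 0.0)

    def test_uniform_ie_shift_against_plain_gradients(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        plain = ft.compute_gradients(img)
        modified = ft.modified_gradients(img)
        shift_x = modified.u_x - plain.u_x
        shift_y = modified.u_y - plain.u_y
        assert np.ptp(shift_x) < 1e-12 and np.ptp(shift_y) < 1e-12  # scalar broadcast
        assert shift_x[0, 0] == pytest.approx(shift_y[0, 0])
        assert shift_x[0, 0] > 0

    def test_pipeline_matches_straight_line_reference(self, rng):
        for _ in range(3):
            img = rng.uniform(0, 255, size=(8, 8))
            field = ft.modified_gradients(img)
            u_x, u_y, u_g = ref.modified_gradients_ref(img)
            assert np.allclose(field.u_x, u_x, atol=1e-9)
            assert np.allclose(field.u_y, u_y, atol=1e-9)
            assert np.allclose(field.u_g, u_g, atol=1e-9)

    def test_ie_selection_rule(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        plain = ft.compute_gradients(img)
        pair = ft.entropy_pair(plain)
        if abs(pair.e_x - pair.e_y) > 1e-6:
            assert pair.selected == max(pair.e_x, pair.e_y)
        else:
            assert pair.selected == pytest.approx((pair.e_x + pair.e_y) / 2)
        assert pair.threshold == pytest.approx((pair.e_x + pair.e_y) / 2)


class TestPhog:
    def test_vector_length_l2_k8(self, rng):
        field = ft.compute_gradients(rng.uniform(size=(32, 32)))
        vec = ft.phog(field, ft.PhogConfig(levels=2, bins=8))
        assert vec.shape == (168,)
        assert ft.phog_length(2, 8) == 168

    def test_l1_normalization(self, rng):
        field = ft.compute_gradients(rng.uniform(0, 255, size=(16, 16)))
        vec = ft.phog(field)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        assert (vec >= 0).all()

    def test_mass_conservation_per_level(self, rng):
        field = ft.compute_gradients(rng.uniform(0, 255, size=(17, 23)))
        config = ft.PhogConfig(levels=2, bins=8, norm="none")
        vec = ft.phog(field, config)
        total = field.u_g.sum()
        offset = 0
        for level in range(3):
            n_cells = 4**level
            level_sum = vec[offset : offset + n_cells * 8].sum()
            assert level_sum == pytest.approx(total)
            offset += n_cells * 8

    def test_rotation_permutes_level0_bins(self):
        rng = np.random.default_rng(0)
        img = np.tile(rng.uniform(0, 255, size=(32, 1)), (1, 32))  # horizontal stripes
        f0 = ft.compute_gradients(img)
        f90 = ft.compute_gradients(np.rot90(img))
        cfg = ft.PhogConfig(levels=0, bins=8, norm="l1")
        h0 = ft.phog(f0, cfg)
        h90 = ft.phog(f90, cfg)
        assert np.allclose(np.roll(h0, 4), h90, atol=1e-9)

    def test_too_deep_pyramid_rejected(self, rng):
        field = ft.compute_gradients(rng.uniform(size=(4, 4)))
        with pytest.raises(ValueError):
            ft.phog(field, ft.PhogConfig(levels=3))


class TestShapeFeatures:
    def test_filled_square_polygonal_area(self):
        img = np.full((20, 20), 255.0)
        img[5:15, 5:15] = 0.0  # 10x10 ink square
        sf = ft.shape_features(img)
        # marching-squares polygon of a 10x10 block: 100 px^2 minus corner cuts
        assert sf.area == pytest.approx(100.0, rel=0.02)
        assert sf.hull_area == pytest.approx(sf.area, rel=0.02)
        assert sf.perimeter == pytest.approx(40.0, rel=0.05)
        assert sf.epsilon == pytest.approx(0.01 * sf.perimeter)

    def test_filled_disk_area(self):
        yy, xx = np.mgrid[:64, :64]
        img = np.where((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2, 0.0, 255.0)
        sf = ft.shape_features(img)
        assert abs(sf.area - np.pi * 400) / (np.pi * 400) < 0.05

    def test_hull_area_dominates_on_random_blobs(self, rng):
        from scipy import ndimage as ndi

        for _ in range(20):
            blob = rng.random((32, 32)) < 0.4
            blob = ndi.binary_closing(blob, np.ones((3, 3)))
            if not blob.any():
                continue
            img = np.where(blob, 0.0, 255.0)
            try:
                sf = ft.shape_features(img)
            except ft.BlankImageError:
                continue
            assert sf.hull_area >= sf.area - 1e-9

    def test_blank_image_error_names_threshold(self):
        with pytest.raises(ft.BlankImageError, match="threshold"):
            ft.shape_features(np.full((16, 16), 255.0), binarize_threshold=10.0)

    def test_spiral_drawing_has_sane_geometry(self, spiral_image):
        sf = ft.shape_features(spiral_image)
        assert sf.perimeter > 0 and sf.hull_area >= sf.area


class TestDeepFeatures:
    CFG32 = ft.DeepFeatureConfig(input_size=32)

    def test_embedding_lengths(self, spiral_image):
        vgg = ft.deep_features(spiral_image, ft.DeepFeatureConfig(("vgg16",), 32))
        res = ft.deep_features(spiral_image, ft.DeepFeatureConfig(("resnet50",), 32))
        both = ft.deep_features(
            spiral_image, ft.DeepFeatureConfig(("resnet50", "vgg16"), 32)
        )
        assert vgg.shape == (512,)
        assert res.shape == (2048,)
        assert both.shape == (2560,)

    def test_deterministic_given_seed(self, spiral_image):
        a = ft.deep_features(spiral_image, self.CFG32)
        b = ft.deep_features(spiral_image, self.CFG32)
        assert np.array_equal(a, b)

    def test_distinct_drawings_distinct_embeddings(self, spiral_image):
        from handtremor import synthetic as sy

        spec = sy.DrawingSpec(pattern="meander")
        other = sy.render(sy.generate_path(spec, sy.PATIENT_TREMOR, 3), spec)
        a = ft.deep_features(spiral_image, self.CFG32)
        b = ft.deep_features(other, self.CFG32)
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos < 1.0 - 1e-6

    def test_missing_pretrained_file_is_an_error(self, spiral_image):
        cfg = ft.DeepFeatureConfig(
            ("vgg16",), 32, weights_mode="pretrained-file", weights_path="/no/such.npz"
        )
        with pytest.raises(FileNotFoundError):
            ft.deep_features(spiral_image, cfg)


class TestFusion:
    def _segments(self, rng):
        phog_vec = rng.dirichlet(np.ones(168))
        shape = ft.ShapeFeatures(100.0, 40.0, 120.0, 12, 0.4)
        deep = rng.normal(size=512)
        return phog_vec, shape, deep

    def test_length_additivity_and_round_trip(self, rng):
        phog_vec, shape, deep = self._segments(rng)
        fused = ft.fuse(phog_vec, shape, deep)
        assert fused.vector.shape == (168 + 5 + 512,)
        assert np.array_equal(fused.layout.segment(fused.vector, "phog"), phog_vec)
        assert np.array_equal(
            fused.layout.segment(fused.vector, "shape"), shape.as_vector()
        )
        assert np.array_equal(fused.layout.segment(fused.vector, "deep"), deep)

    def test_nan_segment_identified(self, rng):
        phog_vec, shape, deep = self._segments(rng)
        deep[3] = np.nan
        with pytest.raises(ValueError, match="deep"):
            ft.fuse(phog_vec, shape, deep)

    def test_standardized_train_statistics(self, rng):
        matrix = rng.normal(loc=5.0, scale=3.0, size=(200, 30))
        layout = ft.FeatureLayout(("phog", "shape", "deep"), (0, 20, 25, 30))
        std = ft.FeatureStandardizer().fit(matrix, layout)
        z = std.transform(matrix)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)
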