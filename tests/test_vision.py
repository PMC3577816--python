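"""Early vision: stream splitting, filters, saliency, stimuli, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazesim.vision import (
    FeatureClass,
    IntensityMaps,
    SaliencyWeights,
    colour_filter,
    compute_saliency,
    extract_feature_vector,
    extract_stimuli,
    movement_filter,
    split_streams,
)
from gazesim.world import RetinalImage


def frame(pixels, fovea_side=2):
    return RetinalImage(pixels=np.asarray(pixels, dtype=float), fovea_side=fovea_side)


class TestSplitStreams:
    def test_factor_one_is_identity(self):
        px = np.random.default_rng(0).random((4, 4, 3))
        _, low = split_streams(frame(px), 1)
        assert np.allclose(low, px)

    def test_uniform_image_downsamples_to_itself(self):
        px = np.full((8, 8, 3), 0.3)
        _, low = split_streams(frame(px), 4)
        assert low.shape == (2, 2, 3)
        assert np.allclose(low, 0.3)

    def test_checkerboard_blocks_average_to_grey(self):
        px = np.zeros((4, 4, 3))
        px[::2, 1::2] = 1.0
        px[1::2, ::2] = 1.0
        _, low = split_streams(frame(px), 2)
        assert np.allclose(low, 0.5)

    def test_foveal_patch_is_centred_window(self):
        px = np.zeros((6, 6, 3))
        px[2:4, 2:4] = 1.0
        fov, _ = split_streams(frame(px, fovea_side=2), 2)
        assert np.all(fov == 1.0)

    def test_factor_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            split_streams(frame(np.zeros((4, 4, 3))), 8)


class TestColourFilter:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),  # pure colour scores 1
            ((0.5, 0.5, 0.5), (0.0, 0.0, 0.0)),  # grey is colourless
            ((0.8, 0.3, 0.1), (0.5, 0.0, 0.0)),  # dominance = C - max(others)
            ((0.0, 0.2, 0.9), (0.0, 0.0, 0.7)),
        ],
    )
    def test_dominance(self, cell, expected):
        maps = colour_filter(np.array([[cell]]))
        got = (maps.i_red[0, 0], maps.i_green[0, 0], maps.i_blue[0, 0])
        assert got == pytest.approx(expected)


class TestMovementFilter:
    def test_identical_frames_give_zero(self):
        a = np.random.default_rng(1).random((3, 3, 3))
        assert np.all(movement_filter(a, a.copy()) == 0.0)

    def test_black_to_white_gives_one(self):
        assert movement_filter(np.ones((1, 1, 3)), np.zeros((1, 1, 3)))[0, 0] == 1.0

    def test_mean_absolute_difference(self):
        prev = np.full((1, 1, 3), 0.2)
        cur = np.full((1, 1, 3), 0.5)
        assert movement_filter(cur, prev)[0, 0] == pytest.approx(0.3)

    def test_first_frame_is_all_zero(self):
        assert np.all(movement_filter(np.ones((2, 2, 3)), None) == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            movement_filter(np.zeros((2, 2, 3)), np.zeros((3, 3, 3)))


def maps_from(i_red=0.0, i_green=0.0, i_blue=0.0, i_mov=0.0):
    one = np.ones((1, 1))
    return IntensityMaps(i_red * one, i_green * one, i_blue * one, i_mov * one)


class TestComputeSaliency:
    def test_single_attribute_maximum(self):
        s = compute_saliency(maps_from(i_red=1.0), SaliencyWeights(1, 0, 0, 0))
        assert s[0, 0] == 1.0

    def test_no_intensity_gives_zero(self):
        s = compute_saliency(maps_from(), SaliencyWeights(1, 1, 1, 1))
        assert s[0, 0] == 0.0

    def test_weighted_sum_normalised_by_weight_total(self):
        w = SaliencyWeights(1.0, 0.5, 0.0, 0.0)
        assert compute_saliency(maps_from(i_red=1, i_green=1), w)[0, 0] == pytest.approx(1.0)
        assert compute_saliency(maps_from(i_green=1), w)[0, 0] == pytest.approx(0.5 / 1.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            compute_saliency(maps_from(i_red=1), SaliencyWeights(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(*[st.floats(0, 1) for _ in range(4)]), min_size=1, max_size=9
        ),
        weights=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    def test_bounds_and_scale_invariance(self, data, weights):
        if sum(weights) == 0:
            weights = (0.3, *weights[1:])
        arr = np.array(data).reshape(-1, 1, 4)
        maps = IntensityMaps(arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3])
        s1 = compute_saliency(maps, SaliencyWeights(*weights))
        assert np.all((0.0 <= s1) & (s1 <= 1.0))
        s2 = compute_saliency(maps, SaliencyWeights(*[w * 0.5 for w in weights]))
        assert np.allclose(s1, s2, atol=1e-12)


def brute_force_components(smap, s_min):
    """Independent oracle: BFS connected components with 4-connectivity."""
    mask = smap > s_min
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, cells = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    cells.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if 0 <= na < h and 0 <= nb < w and mask[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
                comps.append(cells)
    return comps


class TestExtractStimuli:
    def test_all_zero_map_is_empty(self):
        assert extract_stimuli(np.zeros((4, 4))) == []

    def test_single_cell_stimulus_at_cell_centre(self):
        smap = np.zeros((4, 4))
        smap[1, 2] = 0.7
        (st1,) = extract_stimuli(smap, 0.05, lattice_factor=8)
        assert (st1.x, st1.y, st1.s) == pytest.approx((2.5 * 8, 1.5 * 8, 0.7))

    def test_two_blobs_ordered_by_descending_saliency(self):
        smap = np.zeros((6, 6))
        smap[0:2, 0:2] = 0.4
        smap[4:6, 4:6] = 0.9
        out = extract_stimuli(smap, 0.05)
        assert [st1.s for st1 in out] == [0.9, 0.4]

    def test_matches_brute_force_components_on_random_maps(self, rng):
        for _ in range(200):
            smap = rng.choice([0.0, 0.0, 0.2, 0.5, 0.9], size=(8, 8))
            got = extract_stimuli(smap, 0.05)
            comps = brute_force_components(smap, 0.05)
            assert len(got) == len(comps)
            expected = set()
            for cells in comps:
                svals = np.array([smap[c] for c in cells])
                ys = np.array([c[0] + 0.5 for c in cells])
                xs = np.array([c[1] + 0.5 for c in cells])
                w = svals / svals.sum()
                expected.add(
                    (round((xs * w).sum(), 9), round((ys * w).sum(), 9), svals.max())
                )
            assert {(round(s.x, 9), round(s.y, 9), s.s) for s in got} == expected


class TestExtractFeatureVector:
    def test_fully_red_fovea_classifies_red(self):
        patch = np.tile([1.0, 0.0, 0.0], (8, 8, 1))
        fv = extract_feature_vector(patch)
        assert fv.cls is FeatureClass.RED
        assert list(fv.onehot) == [1, 0, 0, 0]
        assert fv.intensities == pytest.approx((1.0, 0.0, 0.0))

    def test_background_only_is_undefined(self):
        patch = np.tile([0.5, 0.5, 0.5], (8, 8, 1))
        assert extract_feature_vector(patch).cls is FeatureClass.UNDEFINED

    def test_low_coverage_degrades_to_undefined(self):
        # 30 red pixels in a 10x10 patch: 30% < the 50% coverage rule
        patch = np.tile([0.5, 0.5, 0.5], (10, 10, 1))
        patch[:3, :, :] = [1.0, 0.0, 0.0]
        fv = extract_feature_vector(patch)
        assert fv.cls is FeatureClass.UNDEFINED
        # the colour information itself is still reported
        assert fv.intensities == pytest.approx((1.0, 0.0, 0.0))

    def test_ambiguous_colour_is_undefined(self):
        patch = np.tile([0.6, 0.6, 0.0], (8, 8, 1))  # red/green tie: no dominance
        assert extract_feature_vector(patch).cls is FeatureClass.UNDEFINED

    def test_classification_is_deterministic(self, rng):
        patch = rng.random((8, 8, 3))
        assert extract_feature_vector(patch) == extract_feature_vector(patch.copy())
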