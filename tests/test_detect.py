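"""The three-band PCA detection pipeline and its boundary semantics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vnspi import detect
from vnspi.detect import (
    DetectParams,
    SpectralStack,
    binarize,
    classify,
    denoise,
    pca_pc1,
    reference_correct,
    run_pipeline,
    scale_pc1,
)

BANDS = (850, 910, 970)


def make_stack(images, refs=None):
    refs = refs or {b: np.full_like(images[b], 0.9) for b in images}
    return SpectralStack(bands=tuple(sorted(images)), images=dict(images), reference=refs)


def flood_fill_oracle(mask, connectivity=8):
    """Brute-force connected components by BFS; returns list of pixel sets."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                comp, queue = set(), [(r0, c0)]
                seen[r0, c0] = True
                while queue:
                    r, c = queue.pop()
                    comp.add((r, c))
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.append(comp)
    return comps


class TestReferenceCorrect:
    def test_sample_equal_reference_gives_ones(self):
        img = np.random.default_rng(0).uniform(0.1, 0.9, (8, 8))
        stack = make_stack({b: img.copy() for b in BANDS}, {b: img.copy() for b in BANDS})
        corrected = reference_correct(stack)
        for b in BANDS:
            np.testing.assert_allclose(corrected[b], 1.0)

    def test_source_intensity_scaling_cancels(self, rng):
        imgs = {b: rng.uniform(0.1, 0.5, (8, 8)) for b in BANDS}
        refs = {b: rng.uniform(0.5, 1.0, (8, 8)) for b in BANDS}
        base = reference_correct(make_stack(imgs, refs))
        doubled = reference_correct(
            make_stack({b: 2 * imgs[b] for b in BANDS}, {b: 2 * refs[b] for b in BANDS})
        )
        for b in BANDS:
            np.testing.assert_allclose(base[b], doubled[b], rtol=1e-12)

    def test_dark_reference_pixel_floored_and_counted(self):
        imgs = {b: np.full((4, 4), 0.5) for b in BANDS}
        refs = {b: np.full((4, 4), 0.9) for b in BANDS}
        refs[970][0, 0] = 0.0
        stack = make_stack(imgs, refs)
        corrected = reference_correct(stack, floor=1e-6)
        assert corrected[970][0, 0] == pytest.approx(0.5 / 1e-6)
        assert stack.floored_pixels == 1

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            SpectralStack(
                bands=BANDS,
                images={b: np.zeros((4, 4)) for b in BANDS},
                reference={850: np.zeros((4, 4))},
            )


class TestPca:
    def test_rank_one_two_band_loadings(self):
        shared = np.random.default_rng(1).uniform(0, 1, (6, 6))
        res = pca_pc1({1: shared, 2: shared.copy()}, bands=(1, 2))
        np.testing.assert_allclose(np.abs(res.loadings), [1, 1] / np.sqrt(2), atol=1e-9)
        centered = shared - shared.mean()
        np.testing.assert_allclose(res.scores, centered * np.sqrt(2), atol=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        corrected = {b: rng.uniform(0, 1, (10, 10)) for b in BANDS}
        res = pca_pc1(corrected, bands=BANDS)
        X = np.stack([corrected[b].ravel() for b in BANDS], axis=1)
        xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (xc.shape[0] - 1))
        lead = evecs[:, np.argmax(evals)]
        cos = abs(float(res.loadings @ lead))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_insect_contrast_concentrates_loading_at_970(self):
        rng = np.random.default_rng(2)
        corrected = {b: np.full((16, 16), 0.8) + 1e-4 * rng.standard_normal((16, 16))
                     for b in BANDS}
        drop = {850: 0.05, 910: 0.10, 970: 0.50}
        for b in BANDS:
            corrected[b][6:10, 6:10] -= drop[b]
        res = pca_pc1(corrected, bands=BANDS)
        assert np.argmax(np.abs(res.loadings)) == BANDS.index(970)

    def test_sign_anchored_to_brightness(self, rng):
        corrected = {b: rng.uniform(0, 1, (8, 8)) for b in BANDS}
        res = pca_pc1(corrected, bands=BANDS)
        brightness = np.mean([corrected[b] for b in BANDS], axis=0).ravel()
        corr = np.corrcoef(res.scores.ravel(), brightness)[0, 1]
        assert corr >= 0

    def test_constant_stack_flagged_degenerate(self):
        res = pca_pc1({b: np.full((4, 4), 0.3) for b in BANDS}, bands=BANDS)
        assert res.degenerate
        assert np.all(res.scores == 0)

    def test_affine_band_rescaling_invariance(self, rng):
        corrected = {b: rng.uniform(0, 1, (8, 8)) for b in BANDS}
        res = pca_pc1(corrected, bands=BANDS)
        shifted = {b: corrected[b] + off for b, off in zip(BANDS, (0.3, -0.1, 0.7))}
        res2 = pca_pc1(shifted, bands=BANDS)
        np.testing.assert_allclose(res.scores, res2.scores, atol=1e-9)


class TestScale:
    def test_three_point_map(self):
        scaled, flag = scale_pc1(np.array([[0.0, 5.0], [10.0, 5.0]]))
        np.testing.assert_allclose(scaled, [[-1.0, 0.0], [1.0, 0.0]])
        assert not flag

    def test_constant_image_degenerate(self):
        scaled, flag = scale_pc1(np.full((4, 4), 2.0))
        assert flag
        assert np.all(scaled == 0)

    @given(hnp.arrays(np.float64, (5, 5), elements=st.floats(-100, 100)))
    def test_bounds_exact_for_nonconstant(self, img):
        scaled, flag = scale_pc1(img)
        if not flag:
            assert scaled.min() == pytest.approx(-1.0)
            assert scaled.max() == pytest.approx(1.0)


class TestBinarize:
    def test_all_high_gives_empty_mask(self):
        assert not binarize(np.ones((4, 4))).any()

    def test_strict_less_than_at_threshold(self):
        vals = np.array([[0.69, 0.70, 0.71]])
        mask = binarize(vals, threshold=0.7)
        np.testing.assert_array_equal(mask, [[True, False, False]])

    def test_threshold_minus_one_flags_nothing(self, rng):
        assert not binarize(rng.uniform(-1, 1, (6, 6)), threshold=-1.0).any()

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=1.5)


class TestDenoise:
    def test_four_pixel_blob_removed(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True  # 4 pixels
        cleaned, removed = denoise(mask, min_area_px=5)
        assert not cleaned.any()
        assert removed == 1

    def test_five_pixel_blob_kept(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        mask[4, 2] = True  # 5 pixels
        cleaned, removed = denoise(mask, min_area_px=5)
        assert cleaned.sum() == 5
        assert removed == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((20, 20)) < 0.25
        cleaned, removed = denoise(mask, min_area_px=5, connectivity=connectivity)
        comps = flood_fill_oracle(mask, connectivity)
        survivors = set().union(*[c for c in comps if len(c) >= 5]) if comps else set()
        got = {tuple(p) for p in np.argwhere(cleaned)}
        assert got == survivors
        assert removed == sum(1 for c in comps if len(c) < 5)

    def test_mixed_sizes(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[1, 1:4] = True               # 3 px
        mask[5, 5:9] = True               # 4 px
        mask[10, 10:15] = True            # 5 px
        mask[20:22, 20:25] = True         # 10 px
        cleaned, removed = denoise(mask, min_area_px=5)
        assert removed == 2
        assert cleaned.sum() == 15

    def test_idempotent(self, rng):
        mask = rng.random((20, 20)) < 0.3
        once, _ = denoise(mask)
        twice, removed_again = denoise(once)
        np.testing.assert_array_equal(once, twice)
        assert removed_again == 0

    def test_diagonal_touch_is_8_connected_only(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = mask[3, 3] = mask[4, 4] = mask[1, 2] = True  # 5 via 8-conn
        kept8, _ = denoise(mask, min_area_px=5, connectivity=8)
        kept4, _ = denoise(mask, min_area_px=5, connectivity=4)
        assert kept8.sum() == 5
        assert kept4.sum() == 0


class TestClassify:
    def test_empty_mask_clean(self):
        assert not classify(np.zeros((4, 4), dtype=bool))

    def test_surviving_component_contaminated(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:5] = True
        assert classify(mask)


class TestPipeline:
    def _insect_stack(self, rng, insect=True, extra_970=0.5):
        imgs = {}
        for b, base in zip(BANDS, (0.10, 0.15, 0.20)):
            img = np.full((16, 16), base)
            img *= 10 ** (-0.004 * np.abs(rng.standard_normal((16, 16))))
            img[3, 12] *= 10 ** -0.3  # isolated dark speck
            imgs[b] = img
        if insect:
            drop = {850: 0.1, 910: 0.2, 970: extra_970}
            for b in BANDS:
                imgs[b][6:9, 6:8] *= 10 ** (-drop[b])  # 6-px insect
        return make_stack(imgs)

    def test_uniform_clean_phantom_is_clean(self):
        stack = make_stack({b: np.full((8, 8), t) for b, t in zip(BANDS, (0.1, 0.15, 0.2))})
        result = run_pipeline(stack)
        assert not result.contaminated
        assert result.degenerate

    def test_six_pixel_insect_detected(self, rng):
        result = run_pipeline(self._insect_stack(rng))
        assert result.contaminated
        assert result.binary_denoised.sum() >= 5

    def test_textured_clean_sample_is_clean(self, rng):
        result = run_pipeline(self._insect_stack(rng, insect=False))
        assert not result.contaminated

    def test_global_intensity_scaling_invariance(self, rng):
        imgs = {b: rng.uniform(0.1, 0.4, (8, 8)) for b in BANDS}
        refs = {b: rng.uniform(0.6, 1.0, (8, 8)) for b in BANDS}
        a = run_pipeline(make_stack(imgs, refs))
        b = run_pipeline(
            make_stack({k: 3 * v for k, v in imgs.items()},
                       {k: 3 * v for k, v in refs.items()})
        )
        assert a.contaminated == b.contaminated
        np.testing.assert_allclose(a.pc1_scaled, b.pc1_scaled, atol=1e-9)

    def test_increasing_970_absorbance_never_unflags(self, rng):
        state = np.random.default_rng(7)
        flags = []
        for extra in (0.3, 0.5, 0.8, 1.2):
            stack = self._insect_stack(np.random.default_rng(7), extra_970=extra)
            flags.append(run_pipeline(stack).contaminated)
        assert flags == sorted(flags)  # once contaminated, stays contaminated

    def test_intermediates_retained(self, rng):
        result = run_pipeline(self._insect_stack(rng))
        assert result.pc1.shape == result.binary.shape == result.binary_denoised.shape
        assert result.loadings.shape == (3,)
        assert result.threshold == 0.7
        assert result.min_area_px == 5


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"threshold": 1.5}, {"min_area_px": 0}, {"connectivity": 6}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectParams(**kwargs)
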