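"""Stain-specific per-pixel rules, the H&E reveal transform, and tissue masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    background_rule_oracle,
    he_transform_oracle,
    mts_rule_oracle,
    psr_rule_oracle,
    random_rgb,
    ttc_rule_oracle,
)
from scarquant.classifiers import (
    HEClassifier,
    MTSClassifier,
    PSRClassifier,
    StainParams,
    TissueSegmenter,
    TTCClassifier,
    classify,
    classify_he,
    classify_mts,
    get_classifier,
    tissue_mask,
    transform_he,
)
from scarquant.synthetic import FixtureSpec, make_section


def _pixel_image(rgb):
    return np.array(rgb, np.uint8).reshape(1, 1, 3)


ALL_TISSUE = np.ones((1, 1), bool)


class TestPrintedPalettePixels:
    """The example pixels of each stain's palette classify as documented."""

    def test_mts_low_red_blue_pixel_is_infarct(self):
        clf = MTSClassifier()
        assert clf.predict(_pixel_image((41, 80, 200)), tissue=ALL_TISSUE)[0, 0]
        assert not clf.predict(_pixel_image((251, 120, 120)), tissue=ALL_TISSUE)[0, 0]

    def test_ttc_achromatic_pixel_is_infarct(self):
        clf = TTCClassifier()
        assert clf.predict(_pixel_image((133, 136, 134)), tissue=ALL_TISSUE)[0, 0]  # stddev ~1.53
        assert not clf.predict(_pixel_image((187, 69, 61)), tissue=ALL_TISSUE)[0, 0]  # stddev ~70.9

    def test_psr_red_margin_pixel_is_infarct(self):
        clf = PSRClassifier()
        assert clf.predict(_pixel_image((240, 129, 143)), tissue=ALL_TISSUE)[0, 0]  # margin 104
        assert not clf.predict(_pixel_image((204, 191, 174)), tissue=ALL_TISSUE)[0, 0]  # margin 21.5

    def test_he_green_dominant_pixel_survives_transform(self):
        out = transform_he(_pixel_image((140, 174, 150)))
        assert tuple(out[0, 0]) == (0, 174, 0)
        # normal-palette pixel: all channels exceed none of the limits but G
        # is not dominant, so the pixel is blacked out entirely
        out = transform_he(_pixel_image((170, 99, 160)))
        assert tuple(out[0, 0]) == (0, 0, 0)

    def test_degenerate_pixels(self):
        assert not classify_mts(np.zeros((4, 4, 3), np.uint8)).any()  # all black
        assert not classify(np.full((4, 4, 3), 255, np.uint8), StainParams.for_stain("ttc")).any()  # white bg
        gray = np.full((1, 1, 3), 90, np.uint8)
        assert not PSRClassifier().predict(gray, tissue=ALL_TISSUE)[0, 0]  # zero margin
        assert tuple(transform_he(_pixel_image((0, 255, 0)), StainParams.for_stain("he", r_limit=255))[0, 0]) == (0, 255, 0)


class TestOracleEquivalence:
    """Vectorized rules match the literal per-pixel loops bit-exactly."""

    @pytest.mark.parametrize("seed", range(5))
    def test_rules_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = random_rgb(rng)
        assert np.array_equal(MTSClassifier().predict(img, tissue=np.ones(img.shape[:2], bool)), mts_rule_oracle(img, 150, 1.2))
        assert np.array_equal(TTCClassifier().predict(img, tissue=np.ones(img.shape[:2], bool)), ttc_rule_oracle(img, 20.0))
        assert np.array_equal(PSRClassifier().predict(img, tissue=np.ones(img.shape[:2], bool)), psr_rule_oracle(img, 60.0))
        assert np.array_equal(transform_he(img), he_transform_oracle(img, 200))
        assert np.array_equal(tissue_mask(img, postprocess=False), background_rule_oracle(img, 230))

    def test_he_candidate_stage_matches_transform_green(self):
        rng = np.random.default_rng(11)
        img = random_rgb(rng)
        tissue = np.ones(img.shape[:2], bool)
        candidates = HEClassifier().candidate_mask(img, tissue=tissue)
        assert np.array_equal(candidates, he_transform_oracle(img, 200)[..., 1] > 0)


class TestMonotonicity:
    """Loosening a stain's threshold never shrinks its mask (tissue fixed)."""

    IMG = random_rgb(np.random.default_rng(42), shape=(24, 24))
    TISSUE = np.ones((24, 24), bool)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lo=st.integers(0, 255), hi=st.integers(0, 255))
    def test_mts_grows_with_r_limit(self, lo, hi):
        lo, hi = sorted((lo, hi))
        small = MTSClassifier(r_limit=lo).predict(self.IMG, tissue=self.TISSUE)
        large = MTSClassifier(r_limit=hi).predict(self.IMG, tissue=self.TISSUE)
        assert not (small & ~large).any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lo=st.floats(0, 150), hi=st.floats(0, 150))
    def test_ttc_grows_with_std_max(self, lo, hi):
        lo, hi = sorted((lo, hi))
        small = TTCClassifier(std_max=lo).predict(self.IMG, tissue=self.TISSUE)
        large = TTCClassifier(std_max=hi).predict(self.IMG, tissue=self.TISSUE)
        assert not (small & ~large).any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lo=st.floats(0, 255), hi=st.floats(0, 255))
    def test_psr_grows_as_thd_drops(self, lo, hi):
        lo, hi = sorted((lo, hi))
        strict = PSRClassifier(thd=hi).predict(self.IMG, tissue=self.TISSUE)
        loose = PSRClassifier(thd=lo).predict(self.IMG, tissue=self.TISSUE)
        assert not (strict & ~loose).any()


class TestFixtureRecovery:
    def test_noise_free_palette_classification_is_exact(self, stain, default_params):
        fx = make_section(FixtureSpec(stain=stain, noise_sd=0, seed=1))
        tissue = tissue_mask(fx.image, default_params)
        infarct = classify(fx.image, default_params, tissue=tissue)
        assert np.array_equal(tissue, fx.truth_tissue)
        assert np.array_equal(infarct, fx.truth_infarct)

    def test_infarct_mask_is_subset_of_tissue_mask(self, stain, default_params):
        fx = make_section(FixtureSpec(stain=stain, seed=2))
        tissue = tissue_mask(fx.image, default_params)
        infarct = classify(fx.image, default_params)
        assert not (infarct & ~tissue).any()

    def test_tissue_mask_area_matches_truth_within_two_percent(self, stain, default_params):
        fx = make_section(FixtureSpec(stain=stain, seed=3))
        area = tissue_mask(fx.image, default_params).sum()
        assert abs(area - fx.tissue_pixels) <= 0.02 * fx.tissue_pixels


class TestHEDensityFilter:
    def test_single_blob_recovered_despite_speckle(self):
        fx = make_section(FixtureSpec(stain="he", seed=4))
        mask = classify_he(fx.image)
        truth = fx.truth_infarct
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice > 0.8
        from scipy import ndimage

        _, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        assert n == 1

    def test_two_blobs_give_two_components(self):
        blobs = ((50.0, 45.0, 12.0), (110.0, 115.0, 15.0))
        fx = make_section(FixtureSpec(stain="he", blobs=blobs, seed=5))
        from scipy import ndimage

        _, n = ndimage.label(classify_he(fx.image), structure=np.ones((3, 3), bool))
        assert n == 2

    def test_no_green_dominant_pixels_gives_empty_mask(self):
        img = np.full((20, 20, 3), (170, 99, 160), np.uint8)
        assert not classify_he(img).any()


class TestTissueSegmenter:
    def test_all_white_image_has_no_tissue(self):
        assert not tissue_mask(np.full((10, 10, 3), 255, np.uint8)).any()

    def test_speckle_components_are_dropped(self):
        img = np.full((40, 40, 3), 245, np.uint8)
        img[10:30, 10:30] = (251, 120, 120)  # main section
        img[2, 2] = (0, 0, 0)  # dust
        mask = TissueSegmenter().predict(img)
        assert mask[15, 15] and not mask[2, 2]

    def test_holes_are_filled(self):
        img = np.full((40, 40, 3), 245, np.uint8)
        img[5:35, 5:35] = (251, 120, 120)
        img[18:22, 18:22] = 245  # interior hole (lumen)
        assert TissueSegmenter().predict(img)[20, 20]


def test_params_validation_and_dispatch():
    with pytest.raises(ValueError):
        StainParams.for_stain("giemsa")
    with pytest.raises(ValueError):
        StainParams(stain="mts", r_limit=300)
    with pytest.raises(ValueError):
        StainParams(stain="psr", thd=-1)
    with pytest.raises(ValueError):
        classify_mts(np.zeros((2, 2, 3), np.uint8), StainParams.for_stain("psr"))
    for name, cls in (("mts", MTSClassifier), ("ttc", TTCClassifier), ("psr", PSRClassifier), ("he", HEClassifier)):
        assert isinstance(get_classifier(StainParams.for_stain(name)), cls)


def test_estimators_follow_sklearn_param_protocol():
    clf = PSRClassifier(thd=50)
    assert clf.get_params()["thd"] == 50
    clf.set_params(thd=70)
    assert clf.params().thd == 70
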