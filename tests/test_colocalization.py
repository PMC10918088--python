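import numpy as np
import pytest

import acetograd as ag
from acetograd.colocalization import coloc_analysis, manders, mask_restrict, sparse_tile_mask


class TestMaskRestrict:
    def test_full_mask_passes_channel(self):
        ch = np.random.default_rng(0).random((8, 8)) * 50
        mask = np.full((8, 8), ch.max())
        np.testing.assert_allclose(mask_restrict(mask, ch), ch)

    def test_zero_mask_blanks_channel(self):
        ch = np.ones((6, 6))
        assert mask_restrict(np.zeros((6, 6)), ch).sum() == 0.0

    def test_toy_minimum(self):
        mask = np.array([[0.0, 9, 9], [9, 0, 9], [0, 0, 9]])
        ch = np.array([[5.0, 3, 12], [1, 7, 0], [2, 8, 4]])
        expect = np.minimum(mask, ch)
        np.testing.assert_allclose(mask_restrict(mask, ch), expect)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_restrict(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_non_binary_mask_rejected(self):
        mask = np.array([[0.0, 1.0, 2.0]])
        with pytest.raises(ValueError):
            mask_restrict(mask, np.ones((1, 3)))


class TestManders:
    def test_identical_binary_channels(self):
        a = (np.random.default_rng(1).random((16, 16)) > 0.7).astype(float)
        res = manders(a, a, thresholdA=0.5, thresholdB=0.5)
        assert res.M_hdac6_on_ac == pytest.approx(1.0)
        assert res.M_ac_on_hdac6 == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[:4] = 1.0
        b[4:] = 1.0
        res = manders(a, b, thresholdA=0.5, thresholdB=0.5)
        assert res.M_hdac6_on_ac == 0.0
        assert res.M_ac_on_hdac6 == 0.0

    def test_half_overlap_pixel_count(self):
        a = np.zeros((10, 10))
        a[:, :] = 0.0
        a.flat[:100] = 1.0  # uniform on 100 px
        b = np.zeros((10, 10))
        b.flat[:50] = 2.0  # covers 50 of them
        res = manders(a, b, thresholdA=0.5, thresholdB=0.5)
        assert res.M_hdac6_on_ac == pytest.approx(0.5)

    def test_rescaling_invariance_with_auto_thresholds(self):
        rng = np.random.default_rng(2)
        a = rng.random((32, 32)) * (rng.random((32, 32)) > 0.6)
        b = rng.random((32, 32)) * (rng.random((32, 32)) > 0.6)
        r1 = manders(a, b)
        r2 = manders(5.0 * a, 0.3 * b)
        assert r1.M_hdac6_on_ac == pytest.approx(r2.M_hdac6_on_ac, abs=1e-9)
        assert r1.M_ac_on_hdac6 == pytest.approx(r2.M_ac_on_hdac6, abs=1e-9)

    def test_all_zero_channel_rejected(self):
        with pytest.raises(ValueError):
            manders(np.zeros((4, 4)), np.ones((4, 4)))


def test_sparse_tiles_prefer_low_density_regions():
    mask = np.zeros((128, 128), bool)
    mask[:64, :] = np.random.default_rng(0).random((64, 128)) > 0.6  # dense half
    mask[64:, :] = np.random.default_rng(1).random((64, 128)) > 0.97  # sparse half
    roi = np.array([(0, 0), (127, 0), (127, 127), (0, 127)], float)
    tiles = sparse_tile_mask(mask, roi, tile_px=32, quantile=0.5)
    assert tiles[64:].sum() > tiles[:64].sum()


def test_on_acetylated_fraction_recovery():
    """M(HDAC6 on AcMT) recovers the generator's placement fraction."""
    vals = []
    p = ag.preset("hdac6_oe")
    for seed in (1, 2, 3, 4, 5, 6):
        cell, _ = ag.generate_cell(
            p, seed, channels=("alpha_tubulin", "ac_tubulin", "hdac6")
        )
        vals.append(coloc_analysis(cell).M_hdac6_on_ac)
    assert np.mean(vals) == pytest.approx(p.hdac6_on_ac_fraction, abs=0.12)
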