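import numpy as np
import pytest

import acetograd as ag
from acetograd.metrics import (
    acetylated_area_fraction,
    acetylated_fraction,
    classify_expression_level,
    segment_length_stats,
)
from acetograd.segmentation import NetworkSegmentation, Polyline


def _seg(lengths):
    pls = [Polyline([(0.0, 2.0 * i), (float(l), 2.0 * i)]) for i, l in enumerate(lengths)]
    return NetworkSegmentation(polylines=pls, skeleton_mask=np.zeros((4, 4), bool))


class TestAcetylatedFraction:
    def test_simple_division(self):
        assert acetylated_fraction(_seg([36.0]), _seg([60.0, 40.0])) == pytest.approx(0.36)

    def test_empty_acetylation_gives_zero(self):
        assert acetylated_fraction(_seg([]), _seg([10.0])) == 0.0

    def test_marginal_overshoot_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert acetylated_fraction(_seg([103.0]), _seg([100.0])) == 1.0

    def test_large_overshoot_raises(self):
        with pytest.raises(ValueError):
            acetylated_fraction(_seg([120.0]), _seg([100.0]))

    def test_zero_network_raises(self):
        with pytest.raises(ValueError):
            acetylated_fraction(_seg([1.0]), _seg([]))

    def test_self_fraction_is_one(self):
        s = _seg([2.0, 5.0])
        assert acetylated_fraction(s, s) == pytest.approx(1.0)


class TestSegmentStats:
    def test_mean_and_count(self):
        s = segment_length_stats(_seg([2.0, 3.0]), min_len_um=0.0)
        assert s.mean_segment_um == pytest.approx(2.5)
        assert s.segment_count == 2

    def test_min_length_filter(self):
        s = segment_length_stats(_seg([2.0, 3.0]), min_len_um=2.5)
        assert s.mean_segment_um == pytest.approx(3.0)
        assert s.segment_count == 1

    def test_empty_input(self):
        s = segment_length_stats(_seg([]))
        assert s.segment_count == 0
        assert np.isnan(s.mean_segment_um)


class TestAreaFraction:
    def _roi(self, n=64):
        return np.array([(0, 0), (n - 1, 0), (n - 1, n - 1), (0, n - 1)], float)

    def test_half_bright_block(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        assert acetylated_area_fraction(img, self._roi()) == pytest.approx(0.5, abs=0.02)

    def test_single_bright_pixel(self):
        img = np.zeros((64, 64))
        img[10, 10] = 100.0
        frac = acetylated_area_fraction(img, self._roi())
        assert frac == pytest.approx(1 / (64 * 64), abs=3 / (64 * 64))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64)) + (rng.random((64, 64)) > 0.8) * 5.0
        f1 = acetylated_area_fraction(img, self._roi())
        f2 = acetylated_area_fraction(3.7 * img, self._roi())
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_flat_image_raises(self):
        with pytest.raises(ValueError):
            acetylated_area_fraction(np.full((64, 64), 3.0), self._roi())


class TestExpressionLevel:
    def _roi(self, n=128):
        return np.array([(2, 2), (n - 3, 2), (n - 3, n - 3), (2, n - 3)], float)

    def test_uniform_marker_is_high(self):
        img = np.full((128, 128), 50.0)
        assert classify_expression_level(img, self._roi()) == "high"

    def test_peripheral_gradient_is_low(self):
        yy, xx = np.mgrid[0:128, 0:128]
        rr = np.hypot(xx - 64, yy - 64)
        img = 20.0 + 80.0 * np.clip(rr / 60.0, 0, 1)  # center value 20
        assert classify_expression_level(img, self._roi()) == "low"

    def test_recovers_preset_labels(self, mini_preset):
        correct = 0
        for name, want in (("kinesin_low", "low"), ("kinesin_high", "high")):
            base = ag.preset(name)
            p = mini_preset.replace(
                kinesin_profile=base.kinesin_profile,
                gradient_lambda=base.gradient_lambda,
                ac_fraction_target=base.ac_fraction_target,
            )
            for seed in range(1, 6):
                cell, _ = ag.generate_cell(p, seed, channels=("kinesin",))
                got = classify_expression_level(cell.channels["kinesin"], cell.cell_roi)
                correct += got == want
        assert correct >= 9  # >= 90% of 10 cells


def test_pipeline_fraction_tracks_ground_truth(mini_preset):
    from acetograd.metrics import analyze_cell

    diffs = []
    for seed in (1, 2, 3):
        cell, gt = ag.generate_cell(mini_preset, seed)
        summ = analyze_cell(cell)
        diffs.append(summ.ac_fraction - gt.ac_fraction)
    assert abs(np.mean(diffs)) < 0.06
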