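import numpy as np
import pytest

from acetograd.segmentation import (
    Polyline,
    binarize_network,
    refine_polylines,
    subtract_background,
    total_length,
    trace_curves,
)
from tests.conftest import render_line

PX = 0.065


class TestPolyline:
    def test_length_is_sum_of_steps(self):
        pl = Polyline([(0, 0), (3, 0), (3, 4)])
        assert pl.length_um == pytest.approx(7.0, abs=1e-9)

    def test_length_invariant_under_reversal(self):
        rng = np.random.default_rng(0)
        pl = Polyline(np.cumsum(rng.normal(0.3, 0.1, (20, 2)), axis=0))
        assert pl.length_um == pytest.approx(pl.reversed().length_um, abs=1e-9)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            Polyline([(1.0, 1.0)])


class TestTraceCurves:
    def test_blank_image_gives_empty_list(self):
        assert trace_curves(np.zeros((64, 64)), pixel_size_um=PX) == []

    def test_rejects_bad_parameters(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            trace_curves(img, sigma_um=-1.0)
        with pytest.raises(ValueError):
            trace_curves(img, low_contrast=0.5, high_contrast=0.2)

    def test_single_straight_filament_length(self):
        pts = [(1.0, 5.2), (21.0, 5.2)]
        img = render_line(pts, shape=(160, 352))
        pls = trace_curves(img, pixel_size_um=PX)
        pls = refine_polylines(pls, img, PX)
        assert len(pls) == 1
        assert pls[0].length_um == pytest.approx(20.0, abs=0.5)

    def test_two_parallel_filaments_stay_separate(self):
        a = [(1.0, 4.0), (15.0, 4.0)]
        b = [(1.0, 5.0), (15.0, 5.0)]  # 1 µm apart
        img = render_line(a, shape=(160, 256)) + render_line(b, shape=(160, 256))
        pls = trace_curves(img, pixel_size_um=PX)
        long_ones = [p for p in pls if p.length_um > 5]
        assert len(long_ones) == 2
        ys = sorted(p.points[:, 1].mean() for p in long_ones)
        assert ys[0] == pytest.approx(4.0, abs=0.2)
        assert ys[1] == pytest.approx(5.0, abs=0.2)

    def test_detection_recall_and_precision_on_noiseless_render(self):
        rng = np.random.default_rng(1)
        lines = []
        img = np.zeros((256, 256))
        for k in range(4):
            y = 3.0 + 3.2 * k
            pts = [(1.5, y), (14.5, y + rng.uniform(-0.5, 0.5))]
            img = img + render_line(pts, shape=(256, 256))
            lines.append(np.asarray(pts))
        pls = trace_curves(img, pixel_size_um=PX)
        traced = np.vstack([p.resample(0.13).points for p in pls])
        hits = 0
        for pt in traced:
            d = min(_point_to_segment(pt, ln[0], ln[1]) for ln in lines)
            hits += d <= 2 * PX
        assert hits / len(traced) >= 0.9  # precision
        recall_pts = np.vstack([
            np.linspace(ln[0], ln[1], 60) for ln in lines
        ])
        tr_cat = traced
        rec = np.mean([
            np.min(np.linalg.norm(tr_cat - q, axis=1)) <= 2 * PX for q in recall_pts
        ])
        assert rec >= 0.9


def _point_to_segment(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
    return float(np.linalg.norm(a + t * ab - p))


class TestBinarize:
    def test_empty_gives_all_zero(self):
        assert binarize_network([], (32, 32), PX).sum() == 0

    def test_horizontal_line_pixel_count(self):
        y = 10 * PX
        pl = Polyline([(0.0, y), (99 * PX, y)])
        mask = binarize_network([pl], (32, 128), PX)
        assert mask.sum() == 100
        assert not _has_2x2_block(mask)

    def test_x_crossing_counts_overlap_once(self):
        h = Polyline([(0.0, 10 * PX), (59 * PX, 10 * PX)])
        v = Polyline([(30 * PX, 0.0), (30 * PX, 20 * PX)])
        mask = binarize_network([h, v], (40, 80), PX)
        assert mask.sum() == 60 + 21 - 1

    def test_idempotent(self):
        pl = Polyline([(0.5, 0.5), (3.0, 2.0), (5.0, 2.2)])
        m1 = binarize_network([pl], (64, 96), PX)
        m2 = binarize_network([pl], (64, 96), PX)
        assert np.array_equal(m1, m2)


def _has_2x2_block(mask):
    return bool((mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]).any())


class TestTotalLength:
    def test_empty_is_zero(self):
        assert total_length([]) == 0.0

    def test_sums_lengths(self):
        pls = [Polyline([(0, 0), (3, 0)]), Polyline([(0, 0), (0, 7)])]
        assert total_length(pls) == pytest.approx(10.0)

    def test_matches_ground_truth_record(self, mini_cell):
        _, gt = mini_cell
        assert total_length(gt.filaments) == pytest.approx(gt.total_length_um, abs=1e-6)


class TestSubtractBackground:
    def _roi(self):
        return np.array([(2, 2), (60, 2), (60, 60), (2, 60)], float)

    def test_constant_image_goes_to_zero(self):
        img = np.full((64, 64), 7.5)
        out = subtract_background(img, self._roi())
        assert np.allclose(out, 0.0)

    def test_ridge_peak_reduced_by_background(self):
        img = render_line([(0.5, 2.0), (3.5, 2.0)], shape=(64, 64), bg=10.0)
        out = subtract_background(img, self._roi())
        assert out.max() == pytest.approx(img.max() - 10.0, rel=0.05)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((32, 32)), np.array([(100, 100), (101, 100), (101, 101)], float))
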