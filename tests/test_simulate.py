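import numpy as np
import pytest

import acetograd as ag
from acetograd._util import channel_rng, sample_truncnorm
from acetograd.damage import classify_line_scan
from acetograd.simulate import generate_cell, make_line_scan_fixture


def test_same_preset_and_seed_is_bit_identical(mini_preset):
    c1, g1 = generate_cell(mini_preset, 3)
    c2, g2 = generate_cell(mini_preset, 3)
    for ch in c1.channels:
        assert np.array_equal(c1.channels[ch], c2.channels[ch])
    assert len(g1.filaments) == len(g2.filaments)
    for f1, f2 in zip(g1.filaments, g2.filaments):
        assert np.array_equal(f1.points, f2.points)
    assert g1.ac_segments == g2.ac_segments


def test_different_seeds_differ(mini_preset):
    c1, _ = generate_cell(mini_preset, 3)
    c2, _ = generate_cell(mini_preset, 4)
    assert not np.array_equal(c1.channels["ac_tubulin"], c2.channels["ac_tubulin"])


def test_noiseless_render_ridge_follows_filament(mini_preset):
    p = mini_preset.replace(
        n_filaments=1,
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        background_level=0.0,
        psf_sigma_um=1e-6,
        gradient_amplitude=1.0,
    )
    cell, gt = generate_cell(p, 5)
    img = cell.channels["alpha_tubulin"]
    fil = gt.filaments[0]
    px = p.pixel_size_um
    # at each sampled arc position the brightest pixel in the local column
    # block must lie within half a pixel of the polyline
    pts = fil.resample(5 * px).points / px
    for x, y in pts[2:-2]:
        c = int(round(x))
        block = img[:, c]
        peak = np.argmax(block)
        assert abs(peak - y) <= 0.51 + 1.0  # discrete argmax adds half a pixel


def test_ground_truth_intervals_are_consistent(mini_cell):
    cell, gt = mini_cell
    for fi, f in enumerate(gt.filaments):
        length = f.length_um
        for a, b in gt.ac_segments[fi]:
            assert 0.0 <= a < b <= length + 1e-9
        for site in gt.damage_sites[fi]:
            da, db = site.deac
            for a, b in gt.ac_segments[fi]:
                assert min(db, b) - max(da, a) <= 1e-9  # disjoint
    # fraction reproducible from the record alone
    total = sum(f.length_um for f in gt.filaments)
    ac = sum(b - a for segs in gt.ac_segments for a, b in segs)
    assert gt.ac_fraction == pytest.approx(ac / total, abs=1e-12)


def test_acetylated_fraction_converges_to_target():
    """Monte-Carlo: ground-truth fraction within 3 SE of the preset target."""
    p = ag.preset("control")
    fracs = [generate_cell(p, s, channels=())[1].ac_fraction for s in range(1, 25)]
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(np.mean(fracs) - p.ac_fraction_target) < 3 * se + 1e-3


def test_segment_length_statistics_converge():
    """Countable segments (>= 0.5 µm, the measurement floor) hit the preset mean."""
    from acetograd.simulate import MIN_COUNT_UM

    p = ag.preset("control")
    means = []
    for s in range(1, 19):
        lens = generate_cell(p, s, channels=())[1].segment_lengths_um()
        means.append(lens[lens >= MIN_COUNT_UM].mean())
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - p.ac_segment_mean_um) < 3 * se + 0.02


def test_rendering_is_linear(mini_preset):
    base = mini_preset.replace(
        noise_gaussian_sd=0.0, noise_poisson_scale=0.0, background_level=0.0,
        gradient_amplitude=0.8,
    )
    bright = dict(base.brightness)
    bright["ac_tubulin"] *= 2
    doubled = base.replace(brightness=bright)
    c1, _ = generate_cell(base, 11)
    c2, _ = generate_cell(doubled, 11)
    assert np.allclose(2 * c1.channels["ac_tubulin"], c2.channels["ac_tubulin"], atol=1e-9)


def test_no_acetylation_signal_in_deacetylated_intervals(mini_preset):
    p = mini_preset.replace(
        noise_gaussian_sd=0.0, noise_poisson_scale=0.0, background_level=0.0,
        damage_density_per_um=0.3,
    )
    cell, gt = generate_cell(p, 9)
    img = cell.channels["ac_tubulin"]
    px = p.pixel_size_um
    checked = 0
    for fi, f in enumerate(gt.filaments):
        for site in gt.damage_sites[fi]:
            mid = 0.5 * (site.deac[0] + site.deac[1])
            x, y = f.point_at(np.array([mid]))[0] / px
            assert img[int(round(y)), int(round(x))] < 0.25 * img.max()
            checked += 1
    assert checked > 0


class TestLineScanFixture:
    def test_concentric_construction(self):
        h, a, truth = make_line_scan_fixture(0.5, 0.76, 0.0, 0.0, 1)
        assert truth["dr"] == (-0.25, 0.25)
        assert truth["deac"] == (-0.38, 0.38)
        np.testing.assert_allclose(h.x_um, a.x_um)

    def test_plusward_offset(self):
        _, _, truth = make_line_scan_fixture(0.5, 0.76, 0.24, 0.0, 1)
        dr_c = 0.5 * (truth["dr"][0] + truth["dr"][1])
        deac_c = 0.5 * (truth["deac"][0] + truth["deac"][1])
        assert deac_c - dr_c == pytest.approx(0.24)

    def test_embedded_case(self):
        _, _, truth = make_line_scan_fixture(0.5, 0.3, 0.0, 0.0, 1)
        assert truth["deac"][0] > truth["dr"][0]
        assert truth["deac"][1] < truth["dr"][1]

    def test_noiseless_classification_recovers_truth(self):
        h, a, truth = make_line_scan_fixture(0.5, 0.76, 0.0, 0.0, 1)
        damage, deac = classify_line_scan(h, a)
        assert len(damage) == 1
        (da, db), (sa, sb) = damage[0], max(deac, key=lambda iv: iv[1] - iv[0])
        assert db - da == pytest.approx(0.5, abs=0.065)
        assert sb - sa == pytest.approx(0.76, abs=0.065)

    def test_rejects_degenerate_lengths(self):
        with pytest.raises(ValueError):
            make_line_scan_fixture(0.0, 0.76)


def test_truncated_normal_sampler_is_moment_matched():
    rng = channel_rng(0, "fixture")
    draws = sample_truncnorm(rng, 0.24, 0.239, 0.065, size=40000)
    assert draws.min() >= 0.065
    assert np.mean(draws) == pytest.approx(0.24, abs=0.005)
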