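import numpy as np
import pytest

import acetograd as ag
from acetograd.gradient import (
    BinnedProfile,
    IntensityProfile,
    RawProfile,
    bin_and_average,
    cell_radial_profile,
    extract_profile,
    fit_exponential,
    normalize_profile,
    relative_amplitude,
)


def _profile(d, v):
    return IntensityProfile(distance=np.asarray(d, float), value=np.asarray(v, float))


class TestExtractProfile:
    def test_uniform_images_give_constant_profile(self):
        img = np.full((64, 64), 5.0)
        raw = extract_profile(img, img, ((5, 32), (58, 32)), width_px=9)
        assert np.allclose(raw.num, 5.0)
        assert np.allclose(raw.den, 5.0)

    def test_footprint_mean_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.random((40, 40))
        raw = extract_profile(img, img, ((5.0, 20.0), (30.0, 20.0)), width_px=3)
        # horizontal scan: footprint = 3 vertically adjacent pixels
        for k, x in enumerate(range(5, 31)):
            expect = img[19:22, x].mean()
            assert raw.num[k] == pytest.approx(expect, abs=1e-9)

    def test_even_width_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            extract_profile(img, img, ((1, 8), (14, 8)), width_px=4)


class TestNormalizeProfile:
    def test_equal_channels_give_unity(self):
        raw = RawProfile(np.arange(5.0), np.full(5, 3.0), np.full(5, 3.0))
        prof = normalize_profile(raw)
        assert np.allclose(prof.value, 1.0)

    def test_scale_invariance_of_numerator(self):
        pos = np.arange(6.0)
        num = np.array([4.0, 3, 2, 1.5, 1, 0.5])
        den = np.ones(6)
        p1 = normalize_profile(RawProfile(pos, num, den))
        p2 = normalize_profile(RawProfile(pos, num / 2, den))
        np.testing.assert_allclose(p1.value, p2.value)

    def test_ratio_series_normalized_by_max(self):
        raw = RawProfile(np.array([0.0, 1, 2]), np.array([4.0, 2, 1]), np.ones(3))
        prof = normalize_profile(raw)
        np.testing.assert_allclose(prof.value, [1.0, 0.5, 0.25])

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            normalize_profile(RawProfile(np.arange(4.0), np.ones(4), np.zeros(4)))


class TestBinning:
    def test_single_profile_reproduced(self):
        prof = _profile([0.05, 0.15, 0.25], [1.0, 0.5, 0.2])
        b = bin_and_average([prof], bin_width=0.1)
        assert np.allclose(b.sd[b.populated], 0.0)
        assert b.mean[b.populated] == pytest.approx([1.0, 0.5, 0.2])

    def test_two_constant_profiles_average(self):
        d = np.linspace(0.01, 0.99, 40)
        b = bin_and_average(
            [_profile(d, np.full(40, 0.4)), _profile(d, np.full(40, 0.6))], 0.05
        )
        assert np.allclose(b.mean[b.populated], 0.5)

    def test_default_width_gives_at_most_200_bins(self):
        d = np.linspace(0.0, 0.999, 500)
        b = bin_and_average([_profile(d, np.ones(500))], 0.005)
        assert len(b.bin_center) == 200
        assert b.populated.sum() <= 200

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        profs = [
            _profile(np.sort(rng.uniform(0, 1, 30)), rng.random(30)) for _ in range(4)
        ]
        b1 = bin_and_average(profs)
        b2 = bin_and_average(profs[::-1])
        np.testing.assert_allclose(
            b1.mean[b1.populated], b2.mean[b2.populated], equal_nan=True
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            bin_and_average([])


class TestFitExponential:
    def _binned(self, x, y):
        return BinnedProfile(x, y, np.zeros_like(x), np.ones_like(x, dtype=int))

    @pytest.mark.parametrize("y0,lam", [(1.0, 0.33), (0.5, 0.2), (2.0, 0.79)])
    def test_exact_recovery_on_model_samples(self, y0, lam):
        x = np.linspace(0.0025, 0.9975, 200)
        fit = fit_exponential(self._binned(x, y0 * np.exp(-x / lam)))
        assert fit.lambda_ == pytest.approx(lam, abs=1e-6)
        assert fit.Y0 == pytest.approx(y0, abs=1e-6)
        assert fit.plateau == 0.0

    def test_free_plateau_recovery(self):
        x = np.linspace(0.0025, 0.9975, 200)
        y = 0.8 * np.exp(-x / 0.4) + 0.1
        fit = fit_exponential(self._binned(x, y), plateau_fixed=False)
        assert fit.lambda_ == pytest.approx(0.4, abs=1e-6)
        assert fit.plateau == pytest.approx(0.1, abs=1e-6)

    def test_constant_profile_is_degenerate(self):
        x = np.linspace(0.0025, 0.9975, 100)
        with pytest.raises(ValueError):
            fit_exponential(self._binned(x, np.full(100, 0.7)))

    def test_too_few_bins_rejected(self):
        x = np.array([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            fit_exponential(self._binned(x, np.exp(-x)))


class TestRelativeAmplitude:
    def test_equal_signals_give_one(self):
        region = np.zeros((8, 8), bool)
        region[2:6, 2:6] = True
        img = np.random.default_rng(0).random((8, 8))
        assert relative_amplitude(img, img, region) == pytest.approx(1.0)

    def test_zero_numerator(self):
        region = np.ones((4, 4), bool)
        assert relative_amplitude(np.zeros((4, 4)), np.ones((4, 4)), region) == 0.0

    def test_zero_tubulin_raises(self):
        region = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            relative_amplitude(np.ones((4, 4)), np.zeros((4, 4)), region)

    def test_control_amplitude_exceeds_high_kinesin(self, mini_preset):
        amps = {}
        for name in ("control", "kinesin_high"):
            base = ag.preset(name)
            p = mini_preset.replace(
                gradient_lambda=base.gradient_lambda,
                ac_fraction_target=base.ac_fraction_target,
                ac_segment_mean_um=1.2,
                ac_segment_sd_um=0.2,
            )
            vals = []
            for seed in (1, 2, 3):
                cell, _ = ag.generate_cell(p, seed)
                px = cell.pixel_size_um
                h, w = cell.shape
                yy, xx = np.mgrid[0:h, 0:w]
                cx, cy = cell.nucleus_center
                r_n = p.nucleus_radius_um / px
                region = (np.hypot(xx - cx, yy - cy) > r_n) & (
                    np.hypot(xx - cx, yy - cy) < r_n + 1.0 / px
                )
                vals.append(
                    relative_amplitude(
                        cell.channels["ac_tubulin"], cell.channels["alpha_tubulin"], region
                    )
                )
            amps[name] = np.mean(vals)
        assert amps["control"] > amps["kinesin_high"]


def test_master_curve_collapse_across_cell_sizes():
    """Profiles from two cell sizes with one λ overlap after normalization."""
    profs = {}
    for radius, nuc, size in ((16.0, 5.0, 560), (20.0, 6.0, 672)):
        p = ag.preset("control").replace(
            name=f"scale{int(radius)}",
            cell_radius_um=radius,
            nucleus_radius_um=nuc,
            image_size_px=size,
            n_filaments=48,
        )
        profs[radius] = [
            cell_radial_profile(ag.generate_cell(p, s)[0]) for s in range(1, 7)
        ]
    b1 = bin_and_average(profs[16.0], 0.05)
    b2 = bin_and_average(profs[20.0], 0.05)
    both = b1.populated & b2.populated & (b1.bin_center < 0.9)
    diff = np.abs(b1.mean[both] - b2.mean[both])
    assert diff.max() < 0.15


def test_lambda_recovery_is_unbiased_on_mini_cells(mini_preset):
    profs = [
        cell_radial_profile(ag.generate_cell(mini_preset, s)[0]) for s in range(1, 11)
    ]
    fit = fit_exponential(bin_and_average(profs))
    assert fit.lambda_ == pytest.approx(mini_preset.gradient_lambda, abs=0.12)
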