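import numpy as np
import pytest

import acetograd as ag
from acetograd.damage import (
    LineScan,
    classify_line_scan,
    filter_shaft_sites,
    measure_fixture,
    measure_site,
)
from acetograd.segmentation import Polyline
from acetograd.simulate import make_line_scan_fixture, sample_damage_fixtures


def _scan(x, y):
    return LineScan(np.asarray(x, float), np.asarray(y, float))


class TestClassify:
    def test_rectangular_pulse_and_dip(self):
        x = np.arange(-2.0, 2.0, 0.02)
        h = np.where(np.abs(x) <= 0.25, 80.0, 5.0)
        a = np.where(np.abs(x) <= 0.38, 10.0, 90.0)
        damage, deac = classify_line_scan(_scan(x, h), _scan(x, a))
        assert len(damage) == 1 and len(deac) == 1
        assert damage[0][1] - damage[0][0] == pytest.approx(0.5, abs=0.03)
        assert deac[0][1] - deac[0][0] == pytest.approx(0.76, abs=0.03)

    def test_high_acetylation_everywhere_gives_no_stretch(self):
        x = np.arange(0.0, 3.0, 0.05)
        h = np.full_like(x, 10.0)
        h[20:25] = 90.0
        a = np.full_like(x, 80.0)
        a[0] = 100.0  # normalization anchor
        _, deac = classify_line_scan(_scan(x, h), _scan(x, a))
        assert deac == []

    def test_noisy_fixture_borders_within_two_samples(self):
        h, a, truth = make_line_scan_fixture(0.5, 0.76, 0.0, noise_sd=5.0, seed=4)
        damage, deac = classify_line_scan(h, a)
        dr = max(damage, key=lambda iv: iv[1] - iv[0])
        best = max(deac, key=lambda iv: min(iv[1], truth["deac"][1]) - max(iv[0], truth["deac"][0]))
        step = h.x_um[1] - h.x_um[0]
        for got, want in ((dr, truth["dr"]), (best, truth["deac"])):
            assert abs(got[0] - want[0]) <= 2 * step
            assert abs(got[1] - want[1]) <= 2 * step

    def test_misaligned_axes_rejected(self):
        x = np.arange(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            classify_line_scan(_scan(x, np.ones(10)), _scan(x + 0.05, np.ones(10)))


class TestMeasureSite:
    def test_symmetric_extension(self):
        m = measure_site((0.0, 0.5), [(-0.13, 0.63)])
        assert m.L_dr == pytest.approx(0.5)
        assert m.L_deac == pytest.approx(0.76)
        assert m.center_displacement == pytest.approx(0.0, abs=1e-12)
        assert m.ext_plus == pytest.approx(0.13)
        assert m.ext_minus == pytest.approx(0.13)
        assert not m.embedded

    def test_plusward_displacement(self):
        m = measure_site((0.0, 0.4), [(0.0, 1.0)])
        assert m.center_displacement == pytest.approx(0.3)
        assert m.ext_plus == pytest.approx(0.6)
        assert m.ext_minus == pytest.approx(0.0)

    def test_embedded_stretch_and_formula(self):
        m = measure_site((0.0, 0.6), [(0.1, 0.5)])
        assert m.embedded
        assert m.ext_plus == 0.0 and m.ext_minus == 0.0
        assert m.formula_displacement == pytest.approx(0.3 - 0.2)

    def test_formula_is_half_length_difference(self):
        m = measure_site((0.0, 0.5), [(-0.2, 0.7)])
        assert m.formula_displacement == pytest.approx(0.5 / 2 - 0.9 / 2)

    def test_pairing_prefers_larger_overlap(self):
        m = measure_site((0.0, 0.5), [(0.4, 0.6), (-0.1, 0.45)])
        assert m.L_deac == pytest.approx(0.55)

    def test_unpaired_when_too_far(self):
        assert measure_site((0.0, 0.5), [(2.0, 2.5)]) is None

    def test_polarity_flips_sign_and_extensions(self):
        m = measure_site((0.0, 0.4), [(0.0, 1.0)], polarity=-1)
        assert m.center_displacement == pytest.approx(-0.3)
        assert m.ext_plus == pytest.approx(0.0)
        assert m.ext_minus == pytest.approx(0.6)

    def test_requires_damage_interval(self):
        with pytest.raises(ValueError):
            measure_site(None, [])


class TestShaftFilter:
    def _filaments(self):
        f1 = Polyline([(1.0, 2.0), (9.0, 2.0)])  # 8 µm horizontal
        f2 = Polyline([(5.0, 0.5), (5.0, 3.5)])  # crosses f1 at (5, 2)
        f3 = Polyline([(1.0, 5.0), (9.0, 5.0)])  # isolated
        return [f1, f2, f3]

    def test_tip_site_dropped(self):
        fils = self._filaments()
        kept = filter_shaft_sites([(2, (7.7, 7.9))], fils, tip_exclusion_um=0.5)
        assert kept == []

    def test_shaft_site_on_isolated_filament_kept(self):
        fils = self._filaments()
        kept = filter_shaft_sites([(2, (3.0, 3.6))], fils)
        assert len(kept) == 1

    def test_crossing_site_dropped(self):
        fils = self._filaments()
        kept = filter_shaft_sites([(0, (3.7, 4.3))], fils)  # footprint spans (5,2)
        assert kept == []


class TestFixturePopulation:
    def test_no_mean_polarity_of_displacement(self):
        fx = sample_damage_fixtures(ag.preset("control"), 80, seed=11)
        disp = []
        for h, a, _ in fx:
            m = measure_fixture(h, a)
            if m is not None:
                disp.append(m.center_displacement)
        disp = np.array(disp)
        se = disp.std(ddof=1) / np.sqrt(len(disp))
        assert abs(disp.mean()) < 2 * se + 0.01

    def test_stretch_to_damage_ratio(self):
        fx = sample_damage_fixtures(ag.preset("control"), 65, seed=2)
        ld, lr = [], []
        for h, a, _ in fx:
            m = measure_fixture(h, a)
            if m is not None:
                ld.append(m.L_deac)
                lr.append(m.L_dr)
        ratio = np.mean(ld) / np.mean(lr)
        assert ratio == pytest.approx(1.5, abs=0.25)
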