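import pytest

import acetograd as ag
from acetograd.presets import PRESET_NAMES


def test_condition_values_match_reported_measurements():
    control = ag.preset("control")
    assert control.gradient_lambda == 0.33
    assert control.ac_segment_mean_um == 2.5
    assert control.ac_fraction_target == 0.36
    assert control.deac_len_mean_um == 0.76
    assert control.center_offset_mean_nm == 240.0
    assert control.center_coloc_prob == 0.12
    kin = ag.preset("kinesin_high")
    assert kin.gradient_lambda == 0.79
    assert kin.ac_segment_mean_um == 1.2
    assert ag.preset("tubacin").ac_fraction_target == 0.80
    assert ag.preset("nocodazole").area_fraction_target == 0.167


def test_unknown_preset_raises_with_valid_names():
    with pytest.raises(KeyError) as err:
        ag.preset("nope")
    for name in PRESET_NAMES:
        assert name in str(err.value)


@pytest.mark.parametrize("name", PRESET_NAMES)
def test_preset_invariants(name):
    p = ag.preset(name)
    assert 0 < p.nucleus_radius_um < p.cell_radius_um
    assert p.gradient_lambda > 0
    assert 0 <= p.ac_fraction_target <= 1
    assert 0 <= p.center_coloc_prob <= 1
    assert p.ac_segment_mean_um >= p.pixel_size_um
    for field in ("ac_segment_mean_um", "deac_len_mean_um", "damage_len_mean_um",
                  "psf_sigma_um", "pixel_size_um"):
        assert getattr(p, field) > 0


def test_geometry_validation():
    with pytest.raises(ValueError):
        ag.preset("control").replace(nucleus_radius_um=25.0)
    with pytest.raises(ValueError):
        ag.preset("control").replace(kinesin_profile="sideways")
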