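"""Gabor rendering: photometry, geometry and symmetry of the triplet."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import latmask as lm
from latmask.stimulus import michelson_contrast


def test_zero_contrast_is_uniform_mean_luminance(small_geometry):
    img = lm.render_gabor(0.0, geometry=small_geometry)
    assert np.all(img.luminance == pytest.approx(47.6))


def test_center_luminance_matches_closed_form(small_geometry):
    # L = L_mean * (1 + c) at the envelope center for cosine phase
    img = lm.render_gabor(0.5, sf=1.0, sigma=0.5, phase=0.0, geometry=small_geometry)
    r, c = img.element_centers[0]
    assert img.luminance[int(r), int(c)] == pytest.approx(47.6 * 1.5)


@pytest.mark.parametrize("contrast", [0.217, 0.05, 1.0])
def test_rendered_contrast_matches_nominal(contrast, small_geometry):
    img = lm.render_gabor(contrast, geometry=small_geometry)
    measured = michelson_contrast(img.luminance, small_geometry.mean_luminance)
    assert measured == pytest.approx(contrast, rel=0.01)


@given(
    contrast=st.floats(0.01, 1.0),
    phase=st.sampled_from([0.0, np.pi]),
)
def test_contrast_fidelity_property(contrast, phase):
    """At even-symmetric carrier phases the carrier extremum sits on the
    envelope peak and the rendered contrast equals the nominal one."""
    geometry = lm.DisplayGeometry(width_px=65, height_px=65, arcmin_per_pixel=2.14)
    img = lm.render_gabor(contrast, phase=phase, geometry=geometry)
    measured = michelson_contrast(img.luminance, geometry.mean_luminance)
    assert measured <= contrast * 1.0001
    assert measured == pytest.approx(contrast, rel=0.01)


@given(contrast=st.floats(0.01, 1.0), phase=st.floats(0.0, 6.28))
def test_contrast_estimate_bounded_for_any_phase(contrast, phase):
    """Away from cosine phase the windowed carrier extremum is
    attenuated by at most exp(-(lambda/4)^2 / (2 sigma^2)) ~ 0.88 at the
    default sigma = lambda/2, and the estimate never exceeds the nominal
    contrast."""
    geometry = lm.DisplayGeometry(width_px=65, height_px=65, arcmin_per_pixel=2.14)
    img = lm.render_gabor(contrast, phase=phase, geometry=geometry)
    measured = michelson_contrast(img.luminance, geometry.mean_luminance)
    assert contrast * 0.88 <= measured <= contrast * 1.0001


def test_triplet_offset_arithmetic(small_geometry):
    # 3 lambda at 1 cpd and 2.14 arcmin/px -> round(3 * 60 / 2.14) = 84 px
    config = lm.StimulusConfig(
        separation_lambda=3.0,
        orientation_condition="collinear",
        target_contrast=0.2,
        geometry=lm.DisplayGeometry(),
    )
    img = lm.render_triplet(config)
    (r0, _), (r1, _), (r2, _) = img.element_centers
    assert r1 - r0 == 84
    assert r2 - r1 == 84


@pytest.mark.parametrize("sep,expected", [(3.0, 84), (4.0, 112), (6.0, 168), (8.0, 224)])
def test_separation_linearity(sep, expected):
    config = lm.StimulusConfig(
        separation_lambda=sep,
        orientation_condition="collinear",
        target_contrast=0.2,
    )
    img = lm.render_triplet(config)
    (r0, _), (r1, _), _ = img.element_centers
    assert r1 - r0 == expected


def test_orthogonal_flankers_are_rotated_90_deg(small_geometry):
    """Orthogonal flankers modulate along the perpendicular axis: rows
    through a flanker center are constant where columns vary."""
    config = lm.StimulusConfig(
        separation_lambda=1.5,
        orientation_condition="orthogonal",
        target_contrast=0.5,
        geometry=small_geometry,
    )
    img = lm.render_triplet(config)
    r, c = img.element_centers[0]
    r, c = int(r), int(c)
    # vertical target: modulation along columns; orthogonal flanker:
    # modulation along rows, constant along columns near its center
    flank_row = img.luminance[r, c - 5 : c + 6]
    flank_col = img.luminance[r - 5 : r + 6, c]
    assert np.ptp(flank_col) > 5 * np.ptp(flank_row)


def test_mirror_symmetry_vertical_axis(small_geometry):
    config = lm.StimulusConfig(
        separation_lambda=3.0,
        orientation_condition="collinear",
        target_contrast=0.3,
        phase=0.0,
        geometry=small_geometry,
    )
    img = lm.render_triplet(config)
    assert np.allclose(img.luminance, img.luminance[:, ::-1])


def test_zero_separation_rejected():
    with pytest.raises(lm.ParameterError):
        lm.StimulusConfig(
            separation_lambda=0.0,
            orientation_condition="collinear",
            target_contrast=0.2,
        )


def test_flanker_outside_raster_names_separation(small_geometry):
    config = lm.StimulusConfig(
        separation_lambda=8.0,
        orientation_condition="collinear",
        target_contrast=0.2,
        geometry=small_geometry,  # 257 rows cannot hold +/- 224 px offsets
    )
    with pytest.raises(lm.GeometryError, match="8"):
        lm.render_triplet(config)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"contrast": 1.5},
        {"contrast": -0.1},
        {"contrast": 0.5, "sf": 0.0},
        {"contrast": 0.5, "sigma": -1.0},
    ],
)
def test_invalid_gabor_parameters_rejected(kwargs, small_geometry):
    with pytest.raises(lm.ParameterError):
        lm.render_gabor(geometry=small_geometry, **kwargs)


def test_quantization_and_text_export(small_geometry, tmp_path):
    img = lm.render_gabor(0.5, geometry=small_geometry)
    gray = img.to_grayscale()
    assert gray.dtype == np.uint8
    # mean luminance maps to mid-gray
    uniform = lm.render_gabor(0.0, geometry=small_geometry).to_grayscale()
    assert np.all((uniform == 127) | (uniform == 128))
    text = img.to_text()
    parsed = np.loadtxt(text.splitlines())
    assert np.allclose(parsed, img.luminance, rtol=1e-4)
    png = tmp_path / "stim.png"
    img.save_png(png)
    assert png.stat().st_size > 0
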