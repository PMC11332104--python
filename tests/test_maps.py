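"""Map builders: fixation map, central bias, meaning map, fixture model, I/O."""

import numpy as np
import pandas as pd
import pytest

from gazebench.geometry import STUDY_GEOMETRY as G, ScreenGeometry
from gazebench.evaluate import nss
from gazebench.maps import (
    MapParams,
    SalienceGrid,
    aggregate_meaning_map,
    central_bias_map,
    fixture_saliency,
    load_grid,
    make_fixation_map,
    save_grid,
)


def fix_df(points):
    return pd.DataFrame([{"participant_id": "p0", "x_px": x, "y_px": y} for x, y in points])


# --- fixation map ----------------------------------------------------------


def test_single_central_fixation_peaks_at_center():
    m = make_fixation_map(fix_df([(960.0, 540.0)]), G)
    iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
    assert (ix, iy) == (960, 540)
    assert m.values[540, 960] > 0


def test_fixation_map_is_linear_in_multiplicity():
    one = make_fixation_map(fix_df([(960.0, 540.0)]), G)
    two = make_fixation_map(fix_df([(960.0, 540.0), (960.0, 540.0)]), G)
    np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)


def test_fixation_map_gaussian_falloff_at_one_dva():
    m = make_fixation_map(fix_df([(960.0, 540.0)]), G).values
    # 1 dva horizontally = 38.4 px; nearest integer pixel offset
    ratio = m[540, 960 + 38] / m[540, 960]
    assert ratio == pytest.approx(np.exp(-0.5), rel=0.03)


def test_fixation_map_mass_is_preserved():
    pts = [(960.0, 540.0), (100.0, 100.0), (1900.0, 1000.0)]  # incl. near-edge
    m = make_fixation_map(fix_df(pts), G)
    assert m.values.sum() == pytest.approx(len(pts), rel=1e-6)


def test_fixation_map_permutation_invariance():
    pts = [(300.0, 400.0), (1200.0, 800.0), (700.0, 200.0)]
    a = make_fixation_map(fix_df(pts), G).values
    b = make_fixation_map(fix_df(pts[::-1]), G).values
    np.testing.assert_array_equal(a, b)


def test_empty_fixation_set_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        make_fixation_map(fix_df([]), G)


# --- central bias ----------------------------------------------------------


def test_central_bias_peaks_at_center_and_is_flip_symmetric():
    m = central_bias_map(G).values
    iy, ix = np.unravel_index(np.argmax(m), m.shape)
    assert ix in (959, 960) and iy in (539, 540)
    np.testing.assert_array_equal(m, m[:, ::-1])
    np.testing.assert_array_equal(m, m[::-1, :])


def test_central_bias_sd_equals_screen_half_dimensions():
    m = central_bias_map(G).values
    center = m[540, 960]
    # value one SD (960 px) to the right of center, sampled at pixel centres
    edge = m[540, 1919]  # centre 1919.5, offset 959.5 px
    assert edge / center == pytest.approx(np.exp(-0.5 * (959.5 / 960) ** 2), rel=1e-6)


# --- meaning map -----------------------------------------------------------


def rating(x, y, d, r):
    return {"x_px": x, "y_px": y, "diameter_dva": d, "rating": r}


def test_single_patch_paints_its_rating(small_geometry):
    df = pd.DataFrame([rating(240, 135, 7.0, 4.0)])
    m = aggregate_meaning_map(df, small_geometry).values
    assert m[135, 240] == 4.0
    assert m.min() == 4.0  # uncovered pixels take the grid minimum


def test_overlapping_same_scale_patches_average(small_geometry):
    df = pd.DataFrame([rating(230, 135, 7.0, 1.0), rating(250, 135, 7.0, 3.0)])
    m = aggregate_meaning_map(df, small_geometry).values
    assert m[135, 240] == pytest.approx(2.0)


def test_meaning_map_predicts_fixations_placed_in_high_rated_patches(small_geometry):
    rng = np.random.default_rng(4)
    rows, high_centers = [], []
    for i, x in enumerate(range(30, 480, 60)):
        for j, y in enumerate(range(30, 270, 60)):
            r = 5.0 if (i + j) % 2 == 0 else 1.0
            rows.append(rating(x, y, 3.0, r))
            if r == 5.0:
                high_centers.append((x, y))
    m = aggregate_meaning_map(pd.DataFrame(rows), small_geometry)
    picks = rng.choice(len(high_centers), size=60)
    pts = [
        (high_centers[i][0] + rng.normal(0, 3), high_centers[i][1] + rng.normal(0, 3))
        for i in picks
    ]
    assert nss(m, fix_df(pts)).nss > 0


def test_empty_ratings_error(small_geometry):
    with pytest.raises(ValueError):
        aggregate_meaning_map(pd.DataFrame(columns=["x_px", "y_px", "diameter_dva", "rating"]), small_geometry)


# --- fixture model ---------------------------------------------------------


def test_constant_image_gives_constant_map(small_geometry):
    img = np.full(small_geometry.shape, 7.0)
    m = fixture_saliency(img, small_geometry)
    assert np.all(m.values == m.values.flat[0])


def test_isolated_bright_pixel_is_most_salient(small_geometry):
    img = np.zeros(small_geometry.shape)
    img[100, 300] = 1.0
    m = fixture_saliency(img, small_geometry).values
    iy, ix = np.unravel_index(np.argmax(m), m.shape)
    assert abs(ix - 300) <= 2 and abs(iy - 100) <= 2


def test_fixture_is_invariant_to_added_constant(small_geometry):
    rng = np.random.default_rng(8)
    img = rng.random(small_geometry.shape)
    a = fixture_saliency(img, small_geometry).values
    b = fixture_saliency(img + 123.4, small_geometry).values
    # mean subtraction removes the DC component up to float cancellation,
    # which the log-spectrum amplifies in near-zero-salience pixels; the
    # map is unchanged relative to its peak
    assert np.abs(a - b).max() < 1e-2 * a.max()
    assert np.unravel_index(np.argmax(a), a.shape) == np.unravel_index(np.argmax(b), b.shape)


# --- container and I/O -----------------------------------------------------


def test_grid_validation_rejects_bad_shape_and_nonfinite(small_geometry):
    with pytest.raises(ValueError, match="shape"):
        SalienceGrid(np.zeros((5, 5)), small_geometry)
    bad = np.zeros(small_geometry.shape)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        SalienceGrid(bad, small_geometry)


@pytest.mark.parametrize("suffix", [".npy", ".txt"])
def test_grid_roundtrip_lossless(tmp_path, small_geometry, suffix):
    rng = np.random.default_rng(0)
    grid = SalienceGrid(rng.random(small_geometry.shape), small_geometry, kind="fixture")
    save_grid(grid, tmp_path / f"g{suffix}")
    back = load_grid(tmp_path / f"g{suffix}")
    np.testing.assert_allclose(back.values, grid.values, rtol=1e-12)
    assert back.kind == "fixture"
    assert back.geometry == small_geometry


def test_grid_roundtrip_png_is_close(tmp_path, small_geometry):
    rng = np.random.default_rng(1)
    grid = SalienceGrid(rng.random(small_geometry.shape), small_geometry, kind="central_bias")
    save_grid(grid, tmp_path / "g.png")
    back = load_grid(tmp_path / "g.png")
    assert np.abs(back.values - grid.values).max() < 1.0 / 65534
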