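"""Phantom generator: geometry fidelity, determinism, speckle statistics."""

import numpy as np
import pytest

from ezoct.phantom import (
    LABELS,
    BScanImage,
    PhantomSpec,
    apply_speckle,
    band_geometry,
    compact_spec,
    generate_bscan,
    generate_volume,
)


def test_mask_bands_follow_spec_geometry_per_column(clean_spec, clean_pair):
    """Every labeled band in the mask must match the analytic geometry exactly."""
    _, mask = clean_pair
    geom = band_geometry(clean_spec)
    lab = mask.labels
    H = lab.shape[0]
    rows = np.arange(H)[:, None]
    for name in ("opl", "elm", "ez", "rpe"):
        lu, ll, present = geom[name]
        expected = (rows >= lu) & (rows <= ll) & present
        np.testing.assert_array_equal(lab == LABELS[name], expected, err_msg=name)


def test_zero_ez_extent_has_no_ez_label():
    spec = PhantomSpec(ez_extent_mm=0.0, speckle_level=0.0)
    _, mask = generate_bscan(spec, seed=0)
    assert not (mask.labels == LABELS["ez"]).any()


def test_seed_determinism(clean_spec):
    img1, mask1 = generate_bscan(clean_spec, seed=7)
    img2, mask2 = generate_bscan(clean_spec, seed=7)
    np.testing.assert_array_equal(img1.pixels, img2.pixels)
    np.testing.assert_array_equal(mask1.labels, mask2.labels)
    noisy = PhantomSpec(speckle_level=0.25)
    n1, _ = generate_bscan(noisy, seed=7)
    n2, _ = generate_bscan(noisy, seed=7)
    np.testing.assert_array_equal(n1.pixels, n2.pixels)


def test_ez_band_height_is_exactly_spec_thickness(clean_spec, clean_pair):
    _, mask = clean_pair
    ez = mask.labels == LABELS["ez"]
    heights = ez.sum(axis=0)
    assert set(np.unique(heights)) == {clean_spec.thicknesses["ez"]}


def test_overlapping_bands_rejected():
    spec = PhantomSpec(center_rows={"opl": 263, "elm": 266, "ez": 268, "rpe": 275})
    with pytest.raises(ValueError, match="overlaps"):
        spec.validate()


def test_bands_exceeding_height_rejected():
    with pytest.raises(ValueError, match="height"):
        compact_spec(40, 64)


def test_speckle_identity_at_level_zero(clean_pair):
    img, _ = clean_pair
    assert apply_speckle(img, 0.0, seed=3) is img


def test_speckle_reproducible_and_unit_mean():
    """Noisy/clean ratio over a bright constant region has mean 1 within 3 SE."""
    const = BScanImage(pixels=np.full((200, 200), 0.5))
    level = 0.3
    a = apply_speckle(const, level, seed=5)
    b = apply_speckle(const, level, seed=5)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    ratio = a.pixels / 0.5
    n = ratio.size
    se = level / np.sqrt(n)
    assert abs(ratio.mean() - 1.0) < 3 * se


def test_volume_zero_radius_is_ez_free():
    spec = compact_spec(96, 128, speckle_level=0.0)
    _, masks = generate_volume(spec, 5, footprint_mm=(0.0, 0.0), seed=0)
    assert all(not (m.labels == 1).any() for m in masks)


def test_volume_center_bscan_width_matches_footprint():
    spec = PhantomSpec(speckle_level=0.0)
    a = 2.0  # mm
    imgs, masks = generate_volume(spec, 21, footprint_mm=(a, 2.5), seed=0)
    mid = masks[10]
    cols = np.flatnonzero((mid.labels == 1).any(axis=0))
    width_mm = (cols[-1] - cols[0]) * spec.lateral_um_per_px / 1000.0
    assert abs(width_mm - 2 * a) <= 2 * spec.lateral_um_per_px / 1000.0 + 1e-9
    assert imgs[0].bscan_spacing_um == pytest.approx(6000.0 / 20)


def test_volume_seed_stability():
    spec = compact_spec(96, 96, speckle_level=0.2)
    i1, m1 = generate_volume(spec, 4, (0.3, 2.0), seed=9)
    i2, m2 = generate_volume(spec, 4, (0.3, 2.0), seed=9)
    for a, b in zip(i1, i2):
        np.testing.assert_array_equal(a.pixels, b.pixels)
    with pytest.raises(ValueError):
        generate_volume(spec, 1, (1.0, 1.0))
    with pytest.raises(ValueError):
        generate_volume(spec, 4, (-1.0, 1.0))
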