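"""En-face EZ mapping: limits, interpolation, area, width, ETDRS ROI."""

import numpy as np
import pytest

from ezoct.enface import (
    EZLimits,
    collect_limits,
    etdrs_roi,
    ez_area,
    ez_limits_per_bscan,
    ez_width_percent,
    interpolate_limits,
    analyze_volume,
)
from ezoct.phantom import ClassMap, PhantomSpec, generate_volume


def _mask(cols, width=600, height=20):
    lab = np.zeros((height, width), dtype=np.uint8)
    for c in cols:
        lab[10, c] = 1
    return ClassMap(labels=lab)


def test_limits_envelope_and_absent():
    assert ez_limits_per_bscan(_mask(range(200, 501))) == (200, 500)
    assert ez_limits_per_bscan(_mask([])) is None
    # interior gap bridged by the outer envelope
    assert ez_limits_per_bscan(_mask(list(range(200, 301)) + list(range(400, 501)))) == (200, 500)


def test_interpolation_constant_limits_across_gap():
    lims = EZLimits(
        left=np.array([100.0, np.nan, 100.0]),
        right=np.array([200.0, np.nan, 200.0]),
        positions_mm=np.array([-0.011, 0.0, 0.011]),
    )
    emap = interpolate_limits(lims, lateral_um_per_px=11.0, n_columns=300)
    # the middle grid row is interpolated to the same limits
    mid = emap.presence[1]
    assert mid[100] and mid[200] and not mid[99] and not mid[201]


def test_interpolation_linear_midpoint():
    lims = EZLimits(
        left=np.array([100.0, np.nan, 200.0]),
        right=np.array([200.0, np.nan, 300.0]),
        positions_mm=np.array([-0.011, 0.0, 0.011]),
    )
    emap = interpolate_limits(lims, lateral_um_per_px=11.0, n_columns=400)
    mid = emap.presence[1]
    cols = np.flatnonzero(mid)
    assert cols[0] == 150 and cols[-1] == 250


def test_edge_absent_bscans_not_extrapolated():
    lims = EZLimits(
        left=np.array([np.nan, 100.0, 100.0, np.nan]),
        right=np.array([np.nan, 200.0, 200.0, np.nan]),
        positions_mm=np.array([-0.033, -0.011, 0.011, 0.033]),
    )
    emap = interpolate_limits(lims, lateral_um_per_px=11.0, n_columns=300)
    assert not emap.presence[0].any() and not emap.presence[-1].any()


def test_all_absent_gives_empty_map():
    lims = EZLimits(
        left=np.array([np.nan, np.nan]),
        right=np.array([np.nan, np.nan]),
        positions_mm=np.array([0.0, 0.011]),
    )
    emap = interpolate_limits(lims, n_columns=10)
    assert not emap.presence.any()
    assert ez_area(emap) == 0.0


def test_single_anchor_warns():
    lims = EZLimits(
        left=np.array([np.nan, 120.0]),
        right=np.array([np.nan, 140.0]),
        positions_mm=np.array([0.0, 0.011]),
    )
    with pytest.warns(UserWarning, match="fewer than 2"):
        emap = interpolate_limits(lims, n_columns=200)
    assert emap.presence.sum() == 21


def test_area_pixel_tally():
    """8,264 present pixels at 121 um^2 tally to 0.999944 mm^2."""
    lims = EZLimits(
        left=np.full(2, 0.0),
        right=np.full(2, 1032.0),  # 1033 columns per row
        positions_mm=np.array([0.0, 0.077]),  # 8 grid rows at 11 um pitch
    )
    emap = interpolate_limits(lims, lateral_um_per_px=11.0, n_columns=1100)
    assert emap.presence.sum() == 8264
    assert ez_area(emap) == pytest.approx(8264 * 121e-6)
    assert ez_area(emap) == pytest.approx(0.999944)


def test_area_monotone_in_presence():
    lims = EZLimits(
        left=np.array([50.0, 50.0]),
        right=np.array([80.0, 80.0]),
        positions_mm=np.array([0.0, 0.055]),
    )
    emap = interpolate_limits(lims, n_columns=100)
    a0 = ez_area(emap)
    emap.presence[0, 90] = True
    assert ez_area(emap) > a0


def test_elliptical_volume_recovers_analytic_area():
    """A 61-B-scan volume with an elliptical EZ footprint recovers pi*a*b within 2%."""
    spec = PhantomSpec(image_width=1024, speckle_level=0.0)
    a, b = 2.0, 2.5
    imgs, masks = generate_volume(spec, 61, footprint_mm=(a, b), seed=0)
    positions = (np.arange(61) - 30) * imgs[0].bscan_spacing_um / 1000.0
    rep = analyze_volume(masks, positions, spec.fovea_column, spec.lateral_um_per_px)
    analytic = np.pi * a * b
    assert abs(rep["ez_area_mm2"] - analytic) / analytic < 0.02


def test_width_percent_cases():
    lat = 10.0
    fovea = 500
    # spans the full 6-mm ROI (and beyond): 100%
    assert ez_width_percent((0, 999), fovea, lat) == 100.0
    # 3 mm centered on the fovea: 50%
    assert ez_width_percent((fovea - 150, fovea + 150), fovea, lat) == pytest.approx(50.0)
    # absent EZ: 0%
    assert ez_width_percent(None, fovea, lat) == 0.0
    with pytest.raises(ValueError):
        ez_width_percent((10, 5), fovea, lat)


def test_etdrs_roi_disc_and_square_areas():
    shape = (700, 700)
    center = (350, 350)
    pitch = (11.0, 11.0)
    disc = etdrs_roi(shape, center, pitch, 6.0, "disc")
    disc_area = disc.sum() * 121e-6
    assert abs(disc_area - np.pi * 9.0) / (np.pi * 9.0) < 0.01
    square = etdrs_roi(shape, center, pitch, 6.0, "square")
    sq_area = square.sum() * 121e-6
    assert abs(sq_area - 36.0) / 36.0 < 0.01
    assert not etdrs_roi(shape, center, pitch, 0.0, "disc").any()


def test_etdrs_rings_and_quadrants():
    roi, zones, quad = etdrs_roi((700, 700), (350, 350), (11.0, 11.0), 6.0, "disc",
                                 laterality="right", rings=True)
    assert set(np.unique(zones)) == {0, 1, 2, 3}
    assert set(np.unique(quad)) == {0, 1, 2, 3, 4}
    # right eye: nasal quadrant lies left of the fovea
    assert quad[350, 100] == 2
    assert quad[350, 600] == 4
    roiL, _, quadL = etdrs_roi((700, 700), (350, 350), (11.0, 11.0), 6.0, "disc",
                               laterality="left", rings=True)
    assert quadL[350, 100] == 4 and quadL[350, 600] == 2


def test_roi_clipping_warns():
    with pytest.warns(UserWarning, match="clip"):
        etdrs_roi((100, 100), (50, 50), (11.0, 11.0), 6.0, "square")
    with pytest.raises(ValueError):
        etdrs_roi((100, 100), (200, 50), (11.0, 11.0))
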