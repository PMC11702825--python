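"""Total-variation denoising (ROF) and EZ granularity against naive oracles."""

import numpy as np
import pytest

from ezoct.biomarkers import ez_granularity, extract_layer_bands, tv_denoise
from ezoct.phantom import BScanImage, ClassMap, PhantomSpec, generate_bscan


def total_variation(img):
    return np.abs(np.diff(img, axis=0)).sum() + np.abs(np.diff(img, axis=1)).sum()


def test_constant_image_unchanged():
    const = np.full((32, 32), 0.4)
    np.testing.assert_allclose(tv_denoise(const, alpha=0.2), const, atol=1e-8)


def test_alpha_zero_is_identity():
    rng = np.random.default_rng(0)
    img = rng.random((24, 24))
    np.testing.assert_allclose(tv_denoise(img, alpha=0.0), img, atol=1e-4)


def test_total_variation_never_increases():
    rng = np.random.default_rng(1)
    img = rng.random((40, 40))
    for alpha in (0.01, 0.05, 0.5):
        out = tv_denoise(img, alpha=alpha)
        assert total_variation(out) <= total_variation(img) + 1e-9


def test_1d_step_matches_closed_form_rof():
    """For a two-level 1-D step (n samples per plateau, height h), the ROF
    minimizer of 0.5||u-f||^2 + alpha*TV moves each plateau alpha/n toward the
    other while alpha < n*h/2."""
    n, h, alpha = 25, 1.0, 0.4
    f = np.concatenate([np.zeros(n), np.full(n, h)])
    u = tv_denoise(f, alpha=alpha, eps=1e-12, max_iter=20000)
    assert u[:n] == pytest.approx(alpha / n, abs=1e-4)
    assert u[n:] == pytest.approx(h - alpha / n, abs=1e-4)


def test_non_finite_input_rejected():
    img = np.full((8, 8), np.nan)
    with pytest.raises(ValueError):
        tv_denoise(img, alpha=0.1)
    with pytest.raises(ValueError):
        tv_denoise(np.zeros((8, 8)), alpha=-0.1)


def naive_ez_lv(pix, up, lo, pres, beta):
    """Triple-loop oracle for the local-variation sum."""
    W = pix.shape[1]
    lv = np.full(W, np.nan)
    for x in range(W):
        if not pres[x]:
            continue
        acc = 0.0
        for k in range(-beta, beta + 1):
            if 0 <= x + k < W:
                for y in range(up[x], lo[x] + 1):
                    acc += abs(pix[y, x + k] - pix[y, x])
        lv[x] = acc
    return lv


def _bands_for(lab):
    return extract_layer_bands(ClassMap(labels=lab))


def test_constant_ez_band_has_zero_granularity():
    lab = np.zeros((20, 30), dtype=np.uint8)
    lab[8:12] = 1
    pix = np.where(lab == 1, 0.7, 0.0)
    lv, tv = ez_granularity(pix, _bands_for(lab), beta=3, alpha=0.0)
    np.testing.assert_allclose(lv[np.isfinite(lv)], 0.0, atol=1e-12)
    assert tv == 0.0


def test_alternating_single_row_band_beta1_matches_oracle():
    W = 12
    lab = np.zeros((5, W), dtype=np.uint8)
    lab[2] = 1
    pix = np.zeros((5, W))
    pix[2] = np.arange(W) % 2  # alternating 0/1
    bands = _bands_for(lab)
    lv, tv = ez_granularity(pix, bands, beta=1, alpha=0.0)
    up, lo, pres = bands.band("ez")
    expected = naive_ez_lv(pix, up, lo, pres, 1)
    np.testing.assert_allclose(lv, expected)
    assert tv == pytest.approx(np.nansum(expected) / (2 * 1 * W) * 100.0)


@pytest.mark.parametrize("beta", [1, 3, 5, 7])
def test_random_regions_match_naive_oracle(beta):
    rng = np.random.default_rng(beta)
    for _ in range(30):
        W, H = 10, 10
        lab = np.zeros((H, W), dtype=np.uint8)
        # random EZ band: per-column row ranges, some columns empty
        for x in range(W):
            if rng.random() < 0.8:
                r0 = int(rng.integers(0, H - 2))
                r1 = int(rng.integers(r0, min(r0 + 4, H - 1)))
                lab[r0 : r1 + 1, x] = 1
        if not (lab == 1).any():
            continue
        pix = rng.random((H, W))
        bands = _bands_for(lab)
        lv, tv = ez_granularity(pix, bands, beta=beta, alpha=0.0)
        up, lo, pres = bands.band("ez")
        expected = naive_ez_lv(pix, up, lo, pres, beta)
        np.testing.assert_allclose(lv, expected, atol=1e-12)
        n = pres.sum()
        assert tv == pytest.approx(np.nansum(expected) / (2 * beta * n) * 100.0)


def test_invalid_beta_rejected():
    lab = np.zeros((6, 6), dtype=np.uint8)
    lab[2] = 1
    with pytest.raises(ValueError):
        ez_granularity(np.zeros((6, 6)), _bands_for(lab), beta=2)
    with pytest.raises(ValueError):
        ez_granularity(np.zeros((6, 6)), _bands_for(lab), beta=0)


def test_granularity_decreases_with_stronger_denoising():
    """EZ granularity of a fixed speckled phantom falls as alpha rises."""
    spec = PhantomSpec(image_height=256, image_width=256,
                       center_rows={"opl": 120, "elm": 150, "ez": 165, "rpe": 180},
                       pit_depth=10.0, pit_width=30.0, speckle_level=0.3)
    img, mask = generate_bscan(spec, seed=4)
    bands = extract_layer_bands(mask)
    tvs = [ez_granularity(img, bands, beta=3, alpha=a)[1] for a in (0.005, 0.05, 0.5)]
    assert tvs[0] > tvs[1] > tvs[2]
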