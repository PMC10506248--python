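import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bcseg import preprocess as pp
from bcseg.types import CTSlice, SliceType


def _slc(pixels, stype=SliceType.THIGH):
    return CTSlice(np.asarray(pixels), stype)


# ---------------------------------------------------------------------------
# HU windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("target, expected", [
    ("liver_crude", (-25, 125)),
    ("liver_accurate", (-25, 125)),
    ("spleen", (-25, 125)),
    ("sat", (-219, 190)),
    ("vat", (-219, 190)),
    ("thigh_sat", (-198, 189)),
    ("imat", (-198, 189)),
    ("skeleton_muscle", (-181, 216)),
    ("spine_bone_marrow", (-181, 216)),
])
def test_default_windows(target, expected):
    w = pp.default_window(target)
    assert (w.lo, w.hi) == expected


def test_unknown_target_rejected():
    with pytest.raises(KeyError):
        pp.default_window("gallbladder")


def test_windowing_clamps():
    slc = _slc([[-1000, 50, 3000]], SliceType.LIVER)
    out = pp.hu_window(slc, pp.HUWindow(-25, 125))
    assert out.pixels.tolist() == [[-25, 50, 125]]


@given(hnp.arrays(np.int16, (9, 9), elements=st.integers(-1024, 3071)))
@settings(max_examples=30, deadline=None)
def test_windowing_idempotent_and_bounded(pixels):
    w = pp.HUWindow(-198, 189)
    once = pp.hu_window(_slc(pixels), w)
    twice = pp.hu_window(once, w)
    assert np.array_equal(once.pixels, twice.pixels)
    assert once.pixels.min() >= w.lo and once.pixels.max() <= w.hi


# ---------------------------------------------------------------------------
# adaptive median: brute-force per-pixel reference
# ---------------------------------------------------------------------------

def amf_reference(img, smax):
    """Direct per-pixel transcription of the growing-aperture rule."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    p = smax // 2
    xp = np.pad(img, p, mode="reflect")
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            x = img[r, c]
            for win in range(3, smax + 1, 2):
                q = win // 2
                block = xp[r + p - q: r + p + q + 1, c + p - q: c + p + q + 1]
                med, mn, mx = np.median(block), block.min(), block.max()
                if mn < med < mx:
                    out[r, c] = x if mn < x < mx else med
                    break
                if win == smax:
                    out[r, c] = med
    return out


@pytest.mark.parametrize("smax", [3, 5, 7])
def test_adaptive_median_matches_reference(rng, smax):
    img = rng.integers(-200, 200, size=(17, 19)).astype(np.int16)
    # sprinkle impulses
    idx = rng.integers(0, 17, 12), rng.integers(0, 19, 12)
    img[idx] = 3071
    got = pp.adaptive_median(_slc(img), smax).pixels
    assert np.array_equal(got.astype(np.float64), amf_reference(img, smax))


def test_adaptive_median_constant_and_impulse():
    const = pp.adaptive_median(_slc(np.full((8, 8), 42)), 7)
    assert np.all(const.pixels == 42)

    img = np.zeros((9, 9), dtype=np.int16)
    img[4, 4] = 3071
    out = pp.adaptive_median(_slc(img), 7)
    assert out.pixels[4, 4] == 0
    assert np.all(out.pixels == 0)


def test_adaptive_median_smooth_gradient_interior_unchanged():
    yy, xx = np.mgrid[0:20, 0:24]
    img = (3 * yy + 2 * xx).astype(np.int16)
    out = pp.adaptive_median(_slc(img), 7).pixels
    assert np.array_equal(out[3:-3, 3:-3], img[3:-3, 3:-3])


def test_adaptive_median_idempotent_on_impulse_free(rng):
    yy, xx = np.mgrid[0:24, 0:24]
    img = (2 * yy + xx).astype(np.int16)
    once = pp.adaptive_median(_slc(img), 5)
    twice = pp.adaptive_median(once, 5)
    assert np.array_equal(once.pixels[2:-2, 2:-2], twice.pixels[2:-2, 2:-2])


@pytest.mark.parametrize("bad", [2, 1, 4, -3])
def test_adaptive_median_rejects_bad_aperture(bad):
    with pytest.raises(ValueError):
        pp.adaptive_median(_slc(np.zeros((4, 4))), bad)


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def test_zscore_two_level_closed_form():
    img = np.array([[0, 2], [0, 2]])
    out = pp.zscore(_slc(img))
    assert np.allclose(out, [[-1, 1], [-1, 1]])  # population sd = 1


def test_zscore_degenerate_and_affine_invariance(rng):
    assert np.all(pp.zscore(_slc(np.full((5, 5), 123))) == 0)
    img = rng.normal(0, 50, (16, 16))
    a, b = 3.7, -250.0
    assert np.allclose(pp.zscore(_slc(img)), pp.zscore(_slc(a * img + b)), atol=1e-9)


@given(hnp.arrays(np.int16, (12, 12), elements=st.integers(-1000, 1000)))
@settings(max_examples=30, deadline=None)
def test_zscore_moments(pixels):
    out = pp.zscore(_slc(pixels))
    if np.std(pixels) > 1e-8:
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6
    else:
        assert np.all(out == 0)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_preprocess_composition_and_determinism(rng):
    cfg = pp.PreprocessConfig.for_target("thigh_sat")
    img = rng.integers(-300, 300, size=(24, 24)).astype(np.int16)
    img[5, 5] = 3071  # impulse above the window: clamped then smoothed away
    slc = _slc(img)
    got = pp.preprocess(slc, cfg)
    manual = pp.zscore(pp.adaptive_median(pp.hu_window(slc, cfg.window),
                                          cfg.amf_max_window), cfg.eps)
    assert np.array_equal(got, manual)
    assert np.array_equal(got, pp.preprocess(slc, cfg))  # deterministic


def test_preprocess_constant_slice_all_zero():
    cfg = pp.PreprocessConfig.for_target("liver_crude")
    out = pp.preprocess(_slc(np.full((16, 16), 60), SliceType.LIVER), cfg)
    assert np.all(out == 0)
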