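import numpy as np
import pytest

from defringe import (FILTER_DESIGNS, HoneycombNotchFilter, NotchWindow,
                      SizingParams, affected_extent, apply_notch, forward_fft,
                      inverse_fft, log_magnitude, make_filter,
                      remove_honeycomb, window_size)
from defringe.peaks import Peak


def brute_extent(s, peak):
    """Independent fixpoint growth by path-monotone strict descent."""
    h, w = s.shape
    region = {peak}
    changed = True
    while changed:
        changed = False
        for r in range(h):
            for c in range(w):
                if (r, c) in region:
                    continue
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        nr, nc = r + dr, c + dc
                        if (nr, nc) in region and s[r, c] < s[nr, nc]:
                            region.add((r, c))
                            changed = True
                            break
                    else:
                        continue
                    break
    d = max(np.hypot(r - peak[0], c - peak[1]) for r, c in region)
    return region, d


class TestAffectedExtent:
    def test_isolated_peak_has_zero_extent(self):
        s = np.full((5, 5), 9.0)
        s[2, 2] = 1.0  # surrounded by strictly higher values
        region, d = affected_extent(s, Peak((2, 2), 1.0))
        assert d == 0
        assert region.sum() == 1

    def test_radial_bump_extent_matches_radius(self):
        h = w = 9
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        dist = np.hypot(rr - 4, cc - 4)
        s = np.where(dist <= 3, 10.0 - dist, 20.0)  # flat higher background
        region, d = affected_extent(s, Peak((4, 4), 10.0))
        assert d == pytest.approx(3.0)
        bruteR, bruteD = brute_extent(s, (4, 4))
        assert d == pytest.approx(bruteD)
        assert set(zip(*np.nonzero(region))) == bruteR

    def test_monotone_ridge(self):
        s = np.zeros((3, 7)) + 50.0
        s[1, 1:6] = [10, 9, 8, 7, 6]  # descending 4 px east
        region, d = affected_extent(s, Peak((1, 1), 10.0))
        assert d == pytest.approx(4.0)

    def test_matches_bruteforce_on_random_surfaces(self, rng):
        for _ in range(10):
            s = np.round(rng.uniform(0, 10, (9, 9)), 1)
            peak = tuple(int(v) for v in rng.integers(0, 9, 2))
            region, d = affected_extent(s, peak)
            bruteR, bruteD = brute_extent(s, peak)
            assert set(zip(*np.nonzero(region))) == bruteR
            assert d == pytest.approx(bruteD)


class TestWindowSize:
    @pytest.mark.parametrize("d,a,expected", [
        (3, 1.0, 7),       # n = 2*3+1
        (0, 1.0, 3),       # minimum window
        (2.5, 1.2, 7),     # ceil(3.0) = 3 -> 7
        (1.1, 1.0, 5),     # ceil rounds up
    ])
    def test_formula(self, d, a, expected):
        assert window_size(d, SizingParams(scale_a=a)) == expected

    def test_cap_by_spectrum_fraction(self):
        n = window_size(100, SizingParams(scale_a=1.0, max_fraction=0.25),
                        spectrum_shape=(64, 64))
        assert n == 15  # floor(0.25*64)=16 -> odd 15
        assert n % 2 == 1

    def test_monotone_in_d_and_a(self):
        params = SizingParams(scale_a=1.3)
        sizes = [window_size(d, params) for d in np.linspace(0, 9, 25)]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        for d in (0.5, 2.0, 5.0):
            n_small = window_size(d, SizingParams(scale_a=0.7))
            n_big = window_size(d, SizingParams(scale_a=2.0))
            assert n_big >= n_small

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            SizingParams(scale_a=0.0)


class TestMakeFilter:
    @pytest.mark.parametrize("design", FILTER_DESIGNS)
    @pytest.mark.parametrize("n", [3, 9, 33])
    def test_range_and_center(self, design, n):
        m = make_filter(design, n)
        assert m.shape == (n, n)
        assert m.min() >= 0 and m.max() <= 1
        center = m[n // 2, n // 2]
        assert center == m.min()  # center is the design's minimum
        if design != "smoothed_ideal":
            assert center == 0.0

    @pytest.mark.parametrize("n", [3, 9, 33])
    def test_closed_forms_match_direct_evaluation(self, n):
        half = (n - 1) / 2
        for design in ("gaussian", "super_gaussian", "hanning", "bartlett",
                       "ideal"):
            m = make_filter(design, n)
            for x in range(n):
                for y in range(n):
                    r = np.hypot((x - half) / half, (y - half) / half)
                    if design == "gaussian":
                        expect = 1 - np.exp(-r**2 / (2 * 0.3**2))
                    elif design == "super_gaussian":
                        expect = 1 - np.exp(-(r / 0.3)**6.0)
                    elif design == "hanning":
                        expect = 1 - 0.5 * (np.cos(np.pi * r) + 1) if r <= 1 else 1.0
                    elif design == "bartlett":
                        expect = r if r <= 1 else 1.0
                    else:
                        expect = 0.0 if r <= 1 else 1.0
                    assert abs(m[x, y] - expect) < 1e-12

    def test_gaussian_at_unit_radius(self):
        m = make_filter("gaussian", 5)
        assert m[2, 0] == pytest.approx(1 - np.exp(-1 / 0.18), abs=1e-10)

    def test_ideal_corner_passes(self):
        assert make_filter("ideal", 5)[0, 0] == 1.0

    @pytest.mark.parametrize("design", ["gaussian", "super_gaussian",
                                        "hanning", "bartlett", "ideal"])
    def test_monotone_along_rays(self, design):
        m = make_filter(design, 21)
        center = 10
        for axis_slice in (m[center, center:], m[center:, center],
                           np.diag(m)[center:]):
            assert np.all(np.diff(axis_slice) >= -1e-12)

    def test_unknown_design_and_even_n(self):
        with pytest.raises(ValueError):
            make_filter("boxcar", 5)
        with pytest.raises(ValueError):
            make_filter("ideal", 4)


class TestApplyNotch:
    def test_identity_filter_leaves_spectrum_unchanged(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        spec = forward_fft(img)
        win = NotchWindow(peak=Peak((4, 6), 1.0), size_n=5, design="ideal",
                          matrix=np.ones((5, 5)))
        out = apply_notch(spec, win)
        np.testing.assert_allclose(out.coeffs, spec.coeffs)

    def test_ideal_notch_removes_cosine_exactly(self):
        w, h = 32, 32
        x = np.arange(w)
        base = np.full((h, w), 1000.0)
        img = base + 200 * np.cos(2 * np.pi * 5 * x / w)
        spec = forward_fft(img)
        peak = (h // 2, w // 2 + 5)
        win = NotchWindow(peak=Peak(peak, 1.0), size_n=3, design="ideal",
                          matrix=make_filter("ideal", 3))
        out = apply_notch(spec, win)
        # mirror is handled inside the call; result must be the flat base
        np.testing.assert_allclose(inverse_fft(out), base, atol=1e-9)

    def test_partial_window_at_border_matches_padded_oracle(self, rng):
        img = rng.uniform(0, 10, (16, 16))
        spec = forward_fft(img)
        mat = make_filter("gaussian", 9)
        peak = (1, 2)  # window extends past the top/left edges
        win = NotchWindow(peak=Peak(peak, 1.0), size_n=9, design="gaussian",
                          matrix=mat)
        out = apply_notch(spec, win)
        # oracle: build the full-size gain by zero-padded placement
        gain = np.ones((22, 22))
        gain[peak[0] - 4 + 3:peak[0] + 5 + 3, peak[1] - 4 + 3:peak[1] + 5 + 3] = mat
        gain = gain[3:19, 3:19]
        mirror = np.roll(gain[::-1, ::-1], (1, 1), axis=(0, 1))
        gain = np.minimum(gain, mirror)
        np.testing.assert_allclose(out.coeffs, spec.coeffs * gain)

    def test_dc_never_attenuated(self, rng):
        img = rng.uniform(0, 10, (16, 16))
        spec = forward_fft(img)
        win = NotchWindow(peak=Peak((8, 9), 1.0), size_n=9, design="ideal",
                          matrix=make_filter("ideal", 9))
        with pytest.warns(UserWarning, match="DC"):
            out = apply_notch(spec, win)
        assert out.coeffs[8, 8] == spec.coeffs[8, 8]

    def test_output_stays_hermitian(self, rng):
        img = rng.uniform(0, 10, (17, 16))  # odd x even
        spec = forward_fft(img)
        win = NotchWindow(peak=Peak((3, 12), 1.0), size_n=7, design="hanning",
                          matrix=make_filter("hanning", 7))
        out = apply_notch(spec, win)
        back = np.fft.ifft2(np.fft.ifftshift(out.coeffs))
        assert np.max(np.abs(back.imag)) < 1e-6 * max(np.ptp(back.real), 1)


class TestRemoveHoneycomb:
    def test_noop_on_pattern_free_image(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = 1000 + 200 * np.exp(-((rr - 32)**2 + (cc - 32)**2) / 400)
        out, report = remove_honeycomb(img)
        assert np.max(np.abs(out - img)) < 1e-6 * np.ptp(img)
        assert report == []

    def test_pattern_suppression_and_mae(self, flat_honeycomb):
        rendered, truth = flat_honeycomb
        out, report = remove_honeycomb(rendered, design="super_gaussian")
        assert len(report) >= 6
        mae_before = np.abs(rendered - truth).mean()
        mae_after = np.abs(out - truth).mean()
        assert mae_after < mae_before
        # spatial variance of the pattern collapses on the flat scene
        assert out.std() < 0.35 * rendered.std()

    def test_output_real_nonnegative(self, flat_honeycomb):
        rendered, _ = flat_honeycomb
        out, _ = remove_honeycomb(rendered)
        assert np.isrealobj(out)
        assert out.min() >= 0

    def test_deterministic(self, flat_honeycomb):
        rendered, _ = flat_honeycomb
        out1, rep1 = remove_honeycomb(rendered)
        out2, rep2 = remove_honeycomb(rendered)
        np.testing.assert_array_equal(out1, out2)
        assert rep1 == rep2


class TestEstimator:
    def test_transform_stack_is_per_band(self, flat_honeycomb):
        rendered, _ = flat_honeycomb
        small = rendered[:96, :96]
        stack = np.stack([small, small * 2.0])
        filt = HoneycombNotchFilter()
        out = filt.transform(stack)
        assert len(filt.reports_) == 2
        single = HoneycombNotchFilter().transform(small)
        np.testing.assert_allclose(out[0], single)
        np.testing.assert_allclose(out[1], 2.0 * single, rtol=1e-10)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        filt = HoneycombNotchFilter(design="ideal", scale_a=2.0)
        cl = clone(filt)
        assert cl.get_params()["scale_a"] == 2.0
        cl.set_params(design="bartlett")
        assert cl.design == "bartlett"
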