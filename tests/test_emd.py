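"""Bidimensional EMD: extrema detection, envelopes, sifting, decomposition."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emdir.emd import (
    ChannelStack,
    DegenerateEnvelopeError,
    EMDChannelStacker,
    MonotoneComponentError,
    SiftConfig,
    build_envelope,
    decompose,
    find_local_extrema,
    mean_envelope,
    select_channels,
    sift_imf,
)


def brute_force_extrema(image, connectivity=8, margin=8):
    """Independent oracle: per-pixel scan of the mirror-extended neighbourhood."""
    m = min(margin, image.shape[0] - 1, image.shape[1] - 1)
    padded = np.pad(image, m, mode="reflect") if m else image
    h, w = image.shape
    maxima, minima = set(), set()
    if connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for r in range(h):
        for c in range(w):
            v = padded[r + m, c + m]
            neigh = []
            for dr, dc in offsets:
                rr, cc = r + m + dr, c + m + dc
                if 0 <= rr < padded.shape[0] and 0 <= cc < padded.shape[1]:
                    neigh.append(padded[rr, cc])
            if all(v > n for n in neigh):
                maxima.add((r, c, float(v)))
            if all(v < n for n in neigh):
                minima.add((r, c, float(v)))
    return maxima, minima


class TestFindLocalExtrema:
    def test_constant_image_has_no_strict_extrema(self):
        maxima, minima = find_local_extrema(np.full((16, 16), 3.0))
        assert maxima == set() and minima == set()

    def test_single_peak_in_plateau(self):
        img = np.ones((5, 5))
        img[2, 2] = 9.0
        maxima, minima = find_local_extrema(img)
        assert maxima == {(2, 2, 9.0)}
        assert minima == set()  # the plateau of ones has no strict minimum

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan(self, connectivity, seed):
        img = np.random.default_rng(seed).uniform(size=(32, 32))
        cfg = SiftConfig(extrema_connectivity=connectivity)
        got_max, got_min = find_local_extrema(img, cfg)
        exp_max, exp_min = brute_force_extrema(img, connectivity, cfg.boundary_margin)
        assert got_max == exp_max
        assert got_min == exp_min
        assert not (got_max & got_min)


class TestBuildEnvelope:
    def test_constant_data_gives_constant_surface(self):
        pts = {(2, 3, 2.5), (10, 4, 2.5), (5, 12, 2.5), (14, 14, 2.5)}
        surf = build_envelope(pts, (16, 16))
        assert surf.shape == (16, 16)
        np.testing.assert_allclose(surf, 2.5, atol=1e-8)

    def test_reproduces_affine_data(self, rng):
        coords = rng.uniform(0, 20, size=(15, 2))
        pts = {(r, c, 0.1 * r + 0.2 * c) for r, c in coords}
        surf = build_envelope(pts, (20, 20))
        rr, cc = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        np.testing.assert_allclose(surf, 0.1 * rr + 0.2 * cc, atol=1e-5)

    def test_interpolation_condition(self, rng):
        pts = {
            (int(r), int(c), float(v))
            for r, c, v in zip(
                rng.choice(24, 12, replace=False),
                rng.choice(24, 12, replace=False),
                rng.normal(size=12),
            )
        }
        surf = build_envelope(pts, (24, 24))
        for r, c, v in pts:
            assert abs(surf[r, c] - v) < 1e-6
        assert np.all(np.isfinite(surf))

    def test_too_few_points_is_degenerate(self):
        with pytest.raises(DegenerateEnvelopeError):
            build_envelope({(0, 0, 1.0), (5, 5, 2.0)}, (8, 8))

    def test_collinear_points_are_degenerate(self):
        pts = {(i, i, float(i)) for i in range(6)}
        with pytest.raises(DegenerateEnvelopeError):
            build_envelope(pts, (8, 8))


class TestSiftIMF:
    def test_single_scale_oscillation_is_its_own_imf(self):
        n = 128
        y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        s = np.sin(2 * np.pi * 8 * x / n) * np.sin(2 * np.pi * 8 * y / n)
        imf, converged = sift_imf(s)
        r = np.corrcoef(imf.ravel(), s.ravel())[0, 1]
        assert r >= 0.95
        assert converged

    def test_constant_image_signals_monotone(self):
        with pytest.raises(MonotoneComponentError):
            sift_imf(np.full((16, 16), 1.0))

    def test_sifting_shrinks_the_mean_envelope(self):
        n = 64
        y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        s = np.sin(2 * np.pi * 6 * x / n) * np.sin(2 * np.pi * 6 * y / n) + 0.02 * x
        imf, converged = sift_imf(s)
        assert converged
        before = np.abs(mean_envelope(s)).max()
        after = np.abs(mean_envelope(imf)).max()
        assert after < before


class TestDecompose:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_reconstruction_identity(self, seed):
        img = np.random.default_rng(seed).normal(size=(64, 64))
        stack = decompose(img)
        err = np.abs(stack.reconstruct() - img).max()
        assert err <= 1e-8 * (img.max() - img.min())
        assert all(c.shape == stack.source_shape for c in stack.imfs)

    def test_constant_image_is_pure_residual(self):
        img = np.full((32, 32), 5.0)
        stack = decompose(img)
        assert stack.n_imfs == 0
        np.testing.assert_array_equal(stack.residual, img)

    def test_three_component_separation(self):
        # high-frequency and low-frequency product sinusoids plus a planar
        # trend; the generating components are the oracle
        n = 128
        y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        hi = np.sin(2 * np.pi * x / 8) * np.sin(2 * np.pi * y / 8)
        lo = np.sin(2 * np.pi * x / 64) * np.sin(2 * np.pi * y / 64)
        trend = 0.01 * x + 0.02 * y
        stack = decompose(0.5 * hi + lo + trend)
        assert stack.n_imfs >= 2

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        assert corr(stack.imfs[0], hi) >= 0.9
        # low-frequency recovery suffers mild mode mixing from first-IMF
        # ripple (see docs/methods.md); 0.85 is what sifting delivers here
        assert corr(stack.imfs[1], lo) >= 0.85
        assert corr(stack.residual, trend) >= 0.9

    def test_deterministic(self):
        img = np.random.default_rng(3).normal(size=(48, 48))
        a = decompose(img)
        b = decompose(img)
        assert a.n_imfs == b.n_imfs
        for ca, cb in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ca, cb)
        np.testing.assert_array_equal(a.residual, b.residual)

    def test_component_cap(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        stack = decompose(img, SiftConfig(max_imfs=2))
        assert stack.n_imfs <= 2

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller than the minimum"):
            decompose(np.ones((4, 4)))

    def test_non_finite_rejected(self):
        img = np.ones((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            decompose(img)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_reconstruction_property(seed):
    """sum(IMFs) + residual == input, for arbitrary random images."""
    img = np.random.default_rng(seed).uniform(-3, 3, size=(24, 24))
    stack = decompose(img, SiftConfig(max_imfs=3))
    assert np.abs(stack.reconstruct() - img).max() <= 1e-8 * np.ptp(img)


class TestSelectChannels:
    def _image_and_stack(self, seed=0, size=64):
        img = np.random.default_rng(seed).normal(size=(size, size))
        return img, decompose(img)

    def test_channel_order_and_shape(self):
        img, stack = self._image_and_stack()
        cs = select_channels(img, stack, normalize=False)
        assert isinstance(cs, ChannelStack)
        assert cs.shape == (64, 64, 4)
        np.testing.assert_array_equal(cs.channels[..., 0], img)
        for j in range(1, 4):
            if j < stack.n_imfs:
                np.testing.assert_array_equal(cs.channels[..., j], stack.imfs[j])

    def test_normalization(self):
        img, stack = self._image_and_stack(seed=1)
        cs = select_channels(img, stack, normalize=True)
        for j in range(4):
            ch = cs.channels[..., j]
            if ch.std() > 0:
                assert abs(ch.mean()) <= 1e-6
                assert abs(ch.std() - 1) <= 1e-6

    def test_missing_imfs_zero_filled_with_warning(self, caplog):
        img, _ = self._image_and_stack(seed=2)
        short = decompose(img, SiftConfig(max_imfs=2))
        assert short.n_imfs == 2
        with caplog.at_level(logging.WARNING, logger="emdir.emd"):
            cs = select_channels(img, short, normalize=False)
        assert "zero-filling" in caplog.text
        np.testing.assert_array_equal(cs.channels[..., 2], 0)
        np.testing.assert_array_equal(cs.channels[..., 3], 0)

    def test_shape_mismatch_rejected(self):
        img, stack = self._image_and_stack()
        with pytest.raises(ValueError, match="does not match"):
            select_channels(np.ones((32, 32)), stack)


class TestEMDChannelStacker:
    def test_transform_shape_and_sklearn_api(self):
        from sklearn.base import clone

        stacker = EMDChannelStacker(max_imfs=3, sd_threshold=0.25)
        assert clone(stacker).get_params()["sd_threshold"] == 0.25
        imgs = np.random.default_rng(0).normal(size=(2, 32, 32))
        out = stacker.fit(imgs).transform(imgs)
        assert out.shape == (2, 32, 32, 4)
        assert np.all(np.isfinite(out))
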