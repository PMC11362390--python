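"""Windowed sigma/mu contrast and the LSPU mapping."""

import numpy as np
import pytest

from lsci.contrast import (
    PerfusionMap,
    contrast_map,
    lspu_map,
    mean_perfusion_map,
)
from lsci.errors import ConfigurationError, UsageError


def naive_contrast(frame, window):
    """Reference double-loop sigma/mu (population SD)."""
    half = window // 2
    rows, cols = frame.shape
    k = np.full(frame.shape, np.nan)
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            patch = frame[r - half : r + half + 1, c - half : c + half + 1]
            mu = patch.mean()
            if mu != 0:
                k[r, c] = patch.std() / mu
    return k


class TestContrastMap:
    def test_constant_frame_has_zero_contrast(self):
        cm = contrast_map(np.full((16, 16), 50.0), 7)
        assert np.all(cm.k_values[cm.valid_mask] == 0.0)

    def test_checkerboard_single_window(self):
        # 7x7 checkerboard: 25 zeros, 24 twos -> mu = 48/49, population
        # SD = sqrt(2400)/49, hence K = sqrt(2400)/48
        frame = np.indices((7, 7)).sum(axis=0) % 2 * 2.0
        assert frame.sum() == 48
        cm = contrast_map(frame, 7)
        assert cm.valid_mask.sum() == 1
        assert cm.k_values[3, 3] == pytest.approx(np.sqrt(2400) / 48, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(4):
            frame = rng.uniform(0.0, 255.0, size=(32, 32))
            cm = contrast_map(frame, 7)
            ref = naive_contrast(frame, 7)
            assert np.allclose(
                cm.k_values[cm.valid_mask], ref[cm.valid_mask], rtol=0, atol=1e-10
            )

    def test_gain_invariance(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(1.0, 200.0, size=(24, 24))
        a = contrast_map(frame, 7)
        b = contrast_map(frame * 3.7, 7)
        assert np.allclose(a.k_values[a.valid_mask], b.k_values[b.valid_mask],
                           rtol=0, atol=1e-10)
        assert np.array_equal(a.valid_mask, b.valid_mask)

    def test_border_masked(self):
        cm = contrast_map(np.ones((10, 12)), 5)
        assert not cm.valid_mask[:2].any() and not cm.valid_mask[-2:].any()
        assert not cm.valid_mask[:, :2].any() and not cm.valid_mask[:, -2:].any()
        assert cm.valid_mask[2:-2, 2:-2].all()

    def test_zero_mean_windows_invalid(self):
        frame = np.zeros((9, 9))
        frame[0, 0] = 5.0
        cm = contrast_map(frame, 7)
        assert not cm.valid_mask[4, 4]  # central window is all-zero

    @pytest.mark.parametrize("window", [4, 9])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ConfigurationError):
            contrast_map(np.ones((8, 8)), window)


class TestLspuMap:
    def _cm(self, k):
        k = np.asarray(k, dtype=float)
        from lsci.contrast import ContrastMap

        return ContrastMap(k_values=k, valid_mask=np.ones_like(k, bool), window=7)

    def test_inverse_square_value(self):
        pm = lspu_map(self._cm([[0.1]]), {"form": "inverse_square", "cap": 200})
        assert pm.lspu[0, 0] == pytest.approx(100.0)

    def test_zero_contrast_maps_to_cap(self):
        pm = lspu_map(self._cm([[0.0]]), {"cap": 200})
        assert pm.lspu[0, 0] == 200.0

    def test_monotone_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        k = np.sort(rng.uniform(0.0, 1.5, size=(1, 50)))
        pm = lspu_map(self._cm(k))
        assert np.all(np.diff(pm.lspu[0]) <= 0)

    def test_raw_contrast_mode(self):
        pm = lspu_map(self._cm([[0.3]]), {"form": "raw_contrast"})
        assert pm.lspu[0, 0] == pytest.approx(0.3)

    def test_bad_cap_rejected(self):
        with pytest.raises(ConfigurationError):
            lspu_map(self._cm([[0.1]]), {"cap": 0.0})


class TestMeanPerfusionMap:
    def _pm(self, value, shape=(8, 8)):
        data = np.full(shape, float(value))
        return PerfusionMap(lspu=data, valid_mask=np.ones(shape, bool),
                            mapping={"form": "inverse_square", "cap": 200.0})

    def test_single_map_identity(self):
        m = self._pm(70.0)
        out = mean_perfusion_map([m])
        assert np.array_equal(out.lspu, m.lspu)

    def test_two_maps_average(self):
        out = mean_perfusion_map([self._pm(40.0), self._pm(60.0)])
        assert np.all(out.lspu == 50.0)

    def test_many_identical_maps_idempotent(self):
        out = mean_perfusion_map([self._pm(83.0)] * 96)
        assert np.allclose(out.lspu, 83.0)

    def test_masks_conjoined(self):
        a, b = self._pm(10.0), self._pm(20.0)
        b.valid_mask[0, 0] = False
        out = mean_perfusion_map([a, b])
        assert not out.valid_mask[0, 0] and out.valid_mask[1:].all()

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(UsageError):
            mean_perfusion_map([])
        with pytest.raises(UsageError):
            mean_perfusion_map([self._pm(1.0, (4, 4)), self._pm(1.0, (5, 5))])
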