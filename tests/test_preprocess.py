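import math

import numpy as np
import pytest

from maldiclust import (
    DenoiseParams,
    GridSpec,
    GridSpectrum,
    RawSpectrum,
    denoise,
    log_transform,
    preprocess_pipeline,
    resample_to_grid,
)
from maldiclust.preprocess import SpectrumPreprocessor, denoise_intensities


def naive_denoise(x, w, keep_fraction, step_pts=1, rule="union"):
    """Independent re-ranking oracle: enumerate every window naively."""
    n = len(x)
    starts = list(range(0, n - w + 1, step_pts))
    if starts[-1] != n - w:
        starts.append(n - w)
    k = math.ceil(keep_fraction * w)
    marked = []
    for s in starts:
        ranked = sorted(range(s, s + w), key=lambda i: (-x[i], i))
        marked.append(set(ranked[:k]))
    if rule == "union":
        keep = set().union(*marked)
    else:
        decision = {}
        for m, s in zip(marked, starts):
            for i in range(s, s + w):
                decision[i] = i in m
        keep = {i for i, v in decision.items() if v}
    return np.array([x[i] if i in keep else 0.0 for i in range(n)])


def random_gridded(rng, n):
    x = np.zeros(n)
    hot = rng.choice(n, size=max(1, n // 6), replace=False)
    x[hot] = rng.lognormal(3, 1, hot.size)
    # duplicate some values to exercise tie handling
    if hot.size > 3:
        x[hot[1]] = x[hot[0]]
        x[hot[3]] = x[hot[2]]
    return x


class TestResample:
    GRID = GridSpec(2000, 2010, 1)

    def test_round_half_up_binning(self):
        grid = GridSpec(3000, 3010, 1)
        s = resample_to_grid(RawSpectrum([3005.4, 3005.6], [10.0, 7.0]), grid)
        assert s.intensity[5] == 10.0 and s.intensity[6] == 7.0

    def test_single_peak_at_grid_start(self):
        s = resample_to_grid(RawSpectrum([2000.0], [5.0]), self.GRID)
        assert s.intensity[0] == 5.0 and s.intensity[1:].sum() == 0

    def test_colliding_peaks_take_max(self):
        s = resample_to_grid(RawSpectrum([2004.9, 2005.1], [3.0, 8.0]), self.GRID)
        assert s.intensity[5] == 8.0

    def test_empty_spectrum_errors(self):
        with pytest.raises(ValueError, match="empty"):
            resample_to_grid(RawSpectrum([], []), self.GRID)

    def test_support_never_exceeds_peak_count(self, rng):
        grid = GridSpec(2000, 2200, 1)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            mz = np.unique(np.round(rng.uniform(2000, 2200, n), 1))
            s = resample_to_grid(RawSpectrum(mz, rng.uniform(1, 100, mz.size)), grid)
            assert s.support.size <= mz.size


class TestLogTransform:
    def _spec(self, values):
        grid = GridSpec(2000, 2000 + len(values) - 1, 1)
        return GridSpectrum(grid, np.asarray(values, float), resampled=True)

    def test_reference_values(self):
        out = log_transform(self._spec([0, 9, 999]))
        np.testing.assert_allclose(out.intensity, [0.0, 1.0, 3.0])

    def test_preserves_order(self, rng):
        x = rng.uniform(0, 1e5, 64)
        out = log_transform(self._spec(x)).intensity
        assert np.all(np.diff(out[np.argsort(x)]) >= 0)

    def test_double_transform_rejected(self):
        with pytest.raises(ValueError, match="already"):
            log_transform(log_transform(self._spec([1, 2])))


class TestDenoise:
    def test_two_peak_worked_example(self):
        # 10 points, 5-point window, keep 20% -> 1 point per window.
        x = np.array([5, 1, 1, 1, 1, 9, 1, 1, 1, 1], float)
        out = denoise_intensities(x, 1.0, DenoiseParams(5, 0.2, 1))
        np.testing.assert_array_equal(out, [5, 0, 0, 0, 0, 9, 0, 0, 0, 0])

    def test_all_zero_stays_zero(self):
        out = denoise_intensities(np.zeros(50), 1.0, DenoiseParams(10, 0.2))
        assert not out.any()

    def test_constant_spectrum_matches_oracle_and_is_reproducible(self):
        x = np.full(30, 3.5)
        p = DenoiseParams(10, 0.2)
        out1 = denoise_intensities(x, 1.0, p)
        out2 = denoise_intensities(x, 1.0, p)
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_array_equal(out1, naive_denoise(x, 10, 0.2))

    @pytest.mark.parametrize("rule", ["union", "per_window"])
    def test_oracle_equivalence_random_spectra(self, rng, rule):
        for _ in range(40):
            n = int(rng.integers(20, 120))
            w = int(rng.integers(2, min(n, 30)))
            keep = float(rng.uniform(0.05, 1.0))
            step = int(rng.integers(1, min(w, 3) + 1))
            x = random_gridded(rng, n)
            p = DenoiseParams(float(w), keep, float(step), combine_rule=rule)
            got = denoise_intensities(x, 1.0, p)
            want = naive_denoise(x, w, keep, step, rule)
            np.testing.assert_array_equal(got, want)

    def test_output_support_subset_of_input(self, rng):
        for _ in range(20):
            x = random_gridded(rng, 80)
            out = denoise_intensities(x, 1.0, DenoiseParams(20, 0.2))
            assert set(np.flatnonzero(out)) <= set(np.flatnonzero(x))

    def test_per_window_marking_cap(self, rng):
        # Each window's own marking keeps at most ceil(keep * w) points.
        x = random_gridded(rng, 60)
        w, keep = 15, 0.2
        k = math.ceil(keep * w)
        for s in range(0, 60 - w + 1):
            ranked = sorted(range(s, s + w), key=lambda i: (-x[i], i))[:k]
            assert len(ranked) == k

    def test_monotone_transform_leaves_support_unchanged(self, rng):
        x = random_gridded(rng, 100)
        p = DenoiseParams(20, 0.2)
        base = np.flatnonzero(denoise_intensities(x, 1.0, p))
        squashed = np.flatnonzero(denoise_intensities(np.log1p(x), 1.0, p))
        np.testing.assert_array_equal(base, squashed)

    def test_window_larger_than_grid_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            denoise_intensities(np.ones(5), 1.0, DenoiseParams(10, 0.2))

    def test_bad_keep_fraction_rejected(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            DenoiseParams(10, 0.0)

    def test_clamped_final_window_covers_tail(self):
        # 11 points, window 4, step 3: starts 0,3,6 then clamped 7.
        x = np.zeros(11)
        x[10] = 9.0
        out = denoise_intensities(x, 1.0, DenoiseParams(4.0, 0.25, 3.0))
        assert out[10] == 9.0


class TestPipeline:
    def _raw(self, rng):
        mz = np.unique(np.round(rng.uniform(2000, 2200, 40), 1))
        return RawSpectrum(mz, rng.lognormal(4, 1, mz.size))

    GRID = GridSpec(2000, 2200, 1)
    PARAMS = DenoiseParams(20, 0.2)

    def test_default_order_is_composition(self, rng):
        raw = self._raw(rng)
        got = preprocess_pipeline(raw, self.GRID, self.PARAMS)
        want = denoise(log_transform(resample_to_grid(raw, self.GRID)), self.PARAMS)
        np.testing.assert_allclose(got.intensity, want.intensity)
        assert got.resampled and got.log_transformed and got.denoised

    def test_retained_support_identical_under_both_orders(self, rng):
        for _ in range(25):
            raw = self._raw(rng)
            a = preprocess_pipeline(raw, self.GRID, self.PARAMS, "log_then_denoise")
            b = preprocess_pipeline(raw, self.GRID, self.PARAMS, "denoise_then_log")
            np.testing.assert_array_equal(a.support, b.support)

    def test_empty_raw_errors(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_pipeline(RawSpectrum([], []), self.GRID, self.PARAMS)

    def test_transformer_matches_function_path(self, rng):
        raws = [self._raw(rng) for _ in range(3)]
        pre = SpectrumPreprocessor(start=2000, stop=2200, window_width=20)
        X = pre.fit_transform(raws)
        for row, raw in zip(X, raws):
            np.testing.assert_allclose(
                row, preprocess_pipeline(raw, self.GRID, self.PARAMS).intensity
            )
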