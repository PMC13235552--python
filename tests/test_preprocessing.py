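"""Resampling, baseline correction, normalization and smoothing contracts."""

import numpy as np
import pytest

from mpspec.preprocessing import (
    correct_baseline,
    iarpls_baseline,
    normalize_max,
    preprocess,
    resample,
    smooth_savgol,
)
from mpspec.synth import _gaussian
from mpspec.types import CanonicalSpectrum, RAMAN_GRID, Spectrum, ValidationError


def _canon(v, **kw):
    return CanonicalSpectrum(intensities=np.asarray(v, dtype=float), modality="raman", **kw)


class TestResample:
    def test_identity_on_exactly_gridded_input(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(size=1000)
        s = Spectrum(axis=RAMAN_GRID.copy(), intensities=y, modality="raman")
        c = resample(s)
        assert np.array_equal(c.intensities, y)  # bitwise-stable at knots
        assert c.padded_regions == []

    def test_uncovered_region_filled_from_class_mean(self):
        mask = RAMAN_GRID >= 500
        s = Spectrum(
            axis=RAMAN_GRID[mask], intensities=np.ones(mask.sum()), modality="raman"
        )
        c = resample(s, class_mean=np.full(1000, 0.5))
        below = RAMAN_GRID < 500
        assert np.all(c.intensities[below] == 0.5)
        assert np.all(c.intensities[~below] == 1.0)
        (lo, hi), = c.padded_regions
        assert lo == 0 and hi == below.sum()

    def test_self_mean_padding_warns(self):
        mask = RAMAN_GRID >= 500
        s = Spectrum(axis=RAMAN_GRID[mask], intensities=np.full(mask.sum(), 2.0), modality="raman")
        with pytest.warns(UserWarning):
            c = resample(s)
        assert np.all(c.intensities[RAMAN_GRID < 500] == 2.0)

    def test_no_overlap_with_grid_is_error(self):
        s = Spectrum(axis=[3500.0, 3600.0], intensities=[1.0, 2.0], modality="raman")
        with pytest.raises(ValidationError):
            resample(s)

    def test_linear_ramp_interpolates_exactly(self):
        # input at half the grid density; linear interpolation is exact on a ramp
        axis = np.linspace(200.0, 3200.0, 500)
        ramp = 0.1 + 0.3 * (axis - 200.0) / 3000.0
        s = Spectrum(axis=axis, intensities=ramp, modality="raman")
        expected = 0.1 + 0.3 * (RAMAN_GRID - 200.0) / 3000.0
        assert np.allclose(resample(s).intensities, expected, atol=1e-12)


class TestBaseline:
    def test_constant_spectrum_yields_flat_baseline(self):
        res = iarpls_baseline(np.full(1000, 5.0), lam=1e5)
        assert np.max(np.abs(res.corrected)) < 1e-6 * 5.0
        assert res.converged

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0.2, 1.0, 1000)
        res = iarpls_baseline(y, lam=1e5)
        assert np.allclose(res.baseline + res.corrected, y, atol=1e-9)
        assert res.iterations <= 50

    def test_recovers_linear_baseline_under_gaussian_peaks(self):
        g = RAMAN_GRID
        x = (g - g[0]) / (g[-1] - g[0])
        base = 0.3 + 0.4 * x
        sig = (
            _gaussian(g, 700, 12, 1.0)
            + _gaussian(g, 1400, 15, 0.7)
            + _gaussian(g, 2900, 20, 0.9)
        )
        y = base + sig + np.random.default_rng(0).normal(0, 0.01, 1000)
        res = iarpls_baseline(y, lam=1e5)
        rmse = float(np.sqrt(np.mean((res.baseline - base) ** 2)))
        assert rmse < 0.02 * (base.max() - base.min())
        for center, height in [(700, 1.0), (1400, 0.7), (2900, 0.9)]:
            i = int(np.argmin(np.abs(g - center)))
            got = res.corrected[i - 2 : i + 3].max()
            assert abs(got - height) < 0.05 * height

    def test_peak_positions_survive_fluorescence_hump(self):
        g = RAMAN_GRID
        base = 0.5 * np.exp(-0.5 * ((g - 1500) / 500) ** 2)
        centers = [600.5, 1200.2, 2500.8]
        y = base + sum(_gaussian(g, c, 10, 0.8) for c in centers)
        y = y + np.random.default_rng(2).normal(0, 0.005, 1000)
        res = iarpls_baseline(y, lam=1e5)
        for c in centers:
            i = int(np.argmin(np.abs(g - c)))
            j = int(np.argmax(res.corrected[i - 3 : i + 4])) + i - 3
            assert abs(j - i) <= 1

    def test_near_idempotent_on_corrected_spectra(self):
        g = RAMAN_GRID
        y = 0.3 + 0.4 * (g - g[0]) / 3000.0 + _gaussian(g, 1000, 12, 1.0)
        first = iarpls_baseline(y, lam=1e5)
        second = iarpls_baseline(first.corrected, lam=1e5)
        span = first.corrected.max() - first.corrected.min()
        assert np.max(np.abs(second.corrected - first.corrected)) < 0.01 * span

    def test_non_convergence_flagged_not_raised(self):
        y = _gaussian(RAMAN_GRID, 1000, 12, 1.0) + 0.5
        res = iarpls_baseline(y, lam=1e5, max_iter=1)
        assert res.iterations == 1
        assert not res.converged

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValidationError):
            iarpls_baseline(np.ones(1000), lam=0.0)


class TestNormalizeSmooth:
    def test_normalize_sets_max_to_exactly_one(self):
        v = np.zeros(1000)
        v[10], v[20] = 2.0, 4.0
        out = normalize_max(_canon(v))
        assert out.intensities.max() == 1.0
        assert out.normalized

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            normalize_max(_canon(np.zeros(1000)))

    def test_savgol_exact_on_low_order_polynomial(self):
        x = np.linspace(-1, 1, 1000)
        quad = 0.3 + 0.5 * x + 0.2 * x**2
        out = smooth_savgol(_canon(quad), window=11, polyorder=3)
        assert np.allclose(out.intensities, quad, atol=1e-9)

    def test_savgol_reduces_white_noise_variance(self):
        noise = np.random.default_rng(5).normal(0, 1.0, 1000)
        out = smooth_savgol(_canon(noise))
        assert out.intensities.var() < noise.var()

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (11, 11), (1, 0)])
    def test_invalid_savgol_parameters(self, window, polyorder):
        with pytest.raises(ValidationError):
            smooth_savgol(_canon(np.ones(1000)), window=window, polyorder=polyorder)


class TestPipelineOrder:
    def test_artifact_removal_runs_after_baseline_before_normalization(self):
        g = RAMAN_GRID
        y = 0.3 + _gaussian(g, 1000, 12, 2.0)
        s = Spectrum(axis=g.copy(), intensities=y, modality="raman")
        seen = {}

        def probe(c):
            seen["baseline_corrected"] = c.baseline_corrected
            seen["normalized"] = c.normalized
            seen["max"] = float(c.intensities.max())
            return c, {"probe": True}

        out, report = preprocess(s, artifact_remover=probe)
        assert seen["baseline_corrected"] and not seen["normalized"]
        assert report["artifacts"] == {"probe": True}
        assert out.smoothed  # smoothing is the final stage
        # normalize ran after the probe; smoothing attenuates a narrow band
        # but the maximum stays of order one and never exceeds it
        assert 0.5 < out.intensities.max() <= 1.0 + 1e-9

    def test_correct_baseline_sets_flag(self):
        s = _canon(0.5 + _gaussian(RAMAN_GRID, 900, 12, 1.0))
        out, res = correct_baseline(s)
        assert out.baseline_corrected
        assert res.lam == 1e5  # Raman default
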