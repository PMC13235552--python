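"""Cosmic-ray detection/correction and CO2 excision behaviour."""

import pickle

import numpy as np
import pytest

from mpspec.artifacts import (
    BROAD_FWHM,
    CO2Params,
    detect_rays_rule,
    extract_ray_features,
    remove_co2,
    remove_rays_hybrid,
    train_ray_classifier,
)
from mpspec.synth import (
    FTIR_PRESETS,
    RAMAN_PRESETS,
    _gaussian,
    generate_canonical_class,
    generate_ray_scenario,
    inject_co2,
)
from mpspec.types import CanonicalSpectrum, FTIR_GRID, RAMAN_GRID, ValidationError


def _canon(v, modality="raman", **kw):
    return CanonicalSpectrum(intensities=np.asarray(v, float), modality=modality, **kw)


def _hits(detections, centers, tol=2.0):
    return sum(
        1 for c in centers if any(abs(d.center_wavenumber - c) <= tol for d in detections)
    )


class TestRuleStage:
    def test_noise_only_spectrum_yields_no_detections(self):
        y = 0.3 + np.random.default_rng(0).normal(0, 0.01, 1000)
        assert detect_rays_rule(_canon(y, baseline_corrected=True)) == []

    def test_genuine_polymer_band_not_flagged(self):
        y = 0.1 + _gaussian(RAMAN_GRID, 1000.0, 10.0, 1.0)
        y = y + np.random.default_rng(1).normal(0, 0.005, 1000)
        assert detect_rays_rule(_canon(y, baseline_corrected=True)) == []

    def test_rule_stage_is_strict_subset_of_hybrid(self, ray_classifier):
        rule_total = hybrid_total = n_total = 0
        for k in range(10):
            spec = list(RAMAN_PRESETS.values())[k % 5]
            corrected, record = generate_ray_scenario(spec, 20, seed=40000 + k)
            rule = detect_rays_rule(corrected)
            _, detections = remove_rays_hybrid(corrected, ray_classifier)
            rule_total += _hits(rule, record.positions)
            hybrid_total += _hits(detections, record.positions)
            n_total += 20
        assert rule_total < hybrid_total <= n_total
        assert hybrid_total / n_total > 0.95

    def test_detections_carry_all_scores(self):
        corrected, _ = generate_ray_scenario(RAMAN_PRESETS["PVC"], 10, seed=3)
        for d in detect_rays_rule(corrected):
            assert d.stage == "rule"
            assert d.fwhm > 0 and d.amplitude_ratio > 1
            assert np.isfinite([d.sharpness, d.derivative_score, d.zscore]).all()

    def test_ftir_modality_rejected(self):
        with pytest.raises(ValidationError):
            detect_rays_rule(_canon(np.ones(1000), modality="ftir"))


class TestRayFeatures:
    def test_symmetric_triangular_spike_has_zero_asymmetry(self):
        y = np.full(1000, 0.1)
        y[499], y[500], y[501] = 0.3, 0.6, 0.3
        f = extract_ray_features(_canon(y), 500)
        assert abs(f.asymmetry) < 1e-9

    def test_subgrid_spike_width_estimated_within_one_grid_step(self):
        y = np.full(1000, 0.1) + _gaussian(RAMAN_GRID, RAMAN_GRID[500], 0.8, 1.5)
        f = extract_ray_features(_canon(y), 500)
        assert abs(f.fwhm - 0.8) <= 3.1  # one grid step of the Raman grid

    def test_features_are_deterministic(self):
        corrected, _ = generate_ray_scenario(RAMAN_PRESETS["PE"], 5, seed=9)
        a = extract_ray_features(corrected, 400).as_array()
        b = extract_ray_features(corrected, 400).as_array()
        assert np.array_equal(a, b)

    def test_edge_candidate_uses_one_sided_window_and_flags(self):
        y = np.full(1000, 0.2)
        y[3] = 1.5
        f = extract_ray_features(_canon(y), 3)
        assert f.edge
        assert np.isfinite(f.as_array()).all()


class TestRayClassifier:
    def test_cross_validated_f1_exceeds_095(self, ray_classifier):
        assert ray_classifier.cv_metrics["weighted_f1"] >= 0.95

    def test_width_feature_dominates_importances(self, ray_classifier):
        imp = ray_classifier.feature_importances
        others = {k: v for k, v in imp.items() if k not in ("fwhm", "second_derivative")}
        assert imp["fwhm"] > max(others.values())

    def test_single_class_training_rejected(self):
        x = np.random.default_rng(0).uniform(size=(10, 7))
        with pytest.raises(ValidationError):
            train_ray_classifier(x, np.ones(10), seed=0)

    def test_training_is_deterministic_under_fixed_seed(self, raman_specs):
        from mpspec.artifacts import build_ray_training_set

        x, y = build_ray_training_set(raman_specs[:2], n_scenarios_per_class=2, seed=3)
        a = train_ray_classifier(x, y, model="gb", seed=5)
        b = train_ray_classifier(x, y, model="gb", seed=5)
        assert a.cv_metrics == b.cv_metrics

    def test_rf_alternative_trains(self, raman_specs):
        from mpspec.artifacts import build_ray_training_set

        x, y = build_ray_training_set(raman_specs[:2], n_scenarios_per_class=2, seed=3)
        clf = train_ray_classifier(x, y, model="rf", seed=0)
        assert clf.cv_metrics["weighted_f1"] > 0.9

    def test_model_pickles(self, ray_classifier):
        blob = pickle.dumps(ray_classifier)
        back = pickle.loads(blob)
        probe = np.array([[1.0, 0.3, 0.0, 8.0, 40.0, 0.5, 50.0]])
        assert np.array_equal(back.predict(probe), ray_classifier.predict(probe))


class TestHybridRemoval:
    def test_clean_spectrum_returned_bit_identical(self, ray_classifier):
        y = 0.3 + np.random.default_rng(4).normal(0, 0.01, 1000)
        s = _canon(y, baseline_corrected=True)
        out, detections = remove_rays_hybrid(s, ray_classifier)
        assert detections == []
        assert np.array_equal(out.intensities, y)

    def test_correction_is_local_to_detection_supports(self, ray_classifier):
        corrected, _ = generate_ray_scenario(RAMAN_PRESETS["PS"], 15, seed=77)
        out, detections = remove_rays_hybrid(corrected, ray_classifier)
        assert detections
        touched = np.zeros(1000, dtype=bool)
        for d in detections:
            touched[d.support[0] : d.support[1]] = True
        assert np.array_equal(out.intensities[~touched], corrected.intensities[~touched])

    def test_corrected_regions_approach_preinjection_truth(self, ray_classifier):
        """Rays away from genuine bands restore to within 5% of the peak
        scale; a ray that hides part of a band is harder, so only the median
        is constrained over all detections."""
        errors, isolated_errors = [], []
        for k in range(5):
            spec = list(RAMAN_PRESETS.values())[k]
            corrected, record = generate_ray_scenario(spec, 20, seed=88 + k)
            out, detections = remove_rays_hybrid(corrected, ray_classifier)
            scale = record.clean.max()
            for d in detections:
                lo, hi = d.support
                err = np.max(np.abs(out.intensities[lo:hi] - record.clean[lo:hi])) / scale
                errors.append(err)
                matched = [
                    c for c in record.positions if abs(d.center_wavenumber - c) <= 2.0
                ]
                if matched and all(
                    abs(matched[0] - bc) > 2.0 * bw
                    for bc, bw in zip(spec.centers, spec.widths)
                ):
                    isolated_errors.append(err)
        assert isolated_errors and max(isolated_errors) < 0.05
        assert np.median(errors) < 0.05

    def test_pchip_bridge_bounded_by_flank_extrema(self):
        """The bridge never rings beyond the extrema of its anchoring knots
        (shape preservation of the monotone interpolant)."""
        from mpspec.artifacts import _pchip_bridge

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0.0, 1.0, 60)
            lo, hi = 28, 31
            bridge = _pchip_bridge(y, lo, hi)
            knots = np.r_[y[lo - 5 : lo], y[hi + 1 : hi + 6]]
            assert bridge.max() <= knots.max() + 1e-9
            assert bridge.min() >= knots.min() - 1e-9

    def test_stage_union_has_no_double_counting(self, ray_classifier):
        corrected, _ = generate_ray_scenario(RAMAN_PRESETS["PP"], 20, seed=111)
        _, detections = remove_rays_hybrid(corrected, ray_classifier)
        indices = [d.center_index for d in detections]
        assert len(indices) == len(set(indices))
        assert {d.stage for d in detections} <= {"rule", "ml"}
        for d in detections:
            if d.stage == "ml":
                assert d.fwhm < BROAD_FWHM


class TestCO2Removal:
    def test_nothing_to_remove_is_near_identity(self):
        clean = generate_canonical_class(FTIR_PRESETS["PE"], 1, seed=5, clean=True)[0]
        out, _ = remove_co2(clean)
        assert np.max(np.abs(out.intensities - clean.intensities)) < 1e-6

    def test_doublet_removed_at_both_band_centers(self):
        clean = generate_canonical_class(FTIR_PRESETS["PET"], 1, seed=6)[0]
        injected, record = inject_co2(clean, seed=7)
        out, report = remove_co2(injected)
        for center in (2288, 2392):
            ic = int(np.argmin(np.abs(FTIR_GRID - center)))
            added = injected.intensities[ic] - record.clean[ic]
            residual = out.intensities[ic] - record.clean[ic]
            assert abs(residual) / added < 0.05
        assert report["reduction_at_2288"] > 0.3  # observable drop at the centre

    def test_adjacent_nitrile_band_preserved(self):
        clean = generate_canonical_class(FTIR_PRESETS["ABS"], 1, seed=8)[0]
        injected, _ = inject_co2(clean, seed=9)
        out, _ = remove_co2(injected)
        window = np.abs(FTIR_GRID - 2240.0) <= 15.0
        before = clean.intensities[window].max()
        after = out.intensities[window].max()
        assert abs(after - before) / before < 0.05

    def test_identity_outside_region_plus_buffer(self):
        clean = generate_canonical_class(FTIR_PRESETS["PS"], 1, seed=10)[0]
        injected, _ = inject_co2(clean, seed=11)
        out, report = remove_co2(injected)
        i0, i1 = report["region_indices"]
        b = report["buffer"]
        outside = np.ones(1000, dtype=bool)
        outside[i0 - b : i1 + b + 1] = False
        assert np.array_equal(out.intensities[outside], injected.intensities[outside])

    def test_raman_modality_rejected(self):
        with pytest.raises(ValidationError):
            remove_co2(_canon(np.ones(1000), modality="raman"))

    def test_region_outside_grid_rejected(self):
        clean = generate_canonical_class(FTIR_PRESETS["PE"], 1, seed=5, clean=True)[0]
        with pytest.raises(ValidationError):
            remove_co2(clean, CO2Params(region=(100.0, 2392.0)))

    def test_smoothing_factor_bounds_enforced(self):
        with pytest.raises(ValidationError):
            CO2Params(smoothing_factor=1.5)
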