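"""Three-tier out-of-distribution filter: closed forms, tiering, safety."""

import numpy as np
import pytest

from mpspec.classification import DRNConfig, train_ensemble
from mpspec.ood import (
    ClassStats,
    DEFAULT_TAUS,
    DisambiguationModel,
    TierDecision,
    build_mixture_classes,
    disambiguate,
    pcc_screen,
    predictive_entropy,
    tier,
    train_tier_model,
    uncertainty_features,
)
from mpspec.synth import (
    NONPOLYMER_PRESETS,
    RAMAN_PRESETS,
    generate_canonical_class,
    generate_library,
)
from mpspec.types import SpectralLibrary, ValidationError


class TestClosedForms:
    def test_uniform_softmax_entropy_is_log_k(self):
        assert predictive_entropy(np.full(10, 0.1)) == pytest.approx(np.log(10), abs=1e-9)

    def test_one_hot_softmax_entropy_is_zero(self):
        p = np.zeros(10)
        p[3] = 1.0
        assert predictive_entropy(p) == pytest.approx(0.0, abs=1e-9)

    def test_mahalanobis_zero_at_class_mean(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(60, 4))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        stats = ClassStats.fit(emb, labels)
        assert stats.distance(stats.means["a"], "a") == pytest.approx(0.0, abs=1e-9)
        assert stats.distance(stats.means["a"] + 5.0, "a") > 1.0

    def test_singular_covariance_is_ridge_regularized(self):
        emb = np.zeros((20, 3))  # zero-variance embeddings
        labels = np.array(["a"] * 10 + ["b"] * 10)
        stats = ClassStats.fit(emb, labels)
        assert np.isfinite(stats.precision).all()
        assert stats.ridge > 0

    def test_entropy_margin_antitone_on_two_class_softmaxes(self):
        margins = np.linspace(0.0, 0.98, 25)
        entropies = [predictive_entropy([(1 + m) / 2, (1 - m) / 2]) for m in margins]
        assert all(a > b for a, b in zip(entropies, entropies[1:]))


class TestScreen:
    def test_identical_nonpolymer_fails_screen_with_r_one(self, nonpolymer_library):
        label, spectrum = nonpolymer_library.entries[0]
        passed, best = pcc_screen(spectrum, nonpolymer_library)
        assert not passed
        assert best[1] == pytest.approx(1.0)

    def test_decorrelated_query_passes(self, nonpolymer_library):
        rng = np.random.default_rng(3)
        from mpspec.types import CanonicalSpectrum

        noise = CanonicalSpectrum(intensities=rng.normal(0.5, 0.1, 1000), modality="raman")
        passed, _ = pcc_screen(noise, nonpolymer_library)
        assert passed

    def test_threshold_one_always_passes_non_identical_input(self, nonpolymer_library):
        _, spectrum = nonpolymer_library.entries[0]
        from mpspec.types import CanonicalSpectrum

        tweaked = CanonicalSpectrum(
            intensities=spectrum.intensities + np.linspace(0, 0.2, 1000),
            modality="raman",
        )
        passed, _ = pcc_screen(tweaked, nonpolymer_library, r_threshold=1.0)
        assert passed

    def test_empty_library_disables_screen_with_warning(self, raman_library):
        _, spectrum = raman_library.entries[0]
        with pytest.warns(UserWarning):
            passed, best = pcc_screen(spectrum, SpectralLibrary("raman"))
        assert passed and best is None


class _FixedScore:
    def __init__(self, value):
        self.value = value

    def score(self, features):
        return self.value


class TestTiering:
    @pytest.mark.parametrize(
        "score,modality,expected",
        [
            (0.05, "raman", "reject"),
            (0.95, "raman", "accept"),
            (0.50, "raman", "verify"),
            (0.50, "ftir", "verify"),
            (0.40, "ftir", "reject"),
            (0.75, "ftir", "accept"),
        ],
    )
    def test_printed_dual_thresholds(self, score, modality, expected):
        decision = tier(None, _FixedScore(score), modality=modality)
        assert decision.tier == expected
        assert (decision.tau_low, decision.tau_high) == DEFAULT_TAUS[modality]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            tier(None, _FixedScore(0.5), tau_low=0.9, tau_high=0.1)

    def test_failed_screen_short_circuits_to_reject(self):
        decision = tier(None, _FixedScore(0.99), screen_result=(False, ("quartz", 0.97)))
        assert decision.tier == "reject"
        assert decision.screen_failed
        assert decision.screen_match == ("quartz", 0.97)

    def test_raising_tau_high_never_creates_accepts(self):
        scores = np.linspace(0, 1, 21)
        for lo, hi, hi2 in [(0.1, 0.6, 0.9), (0.45, 0.7, 0.95)]:
            before = [tier(None, _FixedScore(s), tau_low=lo, tau_high=hi).tier for s in scores]
            after = [tier(None, _FixedScore(s), tau_low=lo, tau_high=hi2).tier for s in scores]
            for b, a in zip(before, after):
                if b != "accept":
                    assert a != "accept"

    def test_tier_decision_invariant_enforced(self):
        with pytest.raises(ValidationError):
            TierDecision(tier="maybe", score=0.5, tau_low=0.1, tau_high=0.9)


class TestUncertaintyPipeline:
    @pytest.fixture(scope="class")
    def tier_setup(self, toy_ensemble, toy_class_stats, raman_specs):
        id_hold = [
            s.intensities
            for i, spec in enumerate(raman_specs)
            for s in generate_canonical_class(spec, 10, 900 + i)
        ]
        ood_specs = list(NONPOLYMER_PRESETS.values())
        # tier model trained on the fatty-acid confounders; evaluated on the
        # well-separated mineral/biopolymer classes
        train_x = [
            s.intensities
            for spec in ood_specs[2:]
            for s in generate_canonical_class(spec, 25, 71)
        ]
        eval_x = [
            s.intensities
            for spec in ood_specs[:2]
            for s in generate_canonical_class(spec, 25, 72)
        ]
        feat = lambda vs: np.array(  # noqa: E731
            [uncertainty_features(toy_ensemble, v, toy_class_stats).as_array() for v in vs]
        )
        f_id, f_tr, f_ev = feat(id_hold), feat(train_x), feat(eval_x)
        return train_tier_model(f_id, f_tr, seed=0), f_id, f_ev

    def test_feature_ranges(self, toy_ensemble, toy_class_stats, toy_dataset):
        x, _ = toy_dataset
        f = uncertainty_features(toy_ensemble, x[0], toy_class_stats)
        assert 0.0 <= f.entropy <= np.log(len(toy_ensemble.classes)) + 1e-9
        assert f.min_mahalanobis >= 0.0
        assert 0.0 <= f.top2_margin <= 1.0
        assert min(f.mahalanobis.values()) == f.min_mahalanobis

    def test_no_ood_reaches_accept_tier_at_raman_defaults(self, tier_setup):
        rf, _, f_eval = tier_setup
        tiers = [tier(f, rf, modality="raman").tier for f in f_eval]
        assert "accept" not in tiers

    def test_most_id_spectra_accepted(self, tier_setup):
        rf, f_id, _ = tier_setup
        tiers = [tier(f, rf, modality="raman").tier for f in f_id]
        assert tiers.count("accept") / len(tiers) >= 0.8
        assert "reject" not in tiers or tiers.count("reject") / len(tiers) < 0.1


class TestDisambiguation:
    @pytest.fixture(scope="class")
    def disambiguation_model(self):
        pe = [
            s.intensities
            for s in generate_canonical_class(RAMAN_PRESETS["PE"], 25, 5)
        ]
        stearic = [
            s.intensities
            for s in generate_canonical_class(NONPOLYMER_PRESETS["stearic_acid"], 25, 6)
        ]
        x_mix, labels, ratio_map = build_mixture_classes(
            pe, stearic, "PE", "stearic_acid", ratios=(0.9, 0.5, 0.1), n_per_class=25, seed=0
        )
        x = np.vstack([np.array(pe), np.array(stearic), x_mix])
        y = ["PE"] * 25 + ["stearic_acid"] * 25 + labels
        cfg = DRNConfig(
            n_classes=5, channels=(6, 12), se_reduction=2, stem_stride=4, pool=4,
            epochs=30, folds=2,
        )
        ensemble = train_ensemble(x, y, cfg, seed=1)
        return DisambiguationModel(ensemble=ensemble, mixture_ratios=ratio_map)

    def test_untriggered_label_passes_through(self, disambiguation_model):
        out = disambiguate(np.ones(1000), disambiguation_model, primary_label="PP")
        assert out == {"label": "PP", "triggered": False, "proportions": None}

    def test_pure_confounder_not_assigned_polymer_label(self, disambiguation_model):
        hits = 0
        for s in generate_canonical_class(NONPOLYMER_PRESETS["stearic_acid"], 10, 777):
            out = disambiguate(s.intensities, disambiguation_model, primary_label="PE")
            assert out["triggered"]
            if out["label"] != "PE":
                hits += 1
        assert hits >= 8

    def test_mixture_prediction_reports_proportions(self, disambiguation_model):
        pe = generate_canonical_class(RAMAN_PRESETS["PE"], 1, 12)[0].intensities
        st = generate_canonical_class(NONPOLYMER_PRESETS["stearic_acid"], 1, 13)[0].intensities
        v = 0.9 * pe + 0.1 * st
        out = disambiguate(v / v.max(), disambiguation_model, primary_label="PE")
        if out["proportions"] is not None:
            assert out["proportions"][0] + out["proportions"][1] == pytest.approx(1.0)

    def test_identical_twin_classes_share_the_confusion(self):
        """Two classes built from identical spectra (r = 1) split the softmax
        mass between exactly themselves."""
        base = generate_canonical_class(RAMAN_PRESETS["PS"], 30, 21)
        other = generate_canonical_class(RAMAN_PRESETS["PVC"], 30, 22)
        x = np.array([s.intensities for s in base] * 2 + [s.intensities for s in other])
        y = ["twin_a"] * 30 + ["twin_b"] * 30 + ["PVC"] * 30
        cfg = DRNConfig(
            n_classes=3, channels=(6, 12), se_reduction=2, stem_stride=4, pool=4,
            epochs=40, folds=2,
        )
        ensemble = train_ensemble(x, y, cfg, seed=3)
        proba = ensemble.predict_proba(x[:30])
        twin_mass = proba[:, ensemble.classes.index("twin_a")] + proba[
            :, ensemble.classes.index("twin_b")
        ]
        assert twin_mass.mean() > 0.9
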