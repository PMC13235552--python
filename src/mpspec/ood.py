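"""Three-tier out-of-distribution (OOD) handling.

Stage 1: PCC screening against a non-polymer reference library — a query
matching a non-polymer entry above the screening threshold is rejected
immediately with the matched identity.

Stage 2: a random forest trained on ensemble uncertainty features (max
softmax, predictive entropy, per-class Mahalanobis distances in the
penultimate embedding space, fold disagreement, top-2 margin) produces an
acceptance score in [0, 1]; dual thresholds split the score range into
Reject (< tau_low), Verify (in between, queued for human review) and Accept
(> tau_high). Defaults: Raman (0.10, 0.90), FTIR (0.45, 0.70).

Stage 3: for predictions in a confusable trigger set (by default PE, which
overlaps spectrally with fatty-acid slip additives), a dedicated classifier
over {target polymer, confounder standards, graded mixtures} refines the
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .classification import DRNEnsemble, pcc_match
from .types import CanonicalSpectrum, SpectralLibrary, ValidationError

DEFAULT_TAUS = {"raman": (0.10, 0.90), "ftir": (0.45, 0.70)}
DEFAULT_PCC_SCREEN_THRESHOLD = 0.90

UNCERTAINTY_FEATURE_NAMES = (
    "max_softmax",
    "entropy",
    "min_mahalanobis",
    "fold_disagreement",
    "top2_margin",
)


@dataclass
class UncertaintyFeatures:
    """Ensemble uncertainty summary for one spectrum."""

    max_softmax: float
    entropy: float  # nats, in [0, ln K]
    mahalanobis: dict[str, float]
    min_mahalanobis: float
    fold_disagreement: float  # sd over folds of each fold's top-class confidence
    top2_margin: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.max_softmax,
                self.entropy,
                self.min_mahalanobis,
                self.fold_disagreement,
                self.top2_margin,
            ]
        )


@dataclass
class TierDecision:
    """Accept / Verify / Reject outcome with its provenance."""

    tier: str
    score: float
    tau_low: float
    tau_high: float
    screen_failed: bool = False
    screen_match: tuple[str, float] | None = None
    disambiguation: dict | None = None

    def __post_init__(self) -> None:
        if self.tau_low > self.tau_high:
            raise ValidationError("tau_low must not exceed tau_high")
        if self.tier not in ("accept", "verify", "reject"):
            raise ValidationError(f"unknown tier {self.tier!r}")


def predictive_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in nats."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, None)
    return float(-(p * np.log(p)).sum())


@dataclass
class ClassStats:
    """Per-class embedding means and a shared ridge-regularized covariance."""

    means: dict[str, np.ndarray]
    precision: np.ndarray
    ridge: float

    @classmethod
    def fit(
        cls, embeddings: np.ndarray, labels: np.ndarray, ridge_scale: float = 1e-3
    ) -> "ClassStats":
        labels = np.asarray(labels)
        means = {str(c): embeddings[labels == c].mean(axis=0) for c in np.unique(labels)}
        centered = np.vstack(
            [embeddings[labels == c] - means[str(c)] for c in np.unique(labels)]
        )
        cov = np.cov(centered, rowvar=False)
        cov = np.atleast_2d(cov)
        ridge = max(ridge_scale * np.trace(cov) / cov.shape[0], 1e-9)
        cov_r = cov + ridge * np.eye(cov.shape[0])
        return cls(means=means, precision=np.linalg.inv(cov_r), ridge=float(ridge))

    def distance(self, embedding: np.ndarray, label: str) -> float:
        d = embedding - self.means[label]
        return float(np.sqrt(max(d @ self.precision @ d, 0.0)))


def pcc_screen(
    s: CanonicalSpectrum,
    nonpolymer_library: SpectralLibrary | None,
    r_threshold: float = DEFAULT_PCC_SCREEN_THRESHOLD,
) -> tuple[bool, tuple[str, float] | None]:
    """Stage-1 screen. Returns (passed, best non-polymer match).

    Fails (-> immediate reject) when the best non-polymer correlation is at
    or above ``r_threshold``. An empty/absent library disables the screen
    with a warning.
    """
    if nonpolymer_library is None or len(nonpolymer_library) == 0:
        import warnings

        warnings.warn("non-polymer library empty; PCC screen disabled", stacklevel=2)
        return True, None
    match = pcc_match(s, nonpolymer_library)
    best = (match.top_label, match.top_r)
    return match.top_r < r_threshold, best


def uncertainty_features(
    ensemble: DRNEnsemble, s: CanonicalSpectrum | np.ndarray, class_stats: ClassStats
) -> UncertaintyFeatures:
    """Stage-2 feature extraction from the trained ensemble."""
    v = s.intensities if isinstance(s, CanonicalSpectrum) else np.asarray(s, dtype=float)
    x = v[None, :]
    fold = ensemble.fold_proba(x)[:, 0, :]  # (folds, classes)
    mean = fold.mean(axis=0)
    order = np.sort(mean)[::-1]
    emb = ensemble.embed(x)[0]
    maha = {label: class_stats.distance(emb, label) for label in class_stats.means}
    return UncertaintyFeatures(
        max_softmax=float(mean.max()),
        entropy=predictive_entropy(mean),
        mahalanobis=maha,
        min_mahalanobis=float(min(maha.values())),
        fold_disagreement=float(fold.max(axis=1).std()),
        top2_margin=float(order[0] - order[1]) if len(order) > 1 else float(order[0]),
    )


@dataclass
class TierModel:
    """Stage-2 random forest over uncertainty features."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...] = UNCERTAINTY_FEATURE_NAMES

    def score(self, features: UncertaintyFeatures | np.ndarray) -> float:
        """Probability that the spectrum is in-distribution."""
        arr = features.as_array() if isinstance(features, UncertaintyFeatures) else features
        proba = self.forest.predict_proba(np.atleast_2d(arr))[0]
        id_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
        return float(proba[id_col])


def train_tier_model(
    id_features: np.ndarray, ood_features: np.ndarray, seed: int = 0
) -> TierModel:
    """Fit the acceptance forest on labelled ID (1) vs OOD (0) features.

    The two classes are balanced 1:1 by downsampling the larger side.
    """
    rng = np.random.default_rng(seed)
    n = min(len(id_features), len(ood_features))
    if n == 0:
        raise ValidationError("need both ID and OOD examples")
    idx_id = rng.choice(len(id_features), n, replace=False)
    idx_ood = rng.choice(len(ood_features), n, replace=False)
    x = np.vstack([id_features[idx_id], ood_features[idx_ood]])
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    forest = RandomForestClassifier(n_estimators=200, random_state=seed).fit(x, y)
    return TierModel(forest=forest)


def tier(
    features: UncertaintyFeatures | np.ndarray,
    rf_model: TierModel,
    tau_low: float | None = None,
    tau_high: float | None = None,
    modality: str = "raman",
    screen_result: tuple[bool, tuple[str, float] | None] = (True, None),
) -> TierDecision:
    """Stage-2 tiering. score < tau_low -> reject; > tau_high -> accept;
    otherwise verify. A failed stage-1 screen rejects outright."""
    defaults = DEFAULT_TAUS[modality]
    tau_low = defaults[0] if tau_low is None else tau_low
    tau_high = defaults[1] if tau_high is None else tau_high
    if tau_low > tau_high:
        raise ValidationError("tau_low must not exceed tau_high")
    passed, best = screen_result
    if not passed:
        return TierDecision(
            tier="reject",
            score=0.0,
            tau_low=tau_low,
            tau_high=tau_high,
            screen_failed=True,
            screen_match=best,
        )
    score = rf_model.score(features)
    if score < tau_low:
        t = "reject"
    elif score > tau_high:
        t = "accept"
    else:
        t = "verify"
    return TierDecision(tier=t, score=score, tau_low=tau_low, tau_high=tau_high)


# ---------------------------------------------------------------------------
# Stage 3: disambiguation of confusable classes
# ---------------------------------------------------------------------------


@dataclass
class DisambiguationModel:
    """Classifier over {target polymer, confounders, graded mixtures}."""

    ensemble: DRNEnsemble
    trigger_labels: tuple[str, ...] = ("PE",)
    mixture_ratios: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_mixture_classes(
    pure_a: list[np.ndarray],
    pure_b: list[np.ndarray],
    label_a: str,
    label_b: str,
    ratios: tuple[float, ...] = (0.9, 0.7, 0.5, 0.3, 0.1),
    n_per_class: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], dict[str, tuple[float, float]]]:
    """Synthetic graded-mixture classes as convex combinations of two pools.

    Ratio ``r`` yields class ``mix_{label_a}_{int(100 r)}`` = r * a + (1-r) * b
    from randomly paired pool members. Returns (X, labels, ratio map).
    """
    rng = np.random.default_rng(seed)
    xs: list[np.ndarray] = []
    labels: list[str] = []
    ratio_map: dict[str, tuple[float, float]] = {
        label_a: (1.0, 0.0),
        label_b: (0.0, 1.0),
    }
    for r in ratios:
        name = f"mix_{label_a}_{int(round(100 * r))}"
        ratio_map[name] = (float(r), float(1.0 - r))
        for _ in range(n_per_class):
            a = pure_a[rng.integers(0, len(pure_a))]
            b = pure_b[rng.integers(0, len(pure_b))]
            v = r * a + (1.0 - r) * b
            xs.append(v / v.max())
            labels.append(name)
    return np.array(xs), labels, ratio_map


def disambiguate(
    s: CanonicalSpectrum | np.ndarray,
    model: DisambiguationModel,
    primary_label: str,
    trigger_labels: tuple[str, ...] | None = None,
) -> dict:
    """Stage-3 refinement. Untriggered primary labels pass through unchanged."""
    triggers = trigger_labels if trigger_labels is not None else model.trigger_labels
    if primary_label not in triggers:
        return {"label": primary_label, "triggered": False, "proportions": None}
    from .classification import predict as drn_predict

    pred = drn_predict(model.ensemble, s)
    proportions = model.mixture_ratios.get(pred.label)
    return {
        "label": pred.label,
        "triggered": True,
        "confidence": pred.confidence,
        "proportions": proportions,
        "softmax": dict(zip(model.ensemble.classes, pred.softmax.tolist())),
    }
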