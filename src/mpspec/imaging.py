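"""Semisupervised substrate masking for spectral images (SSEM).

A random forest trained on per-pixel features (principal-component scores of
the pixel spectra, peak intensity, variance, skewness, normalized spatial
coordinates) is combined with PCA-informed K-means clustering. Per pixel the
two stages are fused by weighted confidence scoring: a pixel is labelled
substrate when ``w_rf * P_rf(substrate) + w_cluster * 1[cluster=substrate]``
exceeds 0.5. The cluster whose centroid has the lower mean peak intensity is
taken as substrate (substrates are spectrally flat); this mapping is
overridable. Masking never mutates the spectra — only labels and confidences
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import skew
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .types import SpectralImage, ValidationError

DEFAULT_WEIGHTS = (0.7, 0.3)
SPATIAL_FEATURES = ("x_norm", "y_norm")


@dataclass
class SSEMConfig:
    n_components: int = 10
    k: int = 2
    n_estimators: int = 200
    cv_folds: int = 10
    use_spatial: bool = True


@dataclass
class MaskResult:
    """Per-pixel labels, confidences and particle-region accounting."""

    mask: np.ndarray  # (h, w) of {"substrate", "particle"}
    confidence: np.ndarray  # (h, w) in [0, 1]
    substrate_fraction: float
    regions: list[dict] = field(default_factory=list)  # pixel count + bbox per region


def pixel_features(
    image: SpectralImage, config: SSEMConfig | None = None
) -> tuple[np.ndarray, PCA]:
    """Per-pixel feature matrix from the image's own fitted PCA.

    Columns: ``n_components`` PC scores, peak intensity, variance, skewness,
    then normalized (x, y) if spatial features are enabled. PCA component
    signs are fixed deterministically (largest-magnitude loading positive).
    """
    config = config or SSEMConfig()
    flat = image.pixel_spectra()
    n_comp = min(config.n_components, flat.shape[1], max(flat.shape[0] - 1, 1))
    pca = PCA(n_components=n_comp, random_state=0).fit(flat)
    # deterministic sign convention
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
    scores = pca.transform(flat)
    stats = np.column_stack([flat.max(axis=1), flat.var(axis=1), skew(flat, axis=1)])
    cols = [scores, stats]
    if config.use_spatial:
        yy, xx = np.meshgrid(
            np.arange(image.height), np.arange(image.width), indexing="ij"
        )
        cols.append(
            np.column_stack(
                [
                    xx.ravel() / max(image.width - 1, 1),
                    yy.ravel() / max(image.height - 1, 1),
                ]
            )
        )
    return np.column_stack(cols), pca


def _feature_names(config: SSEMConfig, n_comp: int) -> list[str]:
    names = [f"pc{i + 1}" for i in range(n_comp)] + ["peak_intensity", "variance", "skewness"]
    if config.use_spatial:
        names += list(SPATIAL_FEATURES)
    return names


@dataclass
class SSEMModel:
    forest: RandomForestClassifier
    config: SSEMConfig
    classes: np.ndarray
    cv_report: dict
    feature_names: list[str]

    @property
    def importance_split(self) -> dict[str, float]:
        """Feature-importance mass split into spectral vs spatial groups."""
        imp = self.forest.feature_importances_
        spatial = sum(
            v for n, v in zip(self.feature_names, imp) if n in SPATIAL_FEATURES
        )
        return {"spectral": float(imp.sum() - spatial), "spatial": float(spatial)}


def fit_ssem(
    images: list[tuple[SpectralImage, np.ndarray]],
    config: SSEMConfig | None = None,
    seed: int = 0,
) -> SSEMModel:
    """Fit the ensemble on labelled training images.

    ``images`` is a list of (image, label array) pairs where labels are
    "substrate"/"particle" per pixel. Reports stratified k-fold CV accuracy,
    precision and recall over the pooled labelled pixels.
    """
    config = config or SSEMConfig()
    feats, labs = [], []
    for image, labels in images:
        f, _ = pixel_features(image, config)
        feats.append(f)
        labs.append(np.asarray(labels, dtype=object).ravel())
    x = np.vstack(feats)
    y = (np.concatenate(labs) == "particle").astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training images must contain both substrate and particle pixels")
    folds = min(config.cv_folds, np.bincount(y).min())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, precs, recs = [], [], []
    for tr, te in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed)
        clf.fit(x[tr], y[tr])
        p = clf.predict(x[te])
        accs.append(accuracy_score(y[te], p))
        precs.append(precision_score(y[te], p, zero_division=0))
        recs.append(recall_score(y[te], p, zero_division=0))
    forest = RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed)
    forest.fit(x, y)
    n_comp = x.shape[1] - 3 - (2 if config.use_spatial else 0)
    return SSEMModel(
        forest=forest,
        config=config,
        classes=np.array(["substrate", "particle"]),
        cv_report={
            "folds": folds,
            "accuracy": float(np.mean(accs)),
            "accuracy_sd": float(np.std(accs)),
            "precision": float(np.mean(precs)),
            "recall": float(np.mean(recs)),
        },
        feature_names=_feature_names(config, n_comp),
    )


def mask_image(
    image: SpectralImage,
    ssem: SSEMModel,
    confidence_weights: tuple[float, float] = DEFAULT_WEIGHTS,
    seed: int = 0,
) -> MaskResult:
    """Label every pixel substrate/particle by the weighted two-stage vote.

    The input image's cube is never modified; the returned mask/confidence
    are also written onto ``image.mask`` and ``image.confidence``.
    """
    w_rf, w_cluster = confidence_weights
    if abs(w_rf + w_cluster - 1.0) > 1e-9:
        raise ValidationError("confidence weights must sum to 1")
    config = ssem.config
    x, pca = pixel_features(image, config)
    p_particle = ssem.forest.predict_proba(x)[:, list(ssem.forest.classes_).index(1)]
    n_comp = pca.n_components_
    scores = x[:, :n_comp]
    km = KMeans(n_clusters=config.k, n_init=10, random_state=seed).fit(scores)
    # substrate cluster = lower mean peak intensity (peak column follows PCs)
    peak = x[:, n_comp]
    cluster_peak = [peak[km.labels_ == c].mean() for c in range(config.k)]
    substrate_cluster = int(np.argmin(cluster_peak))
    cluster_substrate = (km.labels_ == substrate_cluster).astype(float)
    score_substrate = w_rf * (1.0 - p_particle) + w_cluster * cluster_substrate
    is_substrate = score_substrate > 0.5
    labels = np.where(is_substrate, "substrate", "particle").astype(object)
    rf_prob_assigned = np.where(is_substrate, 1.0 - p_particle, p_particle)
    cluster_agrees = (cluster_substrate.astype(bool) == is_substrate).astype(float)
    confidence = w_rf * rf_prob_assigned + w_cluster * cluster_agrees
    mask = labels.reshape(image.height, image.width)
    conf = confidence.reshape(image.height, image.width)
    image.mask = mask
    image.confidence = conf
    particle_grid = (mask == "particle").astype(int)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labelled, n_regions = ndimage.label(particle_grid, structure=structure)
    regions = []
    for ridx, sl in enumerate(ndimage.find_objects(labelled), start=1):
        count = int((labelled[sl] == ridx).sum())
        regions.append(
            {
                "id": ridx,
                "pixels": count,
                "bbox": (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop),
            }
        )
    return MaskResult(
        mask=mask,
        confidence=conf,
        substrate_fraction=float(is_substrate.mean()),
        regions=regions,
    )


def classify_particles(
    image: SpectralImage,
    mask_result: MaskResult,
    classify_fn,
) -> dict:
    """Classify only particle pixels; substrate pixels are skipped.

    ``classify_fn`` maps a pixel intensity vector (on the image axis) to a
    class label. Returns the per-pixel composition map (None on substrate),
    per-region majority labels, and the classified/skipped pixel accounting
    that underlies the masking speedup.
    """
    mask = mask_result.mask
    composition = np.full((image.height, image.width), None, dtype=object)
    n_classified = 0
    for iy in range(image.height):
        for ix in range(image.width):
            if mask[iy, ix] == "particle":
                composition[iy, ix] = classify_fn(image.cube[iy, ix])
                n_classified += 1
    particle_grid = (mask == "particle").astype(int)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labelled, _ = ndimage.label(particle_grid, structure=structure)
    region_labels: dict[int, str] = {}
    for region in mask_result.regions:
        rid = region["id"]
        votes: dict[str, int] = {}
        for iy, ix in zip(*np.nonzero(labelled == rid)):
            lab = composition[iy, ix]
            votes[lab] = votes.get(lab, 0) + 1
        region_labels[rid] = max(votes, key=votes.get) if votes else None
    return {
        "composition": composition,
        "region_labels": region_labels,
        "n_classified": n_classified,
        "n_skipped": image.n_pixels - n_classified,
        "classified_fraction": n_classified / image.n_pixels,
    }
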