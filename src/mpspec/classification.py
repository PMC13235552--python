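"""Spectral classification: PCC library matching and the SE-residual network.

Two complementary classifiers:

* :func:`pcc_match` — classical library matching by Pearson correlation
  between a query and every library entry on the shared canonical grid.
* A deep residual network (DRN) for in-distribution polymer classes: stem
  convolution, residual blocks with parallel multiscale kernels and
  squeeze-and-excitation gating, global average pooling and a linear head.
  Predictions come from a stratified k-fold ensemble whose softmax is the
  mean of the fold softmaxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .types import CanonicalSpectrum, SpectralLibrary, ValidationError

# ---------------------------------------------------------------------------
# PCC matching
# ---------------------------------------------------------------------------


@dataclass
class PCCMatch:
    """Ranked per-class best Pearson correlations for one query."""

    ranked: list[tuple[str, float]]  # sorted descending by r

    @property
    def top_label(self) -> str:
        return self.ranked[0][0]

    @property
    def top_r(self) -> float:
        return self.ranked[0][1]


def pcc_match(
    s: CanonicalSpectrum,
    library: SpectralLibrary,
    top_k: int | None = None,
    use_class_means: bool = False,
) -> PCCMatch:
    """Pearson-correlate a spectrum against a library.

    By default each entry is matched individually and the best r per class is
    reported; ``use_class_means`` matches against per-class mean spectra
    instead. Deterministic; raises on a zero-variance query.
    """
    if library.modality != s.modality:
        raise ValidationError("query and library modalities differ")
    q = s.intensities
    if np.std(q) == 0:
        raise ValidationError("zero-variance spectrum cannot be correlated")
    best: dict[str, float] = {}
    if use_class_means:
        items = list(library.class_means.items())
    else:
        items = [(label, spec.intensities) for label, spec in library.entries]
    for label, ref in items:
        ref = np.asarray(ref) if not isinstance(ref, np.ndarray) else ref
        if isinstance(ref, CanonicalSpectrum):
            ref = ref.intensities
        if np.std(ref) == 0:
            continue
        r = float(np.corrcoef(q, ref)[0, 1])
        if label not in best or r > best[label]:
            best[label] = r
    ranked = sorted(best.items(), key=lambda kv: -kv[1])
    if top_k is not None:
        ranked = ranked[:top_k]
    return PCCMatch(ranked=ranked)


# ---------------------------------------------------------------------------
# DRN
# ---------------------------------------------------------------------------


@dataclass
class DRNConfig:
    """Architecture and training hyperparameters for the residual network.

    The default layout is a stem convolution followed by four residual
    blocks with channels (32, 64, 64, 128), multiscale kernels covering
    roughly 10-45 cm^-1 of spectral context, SE gating, average pooling
    between blocks, global average pooling and a linear head.
    """

    n_classes: int = 2
    channels: tuple[int, ...] = (32, 64, 64, 128)
    kernels: tuple[int, ...] = (3, 7, 15)
    se_reduction: int = 4
    dropout: float = 0.1
    stem_kernel: int = 7
    stem_stride: int = 2
    pool: int = 2
    lr: float = 1e-2
    epochs: int = 20
    batch_size: int = 64
    folds: int = 10

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least two classes")
        if any(k % 2 == 0 for k in self.kernels) or self.stem_kernel % 2 == 0:
            raise ValidationError("kernel sizes must be odd")
        if any(c % len(self.kernels) for c in self.channels):
            raise ValidationError("channels must be divisible by the number of kernel scales")


class DRNModel:
    """One trained fold: the network plus its class labels."""

    def __init__(self, config: DRNConfig, classes: list[str], seed: int = 0):
        self.config = config
        self.classes = list(classes)
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = [
            nn.Conv1d(1, config.channels[0], config.stem_kernel, stride=config.stem_stride, rng=rng),
            nn.ReLU(),
        ]
        c_prev = config.channels[0]
        for c in config.channels:
            layers.append(
                nn.ResidualBlock(c_prev, c, kernels=config.kernels, se_reduction=config.se_reduction, rng=rng)
            )
            layers.append(nn.AvgPool1d(config.pool))
            c_prev = c
        self.backbone = nn.Sequential(layers)
        self.gap = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(config.dropout, rng=rng)
        self.head = nn.Dense(c_prev, len(classes), rng=rng)
        # input standardization fitted on the training split
        self._mu = 0.0
        self._sd = 1.0

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.gap.forward(self.backbone.forward(x, train), train)
        return self.head.forward(self.dropout.forward(h, train), train)

    def _backward(self, grad: np.ndarray) -> None:
        g = self.dropout.backward(self.head.backward(grad))
        self.backbone.backward(self.gap.backward(g))

    def params(self):
        return self.backbone.params() + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def fit(self, x: np.ndarray, y: np.ndarray, seed: int = 0) -> list[float]:
        cfg = self.config
        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.params(), lr=cfg.lr)
        losses = []
        self._mu = float(x.mean())
        self._sd = float(x.std()) or 1.0
        xb = ((x - self._mu) / self._sd)[:, None, :]
        for _ in range(cfg.epochs):
            order = rng.permutation(len(y))
            epoch_loss = 0.0
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._forward(xb[idx], train=True)
                loss, grad = nn.cross_entropy_grad(logits, y[idx])
                opt.zero_grad()
                self._backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / len(y))
        return losses

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        xb = ((x - self._mu) / self._sd)[:, None, :]
        out = []
        for start in range(0, len(x), batch_size):
            logits = self._forward(xb[start : start + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.vstack(out)

    def embed(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate-layer (global-average-pooled) embeddings."""
        xb = ((x - self._mu) / self._sd)[:, None, :]
        out = []
        for start in range(0, len(x), batch_size):
            h = self.backbone.forward(xb[start : start + batch_size], train=False)
            out.append(self.gap.forward(h, train=False))
        return np.vstack(out)


def build_drn(config: DRNConfig, classes: list[str] | None = None, seed: int = 0) -> DRNModel:
    """Construct an untrained DRN for the given class list."""
    classes = classes or [str(i) for i in range(config.n_classes)]
    return DRNModel(config, classes, seed=seed)


@dataclass
class Prediction:
    """Ensemble prediction for one spectrum."""

    label: str
    softmax: np.ndarray  # ensemble mean, sums to 1
    fold_softmax: np.ndarray  # (n_folds, n_classes)
    confidence: float
    classes: list[str] = field(default_factory=list)

    def top(self, k: int = 3) -> list[tuple[str, float]]:
        order = np.argsort(self.softmax)[::-1][:k]
        return [(self.classes[i], float(self.softmax[i])) for i in order]


class DRNEnsemble:
    """Stratified k-fold ensemble: mean-of-folds softmax, argmax label."""

    def __init__(self, models: list[DRNModel], classes: list[str], cv_report: dict):
        self.models = models
        self.classes = list(classes)
        self.cv_report = cv_report

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(x) for m in self.models], axis=0)

    def fold_proba(self, x: np.ndarray) -> np.ndarray:
        """(n_folds, n_samples, n_classes) per-fold softmaxes."""
        return np.stack([m.predict_proba(x) for m in self.models])

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Ensemble-mean penultimate embedding."""
        return np.mean([m.embed(x) for m in self.models], axis=0)

    @property
    def model_card(self) -> dict:
        return {
            "n_folds": len(self.models),
            "n_parameters": self.models[0].n_parameters(),
            "classes": self.classes,
            "config": vars(self.models[0].config),
            "cv": self.cv_report,
        }


def train_ensemble(
    x: np.ndarray,
    labels: list[str] | np.ndarray,
    config: DRNConfig,
    seed: int = 0,
) -> DRNEnsemble:
    """Train a stratified k-fold DRN ensemble and report per-fold accuracy.

    Folds preserve label proportions (within one member); each fold's model
    is trained on its training split and evaluated on its held-out split.

    Raises
    ------
    ValidationError
        If any class has fewer members than the number of folds.
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    y = np.searchsorted(classes, labels)
    counts = np.bincount(y)
    if counts.min() < config.folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members; need >= folds ({config.folds})"
        )
    if len(classes) != config.n_classes:
        config = DRNConfig(**{**vars(config), "n_classes": len(classes)})
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed)
    models: list[DRNModel] = []
    accs: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, y)):
        model = DRNModel(config, classes, seed=seed + fold)
        model.fit(x[train_idx], y[train_idx], seed=seed + 100 + fold)
        pred = model.predict_proba(x[test_idx]).argmax(axis=1)
        accs.append(float((pred == y[test_idx]).mean()))
        models.append(model)
    report = {
        "fold_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs)),
    }
    return DRNEnsemble(models, classes, report)


def predict(ensemble: DRNEnsemble, s: CanonicalSpectrum | np.ndarray) -> Prediction:
    """Ensemble prediction for a single canonical spectrum."""
    v = s.intensities if isinstance(s, CanonicalSpectrum) else np.asarray(s, dtype=float)
    if v.ndim != 1:
        raise ValidationError("predict expects a single spectrum")
    fold = ensemble.fold_proba(v[None, :])[:, 0, :]
    mean = fold.mean(axis=0)
    label = ensemble.classes[int(mean.argmax())]
    return Prediction(
        label=label,
        softmax=mean,
        fold_softmax=fold,
        confidence=float(mean.max()),
        classes=ensemble.classes,
    )
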