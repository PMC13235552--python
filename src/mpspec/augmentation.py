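"""Class balancing: minimum-seed routing and spectral augmentation.

Classes with at least ``min_seed`` (default 50) original spectra are routed
to deep-model training and expanded to ``target_per_class`` spectra; smaller
classes are reserved for correlation (PCC) matching only. Three augmentation
strategies are provided:

* ``original`` — resampling with replacement plus intensity jitter;
* ``iarpls``  — baseline-resampling augmentation: each output is a seed's
  corrected signal plus a synthetic baseline drawn from the same family the
  baseline corrector is built to remove (broad Gaussian fluorescence / linear
  drift), plus noise, renormalized;
* ``smote``   — convex interpolation between a seed and one of its k nearest
  neighbours with a uniform random weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CanonicalSpectrum, SpectralLibrary, ValidationError, modality_grid

MIN_SEED_DEFAULT = 50
TARGET_PER_CLASS_DEFAULT = 8000


@dataclass
class AugmentationPlan:
    """Per-class routing and augmentation targets."""

    min_seed: int = MIN_SEED_DEFAULT
    target_per_class: int = TARGET_PER_CLASS_DEFAULT
    method: str = "iarpls"  # "original" | "iarpls" | "smote"
    routing: dict[str, str] = field(default_factory=dict)  # label -> dlm_train | pcc_only
    seed_counts: dict[str, int] = field(default_factory=dict)

    def dlm_classes(self) -> list[str]:
        return sorted(k for k, v in self.routing.items() if v == "dlm_train")

    def pcc_classes(self) -> list[str]:
        return sorted(k for k, v in self.routing.items() if v == "pcc_only")


def route_classes(
    library: SpectralLibrary,
    min_seed: int = MIN_SEED_DEFAULT,
    target_per_class: int = TARGET_PER_CLASS_DEFAULT,
    method: str = "iarpls",
) -> AugmentationPlan:
    """Deterministically route classes by seed count.

    Classes with ``seed >= min_seed`` go to deep-model training; the rest are
    reserved for PCC prediction. Empty classes cannot occur in a library
    (labels exist only through entries).
    """
    if len(library) == 0:
        raise ValidationError("cannot route an empty library")
    counts = library.class_counts()
    routing = {
        label: ("dlm_train" if n >= min_seed else "pcc_only") for label, n in counts.items()
    }
    return AugmentationPlan(
        min_seed=min_seed,
        target_per_class=target_per_class,
        method=method,
        routing=routing,
        seed_counts=dict(counts),
    )


def _renormalize(v: np.ndarray) -> np.ndarray:
    peak = v.max()
    return v / peak if peak > 0 else v


def _synthetic_baseline(n: int, grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random draw from the baseline family the corrector removes."""
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    kind = rng.integers(0, 2)
    if kind == 0:
        return rng.uniform(0.1, 0.6) + rng.uniform(-0.3, 0.5) * x
    center = rng.uniform(grid[0], grid[-1])
    sigma = rng.uniform(300.0, 700.0)
    return rng.uniform(0.2, 1.0) * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def augment_iarpls(
    seeds: list[CanonicalSpectrum],
    n_out: int,
    perturb_scale: float = 0.1,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> list[CanonicalSpectrum]:
    """Baseline-resampling augmentation.

    Each output is a cyclically chosen seed's intensities plus a synthetic
    baseline scaled by ``perturb_scale`` (relative to the seed's maximum) and
    Gaussian intensity jitter, renormalized to unit maximum. With
    ``perturb_scale == 0`` outputs are exact copies of the seeds (cycled).
    """
    if n_out <= 0:
        raise ValidationError("n_out must be positive")
    if not seeds:
        raise ValidationError("need at least one seed spectrum")
    rng = np.random.default_rng(seed)
    grid = modality_grid(seeds[0].modality)
    out: list[CanonicalSpectrum] = []
    for j in range(n_out):
        base = seeds[j % len(seeds)]
        if perturb_scale == 0:
            out.append(base.copy())
            continue
        scale = float(base.intensities.max())
        v = (
            base.intensities
            + perturb_scale * scale * _synthetic_baseline(len(grid), grid, rng)
            + rng.normal(0.0, noise_sigma * max(scale, 1e-12), len(grid))
        )
        aug = base.copy()
        aug.intensities = _renormalize(v)
        aug.normalized = True
        aug.metadata["augmented"] = "iarpls"
        out.append(aug)
    return out


def augment_smote(
    seeds: list[CanonicalSpectrum],
    n_out: int,
    k_neighbors: int = 5,
    seed: int = 0,
) -> list[CanonicalSpectrum]:
    """Convex (SMOTE-style) interpolation between nearest-neighbour seeds.

    Every output lies elementwise within the min/max envelope of its parent
    pair.
    """
    if n_out <= 0:
        raise ValidationError("n_out must be positive")
    if len(seeds) < k_neighbors + 1:
        raise ValidationError(
            f"need at least k_neighbors+1 = {k_neighbors + 1} seeds, got {len(seeds)}"
        )
    rng = np.random.default_rng(seed)
    mat = np.stack([s.intensities for s in seeds])
    # pairwise distances; each seed's k nearest other seeds
    d2 = ((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1)[:, :k_neighbors]
    out: list[CanonicalSpectrum] = []
    for j in range(n_out):
        i = j % len(seeds)
        partner = int(neighbors[i, rng.integers(0, k_neighbors)])
        w = float(rng.uniform(0.0, 1.0))
        v = (1.0 - w) * mat[i] + w * mat[partner]
        aug = seeds[i].copy()
        aug.intensities = v
        aug.normalized = abs(float(v.max()) - 1.0) <= 1e-9
        aug.metadata["augmented"] = "smote"
        aug.metadata["smote_parents"] = (i, partner)
        aug.metadata["smote_weight"] = w
        out.append(aug)
    return out


def augment_original(
    seeds: list[CanonicalSpectrum],
    n_out: int,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> list[CanonicalSpectrum]:
    """Resampling with replacement plus Gaussian intensity jitter."""
    if n_out <= 0:
        raise ValidationError("n_out must be positive")
    if not seeds:
        raise ValidationError("need at least one seed spectrum")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_out):
        base = seeds[rng.integers(0, len(seeds))]
        aug = base.copy()
        scale = float(base.intensities.max())
        aug.intensities = _renormalize(
            base.intensities + rng.normal(0.0, noise_sigma * max(scale, 1e-12), len(base))
        )
        aug.metadata["augmented"] = "original"
        out.append(aug)
    return out


_METHODS = {"original": augment_original, "iarpls": augment_iarpls, "smote": augment_smote}


def execute_plan(
    library: SpectralLibrary, plan: AugmentationPlan, seed: int = 0
) -> dict[str, list[CanonicalSpectrum]]:
    """Expand every dlm_train class to exactly ``target_per_class`` spectra.

    Original seeds are always retained at the head of each class pool, and
    every augmented spectrum carries its seed class label.
    """
    fn = _METHODS.get(plan.method)
    if fn is None:
        raise ValidationError(f"unknown augmentation method {plan.method!r}")
    pools: dict[str, list[CanonicalSpectrum]] = {}
    for ci, label in enumerate(plan.dlm_classes()):
        seeds = library.spectra_for(label)
        n_extra = plan.target_per_class - len(seeds)
        if n_extra < 0:
            pool = seeds[: plan.target_per_class]
        else:
            pool = list(seeds) + (fn(seeds, n_extra, seed=seed + 7919 * ci) if n_extra else [])
        for s in pool:
            s.metadata.setdefault("label", label)
        pools[label] = pool
    return pools
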