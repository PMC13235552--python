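"""Core domain types for spectra, libraries and spectral images.

Conventions
-----------
All wavenumber axes are stored ascending, in cm^-1, for both modalities.
FTIR instruments conventionally print 4000 -> 400 cm^-1; readers flip such
input and record the flip in metadata, so a single interpolation / peak-finding
code path serves both modalities.

Canonical grids are 1000 uniformly spaced points:

* Raman: 200 - 3200 cm^-1 (step ~3.003 cm^-1)
* FTIR:  400 - 4000 cm^-1 (step ~3.604 cm^-1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

N_CANONICAL = 1000

RAMAN_RANGE = (200.0, 3200.0)
FTIR_RANGE = (400.0, 4000.0)

RAMAN_GRID = np.linspace(*RAMAN_RANGE, N_CANONICAL)
FTIR_GRID = np.linspace(*FTIR_RANGE, N_CANONICAL)

MODALITIES = ("raman", "ftir")
CONDITIONS = ("virgin", "consumer", "weathered", "biofouled", "unspecified")
MASK_LABELS = ("substrate", "particle", "unassigned")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def modality_grid(modality: str) -> np.ndarray:
    """Return the canonical 1000-point grid for a modality."""
    if modality == "raman":
        return RAMAN_GRID
    if modality == "ftir":
        return FTIR_GRID
    raise ValidationError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def grid_step(modality: str) -> float:
    g = modality_grid(modality)
    return float(g[1] - g[0])


@dataclass
class Spectrum:
    """A single acquisition: wavenumber axis plus intensities.

    Parameters
    ----------
    axis : strictly increasing wavenumbers in cm^-1.
    intensities : same length as ``axis``, arbitrary units, finite.
    modality : ``"raman"`` or ``"ftir"``.
    metadata : free key-value map (polymer label, sample condition,
        laser wavelength for Raman, axis-reversal flags, ...).
    """

    axis: np.ndarray
    intensities: np.ndarray
    modality: str = "raman"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("axis and intensities must be 1-D")
        if len(self.axis) != len(self.intensities):
            raise ValidationError(
                f"axis length {len(self.axis)} != intensities length {len(self.intensities)}"
            )
        if len(self.axis) == 0:
            raise ValidationError("empty spectrum")
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite values in spectrum")
        if np.any(np.diff(self.axis) <= 0):
            raise ValidationError("axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.axis)


@dataclass
class CanonicalSpectrum:
    """A spectrum resampled to the fixed 1000-point modality grid.

    ``padded_regions`` lists half-open index intervals ``(start, stop)`` that
    were filled from a class-mean (or self-mean) rather than measured.
    """

    intensities: np.ndarray
    modality: str = "raman"
    metadata: dict[str, Any] = field(default_factory=dict)
    baseline_corrected: bool = False
    normalized: bool = False
    smoothed: bool = False
    padded_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.intensities.shape != (N_CANONICAL,):
            raise ValidationError(
                f"canonical spectrum must have exactly {N_CANONICAL} points, "
                f"got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite values in canonical spectrum")
        if self.normalized and abs(float(self.intensities.max()) - 1.0) > 1e-9:
            raise ValidationError("normalized spectrum must have max exactly 1")

    @property
    def grid(self) -> np.ndarray:
        return modality_grid(self.modality)

    def copy(self) -> "CanonicalSpectrum":
        return CanonicalSpectrum(
            intensities=self.intensities.copy(),
            modality=self.modality,
            metadata=dict(self.metadata),
            baseline_corrected=self.baseline_corrected,
            normalized=self.normalized,
            smoothed=self.smoothed,
            padded_regions=list(self.padded_regions),
        )

    def __len__(self) -> int:
        return N_CANONICAL


class SpectralLibrary:
    """A labelled collection of canonical spectra on one shared grid.

    Maintains a per-label mean intensity vector (used for PCC matching
    against class means and for class-mean padding during resampling).
    """

    def __init__(self, modality: str, entries: list[tuple[str, CanonicalSpectrum]] | None = None):
        if modality not in MODALITIES:
            raise ValidationError(f"unknown modality {modality!r}")
        self.modality = modality
        self.entries: list[tuple[str, CanonicalSpectrum]] = []
        for label, spectrum in entries or []:
            self.add(label, spectrum)

    def add(self, label: str, spectrum: CanonicalSpectrum) -> None:
        if spectrum.modality != self.modality:
            raise ValidationError(
                f"library modality {self.modality!r} != spectrum modality {spectrum.modality!r}"
            )
        self.entries.append((str(label), spectrum))

    @property
    def labels(self) -> list[str]:
        """Sorted unique class labels."""
        return sorted({label for label, _ in self.entries})

    def spectra_for(self, label: str) -> list[CanonicalSpectrum]:
        return [s for lab, s in self.entries if lab == label]

    @property
    def class_means(self) -> dict[str, np.ndarray]:
        """Mean intensity vector per label (labels with >= 1 entry)."""
        means: dict[str, np.ndarray] = {}
        for label in self.labels:
            stack = np.stack([s.intensities for s in self.spectra_for(label)])
            means[label] = stack.mean(axis=0)
        return means

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label, _ in self.entries:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SpectralImage:
    """A 2-D pixel grid of spectra on a shared axis plus a substrate mask.

    ``cube`` has shape (height, width, len(axis)); ``mask`` holds string
    labels from :data:`MASK_LABELS`; ``confidence`` holds per-pixel scores
    in [0, 1].
    """

    height: int
    width: int
    axis: np.ndarray
    cube: np.ndarray
    mask: np.ndarray | None = None
    confidence: np.ndarray | None = None
    modality: str = "raman"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.shape != (self.height, self.width, len(self.axis)):
            raise ValidationError(
                f"cube shape {self.cube.shape} inconsistent with "
                f"({self.height}, {self.width}, {len(self.axis)})"
            )
        if self.mask is None:
            self.mask = np.full((self.height, self.width), "unassigned", dtype=object)
        else:
            self.mask = np.asarray(self.mask, dtype=object)
            if self.mask.shape != (self.height, self.width):
                raise ValidationError("mask shape inconsistent with pixel grid")
            bad = set(np.unique(self.mask)) - set(MASK_LABELS)
            if bad:
                raise ValidationError(f"unknown mask labels {bad}")
        if self.confidence is None:
            self.confidence = np.zeros((self.height, self.width))
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (self.height, self.width):
                raise ValidationError("confidence shape inconsistent with pixel grid")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def pixel_spectra(self) -> np.ndarray:
        """Row-major (n_pixels, n_channels) view of the cube."""
        return self.cube.reshape(self.n_pixels, len(self.axis))
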