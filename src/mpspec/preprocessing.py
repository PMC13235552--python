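"""Canonical resampling, baseline correction, normalization and smoothing.

Pipeline order contract: resample -> baseline correction -> spurious-peak
removal -> maximum-intensity normalization -> Savitzky-Golay smoothing.
Artifacts are removed before normalization so a cosmic ray or CO2 band can
never become the normalization maximum and suppress genuine polymer signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import splu

from .types import CanonicalSpectrum, Spectrum, ValidationError, modality_grid

logger = logging.getLogger(__name__)

#: Default smoothness penalties per modality. FTIR baselines (ATR drift,
#: scattering slopes) are smoother than fluorescence-dominated Raman
#: baselines, so a stiffer penalty is used.
DEFAULT_LAMBDA = {"raman": 1e5, "ftir": 1e6}

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 3


@dataclass
class BaselineResult:
    """Outcome of iterative asymmetric penalized least-squares correction."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations: int
    converged: bool
    lam: float
    ratio_trace: list[float] = field(default_factory=list)


def resample(
    s: Spectrum,
    class_mean: np.ndarray | None = None,
) -> CanonicalSpectrum:
    """Linearly interpolate a spectrum onto its modality's 1000-point grid.

    Grid regions the input does not cover are filled from ``class_mean``
    (the library mean of the spectrum's class, computed after baseline
    correction but before normalization) and recorded in ``padded_regions``.
    With no class mean available the spectrum's own mean intensity is used
    and a warning logged.

    Raises
    ------
    ValidationError
        If the input does not overlap the target grid at all.
    """
    grid = modality_grid(s.modality)
    lo, hi = s.axis[0], s.axis[-1]
    covered = (grid >= lo) & (grid <= hi)
    if not covered.any():
        raise ValidationError(
            f"spectrum range [{lo}, {hi}] cm^-1 has no overlap with the "
            f"{s.modality} grid [{grid[0]}, {grid[-1]}]"
        )
    out = np.interp(grid, s.axis, s.intensities)
    padded_regions: list[tuple[int, int]] = []
    if not covered.all():
        if class_mean is not None:
            fill = np.asarray(class_mean, dtype=float)
            if fill.shape != grid.shape:
                raise ValidationError("class_mean must be a length-1000 vector")
        else:
            fill = np.full_like(grid, float(s.intensities.mean()))
            logger.warning(
                "no class mean available; padding uncovered grid regions with the "
                "spectrum's own mean intensity"
            )
            warnings.warn("padding uncovered regions with self-mean", stacklevel=2)
        idx = np.flatnonzero(~covered)
        out[idx] = fill[idx]
        # collapse indices into maximal contiguous half-open intervals
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
        padded_regions = [(int(a), int(b)) for a, b in zip(starts, stops)]
    return CanonicalSpectrum(
        intensities=out,
        modality=s.modality,
        metadata=dict(s.metadata),
        padded_regions=padded_regions,
    )


def _second_difference_penalty(n: int, lam: float) -> sparse.csc_matrix:
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return (lam * (d.T @ d)).tocsc()


def iarpls_baseline(
    s: CanonicalSpectrum | np.ndarray,
    lam: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    modality: str = "raman",
) -> BaselineResult:
    """Iterative asymmetric penalized least-squares baseline estimation.

    The baseline ``z`` minimizes ``sum_i w_i (y_i - z_i)^2 + lam * ||D2 z||^2``
    where ``D2`` is the second-difference operator. Weights are updated each
    iteration from the residual distribution: points far above the baseline
    (spectral bands) receive asymptotically zero weight through a logistic
    function of the residual scaled by the mean and standard deviation of the
    negative residuals, so the baseline relaxes under the peaks while
    following fluorescence humps. Iteration stops when the adaptive
    convergence ratio ``||w_new - w|| / ||w||`` drops below ``tol``.

    Non-convergence within ``max_iter`` is flagged (``converged=False``),
    never raised.
    """
    if isinstance(s, CanonicalSpectrum):
        y = s.intensities
        modality = s.modality
    else:
        y = np.asarray(s, dtype=float)
    if lam is None:
        lam = DEFAULT_LAMBDA[modality]
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite intensities")
    n = len(y)
    h = _second_difference_penalty(n, lam)
    w = np.ones(n)
    z = y.copy()
    ratio_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        lhs = (sparse.diags(w) + h).tocsc()
        z = splu(lhs).solve(w * y)
        d = y - z
        if np.max(np.abs(d)) <= 1e-10 * max(1.0, float(np.abs(y).max())):
            # baseline explains the signal to numerical precision (flat input)
            converged = True
            ratio_trace.append(0.0)
            break
        neg = d[d < 0]
        if neg.size < 2:
            converged = True
            ratio_trace.append(0.0)
            break
        m, sd = neg.mean(), neg.std()
        if sd == 0:
            converged = True
            ratio_trace.append(0.0)
            break
        arg = np.clip(2.0 * (d - (2.0 * sd - m)) / sd, -500, 500)
        w_new = 1.0 / (1.0 + np.exp(arg))
        ratio = float(np.linalg.norm(w - w_new) / np.linalg.norm(w))
        ratio_trace.append(ratio)
        w = w_new
        if ratio < tol:
            converged = True
            break
    return BaselineResult(
        baseline=z,
        corrected=y - z,
        iterations=iterations,
        converged=converged,
        lam=float(lam),
        ratio_trace=ratio_trace,
    )


def correct_baseline(
    s: CanonicalSpectrum,
    lam: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> tuple[CanonicalSpectrum, BaselineResult]:
    """Apply :func:`iarpls_baseline` and return the corrected spectrum."""
    result = iarpls_baseline(s, lam=lam, max_iter=max_iter, tol=tol)
    out = s.copy()
    out.intensities = result.corrected
    out.baseline_corrected = True
    return out, result


def normalize_max(s: CanonicalSpectrum) -> CanonicalSpectrum:
    """Scale so the maximum intensity is exactly 1. Negative overshoot from
    baseline correction is left untouched (nothing is clipped)."""
    peak = float(s.intensities.max())
    if peak <= 0:
        raise ValidationError("cannot normalize: maximum intensity is not positive")
    out = s.copy()
    out.intensities = s.intensities / peak
    out.normalized = True
    return out


def smooth_savgol(
    s: CanonicalSpectrum,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> CanonicalSpectrum:
    """Savitzky-Golay smoothing; polynomials of degree <= polyorder pass
    through unchanged."""
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValidationError("polyorder must be smaller than window")
    out = s.copy()
    out.intensities = savgol_filter(s.intensities, window, polyorder)
    if out.normalized:
        # smoothing can nudge the maximum off exactly 1; the normalized flag
        # only survives if it still holds
        out.normalized = abs(float(out.intensities.max()) - 1.0) <= 1e-9
    out.smoothed = True
    return out


def preprocess(
    s: Spectrum,
    class_mean: np.ndarray | None = None,
    lam: float | None = None,
    artifact_remover=None,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_polyorder: int = DEFAULT_SG_POLYORDER,
    smooth: bool = True,
) -> tuple[CanonicalSpectrum, dict]:
    """Full preprocessing chain in the contract order.

    ``artifact_remover`` is an optional callable
    ``CanonicalSpectrum -> (CanonicalSpectrum, report)`` slotted between
    baseline correction and normalization (cosmic-ray removal for Raman,
    CO2 excision for FTIR; see :mod:`mpspec.artifacts`).
    """
    report: dict = {}
    canonical = resample(s, class_mean=class_mean)
    report["padded_regions"] = canonical.padded_regions
    canonical, baseline_result = correct_baseline(canonical, lam=lam)
    report["baseline"] = {
        "iterations": baseline_result.iterations,
        "converged": baseline_result.converged,
        "lambda": baseline_result.lam,
    }
    if artifact_remover is not None:
        canonical, artifact_report = artifact_remover(canonical)
        report["artifacts"] = artifact_report
    canonical = normalize_max(canonical)
    if smooth:
        canonical = smooth_savgol(canonical, window=sg_window, polyorder=sg_polyorder)
    return canonical, report
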