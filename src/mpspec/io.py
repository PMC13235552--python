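"""Readers and writers for spectra and spectral images.

Native on-disk formats are plain text:

* Spectra: two numeric columns (wavenumber, intensity), whitespace, comma or
  semicolon separated, with optional ``#``-prefixed ``key: value`` metadata
  header lines. Vendor binary formats are explicit non-goals.
* Spectral images: long-format CSV with columns
  ``x_pixel,y_pixel,wavenumber,intensity`` preceded by a single ``#``-prefixed
  JSON header carrying dimensions, modality, mask and confidence.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import (
    MASK_LABELS,
    CanonicalSpectrum,
    Spectrum,
    SpectralImage,
    ValidationError,
    modality_grid,
)

DIALECT_SEPARATORS = {"whitespace": None, "comma": ",", "semicolon": ";"}


class ParseError(ValueError):
    """Raised on malformed input files; names the offending line."""


def _split_row(line: str, dialect: str) -> list[str]:
    sep = DIALECT_SEPARATORS[dialect]
    return line.split(sep) if sep else line.split()


def _sniff_dialect(line: str) -> str:
    if ";" in line:
        return "semicolon"
    if "," in line:
        return "comma"
    return "whitespace"


def read_spectrum(path: str | Path, modality: str = "raman", dialect: str = "auto") -> Spectrum:
    """Read a two-column text spectrum.

    Metadata header lines of the form ``# key: value`` are collected into
    ``Spectrum.metadata``. Descending axes (the FTIR print convention) are
    reversed to ascending and the flip recorded under ``axis_reversed``.

    Raises
    ------
    ParseError
        On a malformed data row (names the 1-based line number).
    ValidationError
        If the axis is non-monotonic after orientation (e.g. duplicates).
    """
    path = Path(path)
    metadata: dict[str, object] = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            if dialect == "auto":
                dialect = _sniff_dialect(line)
            parts = _split_row(line, dialect)
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not xs:
        raise ParseError(f"{path}: no data rows")
    axis = np.array(xs)
    intensities = np.array(ys)
    if len(axis) > 1 and np.all(np.diff(axis) < 0):
        axis = axis[::-1].copy()
        intensities = intensities[::-1].copy()
        metadata["axis_reversed"] = True
    if np.any(np.diff(axis) <= 0):
        raise ValidationError(f"{path}: axis not strictly monotonic (duplicate or unsorted rows)")
    return Spectrum(axis=axis, intensities=intensities, modality=modality, metadata=metadata)


def write_spectrum(s: Spectrum | CanonicalSpectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with ``# key: value`` headers.

    Round-trips through :func:`read_spectrum` to 1e-9 relative precision.
    """
    path = Path(path)
    if isinstance(s, CanonicalSpectrum):
        axis, intensities = s.grid, s.intensities
    else:
        axis, intensities = s.axis, s.intensities
    if len(axis) == 0:
        raise ValidationError("cannot write an empty spectrum")
    lines = [f"# modality: {s.modality}"]
    for key, value in s.metadata.items():
        # header values must stay on one line (arrays, lists -> flattened str)
        lines.append(f"# {key}: {' '.join(str(value).split())}")
    for x, y in zip(axis, intensities):
        lines.append(f"{float(x):.17g} {float(y):.17g}")
    path.write_text("\n".join(lines) + "\n")


def write_image(image: SpectralImage, path: str | Path) -> None:
    """Write a spectral image as long-format CSV with a JSON header line."""
    path = Path(path)
    header = {
        "height": image.height,
        "width": image.width,
        "modality": image.modality,
        "mask": image.mask.ravel().tolist(),
        "confidence": image.confidence.ravel().tolist(),
        "metadata": image.metadata,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        fh.write("x_pixel,y_pixel,wavenumber,intensity\n")
        for iy in range(image.height):
            for ix in range(image.width):
                for wn, val in zip(image.axis, image.cube[iy, ix]):
                    fh.write(f"{ix},{iy},{float(wn):.17g},{float(val):.17g}\n")


def read_image(path: str | Path) -> SpectralImage:
    """Read a long-format CSV spectral image written by :func:`write_image`.

    A missing mask in the header yields all-``unassigned`` pixels.
    """
    path = Path(path)
    header: dict = {}
    rows: list[tuple[int, int, float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = json.loads(line.lstrip("#"))
                continue
            if line.startswith("x_pixel"):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {line!r}")
            try:
                rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not rows:
        raise ParseError(f"{path}: no data rows")
    height = int(header.get("height", max(r[1] for r in rows) + 1))
    width = int(header.get("width", max(r[0] for r in rows) + 1))
    axis = np.array(sorted({r[2] for r in rows}))
    n_chan = len(axis)
    if len(rows) != height * width * n_chan:
        raise ValidationError(
            f"{path}: {len(rows)} rows inconsistent with "
            f"{height}x{width} pixels x {n_chan} channels"
        )
    index = {wn: i for i, wn in enumerate(axis)}
    cube = np.empty((height, width, n_chan))
    for ix, iy, wn, val in rows:
        cube[iy, ix, index[wn]] = val
    mask = None
    if "mask" in header:
        mask = np.array(header["mask"], dtype=object).reshape(height, width)
        bad = set(np.unique(mask)) - set(MASK_LABELS)
        if bad:
            raise ValidationError(f"{path}: unknown mask labels {bad}")
    confidence = None
    if "confidence" in header:
        confidence = np.array(header["confidence"], dtype=float).reshape(height, width)
    return SpectralImage(
        height=height,
        width=width,
        axis=axis,
        cube=cube,
        mask=mask,
        confidence=confidence,
        modality=header.get("modality", "raman"),
        metadata=header.get("metadata", {}),
    )


def read_canonical(path: str | Path, modality: str = "raman") -> CanonicalSpectrum:
    """Read a spectrum already on the canonical grid as a CanonicalSpectrum."""
    s = read_spectrum(path, modality=modality)
    grid = modality_grid(modality)
    if len(s.axis) != len(grid) or not np.allclose(s.axis, grid, rtol=1e-9, atol=1e-6):
        raise ValidationError(f"{path}: spectrum is not on the canonical {modality} grid")
    return CanonicalSpectrum(intensities=s.intensities, modality=modality, metadata=s.metadata)
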