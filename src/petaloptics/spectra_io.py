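"""Reading, writing, resampling and averaging wavelength-indexed spectra.

Spectra are two-column delimited text (wavelength in nm, dimensionless
value), comma or tab separated, with an optional header row and optional
``# key=value`` comment lines.  The in-memory container is a small frozen
dataclass around numpy arrays; pandas handles the file parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SpectrumFormatError

__all__ = [
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "average_spectra",
    "make_grid",
]

logger = logging.getLogger(__name__)

KINDS = ("reflectance", "transmittance", "parameter", "absorbance")
_FRACTION_KINDS = ("reflectance", "transmittance")
_CLIP_LO, _CLIP_HI = 1e-6, 1.0 - 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed series of one dimensionless optical quantity."""

    wavelengths: np.ndarray  # nm, strictly ascending
    values: np.ndarray
    kind: str = "reflectance"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in KINDS:
            raise SpectrumFormatError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or wl.size < 2:
            raise SpectrumFormatError("a spectrum needs >= 2 wavelength points")
        if not np.all(np.isfinite(wl)) or np.any(np.diff(wl) <= 0):
            raise SpectrumFormatError("wavelengths must be finite and strictly ascending")
        if vals.shape != wl.shape:
            raise SpectrumFormatError("wavelengths and values must have equal length")

    def __len__(self) -> int:
        return self.wavelengths.size

    def at(self, wavelength: float) -> float:
        """Linearly interpolated value at one wavelength (no extrapolation)."""
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise AlignmentError(f"{wavelength} nm outside spectrum range")
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def with_values(self, values) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))


def make_grid(spec: str | Sequence[float]) -> np.ndarray:
    """Build a wavelength grid from 'start:stop:step' or an explicit sequence."""
    if isinstance(spec, str):
        try:
            start, stop, step = (float(x) for x in spec.split(":"))
        except ValueError as exc:
            raise SpectrumFormatError(f"bad grid spec {spec!r}; want start:stop:step") from exc
        if step <= 0 or stop <= start:
            raise SpectrumFormatError(f"bad grid spec {spec!r}")
        n = int(round((stop - start) / step))
        return start + step * np.arange(n + 1)
    grid = np.asarray(spec, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise SpectrumFormatError("grid must be >= 2 strictly ascending values")
    return grid


def read_spectrum(path, kind: str = "reflectance", label: str | None = None) -> Spectrum:
    """Read a two-column wavelength/value file.

    Delimiter (comma or tab) is sniffed; a non-numeric first row is treated
    as a header; a ``# kind=...`` comment overrides the ``kind`` argument.
    Reflectance/transmittance values outside [0, 1] are clipped just inside
    and counted in the log.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SpectrumFormatError(f"cannot read {path}: {exc}") from exc

    file_kind = None
    data_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("kind="):
                file_kind = body.split("=", 1)[1].strip()
            continue
        data_lines.append(line)
    if not data_lines:
        raise SpectrumFormatError(f"{path}: no data rows")

    delim = "\t" if "\t" in data_lines[0] else ","
    try:
        df = pd.read_csv(StringIO("\n".join(data_lines)), sep=delim, header=None,
                         comment=None, skipinitialspace=True)
    except Exception as exc:
        raise SpectrumFormatError(f"{path}: unparseable ({exc})") from exc

    # drop a header row if the first row is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected two columns, found {df.shape[1]}")
    num = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        line_no = int(num.index[bad][0]) + 1
        raise SpectrumFormatError(f"{path}: unparseable row near line {line_no}")
    wl = num.iloc[:, 0].to_numpy(dtype=float)
    vals = num.iloc[:, 1].to_numpy(dtype=float)
    if wl.size < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    if np.any(np.diff(wl) <= 0):
        i = int(np.argmax(np.diff(wl) <= 0))
        raise SpectrumFormatError(f"{path}: wavelengths not ascending near line {i + 2}")

    kind = file_kind or kind
    if kind in _FRACTION_KINDS:
        n_clip = int(np.sum((vals < 0) | (vals > 1)))
        if n_clip:
            logger.warning("%s: clipped %d out-of-range values into [0, 1]", path, n_clip)
        vals = np.clip(vals, _CLIP_LO, _CLIP_HI)
    return Spectrum(wl, vals, kind=kind, label=label if label is not None else path.stem)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV with a header and a '# kind=' sidecar comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={spectrum.kind}\n")
        if spectrum.label:
            fh.write(f"# label={spectrum.label}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{float(wl)!r},{float(v)!r}\n")


def resample(spectra: Iterable[Spectrum], grid) -> list[Spectrum]:
    """Linearly interpolate spectra onto a common grid; never extrapolates."""
    spectra = list(spectra)
    grid = make_grid(grid) if not isinstance(grid, np.ndarray) else grid
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if lo > hi:
        raise AlignmentError("input spectra have no common wavelength range")
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise AlignmentError(
            f"grid [{grid[0]}, {grid[-1]}] nm exceeds the common range [{lo}, {hi}] nm"
        )
    return [
        replace(s, wavelengths=grid, values=np.interp(grid, s.wavelengths, s.values))
        for s in spectra
    ]


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra on a shared grid."""
    if not spectra:
        raise AlignmentError("nothing to average")
    kinds = {s.kind for s in spectra}
    if len(kinds) > 1:
        raise AlignmentError(f"cannot average mixed kinds {sorted(kinds)}")
    ref = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != ref.shape or not np.allclose(s.wavelengths, ref):
            raise AlignmentError("spectra must share a grid; resample first")
    mean = np.mean([s.values for s in spectra], axis=0)
    return Spectrum(ref, mean, kind=spectra[0].kind,
                    label=f"mean of {len(spectra)} spectra")
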