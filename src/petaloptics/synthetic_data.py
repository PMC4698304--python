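"""Synthetic pigment spectra and simulated integrating-sphere measurements.

Ground-truth absorption parameter spectra K*(lambda) are built as sums of
Gaussian bands.  The default template emulates a purple corolla pigment:
a green absorption band peaking at 545 nm with K* = 1.4 at the peak, plus
a much stronger ultraviolet band below 350 nm, leaving a violet window of
weak absorption between them.  Scattering parameter spectra are flat at a
base level (default long-wavelength asymptote 0.5), optionally depressed in
proportion to the normalised absorption to mimic the troughs that strongly
absorbing wavelength bands carve into recovered scattering spectra.

Simulated measurements run the four-layer stack forward and add independent
truncated-Gaussian noise per wavelength; every stochastic call takes an
explicit seed and there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .flower_model import StackModel, stack_spectra
from .spectra_io import Spectrum, make_grid

__all__ = [
    "PigmentTemplate",
    "DEFAULT_PIGMENT",
    "make_pigment_kstar",
    "make_scatter_sstar",
    "simulate_measurement",
    "default_grid",
]


def default_grid() -> np.ndarray:
    """Working wavelength grid: 300-700 nm at 1-nm steps."""
    return make_grid("300:700:1")


@dataclass(frozen=True)
class PigmentTemplate:
    """K*(lambda) as a sum of Gaussian bands (center nm, width nm, amplitude)."""

    bands: tuple

    def __post_init__(self):
        if len(self.bands) < 1:
            raise InvalidParameterError("a pigment template needs >= 1 band")
        for c, w, a in self.bands:
            if w <= 0:
                raise InvalidParameterError(f"band width must be > 0, got {w}")
            if a < 0:
                raise InvalidParameterError(f"band amplitude must be >= 0, got {a}")


#: Green band at 545 nm (peak K* = 1.4) plus a dominant UV band.
DEFAULT_PIGMENT = PigmentTemplate(bands=((545.0, 40.0, 1.4), (310.0, 35.0, 3.5)))


def make_pigment_kstar(template: PigmentTemplate = DEFAULT_PIGMENT,
                       grid=None) -> Spectrum:
    """Evaluate a pigment template: K*(l) = sum_i a_i exp(-(l-c_i)^2 / 2 w_i^2)."""
    grid = default_grid() if grid is None else np.asarray(make_grid(grid) if isinstance(grid, str) else grid, float)
    K = np.zeros_like(grid)
    for c, w, a in template.bands:
        K += a * np.exp(-((grid - c) ** 2) / (2.0 * w * w))
    return Spectrum(grid, K, kind="parameter", label="K_p* synthetic")


def make_scatter_sstar(base: float = 0.5, grid=None,
                       trough_coupling: float | None = None,
                       pigment: Spectrum | None = None) -> Spectrum:
    """Scattering parameter spectrum: flat at `base`, optionally with troughs.

    With ``trough_coupling`` = c in [0, 1], S*(l) = base * (1 - c * K*(l)/max K*),
    reproducing the dips of recovered scattering spectra where absorption is
    severe; the long-wavelength value stays at `base` because the pigment
    does not absorb there.
    """
    if base < 0:
        raise InvalidParameterError(f"base scattering must be >= 0, got {base}")
    grid = default_grid() if grid is None else np.asarray(make_grid(grid) if isinstance(grid, str) else grid, float)
    S = np.full_like(grid, float(base))
    if trough_coupling:
        if not (0 <= trough_coupling <= 1):
            raise InvalidParameterError("trough_coupling must be in [0, 1]")
        if pigment is None:
            pigment = make_pigment_kstar(grid=grid)
        K = np.interp(grid, pigment.wavelengths, pigment.values)
        peak = K.max()
        if peak > 0:
            S = S * (1.0 - trough_coupling * K / peak)
    return Spectrum(grid, S, kind="parameter", label="S_p* synthetic")


def simulate_measurement(stack: StackModel, noise_sd: float = 0.0,
                         seed: int | None = None):
    """Simulate integrating-sphere spectra of a model petal.

    Returns (R_ad, T_ad, R_ab, T_ab) Spectrum objects: the forward stack
    observables plus independent additive Gaussian noise of standard
    deviation ``noise_sd`` truncated to [0, 1].  ``noise_sd = 0`` returns
    the exact model output (and then T_ad == T_ab identically); a seed is
    required whenever noise is requested, and equal seeds give bitwise-equal
    spectra.
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd > 0 and seed is None:
        raise InvalidParameterError("a seed is required when noise_sd > 0")
    R_ad, T, R_ab = stack_spectra(stack)
    T_ad = T.copy()
    T_ab = T.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = []
        for clean in (R_ad, T_ad, R_ab, T_ab):
            noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
            out.append(np.clip(noisy, 0.0, 1.0))
        R_ad, T_ad, R_ab, T_ab = out
    wl = stack.wavelengths
    return (
        Spectrum(wl, R_ad, "reflectance", "R_ad simulated"),
        Spectrum(wl, T_ad, "transmittance", "T_ad simulated"),
        Spectrum(wl, R_ab, "reflectance", "R_ab simulated"),
        Spectrum(wl, T_ab, "transmittance", "T_ab simulated"),
    )
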