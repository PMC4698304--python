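"""Four-layer corolla model: surface / pigmented / unpigmented / surface.

A petal is modelled top (adaxial) to bottom (abaxial) as

    #1  upper surface     non-absorbing plate, r = r_surface, t = 1 - r
    #2  pigmented layer    Kubelka-Munk layer (K_p*(lambda), S_p*(lambda))
    #3  unpigmented layer  Kubelka-Munk layer (K = 0, S_u*)
    #4  lower surface      identical to #1

Fitting inverts measured adaxial reflectance and transmittance spectra to
the pigmented layer's per-wavelength (r_p, t_p) and from those the
absorption and scattering parameters K_p*, S_p* and the equivalent decadic
absorbance D = 0.4343 K_p*.  Prediction runs the stack forward from either
side; because every individual layer is symmetric, the stack transmittance
is identical for adaxial and abaxial illumination while the two reflectances
differ.  The scenario builder redistributes a fixed total amount of pigment
and scattering into one-sided, homogeneous, or two-sided arrangements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np

from .errors import (
    AlignmentError,
    FitDegenerateError,
    InvalidParameterError,
)
from .kubelka_munk import KMParams, PlateRT, invert_rt, km_plate_rt
from .plate_stack import combine_stack, peel_top, solve_symmetric_middle
from .spectra_io import Spectrum, resample

__all__ = [
    "FlowerConfig",
    "SurfaceLayer",
    "KMLayer",
    "StackModel",
    "FitResult",
    "ScenarioSpec",
    "surface_plate",
    "build_flower_stack",
    "fit_pigmented_layer",
    "predict_spectra",
    "stack_spectra",
    "build_scenario",
    "saturation_metric",
]

logger = logging.getLogger(__name__)

LAMBDA_MAX_DEFAULT = 545.0  # nm, green absorption peak of the modelled pigment


@dataclass(frozen=True)
class FlowerConfig:
    """Fixed model assumptions for the four-layer corolla.

    r_surface    surface reflectance of layers 1 and 4 (wavelength
                 independent, default 0.03 as for plant cuticle facing air)
    S_u_star     scattering parameter of the unpigmented layer 3
    d_pigmented, d_unpigmented   effective layer thicknesses in micrometres,
                 used only to convert parameters to coefficients
    """

    r_surface: float = 0.03
    S_u_star: float = 0.1
    d_pigmented: float = 40.0
    d_unpigmented: float = 40.0

    def __post_init__(self):
        if not (0 <= self.r_surface < 1):
            raise InvalidParameterError(f"r_surface must be in [0, 1), got {self.r_surface}")
        if self.S_u_star < 0:
            raise InvalidParameterError(f"S_u_star must be >= 0, got {self.S_u_star}")
        if self.d_pigmented <= 0 or self.d_unpigmented <= 0:
            raise InvalidParameterError("layer thicknesses must be > 0 um")


@dataclass(frozen=True)
class SurfaceLayer:
    """Non-absorbing surface plate: t = 1 - r at every wavelength."""

    r: float

    def plate(self, n_wavelengths: int | None = None) -> PlateRT:
        if n_wavelengths is None:
            return PlateRT(self.r, 1.0 - self.r)
        r = np.full(n_wavelengths, self.r)
        return PlateRT(r, 1.0 - r)


@dataclass(frozen=True)
class KMLayer:
    """Homogeneous Kubelka-Munk layer with (possibly spectral) parameters."""

    params: KMParams

    def plate(self, n_wavelengths: int | None = None) -> PlateRT:
        return _km_plate_nan(self.params.K_star, self.params.S_star, n_wavelengths)


Layer = Union[SurfaceLayer, KMLayer]


@dataclass(frozen=True)
class StackModel:
    """Ordered top-to-bottom layer stack on a wavelength grid."""

    wavelengths: np.ndarray
    layers: tuple

    def plates(self) -> list[PlateRT]:
        n = np.asarray(self.wavelengths).size
        return [layer.plate(n) for layer in self.layers]

    def total_interior_kstar(self) -> np.ndarray:
        """Per-wavelength sum of K* over Kubelka-Munk layers."""
        return sum(
            np.broadcast_to(np.asarray(l.params.K_star, float), np.shape(self.wavelengths))
            for l in self.layers
            if isinstance(l, KMLayer)
        )

    def total_interior_sstar(self) -> np.ndarray:
        """Per-wavelength sum of S* over Kubelka-Munk layers."""
        return sum(
            np.broadcast_to(np.asarray(l.params.S_star, float), np.shape(self.wavelengths))
            for l in self.layers
            if isinstance(l, KMLayer)
        )


def _km_plate_nan(K_star, S_star, n: int | None = None) -> PlateRT:
    """km_plate_rt that lets NaN (invalid-wavelength flags) pass through."""
    K = np.asarray(K_star, dtype=float)
    S = np.asarray(S_star, dtype=float)
    if n is not None:
        K = np.broadcast_to(K, (n,)).copy()
        S = np.broadcast_to(S, (n,)).copy()
    K, S = np.broadcast_arrays(K, S)
    if K.ndim == 0:
        return km_plate_rt(KMParams(float(K), float(S)))
    valid = np.isfinite(K) & np.isfinite(S)
    r = np.full(K.shape, np.nan)
    t = np.full(K.shape, np.nan)
    if np.any(valid):
        plate = km_plate_rt(KMParams(K[valid], S[valid]))
        r[valid] = plate.r_top
        t[valid] = plate.t_down
    return PlateRT(r, t)


def surface_plate(r_surface: float, n: int | None = None) -> PlateRT:
    return SurfaceLayer(r_surface).plate(n)


def build_flower_stack(config: FlowerConfig, pigment: KMParams,
                       wavelengths=None) -> StackModel:
    """Assemble the four-layer stack for a pigmented-layer parameter spectrum."""
    if wavelengths is None:
        wavelengths = np.arange(np.asarray(pigment.K_star).size, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    layers = (
        SurfaceLayer(config.r_surface),
        KMLayer(pigment),
        KMLayer(KMParams(0.0, config.S_u_star)),
        SurfaceLayer(config.r_surface),
    )
    return StackModel(wavelengths, layers)


def stack_spectra(stack: StackModel):
    """Forward observables of a stack for both illumination sides.

    Returns (R_ad, T, R_ab) arrays.  The abaxial reflectance is computed by
    re-folding the reversed layer list (every single layer is symmetric), so
    both directions run through one code path; the transmittances of the two
    folds agree identically.
    """
    plates = stack.plates()
    fwd = combine_stack(plates)
    bwd = combine_stack(plates[::-1])
    R_ad = np.asarray(fwd.r_top, float)
    T = np.asarray(fwd.t_down, float)
    R_ab = np.asarray(bwd.r_top, float)
    return R_ad, T, R_ab


@dataclass(frozen=True)
class FitResult:
    """Per-wavelength recovered pigmented-layer quantities."""

    wavelengths: np.ndarray
    r_p: np.ndarray
    t_p: np.ndarray
    K_p_star: np.ndarray
    S_p_star: np.ndarray
    D: np.ndarray
    valid: np.ndarray
    config: FlowerConfig
    failure_counts: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def fit_pigmented_layer(R_ad: Spectrum, T_ad: Spectrum,
                        config: FlowerConfig | None = None) -> FitResult:
    """Recover the pigmented layer from adaxial stack spectra.

    Per wavelength: (i) peel the upper surface off the measured (R, T);
    (ii) solve for the symmetric middle plate against the known bottom
    sub-stack (unpigmented layer + lower surface), giving (r_p, t_p);
    (iii) invert the two-flux mapping to (K_p*, S_p*); (iv) convert K_p* to
    absorbance.  Wavelengths failing any step carry NaN and valid=False;
    they are counted per step, never silently dropped.
    """
    if config is None:
        config = FlowerConfig()
    if R_ad.kind != "reflectance" or T_ad.kind != "transmittance":
        raise InvalidParameterError("expected a reflectance and a transmittance spectrum")

    wl_R, wl_T = R_ad.wavelengths, T_ad.wavelengths
    if wl_R.shape == wl_T.shape and np.allclose(wl_R, wl_T):
        grid = wl_R
    else:
        lo = max(wl_R[0], wl_T[0])
        hi = min(wl_R[-1], wl_T[-1])
        if lo >= hi:
            raise AlignmentError("reflectance and transmittance ranges do not overlap")
        grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
        R_ad, T_ad = resample([R_ad, T_ad], grid)
    R = np.asarray(R_ad.values, float).copy()
    T = np.asarray(T_ad.values, float).copy()
    n = grid.size
    counts = {"energy": 0, "peel": 0, "solve": 0, "invert": 0}

    # energy screen: R + T must leave room for absorption or equal 1
    bad_energy = ~(np.isfinite(R) & np.isfinite(T)) | (R + T > 1 + 1e-12)
    counts["energy"] = int(bad_energy.sum())
    R[bad_energy] = np.nan
    T[bad_energy] = np.nan

    surf = surface_plate(config.r_surface, n)
    bottom = combine_stack(
        [_km_plate_nan(0.0, config.S_u_star, n), surface_plate(config.r_surface, n)]
    )

    R_rest, T_rest = peel_top(R, T, surf)
    counts["peel"] = int(np.sum(~np.isfinite(R_rest) & ~bad_energy))

    r_p, t_p = solve_symmetric_middle(R_rest, T_rest, bottom)
    counts["solve"] = int(np.sum(~np.isfinite(r_p) & np.isfinite(R_rest)))

    K_p, S_p, valid = invert_rt(r_p, t_p)
    counts["invert"] = int(np.sum(~valid & np.isfinite(r_p)))

    D = np.where(valid, np.log10(np.e) * K_p, np.nan)
    if not valid.any():
        raise FitDegenerateError(
            f"all {n} wavelengths failed the fit (per-step failures: {counts})",
            failure_counts=counts,
        )
    n_bad = n - int(valid.sum())
    if n_bad:
        logger.info("fit_pigmented_layer: %d/%d wavelengths invalid %s", n_bad, n, counts)
    return FitResult(grid, r_p, t_p, K_p, S_p, D, valid, config, counts)


def predict_spectra(fit: FitResult, config: FlowerConfig | None = None):
    """Forward-predict the four stack spectra from a fitted pigmented layer.

    Uses the fitted plate observables (r_p, t_p) directly for layer 2, so
    with the fitting config the adaxial prediction reproduces the measured
    input exactly at valid wavelengths.  Returns Spectrum objects
    (R_ad, T_ad, R_ab, T_ab); T_ad and T_ab are identical by stack symmetry.
    """
    if config is None:
        config = fit.config
    if fit.n_valid == 0:
        raise FitDegenerateError("fit has no valid wavelengths")
    n = fit.wavelengths.size
    plates = [
        surface_plate(config.r_surface, n),
        PlateRT(np.asarray(fit.r_p, float), np.asarray(fit.t_p, float)),
        _km_plate_nan(0.0, config.S_u_star, n),
        surface_plate(config.r_surface, n),
    ]
    fwd = combine_stack(plates)
    bwd = combine_stack(plates[::-1])
    wl = fit.wavelengths
    # T is side-invariant for a stack of symmetric plates, so a single
    # transmittance array serves both illumination directions exactly
    T = np.asarray(fwd.t_down, float)
    return (
        Spectrum(wl, np.asarray(fwd.r_top, float), "reflectance", "R_ad predicted"),
        Spectrum(wl, T, "transmittance", "T_ad predicted"),
        Spectrum(wl, np.asarray(bwd.r_top, float), "reflectance", "R_ab predicted"),
        Spectrum(wl, T.copy(), "transmittance", "T_ab predicted"),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One pigment-distribution scenario sharing a fixed budget of K* and S*.

    The same total pigment (K* spectrum) and total interior scattering
    (S_p* + S_u*) are arranged asymmetrically (all pigment in the adaxial
    layer), homogeneously (one pooled layer), or symmetrically (pigment and
    its scattering split equally between an adaxial and an abaxial flank).
    """

    distribution: Literal["asymmetric", "homogeneous", "symmetric"]
    K_p_star: np.ndarray
    S_p_star: float | np.ndarray = 0.5
    S_u_star: float = 0.1
    r_surface: float = 0.03
    wavelengths: np.ndarray | None = None

    def __post_init__(self):
        if self.distribution not in ("asymmetric", "homogeneous", "symmetric"):
            raise InvalidParameterError(
                f"unknown distribution {self.distribution!r}; "
                "want asymmetric | homogeneous | symmetric"
            )


def build_scenario(spec: ScenarioSpec) -> StackModel:
    """Build the layer stack for one pigment-distribution scenario."""
    K = np.asarray(spec.K_p_star, dtype=float)
    S_p = np.asarray(spec.S_p_star, dtype=float)
    wl = (np.asarray(spec.wavelengths, float) if spec.wavelengths is not None
          else np.arange(K.size, dtype=float))
    surf = SurfaceLayer(spec.r_surface)
    if spec.distribution == "asymmetric":
        interior = (
            KMLayer(KMParams(K, S_p)),
            KMLayer(KMParams(0.0, spec.S_u_star)),
        )
    elif spec.distribution == "homogeneous":
        interior = (KMLayer(KMParams(K, S_p + spec.S_u_star)),)
    else:  # symmetric
        interior = (
            KMLayer(KMParams(K / 2.0, S_p / 2.0)),
            KMLayer(KMParams(0.0, spec.S_u_star)),
            KMLayer(KMParams(K / 2.0, S_p / 2.0)),
        )
    return StackModel(wl, (surf, *interior, surf))


def saturation_metric(R: Spectrum, lambda_max: float = LAMBDA_MAX_DEFAULT) -> float:
    """Depth of the reflectance trough at the pigment peak: 1 - R(lmax)/max R.

    0 for flat spectra; approaches 1 when the absorption band removes
    essentially all reflected light at its peak wavelength.
    """
    if not (R.wavelengths[0] <= lambda_max <= R.wavelengths[-1]):
        raise AlignmentError(f"lambda_max={lambda_max} nm outside spectrum range")
    peak = float(np.nanmax(R.values))
    if peak == 0:
        return 0.0
    return 1.0 - R.at(lambda_max) / peak
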