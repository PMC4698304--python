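"""Single-layer two-flux (Kubelka-Munk) optics.

A homogeneous layer of thickness ``d`` with absorption coefficient ``K`` and
scattering coefficient ``S`` under diffuse illumination is fully described by
the dimensionless parameters ``K* = K d`` and ``S* = S d``.  The two-flux
model gives its diffuse reflectance ``r`` and transmittance ``t`` in closed
form,

    a = 1 + K*/S*,   b = sqrt(a^2 - 1),   x = b S*,
    r = sinh(x) / (a sinh(x) + b cosh(x)),
    t = b       / (a sinh(x) + b cosh(x)),

and the mapping is exactly invertible:

    a  = (1 + r^2 - t^2) / (2 r),    b = sqrt(a^2 - 1),
    S* = arccoth((1 - a r) / (b r)) / b,    K* = (a - 1) S*.

All functions here are vectorised: scalars or same-shape numpy arrays are
accepted wherever a parameter may be a spectrum.  Invalid per-wavelength
inversions (possible for noisy measured data) are returned as NaN with an
accompanying validity mask rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, UnphysicalInputError

__all__ = [
    "KMParams",
    "PlateRT",
    "km_nonabsorbing_rt",
    "km_plate_rt",
    "km_invert_rt",
    "invert_rt",
    "absorbance_from_kstar",
    "coefficients_from_parameters",
]

logger = logging.getLogger(__name__)

# x = b*S* beyond which sinh/cosh are replaced by their e^x/2 asymptote
_OVERFLOW_X = 350.0
# |negative K*| below this is rounding noise and clamped to zero
_CLAMP_TOL = 1e-9
# a <= 1 + this is treated as the non-absorbing (K*=0) branch
_NONABS_TOL = 1e-9


def _asarray(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must be finite, got {x!r}")
    return arr


@dataclass(frozen=True)
class KMParams:
    """Dimensionless Kubelka-Munk parameters of one homogeneous layer.

    ``K_star`` and ``S_star`` may be scalars or same-shape arrays (a spectrum
    of parameters).  NaN entries mark wavelengths flagged invalid during an
    inversion; negative or infinite entries are rejected.
    """

    K_star: float | np.ndarray
    S_star: float | np.ndarray
    d: float | None = None  # thickness in micrometres

    def __post_init__(self):
        for name in ("K_star", "S_star"):
            v = np.asarray(getattr(self, name), dtype=float)
            finite = v[np.isfinite(v)]
            if np.any(np.isinf(v)) or np.any(finite < 0):
                raise InvalidParameterError(
                    f"{name} must be non-negative and finite (NaN = invalid flag)"
                )
        if self.d is not None and not (np.isfinite(self.d) and self.d > 0):
            raise InvalidParameterError(f"thickness d must be > 0, got {self.d}")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of entries not flagged NaN."""
        return np.isfinite(np.asarray(self.K_star)) & np.isfinite(
            np.asarray(self.S_star)
        )


@dataclass(frozen=True)
class PlateRT:
    """Side-resolved diffuse observables of a plate or sub-stack.

    A single homogeneous layer is symmetric (``r_top == r_bottom``); a stack
    of such layers generally is not, but its transmittance never depends on
    the illuminated side, so ``t_down == t_up`` always holds for physically
    constructed stacks.  Fields may be scalars or per-wavelength arrays.
    """

    r_top: float | np.ndarray
    t_down: float | np.ndarray
    r_bottom: float | np.ndarray = None  # type: ignore[assignment]
    t_up: float | np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.r_bottom is None:
            object.__setattr__(self, "r_bottom", self.r_top)
        if self.t_up is None:
            object.__setattr__(self, "t_up", self.t_down)
        tol = 1e-9
        for name in ("r_top", "t_down", "r_bottom", "t_up"):
            v = np.asarray(getattr(self, name), dtype=float)
            ok = np.isfinite(v)
            if np.any(v[ok] < -tol) or np.any(v[ok] > 1 + tol):
                raise UnphysicalInputError(f"{name} outside [0, 1]")
        for r, t in (("r_top", "t_down"), ("r_bottom", "t_up")):
            rv = np.asarray(getattr(self, r), dtype=float)
            tv = np.asarray(getattr(self, t), dtype=float)
            ok = np.isfinite(rv) & np.isfinite(tv)
            if np.any((rv + tv)[ok] > 1 + tol):
                raise UnphysicalInputError(f"{r} + {t} exceeds 1 (energy)")

    @property
    def symmetric(self) -> bool:
        return bool(
            np.allclose(self.r_top, self.r_bottom, equal_nan=True)
            and np.allclose(self.t_down, self.t_up, equal_nan=True)
        )


#: The identity plate: transmits everything, reflects nothing.
IDENTITY_PLATE = PlateRT(r_top=0.0, t_down=1.0)


def km_nonabsorbing_rt(S_star) -> PlateRT:
    """Reflectance/transmittance of a purely scattering (K* = 0) layer.

    r = S*/(1 + S*) and t = 1/(1 + S*), so r + t = 1 exactly.
    """
    S = _asarray(S_star, "S_star")
    if np.any(S < 0):
        raise InvalidParameterError(f"S_star must be >= 0, got {S_star!r}")
    r = S / (1.0 + S)
    t = 1.0 / (1.0 + S)
    if np.ndim(S_star) == 0:
        return PlateRT(float(r), float(t))
    return PlateRT(r, t)


def km_plate_rt(params: KMParams) -> PlateRT:
    """Forward two-flux solution (K*, S*) -> symmetric (r, t).

    Handles the degenerate limits continuously: S* -> 0 gives the Beer-
    Lambert pure absorber (r = 0, t = exp(-K*)); K* -> 0 reduces to
    :func:`km_nonabsorbing_rt`; very opaque layers (b S* > 350) use the
    semi-infinite asymptote r = 1/(a + b), t = 0 to avoid sinh overflow.
    """
    K = _asarray(params.K_star, "K_star")
    S = _asarray(params.S_star, "S_star")
    if np.any(K < 0) or np.any(S < 0):
        raise InvalidParameterError("K_star and S_star must be >= 0")
    K, S = np.broadcast_arrays(K, S)
    scalar = K.ndim == 0
    K = np.atleast_1d(K).astype(float)
    S = np.atleast_1d(S).astype(float)

    r = np.empty_like(K)
    t = np.empty_like(K)

    pure_scatter = K == 0.0
    pure_absorb = (S == 0.0) & ~pure_scatter
    general = ~pure_scatter & ~pure_absorb

    r[pure_scatter] = S[pure_scatter] / (1.0 + S[pure_scatter])
    t[pure_scatter] = 1.0 / (1.0 + S[pure_scatter])

    r[pure_absorb] = 0.0
    t[pure_absorb] = np.exp(-K[pure_absorb])

    if np.any(general):
        Kg, Sg = K[general], S[general]
        a = 1.0 + Kg / Sg
        b = np.sqrt(a * a - 1.0)
        x = b * Sg
        rg = np.empty_like(Kg)
        tg = np.empty_like(Kg)
        # K*/S* below float resolution: a rounds to 1, b to 0 -> K*=0 limit
        degenerate = b == 0.0
        rg[degenerate] = Sg[degenerate] / (1.0 + Sg[degenerate])
        tg[degenerate] = 1.0 / (1.0 + Sg[degenerate])
        thick = (x > _OVERFLOW_X) & ~degenerate
        # semi-infinite layer: no light reaches the far side
        rg[thick] = 1.0 / (a[thick] + b[thick])
        tg[thick] = 0.0
        thin = ~thick & ~degenerate
        sh, ch = np.sinh(x[thin]), np.cosh(x[thin])
        denom = a[thin] * sh + b[thin] * ch
        rg[thin] = sh / denom
        tg[thin] = b[thin] / denom
        r[general] = rg
        t[general] = tg

    if scalar:
        return PlateRT(float(r[0]), float(t[0]))
    return PlateRT(r, t)


def invert_rt(r, t):
    """Vectorised inverse mapping (r, t) -> (K*, S*, valid).

    Wavelengths where the inversion is impossible (``r + t > 1``, arccoth
    argument <= 1 under noise, non-finite input) get NaN parameters and
    ``valid = False``; the count of such wavelengths is logged.  Recovered
    K* within rounding error below zero is clamped to 0.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    r, t = np.broadcast_arrays(r.copy(), t.copy())
    r, t = r.astype(float), t.astype(float)

    K = np.full_like(r, np.nan)
    S = np.full_like(r, np.nan)
    valid = (
        np.isfinite(r)
        & np.isfinite(t)
        & (r >= 0)
        & (r < 1)
        & (t > 0)
        & (t <= 1)
        & (r + t <= 1 + 1e-12)
    )

    # pure absorber: no reflection at all
    absorber = valid & (r == 0.0)
    K[absorber] = -np.log(t[absorber])
    S[absorber] = 0.0

    gen = valid & ~absorber
    if np.any(gen):
        rg, tg = r[gen], t[gen]
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (1.0 + rg * rg - tg * tg) / (2.0 * rg)
        Kg = np.full_like(rg, np.nan)
        Sg = np.full_like(rg, np.nan)

        nonabs = a <= 1.0 + _NONABS_TOL
        # K*=0 branch: b -> 0 makes the arccoth form 0/0; exact limit S* = r/t
        Sg[nonabs] = rg[nonabs] / tg[nonabs]
        Kg[nonabs] = 0.0

        g = ~nonabs
        if np.any(g):
            b = np.sqrt(a[g] * a[g] - 1.0)
            arg = (1.0 - a[g] * rg[g]) / (b * rg[g])
            ok = arg > 1.0
            S_ok = np.full_like(b, np.nan)
            K_ok = np.full_like(b, np.nan)
            # arccoth(x) = 0.5 ln((x+1)/(x-1)), x > 1
            S_ok[ok] = 0.5 * np.log((arg[ok] + 1.0) / (arg[ok] - 1.0)) / b[ok]
            K_ok[ok] = (a[g][ok] - 1.0) * S_ok[ok]
            Sg[g] = S_ok
            Kg[g] = K_ok
        K[gen] = Kg
        S[gen] = Sg

    # rounding-level negatives are clamped; anything larger stays invalid
    tiny_neg = np.isfinite(K) & (K < 0) & (K > -_CLAMP_TOL)
    K[tiny_neg] = 0.0
    tiny_neg_s = np.isfinite(S) & (S < 0) & (S > -_CLAMP_TOL)
    S[tiny_neg_s] = 0.0
    bad = np.isfinite(K) & ((K < 0) | (S < 0))
    K[bad] = np.nan
    S[bad] = np.nan

    valid &= np.isfinite(K) & np.isfinite(S)
    n_bad = int(valid.size - valid.sum())
    if n_bad:
        logger.info("invert_rt: %d of %d wavelengths flagged invalid", n_bad, valid.size)
    return K, S, valid


def km_invert_rt(plate: PlateRT) -> KMParams:
    """Invert a symmetric plate's (r, t) to its (K*, S*).

    Raises :class:`UnphysicalInputError` for r + t > 1; per-wavelength
    failures under noisy array input become NaN entries of the result.
    """
    if not plate.symmetric:
        raise InvalidParameterError("km_invert_rt requires a symmetric plate")
    r = np.asarray(plate.r_top, dtype=float)
    t = np.asarray(plate.t_down, dtype=float)
    finite = np.isfinite(r) & np.isfinite(t)
    if np.any((r + t)[finite] > 1 + 1e-12):
        raise UnphysicalInputError("r + t > 1: not a passive layer")
    K, S, _ = invert_rt(r, t)
    if r.ndim == 0:
        return KMParams(float(K[0]), float(S[0]))
    return KMParams(K, S)


def absorbance_from_kstar(K_star):
    """Decadic absorbance D = log10(e) * K* of an equivalent non-scattering layer."""
    K = _asarray(K_star, "K_star")
    if np.any(K < 0):
        raise InvalidParameterError(f"K_star must be >= 0, got {K_star!r}")
    D = np.log10(np.e) * K
    return float(D) if np.ndim(K_star) == 0 else D


def coefficients_from_parameters(params: KMParams, d: float | None = None):
    """Convert (K*, S*) to coefficients (K, S) in mm^-1 given thickness d in um.

    K = K*/d and S = S*/d; with d in micrometres the result is scaled to
    per-millimetre, the unit in which petal tissue coefficients are quoted.
    """
    if d is None:
        d = params.d
    if d is None or not (np.isfinite(d) and d > 0):
        raise InvalidParameterError(f"thickness d must be > 0 um, got {d}")
    d_mm = d / 1000.0
    K = np.asarray(params.K_star, dtype=float) / d_mm
    S = np.asarray(params.S_star, dtype=float) / d_mm
    if np.ndim(params.K_star) == 0 and np.ndim(params.S_star) == 0:
        return float(K), float(S)
    return K, S
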