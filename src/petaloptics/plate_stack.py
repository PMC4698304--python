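"""Adding equations for stacks of diffusely reflecting and transmitting plates.

Two plates with known side-resolved observables combine by summing the
infinite series of inter-plate reflections; the geometric series closes to

    T    = t1 t2 / (1 - r1_b r2_t)
    R_t  = r1_t + t1_down t1_up r2_t / (1 - r1_b r2_t)
    R_b  = r2_b + t2_up t2_down r1_b / (1 - r1_b r2_t)

Stacks are folded top-down; interference is ignored throughout (intensities
add, never amplitudes), which is the premise of the diffuse two-flux picture.
The module also provides the exact algebraic inverses used to strip known
layers off measured stack observables: :func:`peel_top` removes a known top
plate, and :func:`solve_symmetric_middle` solves for an unknown symmetric
plate sitting on a known bottom sub-stack.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, SingularLayerError, UnphysicalInputError
from .kubelka_munk import IDENTITY_PLATE, PlateRT

__all__ = [
    "combine_two",
    "combine_stack",
    "peel_top",
    "solve_symmetric_middle",
    "series_oracle",
    "IDENTITY_PLATE",
]


def combine_two(top: PlateRT, bottom: PlateRT) -> PlateRT:
    """Combine two plates (or sub-stacks) into one equivalent plate."""
    r1t, t1d = np.asarray(top.r_top, float), np.asarray(top.t_down, float)
    r1b, t1u = np.asarray(top.r_bottom, float), np.asarray(top.t_up, float)
    r2t, t2d = np.asarray(bottom.r_top, float), np.asarray(bottom.t_down, float)
    r2b, t2u = np.asarray(bottom.r_bottom, float), np.asarray(bottom.t_up, float)

    denom = 1.0 - r1b * r2t
    finite = np.isfinite(denom)
    if np.any(denom[finite] <= 0):
        raise UnphysicalInputError("inter-plate reflection product r1_b*r2_t >= 1")

    t_down = t1d * t2d / denom
    t_up = t2u * t1u / denom
    r_top = r1t + t1d * t1u * r2t / denom
    r_bottom = r2b + t2u * t2d * r1b / denom

    if all(np.ndim(v) == 0 for v in (r_top, t_down, r_bottom, t_up)):
        return PlateRT(float(r_top), float(t_down), float(r_bottom), float(t_up))
    return PlateRT(r_top, t_down, r_bottom, t_up)


def combine_stack(layers: Sequence[PlateRT]) -> PlateRT:
    """Left-fold of :func:`combine_two` over an ordered top-to-bottom stack."""
    if len(layers) == 0:
        raise InvalidParameterError("combine_stack requires at least one layer")
    out = layers[0]
    for layer in layers[1:]:
        out = combine_two(out, layer)
    return out


def peel_top(total_R, total_T, top: PlateRT):
    """Remove a known symmetric top plate from measured stack observables.

    Given the whole stack's top-illumination (R, T) and the top plate's
    (r1, t1), returns the observables (R_rest, T_rest) the remaining
    sub-stack would show, such that re-adding the top plate reproduces the
    inputs exactly.  Wavelengths where the recovered R_rest leaves [0, 1)
    (noise-inconsistent data) come back as NaN.
    """
    if not top.symmetric:
        raise InvalidParameterError("peel_top requires a symmetric top plate")
    r1 = np.asarray(top.r_top, float)
    t1 = np.asarray(top.t_down, float)
    if np.any(t1 == 0):
        raise SingularLayerError("cannot peel an opaque top plate (t1 = 0)")
    R = np.asarray(total_R, float)
    T = np.asarray(total_T, float)

    with np.errstate(invalid="ignore", divide="ignore"):
        R_rest = (R - r1) / (t1 * t1 + r1 * (R - r1))
        T_rest = T * (1.0 - r1 * R_rest) / t1

    scalar = all(np.ndim(v) == 0 for v in (R, T, r1))
    R_rest = np.atleast_1d(R_rest).astype(float)
    T_rest = np.atleast_1d(T_rest).astype(float)
    bad = ~(np.isfinite(R_rest) & (R_rest >= -1e-12) & (R_rest < 1.0))
    R_rest[bad] = np.nan
    T_rest[bad] = np.nan
    np.clip(R_rest, 0.0, None, out=R_rest)
    if scalar:
        return float(R_rest[0]), float(T_rest[0])
    return R_rest, T_rest


def solve_symmetric_middle(R_rest, T_rest, bottom: PlateRT):
    """Solve for the symmetric plate sitting on a known bottom sub-stack.

    ``(R_rest, T_rest)`` are the top-illumination observables of the
    (middle + bottom) combination; ``bottom`` supplies its top-illumination
    observables (R_B, T_B).  The adding equations close to

        tau = T_rest / T_B
        r = (R_rest - tau^2 R_B) / (1 - (tau R_B)^2)
        t = T_rest (1 - r R_B) / T_B

    Recovered (r, t) outside the physical region are flagged NaN rather
    than raised, since they arise from measurement noise.
    """
    R_B = np.asarray(bottom.r_top, float)
    T_B = np.asarray(bottom.t_down, float)
    if np.any(T_B == 0):
        raise SingularLayerError("bottom sub-stack is opaque (T_B = 0)")
    R = np.asarray(R_rest, float)
    T = np.asarray(T_rest, float)

    with np.errstate(invalid="ignore", divide="ignore"):
        tau = T / T_B
        r = (R - tau * tau * R_B) / (1.0 - (tau * R_B) ** 2)
        t = T * (1.0 - r * R_B) / T_B

    scalar = all(np.ndim(v) == 0 for v in (R, T, R_B, T_B))
    r = np.atleast_1d(r).astype(float)
    t = np.atleast_1d(t).astype(float)
    tol = 1e-9
    bad = ~(
        np.isfinite(r)
        & np.isfinite(t)
        & (r >= -tol)
        & (t >= -tol)
        & (r <= 1 + tol)
        & (t <= 1 + tol)
        & (r + t <= 1 + tol)
    )
    r[bad] = np.nan
    t[bad] = np.nan
    np.clip(r, 0.0, 1.0, out=r)
    np.clip(t, 0.0, 1.0, out=t)
    if scalar:
        return float(r[0]), float(t[0])
    return r, t


def series_oracle(top: PlateRT, bottom: PlateRT, tol: float = 1e-14,
                  max_bounces: int = 100_000) -> PlateRT:
    """Combine two plates by explicit bounce-by-bounce summation.

    Sums the multiple-reflection geometric series until every increment
    falls below ``tol``.  Exists as an independent cross-check of
    :func:`combine_two`; it is never the production path.
    """
    r1t, t1d = np.asarray(top.r_top, float), np.asarray(top.t_down, float)
    r1b, t1u = np.asarray(top.r_bottom, float), np.asarray(top.t_up, float)
    r2t, t2d = np.asarray(bottom.r_top, float), np.asarray(bottom.t_down, float)
    r2b, t2u = np.asarray(bottom.r_bottom, float), np.asarray(bottom.t_up, float)

    q = r1b * r2t  # per-bounce attenuation inside the gap
    if np.any(np.atleast_1d(q) >= 1):
        raise UnphysicalInputError("bounce series diverges: r1_b*r2_t >= 1")

    T = np.zeros_like(np.asarray(q, float) * t1d)
    Rt = np.array(r1t, float).copy()
    Rb = np.array(r2b, float).copy()
    Tu = np.zeros_like(T)
    gain = np.ones_like(np.asarray(q, float))
    for _ in range(max_bounces):
        dT = t1d * gain * t2d
        dRt = t1d * gain * r2t * t1u
        dRb = t2u * gain * r1b * t2d
        dTu = t2u * gain * t1u
        T = T + dT
        Rt = Rt + dRt
        Rb = Rb + dRb
        Tu = Tu + dTu
        gain = gain * q
        if np.all(np.atleast_1d(np.abs(dT) + np.abs(dRt)) < tol):
            break
    else:
        raise RuntimeError("series_oracle did not converge within bounce cap")

    if all(np.ndim(v) == 0 for v in (r1t, r2t)):
        return PlateRT(float(Rt), float(T), float(Rb), float(Tu))
    return PlateRT(Rt, T, Rb, Tu)
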