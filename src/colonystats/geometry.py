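"""Sphero-cylinder (capsule) morphometrics.

Rod-shaped bacteria are approximated as capsules: a cylinder of diameter
``w`` capped by two hemispheres, total tip-to-tip length ``L``.  Image
segmentation yields the projected (silhouette) area ``A_p`` and the length
``L``; the width is recovered by inverting the capsule projected-area
formula

    A_p = w (L - w) + pi (w/2)^2

after which surface area and volume follow in closed form

    A = pi L w,
    V = pi (L - w) (w/2)^2 + (4/3) pi (w/2)^3 = pi L w^2 / 4 - pi w^3 / 12.

Both reduce to the sphere (diameter ``w``) at ``L = w``.

The module also provides first-order (delta-method) propagation of squared
coefficients of variation from (L, w) to any derived dimension, and
log-log power-law scaling fits of a dimension against length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CellShape",
    "NoiseBudget",
    "ScalingFit",
    "ShapeInferenceError",
    "projected_area",
    "infer_width",
    "surface_area",
    "volume",
    "shape_from_segmentation",
    "propagate_cv",
    "noise_budget",
    "fit_power_law",
]

_QUAD_A = np.pi / 4.0 - 1.0  # quadratic coefficient of the width equation; negative


class ShapeInferenceError(ValueError):
    """No capsule width in (0, L] is consistent with the observed (A_p, L)."""

    def __init__(self, projected_area_Ap: float, length_L: float, reason: str = ""):
        self.projected_area_Ap = projected_area_Ap
        self.length_L = length_L
        msg = (
            f"cannot infer a capsule width from A_p={projected_area_Ap!r}, "
            f"L={length_L!r}"
        )
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


@dataclass(frozen=True)
class CellShape:
    """Capsule dimensions of one cell at one frame (lengths in µm)."""

    length_L: float
    width_w: float
    projected_area_Ap: float
    surface_area_A: float
    volume_V: float


@dataclass(frozen=True)
class NoiseBudget:
    """Squared CVs of the cell dimensions, all dimensionless and >= 0."""

    cv2_L: float
    cv2_w: float
    cv2_A: float
    cv2_V: float


@dataclass(frozen=True)
class ScalingFit:
    """Power law ``F = prefactor * L**exponent`` fitted in log-log space."""

    exponent: float
    prefactor: float
    r_squared: float


def _check_dims(length_L: float, width_w: float) -> None:
    if not (length_L > 0 and width_w > 0):
        raise ValueError(f"dimensions must be positive, got L={length_L}, w={width_w}")
    if width_w > length_L * (1 + 1e-12):
        raise ValueError(f"width {width_w} exceeds length {length_L}")


def projected_area(length_L: float, width_w: float) -> float:
    """Silhouette area of a capsule: rectangle w·(L−w) plus a disc of diameter w."""
    _check_dims(length_L, width_w)
    return width_w * (length_L - width_w) + np.pi * (width_w / 2.0) ** 2


def surface_area(length_L: float, width_w: float) -> float:
    """Capsule surface area A = πLw (cylinder πw(L−w) plus sphere πw²)."""
    _check_dims(length_L, width_w)
    return np.pi * length_L * width_w


def volume(length_L: float, width_w: float) -> float:
    """Capsule volume πLw²/4 − πw³/12 (cylinder plus two hemispherical caps)."""
    _check_dims(length_L, width_w)
    return np.pi * length_L * width_w**2 / 4.0 - np.pi * width_w**3 / 12.0


def infer_width(projected_area_Ap: float, length_L: float) -> float:
    """Invert the capsule projected-area formula for the width.

    Solves ``(π/4 − 1)·w² + L·w − A_p = 0`` and returns the unique root in
    ``(0, L]``.  The quadratic coefficient is negative, so the parabola opens
    downward and has at most one root in that interval; it exists iff
    ``0 < A_p <= π L²/4`` (the disc of diameter L being the widest capsule of
    length L).

    Raises
    ------
    ShapeInferenceError
        If no admissible root exists, e.g. ``A_p`` larger than the circular
        limit or nonpositive inputs.
    """
    if not np.isfinite(projected_area_Ap) or not np.isfinite(length_L):
        raise ShapeInferenceError(projected_area_Ap, length_L, "non-finite input")
    if length_L <= 0 or projected_area_Ap <= 0:
        raise ShapeInferenceError(projected_area_Ap, length_L, "nonpositive input")
    a, b, c = _QUAD_A, length_L, -projected_area_Ap
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ShapeInferenceError(projected_area_Ap, length_L, "no real root")
    sq = np.sqrt(disc)
    # a < 0: the root on the increasing branch of the (downward) parabola is
    # (-b + sq) / (2a); it is the smaller of the two and the one in (0, L].
    w = (-b + sq) / (2.0 * a)
    tol = 1e-9 * length_L
    if not (0.0 < w <= length_L + tol):
        raise ShapeInferenceError(
            projected_area_Ap, length_L, f"root w={w} outside (0, L]"
        )
    return min(w, length_L)


def shape_from_segmentation(projected_area_Ap: float, length_L: float) -> CellShape:
    """Full capsule morphometrics of one segmented cell from (A_p, L)."""
    w = infer_width(projected_area_Ap, length_L)
    return CellShape(
        length_L=length_L,
        width_w=w,
        projected_area_Ap=projected_area_Ap,
        surface_area_A=surface_area(length_L, w),
        volume_V=volume(length_L, w),
    )


# ---------------------------------------------------------------------------
# delta-method noise propagation


def _partials(dimension: str, L: float, w: float) -> tuple[float, float, float]:
    """(F, dF/dL, dF/dw) evaluated at the means for a named dimension."""
    if dimension == "A":
        return np.pi * L * w, np.pi * w, np.pi * L
    if dimension == "V_simplified":
        F = np.pi * L * w**2 / 4.0
        return F, np.pi * w**2 / 4.0, np.pi * L * w / 2.0
    if dimension == "V":
        F = np.pi * L * w**2 / 4.0 - np.pi * w**3 / 12.0
        return F, np.pi * w**2 / 4.0, np.pi * L * w / 2.0 - np.pi * w**2 / 4.0
    if dimension == "Ap":
        F = w * (L - w) + np.pi * (w / 2.0) ** 2
        return F, w, L - 2.0 * w + np.pi * w / 2.0
    if dimension == "L":
        return L, 1.0, 0.0
    if dimension == "w":
        return w, 0.0, 1.0
    raise ValueError(f"unknown dimension {dimension!r}")


def propagate_cv(
    dimension: str | Callable[[float, float], float],
    mean_L: float,
    mean_w: float,
    cv2_L: float,
    cv2_w: float,
) -> float:
    """First-order squared CV of a dimension F(L, w) from CVs of L and w.

    L and w are treated as independent, so

        CV_F² ≈ CV_w² · (w ∂F/∂w / F)² + CV_L² · (L ∂F/∂L / F)²

    evaluated at the means.  For ``dimension="A"`` (surface area πLw) this is
    exactly ``cv2_w + cv2_L``; for ``"V_simplified"`` (πLw²/4) exactly
    ``4·cv2_w + cv2_L``; ``"V"`` uses the full capsule partials; ``"Ap"`` the
    projected area.  A callable ``F(L, w)`` is differentiated numerically.
    """
    if mean_L <= 0 or mean_w <= 0:
        raise ValueError("means must be positive")
    if cv2_L < 0 or cv2_w < 0:
        raise ValueError("squared CVs must be nonnegative")
    if callable(dimension):
        F = dimension(mean_L, mean_w)
        hL = 1e-6 * mean_L
        hw = 1e-6 * mean_w
        dFdL = (dimension(mean_L + hL, mean_w) - dimension(mean_L - hL, mean_w)) / (2 * hL)
        dFdw = (dimension(mean_L, mean_w + hw) - dimension(mean_L, mean_w - hw)) / (2 * hw)
    else:
        F, dFdL, dFdw = _partials(dimension, mean_L, mean_w)
    if F == 0:
        raise ValueError("dimension evaluates to zero at the means")
    return cv2_w * (mean_w * dFdw / F) ** 2 + cv2_L * (mean_L * dFdL / F) ** 2


def noise_budget(mean_L: float, mean_w: float, cv2_L: float, cv2_w: float) -> NoiseBudget:
    """Propagated noise of all dimensions; satisfies CV_L² ≤ CV_A² ≤ CV_V²."""
    return NoiseBudget(
        cv2_L=cv2_L,
        cv2_w=cv2_w,
        cv2_A=propagate_cv("A", mean_L, mean_w, cv2_L, cv2_w),
        cv2_V=propagate_cv("V", mean_L, mean_w, cv2_L, cv2_w),
    )


def fit_power_law(
    lengths: Sequence[float], dimension_values: Sequence[float]
) -> ScalingFit:
    """Least-squares power law of a dimension against length in log-log space.

    Fits ``log F = exponent · log L + log prefactor`` by OLS and reports R²
    of the log-log regression.
    """
    L = np.asarray(lengths, dtype=float)
    F = np.asarray(dimension_values, dtype=float)
    if L.shape != F.shape or L.ndim != 1:
        raise ValueError("lengths and dimension_values must be 1-D of equal length")
    if L.size < 3:
        raise ValueError(f"need at least 3 points, got {L.size}")
    if np.any(L <= 0) or np.any(F <= 0):
        raise ValueError("power-law fitting requires strictly positive data")
    x, y = np.log(L), np.log(F)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ScalingFit(exponent=float(slope), prefactor=float(np.exp(intercept)), r_squared=r2)
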