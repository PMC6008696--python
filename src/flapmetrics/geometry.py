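"""Closed-form reference areas for idealized skulls and craniectomy defects.

The skull is idealized as a sphere of radius ``R`` and the craniectomy defect
as an angular patch on it: azimuthal half-angle ``theta`` (so the defect spans
an azimuth of 2θ) and a polar-angle band [polar_lo, polar_hi] measured from
the +z (axial) axis.  The exact outer-surface area of such a patch,

    S = R² · 2θ · (cos polar_lo − cos polar_hi),

is the ground-truth oracle against which the voxel-based estimators are
validated.  The module also provides the two prior-literature estimators for
craniectomy area (spherical-cap and ellipse-base formulas) and the chord
lengths A, C, C′ that the manual length-times-height (AC) product uses.

Lengths are millimetres; returned areas are cm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .core import FlapMetricsError

__all__ = [
    "DomePatch",
    "spherical_cap_area",
    "ellipse_base_area",
    "dome_patch_outer_area",
    "dome_patch_outer_area_quadrature",
    "chord_lengths",
]

MM2_PER_CM2 = 100.0


@dataclass(frozen=True)
class DomePatch:
    """Angular patch on a sphere of radius ``R_mm``.

    ``theta_rad`` is the azimuthal half-angle (defect azimuth = 2θ);
    ``polar_lo_rad`` / ``polar_hi_rad`` bound the polar extent (from +z).
    """

    R_mm: float
    theta_rad: float
    polar_lo_rad: float
    polar_hi_rad: float

    def __post_init__(self) -> None:
        if self.R_mm <= 0:
            raise FlapMetricsError(f"sphere radius must be positive, got {self.R_mm}")
        if not (0 < self.theta_rad <= np.pi):
            raise FlapMetricsError(f"theta must lie in (0, pi], got {self.theta_rad}")
        if not (0 <= self.polar_lo_rad < self.polar_hi_rad <= np.pi):
            raise FlapMetricsError(
                f"polar bounds must satisfy 0 <= lo < hi <= pi, got "
                f"({self.polar_lo_rad}, {self.polar_hi_rad})"
            )

    @property
    def polar_extent_rad(self) -> float:
        return self.polar_hi_rad - self.polar_lo_rad


def spherical_cap_area(d_mm: float, h_mm: float) -> float:
    """Spherical-cap estimate π[(d/2)² + h²] of the craniectomy surface, in cm².

    ``d`` is the anteroposterior defect diameter and ``h`` the largest height
    of the cap above that diameter.
    """
    if d_mm < 0 or h_mm < 0:
        raise FlapMetricsError("cap diameter and height must be nonnegative")
    return float(np.pi * ((d_mm / 2.0) ** 2 + h_mm**2) / MM2_PER_CM2)


def ellipse_base_area(d_mm: float, D_mm: float) -> float:
    """Elliptical base-area estimate (π/4)·d·D, in cm²."""
    if d_mm < 0 or D_mm < 0:
        raise FlapMetricsError("ellipse diameters must be nonnegative")
    return float(np.pi / 4.0 * d_mm * D_mm / MM2_PER_CM2)


def dome_patch_outer_area(patch: DomePatch) -> float:
    """Exact outer-surface area of an angular sphere patch, in cm².

    Integral of the surface element R² sinφ dφ da over azimuth width 2θ and
    the polar band, which evaluates to R²·2θ·(cos lo − cos hi).
    """
    area_mm2 = (
        patch.R_mm**2
        * 2.0
        * patch.theta_rad
        * (np.cos(patch.polar_lo_rad) - np.cos(patch.polar_hi_rad))
    )
    return float(area_mm2 / MM2_PER_CM2)


def dome_patch_outer_area_quadrature(patch: DomePatch) -> float:
    """Adaptive 2-D quadrature of the surface element; independent slow oracle."""
    val, _ = integrate.dblquad(
        lambda phi, _a: patch.R_mm**2 * np.sin(phi),
        -patch.theta_rad,
        patch.theta_rad,
        patch.polar_lo_rad,
        patch.polar_hi_rad,
    )
    return float(val / MM2_PER_CM2)


def chord_lengths(patch: DomePatch) -> tuple[float, float, float]:
    """Chords (A, C, C′) of a dome patch, in mm.

    A  — straight-line span of the azimuthal width 2θ measured on the patch's
         widest polar ring (the ring closest to the equator): 2·R·sinφ*·sinθ.
    C  — axial height extent R·(cos lo − cos hi); this is what summing slice
         spacings over the defect measures.
    C′ — great-circle chord of the polar extent, 2R·sin((hi − lo)/2); the
         true base diameter of the defect in the coronal plane.
    """
    lo, hi = patch.polar_lo_rad, patch.polar_hi_rad
    if lo <= np.pi / 2 <= hi:
        sin_star = 1.0
    else:
        sin_star = max(np.sin(lo), np.sin(hi))
    A = 2.0 * patch.R_mm * sin_star * np.sin(min(patch.theta_rad, np.pi / 2))
    C = patch.R_mm * (np.cos(lo) - np.cos(hi))
    C_prime = 2.0 * patch.R_mm * np.sin((hi - lo) / 2.0)
    return float(A), float(C), float(C_prime)
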