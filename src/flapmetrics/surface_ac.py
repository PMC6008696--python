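"""The AC method: craniectomy area = greatest axial defect length × height.

This automates the bedside measurement a clinician makes on axial CT slices:
A is the longest in-plane straight-line span of the defect, measured between
the outer-table corners on the slice where the defect is widest; C is the
number of axial slices showing a full-thickness defect multiplied by the
slice spacing.  The product A·C approximates the outer-surface area of the
removed flap for the lateral, moderately curved defects it was designed for.

The outer table is approximated by the radially outermost flap voxels per
in-plane angular bin around the skull centre; "full thickness" is checked
against the pre-operative skull: a slice counts only if some angular sector
of its bone annulus was removed entirely, not merely drilled partway through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import AreaEstimate, FlapMetricsError, VoxelMask

__all__ = [
    "ACMeasurement",
    "slice_defect_length",
    "craniectomy_A",
    "craniectomy_C",
    "ac_area",
]

_N_ANGLE_BINS = 720


@dataclass(frozen=True)
class ACMeasurement:
    """The two lengths (cm) behind the AC product, with provenance."""

    A_cm: float
    C_cm: float
    slice_index_of_A: int
    n_slices: int

    @property
    def area_cm2(self) -> float:
        return self.A_cm * self.C_cm


def _outer_voxels_in_slice(
    flap: VoxelMask, z_index: int, center_xy_mm: np.ndarray
) -> np.ndarray:
    """In-plane mm coordinates of the radially outermost flap voxels at a slice."""
    sl = flap.grid[:, :, z_index]
    ij = np.argwhere(sl)
    if len(ij) == 0:
        return np.empty((0, 2))
    xy = np.asarray(flap.origin_mm[:2]) + ij * np.asarray(flap.spacing_mm[:2])
    rel = xy - center_xy_mm
    radius = np.hypot(rel[:, 0], rel[:, 1])
    angle = np.arctan2(rel[:, 1], rel[:, 0])
    bins = ((angle + np.pi) / (2 * np.pi) * _N_ANGLE_BINS).astype(int) % _N_ANGLE_BINS
    order = np.lexsort((radius, bins))
    b_sorted = bins[order]
    last_of_bin = np.r_[b_sorted[1:] != b_sorted[:-1], True]
    return xy[order[last_of_bin]]


def slice_defect_length(
    flap: VoxelMask, z_index: int, center_mm: np.ndarray | None = None
) -> float:
    """Greatest in-plane span (cm) of the defect's outer table at one slice.

    ``center_mm`` locates the skull centre used to pick the outer-table voxel
    per angular bin; the flap centroid is the fallback when no pre-operative
    mask is at hand.  Empty slices measure zero.
    """
    if not (0 <= z_index < flap.shape[2]):
        raise FlapMetricsError(f"slice index {z_index} out of range")
    if not flap.grid[:, :, z_index].any():
        return 0.0
    if center_mm is None:
        center_xy = flap.centroid_mm()[:2]
    else:
        center_xy = np.asarray(center_mm, dtype=float)[:2]
    outer = _outer_voxels_in_slice(flap, z_index, center_xy)
    if len(outer) < 2:
        return 0.0
    return float(pdist(outer).max()) / 10.0


def craniectomy_A(
    flap: VoxelMask, center_mm: np.ndarray | None = None
) -> tuple[float, int]:
    """Greatest axial defect length A (cm) and the slice where it occurs."""
    if flap.is_empty():
        raise FlapMetricsError("empty flap has no defect length")
    if center_mm is None:
        center_mm = flap.centroid_mm()
    best, best_z = 0.0, 0
    lo, hi = flap.bounding_box()
    for z in range(lo[2], hi[2] + 1):
        length = slice_defect_length(flap, z, center_mm)
        if length > best:
            best, best_z = length, z
    return best, best_z


def craniectomy_C(flap: VoxelMask, pre_bone: VoxelMask | None = None) -> float:
    """Craniectomy height C (cm): full-thickness slice count × slice spacing.

    With a pre-operative skull available, a slice counts only when some
    angular sector of its bone annulus (around the pre-op skull centroid) is
    entirely inside the flap — the defect goes through the full skull
    thickness there.  Without it, every slice containing flap voxels counts.
    """
    if flap.is_empty():
        raise FlapMetricsError("empty flap has no height")
    dz_cm = flap.spacing_mm[2] / 10.0
    if pre_bone is None:
        n = int(flap.grid.any(axis=(0, 1)).sum())
        return n * dz_cm
    if pre_bone.shape != flap.shape or pre_bone.spacing_mm != flap.spacing_mm:
        raise FlapMetricsError("flap and pre-operative mask must share a grid")
    center_xy = pre_bone.centroid_mm()[:2]
    sp = np.asarray(flap.spacing_mm[:2])
    org = np.asarray(flap.origin_mm[:2])
    n = 0
    lo, hi = flap.bounding_box()
    for z in range(lo[2], hi[2] + 1):
        pre_sl = pre_bone.grid[:, :, z]
        ij = np.argwhere(pre_sl)
        if len(ij) == 0:
            continue
        xy = org + ij * sp
        rel = xy - center_xy
        angle = np.arctan2(rel[:, 1], rel[:, 0])
        bins = ((angle + np.pi) / (2 * np.pi) * _N_ANGLE_BINS).astype(int) % _N_ANGLE_BINS
        in_flap = flap.grid[ij[:, 0], ij[:, 1], z]
        bone_per_bin = np.bincount(bins, minlength=_N_ANGLE_BINS)
        spared_per_bin = np.bincount(bins, weights=(~in_flap).astype(float), minlength=_N_ANGLE_BINS)
        if np.any((bone_per_bin > 0) & (spared_per_bin == 0)):
            n += 1
    return n * dz_cm


def ac_area(flap: VoxelMask, pre_bone: VoxelMask) -> AreaEstimate:
    """AC surface-area estimate Sac = A × C, in cm², with full measurement metadata."""
    if flap.is_empty():
        raise FlapMetricsError("empty flap")
    center = pre_bone.centroid_mm()
    A_cm, z_A = craniectomy_A(flap, center)
    C_cm = craniectomy_C(flap, pre_bone)
    n_slices = int(flap.grid.any(axis=(0, 1)).sum())
    m = ACMeasurement(A_cm=A_cm, C_cm=C_cm, slice_index_of_A=z_A, n_slices=n_slices)
    return AreaEstimate(
        method="ac",
        area_cm2=m.area_cm2,
        metadata={
            "A_cm": m.A_cm,
            "C_cm": m.C_cm,
            "slice_index_of_A": m.slice_index_of_A,
            "n_slices": m.n_slices,
        },
    )
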