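"""Synthetic skull phantoms with analytically known craniectomy areas.

A phantom skull is a spherical shell digitized onto a voxel grid by the
centre-point rule (a voxel belongs to the shell iff its centre satisfies
r_inner <= ||x - centre|| <= r_outer).  A craniectomy is simulated by removing
a full-thickness angular patch — azimuth width 2θ, polar band [lo, hi] — whose
outer-surface area is known in closed form (:func:`geometry.dome_patch_outer_area`).
Every downstream stage (extraction, the three area estimators, the agreement
statistics) is therefore testable without patient data.

Cohort generation emulates the clinical study population: craniectomy outer
areas drawn uniformly over a configurable range (the reported cohort spanned
9.46–205.32 cm²), axial slices thicker than the in-plane spacing, optional
rigid pre/post misalignment and boundary salt noise standing in for metal
artifacts.  Misaligned post-operative masks are digitized directly from the
rigidly moved analytic geometry — a genuine second acquisition in a different
head pose — rather than by resampling the aligned mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import geometry
from .core import FlapMetricsError, VoxelMask
from .flap_extraction import RigidTransform, apply_transform

__all__ = [
    "ShellSpec",
    "PatchSpec",
    "CohortSpec",
    "PhantomCase",
    "make_skull_shell",
    "remove_patch",
    "perturb_rigid",
    "add_artifacts",
    "simulate_cohort",
    "patch_series",
    "write_case",
    "write_cohort",
]

# Patch-sampling regime for cohort emulation.  The azimuthal half-angle is
# capped well below pi/2 and the polar band kept near the equator so that the
# length-times-height product remains a meaningful estimator, as it is for
# lateral craniectomies on real, locally rather flat skulls.
_THETA_MIN = 0.01
_THETA_MAX = 0.8
_EXTENT_RANGE = (0.8, 1.3)
_POLAR_MID_JITTER = 0.15
_MAX_DRAWS = 1000


#: Skull-base fiducial bumps (polar, azimuth, relative size): coarse stand-ins
#: for the mastoid processes and occipital protuberance.  A perfect spherical
#: shell is rotationally symmetric, so a pose between two scans would be
#: unrecoverable from bone overlap alone; real skulls are asymmetric, and
#: these three features restore that identifiability.  Distinct polar angles,
#: uneven azimuth gaps and distinct sizes leave no approximate rotational
#: self-symmetry; all three sit far below any craniectomy patch the cohort
#: sampler can place.
_FIDUCIAL_ANGLES = ((2.75, 0.4, 1.0), (2.55, 2.0, 0.7), (2.9, 4.6, 1.3))


@dataclass(frozen=True)
class ShellSpec:
    """Digitized spherical-shell skull: outer radius, thickness, grid.

    ``fiducial_radius_mm`` > 0 adds three solid skull-base bumps (see
    :data:`_FIDUCIAL_ANGLES`); zero keeps the analytically pure sphere.
    """

    outer_radius_mm: float
    thickness_mm: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (192, 192, 192)
    center_mm: tuple[float, float, float] | None = None
    fiducial_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.outer_radius_mm <= 0:
            raise FlapMetricsError("outer radius must be positive")
        if not (0 < self.thickness_mm <= self.outer_radius_mm):
            raise FlapMetricsError("thickness must be positive and at most the outer radius")
        if any(s <= 0 for s in self.spacing_mm):
            raise FlapMetricsError("spacing must be positive")
        if self.thickness_mm < 2.0 * max(self.spacing_mm):
            raise FlapMetricsError(
                "shell thickness must be at least twice the largest voxel spacing "
                "to stay watertight after digitization"
            )
        if any(n < 4 for n in self.grid_shape):
            raise FlapMetricsError("grid too small")
        c = np.asarray(self.center)
        hi = (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)
        margin = 2.0 * np.asarray(self.spacing_mm)
        reach = self.outer_radius_mm + max(1.3 * self.fiducial_radius_mm, 0.0)
        if np.any(c - reach < margin) or np.any(c + reach > hi - margin):
            raise FlapMetricsError(
                "shell exceeds grid bounds: the sphere must fit with a 2-voxel margin"
            )

    @property
    def center(self) -> tuple[float, float, float]:
        if self.center_mm is not None:
            return self.center_mm
        return tuple(
            (n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
        )

    @property
    def inner_radius_mm(self) -> float:
        return self.outer_radius_mm - self.thickness_mm

    def fiducials_mm(self) -> list[tuple[np.ndarray, float]]:
        """Absolute (centre, radius) of each skull-base fiducial bump."""
        if self.fiducial_radius_mm <= 0:
            return []
        R = self.outer_radius_mm
        out = []
        for pol, az, scale in _FIDUCIAL_ANGLES:
            c = np.asarray(
                [
                    R * np.sin(pol) * np.cos(az),
                    R * np.sin(pol) * np.sin(az),
                    R * np.cos(pol),
                ]
            ) + np.asarray(self.center)
            out.append((c, scale * self.fiducial_radius_mm))
        return out


@dataclass(frozen=True)
class PatchSpec:
    """Angular extent of the removed (craniectomy) patch."""

    azimuth_center_rad: float
    azimuth_halfwidth_rad: float
    polar_min_rad: float
    polar_max_rad: float

    def __post_init__(self) -> None:
        if not (0 < self.azimuth_halfwidth_rad < np.pi):
            raise FlapMetricsError("azimuth halfwidth must lie in (0, pi)")
        if not (0 <= self.polar_min_rad < self.polar_max_rad <= np.pi):
            raise FlapMetricsError("polar bounds must satisfy 0 <= min < max <= pi")

    def to_dome(self, R_mm: float) -> geometry.DomePatch:
        return geometry.DomePatch(
            R_mm, self.azimuth_halfwidth_rad, self.polar_min_rad, self.polar_max_rad
        )


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort emulation parameters.

    Defaults reproduce the clinical regime: 5 mm axial slices over 1.5 mm
    in-plane spacing, a 110 mm lateral skull-curvature radius with a 10 mm
    shell (twice the axial spacing, the watertightness floor), and craniectomy
    outer areas uniform over the reported 9.46–205.32 cm² range.
    """

    n_cases: int
    area_range_cm2: tuple[float, float] = (9.46, 205.32)
    seed: int = 0
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 5.0)
    misalignment: tuple[float, float] | None = None  # (max |rotation| deg, max |translation| mm)
    artifact_severity: float = 0.0
    outer_radius_mm: float = 110.0
    thickness_mm: float = 10.0
    fiducial_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise FlapMetricsError("cohort needs at least one case")
        low, high = self.area_range_cm2
        if not (0 < low < high):
            raise FlapMetricsError("area range must satisfy 0 < low < high")
        if not (0 <= self.artifact_severity <= 1):
            raise FlapMetricsError("artifact severity must lie in [0, 1]")

    def shell_spec(self) -> ShellSpec:
        reach = self.outer_radius_mm + max(self.thickness_mm, 1.3 * self.fiducial_radius_mm)
        shape = tuple(
            int(np.ceil((2.0 * reach + 8.0 * s) / s)) for s in self.spacing_mm
        )
        return ShellSpec(
            self.outer_radius_mm,
            self.thickness_mm,
            self.spacing_mm,
            shape,
            fiducial_radius_mm=self.fiducial_radius_mm,
        )


@dataclass
class PhantomCase:
    """One synthetic pre/post pair with complete ground truth."""

    case_id: str
    pre_mask: VoxelMask
    post_mask: VoxelMask
    true_flap: VoxelMask
    true_outer_area_cm2: float
    patch_spec: PatchSpec
    shell_spec: ShellSpec
    applied_transform: RigidTransform | None = None


# ---------------------------------------------------------------------------
# shell digitization


def _voxel_coordinate_axes(spec: ShellSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = spec.center
    return tuple(
        (np.arange(n, dtype=np.float32) * s - cc).astype(np.float32)
        for n, s, cc in zip(spec.grid_shape, spec.spacing_mm, c)
    )  # type: ignore[return-value]


def make_skull_shell(spec: ShellSpec) -> VoxelMask:
    """Digitize the spherical shell (plus any fiducial bumps) by the voxel-centre rule."""
    x, y, z = _voxel_coordinate_axes(spec)
    r2 = (
        (x**2)[:, None, None]
        + (y**2)[None, :, None]
        + (z**2)[None, None, :]
    )
    grid = (r2 >= np.float32(spec.inner_radius_mm**2)) & (
        r2 <= np.float32(spec.outer_radius_mm**2)
    )
    for c_abs, radius in spec.fiducials_mm():
        c = c_abs - np.asarray(spec.center)
        d2 = (
            ((x - c[0]) ** 2)[:, None, None]
            + ((y - c[1]) ** 2)[None, :, None]
            + ((z - c[2]) ** 2)[None, None, :]
        )
        grid |= d2 <= np.float32(radius**2)
    return VoxelMask(grid, spec.spacing_mm)


def _patch_membership(
    spec: ShellSpec, patch: PatchSpec, centers: np.ndarray
) -> np.ndarray:
    """Boolean patch membership of the given voxel centres (mm, absolute).

    Membership is angular plus a radial window spanning the shell wall, so
    fiducial bumps protruding beyond the outer radius never join the flap.
    """
    rel = centers - np.asarray(spec.center)
    r = np.linalg.norm(rel, axis=1)
    r = np.maximum(r, 1e-9)
    polar = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
    azim = np.arctan2(rel[:, 1], rel[:, 0])
    dazim = np.abs(((azim - patch.azimuth_center_rad + np.pi) % (2 * np.pi)) - np.pi)
    tol = max(spec.spacing_mm)
    return (
        (dazim <= patch.azimuth_halfwidth_rad)
        & (polar >= patch.polar_min_rad)
        & (polar <= patch.polar_max_rad)
        & (r >= spec.inner_radius_mm - tol)
        & (r <= spec.outer_radius_mm + tol)
    )


def remove_patch(
    shell: VoxelMask, shell_spec: ShellSpec, patch: PatchSpec
) -> tuple[VoxelMask, VoxelMask, float]:
    """Remove the full-thickness angular patch from the shell.

    Returns (post_mask, true_flap, true_outer_area_cm2); post and flap
    partition the shell, and the area is the exact outer-sphere patch area.
    """
    idx = shell.indices()
    centers = shell.voxel_centers_mm(idx)
    inside = _patch_membership(shell_spec, patch, centers)
    if not inside.any():
        raise FlapMetricsError("patch does not intersect the shell: empty flap")
    flap_grid = np.zeros(shell.shape, dtype=bool)
    sel = idx[inside]
    flap_grid[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    post_grid = shell.grid & ~flap_grid
    area = geometry.dome_patch_outer_area(patch.to_dome(shell_spec.outer_radius_mm))
    return (
        VoxelMask(post_grid, shell.spacing_mm, shell.origin_mm),
        VoxelMask(flap_grid, shell.spacing_mm, shell.origin_mm),
        area,
    )


def _digitize_transformed_post(
    spec: ShellSpec, patch: PatchSpec, transform: RigidTransform
) -> VoxelMask:
    """Digitize the rigidly moved post-operative skull analytically.

    A voxel is bone iff its centre, pulled back through the transform, lies in
    the shell but outside the patch — i.e. the moved anatomy is re-sampled
    from its continuous description, as a real second CT acquisition would be.
    """
    x, y, z = _voxel_coordinate_axes(spec)
    shape = spec.grid_shape
    pts = np.empty((np.prod(shape), 3), dtype=np.float64)
    pts[:, 0] = np.repeat(x, shape[1] * shape[2])
    pts[:, 1] = np.tile(np.repeat(y, shape[2]), shape[0])
    pts[:, 2] = np.tile(z, shape[0] * shape[1])
    pts += np.asarray(spec.center)
    back_abs = transform.inverse().apply_points(pts)
    back = back_abs - np.asarray(spec.center)
    r = np.linalg.norm(back, axis=1)
    in_skull = (r >= spec.inner_radius_mm) & (r <= spec.outer_radius_mm)
    for c, radius in spec.fiducials_mm():
        in_skull |= np.sum((back_abs - c) ** 2, axis=1) <= radius**2
    in_patch = _patch_membership(spec, patch, back_abs)
    grid = (in_skull & ~in_patch).reshape(shape)
    return VoxelMask(grid, spec.spacing_mm)


# ---------------------------------------------------------------------------
# degradations


def perturb_rigid(
    mask: VoxelMask,
    rotation_deg: tuple[float, float, float],
    translation_mm: tuple[float, float, float],
    seed: int = 0,
) -> VoxelMask:
    """Rigidly move a mask (nearest-neighbour resampling about the grid centre).

    ``seed`` is accepted for interface uniformity with the other degradations;
    the resampling itself is deterministic.  Raises when the transform pushes
    a noticeable part of the content off the grid (voxel count conservation
    worse than 5%).
    """
    del seed
    center = tuple(
        (n - 1) * s / 2.0 + o
        for n, s, o in zip(mask.shape, mask.spacing_mm, mask.origin_mm)
    )
    t = RigidTransform(rotation_deg, translation_mm, center)
    moved = apply_transform(mask, t)
    if mask.count and abs(moved.count - mask.count) > 0.05 * mask.count:
        raise FlapMetricsError(
            "rigid perturbation pushed mask content outside the grid "
            f"(voxel count {mask.count} -> {moved.count})"
        )
    return moved


def add_artifacts(mask: VoxelMask, severity: float, seed: int = 0) -> VoxelMask:
    """Flip boundary-adjacent voxels to emulate streak-artifact damage.

    The flip budget is ``severity`` × 10% of the mask volume (so never more
    than 10% at full severity), drawn without replacement from the one-voxel
    boundary layers on both sides of the surface.  Deterministic per seed.
    """
    if not (0 <= severity <= 1):
        raise FlapMetricsError("severity must lie in [0, 1]")
    if severity == 0 or mask.is_empty():
        return VoxelMask(mask.grid.copy(), mask.spacing_mm, mask.origin_mm)
    inner = mask.grid & ~ndimage.binary_erosion(mask.grid)
    outer = ndimage.binary_dilation(mask.grid) & ~mask.grid
    candidates = np.argwhere(inner | outer)
    n_flip = min(int(round(severity * 0.1 * mask.count)), len(candidates))
    rng = np.random.default_rng(seed)
    chosen = candidates[rng.choice(len(candidates), size=n_flip, replace=False)]
    grid = mask.grid.copy()
    grid[chosen[:, 0], chosen[:, 1], chosen[:, 2]] ^= True
    return VoxelMask(grid, mask.spacing_mm, mask.origin_mm)


# ---------------------------------------------------------------------------
# cohort simulation


def _max_feasible_area_cm2(R_mm: float) -> float:
    ext = _EXTENT_RANGE[1]
    dcos = 2.0 * np.sin(ext / 2.0) * np.cos(_POLAR_MID_JITTER)
    return 2.0 * _THETA_MAX * dcos * R_mm**2 / 100.0


def _sample_patch(rng: np.random.Generator, R_mm: float, target_area_cm2: float) -> PatchSpec:
    """Draw a patch of exactly the target outer area within the cohort regime."""
    target_mm2 = target_area_cm2 * 100.0
    for _ in range(_MAX_DRAWS):
        extent = rng.uniform(*_EXTENT_RANGE)
        mid = np.pi / 2 + rng.uniform(-_POLAR_MID_JITTER, _POLAR_MID_JITTER)
        lo, hi = mid - extent / 2.0, mid + extent / 2.0
        dcos = np.cos(lo) - np.cos(hi)
        theta = target_mm2 / (2.0 * R_mm**2 * dcos)
        if _THETA_MIN <= theta <= _THETA_MAX:
            return PatchSpec(rng.uniform(0, 2 * np.pi), theta, lo, hi)
    raise FlapMetricsError(
        f"could not place a patch of {target_area_cm2:.2f} cm2 on a "
        f"{R_mm:.0f} mm sphere within the sampling regime"
    )


def simulate_cohort(spec: CohortSpec) -> list[PhantomCase]:
    """Generate ``n_cases`` pre/post phantom pairs with ground truth.

    Target outer areas are drawn uniformly over ``area_range_cm2`` and
    realized exactly by the patch construction, so the cohort's ground-truth
    area distribution is uniform by construction.  All randomness flows from
    ``spec.seed``; the same spec reproduces the identical case set.
    """
    low, high = spec.area_range_cm2
    max_area = _max_feasible_area_cm2(spec.outer_radius_mm)
    if high > max_area:
        raise FlapMetricsError(
            f"area range upper bound {high:.2f} cm2 infeasible for a "
            f"{spec.outer_radius_mm:.0f} mm shell; feasible range is "
            f"(0, {max_area:.2f}] cm2"
        )
    shell_spec = spec.shell_spec()
    shell = make_skull_shell(shell_spec)
    rng = np.random.default_rng(spec.seed)
    cases: list[PhantomCase] = []
    for i in range(spec.n_cases):
        area = rng.uniform(low, high)
        patch = _sample_patch(rng, spec.outer_radius_mm, area)
        post, flap, true_area = remove_patch(shell, shell_spec, patch)
        transform: RigidTransform | None = None
        if spec.misalignment is not None:
            max_rot, max_tr = spec.misalignment
            transform = RigidTransform(
                tuple(rng.uniform(-max_rot, max_rot, 3)),
                tuple(rng.uniform(-max_tr, max_tr, 3)),
                shell_spec.center,
            )
            post = _digitize_transformed_post(shell_spec, patch, transform)
        if spec.artifact_severity > 0:
            post = add_artifacts(post, spec.artifact_severity, seed=int(rng.integers(2**31)))
        cases.append(
            PhantomCase(
                case_id=f"case_{i:03d}",
                pre_mask=shell,
                post_mask=post,
                true_flap=flap,
                true_outer_area_cm2=true_area,
                patch_spec=patch,
                shell_spec=shell_spec,
                applied_transform=transform,
            )
        )
    return cases


def patch_series(
    n: int,
    area_range_cm2: tuple[float, float],
    seed: int,
    shell_spec: ShellSpec,
    max_theta_rad: float = 2.2,
) -> list[tuple[PatchSpec, float]]:
    """Evenly spaced-area patch specs for estimator validation sweeps.

    Areas are spaced linearly across the range; each patch is near-square
    (azimuthal span ≈ polar span), the compact shape with the smallest rim for
    its area.  Returns (patch, exact outer area cm²) pairs.
    """
    rng = np.random.default_rng(seed)
    R = shell_spec.outer_radius_mm
    out: list[tuple[PatchSpec, float]] = []
    for area in np.linspace(*area_range_cm2, n):
        target_mm2 = area * 100.0
        extent = float(np.clip(np.sqrt(target_mm2) / R, 0.25, 2.2))
        mid = np.pi / 2 + rng.uniform(-0.1, 0.1)
        lo = max(mid - extent / 2.0, 0.05)
        hi = min(mid + extent / 2.0, np.pi - 0.05)
        dcos = np.cos(lo) - np.cos(hi)
        theta = target_mm2 / (2.0 * R**2 * dcos)
        if not (0 < theta <= max_theta_rad):
            raise FlapMetricsError(f"area {area:.1f} cm2 infeasible on this shell")
        patch = PatchSpec(rng.uniform(0, 2 * np.pi), theta, lo, hi)
        out.append((patch, geometry.dome_patch_outer_area(patch.to_dome(R))))
    return out


# ---------------------------------------------------------------------------
# persistence


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write one case as NIfTI masks plus a ground-truth JSON sidecar."""
    d = Path(out_dir) / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    case.pre_mask.to_nifti(d / "pre.nii.gz")
    case.post_mask.to_nifti(d / "post.nii.gz")
    case.true_flap.to_nifti(d / "flap_truth.nii.gz")
    meta = {
        "case_id": case.case_id,
        "true_outer_area_cm2": case.true_outer_area_cm2,
        "outer_radius_mm": case.shell_spec.outer_radius_mm,
        "thickness_mm": case.shell_spec.thickness_mm,
        "spacing_mm": list(case.shell_spec.spacing_mm),
        "patch": {
            "azimuth_center_rad": case.patch_spec.azimuth_center_rad,
            "azimuth_halfwidth_rad": case.patch_spec.azimuth_halfwidth_rad,
            "polar_min_rad": case.patch_spec.polar_min_rad,
            "polar_max_rad": case.patch_spec.polar_max_rad,
        },
        "applied_transform": None
        if case.applied_transform is None
        else {
            "rotation_deg": list(case.applied_transform.rotation_deg),
            "translation_mm": list(case.applied_transform.translation_mm),
            "center_mm": list(case.applied_transform.center_mm),
        },
    }
    (d / "case.json").write_text(json.dumps(meta, indent=2))
    return d


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> list[Path]:
    return [write_case(c, out_dir) for c in simulate_cohort(spec)]
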