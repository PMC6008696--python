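"""Isosurface meshing and outward-normal area filtering."""

import numpy as np
import pytest

from flapmetrics import (
    FlapMetricsError,
    PatchSpec,
    ShellSpec,
    VoxelMask,
    extract_mesh,
    make_skull_shell,
    mc_outer_area,
    outer_area_mc,
    remove_patch,
    dome_patch_outer_area,
)


def _ball_mask(r_mm: float, spacing: float) -> VoxelMask:
    n = int(np.ceil(2 * (r_mm + 4 * spacing) / spacing))
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    r2 = (ax**2)[:, None, None] + (ax**2)[None, :, None] + (ax**2)[None, None, :]
    return VoxelMask(r2 <= r_mm**2, (spacing,) * 3)


def test_single_voxel_mesh_within_digitization_bound():
    grid = np.zeros((7, 7, 7), dtype=bool)
    grid[3, 3, 3] = True
    mesh = extract_mesh(VoxelMask(grid, (1.0, 1.0, 1.0)))
    assert mesh.is_closed()
    assert mesh.total_area_mm2 == pytest.approx(6.0, rel=0.5)


def test_ball_mesh_area(solid_ball):
    mesh = extract_mesh(solid_ball)
    assert mesh.is_closed()
    assert mesh.total_area_mm2 == pytest.approx(4 * np.pi * 400.0, rel=0.02)


def test_mirrored_mask_same_area():
    rng = np.random.default_rng(3)
    grid = np.zeros((24, 24, 24), dtype=bool)
    grid[6:18, 6:18, 6:18] = rng.random((12, 12, 12)) > 0.4
    # keep the largest blob so both meshes are well defined
    m = VoxelMask(grid, (1.0, 1.0, 1.0))
    mirrored = VoxelMask(grid[::-1].copy(), (1.0, 1.0, 1.0))
    a = extract_mesh(m).total_area_mm2
    b = extract_mesh(mirrored).total_area_mm2
    # marching cubes resolves ambiguous cube cases asymmetrically, so the two
    # triangulations differ by a handful of saddle facets, not more
    assert a == pytest.approx(b, rel=2e-3)


def test_mesh_normals_unit_and_closed(solid_ball):
    mesh = extract_mesh(solid_ball)
    norms = np.linalg.norm(mesh.face_normals[~mesh.degenerate], axis=1)
    assert np.allclose(norms, 1.0, atol=1e-6)
    assert mesh.signed_volume_mm3 > 0


def test_empty_and_boundary_touching_rejected():
    with pytest.raises(FlapMetricsError):
        extract_mesh(VoxelMask(np.zeros((5, 5, 5), bool), (1, 1, 1)))
    grid = np.zeros((5, 5, 5), bool)
    grid[0, 2, 2] = True
    with pytest.raises(FlapMetricsError, match="boundary"):
        extract_mesh(VoxelMask(grid, (1, 1, 1)))


def test_convex_ball_all_normals_point_outward(solid_ball):
    mesh = extract_mesh(solid_ball)
    est = outer_area_mc(mesh, solid_ball.centroid_mm())
    assert est.area_cm2 == pytest.approx(mesh.total_area_mm2 / 100.0, rel=1e-3)
    assert est.metadata["n_kept"] >= 0.999 * (
        est.metadata["n_triangles"] - est.metadata["n_degenerate"]
    )


def test_far_center_sees_half_the_ball(solid_ball):
    mesh = extract_mesh(solid_ball)
    far = solid_ball.centroid_mm() + np.array([10000.0, 0.0, 0.0])
    est = outer_area_mc(mesh, far)
    assert est.area_cm2 == pytest.approx(mesh.total_area_mm2 / 200.0, rel=0.03)


def test_kept_area_bounded_by_total(solid_ball):
    mesh = extract_mesh(solid_ball)
    est = outer_area_mc(mesh, solid_ball.centroid_mm() + np.array([0.0, 35.0, 0.0]))
    assert 0.0 <= est.area_cm2 <= mesh.total_area_mm2 / 100.0 + 1e-9


def _patch_case(spacing: float, thickness: float):
    R = 40.0
    n = int(np.ceil(2 * (R + 4 * spacing) / spacing))
    spec = ShellSpec(R, thickness, (spacing,) * 3, (n, n, n))
    shell = make_skull_shell(spec)
    patch = PatchSpec(0.7, 0.8, 0.9, 1.9)
    _, flap, truth = remove_patch(shell, spec, patch)
    return shell, flap, truth, spec


def _analytic_total_boundary_cm2(patch: PatchSpec, R: float, t: float) -> float:
    """Closed-form total boundary area of a full-thickness shell patch:
    outer face + inner face + two azimuthal walls + two polar (cone) walls."""
    lo, hi = patch.polar_min_rad, patch.polar_max_rad
    theta = patch.azimuth_halfwidth_rad
    dcos = np.cos(lo) - np.cos(hi)
    outer = 2 * theta * dcos * R**2
    inner = 2 * theta * dcos * (R - t) ** 2
    ring = (R**2 - (R - t) ** 2) / 2.0
    azim_walls = 2 * (hi - lo) * ring
    polar_walls = 2 * theta * (np.sin(lo) + np.sin(hi)) * ring
    return (outer + inner + azim_walls + polar_walls) / 100.0


def test_patch_total_area_converges_with_spacing():
    """Total mesh area converges to the closed-form boundary area of the
    shell patch as the voxel spacing shrinks (2, 1, 0.5 mm)."""
    patch = PatchSpec(0.7, 0.8, 0.9, 1.9)
    exact = _analytic_total_boundary_cm2(patch, R=40.0, t=4.0)
    errs = []
    for spacing in (2.0, 1.0, 0.5):
        _, flap, _, _ = _patch_case(spacing, thickness=4.0)
        mesh = extract_mesh(flap)
        errs.append(abs(mesh.total_area_mm2 / 100.0 - exact) / exact)
    assert errs[0] > errs[1] > errs[2]
    # the residual is the smoothing of the sharp rim edges, itself O(spacing)
    assert errs[2] < 0.04


def test_thick_rim_overestimates_outer_area():
    """Rim triangles tipped outward inflate the estimate for thick flaps."""
    shell, flap, truth, spec = _patch_case(1.0, thickness=8.0)
    est = mc_outer_area(flap, np.asarray(spec.center))
    assert est.area_cm2 > truth


def test_patch_outer_area_close_to_oracle(val_shell):
    from conftest import VAL_SHELL_SPEC

    patch = PatchSpec(0.5, 0.9, 1.0, 2.0)
    _, flap, truth = remove_patch(val_shell, VAL_SHELL_SPEC, patch)
    est = mc_outer_area(flap, np.asarray(VAL_SHELL_SPEC.center))
    assert est.area_cm2 == pytest.approx(truth, rel=0.05)
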