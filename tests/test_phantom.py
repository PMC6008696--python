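"""Synthetic skull phantoms: digitization, patch removal, cohort simulation."""

import numpy as np
import pytest
from scipy import ndimage, stats

from flapmetrics import (
    CohortSpec,
    FlapMetricsError,
    PatchSpec,
    ShellSpec,
    VoxelMask,
    add_artifacts,
    dome_patch_outer_area,
    make_skull_shell,
    perturb_rigid,
    remove_patch,
    simulate_cohort,
)
from flapmetrics.phantom import patch_series, write_case

from conftest import SMALL_SHELL_SPEC


def test_shell_volume_matches_analytic():
    spec = ShellSpec(50.0, 5.0, (1.0, 1.0, 1.0), (112, 112, 112))
    shell = make_skull_shell(spec)
    analytic = 4.0 / 3.0 * np.pi * (50.0**3 - 45.0**3)
    assert shell.count * shell.voxel_volume_mm3 == pytest.approx(analytic, rel=0.03)


def test_solid_ball_degenerate_shell():
    spec = ShellSpec(30.0, 30.0, (1.0, 1.0, 1.0), (72, 72, 72))
    ball = make_skull_shell(spec)
    analytic = 4.0 / 3.0 * np.pi * 30.0**3
    assert ball.count * ball.voxel_volume_mm3 == pytest.approx(analytic, rel=0.03)


def test_shell_exceeding_grid_rejected():
    with pytest.raises(FlapMetricsError, match="exceeds grid"):
        ShellSpec(60.0, 5.0, (1.0, 1.0, 1.0), (100, 100, 100))


def test_shell_single_connected_component(small_shell):
    six_conn = ndimage.generate_binary_structure(3, 1)
    _, n = ndimage.label(small_shell.grid, structure=six_conn)
    assert n == 1


def test_hemisphere_patch_area(small_shell):
    patch = PatchSpec(0.0, np.pi - 1e-9, 0.0, np.pi / 2)
    spec = ShellSpec(50.0, 5.0, (1.0, 1.0, 1.0), (112, 112, 112))
    shell = make_skull_shell(spec)
    _, _, area = remove_patch(shell, spec, patch)
    assert area == pytest.approx(2 * np.pi * 25.0, rel=1e-6)  # 157.08 cm2


def test_patch_partitions_shell(small_shell):
    patch = PatchSpec(1.0, 0.6, 0.8, 1.7)
    post, flap, _ = remove_patch(small_shell, SMALL_SHELL_SPEC, patch)
    assert not np.any(post.grid & flap.grid)
    assert np.array_equal(post.grid | flap.grid, small_shell.grid)
    assert flap.count + post.count == small_shell.count


def test_empty_patch_rejected(small_shell):
    patch = PatchSpec(1.0, 1e-7, 1.2, 1.2 + 1e-9)
    with pytest.raises(FlapMetricsError, match="empty flap"):
        remove_patch(small_shell, SMALL_SHELL_SPEC, patch)


def test_patch_area_against_monte_carlo_surface_sampling():
    """Closed-form patch area vs. uniform sphere sampling, < 0.5% at 1e6 points."""
    patch = PatchSpec(1.0, 0.9, 0.7, 1.9)
    R = 50.0
    exact = dome_patch_outer_area(patch.to_dome(R))
    rng = np.random.default_rng(0)
    z = rng.uniform(-1, 1, 1_000_000)
    az = rng.uniform(-np.pi, np.pi, 1_000_000)
    polar = np.arccos(z)
    dazim = np.abs(((az - patch.azimuth_center_rad + np.pi) % (2 * np.pi)) - np.pi)
    frac = np.mean(
        (dazim <= patch.azimuth_halfwidth_rad)
        & (polar >= patch.polar_min_rad)
        & (polar <= patch.polar_max_rad)
    )
    mc = frac * 4 * np.pi * R**2 / 100.0
    assert mc == pytest.approx(exact, rel=0.005)


# -- rigid perturbation -----------------------------------------------------


def test_perturb_identity(small_shell):
    moved = perturb_rigid(small_shell, (0, 0, 0), (0, 0, 0))
    assert np.array_equal(moved.grid, small_shell.grid)


def test_perturb_translation_shifts_centroid(small_shell):
    moved = perturb_rigid(small_shell, (0, 0, 0), (3.0, 0.0, 0.0))
    shift = moved.centroid_mm() - small_shell.centroid_mm()
    assert shift[0] == pytest.approx(3.0, abs=0.5)
    assert abs(shift[1]) < 0.5 and abs(shift[2]) < 0.5


def test_perturb_rotation_moves_offcenter_blob():
    grid = np.zeros((64, 64, 64), dtype=bool)
    grid[44:50, 29:35, 29:35] = True  # blob ~15 mm off centre along +x
    mask = VoxelMask(grid, (1.0, 1.0, 1.0))
    moved = perturb_rigid(mask, (0, 0, 5.0), (0, 0, 0))
    center = np.asarray([31.5, 31.5, 31.5])
    rel0 = mask.centroid_mm() - center
    rel1 = moved.centroid_mm() - center
    ang = np.deg2rad(5.0)
    expected = np.array(
        [
            np.cos(ang) * rel0[0] - np.sin(ang) * rel0[1],
            np.sin(ang) * rel0[0] + np.cos(ang) * rel0[1],
            rel0[2],
        ]
    )
    assert np.linalg.norm(rel1 - expected) < 1.0


def test_perturb_content_loss_rejected(small_shell):
    with pytest.raises(FlapMetricsError, match="outside the grid"):
        perturb_rigid(small_shell, (0, 0, 0), (30.0, 0.0, 0.0))


# -- artifacts --------------------------------------------------------------


def test_artifacts_zero_severity_is_identity(small_shell):
    out = add_artifacts(small_shell, 0.0, seed=4)
    assert np.array_equal(out.grid, small_shell.grid)


def test_artifacts_deterministic(small_shell):
    a = add_artifacts(small_shell, 0.4, seed=9)
    b = add_artifacts(small_shell, 0.4, seed=9)
    assert np.array_equal(a.grid, b.grid)


def test_artifacts_flip_rate(small_shell):
    severity = 0.5
    out = add_artifacts(small_shell, severity, seed=2)
    flipped = int(np.sum(out.grid != small_shell.grid))
    configured = severity * 0.1 * small_shell.count
    assert flipped == pytest.approx(configured, rel=0.2)
    assert flipped <= 0.1 * small_shell.count


# -- cohort simulation ------------------------------------------------------


def test_cohort_areas_span_and_uniformity():
    spec = CohortSpec(n_cases=118, seed=5)
    cases = simulate_cohort(spec)
    areas = np.array([c.true_outer_area_cm2 for c in cases])
    assert len(cases) == 118
    low, high = spec.area_range_cm2
    assert areas.min() >= low and areas.max() <= high
    ks = stats.kstest(areas, stats.uniform(loc=low, scale=high - low).cdf)
    assert ks.pvalue > 0.01


def test_cohort_single_case_has_ground_truth():
    case = simulate_cohort(CohortSpec(n_cases=1, seed=1))[0]
    assert case.true_outer_area_cm2 > 0
    assert not case.true_flap.is_empty()
    assert not np.any(case.post_mask.grid & case.true_flap.grid)


def test_cohort_seeded_determinism():
    a = simulate_cohort(CohortSpec(n_cases=3, seed=42))
    b = simulate_cohort(CohortSpec(n_cases=3, seed=42))
    for ca, cb in zip(a, b):
        assert ca.true_outer_area_cm2 == cb.true_outer_area_cm2
        assert np.array_equal(ca.post_mask.grid, cb.post_mask.grid)
        assert np.array_equal(ca.true_flap.grid, cb.true_flap.grid)


def test_cohort_partition_invariant():
    for case in simulate_cohort(CohortSpec(n_cases=3, seed=8)):
        pre, post, flap = case.pre_mask, case.post_mask, case.true_flap
        assert not np.any(post.grid & flap.grid)
        assert np.array_equal(post.grid | flap.grid, pre.grid)


def test_cohort_infeasible_range_names_feasible():
    with pytest.raises(FlapMetricsError, match="feasible range"):
        simulate_cohort(CohortSpec(n_cases=2, area_range_cm2=(10.0, 500.0)))


def test_patch_series_spans_range():
    series = patch_series(10, (10.0, 200.0), seed=7, shell_spec=ShellSpec(
        outer_radius_mm=110.0, thickness_mm=10.0, spacing_mm=(1.5, 1.5, 5.0),
        grid_shape=(168, 168, 56)))
    areas = [a for _, a in series]
    assert areas[0] == pytest.approx(10.0, rel=1e-6)
    assert areas[-1] == pytest.approx(200.0, rel=1e-6)
    assert all(np.diff(areas) > 0)


def test_write_case_round_trip(tmp_path):
    case = simulate_cohort(
        CohortSpec(
            n_cases=1,
            seed=3,
            spacing_mm=(2.0, 2.0, 2.0),
            outer_radius_mm=40.0,
            thickness_mm=6.0,
            fiducial_radius_mm=6.0,
            area_range_cm2=(8.0, 15.0),
        )
    )[0]
    d = write_case(case, tmp_path)
    back = VoxelMask.from_nifti(d / "flap_truth.nii.gz")
    assert np.array_equal(back.grid, case.true_flap.grid)
    assert back.spacing_mm == case.true_flap.spacing_mm
    import json

    meta = json.loads((d / "case.json").read_text())
    assert meta["true_outer_area_cm2"] == pytest.approx(case.true_outer_area_cm2)
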