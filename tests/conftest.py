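"""Shared phantom fixtures.

Heavy phantoms are session-scoped: the thin-shell high-resolution skull used
to validate the digital estimators against the closed-form patch area, the
clinical-spacing skull used for the length-times-height method, and the
isotropic extraction pair.
"""

import numpy as np
import pytest

from flapmetrics import CohortSpec, ShellSpec, make_skull_shell, simulate_cohort

# Validation shell for the mesh/Crofton oracle sweeps: thin wall (1 mm) at
# fine isotropic spacing so the rim term stays well under the oracle
# tolerance even for the smallest patches; no fiducials (pure sphere).
VAL_SHELL_SPEC = ShellSpec(
    outer_radius_mm=80.0,
    thickness_mm=1.0,
    spacing_mm=(0.5, 0.5, 0.5),
    grid_shape=(340, 340, 340),
)

# Clinical-regime shell for the AC method: 5 mm axial slices, 10 mm wall.
SAC_SHELL_SPEC = ShellSpec(
    outer_radius_mm=110.0,
    thickness_mm=10.0,
    spacing_mm=(1.5, 1.5, 5.0),
    grid_shape=(168, 168, 56),
)

# Small isotropic shell for cheap unit tests.
SMALL_SHELL_SPEC = ShellSpec(
    outer_radius_mm=30.0,
    thickness_mm=5.0,
    spacing_mm=(1.0, 1.0, 1.0),
    grid_shape=(72, 72, 72),
)

EXTRACTION_SPEC = dict(
    spacing_mm=(1.0, 1.0, 1.0),
    outer_radius_mm=80.0,
    thickness_mm=6.0,
    area_range_cm2=(90.0, 120.0),
)


@pytest.fixture(scope="session")
def val_shell():
    return make_skull_shell(VAL_SHELL_SPEC)


@pytest.fixture(scope="session")
def sac_shell():
    return make_skull_shell(SAC_SHELL_SPEC)


@pytest.fixture(scope="session")
def small_shell():
    return make_skull_shell(SMALL_SHELL_SPEC)


@pytest.fixture(scope="session")
def aligned_case():
    return simulate_cohort(CohortSpec(n_cases=1, seed=11, **EXTRACTION_SPEC))[0]


@pytest.fixture(scope="session")
def misaligned_case():
    return simulate_cohort(
        CohortSpec(n_cases=1, seed=11, misalignment=(5.0, 5.0), **EXTRACTION_SPEC)
    )[0]


@pytest.fixture()
def solid_ball():
    """Digitized solid ball, r = 20 mm at 1 mm spacing."""
    n = 48
    ax = np.arange(n) - (n - 1) / 2
    r2 = (ax**2)[:, None, None] + (ax**2)[None, :, None] + (ax**2)[None, None, :]
    from flapmetrics import VoxelMask

    return VoxelMask(r2 <= 20.0**2, (1.0, 1.0, 1.0))
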