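"""End-to-end workflows: measure phantom cases with all three estimators.

Glue between the phantom generator, the three area estimators and the
agreement statistics; used by the command-line interface and the
reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from .core import VoxelMask
from .phantom import PhantomCase
from .stats import CohortResults
from .surface_ac import ac_area
from .surface_mc import mc_outer_area
from .surface_qmc import qmc_area

__all__ = ["measure_case", "measure_cohort"]


def measure_case(
    flap: VoxelMask,
    pre_bone: VoxelMask,
    n_lines: int = 4000,
    skip: int = 1,
) -> dict[str, float]:
    """All three area estimates (cm²) of one flap mask.

    The image centre for the outward-normal filter is the pre-operative skull
    centroid; the AC height check uses the pre-operative mask as well.
    """
    center = pre_bone.centroid_mm()
    return {
        "mc": mc_outer_area(flap, center).area_cm2,
        "qmc": qmc_area(flap, n_lines=n_lines, skip=skip).area_cm2,
        "ac": ac_area(flap, pre_bone).area_cm2,
    }


def measure_cohort(
    cases: list[PhantomCase],
    n_lines: int = 4000,
    skip: int = 1,
    use_true_flap: bool = True,
) -> CohortResults:
    """Measure every case of a phantom cohort; includes the oracle areas.

    ``use_true_flap`` measures the ground-truth flap directly (estimator
    comparison without the extraction stage, which is how aligned cohorts are
    evaluated); the alternative would re-extract each flap first.
    """
    from .flap_extraction import extract_flap

    rows: dict[str, list[float]] = {"mc": [], "qmc": [], "ac": [], "oracle": []}
    ids = []
    for case in cases:
        if use_true_flap:
            flap = case.true_flap
        else:
            flap, _ = extract_flap(case.pre_mask, case.post_mask)
        areas = measure_case(flap, case.pre_mask, n_lines=n_lines, skip=skip)
        for k, v in areas.items():
            rows[k].append(v)
        rows["oracle"].append(case.true_outer_area_cm2)
        ids.append(case.case_id)
    return CohortResults({k: np.asarray(v) for k, v in rows.items()}, ids)
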