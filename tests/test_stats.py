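"""Agreement statistics: fixtures, identities, report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flapmetrics import (
    AgreementReport,
    CohortResults,
    FlapMetricsError,
    bland_altman,
    build_report,
    mean_deviation_pct,
    paired_t,
    pearson_r,
    rmsd,
)

vectors = st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40)


def test_rmsd_hand_values():
    assert rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmsd([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(25.0 / 2.0), rel=1e-12)


def test_rmsd_length_mismatch():
    with pytest.raises(FlapMetricsError):
        rmsd([1.0, 2.0], [1.0])


def test_pearson_hand_values():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    assert pearson_r(x, [1.0, 3.0, 2.0, 4.0]) == pytest.approx(0.8, rel=1e-12)


def test_pearson_zero_variance_rejected():
    with pytest.raises(FlapMetricsError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bland_altman_hand_values():
    res = bland_altman([10.0, 12.0, 14.0], [9.0, 13.0, 12.0])
    sd = np.std([1.0, -1.0, 2.0], ddof=1)  # 1.5275...
    assert res.bias == pytest.approx(2.0 / 3.0, rel=1e-9)
    assert res.loa_low == pytest.approx(2.0 / 3.0 - 1.96 * sd, rel=1e-9)
    assert res.loa_high == pytest.approx(2.0 / 3.0 + 1.96 * sd, rel=1e-9)


def test_bland_altman_degenerate_cases():
    res = bland_altman([5.0, 5.0], [5.0, 5.0])
    assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)
    res = bland_altman([6.0, 7.0], [4.0, 5.0])  # constant difference 2
    assert (res.bias, res.loa_low, res.loa_high) == (2.0, 2.0, 2.0)


def test_mean_deviation_conventions():
    assert mean_deviation_pct([100.0], [90.0]) == pytest.approx(10.0 / 95.0 * 100.0)
    assert mean_deviation_pct([100.0], [90.0], denominator="reference") == pytest.approx(
        100.0 / 9.0
    )
    assert mean_deviation_pct([10.0, 20.0], [10.0, 20.0]) == 0.0
    # symmetric in the pair for the mean convention
    assert mean_deviation_pct([100.0], [90.0]) == mean_deviation_pct([90.0], [100.0])
    with pytest.raises(FlapMetricsError):
        mean_deviation_pct([1.0], [-1.0])


def test_paired_t_matches_reference_implementation():
    x = np.array([10.0, 12.0, 14.0, 16.0])
    y = np.array([9.0, 13.0, 12.0, 18.0])
    assert paired_t(x, y) == pytest.approx(sps.ttest_rel(x, y).pvalue, rel=1e-10)


def test_paired_t_degenerate_cases():
    assert paired_t([1.0, 3.0], [2.0, 2.0]) == pytest.approx(1.0)  # mean diff 0
    with pytest.raises(FlapMetricsError):
        paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])  # zero-variance differences


@settings(max_examples=60, deadline=None, derandomize=True)
@given(x=vectors, y=vectors)
def test_rmsd_decomposition_identity(x, y):
    """rmsd^2 = bias^2 + ((n-1)/n) sd^2 for paired data."""
    n = min(len(x), len(y))
    x, y = np.asarray(x[:n]), np.asarray(y[:n])
    d = x - y
    bias = d.mean()
    sd = d.std(ddof=1)
    assert rmsd(x, y) ** 2 == pytest.approx(
        bias**2 + (n - 1) / n * sd**2, rel=1e-9, abs=1e-9
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(x=vectors, y=vectors, seed=st.integers(0, 2**16))
def test_statistics_invariant_under_joint_reordering(x, y, seed):
    n = min(len(x), len(y))
    x, y = np.asarray(x[:n]), np.asarray(y[:n])
    perm = np.random.default_rng(seed).permutation(n)
    assert rmsd(x, y) == pytest.approx(rmsd(x[perm], y[perm]), rel=1e-12, abs=1e-12)
    ba, bap = bland_altman(x, y), bland_altman(x[perm], y[perm])
    assert ba.bias == pytest.approx(bap.bias, rel=1e-12, abs=1e-12)
    assert ba.loa_high == pytest.approx(bap.loa_high, rel=1e-12, abs=1e-12)


def test_report_degenerate_cohort_flagged():
    v = np.array([10.0, 10.0, 10.0])
    report = build_report(CohortResults({"mc": v, "qmc": v, "ac": v}))
    for pair in report.pairs:
        assert pair.rmsd_cm2 == 0.0
        assert pair.pearson_r is None and "undefined_correlation" in pair.flags
        assert pair.paired_t_p is None and "degenerate_t_test" in pair.flags


def test_report_recovers_injected_noise_scale():
    """RMSD between a method and itself plus N(0, sigma) noise estimates sigma."""
    rng = np.random.default_rng(12)
    sigma = 7.0
    base = rng.uniform(9.46, 205.32, 118)
    noisy = base + rng.normal(0.0, sigma, 118)
    report = build_report(CohortResults({"mc": base, "qmc": noisy}))
    assert report.pair("mc", "qmc").rmsd_cm2 == pytest.approx(sigma, rel=0.15)


def test_report_limits_bracket_bias_and_rmsd_dominates():
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 200, 50)
    y = x + rng.normal(1.0, 5.0, 50)
    report = build_report(CohortResults({"mc": x, "qmc": y}))
    p = report.pair("mc", "qmc")
    assert p.loa_low_cm2 <= p.bias_cm2 <= p.loa_high_cm2
    assert p.rmsd_cm2 >= abs(p.bias_cm2)


def test_report_metaestimate_and_summaries():
    x = np.array([10.0, 20.0, 30.0])
    y = np.array([12.0, 18.0, 33.0])
    z = np.array([11.0, 22.0, 27.0])
    report = build_report(CohortResults({"mc": x, "qmc": y, "ac": z}))
    assert np.allclose(report.metaestimate_cm2, (x + y + z) / 3.0)
    mc = next(m for m in report.methods if m.method == "mc")
    assert (mc.min_cm2, mc.max_cm2, mc.median_cm2) == (10.0, 30.0, 20.0)


def test_report_json_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    x = rng.uniform(10, 200, 20)
    report = build_report(
        CohortResults({"mc": x, "qmc": x * 1.02 + 1, "ac": x * 0.9 + rng.normal(0, 2, 20)})
    )
    path = tmp_path / "report.json"
    report.to_json(path)
    back = AgreementReport.from_json(path)
    for p0, p1 in zip(report.pairs, back.pairs):
        assert p1.rmsd_cm2 == pytest.approx(p0.rmsd_cm2, rel=1e-6)
        assert p1.mean_deviation_pct == pytest.approx(p0.mean_deviation_pct, rel=1e-6)
    frame = report.pairs_frame()
    assert set(frame["method_x"]) <= {"mc", "qmc", "ac"}
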