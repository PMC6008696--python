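"""Method-agreement statistics over a cohort of area measurements.

Pairs of estimators are compared with the root-mean-square deviation, Pearson
correlation, Bland–Altman bias and 95% limits of agreement, the mean
percentage deviation, and a paired t-test.  Note on terminology: bias ±
1.96·sd of the paired differences are *limits of agreement*, the range within
which ~95% of individual between-method differences fall — not a standard
-error confidence interval for the bias itself; they are labelled as such.

The mean percentage deviation divides each |difference| by the pairwise mean
by default (symmetric in the two methods); ``denominator="reference"``
divides by the second method instead, the convention used in the hematoma-
volume estimation literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FlapMetricsError

__all__ = [
    "rmsd",
    "pearson_r",
    "bland_altman",
    "BlandAltmanResult",
    "mean_deviation_pct",
    "paired_t",
    "CohortResults",
    "PairAgreement",
    "MethodSummary",
    "AgreementReport",
    "build_report",
]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise FlapMetricsError("inputs must be 1-D vectors of equal length")
    if len(x) == 0:
        raise FlapMetricsError("inputs must be nonempty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FlapMetricsError("inputs contain non-finite values")
    return x, y


def rmsd(x, y) -> float:
    """Root-mean-square deviation sqrt(mean((x − y)²))."""
    x, y = _paired(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise FlapMetricsError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FlapMetricsError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, 95% limits of agreement, and the per-case plot coordinates."""

    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)

    def __iter__(self):
        # unpacks as the (bias, loa_low, loa_high) triple
        return iter((self.bias, self.loa_low, self.loa_high))


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement: d = x − y, bias = mean(d), LoA = bias ± 1.96·sd(d).

    The sample (n−1) standard deviation is used.  Per-case (mean, difference)
    pairs are returned for plotting.
    """
    x, y = _paired(x, y)
    if len(x) < 2:
        raise FlapMetricsError("Bland-Altman needs at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(x + y) / 2.0,
        differences=d,
    )


def mean_deviation_pct(x, y, denominator: str = "mean") -> float:
    """Mean percentage deviation between paired measurements.

    ``denominator="mean"``: mean of |x−y| / ((x+y)/2) × 100 (symmetric);
    ``denominator="reference"``: divide by y instead.
    """
    x, y = _paired(x, y)
    if denominator == "mean":
        denom = (x + y) / 2.0
    elif denominator == "reference":
        denom = y
    else:
        raise FlapMetricsError(f"unknown denominator convention {denominator!r}")
    if np.any(denom <= 0):
        raise FlapMetricsError("mean deviation requires positive denominators")
    return float(np.mean(np.abs(x - y) / denom) * 100.0)


def paired_t(x, y) -> float:
    """Two-sided paired t-test p-value, t = mean(d)/(sd(d)/sqrt(n)), df = n−1."""
    x, y = _paired(x, y)
    if len(x) < 2:
        raise FlapMetricsError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise FlapMetricsError("paired t-test undefined for zero-variance differences")
    t = float(np.mean(d) / (sd / np.sqrt(len(d))))
    return float(2.0 * sps.t.sf(abs(t), df=len(d) - 1))


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class CohortResults:
    """Per-case areas (cm²) by method, plus optional ground truth."""

    areas: dict[str, np.ndarray]
    case_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.areas = {k: np.asarray(v, dtype=float) for k, v in self.areas.items()}
        lengths = {len(v) for v in self.areas.values()}
        if len(lengths) != 1:
            raise FlapMetricsError("all method vectors must have equal length")
        (self.n_cases,) = lengths
        if self.case_ids is None:
            self.case_ids = [f"case_{i:03d}" for i in range(self.n_cases)]
        if len(self.case_ids) != self.n_cases:
            raise FlapMetricsError("case_ids length mismatch")
        for name, v in self.areas.items():
            if not np.all(np.isfinite(v)):
                raise FlapMetricsError(f"method {name!r} has missing values")


@dataclass
class PairAgreement:
    method_x: str
    method_y: str
    rmsd_cm2: float
    pearson_r: float | None
    bias_cm2: float
    loa_low_cm2: float
    loa_high_cm2: float
    mean_deviation_pct: float
    paired_t_p: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class MethodSummary:
    method: str
    min_cm2: float
    max_cm2: float
    median_cm2: float
    mean_cm2: float
    sd_cm2: float


@dataclass
class AgreementReport:
    pairs: list[PairAgreement]
    methods: list[MethodSummary]
    metaestimate_cm2: np.ndarray = field(repr=False)
    n_cases: int = 0

    def pair(self, a: str, b: str) -> PairAgreement:
        for p in self.pairs:
            if {p.method_x, p.method_y} == {a, b}:
                return p
        raise KeyError((a, b))

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_cases": self.n_cases,
            "pairs": [vars(p).copy() for p in self.pairs],
            "methods": [vars(m).copy() for m in self.methods],
            "metaestimate_cm2": [float(v) for v in self.metaestimate_cm2],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgreementReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            pairs=[PairAgreement(**p) for p in d["pairs"]],
            methods=[MethodSummary(**m) for m in d["methods"]],
            metaestimate_cm2=np.asarray(d["metaestimate_cm2"], dtype=float),
            n_cases=d["n_cases"],
        )

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])

    def methods_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.methods])


def build_report(
    results: CohortResults,
    pairs: list[tuple[str, str]] | None = None,
    meta_methods: tuple[str, ...] = ("mc", "qmc", "ac"),
    denominator: str = "mean",
) -> AgreementReport:
    """Assemble all pairwise agreement statistics and per-method summaries.

    By default every unordered pair of measured methods is compared.  The
    metaestimate is the per-case mean of the three estimators (when present).
    Degenerate statistics (zero-variance correlation or t-test) are recorded
    as None with an explanatory flag instead of failing the whole report.
    """
    if results.n_cases < 3:
        raise FlapMetricsError("agreement report needs at least 3 cases")
    names = list(results.areas)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    out_pairs: list[PairAgreement] = []
    for a, b in pairs:
        x, y = results.areas[a], results.areas[b]
        flags: list[str] = []
        try:
            r = pearson_r(x, y)
        except FlapMetricsError:
            r, flags = None, flags + ["undefined_correlation"]
        ba = bland_altman(x, y)
        try:
            p = paired_t(x, y)
        except FlapMetricsError:
            p = None
            flags.append("degenerate_t_test")
        out_pairs.append(
            PairAgreement(
                method_x=a,
                method_y=b,
                rmsd_cm2=rmsd(x, y),
                pearson_r=r,
                bias_cm2=ba.bias,
                loa_low_cm2=ba.loa_low,
                loa_high_cm2=ba.loa_high,
                mean_deviation_pct=mean_deviation_pct(x, y, denominator),
                paired_t_p=p,
                flags=flags,
            )
        )
    summaries = [
        MethodSummary(
            method=name,
            min_cm2=float(v.min()),
            max_cm2=float(v.max()),
            median_cm2=float(np.median(v)),
            mean_cm2=float(v.mean()),
            sd_cm2=float(v.std(ddof=1)),
        )
        for name, v in results.areas.items()
    ]
    present = [m for m in meta_methods if m in results.areas]
    meta = (
        np.mean([results.areas[m] for m in present], axis=0)
        if present
        else np.full(results.n_cases, np.nan)
    )
    return AgreementReport(
        pairs=out_pairs, methods=summaries, metaestimate_cm2=meta, n_cases=results.n_cases
    )
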