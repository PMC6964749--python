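"""Cohort comparison statistics: paired tests with normality-based selection,
replicate averaging, inter-delivery variation, and metric-GPR correlations.

Test selection follows the study protocol: differences are checked with
Shapiro-Wilk at alpha = 0.05; normal differences get a two-sided paired
t-test, non-normal ones a two-sided Wilcoxon signed-rank test (exact null
for n <= 25 without ties, normal approximation with continuity correction
otherwise; zero differences are dropped).  No multiple-testing correction is
applied by default (a Holm option exists but is off), matching per-test
reporting at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "CohortReport",
    "choose_paired_test",
    "paired_compare",
    "average_replicates",
    "interdelivery_variation_compare",
    "correlate",
    "build_report",
]


@dataclass
class PairedSample:
    labels: list[str]
    arm_a: np.ndarray
    arm_b: np.ndarray

    def __post_init__(self) -> None:
        self.arm_a = np.asarray(self.arm_a, float)
        self.arm_b = np.asarray(self.arm_b, float)
        if self.arm_a.shape != self.arm_b.shape or len(self.labels) != self.arm_a.size:
            raise ValueError("arms and labels must have equal length")
        if self.arm_a.size < 3:
            raise ValueError("paired comparison needs at least 3 pairs")
        if not (np.all(np.isfinite(self.arm_a)) and np.all(np.isfinite(self.arm_b))):
            raise ValueError("paired values must be finite")

    @property
    def differences(self) -> np.ndarray:
        return self.arm_b - self.arm_a


def choose_paired_test(differences: np.ndarray, alpha: float = 0.05) -> str:
    """'t_test' when Shapiro-Wilk accepts normality of the differences,
    'wilcoxon' otherwise; 'degenerate' for (near-)constant differences."""
    d = np.asarray(differences, float)
    if d.size < 3:
        raise ValueError("need at least 3 differences")
    if np.ptp(d) < 1e-12:
        return "degenerate"
    p = sps.shapiro(d).pvalue
    return "t_test" if p >= alpha else "wilcoxon"


@dataclass
class PairedTestResult:
    test: str
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n: int
    flags: list[str] = field(default_factory=list)


def paired_compare(sample: PairedSample, test: str | None = None) -> PairedTestResult:
    """Two-sided paired comparison of the two arms.

    ``test`` of None triggers normality-based selection.  Identical arms
    yield p = 1 under the t-test convention; a degenerate nonzero constant
    difference is flagged.
    """
    d = sample.differences
    flags: list[str] = []
    if test is None:
        test = choose_paired_test(d)
    base = dict(mean_a=float(sample.arm_a.mean()), sd_a=float(sample.arm_a.std(ddof=1)),
                mean_b=float(sample.arm_b.mean()), sd_b=float(sample.arm_b.std(ddof=1)),
                n=d.size)
    if test == "degenerate" or np.ptp(d) < 1e-12:
        if np.allclose(d, 0.0):
            return PairedTestResult("t_test", 0.0, 1.0, flags=["identical_arms"], **base)
        return PairedTestResult("degenerate", float("nan"), float("nan"),
                                flags=["constant_nonzero_differences"], **base)
    if test == "t_test":
        res = sps.ttest_rel(sample.arm_b, sample.arm_a)
        return PairedTestResult("t_test", float(res.statistic), float(res.pvalue),
                                flags=flags, **base)
    if test == "wilcoxon":
        nz = d[d != 0.0]
        if nz.size == 0:
            return PairedTestResult("wilcoxon", 0.0, 1.0, flags=["all_zero"], **base)
        ties = np.unique(np.abs(nz)).size < nz.size
        method = "exact" if (nz.size <= 25 and not ties) else "approx"
        if method == "approx":
            flags.append("normal_approximation")
        res = sps.wilcoxon(nz, method=method, correction=(method == "approx"))
        return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                                flags=flags, **base)
    raise ValueError(f"unknown test {test!r}")


def average_replicates(gprs: np.ndarray | list) -> tuple[np.ndarray, np.ndarray]:
    """Per-plan mean and sample SD over delivery replicates.

    ``gprs`` has shape (n_plans, n_replicates); a single replicate yields an
    undefined (NaN) SD rather than zero.
    """
    arr = np.atleast_2d(np.asarray(gprs, float))
    mean = arr.mean(axis=1)
    if arr.shape[1] < 2:
        return mean, np.full(arr.shape[0], np.nan)
    return mean, arr.std(axis=1, ddof=1)


def interdelivery_variation_compare(sds_a: np.ndarray, sds_b: np.ndarray,
                                    labels: list[str] | None = None) -> PairedTestResult:
    """Paired comparison of per-plan replicate SDs between the two arms."""
    a = np.asarray(sds_a, float)
    b = np.asarray(sds_b, float)
    labels = labels or [str(i) for i in range(a.size)]
    return paired_compare(PairedSample(labels, a, b))


def correlate(metric: np.ndarray, gpr: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (R, p); (nan, nan) for constant input."""
    m = np.asarray(metric, float)
    g = np.asarray(gpr, float)
    if m.size != g.size or m.size < 3:
        raise ValueError("correlation needs two equal-length vectors, n >= 3")
    if np.ptp(m) < 1e-12 or np.ptp(g) < 1e-12:
        return float("nan"), float("nan")
    res = sps.pearsonr(m, g)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CohortReport:
    """Per-metric arm comparison table plus a metric x GPR correlation matrix."""

    comparisons: pd.DataFrame      # metric, mean_a, sd_a, mean_b, sd_b, test, p, significant
    correlations: pd.DataFrame | None = None   # complexity metric x gamma criteria: R
    correlation_p: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.comparisons.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {"comparisons": self.comparisons.to_dict(orient="records")}
        if self.correlations is not None:
            payload["correlations"] = self.correlations.to_dict()
            payload["correlation_p"] = self.correlation_p.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_report(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                 alpha: float = 0.05, holm: bool = False,
                 gpr_columns: list[str] | None = None,
                 complexity_columns: list[str] | None = None) -> CohortReport:
    """Compare every shared numeric column of two per-plan metric tables.

    Rows are matched by position (paired plans).  When ``gpr_columns`` and
    ``complexity_columns`` are given, a pooled-arms Pearson correlation
    matrix (complexity x GPR) is attached.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("arm tables must have equal row counts (paired plans)")
    rows = []
    labels = [str(i) for i in range(len(metrics_a))]
    for col in metrics_a.columns:
        if col not in metrics_b.columns or not np.issubdtype(metrics_a[col].dtype, np.number):
            continue
        sample = PairedSample(labels, metrics_a[col].to_numpy(), metrics_b[col].to_numpy())
        res = paired_compare(sample)
        rows.append({"metric": col, "mean_a": res.mean_a, "sd_a": res.sd_a,
                     "mean_b": res.mean_b, "sd_b": res.sd_b, "test": res.test,
                     "p": res.p_value, "n": res.n})
    table = pd.DataFrame(rows)
    if holm:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
        table["significant"] = table["p_holm"] < alpha
    else:
        table["significant"] = table["p"] < alpha

    corr = corr_p = None
    if gpr_columns and complexity_columns:
        pooled = pd.concat([metrics_a, metrics_b], ignore_index=True)
        corr = pd.DataFrame(index=complexity_columns, columns=gpr_columns, dtype=float)
        corr_p = corr.copy()
        for m_col in complexity_columns:
            for g_col in gpr_columns:
                r, p = correlate(pooled[m_col].to_numpy(), pooled[g_col].to_numpy())
                corr.loc[m_col, g_col] = r
                corr_p.loc[m_col, g_col] = p
    return CohortReport(table, corr, corr_p)
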