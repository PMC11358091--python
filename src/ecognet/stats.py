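"""Group statistics: gated paired tests and complexity-connectivity correlation.

Each paired comparison runs Shapiro-Wilk normality on both samples and
Levene's test across them at the gate level (default 0.05); the
paired-samples t-test is used only when both samples pass normality and
the variances are homogeneous, otherwise the Wilcoxon signed-rank test
on the paired differences. (A ``literal_rank_sum`` flag swaps in the
unpaired rank-sum statistic for fidelity runs, at the cost of ignoring
the pairing.) Complexity-connectivity association is Pearson's r over
matched epoch x region observations, for all four estimator pairs:
PLZC-coherence, PE-coherence, PLZC-MI, PE-MI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupStatResult:
    comparison: str
    test_used: str  # "paired_t" | "wilcoxon" | "rank_sum"
    statistic: float
    p: float
    n_pairs: int
    normality_p: tuple[float, float]
    levene_p: float

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p": self.p,
            "n_pairs": self.n_pairs,
            "normality_p_a": self.normality_p[0],
            "normality_p_b": self.normality_p[1],
            "levene_p": self.levene_p,
        }


@dataclass
class CorrelationResult:
    condition: str
    region: str
    x_metric: str  # "pe" | "plzc"
    y_metric: str  # "coherence" | "mi"
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _safe_shapiro(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # a degenerate sample is treated as non-normal
    return float(sps.shapiro(x).pvalue)


def select_test(normality_p_a: float, normality_p_b: float, levene_p: float,
                alpha_gate: float = 0.05) -> str:
    """The test-selection gate as a pure function of the three gate p-values."""
    if normality_p_a > alpha_gate and normality_p_b > alpha_gate and levene_p > alpha_gate:
        return "paired_t"
    return "wilcoxon"


def choose_and_run_test(a, b, alpha_gate: float = 0.05, comparison: str = "",
                        literal_rank_sum: bool = False) -> GroupStatResult:
    """Normality/variance-gated paired comparison of two matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must be paired (equal length)")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    sw_a, sw_b = _safe_shapiro(a), _safe_shapiro(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        levene_p = 1.0
    else:
        levene_p = float(sps.levene(a, b).pvalue)
    test = select_test(sw_a, sw_b, levene_p, alpha_gate)
    if test == "paired_t":
        res = sps.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif literal_rank_sum:
        res = sps.ranksums(a, b)
        test, stat, p = "rank_sum", float(res.statistic), float(res.pvalue)
    else:
        diff = a - b
        if np.all(diff == 0):
            stat, p = 0.0, 1.0  # no difference anywhere
        else:
            res = sps.wilcoxon(a, b, zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # identical samples make t undefined; report no difference
        stat, p = 0.0, 1.0
    return GroupStatResult(
        comparison=comparison,
        test_used=test,
        statistic=stat,
        p=p,
        n_pairs=len(a),
        normality_p=(sw_a, sw_b),
        levene_p=levene_p,
    )


COMPLEXITY_METRICS = ("plzc", "pe")
CONNECTIVITY_METRICS = ("coherence", "mi")


def complexity_connectivity_correlation(
    region_complexity: pd.DataFrame,
    region_connectivity: pd.DataFrame,
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Pearson r between complexity and within-region connectivity.

    Inputs are tidy tables keyed by (subject, condition, day, epoch,
    region): ``region_complexity`` with ``pe``/``plzc`` columns (region
    means) and ``region_connectivity`` with ``coherence``/``mi`` columns
    (within-region means). Observations are matched on the full key;
    one result per condition x region x metric pair. Combinations with
    fewer than ``min_n`` matched points are omitted.
    """
    keys = ["subject", "condition", "day", "epoch", "region"]
    merged = region_complexity.merge(region_connectivity, on=keys)
    out: list[CorrelationResult] = []
    for (condition, region), grp in merged.groupby(["condition", "region"]):
        for x_metric in COMPLEXITY_METRICS:
            for y_metric in CONNECTIVITY_METRICS:
                x = grp[x_metric].to_numpy()
                y = grp[y_metric].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_n:
                    continue
                r, p = sps.pearsonr(x[ok], y[ok])
                out.append(
                    CorrelationResult(
                        condition=condition, region=region,
                        x_metric=x_metric, y_metric=y_metric,
                        r=float(r), p=float(p), n=int(ok.sum()),
                    )
                )
    return out
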