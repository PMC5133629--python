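"""Shape-metric time series and first-divergence statistics between conditions.

For each condition, per-object shape metrics are pooled across replicates and
fields of view at every timepoint. For a pair of conditions and one metric,
an F statistic compares the two per-timepoint samples; the divergence time is
the first schedule timestamp at which p < alpha (persisting for k consecutive
timepoints, k = 1 by default). Conditions whose distributions never separate
report NEVER.

"F-test" is implemented in two modes: the default is the two-group one-way
ANOVA F (a location test; identical to the squared pooled-variance t
statistic), with a classical variance-ratio F available as an alternative.
The mode used is recorded in every result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["METRICS", "NEVER", "MetricTimeSeries", "FTestResult",
           "DivergenceResult", "assemble_timeseries", "f_test",
           "divergence_time", "divergence_table", "mean_ratio_trajectory"]

#: canonical metric names -> shape-table columns
METRICS = {
    "area": "area_um2",
    "circularity": "circularity",
    "major_axis": "major_axis_um",
    "minor_axis": "minor_axis_um",
}

NEVER = float("inf")  # sentinel divergence hour for "never diverged"


@dataclass
class MetricTimeSeries:
    """One condition x metric: per-timepoint pooled value lists."""

    condition: str
    metric: str
    timestamps_h: np.ndarray
    values: list[np.ndarray]  # one array per timestamp, pooled over rep/FOV

    @property
    def means(self) -> np.ndarray:
        return np.array([v.mean() if len(v) else np.nan for v in self.values])

    @property
    def stds(self) -> np.ndarray:
        return np.array([v.std(ddof=1) if len(v) > 1 else np.nan for v in self.values])


def assemble_timeseries(records: pd.DataFrame,
                        metrics=tuple(METRICS)) -> dict[tuple[str, str], MetricTimeSeries]:
    """Pool per-object records into per-condition, per-metric time series.

    All objects from the same condition and timestamp are combined across
    replicates and fields of view. Returns ``{(condition, metric): series}``.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; choose from {sorted(METRICS)}")
    out: dict[tuple[str, str], MetricTimeSeries] = {}
    for cond, sub in records.groupby("condition", sort=False):
        ts = np.array(sorted(sub["timestamp_h"].unique()))
        grouped = {t: g for t, g in sub.groupby("timestamp_h")}
        for m in metrics:
            col = METRICS[m]
            vals = [grouped[t][col].to_numpy(float) for t in ts]
            out[(str(cond), m)] = MetricTimeSeries(str(cond), m, ts, vals)
    return out


@dataclass(frozen=True)
class FTestResult:
    F: float
    p: float
    df: tuple[float, float]
    mode: str
    degenerate: bool = False


def f_test(a, b, mode: str = "anova") -> FTestResult:
    """Compare two samples by an F statistic.

    ``mode="anova"`` (default): two-group one-way ANOVA F with df
    (1, n_a + n_b - 2); equals the square of the pooled-variance two-sample
    t statistic, so it tests a difference in means.
    ``mode="variance"``: classical variance-ratio F = s_a^2 / s_b^2 with df
    (n_a - 1, n_b - 1) and a two-sided p-value.

    Zero pooled within-group variance is degenerate: equal means give
    (F=0, p=1); distinct means give p=0 with the degenerate flag set.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    na, nb = len(a), len(b)
    if mode == "anova":
        dfn, dfd = 1.0, float(na + nb - 2)
        ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
        gm = (a.sum() + b.sum()) / (na + nb)
        ssb = na * (a.mean() - gm) ** 2 + nb * (b.mean() - gm) ** 2
        if ssw == 0.0:
            if ssb == 0.0:
                return FTestResult(0.0, 1.0, (dfn, dfd), mode)
            return FTestResult(float("inf"), 0.0, (dfn, dfd), mode, degenerate=True)
        F = (ssb / dfn) / (ssw / dfd)
        p = float(stats.f.sf(F, dfn, dfd))
        return FTestResult(float(F), p, (dfn, dfd), mode)
    if mode == "variance":
        dfn, dfd = float(na - 1), float(nb - 1)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if vb == 0.0:
            if va == 0.0:
                return FTestResult(1.0, 1.0, (dfn, dfd), mode, degenerate=True)
            return FTestResult(float("inf"), 0.0, (dfn, dfd), mode, degenerate=True)
        F = float(va / vb)
        cdf = stats.f.cdf(F, dfn, dfd)
        p = float(2.0 * min(cdf, 1.0 - cdf))
        return FTestResult(F, min(p, 1.0), (dfn, dfd), mode)
    raise ValueError("mode must be 'anova' or 'variance'")


def divergence_time(p_values, timestamps_h, alpha: float = 0.05,
                    persistence_k: int = 1) -> float:
    """First timestamp at which p < alpha for ``persistence_k`` consecutive
    timepoints; ``NEVER`` (inf) if the series never diverges. NaN p-values
    (timepoints without enough objects) break a run."""
    p = np.asarray(p_values, float)
    t = np.asarray(timestamps_h, float)
    if len(p) == 0:
        raise ValueError("empty p-value series")
    if len(p) != len(t):
        raise ValueError("p-values and timestamps must align")
    if persistence_k < 1:
        raise ValueError("persistence_k must be >= 1")
    sig = (p < alpha) & np.isfinite(p)
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= persistence_k:
            return float(t[i - persistence_k + 1])
    return NEVER


@dataclass
class DivergenceResult:
    """Divergence analysis of one condition pair and one metric."""

    condition_pair: tuple[str, str]
    metric: str
    alpha: float
    persistence_k: int
    timestamps_h: np.ndarray
    F: np.ndarray
    p: np.ndarray
    divergence_hour: float  # hours, or NEVER (inf)
    mode: str = "anova"

    @property
    def diverged(self) -> bool:
        return math.isfinite(self.divergence_hour)


def _pair_divergence(sa: MetricTimeSeries, sb: MetricTimeSeries,
                     alpha, persistence_k, mode) -> DivergenceResult:
    if len(sa.timestamps_h) != len(sb.timestamps_h) or not np.allclose(
            sa.timestamps_h, sb.timestamps_h):
        common = np.intersect1d(sa.timestamps_h, sb.timestamps_h)
    else:
        common = sa.timestamps_h
    ia = {t: i for i, t in enumerate(sa.timestamps_h)}
    ib = {t: i for i, t in enumerate(sb.timestamps_h)}
    Fs, ps = [], []
    for t in common:
        va, vb = sa.values[ia[t]], sb.values[ib[t]]
        if len(va) < 2 or len(vb) < 2:
            Fs.append(np.nan)
            ps.append(np.nan)
            continue
        r = f_test(va, vb, mode=mode)
        Fs.append(r.F)
        ps.append(r.p)
    p = np.asarray(ps)
    hour = divergence_time(p, common, alpha=alpha, persistence_k=persistence_k)
    return DivergenceResult((sa.condition, sb.condition), sa.metric, alpha,
                            persistence_k, np.asarray(common, float),
                            np.asarray(Fs), p, hour, mode)


def divergence_table(records: pd.DataFrame, pairs=None,
                     metrics=tuple(METRICS), alpha: float = 0.05,
                     persistence_k: int = 1, mode: str = "anova"):
    """Divergence hours for every metric x condition pair.

    Returns ``(table, results)`` where ``table`` is a wide DataFrame (rows =
    metrics, columns = "condA/condB" pairs, entries = hours or "N/A") and
    ``results`` maps (pair, metric) to the full :class:`DivergenceResult`.
    If ``pairs`` is None all condition pairs are compared.
    """
    series = assemble_timeseries(records, metrics)
    conditions = list(dict.fromkeys(records["condition"]))
    if pairs is None:
        pairs = list(itertools.combinations(conditions, 2))
    results: dict[tuple[tuple[str, str], str], DivergenceResult] = {}
    cells: dict[str, dict[str, object]] = {}
    for ca, cb in pairs:
        col = f"{ca}/{cb}"
        cells[col] = {}
        for m in metrics:
            res = _pair_divergence(series[(ca, m)], series[(cb, m)],
                                   alpha, persistence_k, mode)
            results[((ca, cb), m)] = res
            cells[col][m] = res.divergence_hour if res.diverged else "N/A"
    table = pd.DataFrame({col: [cells[col][m] for m in metrics]
                          for col in cells}, index=list(metrics))
    table.index.name = "metric"
    return table, results


def mean_ratio_trajectory(series_a: MetricTimeSeries,
                          series_b: MetricTimeSeries):
    """Per-timepoint ratio of means mean(A)/mean(B) and its summary distance
    from unity (median absolute log ratio). Zero denominator means yield NaN
    ratios, excluded from the summary."""
    if len(series_a.timestamps_h) != len(series_b.timestamps_h) or not np.allclose(
            series_a.timestamps_h, series_b.timestamps_h):
        raise ValueError("series timestamps must align")
    ma, mb = series_a.means, series_b.means
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mb != 0, ma / mb, np.nan)
    ok = np.isfinite(ratio) & (ratio > 0)
    summary = float(np.median(np.abs(np.log(ratio[ok])))) if ok.any() else float("nan")
    return ratio, summary
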