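"""Relative gene expression by the comparative CT (delta-delta-CT) method.

Target-gene CT values are normalized against one or more housekeeping genes
(several housekeepers are combined by the arithmetic mean of their CTs,
equivalent to the geometric mean of their expression levels), calibrated
against a reference condition, and converted to fold changes via
fold = 2^(-ddCT). Group comparisons use the unpaired two-sample pooled-
variance Student's t-test on per-replicate dCT values. No amplification-
efficiency correction is applied (doubling per cycle is assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from numbers import Real

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "ddct_fold_change", "compare_dct", "ddct_analysis",
           "synthetic_ct_table", "DdctResult", "TTestResult", "CT_COLUMNS"]

CT_COLUMNS = ["sample_id", "condition", "gene", "ct_value", "replicate"]


def delta_ct(ct_target: float, ct_housekeeping) -> float:
    """dCT = CT_target - CT_housekeeping (mean CT if several housekeepers)."""
    if isinstance(ct_housekeeping, Real):
        hk = [float(ct_housekeeping)]
    else:
        hk = [float(x) for x in ct_housekeeping]
    if not hk:
        raise ValueError("at least one housekeeping CT is required")
    vals = [float(ct_target)] + hk
    if not all(math.isfinite(v) and v > 0 for v in vals):
        raise ValueError("CT values must be finite and positive")
    return float(ct_target) - sum(hk) / len(hk)


@dataclass(frozen=True)
class DdctResult:
    gene: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    log_fold: float
    log_base: int
    t_stat: float | None = None
    p_value: float | None = None


def ddct_fold_change(delta_ct_sample: float, delta_ct_calibrator: float,
                     log_base: int = 2, *, gene: str = "", condition: str = "") -> DdctResult:
    """ddCT = dCT_sample - dCT_calibrator; fold = 2^(-ddCT); log-fold in the
    declared base (2 for osteogenic-style panels, 10 for myogenic-style)."""
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    ddct = float(delta_ct_sample) - float(delta_ct_calibrator)
    fold = 2.0 ** (-ddct)
    log_fold = math.log2(fold) if log_base == 2 else math.log10(fold)
    return DdctResult(gene, condition, float(delta_ct_sample), ddct, fold,
                      log_fold, log_base)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    degenerate: bool = False


def compare_dct(group_a, group_b) -> TTestResult:
    """Unpaired two-sample pooled-variance Student's t-test on dCT values.

    Zero pooled variance with equal means gives (t=0, p=1); with unequal
    means the result is flagged degenerate with p=0.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    na, nb = len(a), len(b)
    df = float(na + nb - 2)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(math.copysign(float("inf"), diff), 0.0, df,
                           degenerate=True)
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), p, df)


def _replicate_dct(sub: pd.DataFrame, gene: str, housekeeping: list[str]) -> pd.Series:
    """Per-replicate dCT for one (condition, gene), indexed by replicate."""
    tgt = sub[sub["gene"] == gene].set_index("replicate")["ct_value"]
    hks = []
    for hk in housekeeping:
        h = sub[sub["gene"] == hk].set_index("replicate")["ct_value"]
        hks.append(h)
    if not hks:
        raise ValueError("at least one housekeeping gene is required")
    hk_mean = pd.concat(hks, axis=1).mean(axis=1)
    common = tgt.index.intersection(hk_mean.index)
    if len(common) == 0:
        raise ValueError(f"no replicate has both {gene!r} and housekeeping CTs")
    return (tgt.loc[common] - hk_mean.loc[common]).sort_index()


def ddct_analysis(ct_table: pd.DataFrame, housekeeping, calibrator: str,
                  log_base: int = 2, genes=None) -> pd.DataFrame:
    """Full comparative-CT analysis of a long-format CT table.

    ``ct_table`` columns: sample_id, condition, gene, ct_value, replicate.
    dCT is computed per replicate; ddCT calibrates each condition's mean dCT
    against the ``calibrator`` condition; the t-test compares the
    per-replicate dCT samples of condition vs calibrator.

    Returns one row per (gene, condition) with delta_ct (mean), ddCT, fold
    change, log-fold in ``log_base``, and t/p against the calibrator (NaN for
    the calibrator itself).
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    if isinstance(housekeeping, str):
        housekeeping = [housekeeping]
    housekeeping = list(housekeeping)
    bad = ct_table["ct_value"]
    if not np.all(np.isfinite(bad)) or (bad <= 0).any():
        raise ValueError("CT values must be finite and positive")
    if calibrator not in set(ct_table["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} not in table")
    if genes is None:
        genes = [g for g in ct_table["gene"].unique() if g not in housekeeping]
    rows = []
    for gene in genes:
        cal_dct = _replicate_dct(
            ct_table[ct_table["condition"] == calibrator], gene, housekeeping)
        for cond, sub in ct_table.groupby("condition", sort=False):
            dct = _replicate_dct(sub, gene, housekeeping)
            res = ddct_fold_change(float(dct.mean()), float(cal_dct.mean()),
                                   log_base, gene=gene, condition=str(cond))
            if cond == calibrator:
                t_stat, p_val = float("nan"), float("nan")
            else:
                tt = compare_dct(dct.to_numpy(), cal_dct.to_numpy())
                t_stat, p_val = tt.t, tt.p
            rows.append({
                "gene": gene, "condition": cond,
                "delta_ct": res.delta_ct, "delta_delta_ct": res.delta_delta_ct,
                "fold_change": res.fold_change, "log_fold": res.log_fold,
                "log_base": log_base, "n_replicates": len(dct),
                "t_stat": t_stat, "p_value": p_val,
            })
    return pd.DataFrame(rows)


def synthetic_ct_table(conditions=("flat", "flat-osteo", "random", "aligned"),
                       genes=("ALP", "COL1A1", "OPN", "RUNX2", "BMP2"),
                       housekeeping=("HK18S",), n_replicates: int = 3,
                       effects: dict | None = None, rng_seed: int = 0,
                       ct_noise_sd: float = 0.2) -> pd.DataFrame:
    """Generate a plausible long-format CT table for testing and demos.

    ``effects`` maps (gene, condition) to a true log2 fold change relative to
    the first condition; positive effects lower the target CT by that many
    cycles (one cycle per doubling). Housekeeping genes sit near CT 18 and
    targets near CT 26, with Gaussian replicate noise of ``ct_noise_sd``
    cycles.
    """
    rng = np.random.default_rng(rng_seed)
    effects = effects or {}
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            for hk in housekeeping:
                rows.append({"sample_id": sample, "condition": cond,
                             "gene": hk, "replicate": rep,
                             "ct_value": 18.0 + rng.normal(0, ct_noise_sd)})
            for gene in genes:
                shift = effects.get((gene, cond), 0.0)
                rows.append({"sample_id": sample, "condition": cond,
                             "gene": gene, "replicate": rep,
                             "ct_value": 26.0 - shift + rng.normal(0, ct_noise_sd)})
    return pd.DataFrame(rows, columns=CT_COLUMNS)
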