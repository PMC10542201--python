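"""Pooled-vs-non-pooled genotyping quality comparison and accounting tables.

Sample-level quality metrics (DQC, QC call rate, call rate) are
summarized per group (species x pooled/non-pooled) with n / mean / SD /
median, contrasted with an unequal-variance (Welch) t-test, and the
two-stage sample filtering is reported as an exact integer accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("dqc", "qc_call_rate", "call_rate")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    df is the real-valued Welch-Satterthwaite approximation. Two
    zero-variance groups with equal means give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


@dataclass
class GroupQualityStats:
    group: str
    metric: str
    n: int
    mean: float
    sd: float
    median: float


def group_quality_stats(sample_qc: pd.DataFrame,
                        grouping: pd.Series | list[str] | np.ndarray,
                        ) -> pd.DataFrame:
    """n / mean / SD / median of each quality metric per group.

    ``sample_qc`` needs columns dqc, qc_call_rate, call_rate (call_rate
    NaN for samples that never reached final genotyping — its stats
    therefore cover only successfully genotyped samples). SD is NA for
    n < 2; empty groups yield an all-NA row.
    """
    labels = np.asarray(grouping)
    if len(labels) != len(sample_qc):
        raise ValueError("grouping must label every sample")
    rows = []
    for grp in dict.fromkeys(labels.tolist()):
        sub = sample_qc[labels == grp]
        for metric in METRICS:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(GroupQualityStats(
                grp, metric, n,
                float(vals.mean()) if n else float("nan"),
                float(vals.std(ddof=1)) if n >= 2 else float("nan"),
                float(np.median(vals)) if n else float("nan")))
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_pooled(sample_qc: pd.DataFrame, pooled: pd.Series | np.ndarray,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Welch contrast of each metric between pooled and non-pooled samples."""
    pooled = np.asarray(pooled, dtype=bool)
    rows = []
    for metric in METRICS:
        x = sample_qc.loc[pooled, metric].dropna().to_numpy(dtype=float)
        y = sample_qc.loc[~pooled, metric].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            rows.append({"metric": metric, "t": np.nan, "df": np.nan,
                         "p": np.nan, "significant": pd.NA,
                         "mean_pooled": x.mean() if len(x) else np.nan,
                         "mean_non_pooled": y.mean() if len(y) else np.nan})
            continue
        res = welch_t_test(x, y)
        rows.append({"metric": metric, "t": res.t, "df": res.df, "p": res.p,
                     "significant": res.p < alpha,
                     "mean_pooled": float(x.mean()),
                     "mean_non_pooled": float(y.mean())})
    return pd.DataFrame(rows)


def sample_accounting(screened: int, fail_dqc: int, fail_qccr: int,
                      later_removed: int = 0) -> pd.DataFrame:
    """Exact integer accounting of the two-stage sample filtering.

    passed = screened - fail_dqc - fail_qccr - later_removed; raises on
    inconsistent inputs (negative passed or negative components).
    """
    for name, v in (("screened", screened), ("fail_dqc", fail_dqc),
                    ("fail_qccr", fail_qccr), ("later_removed", later_removed)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer")
    passed = screened - fail_dqc - fail_qccr - later_removed
    if passed < 0:
        raise ValueError("inconsistent accounting: more failures than samples")
    return pd.DataFrame([
        {"stage": "screened", "n": screened},
        {"stage": "fail_dqc", "n": fail_dqc},
        {"stage": "fail_qc_call_rate", "n": fail_qccr},
        {"stage": "removed_later", "n": later_removed},
        {"stage": "passed", "n": passed},
    ])
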