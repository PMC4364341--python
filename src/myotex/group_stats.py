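"""Two-group statistics: Welch's t-test (summary or raw data),
Benjamini-Hochberg FDR adjustment, and significance/trend flagging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "welch_t",
    "welch_t_from_samples",
    "bh_fdr",
    "flag",
    "compare_groups",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_TREND = 0.2


@dataclass
class StatResult:
    endpoint: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    mean_difference: float
    t: float
    df: float
    p: float
    p_adjusted: float | None = None
    flag: str | None = None

    def as_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "mean1": self.mean1, "sd1": self.sd1, "n1": self.n1,
            "mean2": self.mean2, "sd2": self.sd2, "n2": self.n2,
            "mean_difference": self.mean_difference,
            "t": self.t, "df": self.df, "p": self.p,
            "p_adjusted": self.p_adjusted, "flag": self.flag,
        }


def welch_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    endpoint: str = "", pooled: bool = False,
) -> StatResult:
    """Two-sided two-sample t-test from summary statistics.

    Default is Welch's unequal-variance form with Satterthwaite degrees of
    freedom; ``pooled=True`` selects the classic equal-variance Student
    test (used for the histopathology family).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both sds are zero: test degenerate")
    v1, v2 = sd1**2, sd2**2
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (mean1 - mean2) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        endpoint=endpoint,
        mean1=float(mean1), sd1=float(sd1), n1=int(n1),
        mean2=float(mean2), sd2=float(sd2), n2=int(n2),
        mean_difference=float(mean1 - mean2),
        t=float(t), df=float(df), p=p,
    )


def welch_t_from_samples(
    x1: Sequence[float], x2: Sequence[float], endpoint: str = "", pooled: bool = False
) -> StatResult:
    """Same test computed from raw samples (summaries computed first, so
    the result agrees exactly with :func:`welch_t` on those summaries)."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    return welch_t(
        a.mean(), a.std(ddof=1), a.size,
        b.mean(), b.std(ddof=1), b.size,
        endpoint=endpoint, pooled=pooled,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    ``adj[k] = min_{rank >= rank(k)} (p * m / rank)`` capped at 1; the
    adjustment is monotone and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def flag(p: float, alpha_sig: float = ALPHA_SIGNIFICANT, alpha_trend: float = ALPHA_TREND) -> str:
    """'significant' if p < 0.05, 'trend' if p < 0.2, else 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < alpha_sig:
        return "significant"
    if p < alpha_trend:
        return "trend"
    return "ns"


def compare_groups(
    table: pd.DataFrame,
    endpoints: Sequence[str],
    groups: tuple[str, str],
    group_col: str = "group",
    adjust: bool = True,
    pooled: bool = False,
    alpha_sig: float = ALPHA_SIGNIFICANT,
    alpha_trend: float = ALPHA_TREND,
) -> pd.DataFrame:
    """One test per endpoint between two groups, with optional FDR.

    The FDR family is exactly the set of endpoints tested here (family
    membership is the caller's configuration). Endpoints where either
    group has fewer than 2 non-missing values are skipped with a warning
    column rather than an error, but if no endpoint is testable, or a
    requested group is absent, an error is raised.
    """
    g1, g2 = groups
    present = set(table[group_col].unique())
    missing = {g1, g2} - present
    if missing:
        raise ValueError(f"group(s) not present in table: {sorted(missing)}")
    results: list[StatResult] = []
    skipped: list[str] = []
    for ep in endpoints:
        a = table.loc[table[group_col] == g1, ep].dropna().to_numpy(dtype=float)
        b = table.loc[table[group_col] == g2, ep].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            skipped.append(ep)
            continue
        try:
            results.append(welch_t_from_samples(a, b, endpoint=ep, pooled=pooled))
        except ValueError:
            skipped.append(ep)
    if not results:
        raise ValueError("no endpoint testable between the requested groups")
    if adjust:
        adj = bh_fdr([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
            r.flag = flag(float(pa), alpha_sig, alpha_trend)
    else:
        for r in results:
            r.p_adjusted = None
            r.flag = flag(r.p, alpha_sig, alpha_trend)
    df = pd.DataFrame([r.as_dict() for r in results])
    df.attrs["skipped_endpoints"] = skipped
    return df
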