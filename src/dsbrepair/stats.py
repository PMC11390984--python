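"""Exact small-sample statistics and summary reporting.

The study's comparisons are 4-vs-4 biological replicates, where the
two-tailed Mann-Whitney U test admits exact enumeration: all C(8,4) = 70
assignments of the pooled midranks are tabulated, and the two-tailed p is
twice the smaller tail probability of the observed U, capped at 1.  Complete
separation of 4 vs 4 gives p = 2/70 ~ 0.029, the smallest attainable value
at this design size.  Frequency *ratios* between constructs (e.g. a splicing
construct over its non-splicing control) are formed per replicate, pairing
replicates by library-ID order, before the rank test compares cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 12  # pooled sample size up to which full enumeration is used


def mwu_exact(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with exact permutation p for small samples.

    Midranks handle ties.  For pooled sizes above ``EXACT_LIMIT`` the
    normal approximation with tie correction is used instead.
    Returns ``(U_a, p_two_tailed)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    if na + nb > EXACT_LIMIT:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return u_a, float(res.pvalue)
    n = na + nb
    total = comb(n, na)
    lo = hi = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        if u <= u_a + 1e-9:
            lo += 1
        if u >= u_a - 1e-9:
            hi += 1
    p = 2 * min(lo, hi) / total
    return u_a, min(1.0, p)


@dataclass(frozen=True)
class RatioComparison:
    ratios_1: tuple[float, ...]
    ratios_2: tuple[float, ...]
    u: float
    p_two_tailed: float


def ratio_comparison(x) -> RatioComparison:
    """Between-cell-type test on per-replicate construct frequency ratios.

    ``x[i][j][k]``: frequency in cell type i (0/1), construct j (0:
    numerator construct, 1: denominator construct), replicate k, replicates
    ordered by library ID.  Ratios r_ik = x[i][0][k] / x[i][1][k] are formed
    per replicate, then the two cell types' ratio sets are compared with the
    exact two-tailed Mann-Whitney U test.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[0] != 2 or x.shape[1] != 2:
        raise ValueError("x must have shape (2, 2, n_replicates)")
    zeros = np.argwhere(x[:, 1, :] == 0)
    if len(zeros):
        i, k = zeros[0]
        raise ValueError(f"zero denominator at cell type {i + 1}, replicate {k + 1}")
    r = x[:, 0, :] / x[:, 1, :]
    u, p = mwu_exact(r[0], r[1])
    return RatioComparison(tuple(r[0]), tuple(r[1]), u, p)


def box_summary(points) -> dict:
    """Median/quartile box statistics with 1.5*IQR whiskers.

    Quartiles by linear interpolation between order statistics; whiskers are
    the most extreme points within Q1 - 1.5 IQR and Q3 + 1.5 IQR; points
    beyond the whiskers are outliers.
    """
    pts = np.sort(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one point")
    q1, med, q3 = np.percentile(pts, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = pts[(pts >= lo_fence) & (pts <= hi_fence)]
    outliers = pts[(pts < lo_fence) | (pts > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": [float(o) for o in outliers],
    }


def frequency_report(tables: list[dict[str, float]]) -> "pd.DataFrame":
    """Mean +/- sample SD of category frequencies over repeats."""
    import pandas as pd

    if not tables:
        raise ValueError("need at least one repeat")
    cats = sorted({c for t in tables for c in t})
    rows = []
    for cat in cats:
        vals = np.array([t.get(cat, 0.0) for t in tables], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"category": cat, "mean": float(vals.mean()), "sd": sd, "n": len(vals)})
    return pd.DataFrame(rows).set_index("category")


def plot_frequency_report(report, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(report.index, report["mean"], yerr=report["sd"], capsize=3, color="tab:blue")
    ax.set_ylabel("mean frequency over repeats")
    ax.tick_params(axis="x", rotation=45)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
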