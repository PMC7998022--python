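"""Transit-time statistics: summaries, intensity-based grouping, and the
Wilcoxon rank-sum confidence interval for a difference of medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edge_detect import EdgeSet


@dataclass
class TransitSummary:
    n_edges: int
    mean_s: float
    sd_s: float
    negatives: int
    table: pd.DataFrame


def summarize(edgeset: EdgeSet) -> TransitSummary:
    """Mean/sd of included edges' transit times; count of negative transits."""
    kept = edgeset.included()
    if not kept:
        raise ValueError("no included edges to summarize")
    tt = np.array([e.transit_time for e in kept])
    table = pd.DataFrame(
        {
            "center_time_s": [e.center_time for e in kept],
            "polarity": [e.polarity for e in kept],
            "transit_time_s": tt,
            "contrast": [e.contrast for e in kept],
            "r_squared": [e.r_squared for e in kept],
        }
    )
    sd = float(np.std(tt, ddof=1)) if len(tt) > 1 else float("nan")
    return TransitSummary(
        n_edges=len(tt),
        mean_s=float(tt.mean()),
        sd_s=sd,
        negatives=int(np.sum(tt < 0)),
        table=table,
    )


def group_top_fraction(
    edgeset: EdgeSet,
    global_signal: np.ndarray,
    dt: float,
    fraction: float = 0.15,
) -> pd.DataFrame:
    """Split included edges by whether the peak they lead into is in the
    top ``fraction`` of global-signal samples.

    The threshold is the (1 - fraction) quantile over all global-signal
    samples; an edge is "top_fraction" iff the local maximum following its
    center exceeds that threshold.  Mirrors the grouping used to contrast
    putatively neuronal (high-amplitude) and physiological oscillations.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    g = np.asarray(global_signal, dtype=float)
    threshold = float(np.quantile(g, 1.0 - fraction))
    from scipy.signal import find_peaks

    maxima, _ = find_peaks(g)
    rows = []
    for idx, e in enumerate(edgeset.edges):
        if not e.included:
            continue
        i = int(np.clip(round(e.center_time / dt), 0, len(g) - 1))
        nxt = maxima[maxima >= i]
        peak_val = g[nxt[0]] if len(nxt) else g[-1]
        rows.append(
            {
                "edge_index": idx,
                "center_time_s": e.center_time,
                "transit_time_s": e.transit_time,
                "peak_value": float(peak_val),
                "group": "top_fraction" if peak_val > threshold else "remainder",
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["fraction"] = fraction
    df.attrs["threshold"] = threshold
    return df


def ranksum_median_ci(
    a, b, alpha: float = 0.05
) -> tuple[float, float]:
    """Confidence interval for the median difference of two unpaired samples.

    Hodges-Lehmann construction: order the m*n pairwise differences
    a_i - b_j and cut at the rank implied by the normal approximation of
    the Wilcoxon rank-sum (Mann-Whitney) statistic, rounded to the
    nearest integer (the rounding acts as a continuity correction):

        k = max(1, round(mn/2 - z_{alpha/2} * sqrt(mn(m+n+1)/12)))
        CI = (d_(k), d_(mn+1-k))

    For small samples (m, n <= 5) this cut rank coincides with the one
    from exhaustive enumeration of the exact rank-sum distribution.
    Degenerate all-equal samples yield a zero-width interval with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observations per sample")
    diffs = np.sort(np.subtract.outer(a, b).ravel())
    if diffs[0] == diffs[-1]:
        warnings.warn("all pairwise differences equal; zero-width interval")
        return float(diffs[0]), float(diffs[-1])
    mn = m * n
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    k = int(round(mn / 2.0 - z * np.sqrt(mn * (m + n + 1) / 12.0)))
    k = max(1, k)
    return float(diffs[k - 1]), float(diffs[mn - k])


def hodges_lehmann_shift(a, b) -> float:
    """Point estimate of the median difference: median of pairwise diffs."""
    return float(np.median(np.subtract.outer(np.asarray(a, float), np.asarray(b, float))))


@dataclass
class TwoSampleResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float


def compare_polarity(a, b, equal_var: bool = True) -> TwoSampleResult:
    """Two-sample t-test between two transit-time groups (e.g. rising vs
    falling edges).  ``a`` and ``b`` may be EdgeSets or arrays."""
    ta = a.transit_times() if isinstance(a, EdgeSet) else np.asarray(a, dtype=float)
    tb = b.transit_times() if isinstance(b, EdgeSet) else np.asarray(b, dtype=float)
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("need at least 2 transit times per group")
    if np.std(ta) == 0 and np.std(tb) == 0:
        t = 0.0 if ta.mean() == tb.mean() else np.inf
        p = 1.0 if ta.mean() == tb.mean() else 0.0
    else:
        t, p = stats.ttest_ind(ta, tb, equal_var=equal_var)
    return TwoSampleResult(
        mean_a=float(ta.mean()),
        sd_a=float(np.std(ta, ddof=1)),
        n_a=len(ta),
        mean_b=float(tb.mean()),
        sd_b=float(np.std(tb, ddof=1)),
        n_b=len(tb),
        t_statistic=float(t),
        p_value=float(p),
    )
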