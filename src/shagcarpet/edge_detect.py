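"""Slope detection: find tilted intensity edges in a carpet plot and
convert their slopes into transit times.

The algorithm (per edge):

1. smooth the carpet with a 2-D Gaussian blur;
2. apply a horizontal (time-axis) derivative filter (central difference);
3. within a column window around the estimated edge center, record for
   every row the time of the maximum derivative (minimum for falling
   edges) — the per-row breakpoints;
4. ordinary least squares of breakpoint time on row index gives the edge
   line; the transit time is the fitted time difference between the
   largest-delay row and the smallest-delay row, i.e. slope x (R - 1) row
   gaps with a sign fixed by the sorting direction.

Positive transit time means the event reaches small-delay voxels first
and large-delay voxels last (propagation along the sorted-delay
direction); a bolus passing through a TTP-sorted carpet is positive by
construction.  Negative transit time marks an edge tilted against that
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import find_peaks

from .shag import ShagCarpet

DEFAULT_SIGMA_ROWS = 5.0  # blur sd along the voxel axis, in rows
DEFAULT_SIGMA_T = 2.0  # blur sd along the time axis, in samples
DEFAULT_MIN_SEPARATION = 5.0  # s, between edge centers (half of 1/f_max)
DEFAULT_WINDOW_CAP = 10.0  # s, full width cap of the breakpoint search window


@dataclass
class Edge:
    """One detected tilted edge and its linear fit."""

    center_time: float
    polarity: str  # "rising" | "falling"
    rows: np.ndarray  # row indices used
    times: np.ndarray  # per-row breakpoint times (s)
    slope: float  # s per row (time regressed on row index)
    intercept: float  # s (fitted time at row 0)
    transit_time: float  # s, signed
    r_squared: float
    contrast: float = np.nan
    rate: float = np.nan
    included: bool = True
    reason: str = ""

    @property
    def points(self):
        return np.column_stack([self.rows, self.times])


@dataclass
class EdgeSet:
    edges: list
    parameters: dict = field(default_factory=dict)

    def included(self) -> list:
        return [e for e in self.edges if e.included]

    def transit_times(self) -> np.ndarray:
        return np.array([e.transit_time for e in self.included()])

    def __len__(self):
        return len(self.edges)


def edge_budget(duration: float, f_max: float) -> int:
    """Upper bound on detectable oscillation edges: floor(duration * f_max).

    A record of 360 s band-limited at 0.1 Hz can contain at most 36 full
    oscillations, hence at most 36 rising (or falling) edges.
    """
    if duration <= 0 or f_max <= 0:
        raise ValueError("duration and f_max must be positive")
    n = int(np.floor(duration * f_max))
    if n == 0:
        import warnings

        warnings.warn("no detectable oscillation fits in this duration")
    return n


def smooth_carpet(
    data: np.ndarray,
    sigma_rows: float = DEFAULT_SIGMA_ROWS,
    sigma_t: float = DEFAULT_SIGMA_T,
) -> np.ndarray:
    """2-D Gaussian blur (rows x time), reflect boundary."""
    return gaussian_filter(data, sigma=(sigma_rows, sigma_t), mode="reflect")


def time_derivative(data: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference derivative along the time axis: [-1, 0, +1] / (2 dt)."""
    return np.gradient(data, dt, axis=-1)


def estimate_edge_centers(
    carpet: ShagCarpet,
    n: int,
    polarity: str = "rising",
    min_separation: float = DEFAULT_MIN_SEPARATION,
    sigma_t: float = DEFAULT_SIGMA_T,
) -> np.ndarray:
    """Times of the n strongest derivative peaks of the global signal.

    The row-averaged timeseries is lightly smoothed, differentiated, and
    its local maxima (rising) or minima (falling) located with a minimum
    mutual separation.  Peaks within the smoothing kernel's support of
    either record boundary are discarded (the reflect-padded derivative
    there is an artifact of the padding).  Returns at most n times,
    sorted ascending; fewer if fewer qualifying peaks exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = gaussian_filter1d(carpet.global_signal(), sigma_t, mode="reflect")
    dg = time_derivative(g, carpet.dt)
    signal = dg if polarity == "rising" else -dg
    dist = max(1, int(round(min_separation / carpet.dt)))
    peaks, props = find_peaks(signal, distance=dist, height=0.0)
    guard = int(np.ceil(3 * sigma_t))
    inside = (peaks >= guard) & (peaks < carpet.n_samples - guard)
    peaks, props = peaks[inside], {"peak_heights": props["peak_heights"][inside]}
    if len(peaks) == 0:
        return np.array([])
    heights = props["peak_heights"]
    top = peaks[np.argsort(heights)[::-1][:n]]
    return np.sort(top) * carpet.dt


def _transit_sign_rows(carpet: ShagCarpet, n_rows: int) -> tuple[int, int]:
    """(row of largest delay, row of smallest delay) for the sign convention."""
    d = carpet.delays_sorted
    if d is not None and len(d) == n_rows and np.isfinite(d).any():
        dd = np.where(np.isnan(d), -np.inf, d)
        return int(np.argmax(dd)), int(np.argmin(dd))
    # default: descending sort, largest delay at the top row
    return 0, n_rows - 1


def detect_edge(
    carpet: ShagCarpet,
    center_time: float,
    window: float | None = None,
    polarity: str = "rising",
    sigma_rows: float = DEFAULT_SIGMA_ROWS,
    sigma_t: float = DEFAULT_SIGMA_T,
    smoothed: np.ndarray | None = None,
) -> Edge:
    """Fit one tilted edge around ``center_time``.

    ``window`` is the full width (s) of the column range searched for
    per-row breakpoints; by default half the mean peak-to-peak interval of
    the global signal on each side, capped at +-5 s.  ``smoothed`` lets a
    caller reuse a precomputed blurred carpet.
    """
    if polarity not in ("rising", "falling"):
        raise ValueError(f"polarity must be 'rising' or 'falling', got {polarity!r}")
    dt = carpet.dt
    if window is None:
        window = default_window(carpet, sigma_t=sigma_t)
    half = window / 2.0
    if center_time - half < -dt / 2 or center_time + half > (carpet.n_samples - 1) * dt + dt / 2:
        raise ValueError(
            f"window [{center_time - half:.2f}, {center_time + half:.2f}] s does not fit "
            f"inside the scan [0, {(carpet.n_samples - 1) * dt:.2f}] s"
        )
    lo = max(0, int(np.ceil((center_time - half) / dt)))
    hi = min(carpet.n_samples - 1, int(np.floor((center_time + half) / dt)))
    if hi - lo + 1 < 3:
        raise ValueError(f"degenerate window: only {hi - lo + 1} columns around {center_time} s")
    if smoothed is None:
        smoothed = smooth_carpet(carpet.data, sigma_rows, sigma_t)
    deriv = time_derivative(smoothed, dt)
    seg = deriv[:, lo : hi + 1]
    picks = np.argmax(seg, axis=1) if polarity == "rising" else np.argmin(seg, axis=1)
    times = (picks + lo) * dt
    rows = np.arange(carpet.n_rows)
    slope, intercept = np.polyfit(rows, times, 1)
    fit = intercept + slope * rows
    ss_res = float(np.sum((times - fit) ** 2))
    ss_tot = float(np.sum((times - times.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r_late, r_early = _transit_sign_rows(carpet, carpet.n_rows)
    transit = float((intercept + slope * r_late) - (intercept + slope * r_early))
    return Edge(
        center_time=float(center_time),
        polarity=polarity,
        rows=rows,
        times=times,
        slope=float(slope),
        intercept=float(intercept),
        transit_time=transit,
        r_squared=r2,
    )


def detect_edges(
    carpet: ShagCarpet,
    polarity: str = "rising",
    f_max: float = 0.1,
    window: float | None = None,
    contrast_floor: float = 0.2,
    rate_floor: float | None = None,
    sigma_rows: float = DEFAULT_SIGMA_ROWS,
    sigma_t: float = DEFAULT_SIGMA_T,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> EdgeSet:
    """Full detection pass: centers -> per-edge fits -> threshold selection.

    Up to ``edge_budget(duration, f_max)`` candidate centers are fitted.
    Centers whose search window does not fit inside the scan (edges cut
    off by the start or end of the record) are skipped: their breakpoints
    are not measurable.
    """
    budget = edge_budget(carpet.n_samples * carpet.dt, f_max)
    centers = estimate_edge_centers(
        carpet, max(budget, 1), polarity, min_separation=min_separation, sigma_t=sigma_t
    )
    if window is None:
        window = default_window(carpet, sigma_t=sigma_t)
    smoothed = smooth_carpet(carpet.data, sigma_rows, sigma_t)
    edges = []
    for c in centers:
        try:
            edges.append(
                detect_edge(
                    carpet, c, window=window, polarity=polarity,
                    sigma_rows=sigma_rows, sigma_t=sigma_t, smoothed=smoothed,
                )
            )
        except ValueError:
            continue
    return select_edges(
        edges,
        carpet.global_signal(),
        carpet.dt,
        contrast_floor=contrast_floor,
        rate_floor=rate_floor,
        edge_budget_n=budget,
        sigma_t=sigma_t,
    )


def default_window(carpet: ShagCarpet, sigma_t: float = DEFAULT_SIGMA_T) -> float:
    """Full window width: mean peak-to-peak interval of the global signal,
    capped at 10 s (i.e. +-5 s), floored at 5 time samples."""
    g = gaussian_filter1d(carpet.global_signal(), sigma_t, mode="reflect")
    peaks, _ = find_peaks(g)
    if len(peaks) >= 2:
        width = float(np.mean(np.diff(peaks)) * carpet.dt)
    else:
        width = DEFAULT_WINDOW_CAP
    return float(np.clip(width, 5 * carpet.dt, DEFAULT_WINDOW_CAP))


def _local_extrema(g: np.ndarray):
    maxima, _ = find_peaks(g)
    minima, _ = find_peaks(-g)
    return maxima, minima


def edge_contrast_rate(
    edge: Edge, global_signal: np.ndarray, dt: float, sigma_t: float = DEFAULT_SIGMA_T
) -> tuple[float, float]:
    """Contrast and rate of one edge on the (smoothed) global signal.

    For a rising edge, contrast = value at the following local maximum
    minus value at the preceding local minimum; mirrored for falling.
    Rate = |derivative| of the global signal at the edge center.
    """
    g = gaussian_filter1d(global_signal, sigma_t, mode="reflect")
    dg = time_derivative(g, dt)
    i = int(round(edge.center_time / dt))
    i = np.clip(i, 0, len(g) - 1)
    maxima, minima = _local_extrema(g)
    if edge.polarity == "rising":
        before, after = minima, maxima
    else:
        before, after = maxima, minima
    prev = before[before <= i]
    nxt = after[after >= i]
    v_prev = g[prev[-1]] if len(prev) else g[0]
    v_next = g[nxt[0]] if len(nxt) else g[-1]
    contrast = float(v_next - v_prev) if edge.polarity == "rising" else float(v_prev - v_next)
    rate = float(abs(dg[i]))
    return contrast, rate


def select_edges(
    edges: list,
    global_signal: np.ndarray,
    dt: float,
    contrast_floor: float = 0.2,
    rate_floor: float | None = None,
    rate_floor_percentile: float = 25.0,
    edge_budget_n: int | None = None,
    sigma_t: float = DEFAULT_SIGMA_T,
) -> EdgeSet:
    """Keep edges whose global-signal contrast and rate clear the floors.

    ``rate_floor=None`` uses the given percentile of the candidate edges'
    rates (an SNR-adaptive default).  Excluded edges stay in the set with
    an exclusion reason.  Output is sorted by center time and truncated to
    ``edge_budget_n`` included edges if given (weakest-contrast first out).
    """
    annotated = []
    for e in edges:
        c, r = edge_contrast_rate(e, global_signal, dt, sigma_t=sigma_t)
        e.contrast, e.rate = c, r
        annotated.append(e)
    if rate_floor is None and annotated:
        rate_floor = float(np.percentile([e.rate for e in annotated], rate_floor_percentile))
    for e in annotated:
        reasons = []
        if not (e.contrast > contrast_floor):
            reasons.append("contrast")
        if not (e.rate >= rate_floor):
            reasons.append("rate")
        e.included = not reasons
        e.reason = ",".join(reasons)
    annotated.sort(key=lambda e: e.center_time)
    if edge_budget_n is not None:
        kept = [e for e in annotated if e.included]
        if len(kept) > edge_budget_n:
            for e in sorted(kept, key=lambda e: e.contrast)[: len(kept) - edge_budget_n]:
                e.included = False
                e.reason = "budget"
    return EdgeSet(
        edges=annotated,
        parameters={
            "contrast_floor": contrast_floor,
            "rate_floor": rate_floor,
            "edge_budget": edge_budget_n,
        },
    )
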