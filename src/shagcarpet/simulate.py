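"""Validation frameworks for the slope detector.

Two simulations quantify how much trust to place in a transit time read
off a carpet plot:

- the **contrast/noise robustness grid**: a clean single-edge carpet is
  rescaled to a target contrast, i.i.d. Gaussian noise is added, and the
  detector is re-run over repeated trials per (contrast, noise) cell;
- the **TR-sampling error sweep**: an ideal, perfectly linear edge is
  sampled at a finite repetition time for every sampling-start offset in
  [0, TR), exposing the quantization error of breakpoint detection.

The module also provides the contrast and noise estimators used to place
a measured carpet plot on the robustness grid, under the two-component
model (clean image + additive Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .edge_detect import (
    DEFAULT_SIGMA_ROWS,
    DEFAULT_SIGMA_T,
    detect_edge,
    estimate_edge_centers,
    smooth_carpet,
)
from .phantom import gamma_variate
from .shag import ShagCarpet


@dataclass
class NoiseGridResult:
    contrasts: np.ndarray
    noise_sds: np.ndarray
    mean_transit: np.ndarray  # (n_contrasts, n_noise)
    sd_transit: np.ndarray
    n_trials: int
    baseline_transit: float
    transits: np.ndarray = None  # (n_contrasts, n_noise, n_trials)


@dataclass
class TrErrorResult:
    true_transit: float
    tr: float
    offsets: np.ndarray
    errors: np.ndarray  # estimated - true, per offset

    @property
    def max_signed_error(self) -> float:
        return float(self.errors.max())

    @property
    def min_signed_error(self) -> float:
        return float(self.errors.min())

    @property
    def max_abs_error(self) -> float:
        return float(np.abs(self.errors).max())


# ---------------------------------------------------------------------------
# contrast / noise estimators

def estimate_contrast(
    carpet: ShagCarpet,
    sigma_rows: float = DEFAULT_SIGMA_ROWS,
    sigma_t: float = DEFAULT_SIGMA_T,
) -> float:
    """Intensity contrast: averaged lightest minus averaged darkest regions.

    The carpet is smoothed, then contrast = mean of pixels above the 90th
    percentile minus mean of pixels below the 10th percentile.
    """
    s = smooth_carpet(carpet.data, sigma_rows, sigma_t)
    hi = np.percentile(s, 90)
    lo = np.percentile(s, 10)
    top = s[s >= hi]
    bot = s[s <= lo]
    return float(top.mean() - bot.mean())


def _residual_variance_factor(sigma_rows: float, sigma_t: float) -> float:
    """Var[(I - S) n] / Var[n] for the separable Gaussian smoother S.

    For white noise, residual variance is (1 - 2 s0 + sum s^2) * sigma^2
    with s0 the central 2-D kernel weight and sum s^2 the kernel energy;
    both factor over the separable axes.
    """
    size = int(8 * max(sigma_rows, sigma_t, 1.0)) | 1
    delta = np.zeros(size)
    delta[size // 2] = 1.0
    kr = gaussian_filter1d(delta, sigma_rows, mode="constant") if sigma_rows > 0 else delta
    kt = gaussian_filter1d(delta, sigma_t, mode="constant") if sigma_t > 0 else delta
    s0 = kr[size // 2] * kt[size // 2]
    ss = float((kr**2).sum() * (kt**2).sum())
    return 1.0 - 2.0 * s0 + ss


def estimate_noise_sd(
    carpet: ShagCarpet,
    sigma_rows: float = 2.0,
    sigma_t: float = 0.0,
) -> float:
    """Additive Gaussian noise sd under the clean + noise image model.

    The smoothed image estimates the clean component; the sd of the
    (raw - smoothed) residual, corrected for the smoother's residual
    variance factor, estimates the noise sd.

    The default smoother acts along the voxel axis only: in a
    delay-sorted carpet neighbouring rows carry nearly identical clean
    signal, so row-direction residuals are almost pure noise, whereas
    any time-direction smoothing leaks genuine signal (which varies on
    the oscillation timescale) into the residual and inflates the
    estimate.
    """
    if carpet.n_samples < 4:
        raise ValueError("need at least 4 time samples")
    resid = carpet.data - smooth_carpet(carpet.data, sigma_rows, sigma_t)
    factor = _residual_variance_factor(sigma_rows, sigma_t)
    return float(resid.std() / np.sqrt(factor))


# ---------------------------------------------------------------------------
# synthetic single-edge bases

def make_dsc_like_carpet(
    n_rows: int = 20000,
    duration: float = 180.0,
    tr: float = 1.5,
    transit: float = 4.2,
    t_arrival: float = 60.0,
    tp: float = 6.0,
    alpha: float = 3.0,
    contrast: float = 3.0,
    wiggle_sd: float = 0.75,
    wiggle_rows: float = 40.0,
    jitter_sd: float = 0.3,
    seed: int = 7021,
) -> ShagCarpet:
    """Clean synthetic bolus-passage carpet with one falling edge.

    Each row holds a gamma-variate signal dip.  Rows are ordered by the
    sorting key (the estimated per-voxel delay), which spans ``transit``
    seconds linearly, latest arrival in row 0 (descending-delay
    convention).  True bolus onsets deviate from that trend the way a
    measured carpet's do — per-voxel event times are not collinear with
    delay rank — as a slowly varying profile across rows (sd
    ``wiggle_sd`` s, correlation length ``wiggle_rows`` rows, linearly
    detrended so the underlying transit is preserved) plus independent
    per-row scatter (sd ``jitter_sd`` s).  Without that deviation the
    construction would alias a perfectly linear trend against the TR
    sampling lattice, which no measured carpet does.  The clean image is
    scaled so its smoothed-image contrast equals ``contrast``.
    """
    t = np.arange(int(round(duration / tr))) * tr
    rows = np.arange(n_rows)
    trend = t_arrival + transit * (1.0 - rows / (n_rows - 1))
    rng = np.random.default_rng(seed)
    w = gaussian_filter1d(rng.normal(0.0, 1.0, n_rows), wiggle_rows, mode="reflect")
    w = (w - w.mean()) / w.std() * wiggle_sd
    w = w - np.polyval(np.polyfit(rows, w, 1), rows)
    onsets = trend + w + rng.normal(0.0, jitter_sd, size=n_rows)
    data = -gamma_variate(t[None, :] - onsets[:, None], 0.0, tp, alpha)
    carpet = ShagCarpet(
        data=data,
        order=rows,
        delays_sorted=trend + tp,
        quality_sorted=np.ones(n_rows),
        dt=tr,
        meta={"synthetic": "dsc-like", "true_transit": transit},
    )
    native = estimate_contrast(carpet)
    carpet.data *= contrast / native
    return carpet


def make_ideal_edge_carpet(
    true_transit: float,
    tr: float,
    offset: float = 0.0,
    n_rows: int = 1500,
    duration: float = 60.0,
    contrast: float = 3.0,
    polarity: str = "rising",
) -> ShagCarpet:
    """Sample a continuous, perfectly linear step edge at interval ``tr``.

    Row r steps at time t0 + transit * (1 - r/(R-1)) (latest at the top,
    descending-delay convention); samples lie at offset + k * tr.  This is
    the idealized edge used to study pure TR-sampling error.
    """
    n_t = int(np.floor((duration - offset) / tr)) + 1
    t = offset + np.arange(n_t) * tr
    t0 = duration / 2.0 - true_transit / 2.0
    taus = t0 + true_transit * (1.0 - np.arange(n_rows) / (n_rows - 1))
    sign = 1.0 if polarity == "rising" else -1.0
    data = np.where(t[None, :] >= taus[:, None], sign * contrast / 2, -sign * contrast / 2)
    return ShagCarpet(
        data=data,
        order=np.arange(n_rows),
        delays_sorted=taus,
        quality_sorted=np.ones(n_rows),
        dt=tr,
        meta={"synthetic": "ideal-edge", "true_transit": true_transit, "offset": offset},
    )


# ---------------------------------------------------------------------------
# simulations

def _detect_single_edge(carpet: ShagCarpet, polarity: str, window: float, **kw):
    centers = estimate_edge_centers(carpet, n=1, polarity=polarity)
    if len(centers) == 0:
        raise ValueError("no edge detectable in carpet")
    return detect_edge(carpet, centers[0], window=window, polarity=polarity, **kw)


def noise_robustness_grid(
    base: ShagCarpet,
    contrasts=np.linspace(0.5, 3.5, 7),
    noise_sds=np.linspace(0.1, 1.0, 10),
    n_trials: int = 30,
    seed: int = 0,
    polarity: str = "falling",
    window: float | None = None,
    keep_trials: bool = False,
) -> NoiseGridResult:
    """Detector bias/variance over a contrast x noise grid.

    ``base`` must be a clean carpet with one detectable edge.  Per cell
    the clean component is rescaled to the target contrast, Gaussian noise
    of the target sd is added, and the edge is re-detected in ``n_trials``
    independent trials.  The baseline is the transit detected on the clean
    base at native contrast.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    noise_sds = np.asarray(noise_sds, dtype=float)
    native = estimate_contrast(base)
    if window is None:
        tt = base.meta.get("true_transit")
        window = (tt + 6 * base.dt) if tt else None
    baseline_edge = _detect_single_edge(base, polarity, window)
    baseline = baseline_edge.transit_time
    rng = np.random.default_rng(seed)
    mean_t = np.empty((len(contrasts), len(noise_sds)))
    sd_t = np.empty_like(mean_t)
    all_t = np.empty((len(contrasts), len(noise_sds), n_trials))
    for i, c in enumerate(contrasts):
        clean = base.data * (c / native)
        for j, sd in enumerate(noise_sds):
            transits = np.empty(n_trials)
            for k in range(n_trials):
                noisy = clean + rng.normal(0.0, sd, size=clean.shape)
                trial = ShagCarpet(
                    data=noisy,
                    order=base.order,
                    delays_sorted=base.delays_sorted,
                    quality_sorted=base.quality_sorted,
                    dt=base.dt,
                )
                transits[k] = _detect_single_edge(trial, polarity, window).transit_time
            mean_t[i, j] = transits.mean()
            sd_t[i, j] = transits.std(ddof=1)
            all_t[i, j] = transits
    return NoiseGridResult(
        contrasts=contrasts,
        noise_sds=noise_sds,
        mean_transit=mean_t,
        sd_transit=sd_t,
        n_trials=n_trials,
        baseline_transit=float(baseline),
        transits=all_t if keep_trials else None,
    )


def tr_error_sweep(
    true_transit: float,
    tr: float,
    n_offsets: int = 50,
    n_rows: int = 1500,
    duration: float = 60.0,
    polarity: str = "rising",
) -> TrErrorResult:
    """Transit-time error from finite TR sampling of an ideal linear edge.

    For each sampling-start offset phi on a uniform grid over [0, tr), the
    continuous edge is sampled at interval ``tr``, the slope detector is
    run, and the signed error (estimated - true) is recorded.  Worst-case
    |error| is bounded by the TR; the error envelope shrinks as the true
    transit time grows relative to the TR.
    """
    if true_transit <= 0 or tr <= 0:
        raise ValueError("true_transit and tr must be positive")
    offsets = np.arange(n_offsets) * (tr / n_offsets)
    errors = np.empty(n_offsets)
    window = true_transit + 6 * tr
    for i, phi in enumerate(offsets):
        carpet = make_ideal_edge_carpet(
            true_transit, tr, offset=phi, n_rows=n_rows, duration=duration, polarity=polarity
        )
        # the edge center is known by construction (duration/2 in absolute
        # time, shifted into the carpet's sampling frame)
        center = duration / 2.0 - phi
        edge = detect_edge(carpet, center, window=window, polarity=polarity)
        errors[i] = edge.transit_time - true_transit
    return TrErrorResult(true_transit=true_transit, tr=tr, offsets=offsets, errors=errors)
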