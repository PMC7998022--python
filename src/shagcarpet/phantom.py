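"""Synthetic BOLD phantoms with known per-voxel arrival delays.

Three modalities are emulated:

``rs``
    Resting-state fMRI carrying a shared systemic low-frequency
    oscillation (sLFO): a band-limited sum of sinusoids in 0.01-0.1 Hz,
    time-shifted per voxel.
``dsc``
    Dynamic susceptibility contrast MRI: a baseline with a gamma-variate
    signal dip (the T2* drop caused by a gadolinium bolus), delayed per
    voxel.
``co2``
    CO2-challenge fMRI: a block-design vasodilatory response (boxcar
    end-tidal CO2 protocol convolved with a single-exponential response),
    delayed per voxel.

Every phantom carries ground truth (per-voxel delays, the clean matrix,
noise parameters) so delay estimators, sorting, and slope detection can be
validated end to end.  A configurable fraction of voxels carry no pattern
at all ("noise voxels", pure Gaussian noise), emulating the voxels real
carpet plots show no consistent pattern in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .signal_prep import VoxelMatrix

FINE_DT = 0.01  # seconds; internal grid on which clean signals are built

_MODALITIES = ("rs", "dsc", "co2")


@dataclass
class PhantomSpec:
    """Recipe for one synthetic dataset.

    delay_model is ``("linear_span", total_span_s)`` — pattern-voxel delays
    uniformly spaced over ``[0, total_span_s]`` — or
    ``("uniform_random", min_s, max_s)``.
    """

    modality: str
    n_voxels: int = 400
    duration: float = 360.0
    tr: float = 0.72
    delay_model: tuple = ("linear_span", 4.5)
    noise_sd: float = 0.0
    noise_voxel_fraction: float = 0.0
    motion_times: tuple = ()
    seed: int = 0
    modality_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.duration / self.tr < 16:
            raise ValueError("duration must cover at least 16 samples")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.noise_voxel_fraction < 1.0):
            raise ValueError("noise_voxel_fraction must be in [0, 1)")
        span = self.delay_span()
        if span < 0:
            raise ValueError("delay span must be >= 0")
        if span >= self.duration / 2:
            raise ValueError(f"delay span {span} s must be < duration/2")
        for t in self.motion_times:
            if not (0.0 <= t < self.duration):
                raise ValueError(f"motion time {t} outside [0, {self.duration})")

    def delay_span(self) -> float:
        kind = self.delay_model[0]
        if kind == "linear_span":
            return float(self.delay_model[1])
        if kind == "uniform_random":
            lo, hi = self.delay_model[1], self.delay_model[2]
            return float(hi) - float(lo)
        raise ValueError(f"unknown delay model {kind!r}")


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom.

    ``delays`` is NaN for noise voxels (they carry no delayed pattern);
    ``true_transit_time`` is the delay span max-min over pattern voxels.
    """

    delays: np.ndarray
    clean_matrix: np.ndarray
    noise_sd: float
    noise_voxel_ids: np.ndarray
    true_transit_time: float
    base_fine: np.ndarray = None
    t_fine: np.ndarray = None

    @property
    def pattern_voxel_ids(self) -> np.ndarray:
        mask = np.ones(len(self.delays), dtype=bool)
        mask[self.noise_voxel_ids] = False
        return np.flatnonzero(mask)


def _rs_base(spec: PhantomSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of 3-8 sinusoids with frequencies in the sLFO band 0.01-0.1 Hz."""
    p = spec.modality_params
    if "frequencies" in p:
        freqs = np.asarray(p["frequencies"], dtype=float)
        amps = np.asarray(p.get("amplitudes", np.ones_like(freqs)), dtype=float)
        phases = np.asarray(p.get("phases", np.zeros_like(freqs)), dtype=float)
    else:
        k = rng.integers(3, 9)
        freqs = rng.uniform(0.01, 0.1, size=k)
        amps = rng.uniform(0.5, 1.5, size=k)
        phases = rng.uniform(0, 2 * np.pi, size=k)
    out = np.zeros_like(t)
    for f, a, ph in zip(freqs, amps, phases):
        out += a * np.sin(2 * np.pi * f * t + ph)
    return out


def gamma_variate(t: np.ndarray, t0: float, tp: float, alpha: float = 3.0) -> np.ndarray:
    """Standard bolus curve A=1: ((t-t0)/tp)^a * exp(a*(1-(t-t0)/tp)) for t>t0.

    Peaks at exactly t0 + tp with value 1.
    """
    t = np.asarray(t, dtype=float)
    x = (t - t0) / tp
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = x[pos] ** alpha * np.exp(alpha * (1.0 - x[pos]))
    return out


def _dsc_base(spec: PhantomSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = spec.modality_params
    t0 = p.get("t0", 10.0)
    tp = p.get("tp", 4.0)
    depth = p.get("depth", 3.0)
    baseline = p.get("baseline", 0.0)
    alpha = p.get("alpha", 3.0)
    return baseline - depth * gamma_variate(t, t0, tp, alpha)


def co2_protocol(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """End-tidal CO2 boxcar (mmHg above baseline) of the breathing protocol.

    Default: two 120 s blocks of +10 mmHg separated by 120 s baseline
    periods before, in between and after (600 s total when duration=600).
    """
    p = spec.modality_params
    onsets = p.get("block_onsets", (120.0, 360.0))
    dur = p.get("block_duration", 120.0)
    amp = p.get("block_mmhg", 10.0)
    baseline = p.get("baseline_mmhg", 40.0)
    out = np.full_like(t, baseline, dtype=float)
    for on in onsets:
        out[(t >= on) & (t < on + dur)] += amp
    return out


def _co2_base(spec: PhantomSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boxcar protocol convolved with a single-exponential vasodilatory response."""
    p = spec.modality_params
    tau = p.get("tau", 8.0)
    amp = p.get("response_amplitude", 0.1)  # intensity units per mmHg
    box = co2_protocol(spec, t) - p.get("baseline_mmhg", 40.0)
    dt = t[1] - t[0]
    # causal exponential kernel, unit area
    k_t = np.arange(0, 6 * tau, dt)
    kernel = np.exp(-k_t / tau)
    kernel /= kernel.sum()
    resp = np.convolve(box, kernel)[: len(t)]
    return amp * resp


_BASES = {"rs": _rs_base, "dsc": _dsc_base, "co2": _co2_base}


def _draw_delays(spec: PhantomSpec, n_pattern: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.delay_model[0]
    if kind == "linear_span":
        span = float(spec.delay_model[1])
        if n_pattern == 1:
            return np.array([0.0])
        return np.linspace(0.0, span, n_pattern)
    if kind == "uniform_random":
        lo, hi = float(spec.delay_model[1]), float(spec.delay_model[2])
        return rng.uniform(lo, hi, size=n_pattern)
    raise ValueError(f"unknown delay model {kind!r}")


def make_phantom(spec: PhantomSpec) -> tuple[VoxelMatrix, PhantomTruth]:
    """Generate one synthetic dataset with ground truth.

    The clean base signal is built on a 0.01 s grid; each pattern voxel is
    the base signal time-shifted by its delay (cubic interpolation, so
    sub-TR delays are represented exactly up to spline error) and sampled
    at ``tr``.  Noise voxels contain Gaussian noise only.  Additive
    i.i.d. Gaussian measurement noise of sd ``noise_sd`` is then added to
    every sample.  Everything is reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_voxels
    n_t = int(round(spec.duration / spec.tr))
    t_samp = np.arange(n_t) * spec.tr

    span = spec.delay_span()
    pad = span + 1.0
    t_fine = np.arange(-pad, spec.duration + pad, FINE_DT)
    base = _BASES[spec.modality](spec, t_fine, rng)
    base_spline = CubicSpline(t_fine, base)

    n_noise = int(round(spec.noise_voxel_fraction * n))
    noise_ids = rng.choice(n, size=n_noise, replace=False) if n_noise else np.array([], dtype=int)
    is_noise = np.zeros(n, dtype=bool)
    is_noise[noise_ids] = True
    n_pattern = n - n_noise

    delays = np.full(n, np.nan)
    pattern_ids = np.flatnonzero(~is_noise)
    pattern_delays = _draw_delays(spec, n_pattern, rng)
    rng.shuffle(pattern_delays)
    delays[pattern_ids] = pattern_delays

    clean = np.zeros((n, n_t))
    for v in pattern_ids:
        clean[v] = base_spline(t_samp - delays[v])

    # Noise voxels: structureless rows whose sd matches the clean-signal rms,
    # so after z-scoring they are indistinguishable in amplitude.
    if n_noise:
        rms = float(np.sqrt(np.mean(clean[pattern_ids] ** 2))) if n_pattern else 1.0
        sd_nv = spec.modality_params.get("noise_voxel_sd", rms if rms > 0 else 1.0)
        clean[noise_ids] = 0.0
        noise_rows = rng.normal(0.0, sd_nv, size=(n_noise, n_t))
    data = clean.copy()
    if n_noise:
        data[noise_ids] = noise_rows
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    matrix = VoxelMatrix(data=data, dt=spec.tr, voxel_ids=np.arange(n))
    for mt in spec.motion_times:
        matrix = inject_motion(matrix, mt, spec.modality_params.get("motion_amplitude", 5.0))

    if n_pattern:
        tt = float(np.nanmax(delays) - np.nanmin(delays))
    else:
        tt = 0.0
    truth = PhantomTruth(
        delays=delays,
        clean_matrix=clean,
        noise_sd=spec.noise_sd,
        noise_voxel_ids=noise_ids,
        true_transit_time=tt,
        base_fine=base,
        t_fine=t_fine,
    )
    return matrix, truth


def inject_motion(matrix: VoxelMatrix, time: float, amplitude: float) -> VoxelMatrix:
    """Offset one time column (nearest sample) by ``amplitude`` in every voxel.

    Emulates a whole-brain motion spike: it hits all voxels at the same
    instant, which renders as a vertical line in any carpet plot.
    """
    if not (0.0 <= time < matrix.duration):
        raise ValueError(f"motion time {time} outside scan [0, {matrix.duration})")
    col = int(round(time / matrix.dt))
    col = min(col, matrix.n_samples - 1)
    out = matrix.copy()
    out.data[:, col] += amplitude
    return out
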