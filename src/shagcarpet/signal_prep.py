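"""Per-voxel timeseries conditioning: scaling, band-pass filtering, resampling.

All carpet-plot stages operate on a :class:`VoxelMatrix`, a voxels x time
intensity matrix with a uniform sampling interval ``dt``.  Sample ``i`` of
every row is at time ``i * dt`` (the first sample is at time 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt


@dataclass
class VoxelMatrix:
    """Voxels x time intensity matrix.

    Parameters
    ----------
    data
        2-D float array, one row per voxel, one column per time sample.
    dt
        Sampling interval in seconds (> 0).
    voxel_ids
        Integer id per row; ids map rows back to 3-D voxel coordinates.
    coords
        Optional (n_voxels, 3) integer voxel coordinates (x, y, z).
    scaled
        True once rows have been demeaned and scaled to unit variance.
    flat_rows
        Boolean mask of rows that had zero variance and were left at zero
        during scaling (set by :func:`scale_demean`).
    """

    data: np.ndarray
    dt: float
    voxel_ids: np.ndarray = None
    coords: np.ndarray | None = None
    scaled: bool = False
    flat_rows: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("VoxelMatrix data must be 2-D (voxels x time)")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.data.shape[0])
        self.voxel_ids = np.asarray(self.voxel_ids)
        if len(self.voxel_ids) != self.data.shape[0]:
            raise ValueError("voxel_ids length must match number of rows")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Scan duration in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def copy(self, **overrides) -> "VoxelMatrix":
        kwargs = dict(
            data=self.data.copy(),
            dt=self.dt,
            voxel_ids=self.voxel_ids.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            scaled=self.scaled,
            flat_rows=None if self.flat_rows is None else self.flat_rows.copy(),
        )
        kwargs.update(overrides)
        return VoxelMatrix(**kwargs)


def scale_demean(matrix: VoxelMatrix) -> VoxelMatrix:
    """Z-score every voxel row: subtract the row mean, divide by the row sd.

    Rows with zero variance cannot be scaled; they are set to zero and
    flagged in ``flat_rows``.  An all-constant matrix is an error.  The
    operation is idempotent up to floating-point error.
    """
    data = matrix.data
    means = data.mean(axis=1, keepdims=True)
    sds = data.std(axis=1, keepdims=True)
    flat = sds[:, 0] == 0.0
    if flat.all():
        raise ValueError("all rows are constant; nothing to scale")
    safe_sds = np.where(sds == 0.0, 1.0, sds)
    out = (data - means) / safe_sds
    out[flat] = 0.0
    return matrix.copy(data=out, scaled=True, flat_rows=flat)


def bandpass(
    series: np.ndarray,
    dt: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-lag Butterworth band-pass filter (forward-backward application).

    Works on a 1-D series or row-wise on a 2-D array (filtering along the
    last axis).  Forward-backward (``sosfiltfilt``) application doubles the
    effective order and cancels the phase response, so a feature symmetric
    about time t0 stays symmetric about t0.

    Parameters
    ----------
    series : 1-D or 2-D array
    dt : sampling interval, seconds
    low_hz, high_hz : passband edges; must satisfy 0 < low < high < Nyquist
    order : Butterworth order of the one-way filter (default 4)
    """
    series = np.asarray(series, dtype=float)
    nyq = 0.5 / dt
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq:.4g} Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / dt, output="sos")
    n = series.shape[-1]
    # Reflective padding of 3 filter lengths suppresses startup transients;
    # longer padding only amplifies end-of-record mismatch on short scans.
    padlen = int(min(n - 1, 3 * (2 * order + 1)))
    return sosfiltfilt(sos, series, axis=-1, padlen=padlen)


def resample(
    series: np.ndarray,
    dt_in: float,
    dt_out: float,
    kind: str = "cubic",
) -> np.ndarray:
    """Upsample a series (or rows of a matrix) onto a finer uniform grid.

    The output grid starts at time 0 and covers the input support
    ``[0, (n-1) * dt_in]``.  Cubic-spline interpolation by default; ``kind``
    may also be ``"linear"``.  Values at the original sample times are
    preserved (interpolation passes through the data).
    """
    if dt_out >= dt_in:
        raise ValueError(f"resample is upsampling-only: dt_out={dt_out} >= dt_in={dt_in}")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    t_in = np.arange(n) * dt_in
    n_out = int(np.floor(t_in[-1] / dt_out + 1e-9)) + 1
    t_out = np.arange(n_out) * dt_out
    if kind == "linear":
        if series.ndim == 1:
            return np.interp(t_out, t_in, series)
        return np.vstack([np.interp(t_out, t_in, row) for row in series])
    if kind != "cubic":
        raise ValueError(f"unknown interpolation kind {kind!r}")
    spline = CubicSpline(t_in, series, axis=-1)
    return spline(t_out)
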