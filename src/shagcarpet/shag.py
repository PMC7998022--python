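"""Build, crop, segment, and render delay-sorted (SHAG) carpet plots.

A SHAG carpet plot is a voxels x time heatmap whose rows are ordered by
each voxel's estimated signal-arrival delay, in descending order: the
voxel with the largest delay (latest arrival) is the top row.  A shared
signal that propagates through the voxels then appears as a tilted edge
whose horizontal extent is the transit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .delay_map import DelayMap
from .signal_prep import VoxelMatrix


@dataclass
class ShagCarpet:
    """Delay-sorted voxel matrix.

    ``order[r]`` is the voxel_id displayed in row ``r``; ``delays_sorted``
    is non-increasing down the rows; ``crop`` is the (first, last+1) kept
    row range relative to the pre-crop ordering.
    """

    data: np.ndarray
    order: np.ndarray
    delays_sorted: np.ndarray
    quality_sorted: np.ndarray
    dt: float
    crop: tuple = (0, -1)
    n_removed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.crop == (0, -1):
            self.crop = (0, self.data.shape[0])

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def global_signal(self) -> np.ndarray:
        """Across-row mean timeseries (the carpet's global signal)."""
        return self.data.mean(axis=0)


def build_shag(matrix: VoxelMatrix, dmap: DelayMap) -> ShagCarpet:
    """Sort voxel rows by delay, largest delay first; ties by voxel_id.

    Voxels with undefined (NaN) delay sort to the bottom.  Flagged voxels
    keep their (unreliable) delay and participate in the ordering like any
    other voxel; cropping them off is a separate step.
    """
    if matrix.n_voxels != len(dmap.delays) or not np.array_equal(
        np.sort(matrix.voxel_ids), np.sort(dmap.voxel_ids)
    ):
        raise ValueError("matrix and delay map cover different voxel sets")
    # align delay map to matrix row order
    pos = {v: i for i, v in enumerate(dmap.voxel_ids)}
    align = np.array([pos[v] for v in matrix.voxel_ids])
    delays = dmap.delays[align]
    quality = dmap.quality[align]
    key = np.where(np.isnan(delays), -np.inf, delays)
    order_idx = np.lexsort((matrix.voxel_ids, -key))
    return ShagCarpet(
        data=matrix.data[order_idx],
        order=matrix.voxel_ids[order_idx],
        delays_sorted=delays[order_idx],
        quality_sorted=quality[order_idx],
        dt=matrix.dt,
        meta={
            "method": dmap.method,
            "direction": "descending",
            "quality_floor": float(dmap.quality_floor),
        },
    )


def crop_shag(carpet: ShagCarpet, quality_floor: float | None = None) -> ShagCarpet:
    """Remove contiguous low-quality blocks from the top and bottom.

    Low-quality voxels (quality < floor) without a clear, consistent
    pattern collect at the extremes of the sorted carpet because their
    estimated delays are extreme; only maximal contiguous extreme blocks
    are removed, interior low-quality rows are retained.  The default
    floor is the one carried by the delay map that sorted the carpet
    (null-calibrated for the cross-correlation estimators), falling back
    to 0.3.
    """
    if carpet.n_removed:
        raise ValueError("carpet is already cropped")
    if quality_floor is None:
        quality_floor = float(carpet.meta.get("quality_floor", 0.3))
    ok = carpet.quality_sorted >= quality_floor
    n = carpet.n_rows
    first = 0
    while first < n and not ok[first]:
        first += 1
    last = n
    while last > first and not ok[last - 1]:
        last -= 1
    n_removed = n - (last - first)
    if n_removed > 0.9 * n:
        raise ValueError(
            f"quality floor {quality_floor} too strict: would remove {n_removed}/{n} rows"
        )
    return ShagCarpet(
        data=carpet.data[first:last],
        order=carpet.order[first:last],
        delays_sorted=carpet.delays_sorted[first:last],
        quality_sorted=carpet.quality_sorted[first:last],
        dt=carpet.dt,
        crop=(first, last),
        n_removed=n_removed,
        meta=dict(carpet.meta),
    )


def split_by_tissue(carpet: ShagCarpet, masks: dict) -> dict:
    """Partition rows by tissue label, preserving within-tissue delay order.

    ``masks`` maps label (e.g. "GM", "WM", "CSF") to a set/array of
    voxel_ids.  Voxels in no mask land in an "unlabeled" carpet with a
    warning.  Row counts over the outputs sum to the input row count.
    """
    sets = {name: set(np.asarray(list(ids)).tolist()) for name, ids in masks.items()}
    assigned = np.full(carpet.n_rows, "", dtype=object)
    for name, ids in sets.items():
        for r, v in enumerate(carpet.order):
            if int(v) in ids and not assigned[r]:
                assigned[r] = name
    unlabeled = [r for r in range(carpet.n_rows) if not assigned[r]]
    if unlabeled:
        warnings.warn(f"{len(unlabeled)} voxels not covered by any tissue mask")
        for r in unlabeled:
            assigned[r] = "unlabeled"
    out = {}
    labels = list(sets) + (["unlabeled"] if unlabeled else [])
    for name in labels:
        rows = np.flatnonzero(assigned == name)
        out[name] = ShagCarpet(
            data=carpet.data[rows],
            order=carpet.order[rows],
            delays_sorted=carpet.delays_sorted[rows],
            quality_sorted=carpet.quality_sorted[rows],
            dt=carpet.dt,
            crop=carpet.crop,
            n_removed=carpet.n_removed,
            meta={**carpet.meta, "tissue": name},
        )
    return out


def render(carpet: ShagCarpet, path, edges=None, title: str | None = None) -> None:
    """Grayscale heatmap PNG: time on x, rows on y (row 0 on top).

    Intensity limits are symmetric about 0 (appropriate for z-scored
    rows).  Detected edges, if given, are drawn as red fitted lines.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    vmax = float(np.percentile(np.abs(carpet.data), 99)) or 1.0
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.imshow(
        carpet.data,
        aspect="auto",
        cmap="gray",
        vmin=-vmax,
        vmax=vmax,
        extent=(0, carpet.n_samples * carpet.dt, carpet.n_rows, 0),
        interpolation="nearest",
    )
    if edges is not None:
        edge_list = getattr(edges, "edges", edges)
        for e in edge_list:
            if not e.included:
                continue
            rows = np.array([0, carpet.n_rows - 1])
            ax.plot(e.intercept + e.slope * rows, rows, color="red", lw=1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("voxel row (sorted by delay, descending)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
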