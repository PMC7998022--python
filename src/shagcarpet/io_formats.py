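"""File I/O for the pipeline: NIfTI volumes, TSV tables, HDF5 carpets.

Conventions
-----------
- Voxel raster order is x fastest, then y, then z (Fortran order over the
  spatial grid), 0-based.  ``voxel_id`` is the flat index in that order, so
  carpet permutations are reproducible across runs.
- All times are seconds; sample ``i`` is at time ``i * tr`` with the first
  sample at time 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .signal_prep import VoxelMatrix


@dataclass
class BoldRun:
    """A 4-D acquisition plus its brain mask and repetition time."""

    volume: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) boolean
    affine: np.ndarray = None

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 4:
            raise ValueError(f"expected 4D volume, got {self.volume.ndim}D")
        if self.volume.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr is None or self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.volume.shape[:3]:
            raise ValueError("mask shape must match spatial dims of volume")
        if not self.mask.any():
            raise ValueError("mask has no true voxels")
        if self.affine is None:
            self.affine = np.eye(4)


@dataclass
class RegressorTrace:
    """An external reference timeseries, e.g. end-tidal CO2 in mmHg."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty regressor")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("regressor times must be strictly increasing")


def load_bold(path, tr: float | None = None, mask_path=None) -> BoldRun:
    """Load a 4-D NIfTI (and optionally its mask); tr from the header unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not np.isfinite(tr) or tr <= 0:
            raise ValueError(
                f"could not read a valid TR from the header of {path}; pass tr explicitly"
            )
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(volume=data, tr=tr, mask=mask, affine=img.affine)


def save_bold(run: BoldRun, path, mask_path=None) -> None:
    img = nib.Nifti1Image(run.volume, run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine), str(mask_path))


def _mask_order(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat voxel ids (x-fastest raster) and (n, 3) coords for in-mask voxels."""
    flat = np.flatnonzero(mask.ravel(order="F"))
    coords = np.column_stack(np.unravel_index(flat, mask.shape, order="F"))
    return flat, coords


def extract_matrix(run: BoldRun) -> VoxelMatrix:
    """One row per in-mask voxel, x-fastest raster order, ids retained."""
    ids, coords = _mask_order(run.mask)
    data = run.volume[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return VoxelMatrix(data=data, dt=run.tr, voxel_ids=ids, coords=coords)


def matrix_to_volume(matrix: VoxelMatrix, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Write matrix rows back into a 4-D volume (inverse of extract_matrix)."""
    if matrix.coords is None:
        raise ValueError("matrix has no voxel coordinates; cannot map back to a volume")
    vol = np.full(mask.shape + (matrix.n_samples,), fill, dtype=float)
    c = matrix.coords
    vol[c[:, 0], c[:, 1], c[:, 2], :] = matrix.data
    return vol


def values_to_volume(values: np.ndarray, coords: np.ndarray, shape, fill=np.nan) -> np.ndarray:
    """Scatter one value per voxel into a 3-D map (e.g. a delay map)."""
    vol = np.full(shape, fill, dtype=float)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    return vol


def load_regressor(path) -> RegressorTrace:
    """Read a 2-column (time, value) TSV/CSV; the time column must increase."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ValueError(f"empty regressor: {path}")
    if df.shape[1] < 2:
        raise ValueError(f"regressor needs at least two columns (time, value): {path}")
    return RegressorTrace(times=df.iloc[:, 0].to_numpy(float), values=df.iloc[:, 1].to_numpy(float))


def save_regressor(trace: RegressorTrace, path, columns=("time_s", "value")) -> None:
    pd.DataFrame({columns[0]: trace.times, columns[1]: trace.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# delay maps

def save_delay_map(dmap, path, coords: np.ndarray | None = None) -> None:
    """Delay map as TSV: voxel_id, x, y, z, delay_s, quality, flagged.

    Metadata (method, reference, resolution, quality floor) goes in
    ``# key=value`` header comment lines.
    """
    n = len(dmap.delays)
    if coords is None:
        coords = np.zeros((n, 3), dtype=int)
    df = pd.DataFrame(
        {
            "voxel_id": dmap.voxel_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "delay_s": dmap.delays,
            "quality": dmap.quality,
            "flagged": dmap.flagged.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# method={dmap.method}\n")
        fh.write(f"# reference={dmap.reference}\n")
        fh.write(f"# resolution_s={dmap.resolution!r}\n")
        fh.write(f"# quality_floor={dmap.quality_floor!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_delay_map(path):
    from .delay_map import DelayMap

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return DelayMap(
        delays=df["delay_s"].to_numpy(float),
        quality=df["quality"].to_numpy(float),
        method=meta.get("method", "unknown"),
        reference=meta.get("reference", ""),
        resolution=float(meta.get("resolution_s", "0.0")),
        voxel_ids=df["voxel_id"].to_numpy(int),
        flagged=df["flagged"].to_numpy(int).astype(bool),
        quality_floor=float(meta.get("quality_floor", "0.3")),
    ), df[["x", "y", "z"]].to_numpy(int)


# ---------------------------------------------------------------------------
# edge tables

EDGE_COLUMNS = [
    "index",
    "center_time_s",
    "polarity",
    "slope_s_per_row",
    "intercept_s",
    "transit_time_s",
    "contrast",
    "rate",
    "r_squared",
    "included",
    "reason",
]


def save_edge_table(edgeset, path) -> None:
    rows = []
    for i, e in enumerate(edgeset.edges):
        rows.append(
            {
                "index": i,
                "center_time_s": e.center_time,
                "polarity": e.polarity,
                "slope_s_per_row": e.slope,
                "intercept_s": e.intercept,
                "transit_time_s": e.transit_time,
                "contrast": e.contrast,
                "rate": e.rate,
                "r_squared": e.r_squared,
                "included": int(e.included),
                "reason": e.reason or "",
            }
        )
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["reason"] = df["reason"].fillna("")
    return df


# ---------------------------------------------------------------------------
# carpet container (HDF5)

def save_carpet(carpet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=carpet.data)
        f.create_dataset("order", data=carpet.order)
        f.create_dataset("delays_sorted", data=carpet.delays_sorted)
        f.create_dataset("quality_sorted", data=carpet.quality_sorted)
        f.attrs["dt"] = carpet.dt
        f.attrs["crop"] = carpet.crop
        f.attrs["n_removed"] = carpet.n_removed


def load_carpet(path):
    from .shag import ShagCarpet

    with h5py.File(path, "r") as f:
        return ShagCarpet(
            data=f["data"][...],
            order=f["order"][...],
            delays_sorted=f["delays_sorted"][...],
            quality_sorted=f["quality_sorted"][...],
            dt=float(f.attrs["dt"]),
            crop=tuple(int(v) for v in f.attrs["crop"]),
            n_removed=int(f.attrs["n_removed"]),
        )


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
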