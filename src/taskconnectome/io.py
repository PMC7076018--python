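"""File formats: TSV matrices and tables, JSON configs, optional NIfTI input.

All matrices travel as TSV with a header row and a leading id column, so
every artifact is diffable text. Difference matrices are validated to the
ternary alphabet on read and write; density matrices to [0, 1].
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Partition, RoiTimeSeries, UNASSIGNED
from .gppi import DifferenceMatrix

__all__ = ["write_matrix", "read_matrix", "write_partition", "read_partition",
           "read_timeseries_tsv", "extract_roi_timeseries"]

_KINDS = ("connectivity", "difference", "density", "consensus")


def _validate(values: np.ndarray, kind: str):
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    bad = np.argwhere(~np.isfinite(values) & ~np.isnan(values))
    if kind == "difference":
        mask = ~np.isin(values, (-1, 0, 1))
        if mask.any():
            i, j = np.argwhere(mask)[0]
            raise ValueError(
                f"difference matrix entry {values[i, j]!r} at row {i}, "
                f"column {j} outside {{-1, 0, 1}}")
    elif kind in ("density", "consensus"):
        with np.errstate(invalid="ignore"):
            mask = (values < 0) | (values > 1)
        mask &= ~np.isnan(values)
        if mask.any():
            i, j = np.argwhere(mask)[0]
            raise ValueError(
                f"{kind} entry {values[i, j]} at row {i}, column {j} "
                f"outside [0, 1]")
    elif kind == "connectivity":
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite connectivity at row {i}, column {j}")


def write_matrix(path, matrix, kind: str, ids=None) -> Path:
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    values = np.asarray(values, dtype=float)
    _validate(values, kind)
    if ids is None:
        ids = [f"n{i:03d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=ids, columns=ids)
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="id")
    return path


def read_matrix(path, kind: str):
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.nonzero(bad.to_numpy())[0][0])
                raise ValueError(
                    f"malformed numeric cell {df[col].iloc[i]!r} at row {i}, "
                    f"column {j} of {path}") from err
        raise
    _validate(values, kind)
    ids = [str(x) for x in df.index]
    if kind == "difference":
        return DifferenceMatrix(values=values.astype(int)), ids
    return values, ids


def write_partition(path, p: Partition) -> Path:
    path = Path(path)
    p.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    return Partition(labels=df["module_id"].to_numpy(dtype=int),
                     node_ids=[str(x) for x in df["node_id"]])


def read_timeseries_tsv(path, tr: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    runs = df.pop("run").to_numpy() if "run" in df.columns else None
    return RoiTimeSeries(values=df.to_numpy(dtype=float), tr=tr,
                         run_labels=runs, node_ids=list(df.columns))


def extract_roi_timeseries(image_path, atlas_path, tr: float = None
                           ) -> RoiTimeSeries:
    """Label-mean time series from a 4D NIfTI and an integer atlas.

    The atlas and image must share grid shape and affine; every positive
    label becomes one column (ascending label order). Labels absent from the
    image produce NaN columns with a warning.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    atlas = nib.load(str(atlas_path))
    if img.shape[:3] != atlas.shape[:3] or not np.allclose(img.affine, atlas.affine):
        raise ValueError("image and atlas are not on the same grid")
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    labels_img = np.asanyarray(atlas.dataobj).astype(int)
    labels = np.unique(labels_img)
    labels = labels[labels >= 1]
    T = data.shape[3]
    out = np.full((T, labels.size), np.nan)
    flat = data.reshape(-1, T)
    lab_flat = labels_img.reshape(-1)
    for k, lab in enumerate(labels):
        mask = lab_flat == lab
        if not mask.any():
            warnings.warn(f"atlas label {lab} covers no voxels: NaN column")
            continue
        out[:, k] = flat[mask].mean(axis=0)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return RoiTimeSeries(values=out, tr=tr,
                         node_ids=[f"roi{int(l):03d}" for l in labels])
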