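"""Watershed parcellation of statistical volumes into ROIs.

The inverted statistic map is treated as a landscape whose catchment
basins — one per local maximum of the original map — become ROIs.
Basins with <= min_size voxels are discarded (strict >50-voxel criterion
by default) and survivors are renumbered 1..k by descending size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from wmnet.types import BinaryMap, BoldData, Parcellation, StatMap

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}")
    return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])


def watershed_3d(
    stat_map: StatMap,
    mask: BinaryMap | np.ndarray | None = None,
    min_size: int = 50,
    connectivity: int = 26,
) -> Parcellation:
    """Flood catchment basins of the inverted map within a mask.

    Markers are the local minima of the inverted statistic (= local
    maxima of the original) under the chosen connectivity; flooding is
    deterministic, ties broken by voxel scan order. ROIs with
    ``<= min_size`` voxels are removed.
    """
    struct = _structure(connectivity)
    if mask is None:
        mask_arr = stat_map.mask.copy()
    else:
        mask_arr = mask.data if isinstance(mask, BinaryMap) else np.asarray(mask, bool)
    mask_arr = mask_arr & stat_map.mask

    empty = Parcellation(
        labels=np.zeros(stat_map.data.shape, dtype=np.int32),
        roi_table=pd.DataFrame(
            columns=["label", "size", "centroid", "peak_ijk", "peak_value"]
        ),
    )
    if not mask_arr.any():
        return empty

    inverted = -stat_map.data
    # minima are sought within the mask: outside voxels play +inf
    inv_masked = np.where(mask_arr, inverted, np.inf)
    minima = local_minima(inv_masked, connectivity=_CONN_RANK[connectivity]) & mask_arr
    markers, n_markers = ndimage.label(minima, structure=struct)
    if n_markers == 0:
        return empty
    labels = watershed(inverted, markers=markers, mask=mask_arr, connectivity=struct)

    # strict size filter, then renumber by descending size
    sizes = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n_markers + 1)
    ).astype(int)
    keep = np.flatnonzero(sizes > min_size) + 1
    if keep.size == 0:
        return empty
    order = keep[np.argsort(-sizes[keep - 1], kind="stable")]

    out = np.zeros(labels.shape, dtype=np.int32)
    rows = []
    for new_label, old_label in enumerate(order, start=1):
        roi = labels == old_label
        out[roi] = new_label
        idx = np.argwhere(roi)
        vals = stat_map.data[roi]
        peak_local = np.argmax(vals)
        rows.append(
            {
                "label": new_label,
                "size": int(roi.sum()),
                "centroid": tuple(idx.mean(axis=0)),
                "peak_ijk": tuple(int(v) for v in idx[peak_local]),
                "peak_value": float(vals[peak_local]),
            }
        )
    return Parcellation(labels=out, roi_table=pd.DataFrame(rows))


def roi_reduce(
    data: np.ndarray | BoldData,
    parc: Parcellation,
    stat: str = "mean",
) -> np.ndarray:
    """Per-ROI summaries of a 3-D volume or 4-D (x, y, z, t) series.

    Returns an array of shape (n_rois,) for a volume or (t, n_rois) for
    a series, ROI order following label order. An ROI that is empty
    after masking raises, naming the label.
    """
    if isinstance(data, BoldData):
        raise TypeError("roi_reduce expects a voxel volume, not ROI-level BoldData")
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("data must be 3-D or 4-D")
    if data.shape[:3] != parc.labels.shape:
        raise ValueError("spatial shape must match parcellation")
    reducer = {"mean": np.mean, "median": np.median, "max": np.max}.get(stat)
    if reducer is None:
        raise ValueError(f"unknown stat {stat!r}")

    labels = parc.roi_labels
    out = []
    for lab in labels:
        roi = parc.labels == lab
        if not roi.any():
            raise ValueError(f"ROI label {lab} is empty")
        if data.ndim == 3:
            out.append(reducer(data[roi]))
        else:
            out.append(reducer(data[roi, :], axis=0))
    arr = np.asarray(out)
    return arr if data.ndim == 3 else arr.T
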