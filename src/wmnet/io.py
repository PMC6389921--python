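"""Readers/writers for the pipeline's on-disk formats.

Events travel as BIDS-style TSV, ROI series and connectivity matrices as
CSV/TSV, volumes as NIfTI, and reports/ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from wmnet.types import BoldData, FeatureStack, validate_events


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_events(events)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def write_bold_tsv(bold: BoldData, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(bold.data, columns=bold.roi_names).to_csv(path, sep="\t", index=False)
    return path


def read_bold_tsv(path: str | Path, tr: float) -> BoldData:
    df = pd.read_csv(path, sep="\t")
    return BoldData(data=df.to_numpy(), tr=tr, roi_names=list(df.columns))


def write_nifti(volume: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_stack(stack: FeatureStack, prefix: str | Path) -> tuple[Path, Path]:
    """Feature stack as CSV (metadata + features) plus a JSON sidecar."""
    prefix = Path(prefix)
    df = pd.concat(
        [stack.meta, pd.DataFrame(stack.features, columns=stack.feature_names)], axis=1
    )
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    side = {
        "kind": stack.kind,
        "n_events": stack.n_events,
        "n_features": stack.n_features,
        "feature_names": stack.feature_names,
        "meta_columns": list(stack.meta.columns),
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(side, indent=2))
    return csv_path, json_path


def read_stack(prefix: str | Path) -> FeatureStack:
    prefix = Path(prefix)
    side = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".csv"))
    return FeatureStack(
        features=df[side["feature_names"]].to_numpy(),
        meta=df[side["meta_columns"]],
        kind=side["kind"],
        feature_names=side["feature_names"],
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
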