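"""Core data containers shared across pipeline stages.

Events tables and feature-stack metadata are plain :class:`pandas.DataFrame`
objects; the dataclasses here bundle arrays with the bookkeeping that
downstream stages need (TR, ROI names, masks, provenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Columns every events table must carry.
EVENT_COLUMNS = (
    "onset",
    "duration",
    "subject",
    "run",
    "study",
    "trial",
    "stage",
    "domain",
    "load",
    "manipulation",
)

#: Trial stages in presentation order.
STAGES = ("cue", "encode", "maintain", "probe")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an events table for the required columns and basic sanity.

    Onsets must be nondecreasing within each (subject, run), durations
    strictly positive, and stage rows within a trial non-overlapping.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    if (events["duration"] <= 0).any():
        raise ValueError("all event durations must be > 0")
    for (subj, run), grp in events.groupby(["subject", "run"], sort=False):
        onsets = grp["onset"].to_numpy()
        if np.any(np.diff(onsets) < 0):
            raise ValueError(
                f"onsets not nondecreasing for subject={subj} run={run}"
            )
        for trial, tg in grp.groupby("trial", sort=False):
            tg = tg.sort_values("onset")
            ends = (tg["onset"] + tg["duration"]).to_numpy()
            if np.any(tg["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
                raise ValueError(
                    f"overlapping stages in subject={subj} run={run} trial={trial}"
                )
    return events


@dataclass
class BoldData:
    """ROI-by-time signal matrix with acquisition metadata.

    ``data`` is scans x ROIs; ``nuisance`` is the scans x k matrix of
    no-interest regressors (motion expansion, spikes) that was either
    recorded with the data or injected by the simulator.
    """

    data: np.ndarray
    tr: float
    roi_names: list[str] = field(default_factory=list)
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldData.data must be 2-D (scans x ROIs)")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not self.roi_names:
            self.roi_names = [f"roi{i:03d}" for i in range(self.data.shape[1])]
        if len(self.roi_names) != self.data.shape[1]:
            raise ValueError("roi_names length must match number of columns")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.data.shape[0]:
                raise ValueError("nuisance rows must match scan count")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class StatMap:
    """3-D statistic volume with a brain mask and optional smoothness."""

    data: np.ndarray
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fwhm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap.data must be 3-D")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")


@dataclass
class BinaryMap:
    """Boolean volume with provenance and a cluster table.

    The cluster table has columns label, size, peak_value, peak_ijk and
    its sizes sum to the foreground voxel count.
    """

    data: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    clusters: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMap.data must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus an ROI summary table.

    ROI labels are consecutive positive integers ordered by descending
    size; the table carries label, size, centroid and peak per ROI.
    """

    labels: np.ndarray
    roi_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("Parcellation.labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("Parcellation.labels must be integer typed")

    @property
    def n_rois(self) -> int:
        return int(self.roi_table.shape[0])

    @property
    def roi_labels(self) -> np.ndarray:
        return self.roi_table["label"].to_numpy()


@dataclass
class FeatureStack:
    """Events x features matrix with per-event metadata.

    ``kind`` is "activity" (GLM betas) or "connectivity" (vectorized gPPI
    edges). Metadata must carry the full factorial annotation so decoders
    can partition by subject and stratify by stage/domain/load.
    """

    features: np.ndarray
    meta: pd.DataFrame
    kind: str = "activity"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (events x features)")
        if len(self.meta) != self.features.shape[0]:
            raise ValueError("metadata rows must match feature rows")
        if not self.feature_names:
            self.feature_names = [f"f{i:04d}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature count")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureStack":
        """Row-subset the stack, keeping features and metadata aligned."""
        mask = np.asarray(mask)
        return FeatureStack(
            features=self.features[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            kind=self.kind,
            feature_names=list(self.feature_names),
        )


@dataclass
class ClassificationReport:
    """Paired observed/null performance distributions and summary metrics.

    ``observed`` and ``null`` are the accuracy (or F1) values over
    partition x bootstrap resamples, paired by resample; ``p`` is the
    empirical (b+1)/(m+1) probability that the label-shuffled model beats
    the true-label model.
    """

    observed: np.ndarray
    null: np.ndarray
    p: float
    metric: str = "accuracy"
    per_class: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    effect_size: float | None = None
    observed_f1: np.ndarray | None = None
    null_f1: np.ndarray | None = None
    model: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.null = np.asarray(self.null, dtype=float)
        if self.observed.shape != self.null.shape:
            raise ValueError("observed and null distributions must be paired")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("empirical p must lie in (0, 1]")
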