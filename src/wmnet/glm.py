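"""Mini-block GLM: one predictor per trial stage, nuisance + drift model.

Each stage (cue, encode, maintain, probe) of each trial gets its own
HRF-convolved boxcar column, so the fitted betas form an event-level
activity stack. Drift is absorbed by a discrete cosine basis with cutoff
period equal to half the run length (equivalent to high-pass filtering
inside the design); motion goes in as a 24-parameter Volterra expansion
plus spike indicator columns. The unmodeled inter-trial interval serves
as the implicit baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmnet.hrf import convolve_boxcar, double_gamma_hrf
from wmnet.types import BoldData, FeatureStack, validate_events


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with column bookkeeping.

    ``task_slice``/``nuisance_slice``/``drift_slice`` partition the
    columns; ``event_meta`` has one row per task column in column order.
    """

    matrix: np.ndarray
    names: list[str]
    task_slice: slice
    nuisance_slice: slice
    drift_slice: slice
    tr: float
    event_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("names length must match column count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")
        task = self.matrix[:, self.task_slice]
        if task.size and np.any(np.all(task == 0, axis=0)):
            raise ValueError("design contains an all-zero task column")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def task_names(self) -> list[str]:
        return self.names[self.task_slice]


def cosine_drift_basis(n_scans: int, tr: float, cutoff_s: float | None = None) -> np.ndarray:
    """Discrete cosine drift regressors with periods >= cutoff.

    Default cutoff is half the run length. Basis functions are
    ``cos(pi k (2t + 1) / (2N))`` for k = 1..K with K chosen so the
    slowest excluded period is below the cutoff; columns are unit-norm.
    """
    total = n_scans * tr
    if cutoff_s is None:
        cutoff_s = total / 2.0
    k_max = int(np.floor(2 * total / cutoff_s))
    t = np.arange(n_scans)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) * np.sqrt(2.0 / n_scans)
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def motion_expansion(motion: np.ndarray, spikes: np.ndarray | None = None) -> np.ndarray:
    """24-parameter Volterra expansion of 6 rigid-body motion traces.

    [m, m shifted by one scan, m^2, shifted^2], plus one indicator column
    per flagged scan when ``spikes`` (boolean, length scans) is given.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be scans x 6")
    shifted = np.vstack([np.zeros((1, 6)), motion[:-1]])
    cols = np.hstack([motion, shifted, motion**2, shifted**2])
    if spikes is not None:
        spikes = np.asarray(spikes, dtype=bool)
        for idx in np.flatnonzero(spikes):
            ind = np.zeros((motion.shape[0], 1))
            ind[idx] = 1.0
            cols = np.hstack([cols, ind])
    return cols


def build_design_matrix(
    events: pd.DataFrame,
    nuisance: np.ndarray | None,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
    drift_cutoff_s: float | None = None,
) -> DesignMatrix:
    """One HRF-convolved column per (trial, stage) plus nuisance and drift.

    ``events`` must cover a single run. Events ending after the last scan
    are rejected; duplicate (trial, stage) rows are rejected.
    """
    events = validate_events(events)
    if events[["subject", "run"]].drop_duplicates().shape[0] > 1:
        raise ValueError("build_design_matrix expects events from a single run")
    scan_end = n_scans * tr
    ends = events["onset"] + events["duration"]
    if (ends > scan_end + 1e-9).any():
        bad = events.loc[ends > scan_end + 1e-9].iloc[0]
        raise ValueError(
            f"event trial={bad['trial']} stage={bad['stage']} ends at "
            f"{float(ends.max()):.1f} s, beyond scan end {scan_end:.1f} s"
        )
    dup = events.duplicated(subset=["trial", "stage"])
    if dup.any():
        bad = events.loc[dup].iloc[0]
        raise ValueError(f"duplicate (trial, stage) = ({bad['trial']}, {bad['stage']})")

    hrf = double_gamma_hrf(tr, oversampling)
    cols, names, meta_rows = [], [], []
    for _, row in events.iterrows():
        cols.append(
            convolve_boxcar(
                row["onset"], row["duration"], n_scans, tr, oversampling, hrf
            )
        )
        names.append(f"t{int(row['trial']):03d}_{row['stage']}")
        meta_rows.append(row)
    task = np.column_stack(cols)
    n_task = task.shape[1]

    nuis = np.empty((n_scans, 0)) if nuisance is None else np.asarray(nuisance, float)
    if nuis.shape[0] != n_scans:
        raise ValueError("nuisance rows must equal n_scans")
    drift = cosine_drift_basis(n_scans, tr, drift_cutoff_s)
    intercept = np.ones((n_scans, 1))

    matrix = np.hstack([task, nuis, drift, intercept])
    names += [f"nuis{i:02d}" for i in range(nuis.shape[1])]
    names += [f"drift{i:02d}" for i in range(drift.shape[1])]
    names += ["intercept"]
    return DesignMatrix(
        matrix=matrix,
        names=names,
        task_slice=slice(0, n_task),
        nuisance_slice=slice(n_task, n_task + nuis.shape[1]),
        drift_slice=slice(n_task + nuis.shape[1], n_task + nuis.shape[1] + drift.shape[1]),
        tr=tr,
        event_meta=pd.DataFrame(meta_rows).reset_index(drop=True),
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved via QR pivoting
        _, r, piv = _qr_pivot(X)
        dropped = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{X.shape[1]}); collinear columns: {dropped}"
        )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def fit_glm(
    bold: BoldData,
    design: DesignMatrix,
    contrasts: dict[str, np.ndarray] | None = None,
) -> tuple[FeatureStack, np.ndarray, dict[str, pd.DataFrame]]:
    """Ordinary least-squares betas per ROI for every design column.

    Returns the task-column betas as an activity FeatureStack (one row
    per modeled trial-stage event), the residual series, and T statistics
    for any supplied contrast vectors (over task columns).
    """
    Y = bold.data
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("BOLD scan count must match design scan count")
    _check_rank(X, design.names)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    task_beta = beta[design.task_slice]  # events x ROIs

    stats: dict[str, pd.DataFrame] = {}
    if contrasts:
        dof = X.shape[0] - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        for name, cvec in contrasts.items():
            c = np.zeros(X.shape[1])
            c[design.task_slice] = np.asarray(cvec, float)
            var = c @ xtx_inv @ c
            tval = (c @ beta) / np.sqrt(sigma2 * var)
            stats[name] = pd.DataFrame(
                {"roi": bold.roi_names, "t": tval, "dof": dof}
            )

    stack = FeatureStack(
        features=task_beta,
        meta=design.event_meta.copy(),
        kind="activity",
        feature_names=list(bold.roi_names),
    )
    return stack, resid, stats


def assemble_beta_stack(
    runs: list[tuple[pd.DataFrame, BoldData]],
    oversampling: int = 16,
) -> FeatureStack:
    """Fit the mini-block GLM per run and concatenate event betas.

    ``runs`` is a list of (events, bold) pairs, one per subject-run. The
    resulting stack has subjects x runs x trials x stages rows.
    """
    stacks = []
    feature_names = None
    for events, bold in runs:
        design = build_design_matrix(
            events, bold.nuisance, bold.n_scans, bold.tr, oversampling
        )
        stack, _, _ = fit_glm(bold, design)
        if feature_names is None:
            feature_names = stack.feature_names
        elif feature_names != stack.feature_names:
            raise ValueError("ROI names differ across runs")
        stacks.append(stack)
    return FeatureStack(
        features=np.vstack([s.features for s in stacks]),
        meta=pd.concat([s.meta for s in stacks], ignore_index=True),
        kind="activity",
        feature_names=list(feature_names),
    )
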