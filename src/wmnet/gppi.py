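"""Generalized psychophysiological interaction (gPPI) connectivity.

For a source/target ROI pair the model regresses the target series on
the source series, the HRF-convolved psychological regressors H(X), the
nuisance matrix E, and the interaction terms source x H(X):

    Y_T = b0 + [Y_S, H(X), E] b_G + [Y_S * H(X)] b_j + e

The interaction coefficients b_j — one per psychological condition —
are the task-evoked connectivity estimates. The interaction is formed in
BOLD space (no deconvolution), with the source series mean-centered so
the interaction is decorrelated from the H(X) main effect. Directed
estimates for (s -> t) and (t -> s) are averaged into an undirected
matrix per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmnet.simulate import condition_regressors
from wmnet.types import BoldData, FeatureStack


@dataclass
class PpiModel:
    """Estimated gPPI regression for one (source, target) pair."""

    beta_0: float
    beta_G: np.ndarray
    beta_j: np.ndarray
    conditions: list[str]
    residuals: np.ndarray
    design_names: list[str] = field(default_factory=list)


@dataclass
class ConditionConnectivity:
    """Symmetric ROI x ROI interaction-coefficient matrix per condition.

    Diagonals are NaN (self-connectivity undefined); failed pairwise
    fits are NaN with the failure recorded in ``failures``.
    """

    matrices: dict[str, np.ndarray]
    roi_names: list[str]
    failures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cond, mat in self.matrices.items():
            mat = np.asarray(mat, dtype=float)
            if not np.allclose(mat, mat.T, equal_nan=True):
                raise ValueError(f"matrix for {cond!r} is not symmetric")
            np.fill_diagonal(mat, np.nan)
            self.matrices[cond] = mat


def build_psych_matrix(
    events: pd.DataFrame,
    conditions: list[str],
    n_scans: int,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """Scan-resolution boxcar matrix X (one column per condition).

    Each scan holds its fractional overlap with the condition's events,
    so column sums equal the total per-condition duration in scan units.
    """
    if not conditions:
        raise ValueError("condition set must be non-empty")
    return condition_regressors(
        events, list(conditions), n_scans, tr, oversampling, convolved=False
    )


def _interaction_design(
    source: np.ndarray,
    hx: np.ndarray,
    E: np.ndarray | None,
    conditions: list[str],
) -> tuple[np.ndarray, list[str], int]:
    n_scans = source.shape[0]
    src_c = source - source.mean()
    inter = src_c[:, None] * hx
    E_arr = np.empty((n_scans, 0)) if E is None else np.asarray(E, float)
    X_full = np.hstack(
        [np.ones((n_scans, 1)), src_c[:, None], hx, E_arr, inter]
    )
    names = (
        ["intercept", "source"]
        + [f"hx_{c}" for c in conditions]
        + [f"nuis{i:02d}" for i in range(E_arr.shape[1])]
        + [f"ppi_{c}" for c in conditions]
    )
    return X_full, names, X_full.shape[1] - len(conditions)


def gppi_fit(
    target: np.ndarray,
    source: np.ndarray,
    X: np.ndarray,
    E: np.ndarray | None,
    tr: float,
    conditions: list[str] | None = None,
    hx: np.ndarray | None = None,
    oversampling: int = 16,
) -> PpiModel:
    """Least-squares gPPI estimate for one ordered ROI pair.

    ``X`` is the unconvolved psych matrix (scans x conditions); its HRF
    convolution may be passed as ``hx`` to avoid recomputation. Raises
    on rank deficiency, naming the collinear interaction columns.
    """
    target = np.asarray(target, float).ravel()
    source = np.asarray(source, float).ravel()
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("psych matrix X must be 2-D")
    if conditions is None:
        conditions = [f"cond{i}" for i in range(X.shape[1])]
    if hx is None:
        hx = _convolve_psych(X, tr, oversampling)
    if not (len(target) == len(source) == X.shape[0] == hx.shape[0]):
        raise ValueError("target, source, X and H(X) must share scan count")

    X_full, names, n_base = _interaction_design(source, hx, E, list(conditions))
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X_full, mode="economic", pivoting=True)
        dropped = [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"rank-deficient gPPI design; collinear columns: {dropped}"
        )
    beta, _, _, _ = np.linalg.lstsq(X_full, target, rcond=None)
    resid = target - X_full @ beta
    return PpiModel(
        beta_0=float(beta[0]),
        beta_G=beta[1:n_base],
        beta_j=beta[n_base:],
        conditions=list(conditions),
        residuals=resid,
        design_names=names,
    )


def _convolve_psych(X: np.ndarray, tr: float, oversampling: int = 16) -> np.ndarray:
    """HRF-convolve each psych column at scan resolution."""
    from wmnet.hrf import double_gamma_hrf

    hrf_fine = double_gamma_hrf(tr, oversampling)
    n_scans, n_cond = X.shape
    out = np.empty_like(X, dtype=float)
    for j in range(n_cond):
        fine = np.repeat(X[:, j], oversampling)
        conv = np.convolve(fine, hrf_fine)[: len(fine)]
        out[:, j] = conv[::oversampling]
    return out


def gppi_matrix(
    roi_ts: BoldData,
    X: np.ndarray,
    E: np.ndarray | None = None,
    conditions: list[str] | None = None,
    oversampling: int = 16,
) -> ConditionConnectivity:
    """Undirected condition-wise connectivity over all ROI pairs.

    Fits the gPPI model for every ordered pair (one multi-target solve
    per source ROI), then averages the upper and lower triangles:
    M[i, j] = (b_j(i->j) + b_j(j->i)) / 2. Failed fits leave NaN edges
    and are recorded, never silently zeroed.
    """
    if roi_ts.n_rois < 2:
        raise ValueError("need >= 2 ROIs")
    X = np.asarray(X, float)
    if conditions is None:
        conditions = [f"cond{i}" for i in range(X.shape[1])]
    hx = _convolve_psych(X, roi_ts.tr, oversampling)
    n = roi_ts.n_rois
    n_cond = len(conditions)
    directed = np.full((n_cond, n, n), np.nan)
    failures: list[dict] = []

    for s in range(n):
        source = roi_ts.data[:, s]
        try:
            X_full, names, n_base = _interaction_design(
                source, hx, E, list(conditions)
            )
            rank = np.linalg.matrix_rank(X_full)
            if rank < X_full.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient design")
            targets = np.delete(np.arange(n), s)
            beta, _, _, _ = np.linalg.lstsq(
                X_full, roi_ts.data[:, targets], rcond=None
            )
            directed[:, s, targets] = beta[n_base:, :]
        except np.linalg.LinAlgError as err:
            failures.append({"source": roi_ts.roi_names[s], "error": str(err)})

    matrices = {}
    for k, cond in enumerate(conditions):
        d = directed[k]
        sym = (d + d.T) / 2.0  # NaN propagates: a failed direction voids the edge
        np.fill_diagonal(sym, np.nan)
        matrices[cond] = sym
    return ConditionConnectivity(
        matrices=matrices, roi_names=list(roi_ts.roi_names), failures=failures
    )


def edge_names(roi_names: list[str]) -> list[str]:
    """Stable upper-triangle edge labels in row-major order."""
    n = len(roi_names)
    return [
        f"{roi_names[i]}--{roi_names[j]}" for i in range(n) for j in range(i + 1, n)
    ]


def vectorize_edges(
    conn: ConditionConnectivity, meta: pd.DataFrame | None = None
) -> FeatureStack:
    """Flatten each condition matrix's strict upper triangle into a feature row.

    Row order follows the condition order in ``conn.matrices``; optional
    ``meta`` (one row per condition, same order) supplies event metadata.
    """
    names = edge_names(conn.roi_names)
    n = len(conn.roi_names)
    iu = np.triu_indices(n, k=1)
    rows, conds = [], []
    for cond, mat in conn.matrices.items():
        mat = np.asarray(mat, float)
        off_diag = ~np.eye(n, dtype=bool)
        if not np.allclose(
            mat[off_diag], mat.T[off_diag], equal_nan=True
        ):
            raise ValueError(f"matrix for {cond!r} is asymmetric")
        rows.append(mat[iu])
        conds.append(cond)
    if meta is None:
        meta = pd.DataFrame({"condition": conds})
    else:
        meta = meta.reset_index(drop=True).copy()
        meta["condition"] = conds
    return FeatureStack(
        features=np.vstack(rows), meta=meta, kind="connectivity", feature_names=names
    )


def devectorize_edges(row: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric matrix (NaN diagonal) from an edge vector."""
    row = np.asarray(row, float)
    iu = np.triu_indices(n_rois, k=1)
    if row.size != iu[0].size:
        raise ValueError("edge vector length does not match n_rois")
    mat = np.full((n_rois, n_rois), np.nan)
    mat[iu] = row
    mat[(iu[1], iu[0])] = row
    return mat


def event_connectivity_stack(
    roi_ts: BoldData,
    events: pd.DataFrame,
    stages: tuple[str, ...] = ("encode", "maintain", "probe"),
    oversampling: int = 16,
) -> FeatureStack:
    """Single-trial connectivity: one psych column (and edge row) per event.

    Builds the psych matrix with one column per (trial, stage) event and
    runs the same estimator; each event's interaction coefficients give
    one vectorized edge row, annotated with that event's metadata.
    """
    ev = events.loc[events["stage"].isin(stages)].reset_index(drop=True)
    if ev.empty:
        raise ValueError("no events in requested stages")
    from wmnet.hrf import sample_boxcar

    cols = [
        sample_boxcar(
            row["onset"], row["duration"], roi_ts.n_scans, roi_ts.tr, oversampling
        )
        for _, row in ev.iterrows()
    ]
    X = np.column_stack(cols)
    conds = [f"t{int(r['trial']):03d}_{r['stage']}" for _, r in ev.iterrows()]
    conn = gppi_matrix(roi_ts, X, roi_ts.nuisance, conditions=conds, oversampling=oversampling)
    return vectorize_edges(conn, meta=ev)
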