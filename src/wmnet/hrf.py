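"""Haemodynamic response modelling: boxcars and HRF convolution.

The canonical double-gamma HRF (response peak ~5 s, undershoot ~15 s) is
taken from nilearn. Boxcars are built on an oversampled grid, convolved
at that resolution, then decimated to scan times, so event onsets and
durations that are not TR multiples are handled exactly up to the
oversampling grid.
"""

from __future__ import annotations

import numpy as np
from nilearn.glm.first_level import spm_hrf


def double_gamma_hrf(tr: float, oversampling: int = 16) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr / oversampling`` s.

    Normalized to unit peak so convolved regressors keep the boxcar's
    amplitude scale.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    h = spm_hrf(tr, oversampling=oversampling)
    return h / h.max()


def boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """Indicator timecourse on the oversampled grid (length n_scans*oversampling)."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must have equal length")
    n_fine = n_scans * oversampling
    dt = tr / oversampling
    out = np.zeros(n_fine)
    for on, dur in zip(onsets, durations):
        if dur <= 0:
            raise ValueError("durations must be > 0")
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        if i0 >= n_fine:
            raise ValueError(f"event onset {on} s lies beyond scan end")
        out[i0 : min(i1, n_fine)] = 1.0
    return out


def convolve_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar sampled at scan times (length ``n_scans``).

    The same routine serves design-matrix construction and the
    generative simulator, so estimation is exactly matched to the
    generative model.
    """
    if hrf is None:
        hrf = double_gamma_hrf(tr, oversampling)
    box = boxcar(onsets, durations, n_scans, tr, oversampling)
    conv = np.convolve(box, hrf)[: len(box)]
    return conv[::oversampling]


def sample_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """Unconvolved boxcar at scan resolution; each scan holds its overlap fraction.

    Column sums therefore equal total event duration in scan units (up to
    the oversampling grid).
    """
    box = boxcar(onsets, durations, n_scans, tr, oversampling)
    return box.reshape(n_scans, oversampling).mean(axis=1)
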