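"""Independent brute-force oracles used to check the implementations.

These are deliberately naive: priority-queue flooding for the watershed,
exhaustive partition enumeration for Ward's criterion, and explicit
normal-equation solves for the regression estimators. They share no code
with the package paths they validate.
"""

import heapq
import itertools

import numpy as np

_OFFSETS26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def flood_watershed(inverted: np.ndarray, markers: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Meyer-style priority flood from markers; 26-connectivity.

    Pops the lowest-valued queued voxel (ties by scan order) and claims
    unlabeled masked neighbours for its basin.
    """
    labels = np.where(mask, markers, 0).astype(int)
    shape = inverted.shape
    heap = []
    counter = 0
    for idx in np.argwhere(markers > 0):
        i, j, k = map(int, idx)
        if mask[i, j, k]:
            heapq.heappush(heap, (float(inverted[i, j, k]), counter, i, j, k))
            counter += 1
    queued = markers > 0
    while heap:
        _, _, i, j, k = heapq.heappop(heap)
        lab = labels[i, j, k]
        for di, dj, dk in _OFFSETS26:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if mask[ni, nj, nk] and labels[ni, nj, nk] == 0 and not queued[ni, nj, nk]:
                labels[ni, nj, nk] = lab
                queued[ni, nj, nk] = True
                heapq.heappush(
                    heap, (float(inverted[ni, nj, nk]), counter, ni, nj, nk)
                )
                counter += 1
    return labels


def best_two_partition(X: np.ndarray) -> frozenset:
    """Exhaustive 2-partition minimizing total within-cluster variance.

    Returns the smaller side's index set. Feasible for <= 10 items.
    """
    n = X.shape[0]
    best, best_cost = None, np.inf
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            a = np.asarray(combo)
            b = np.setdiff1d(np.arange(n), a)
            cost = ((X[a] - X[a].mean(0)) ** 2).sum() + ((X[b] - X[b].mean(0)) ** 2).sum()
            if cost < best_cost:
                best_cost, best = cost, frozenset(combo)
    return best


def normal_equation_betas(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS solve (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def purity_by_enumeration(omega, classes) -> float:
    """Direct evaluation: sum over clusters of the best class overlap."""
    omega = np.asarray(omega)
    classes = np.asarray(classes)
    total = 0
    for w in np.unique(omega):
        in_cluster = classes[omega == w]
        counts = [np.sum(in_cluster == c) for c in np.unique(classes)]
        total += max(counts)
    return total / len(omega)


def bh_stepup(pvals, q) -> np.ndarray:
    """Textbook BH step-up: largest k with p_(k) <= k q / m."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        mask[order[: k + 1]] = True
    return mask
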