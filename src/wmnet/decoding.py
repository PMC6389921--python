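"""Multi-class decoding of WM factors with permutation-calibrated inference.

Dense models are one-vs-all ensembles of linear max-margin classifiers
combined through an error-correcting output-code contract (decode by
minimal hinge loss over codewords). Sparse models are L1-penalized
multinomial logistic regressions fitted along a regularization path,
with the operating lambda chosen at the knee (maximal absolute second
difference) of the summed cross-entropy curve.

Significance is empirical: events are split 75/25 by subject, training
data are bootstrapped, and a label-shuffled null model is trained beside
every true-label model; over m = partitions x bootstraps paired
resamples, p = (b + 1) / (m + 1) where b counts resamples in which the
null model outperformed the true one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from wmnet.types import ClassificationReport, FeatureStack


# --------------------------------------------------------------------------
# partitioning


def subject_partition(
    stack: FeatureStack, train_frac: float = 0.75, seed: int = 0
) -> tuple[FeatureStack, FeatureStack]:
    """Split events at the subject level; no subject spans both sides.

    Train subject count is round(train_frac * n_subjects), clipped so
    both sides keep at least one subject.
    """
    subjects = np.asarray(sorted(stack.meta["subject"].unique()))
    n = len(subjects)
    if n < 4:
        raise ValueError("need >= 4 subjects for a subject-level split")
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train > n - 1:
        raise ValueError(f"train_frac={train_frac} leaves an empty partition")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(subjects)
    train_subjects = set(shuffled[:n_train])
    in_train = stack.meta["subject"].isin(train_subjects).to_numpy()
    train, holdout = stack.select(in_train), stack.select(~in_train)
    assert not set(train.meta["subject"]) & set(holdout.meta["subject"])
    return train, holdout


# --------------------------------------------------------------------------
# models


@dataclass
class DenseModel:
    """One-vs-all ECOC ensemble of linear SVMs with z-scored features."""

    classes: np.ndarray
    scaler: StandardScaler
    estimators: list[LinearSVC]
    code: np.ndarray  # classes x binary-learners code matrix (+1/-1)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        return np.column_stack([est.decision_function(Xs) for est in self.estimators])

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_values(X)
        # hinge loss of each codeword against the decision vector
        losses = np.maximum(0.0, 1.0 - f[:, None, :] * self.code[None, :, :]).sum(
            axis=2
        )
        return self.classes[np.argmin(losses, axis=1)]


@dataclass
class SparseModel:
    """Per-class sparse weights from a penalized multinomial fit."""

    classes: np.ndarray
    scaler: StandardScaler
    weights: np.ndarray  # classes x features
    bias: np.ndarray
    selected_lambda: float
    lambda_path: np.ndarray
    ce_curve: np.ndarray
    support: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        scores = Xs @ self.weights.T + self.bias
        return self.classes[np.argmax(scores, axis=1)]

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.weights != 0))


def train_dense(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, C: float = 1.0
) -> DenseModel:
    """Fit the one-vs-all linear-SVM ECOC ensemble.

    Features are z-scored with training statistics only. Every class
    must appear at least twice in training.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in training data")
    if counts.min() < 2:
        sparse_cls = classes[counts.argmin()]
        raise ValueError(f"class {sparse_cls!r} has < 2 training rows")
    scaler = StandardScaler().fit(features)
    Xs = scaler.transform(features)
    code = -np.ones((len(classes), len(classes)))
    np.fill_diagonal(code, 1.0)
    estimators = []
    for k, cls in enumerate(classes):
        y = np.where(labels == cls, 1, -1)
        est = LinearSVC(C=C, random_state=seed, dual="auto", max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xs, y)
        estimators.append(est)
    return DenseModel(classes=classes, scaler=scaler, estimators=estimators, code=code)


def select_lambda(ce_curve: np.ndarray) -> int:
    """Index of the knee: maximal absolute second difference of the curve.

    The curve is indexed along a decreasing lambda path; ties break
    toward the larger lambda (smaller index), i.e. the sparser model.
    """
    ce_curve = np.asarray(ce_curve, dtype=float)
    if ce_curve.size < 3:
        raise ValueError("need >= 3 lambda values to locate a knee")
    if not np.all(np.isfinite(ce_curve)):
        raise ValueError("cross-entropy curve contains non-finite values")
    d2 = np.abs(np.diff(ce_curve, n=2))
    # interior index i+1 owns d2[i]; argmax returns first max = larger lambda
    return int(np.argmax(d2) + 1)


def default_lambda_path(
    X: np.ndarray, labels: np.ndarray, n: int = 12, ratio: float = 1e-3
) -> np.ndarray:
    """Data-driven log-spaced path from lambda_max down to ratio*lambda_max.

    lambda_max is the smallest penalty that zeroes every coefficient of
    the multinomial lasso: max over (class, feature) of the score
    |X^T (1[y=k] - pi_k)| / n at the intercept-only fit.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    nobs = len(labels)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    lmax = 0.0
    for cls in np.unique(labels):
        ind = (labels == cls).astype(float)
        resid = ind - ind.mean()
        lmax = max(lmax, np.abs(Xs.T @ resid).max() / nobs)
    lmax = max(lmax, 1e-8)
    return np.geomspace(lmax, lmax * ratio, n)


def train_sparse(
    features: np.ndarray,
    labels: np.ndarray,
    lambda_path: np.ndarray | None = None,
    seed: int = 0,
    val_frac: float = 0.25,
) -> SparseModel:
    """L1-penalized multinomial logistic fit along a lambda path.

    Summed cross-entropy on an internal validation split forms the
    curve handed to :func:`select_lambda`; the returned model carries
    the sparse weights at the selected lambda.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    labels = np.asarray(labels)
    if lambda_path is None:
        lambda_path = default_lambda_path(features, labels)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(lambda_path <= 0) or np.any(np.diff(lambda_path) >= 0):
        raise ValueError("lambda_path must be positive and strictly decreasing")
    classes = np.unique(labels)

    rng = np.random.default_rng(seed)
    n = len(labels)
    val_idx = np.zeros(n, dtype=bool)
    for cls in classes:  # stratified validation split
        idx = np.flatnonzero(labels == cls)
        take = max(1, int(round(val_frac * len(idx))))
        val_idx[rng.choice(idx, size=take, replace=False)] = True
    scaler = StandardScaler().fit(features[~val_idx])
    Xtr, ytr = scaler.transform(features[~val_idx]), labels[~val_idx]
    Xval, yval = scaler.transform(features[val_idx]), labels[val_idx]

    fits, ce = [], []
    for lam in lambda_path:
        clf = LogisticRegression(
            penalty="l1",
            solver="saga",
            C=1.0 / (lam * len(ytr)),
            max_iter=2000,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, ytr)
        proba = np.clip(clf.predict_proba(Xval), 1e-12, 1.0)
        class_index = {c: i for i, c in enumerate(clf.classes_)}
        rows = np.arange(len(yval))
        cols = np.array([class_index[y] for y in yval])
        ce.append(float(-np.log(proba[rows, cols]).sum()))
        fits.append(clf)
    ce = np.asarray(ce)
    k = select_lambda(ce)
    best = fits[k]
    W = best.coef_
    support = {
        str(cls): np.flatnonzero(W[i]).tolist() for i, cls in enumerate(best.classes_)
    }
    return SparseModel(
        classes=best.classes_,
        scaler=scaler,
        weights=W,
        bias=best.intercept_,
        selected_lambda=float(lambda_path[k]),
        lambda_path=lambda_path,
        ce_curve=ce,
        support=support,
    )


# --------------------------------------------------------------------------
# evaluation


def evaluate(
    model, features: np.ndarray, labels: np.ndarray
) -> dict:
    """Per-class precision/recall/F1, macro F1, accuracy and confusion table."""
    labels = np.asarray(labels)
    unseen = set(labels) - set(model.classes)
    if unseen:
        raise ValueError(f"labels contain classes unseen in training: {sorted(unseen)}")
    pred = model.predict(features)
    prec, rec, f1, supp = precision_recall_fscore_support(
        labels, pred, labels=model.classes, zero_division=0
    )
    conf = confusion_matrix(labels, pred, labels=model.classes)
    per_class = pd.DataFrame(
        {
            "class": model.classes,
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": supp,
        }
    )
    return {
        "accuracy": float(np.mean(pred == labels)),
        "macro_f1": float(f1.mean()),
        "per_class": per_class,
        "confusion": pd.DataFrame(conf, index=model.classes, columns=model.classes),
    }


def empirical_p(observed: np.ndarray, null: np.ndarray) -> float:
    """p = (b + 1) / (m + 1), b = # paired resamples with null > observed."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape:
        raise ValueError("observed and null must be paired (equal length)")
    m = observed.size
    if m < 1:
        raise ValueError("need at least one resample")
    b = int(np.sum(null > observed))
    return (b + 1) / (m + 1)


def rank_effect_size(observed: np.ndarray, null: np.ndarray) -> float:
    """Rank-biserial effect size from the two-sample rank-sum statistic."""
    u = stats.mannwhitneyu(observed, null, alternative="two-sided").statistic
    return float(2.0 * u / (len(observed) * len(null)) - 1.0)


def _stratified_bootstrap(
    labels: np.ndarray, rng: np.random.Generator, stratified: bool = True
) -> np.ndarray:
    n = len(labels)
    if not stratified:
        return rng.integers(0, n, size=n)
    idx = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        idx.append(rng.choice(cls_idx, size=len(cls_idx), replace=True))
    return np.concatenate(idx)


def permutation_null(
    stack: FeatureStack,
    label: str = "domain",
    model: str = "dense",
    n_partitions: int = 10,
    n_bootstraps: int = 100,
    train_frac: float = 0.75,
    seed: int = 0,
    stratified: bool = True,
    transfer_stack: FeatureStack | None = None,
) -> ClassificationReport:
    """Paired true/shuffled-label models over partitions x bootstraps.

    For every subject partition and bootstrap resample of its training
    events, one model is trained on the true labels and one on shuffled
    labels (the shuffle breaks only the label-feature linkage), both
    evaluated on the held-out subjects. The paired accuracy
    distributions give the empirical p and a rank-based effect size.
    When ``transfer_stack`` is given, evaluation uses it (cross-study
    transfer) instead of the holdout.
    """
    m = n_partitions * n_bootstraps
    if m < 1:
        raise ValueError("need >= 1 resample")
    if m < 39:
        warnings.warn(
            f"only m={m} resamples: minimum attainable p is {1/(m+1):.3f}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    trainer = {"dense": train_dense}.get(model)
    if trainer is None:
        raise ValueError(f"unknown model kind {model!r}")

    obs_acc = np.empty(m)
    null_acc = np.empty(m)
    obs_f1 = np.empty(m)
    null_f1 = np.empty(m)
    i = 0
    last_eval = None
    for part in range(n_partitions):
        part_seed = int(rng.integers(2**31))
        train, holdout = subject_partition(stack, train_frac, seed=part_seed)
        test = transfer_stack if transfer_stack is not None else holdout
        y_train = train.meta[label].to_numpy()
        y_test = test.meta[label].to_numpy()
        for _ in range(n_bootstraps):
            boot = _stratified_bootstrap(y_train, rng, stratified)
            Xb, yb = train.features[boot], y_train[boot]
            fit_seed = int(rng.integers(2**31))
            true_model = trainer(Xb, yb, seed=fit_seed)
            ev = evaluate(true_model, test.features, y_test)
            y_shuf = rng.permutation(yb)
            null_model = trainer(Xb, y_shuf, seed=fit_seed)
            ev0 = evaluate(null_model, test.features, y_test)
            obs_acc[i], null_acc[i] = ev["accuracy"], ev0["accuracy"]
            obs_f1[i], null_f1[i] = ev["macro_f1"], ev0["macro_f1"]
            last_eval = ev
            i += 1

    p = empirical_p(obs_acc, null_acc)
    return ClassificationReport(
        observed=obs_acc,
        null=null_acc,
        p=p,
        metric="accuracy",
        per_class=last_eval["per_class"] if last_eval is not None else None,
        confusion=last_eval["confusion"] if last_eval is not None else None,
        effect_size=rank_effect_size(obs_acc, null_acc),
        observed_f1=obs_f1,
        null_f1=null_f1,
        model=model,
        seed=seed,
    )


# --------------------------------------------------------------------------
# stage transfer and load stratification


def stage_transfer(
    stack: FeatureStack,
    label: str = "domain",
    stages: tuple[str, ...] = ("encode", "maintain", "probe"),
    train_frac: float = 0.75,
    seed: int = 0,
) -> dict:
    """Match/mismatch generalization of stage-trained label decoders.

    Trains one decoder per stage (train-subject events of that stage
    only) plus a global decoder on all stages, and evaluates every model
    on the holdout events of every stage. Match is the mean of the
    diagonal (train stage == test stage), mismatch the mean off-diagonal.
    """
    present = [s for s in stages if (stack.meta["stage"] == s).any()]
    if len(present) < 2:
        raise ValueError("need >= 2 stages with events")
    train, holdout = subject_partition(stack, train_frac, seed=seed)

    acc = pd.DataFrame(index=list(present) + ["global"], columns=present, dtype=float)
    for train_stage in present:
        sel = (train.meta["stage"] == train_stage).to_numpy()
        y = train.meta.loc[sel, label].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError(f"stage {train_stage!r} has a single class")
        model = train_dense(train.features[sel], y, seed=seed)
        for test_stage in present:
            tsel = (holdout.meta["stage"] == test_stage).to_numpy()
            ev = evaluate(
                model, holdout.features[tsel], holdout.meta.loc[tsel, label].to_numpy()
            )
            acc.loc[train_stage, test_stage] = ev["accuracy"]
    global_model = train_dense(
        train.features, train.meta[label].to_numpy(), seed=seed
    )
    for test_stage in present:
        tsel = (holdout.meta["stage"] == test_stage).to_numpy()
        ev = evaluate(
            global_model,
            holdout.features[tsel],
            holdout.meta.loc[tsel, label].to_numpy(),
        )
        acc.loc["global", test_stage] = ev["accuracy"]

    diag = np.array([acc.loc[s, s] for s in present], dtype=float)
    off = np.array(
        [acc.loc[a, b] for a in present for b in present if a != b], dtype=float
    )
    return {
        "matrix": acc,
        "match": float(diag.mean()),
        "mismatch": float(off.mean()),
        "global": float(acc.loc["global"].mean()),
    }


def load_stratified_eval(model, stack: FeatureStack, label: str = "domain") -> dict:
    """Accuracy per WM load level, with a rank-based high-vs-low contrast.

    Per-subject accuracies at the lowest and highest load feed a
    two-sample rank-sum test; the effect size is rank-biserial.
    """
    if "load" not in stack.meta.columns:
        raise ValueError("stack metadata lacks a 'load' column")
    loads = sorted(stack.meta["load"].unique())
    rows = []
    per_subject: dict = {}
    for load in loads:
        sel = (stack.meta["load"] == load).to_numpy()
        if not sel.any():
            warnings.warn(f"load level {load} has no events; omitted", stacklevel=2)
            continue
        y = stack.meta.loc[sel, label].to_numpy()
        pred = model.predict(stack.features[sel])
        rows.append(
            {"load": load, "accuracy": float(np.mean(pred == y)), "n": int(sel.sum())}
        )
        subj_acc = (
            pd.DataFrame(
                {"subject": stack.meta.loc[sel, "subject"].to_numpy(), "hit": pred == y}
            )
            .groupby("subject")["hit"]
            .mean()
        )
        per_subject[load] = subj_acc
    table = pd.DataFrame(rows)
    result = {"per_load": table}
    if len(per_subject) >= 2:
        lo, hi = min(per_subject), max(per_subject)
        a, b = per_subject[hi], per_subject[lo]
        test = stats.mannwhitneyu(a, b, alternative="greater")
        result.update(
            high_vs_low_p=float(test.pvalue),
            high_vs_low_effect=float(2.0 * test.statistic / (len(a) * len(b)) - 1.0),
        )
    return result
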