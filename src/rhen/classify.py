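"""Class-balanced RBF-SVM classification with leave-one-out cross-validation.

Error trials are the positive class.  The penalty C is chosen by grid search over
10⁻⁸…10⁸ in multiplicative steps of 10^0.8 (21 values); by default the search is
nested — run on each LOOCV training fold with an inner stratified 5-fold split — so
no information from the held-out trial leaks into model selection.  Features are
standardized with training-fold statistics, and the RBF width follows the scale-aware
default γ = 1 / (n_features · var(X)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .entropy import FeatureTable

__all__ = [
    "C_GRID",
    "EvalResult",
    "balance_classes",
    "confusion_metrics",
    "roc_auc",
    "grid_search_C",
    "loocv_rbf_svm",
    "loocv_with_selection",
]

POS_LABEL = "error"

#: C grid: exponents −8, −7.2, …, 8 — multiplicative step 10^0.8, 21 values.
C_GRID: np.ndarray = 10.0 ** np.arange(-8.0, 8.0 + 1e-9, 0.8)


@dataclass
class EvalResult:
    """Pooled LOOCV performance: accuracy, sensitivity, specificity, AUC."""

    ca: float
    se: float
    sp: float
    auc: float
    confusion: dict  # keys TP, TN, FP, FN
    per_fold_predictions: pd.DataFrame  # index = trial; truth, predicted, score, C
    best_C: float
    seed: int | None = None


def balance_classes(features: FeatureTable, seed: int = 0) -> FeatureTable:
    """Randomly subsample the majority class to the minority count.

    The minority class is untouched; surviving trials keep their original order.
    Emits no warning when already balanced (identity).
    """
    labels = features.labels
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any() or classes.size < 2:
        raise ValueError("both classes must be present with at least one trial")
    n_min = counts.min()
    if (counts == n_min).all():
        return features
    rng = np.random.default_rng(seed)
    keep = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return features.subset_trials(keep)


def confusion_metrics(TP: int, TN: int, FP: int, FN: int) -> tuple[float, float, float]:
    """(CA, SE, SP) from confusion counts, evaluated exactly.

    CA = (TP+TN)/total, SE = TP/(TP+FN), SP = TN/(TN+FP).
    """
    counts = (TP, TN, FP, FN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")
    if TP + FN == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if TN + FP == 0:
        raise ValueError("no negative samples: specificity undefined")
    return ((TP + TN) / total, TP / (TP + FN), TN / (TN + FP))


def roc_auc(scores, y_true, pos_label=POS_LABEL) -> float:
    """Area under the ROC curve via the tie-corrected Mann–Whitney statistic.

    Equals P(score₊ > score₋) + ½·P(tie), computed from midranks.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y_true)
    pos = y == pos_label if y.dtype.kind in "USO" else y.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((x - mu) / sd for x in (train, *others))


def _make_svm(C: float, gamma) -> SVC:
    # max_iter is a guard against rare libsvm stalls at extreme C on unseparable
    # folds; problems this size normally converge in well under 10³ iterations
    return SVC(kernel="rbf", C=C, gamma=gamma, max_iter=50_000)


def grid_search_C(
    X: np.ndarray,
    y: np.ndarray,
    C_grid=C_GRID,
    seed: int = 0,
    n_folds: int = 5,
    gamma="scale",
) -> float:
    """Pick C by stratified k-fold accuracy; ties go to the C closest to 1.

    The neutral tie-break matters: at chance level all C perform alike and picking an
    extreme C degenerates the classifier.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(n_folds, counts.min()))
    if n_folds < 2:
        raise ValueError("grid search needs at least 2 samples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = np.zeros(len(C_grid))
    import warnings

    import sklearn
    from sklearn.exceptions import ConvergenceWarning

    with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr_idx, te_idx in skf.split(X, y):
            Xtr, Xte = _standardize(X[tr_idx], X[te_idx])
            ytr = y[tr_idx]
            for ci, C in enumerate(C_grid):
                clf = _make_svm(C, gamma).fit(Xtr, ytr)
                accs[ci] += np.mean(clf.predict(Xte) == y[te_idx])
    best = np.flatnonzero(accs == accs.max())
    logC = np.abs(np.log10(np.asarray(C_grid, float)[best]))
    return float(np.asarray(C_grid)[best[np.argmin(logC)]])


def loocv_rbf_svm(
    X: np.ndarray,
    y: np.ndarray,
    C_grid=C_GRID,
    seed: int = 0,
    nested: bool = True,
    standardize: bool = True,
    gamma="scale",
    selector=None,
) -> EvalResult:
    """Leave-one-out evaluation of the balanced RBF-SVM.

    Each training fold is re-balanced by dropping one random trial of the class
    opposite the held-out trial: under forced overall balance the fold's class
    composition alone would otherwise reveal the held-out label and bias the
    estimate away from chance on uninformative features.

    Parameters
    ----------
    X : ndarray (trials, features)
    y : array of class labels; ``"error"`` is positive.
    nested : bool
        True (default): grid-search C inside every training fold.  False: one grid
        search on all data first — the optimistic variant some studies use.
    selector : callable, optional
        ``selector(X_train, y_train) -> column indices``; when given, feature
        selection is recomputed inside each training fold and applied to both the
        fold and its held-out trial (prevents selection leakage).

    Raises
    ------
    ValueError
        On unbalanced labels, fewer than 6 trials, or a single-class training fold.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y)
    n = X.shape[0]
    if n < 6:
        raise ValueError("LOOCV needs at least 6 trials")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if counts[0] != counts[1]:
        raise ValueError("labels must be balanced (use balance_classes first)")

    # encode as ±1 (positive = "error" when present); avoids per-fit label overhead
    pos_cls = POS_LABEL if POS_LABEL in classes else classes[1]
    y_enc = np.where(y == pos_cls, 1, -1)
    label_of = {1: pos_cls, -1: classes[classes != pos_cls][0]}

    global_C = None
    if not nested:
        Xg = X if selector is None else X[:, selector(X, y)]
        global_C = grid_search_C(Xg, y_enc, C_grid, seed=seed, gamma=gamma)

    import warnings

    import sklearn
    from sklearn.exceptions import ConvergenceWarning

    records = []
    rng = np.random.default_rng(seed)
    with sklearn.config_context(assume_finite=True), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            # re-balance the training fold: removing trial i leaves its class one
            # short, and that composition imbalance alone reveals the held-out
            # label under the forced overall balance — so drop one random trial of
            # the other class, keeping every training fold exactly balanced
            others = np.flatnonzero(mask & (y_enc != y_enc[i]))
            if others.size:
                mask[rng.choice(others)] = False
            Xtr, ytr = X[mask], y_enc[mask]
            if np.unique(ytr).size < 2:
                raise ValueError("single-class training fold")
            cols = slice(None) if selector is None else selector(Xtr, y[mask])
            Xtr_s, Xte_s = Xtr[:, cols], X[i : i + 1, cols]
            C = global_C if global_C is not None else grid_search_C(
                Xtr_s, ytr, C_grid, seed=seed, gamma=gamma
            )
            if standardize:
                Xtr_s, Xte_s = _standardize(Xtr_s, Xte_s)
            clf = _make_svm(C, gamma).fit(Xtr_s, ytr)
            pred = label_of[int(clf.predict(Xte_s)[0])]
            # signed distance to the hyperplane; classes_ = [-1, 1] so positive
            # scores already point at the positive ("error") class
            score = float(clf.decision_function(Xte_s)[0])
            records.append({"truth": y[i], "predicted": pred, "score": score, "C": C})

    folds = pd.DataFrame(records)
    truth_pos = folds["truth"] == pos_cls
    pred_pos = folds["predicted"] == pos_cls
    TP = int((truth_pos & pred_pos).sum())
    TN = int((~truth_pos & ~pred_pos).sum())
    FP = int((~truth_pos & pred_pos).sum())
    FN = int((truth_pos & ~pred_pos).sum())
    ca, se, sp = confusion_metrics(TP, TN, FP, FN)
    auc = roc_auc(folds["score"].to_numpy(), folds["truth"].to_numpy(), pos_label=pos_cls)
    best_C = float(folds["C"].mode().iloc[0])
    return EvalResult(
        ca=ca, se=se, sp=sp, auc=auc,
        confusion={"TP": TP, "TN": TN, "FP": FP, "FN": FN},
        per_fold_predictions=folds, best_C=best_C, seed=seed,
    )


def loocv_with_selection(
    features: FeatureTable,
    threshold_frac: float = 0.6,
    mode: str = "per-fold",
    **kwargs,
) -> EvalResult:
    """LOOCV with R²-threshold dipole selection, recomputed per fold or once globally.

    ``mode="per-fold"`` (default) reruns the R² ranking inside every training fold;
    ``mode="global"`` selects once on all trials, which leaks the held-out trial into
    selection but mirrors the simpler fixed-selection protocol.
    """
    from .select import r_square_map, select_dipoles

    X, y = features.values, features.labels
    if mode == "per-fold":
        selector = lambda Xtr, ytr: select_dipoles(  # noqa: E731
            r_square_map(Xtr, ytr), threshold_frac
        )
        return loocv_rbf_svm(X, y, selector=selector, **kwargs)
    if mode == "global":
        cols = select_dipoles(r_square_map(X, y), threshold_frac)
        return loocv_rbf_svm(X[:, cols], y, **kwargs)
    raise ValueError(f"unknown selection mode: {mode!r}")
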