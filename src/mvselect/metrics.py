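"""Downstream classification/clustering and selection-quality metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC


@dataclass
class SelectionMetrics:
    """Selection quality versus a known signal set, per view.

    All values are fractions in [0, 1]: TPR (recall of the signal set), FPR
    (fraction of noise features selected), precision, and the F-measure
    2PR/(P+R), defined as 0 when precision or recall is undefined/zero.
    """

    tpr: float
    fpr: float
    precision: float
    f_measure: float

    def as_percent(self) -> dict[str, float]:
        return {
            "tpr": 100 * self.tpr,
            "fpr": 100 * self.fpr,
            "precision": 100 * self.precision,
            "f_measure": 100 * self.f_measure,
        }


def selection_metrics(selected, truth, p: int) -> SelectionMetrics:
    """TPR / FPR / precision / F of a selected index set against the truth.

    ``selected`` and ``truth`` are iterables of 0-based feature indices in
    [0, p).  The truth (signal) set must be nonempty and must not exhaust
    the universe (otherwise FPR is undefined).
    """
    sel = set(int(i) for i in selected)
    tru = set(int(i) for i in truth)
    if not tru:
        raise ValueError("empty truth set")
    universe = set(range(p))
    if not (sel <= universe and tru <= universe):
        raise ValueError("indices out of range [0, p)")
    if len(tru) == p:
        raise ValueError("truth set covers all features; FPR undefined")
    tp = len(sel & tru)
    tpr = tp / len(tru)
    fpr = len(sel - tru) / (p - len(tru))
    precision = tp / len(sel) if sel else 0.0
    f = (
        2 * precision * tpr / (precision + tpr)
        if (precision + tpr) > 0
        else 0.0
    )
    return SelectionMetrics(tpr, fpr, precision, f)


def _median_gamma(Z: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth by the median heuristic: gamma = 1 / (2 m^2)."""
    n = Z.shape[0]
    idx = rng.choice(n, size=min(n, 1000), replace=False) if n > 1000 else np.arange(n)
    d = pairwise_distances(Z[idx])
    m = np.median(d[np.triu_indices_from(d, k=1)])
    if m <= 0:
        return 1.0
    return 1.0 / (2.0 * m * m)


def classify(
    train_Z: np.ndarray,
    train_y: np.ndarray,
    test_Z: np.ndarray,
    test_y: np.ndarray | None = None,
    C: float | None = None,
    gamma: float | str = "cv",
    seed: int = 0,
):
    """SVM classification on latent codes.

    Fits an RBF-kernel maximum-margin classifier on (train_Z, train_y) and
    predicts test labels.  By default C and the kernel bandwidth are chosen
    by an internal 3-fold cross-validated grid search (the latent rows live
    on the unit sphere, where class manifolds can be much finer than the
    global scale, so a fixed bandwidth underfits); ``gamma='median'`` uses
    the median pairwise-distance heuristic instead, and explicit numeric
    ``C``/``gamma`` bypass the search.  Returns the predictions, and when
    ``test_y`` is given also the misclassification error in percent.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if gamma == "cv":
        train_Z = np.asarray(train_Z)
        g0 = _median_gamma(train_Z, rng)
        grid = {
            "C": [1.0, 10.0, 100.0, 1000.0] if C is None else [C],
            # bandwidths from the global scale down to fine class structure
            "gamma": [g0 * f for f in (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)],
        }
        folds = StratifiedKFold(5, shuffle=True, random_state=seed)
        # grid-search cost is superlinear in n; tune on a stratified
        # subsample and refit the winner on everything
        n = len(train_y)
        if n > 1200:
            idx = np.concatenate([
                rng.choice(np.flatnonzero(train_y == c),
                           size=max(2, int(1200 * np.mean(train_y == c))),
                           replace=False)
                for c in np.unique(train_y)
            ])
        else:
            idx = np.arange(n)
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=folds, n_jobs=1)
        search.fit(train_Z[idx], train_y[idx])
        clf = SVC(kernel="rbf", **search.best_params_)
        clf.fit(train_Z, train_y)
    else:
        g = _median_gamma(np.asarray(train_Z), rng) if gamma == "median" else gamma
        clf = SVC(C=1.0 if C is None else C, kernel="rbf", gamma=g)
        clf.fit(train_Z, train_y)
    pred = clf.predict(test_Z)
    if test_y is None:
        return pred
    error = 100.0 * float(np.mean(pred != np.asarray(test_y)))
    return pred, error


def cluster(Z: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means cluster labels on latent codes (or reconstructions)."""
    Z = np.asarray(Z)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > Z.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {Z.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(Z)
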