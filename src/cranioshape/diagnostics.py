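"""Diagnostic classifiers: ROC with optimal cutoff, KNN with K selection,
and hierarchical classification on principal components (HCPC).

These are the three decision tools built on the univariate descriptors: the
ROC stage scores one variable at a time and proposes a cutoff (Youden's J by
default); the KNN stage classifies on the standardized multivariate feature
set with the smallest K reaching the best held-out accuracy; the HCPC stage
clusters PCA scores with Ward linkage, picking the cluster count at the
largest relative inertia drop, to confront unsupervised structure with the
expert diagnosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .stats import pca_with_threshold

log = logging.getLogger(__name__)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    positive_label: object
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")

    @property
    def youden_j(self) -> float:
        return self.sensitivity_at_cutoff + self.specificity_at_cutoff - 1.0


def roc_with_cutoff(values: np.ndarray, labels, positive,
                    flip: str = "auto", criterion: str = "youden") -> ROCResult:
    """ROC curve of one quantitative variable with an optimised cutoff.

    Candidate thresholds are the midpoints of consecutive observed values;
    AUC is the trapezoid area (equal to the tie-corrected Mann-Whitney
    pair-counting statistic).  ``flip='auto'`` re-orients the score when the
    positive class has lower values (AUC < 0.5), recording the flip;
    ``flip='none'`` keeps the raw orientation.  The cutoff maximises Youden's
    J (or the distance to the top-left corner with
    ``criterion='closest-topleft'``), ties resolved toward higher
    specificity.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels) == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if flip not in ("auto", "none"):
        raise ValueError("flip must be 'auto' or 'none'")
    if criterion not in ("youden", "closest-topleft"):
        raise ValueError("unknown cutoff criterion")

    def _auc(score):  # tie-corrected Mann-Whitney probability
        r = pd.Series(score).rank().to_numpy()
        n1, n0 = int(y.sum()), int((~y).sum())
        return (r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    flipped = False
    score = x
    if flip == "auto" and _auc(x) < 0.5:
        score = -x
        flipped = True
    auc = float(_auc(score))
    su = np.unique(score)
    mids = (su[:-1] + su[1:]) / 2.0
    thresholds = np.concatenate([[su[0] - 1.0], mids, [su[-1] + 1.0]])
    pos = score[y]
    neg = score[~y]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    if criterion == "youden":
        crit = sens + spec - 1.0
    else:
        crit = -np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    best = np.flatnonzero(crit >= crit.max() - 1e-12)
    j = best[np.argmax(spec[best])]
    cutoff = thresholds[j]
    if flipped:  # report on the original scale (decision rule: value <= cutoff)
        cutoff = -cutoff
    return ROCResult(thresholds=thresholds if not flipped else -thresholds,
                     sensitivity=sens, specificity=spec, auc=auc,
                     cutoff=float(cutoff),
                     sensitivity_at_cutoff=float(sens[j]),
                     specificity_at_cutoff=float(spec[j]),
                     positive_label=positive, flipped=flipped)


@dataclass
class KNNResult:
    k: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    accuracy: float
    per_class_recall: dict
    confusion: pd.DataFrame
    seed: int
    accuracy_by_k: dict = field(default_factory=dict)


def knn_select_k(features: np.ndarray, labels, train_fraction: float = 0.8,
                 k_grid=None, seed: int = 0) -> KNNResult:
    """Stratified-split KNN with the smallest K reaching the best accuracy.

    Features are z-scored on training statistics; the grid defaults to odd
    K in 1..15 (odd avoids vote ties).  Accuracy is the fraction of correct
    test-set assignments.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if n < 10:
        raise ValueError("need n >= 10")
    if k_grid is None:
        k_grid = list(range(1, 16, 2))
    classes = np.unique(y)
    idx = np.arange(n)
    rng_seed = seed
    for attempt in range(10):
        tr, te = train_test_split(idx, train_size=train_fraction,
                                  stratify=y, random_state=rng_seed)
        if set(classes) <= set(y[tr]):
            break
        warnings.warn("class missing from training split; re-drawing",
                      RuntimeWarning, stacklevel=2)
        rng_seed += 1000003
    else:
        raise RuntimeError("could not build a training split with all classes")
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    acc_by_k = {}
    for k in k_grid:
        if k > len(tr):
            continue
        clf = KNeighborsClassifier(n_neighbors=int(k))
        clf.fit(Xz[tr], y[tr])
        acc_by_k[int(k)] = float((clf.predict(Xz[te]) == y[te]).mean())
    best_acc = max(acc_by_k.values())
    best_k = min(k for k, a in acc_by_k.items() if a >= best_acc - 1e-12)
    clf = KNeighborsClassifier(n_neighbors=best_k).fit(Xz[tr], y[tr])
    pred = clf.predict(Xz[te])
    cm = pd.DataFrame(_sk_confusion(y[te], pred, labels=classes),
                      index=classes, columns=classes)
    recall = {c: float(cm.loc[c, c] / cm.loc[c].sum()) if cm.loc[c].sum() else np.nan
              for c in classes}
    return KNNResult(k=best_k, train_idx=tr, test_idx=te, accuracy=best_acc,
                     per_class_recall=recall, confusion=cm, seed=seed,
                     accuracy_by_k=acc_by_k)


@dataclass
class HCPCResult:
    linkage: np.ndarray
    inertia: dict
    relative_loss: dict
    n_clusters: int
    cluster_labels: np.ndarray
    axis_correlations: pd.DataFrame = None
    confusion: "ConfusionResult" = None


@dataclass
class ConfusionResult:
    counts: pd.DataFrame          # rows: predicted clusters, cols: truth labels
    assignment: dict              # cluster -> best-matched truth label
    per_class_agreement: dict     # truth label -> matched fraction
    overall_agreement: float


def confusion_matrix(predicted, truth) -> ConfusionResult:
    """Cluster-vs-diagnosis contingency with maximum-agreement matching."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if len(p) != len(t):
        raise ValueError("predicted/truth length mismatch")
    counts = pd.crosstab(pd.Series(p, name="predicted"), pd.Series(t, name="truth"))
    # pad to square cost for the assignment
    mat = counts.to_numpy()
    r, c = mat.shape
    size = max(r, c)
    cost = np.zeros((size, size))
    cost[:r, :c] = -mat
    ri, ci = linear_sum_assignment(cost)
    assignment = {}
    for i, j in zip(ri, ci):
        if i < r and j < c:
            assignment[counts.index[i]] = counts.columns[j]
    matched = sum(counts.iloc[i, j] for i, j in zip(ri, ci) if i < r and j < c)
    per_class = {}
    for cls in counts.columns:
        clusters = [k for k, v in assignment.items() if v == cls]
        hit = sum(counts.loc[k, cls] for k in clusters)
        per_class[cls] = float(hit / counts[cls].sum())
    return ConfusionResult(counts=counts, assignment=assignment,
                           per_class_agreement=per_class,
                           overall_agreement=float(matched / len(p)))


def _within_inertia(X: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lv in np.unique(labels):
        m = labels == lv
        tot += ((X[m] - X[m].mean(axis=0)) ** 2).sum()
    return float(tot)


def hcpc(features: np.ndarray, standardize: bool = True, consolidate: bool = False,
         variance_threshold: float = 0.95, min_clusters: int = 3,
         max_clusters: int = 10, truth=None, feature_names=None,
         seed: int = 0) -> HCPCResult:
    """Hierarchical classification on principal components.

    PCA on (optionally standardized) features, Ward clustering of the
    retained scores, and the cluster count q in
    min_clusters..min(max_clusters, n/3) with the highest relative loss of
    inertia, i.e. the q minimising i(q)/i(q-1) where i is within-cluster
    inertia (the convention of the classical HCPC implementations, whose
    automatic search also starts at 3 clusters).  Near-coincident raw data
    degenerate to q = 2 with near-zero inertia loss.  ``consolidate`` runs a
    k-means pass seeded at the cluster centroids.  ``axis_correlations`` are
    the correlations of each input variable with the retained axes (the
    correlation-circle table).
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if n < 6:
        raise ValueError("need n >= 6")
    if not np.isfinite(X).all():
        raise ValueError("missing values in features")
    pca = pca_with_threshold(X, variance_threshold=variance_threshold,
                             standardize=standardize)
    S = pca.retained_scores
    if len(np.unique(S, axis=0)) < 2:
        raise ValueError("fewer distinct points than clusters")
    Z = linkage(S, method="ward")
    if min_clusters < 2:
        raise ValueError("min_clusters must be >= 2")
    q_max = max(min_clusters, min(max_clusters, n // 3))
    inertia = {}
    labels_by_q = {}
    for q in range(1, q_max + 1):
        lab = fcluster(Z, t=q, criterion="maxclust") if q > 1 else np.ones(n, dtype=int)
        labels_by_q[q] = lab
        inertia[q] = _within_inertia(S, lab)
    total = inertia[1]
    # relative inertia ratio i(q)/i(q-1): small = large relative loss at q
    rel_loss = {q: inertia[q] / inertia[q - 1] if inertia[q - 1] > 1e-12 * max(total, 1.0)
                else 1.0 for q in range(2, q_max + 1)}
    raw_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    degenerate = raw_ss < 1e-12 * max(1.0, float((X ** 2).sum()))
    if total <= 1e-12 or degenerate:
        chosen = 2  # near-coincident raw data: no real structure to cut
    else:
        cand = {q: v for q, v in rel_loss.items() if q >= min_clusters}
        best = min(cand.values())
        chosen = min(q for q, v in cand.items() if v <= best * (1 + 1e-12))
    labels = labels_by_q[chosen]
    if consolidate:
        centers = np.stack([S[labels == lv].mean(axis=0) for lv in np.unique(labels)])
        km = KMeans(n_clusters=len(centers), init=centers, n_init=1, random_state=seed)
        labels = km.fit_predict(S) + 1
    if feature_names is None:
        feature_names = [f"var{j}" for j in range(X.shape[1])]
    corr = np.empty((X.shape[1], S.shape[1]))
    for j in range(X.shape[1]):
        for a in range(S.shape[1]):
            sx = X[:, j].std()
            corr[j, a] = (np.corrcoef(X[:, j], S[:, a])[0, 1] if sx > 0 else np.nan)
    axis_corr = pd.DataFrame(corr, index=feature_names,
                             columns=[f"Dim{a + 1}" for a in range(S.shape[1])])
    conf = confusion_matrix(labels, truth) if truth is not None else None
    return HCPCResult(linkage=Z, inertia=inertia, relative_loss=rel_loss,
                      n_clusters=chosen, cluster_labels=labels,
                      axis_correlations=axis_corr, confusion=conf)
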