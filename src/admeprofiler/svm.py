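"""SVM classifier-building pipeline for binary ADME endpoints.

Reproduces the model-building methodology used for the P-gp and CYP
classifiers: descriptor rejection (sparsity, coefficient of variation,
pairwise correlation resolved by F-score), class balancing by Ward
hierarchical clustering with cluster-centre selection, training-set
normalization, RBF-kernel SVM with a multi-step (coarse then refined)
log-spaced grid search maximizing 10-fold cross-validated accuracy, and
external evaluation (accuracy, ROC-AUC, sensitivity, specificity).

A synthetic dataset generator stands in for the external substrate/inhibitor
collections so the pipeline is testable without downloads; it draws two
multivariate-Gaussian classes separated on a subset of informative features
and emits matching binary fingerprints for the clustering step.

The estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``transform``, fitted attributes with a trailing underscore) and compose
with sklearn pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array


class AllRejected(ValueError):
    """Every descriptor was rejected by the filtering rules."""


class TargetTooLarge(ValueError):
    """Requested balanced size exceeds the class size."""


class DegenerateLabels(ValueError):
    """Training labels contain a single class."""


class SchemaMismatch(ValueError):
    """Test-set descriptor layout differs from the training layout."""


@dataclass
class LabelledDataset:
    """Feature matrix, binary labels and optional fingerprints."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    fingerprints: np.ndarray | None = None
    role: str = "training"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes are inconsistent")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.feature_names:
            self.feature_names = [f"d{i}" for i in range(self.X.shape[1])]


# --------------------------------------------------------------------------
# Descriptor filtering
# --------------------------------------------------------------------------

def f_score(x: np.ndarray, y: np.ndarray) -> float:
    """Class-separation F-score of one feature.

    Ratio of the squared deviations of the class means from the overall mean
    to the sum of the within-class variances (the feature-selection F-score
    customary in SVM practice).
    """
    x = np.asarray(x, dtype=float)
    pos, neg = x[y == 1], x[y == 0]
    if pos.size == 0 or neg.size == 0:
        return 0.0
    m, mp, mn = x.mean(), pos.mean(), neg.mean()
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = (pos.var(ddof=1) if pos.size > 1 else 0.0) + (
        neg.var(ddof=1) if neg.size > 1 else 0.0
    )
    if den == 0.0:
        return np.inf if num > 0 else 0.0
    return float(num / den)


class DescriptorFilter(BaseEstimator, TransformerMixin):
    """Reject sparse, near-constant and mutually correlated descriptors.

    A descriptor is rejected when its non-zero fraction is below
    ``min_nonzero_fraction``, or its coefficient of variation (sample SD over
    |mean|; infinite for zero mean with positive SD) is below ``min_cv``.
    Among surviving descriptors correlated above ``max_correlation`` in
    absolute value, the one with the higher class-separation F-score is kept.

    Attributes
    ----------
    support_ : boolean mask over columns
    selected_indices_ : sorted indices of the kept columns
    """

    def __init__(
        self,
        min_nonzero_fraction: float = 0.20,
        min_cv: float = 0.03,
        max_correlation: float = 0.90,
    ):
        self.min_nonzero_fraction = min_nonzero_fraction
        self.min_cv = min_cv
        self.max_correlation = max_correlation

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, p = X.shape
        keep = np.ones(p, dtype=bool)

        nonzero_frac = (X != 0).mean(axis=0)
        keep &= nonzero_frac >= self.min_nonzero_fraction

        sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
        mean = X.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / np.abs(mean), np.where(sd > 0, np.inf, 0.0))
        keep &= cv >= self.min_cv

        surviving = np.flatnonzero(keep)
        if surviving.size == 0:
            raise AllRejected("all descriptors rejected by sparsity/CV rules")

        scores = np.array([f_score(X[:, j], y) for j in surviving])
        # visit by descending F-score; greedily keep a feature unless it
        # correlates too strongly with an already-kept one
        order = surviving[np.lexsort((surviving, -scores))]
        kept: list[int] = []
        for j in order:
            ok = True
            for k in kept:
                xj, xk = X[:, j], X[:, k]
                if xj.std() == 0 or xk.std() == 0:
                    continue
                r = abs(np.corrcoef(xj, xk)[0, 1])
                if r > self.max_correlation:
                    ok = False
                    break
            if ok:
                kept.append(int(j))
        self.selected_indices_ = sorted(kept)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_indices_] = True
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        return X[:, self.support_]


def filter_descriptors(X, y, **kwargs) -> list[int]:
    """Functional wrapper: indices of descriptors surviving the three rules."""
    return DescriptorFilter(**kwargs).fit(X, y).selected_indices_


# --------------------------------------------------------------------------
# Cluster balancing (Ward / reciprocal-nearest-neighbour)
# --------------------------------------------------------------------------

def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Tanimoto distances of binary fingerprint rows."""
    fps = np.asarray(fps, dtype=bool)
    inter = fps.astype(int) @ fps.astype(int).T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(sim, 1.0)
    return 1.0 - sim


def cluster_centres(dist: np.ndarray, target_size: int) -> list[int]:
    """Ward clustering into ``target_size`` clusters; return centre indices.

    scipy's Ward linkage uses the nearest-neighbour-chain (reciprocal
    nearest neighbour) algorithm. The centre of a cluster is the member with
    the smallest sum of dissimilarities to the other members; ties break
    toward the lowest input index.
    """
    n = dist.shape[0]
    if target_size >= n:
        return list(range(n))
    if target_size < 1:
        raise TargetTooLarge("target_size must be >= 1")
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=target_size, criterion="maxclust")
    centres = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        centres.append(int(members[np.argmin(sums)]))  # argmin: first = lowest index
    return sorted(centres)


def cluster_balance(
    ds: LabelledDataset, target_size: int, fingerprints: np.ndarray | None = None
) -> LabelledDataset:
    """Reduce the larger class to ``target_size`` cluster centres.

    Dissimilarity is 1 - Tanimoto on the dataset's binary fingerprints (or
    the explicitly supplied ones). The smaller class is untouched.
    """
    fps = fingerprints if fingerprints is not None else ds.fingerprints
    if fps is None:
        raise ValueError("fingerprints required for cluster balancing")
    fps = np.asarray(fps)
    n1 = int((ds.y == 1).sum())
    n0 = int((ds.y == 0).sum())
    large = 1 if n1 >= n0 else 0
    large_idx = np.flatnonzero(ds.y == large)
    if target_size > large_idx.size:
        raise TargetTooLarge(
            f"target_size {target_size} exceeds larger-class size {large_idx.size}"
        )
    dist = tanimoto_distance_matrix(fps[large_idx])
    centres = cluster_centres(dist, target_size)
    keep = np.concatenate([np.flatnonzero(ds.y != large), large_idx[centres]])
    keep.sort()
    return LabelledDataset(
        X=ds.X[keep],
        y=ds.y[keep],
        feature_names=list(ds.feature_names),
        fingerprints=fps[keep],
        role=ds.role,
    )


# --------------------------------------------------------------------------
# RBF-SVM with multi-step grid search
# --------------------------------------------------------------------------

def _log2_grid(lo: int, hi: int, step: int) -> list[float]:
    return [2.0 ** e for e in range(lo, hi + 1, step)]


class RBFGridSearchSVM(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM tuned by coarse-then-refined log2 grid search.

    ``fit`` normalizes features to zero mean / unit variance (parameters
    stored from the training set and reused verbatim on any test data),
    scans (C, gamma) over a coarse log2 grid maximizing mean 10-fold
    stratified cross-validated accuracy, refines around the winner at half
    the log step, and refits on the full training set. Ties prefer smaller C
    then smaller gamma (the simpler model).

    Attributes
    ----------
    best_C_, best_gamma_ : winning hyper-parameters
    acc_cv_, auc_cv_ : cross-validated accuracy and ROC-AUC at the winner
    mean_, scale_ : training normalization parameters
    """

    def __init__(
        self,
        C_exp_range: tuple[int, int] = (-5, 15),
        gamma_exp_range: tuple[int, int] = (-15, 3),
        coarse_step: int = 2,
        folds: int = 10,
        random_state: int = 0,
    ):
        self.C_exp_range = C_exp_range
        self.gamma_exp_range = gamma_exp_range
        self.coarse_step = coarse_step
        self.folds = folds
        self.random_state = random_state

    def _cv_scores(self, X, y, C, gamma, cv) -> tuple[float, float]:
        accs, decisions, truths = [], [], []
        for train, test in cv.split(X, y):
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            accs.append(float((pred == y[test]).mean()))
            decisions.append(clf.decision_function(X[test]))
            truths.append(y[test])
        acc = float(np.mean(accs))
        dec = np.concatenate(decisions)
        truth = np.concatenate(truths)
        auc = float(roc_auc_score(truth, dec)) if len(set(truth)) == 2 else float("nan")
        return acc, auc

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateLabels("training labels contain a single class")
        self.classes_ = classes
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Xs = (X - self.mean_) / self.scale_

        folds = min(self.folds, int(np.bincount(y).min()))
        folds = max(folds, 2)
        cv = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=self.random_state
        )

        def search(pairs):
            best = None
            for C, gamma in pairs:
                acc, auc = self._cv_scores(Xs, y, C, gamma, cv)
                key = (acc, -C, -gamma)  # ties -> smaller C, then smaller gamma
                if best is None or key > best[0]:
                    best = (key, C, gamma, acc, auc)
            return best

        coarse = [
            (C, g)
            for C in _log2_grid(*self.C_exp_range, self.coarse_step)
            for g in _log2_grid(*self.gamma_exp_range, self.coarse_step)
        ]
        _, C0, g0, _, _ = search(coarse)
        half = 2.0 ** (self.coarse_step / 2.0)
        refined = [
            (C0 * cf, g0 * gf)
            for cf in (1 / half, 1.0, half)
            for gf in (1 / half, 1.0, half)
        ]
        _, C1, g1, acc, auc = search(refined)

        self.best_C_, self.best_gamma_ = float(C1), float(g1)
        self.acc_cv_, self.auc_cv_ = acc, auc
        self.svc_ = SVC(C=self.best_C_, gamma=self.best_gamma_, kernel="rbf")
        self.svc_.fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _scale(self, X):
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise SchemaMismatch(
                f"{X.shape[1]} features, model trained with {self.n_features_in_}"
            )
        return (X - self.mean_) / self.scale_

    def predict(self, X):
        dec = self.decision_function(X)
        return self.classes_[(dec > 0).astype(int)]

    def decision_function(self, X):
        Xs = self._scale(X)
        if getattr(self, "svc_", None) is not None:
            return self.svc_.decision_function(Xs)
        # model restored from JSON: evaluate the kernel expansion directly
        sv = self._support_vectors
        d2 = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.best_gamma_ * d2)
        return K @ self._dual_coef.ravel() + self._intercept

    def save(self, path) -> None:
        """Persist the fitted model as a JSON artifact."""
        check_is_fitted(self, "svc_")
        obj = {
            "C": self.best_C_,
            "gamma": self.best_gamma_,
            "acc_cv": self.acc_cv_,
            "auc_cv": self.auc_cv_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "classes": self.classes_.tolist(),
            "support_vectors": self.svc_.support_vectors_.tolist(),
            "dual_coef": self.svc_.dual_coef_.tolist(),
            "intercept": self.svc_.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path) -> "RBFGridSearchSVM":
        obj = json.loads(Path(path).read_text())
        model = cls()
        model.best_C_ = float(obj["C"])
        model.best_gamma_ = float(obj["gamma"])
        model.acc_cv_ = float(obj["acc_cv"])
        model.auc_cv_ = float(obj["auc_cv"])
        model.mean_ = np.asarray(obj["mean"])
        model.scale_ = np.asarray(obj["scale"])
        model.classes_ = np.asarray(obj["classes"])
        sv = np.asarray(obj["support_vectors"])
        model.n_features_in_ = sv.shape[1]
        model.svc_ = None
        model._support_vectors = sv
        model._dual_coef = np.asarray(obj["dual_coef"])
        model._intercept = float(np.asarray(obj["intercept"]).ravel()[0])
        return model


def grid_search_train(
    ds: LabelledDataset, folds: int = 10, seed: int = 0, **grid_kwargs
) -> RBFGridSearchSVM:
    """Train an RBF SVM on a labelled dataset with grid-searched (C, gamma)."""
    return RBFGridSearchSVM(folds=folds, random_state=seed, **grid_kwargs).fit(
        ds.X, ds.y
    )


def evaluate_external(model: RBFGridSearchSVM, test: LabelledDataset) -> dict[str, float]:
    """External-set statistics: ACC, AUC, sensitivity, specificity.

    The test matrix is normalized with the *training* parameters inside the
    model; a differing descriptor layout raises :class:`SchemaMismatch`.
    """
    if test.X.shape[1] != model.n_features_in_:
        raise SchemaMismatch(
            f"test set has {test.X.shape[1]} descriptors, "
            f"model expects {model.n_features_in_}"
        )
    pred = model.predict(test.X)
    dec = model.decision_function(test.X)
    y = test.y
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(y, dec)) if len(set(y)) == 2 else float("nan")
    return {
        "acc_ext": (tp + tn) / y.size,
        "auc_ext": auc,
        "sensitivity": sens,
        "specificity": spec,
    }


# --------------------------------------------------------------------------
# Synthetic dataset generator
# --------------------------------------------------------------------------

def synthesize_dataset(
    n_pos: int,
    n_neg: int,
    n_features: int = 50,
    effect_size: float = 1.0,
    n_informative: int = 10,
    seed: int = 0,
    role: str = "training",
) -> LabelledDataset:
    """Two-class Gaussian dataset with matching binary fingerprints.

    The two classes are unit-variance multivariate Gaussians whose means
    differ by ``effect_size`` standard deviations on the first
    ``n_informative`` features; the remaining features are pure noise.
    Fingerprints are 1024-bit vectors drawn from class-specific prototype
    bit patterns with 10% flip noise, so fingerprint similarity carries
    class structure for the clustering step. Fully reproducible from
    ``seed``.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    rng = np.random.default_rng(seed)
    n_informative = min(n_informative, n_features)
    shift = np.zeros(n_features)
    shift[:n_informative] = effect_size
    X_pos = rng.standard_normal((n_pos, n_features)) + shift
    X_neg = rng.standard_normal((n_neg, n_features))
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])

    proto_pos = rng.random(1024) < 0.15
    proto_neg = rng.random(1024) < 0.15
    fps = np.empty((n_pos + n_neg, 1024), dtype=bool)
    for i in range(n_pos + n_neg):
        proto = proto_pos if y[i] == 1 else proto_neg
        flips = rng.random(1024) < 0.10
        fps[i] = proto ^ flips

    perm = rng.permutation(n_pos + n_neg)
    return LabelledDataset(
        X=X[perm],
        y=y[perm],
        feature_names=[f"d{i}" for i in range(n_features)],
        fingerprints=fps[perm],
        role=role,
    )
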