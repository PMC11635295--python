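"""MCS-vs-UWS discrimination: feature assembly, KNN / LDA, LOOCV.

Feature vectors combine graph-metric AUCs (Eg, Eloc, Lp, Cp) and ROI mean
correlations (R_PFC ... L_OC); six named feature sets pair graph-theory,
correlation and hybrid variants at two granularities.  Classification is
leave-one-out: for each held-out subject the model (and the z-score
standardisation) is fit on the remaining n-1 subjects only.  MCS is the
positive class.

Both classifiers are deliberately small, fully deterministic
implementations: KNN (k = 3, Euclidean) with documented distance- and
vote-tie rules, and the two-class Gaussian equal-covariance discriminant
with empirical priors and an optional ridge fallback for singular pooled
covariance.  The repeat loop exists because repeated computation runs are
part of the evaluation protocol; with deterministic tie rules all repeats
coincide and the mean equals a single run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_SETS",
    "FeatureSetSpec",
    "ClassifierSpec",
    "ClassResult",
    "build_features",
    "knn_predict",
    "lda_fit_predict",
    "loocv",
    "confusion_metrics",
    "classification_report",
]

GRAPH_FEATURES = ("Eg", "Eloc", "Lp", "Cp")
ROI_FEATURES = ("R_PFC", "L_PFC", "R_MC", "L_MC", "R_OC", "L_OC")
POSITIVE_CLASS = "MCS"
NEGATIVE_CLASS = "UWS"


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("feature set must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"feature set {self.name!r} lists a member twice")
        bad = set(self.members) - set(GRAPH_FEATURES) - set(ROI_FEATURES)
        if bad:
            raise ValueError(f"unknown feature members: {sorted(bad)}")


#: The six reference feature sets: all four graph AUCs, all six ROI means,
#: their union, the two discriminative graph AUCs (Eg, Lp), the single
#: discriminative ROI (L_OC), and the discriminative hybrid.
FEATURE_SETS: dict[str, FeatureSetSpec] = {
    s.name: s
    for s in (
        FeatureSetSpec("graph4", GRAPH_FEATURES),
        FeatureSetSpec("roi6", ROI_FEATURES),
        FeatureSetSpec("graph4+roi6", GRAPH_FEATURES + ROI_FEATURES),
        FeatureSetSpec("graph2", ("Eg", "Lp")),
        FeatureSetSpec("roi1", ("L_OC",)),
        FeatureSetSpec("graph2+roi1", ("Eg", "Lp", "L_OC")),
    )
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "knn"  # "knn" or "lda"
    k: int = 3
    n_repeats: int = 20
    ridge: float | None = None  # LDA covariance regularisation (None = strict)

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "lda"):
            raise ValueError("classifier kind must be 'knn' or 'lda'")
        if self.kind == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("k must be odd and >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def build_features(table: pd.DataFrame, spec: FeatureSetSpec) -> np.ndarray:
    """Subjects x members numeric matrix in the spec's column order."""
    for m in spec.members:
        if m not in table.columns:
            raise KeyError(f"feature {m!r} missing from the feature table")
    x = table.loc[:, list(spec.members)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        rows, cols = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(
            f"missing value for subject {table.index[rows]!r}, "
            f"feature {spec.members[cols]!r}"
        )
    return x


def knn_predict(
    x_train: np.ndarray, y_train: np.ndarray, x: np.ndarray, k: int = 3
) -> str:
    """Majority label among the k Euclidean-nearest training rows.

    Tie rules (deterministic): equidistant rows are ordered by training
    index (lower first); a tied vote falls back to the single nearest
    neighbour's label.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if k > len(x_train):
        raise ValueError(f"k = {k} exceeds training-set size {len(x_train)}")
    d = np.sqrt(((x_train - np.asarray(x, dtype=float)) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(d)), d))  # distance, then index
    nearest = order[:k]
    votes: dict = {}
    for i in nearest:
        votes[y_train[i]] = votes.get(y_train[i], 0) + 1
    best = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    return y_train[order[0]]  # vote tie: nearest single neighbour decides


def lda_fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x: np.ndarray,
    ridge: float | None = None,
) -> str:
    """Two-class Gaussian equal-covariance discriminant assignment.

    Pooled within-class covariance with empirical class priors; a singular
    covariance raises unless ``ridge`` adds lam * mean(diag) * I.  A test
    point on the exact decision boundary goes to the class with the larger
    prior, then to the lexicographically smaller label.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    x = np.asarray(x, dtype=float)
    classes = sorted(set(y_train.tolist()))
    if len(classes) != 2:
        raise ValueError("LDA here is two-class; got classes " + repr(classes))
    n, p = x_train.shape
    means, priors, resid = {}, {}, []
    for c in classes:
        xc = x_train[y_train == c]
        means[c] = xc.mean(axis=0)
        priors[c] = len(xc) / n
        resid.append(xc - means[c])
    cov = np.vstack(resid).T @ np.vstack(resid) / max(n - 2, 1)
    if ridge is not None:
        cov = cov + ridge * max(np.trace(cov) / p, np.finfo(float).tiny) * np.eye(p)
    # strictness: refuse silently ill-conditioned systems without the fallback
    if np.linalg.cond(cov) > 1e12:
        if ridge is None:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular; pass ridge=1e-6 "
                "(or larger) to regularise"
            )
        cov = cov + 1e-6 * max(np.trace(cov) / p, 1.0) * np.eye(p)
    cov_inv = np.linalg.inv(cov)
    scores = {
        c: float(
            x @ cov_inv @ means[c]
            - 0.5 * means[c] @ cov_inv @ means[c]
            + np.log(priors[c])
        )
        for c in classes
    }
    c0, c1 = classes
    if scores[c0] > scores[c1]:
        return c0
    if scores[c1] > scores[c0]:
        return c1
    if priors[c0] != priors[c1]:  # boundary tie: larger prior wins
        return c0 if priors[c0] > priors[c1] else c1
    return c0  # equal priors: lexicographically smaller label


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


@dataclass
class ClassResult:
    """Confusion counts and derived rates, per repeat and averaged."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    per_repeat: list[dict] = field(default_factory=list)
    predictions: list = field(default_factory=list)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    MCS is the positive class.  Sensitivity is nan when there are no
    positives, specificity nan when there are no negatives.
    """
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return acc, sens, spec


def _predict_one(clf: ClassifierSpec, x_tr, y_tr, x):
    if clf.kind == "knn":
        return knn_predict(x_tr, y_tr, x, k=clf.k)
    return lda_fit_predict(x_tr, y_tr, x, ridge=clf.ridge)


def loocv(
    features: np.ndarray,
    labels,
    clf: ClassifierSpec,
    positive: str = POSITIVE_CLASS,
) -> ClassResult:
    """Leave-one-out cross-validation with fold-wise standardisation.

    Every subject is predicted by a model trained on the remaining n-1;
    z-score parameters are refit inside each fold and applied to the
    held-out row, so no information leaks from the held-out subject.  The
    protocol is repeated ``clf.n_repeats`` times and averaged; with the
    deterministic tie rules every repeat is identical.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("LOOCV needs two classes with >= 2 subjects each")
    if clf.kind == "knn" and clf.k > len(y) - 1:
        raise ValueError("k exceeds the training-fold size")

    per_repeat = []
    preds_final = None
    for _ in range(clf.n_repeats):
        preds = []
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            mu, sd = _standardize_fit(x[mask])
            preds.append(
                _predict_one(clf, (x[mask] - mu) / sd, y[mask], (x[i] - mu) / sd)
            )
        preds = np.asarray(preds)
        tp = int(np.sum((preds == positive) & (y == positive)))
        fn = int(np.sum((preds != positive) & (y == positive)))
        tn = int(np.sum((preds != positive) & (y != positive)))
        fp = int(np.sum((preds == positive) & (y != positive)))
        acc, sens, spec = confusion_metrics(tp, fn, tn, fp)
        per_repeat.append(
            {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
             "accuracy": acc, "sensitivity": sens, "specificity": spec}
        )
        preds_final = preds
    if all(r == per_repeat[0] for r in per_repeat):  # deterministic: mean == single run
        mean = {k: float(per_repeat[0][k])
                for k in ("accuracy", "sensitivity", "specificity")}
    else:
        mean = {k: float(np.mean([r[k] for r in per_repeat]))
                for k in ("accuracy", "sensitivity", "specificity")}
    last = per_repeat[-1]
    return ClassResult(
        tp=last["tp"], fn=last["fn"], tn=last["tn"], fp=last["fp"],
        accuracy=mean["accuracy"], sensitivity=mean["sensitivity"],
        specificity=mean["specificity"], per_repeat=per_repeat,
        predictions=list(preds_final),
    )


def classification_report(
    feature_table: pd.DataFrame,
    labels,
    feature_sets: dict[str, FeatureSetSpec] | None = None,
    k: int = 3,
    n_repeats: int = 20,
    ridge: float | None = None,
) -> pd.DataFrame:
    """Feature set x classifier table of accuracy/sensitivity/specificity."""
    feature_sets = feature_sets or FEATURE_SETS
    rows = []
    for name, spec in feature_sets.items():
        x = build_features(feature_table, spec)
        for kind in ("knn", "lda"):
            clf = ClassifierSpec(kind=kind, k=k, n_repeats=n_repeats, ridge=ridge)
            res = loocv(x, labels, clf)
            rows.append(
                {"feature_set": name, "classifier": kind.upper(),
                 "accuracy": res.accuracy, "sensitivity": res.sensitivity,
                 "specificity": res.specificity}
            )
    return pd.DataFrame(rows)
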