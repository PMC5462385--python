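"""Baseline prediction of fast- versus slow-declining trajectory membership.

Evaluation harness for the central two-class contrast (the two trajectories
with similar baseline MMSE but different rates of decline): a stratified
80:20 train/test split, down-sampling of the training majority class to
balance it, recursive feature elimination (RFE) under repeated stratified
cross-validation with a pluggable classifier, and confusion-matrix metrics
on the untouched test set — accuracy with an exact (Clopper–Pearson)
binomial interval, sensitivity, specificity, and rank-based AUC from the
classifier's decision scores.

The classifier contract is deliberately small (``fit`` / ``predict`` /
``decision_scores`` / ``rank_features``); the default is an RBF-kernel
support vector machine with a small tuning grid, with feature ranking by
univariate discrimination (distance of the per-feature AUC from 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMetrics",
    "RfeResult",
    "FeatureEncoder",
    "SvmClassifier",
    "split_and_balance",
    "rfe",
    "confusion_metrics",
    "run_prediction",
]


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMetrics:
    """2x2 predicted-vs-true counts and derived performance measures."""

    counts: pd.DataFrame  # rows: predicted, columns: true
    positive_class: object
    accuracy: float
    accuracy_ci: tuple
    sensitivity: float
    specificity: float
    auc: float | None


def _clopper_pearson(successes: int, total: int, alpha: float = 0.05) -> tuple:
    lo = (
        0.0
        if successes == 0
        else stats.beta.ppf(alpha / 2, successes, total - successes + 1)
    )
    hi = (
        1.0
        if successes == total
        else stats.beta.ppf(1 - alpha / 2, successes + 1, total - successes)
    )
    return float(lo), float(hi)


def _rank_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability that a positive outscores a negative."""
    pos = scores[is_positive]
    neg = scores[~is_positive]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def confusion_metrics(
    predicted,
    true,
    positive_class,
    scores=None,
    alpha: float = 0.05,
) -> ConfusionMetrics:
    """Binary confusion-matrix metrics with an exact accuracy interval.

    ``scores`` (higher = more positive-class-like) enable the rank-based
    AUC; without them AUC is absent rather than approximated from hard
    labels.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if len(predicted) == 0:
        raise ValueError("empty predictions")
    if len(predicted) != len(true):
        raise ValueError("predicted and true labels differ in length")
    pos = positive_class
    tp = int(((predicted == pos) & (true == pos)).sum())
    fp = int(((predicted == pos) & (true != pos)).sum())
    fn = int(((predicted != pos) & (true == pos)).sum())
    tn = int(((predicted != pos) & (true != pos)).sum())
    total = tp + fp + fn + tn
    counts = pd.DataFrame(
        [[tp, fp], [fn, tn]],
        index=pd.Index([f"{pos}", f"not {pos}"], name="predicted"),
        columns=pd.Index([f"{pos}", f"not {pos}"], name="true"),
    )
    auc = None
    if scores is not None:
        auc = _rank_auc(np.asarray(scores, dtype=float), true == pos)
    return ConfusionMetrics(
        counts=counts,
        positive_class=pos,
        accuracy=(tp + tn) / total,
        accuracy_ci=_clopper_pearson(tp + tn, total, alpha),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# Split, balance, encode
# ---------------------------------------------------------------------------


def split_and_balance(
    features: pd.DataFrame,
    labels: pd.Series,
    ratio: float = 0.8,
    seed: int | None = 0,
):
    """Stratified train/test split with a class-balanced training set.

    The training majority class is down-sampled (seeded) to the minority
    count; the test set keeps its natural imbalance. Classes with fewer
    than 5 members cannot be split meaningfully and raise.
    """
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"classes with < 5 members cannot be split: {small}")
    idx_train, idx_test = train_test_split(
        features.index.to_numpy(),
        train_size=ratio,
        stratify=labels.to_numpy(),
        random_state=np.random.RandomState(seed),
        shuffle=True,
    )
    y_train = labels.loc[idx_train]
    rng = np.random.default_rng(seed)
    n_min = y_train.value_counts().min()
    keep = []
    for cls, g in y_train.groupby(y_train):
        members = g.index.to_numpy()
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.append(members)
    idx_bal = np.concatenate(keep)
    return (
        features.loc[idx_bal],
        labels.loc[idx_bal],
        features.loc[idx_test],
        labels.loc[idx_test],
    )


class FeatureEncoder:
    """Numeric design for classification, with training-set-only statistics.

    Categorical variables expand to one indicator per non-reference level
    (HoNOS items use 'None' as reference); continuous variables are centered
    and scaled by training mean/SD; near-zero-variance columns (frequency
    ratio above ``freq_ratio`` and unique-value fraction below
    ``unique_frac``, the standard filter definition) are dropped.
    """

    def __init__(self, freq_ratio: float = 95 / 5, unique_frac: float = 0.10):
        self.freq_ratio = freq_ratio
        self.unique_frac = unique_frac
        self.columns_: list[str] | None = None
        self.center_: pd.Series | None = None
        self.scale_: pd.Series | None = None
        self.continuous_: list[str] = []

    def _expand(self, profiles: pd.DataFrame) -> pd.DataFrame:
        from .characterize import build_design

        variables = [c for c in profiles.columns if c != "baseline_date"]
        X, _ = build_design(profiles, variables)
        return X

    def fit(self, profiles: pd.DataFrame) -> "FeatureEncoder":
        X = self._expand(profiles)
        keep = []
        for c in X.columns:
            col = X[c]
            vals, cnts = np.unique(col.to_numpy(), return_counts=True)
            if len(vals) < 2:
                continue  # zero variance
            cnts = np.sort(cnts)[::-1]
            fr = cnts[0] / cnts[1]
            uf = len(vals) / len(col)
            if fr > self.freq_ratio and uf < self.unique_frac:
                continue  # near-zero variance
            keep.append(c)
        self.columns_ = keep
        Xk = X[keep]
        self.continuous_ = [
            c for c in keep if Xk[c].nunique() > 2
        ]
        self.center_ = Xk[self.continuous_].mean()
        self.scale_ = Xk[self.continuous_].std(ddof=0).replace(0.0, 1.0)
        return self

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("encoder not fitted")
        X = self._expand(profiles)
        for c in self.columns_:
            if c not in X.columns:
                X[c] = 0.0
        X = X[self.columns_].copy()
        X[self.continuous_] = (X[self.continuous_] - self.center_) / self.scale_
        return X

    def fit_transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        return self.fit(profiles).transform(profiles)


# ---------------------------------------------------------------------------
# Pluggable classifier and RFE
# ---------------------------------------------------------------------------


class SvmClassifier:
    """RBF-kernel SVM satisfying the fit/predict/score/rank contract.

    ``gamma`` follows the data-driven scale heuristic unless a grid is
    supplied; a small cost grid is tuned by internal cross-validation.
    Feature ranking is univariate: distance of each feature's single-feature
    AUC from 0.5 on the training data.
    """

    def __init__(self, c_grid=(0.25, 0.5, 1.0, 2.0, 4.0), gamma="scale",
                 tune_folds: int = 5, seed: int = 0):
        self.c_grid = c_grid
        self.gamma = gamma
        self.tune_folds = tune_folds
        self.seed = seed
        self.model_: SVC | None = None
        self.classes_: np.ndarray | None = None

    def _make(self, C):
        return SVC(C=C, kernel="rbf", gamma=self.gamma)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SvmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        best = None
        if len(self.c_grid) > 1:
            skf = StratifiedKFold(
                n_splits=self.tune_folds, shuffle=True, random_state=self.seed
            )
            for C in self.c_grid:
                accs = []
                for tr, va in skf.split(X, y):
                    m = self._make(C).fit(X[tr], y[tr])
                    accs.append((m.predict(X[va]) == y[va]).mean())
                score = float(np.mean(accs))
                if best is None or score > best[0]:
                    best = (score, C)
            C = best[1]
        else:
            C = self.c_grid[0]
        self.model_ = self._make(C).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=float))

    def decision_scores(self, X) -> np.ndarray:
        """Signed distance to the margin; positive favours ``classes_[1]``."""
        return self.model_.decision_function(np.asarray(X, dtype=float))

    def rank_features(self, X, y) -> np.ndarray:
        """Feature indices from most to least discriminative (univariate AUC)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pos = y == np.unique(y)[-1]
        strength = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            strength[j] = abs(_rank_auc(X[:, j], pos) - 0.5)
        return np.argsort(-strength, kind="stable")


@dataclass
class RfeResult:
    """Outcome of recursive feature elimination under repeated CV."""

    candidates: list
    selected: list
    subset_sizes: list
    cv_accuracy: list  # mean CV accuracy per subset size
    folds: int
    repeats: int
    seed: int
    profile: pd.DataFrame = field(default=None)


def rfe(
    X: pd.DataFrame,
    y: pd.Series,
    classifier_factory=SvmClassifier,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    subset_sizes=None,
) -> RfeResult:
    """Recursive feature elimination with repeated stratified k-fold CV.

    Within each resample, features are ranked on the analysis fold and the
    classifier is scored on the assessment fold at each subset size. The
    size with the best mean CV accuracy wins; the final feature ranking on
    the full data defines the selected subset of that size.
    """
    if folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    Xa = X.to_numpy(dtype=float)
    ya = y.loc[X.index].to_numpy()
    p = Xa.shape[1]
    if subset_sizes is None:
        subset_sizes = sorted(set(list(range(1, min(p, 8) + 1)) + [p]))
    subset_sizes = [s for s in subset_sizes if 1 <= s <= p]

    acc = np.zeros((repeats * folds, len(subset_sizes)))
    row = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, va in skf.split(Xa, ya):
            clf_rank = classifier_factory(seed=seed)
            ranking = clf_rank.rank_features(Xa[tr], ya[tr])
            for si, size in enumerate(subset_sizes):
                keep = ranking[:size]
                m = classifier_factory(seed=seed).fit(Xa[tr][:, keep], ya[tr])
                acc[row, si] = (m.predict(Xa[va][:, keep]) == ya[va]).mean()
            row += 1
    mean_acc = acc.mean(axis=0)
    best_size = subset_sizes[int(np.argmax(mean_acc))]
    final_ranking = classifier_factory(seed=seed).rank_features(Xa, ya)
    selected = [X.columns[i] for i in final_ranking[:best_size]]
    profile = pd.DataFrame({"subset_size": subset_sizes, "cv_accuracy": mean_acc})
    logger.info("RFE selected %d/%d features: %s", best_size, p, selected)
    return RfeResult(
        candidates=list(X.columns),
        selected=selected,
        subset_sizes=list(subset_sizes),
        cv_accuracy=list(mean_acc),
        folds=folds,
        repeats=repeats,
        seed=seed,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


def run_prediction(
    profiles: pd.DataFrame,
    assignments: pd.Series,
    class_pair: tuple = (3, 4),
    positive_class=4,
    ratio: float = 0.8,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    classifier_factory=SvmClassifier,
) -> dict:
    """Full harness: subset to the class pair, split, balance, RFE, evaluate.

    Returns a dict with the encoder, RFE result, fitted classifier,
    test-set predictions and :class:`ConfusionMetrics`.
    """
    mask = assignments.isin(class_pair)
    sub = profiles.loc[profiles.index.intersection(assignments.index[mask])]
    y = assignments.loc[sub.index]
    feats = sub.drop(columns=[c for c in ("baseline_date",) if c in sub.columns])

    tr_profiles, y_train, te_profiles, y_test = split_and_balance(
        feats, y, ratio=ratio, seed=seed
    )
    enc = FeatureEncoder().fit(tr_profiles)
    X_train = enc.transform(tr_profiles)
    X_test = enc.transform(te_profiles)

    rfe_result = rfe(
        X_train, y_train, classifier_factory=classifier_factory,
        folds=folds, repeats=repeats, seed=seed,
    )
    clf = classifier_factory(seed=seed).fit(
        X_train[rfe_result.selected].to_numpy(), y_train.to_numpy()
    )
    pred = clf.predict(X_test[rfe_result.selected].to_numpy())
    dec = clf.decision_scores(X_test[rfe_result.selected].to_numpy())
    # orient decision scores so larger = more positive-class-like
    if clf.classes_ is not None and positive_class == clf.classes_[0]:
        dec = -dec
    metrics = confusion_metrics(pred, y_test.to_numpy(), positive_class, scores=dec)
    return {
        "encoder": enc,
        "rfe": rfe_result,
        "classifier": clf,
        "y_test": y_test,
        "predictions": pd.Series(pred, index=y_test.index, name="predicted"),
        "decision_scores": pd.Series(dec, index=y_test.index, name="score"),
        "metrics": metrics,
    }
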