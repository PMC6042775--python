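"""Authorship verification by unmasking.

Unmasking asks how *deep* the difference between two sets of text
segments is.  A linear SVM separating the two sets is evaluated by
cross-validation; the most discriminative features (the k largest
positive and k largest negative weights) are then removed, and the
process repeats for f iterations.  Two works by the same author differ
mainly in a handful of superficial features (themes, characters), so
accuracy collapses quickly once those features are gone; works by
different authors stay separable, giving a flat degradation curve.  A
meta-classifier trained on labeled curves (accuracies plus polynomial
and lagged-difference features) then decides whether a questioned work
matches a candidate author, with a Platt-calibrated probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import accuracy_score, balanced_accuracy_score, cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .lexicon import variable_columns

__all__ = [
    "UnmaskingConfig",
    "DegradationCurve",
    "AttributionResult",
    "degradation_curve",
    "build_training_curves",
    "train_meta_learner",
    "attribute_work",
    "evaluate",
    "holdout_benchmark",
]

SAME, DIFFERENT = "same_author", "different_author"


@dataclass
class UnmaskingConfig:
    """Knobs of the unmasking procedure.

    f: elimination iterations (one accuracy per iteration); k: features
    removed per sign per iteration (2k total); cv_folds: stratified CV
    folds for each accuracy estimate; n_randomized_iterations: how many
    reseeded repetitions verdict probabilities are averaged over.
    """

    f: int = 10
    k: int = 2
    cv_folds: int = 5
    n_randomized_iterations: int = 20
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 2:
            raise ValueError("f must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def validate_features(self, n_features: int) -> None:
        if 2 * self.k * self.f > n_features:
            raise ValueError(
                f"2*k*f = {2 * self.k * self.f} exceeds the {n_features} "
                "available features"
            )


@dataclass
class DegradationCurve:
    """One comparison's prediction-degradation curve and derived features."""

    accuracies: np.ndarray  # length f, in [0, 1]
    linear_beta: float  # slope of the degree-1 LS fit to (iteration, accuracy)
    quad_betas: tuple[float, float]  # (quadratic, linear) coefs of the degree-2 fit
    deltas_lag1: np.ndarray  # accuracy(i) - accuracy(i+1)
    deltas_lag2: np.ndarray  # accuracy(i) - accuracy(i+2)
    label: str = "unknown"
    removed_features: list[int] = field(default_factory=list)

    def feature_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.accuracies, [self.linear_beta], self.quad_betas,
             self.deltas_lag1, self.deltas_lag2]
        )


@dataclass
class AttributionResult:
    """Meta-learner verdict for one questioned-work / candidate pair."""

    questioned_doc: str
    candidate_author: str
    verdict: str  # "Match" | "Different"
    probability: float  # calibrated confidence in the verdict


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically so results don't depend on segment order."""
    return X[np.lexsort(X.T[::-1])]


def degradation_curve(
    set_a: np.ndarray | pd.DataFrame,
    set_b: np.ndarray | pd.DataFrame,
    config: UnmaskingConfig,
    rng: np.random.Generator | None = None,
    label: str = "unknown",
) -> DegradationCurve:
    """Iterative feature-elimination curve separating two segment sets.

    Per iteration: stratified-CV accuracy of a linear SVM on the current
    features, then removal of the k most positive and k most negative
    weights of an SVM refit on all current data.  Features are
    standardized per comparison; rows are canonically ordered so the
    curve is invariant to segment order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Xa = np.asarray(
        set_a[variable_columns(set_a)] if isinstance(set_a, pd.DataFrame) else set_a,
        dtype=float,
    )
    Xb = np.asarray(
        set_b[variable_columns(set_b)] if isinstance(set_b, pd.DataFrame) else set_b,
        dtype=float,
    )
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("segment sets have different feature spaces")
    config.validate_features(Xa.shape[1])
    if min(len(Xa), len(Xb)) < config.cv_folds:
        raise ValueError(
            f"each class needs at least cv_folds={config.cv_folds} segments"
        )
    Xa, Xb = _canonical_order(Xa), _canonical_order(Xb)
    X = np.vstack([Xa, Xb])
    y = np.concatenate([np.zeros(len(Xa)), np.ones(len(Xb))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    active = np.arange(X.shape[1])
    accuracies: list[float] = []
    removed: list[int] = []
    for _ in range(config.f):
        if len(active) < 2 * config.k:
            raise ValueError(
                f"only {len(active)} features remain; cannot continue elimination"
            )
        cur = X[:, active]
        cv = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        fold_acc = []
        for tr, te in cv.split(cur, y):
            svm = LinearSVC(C=config.C, dual="auto", max_iter=5000)
            svm.fit(cur[tr], y[tr])
            fold_acc.append(np.mean(svm.predict(cur[te]) == y[te]))
        accuracies.append(float(np.mean(fold_acc)))
        full = LinearSVC(C=config.C, dual="auto", max_iter=5000).fit(cur, y)
        w = full.coef_[0]
        order = np.argsort(w)
        drop_local = np.concatenate([order[: config.k], order[-config.k:]])
        removed.extend(int(i) for i in active[drop_local])
        active = np.delete(active, drop_local)
    acc_arr = np.array(accuracies)
    t = np.arange(config.f, dtype=float)
    linear_beta = float(np.polyfit(t, acc_arr, 1)[0])
    q = np.polyfit(t, acc_arr, 2)
    deltas1 = acc_arr[:-1] - acc_arr[1:]
    deltas2 = acc_arr[:-2] - acc_arr[2:]
    return DegradationCurve(
        accuracies=acc_arr, linear_beta=linear_beta,
        quad_betas=(float(q[0]), float(q[1])),
        deltas_lag1=deltas1, deltas_lag2=deltas2,
        label=label, removed_features=removed,
    )


def _segment_groups(seg_table: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """author -> work -> segment feature matrix."""
    feats = variable_columns(seg_table)
    out: dict[str, dict[str, np.ndarray]] = {}
    for (author, work), grp in seg_table.groupby(["author", "doc_id"], sort=True):
        out.setdefault(str(author), {})[str(work)] = grp[feats].to_numpy(dtype=float)
    return out


def build_training_curves(
    seg_table: pd.DataFrame,
    config: UnmaskingConfig,
    rng: np.random.Generator | None = None,
) -> list[DegradationCurve]:
    """Leave-one-work-out curve construction over a multi-author corpus.

    For each work: a same-author curve (the work vs a size-matched sample
    of the rest of its author's segments) and a different-author curve
    (the work vs a size-matched amalgam sampled from all other authors'
    segments).  Size matching keeps the two classes balanced so CV
    accuracy reflects separability rather than the majority-class rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = _segment_groups(seg_table)
    curves: list[DegradationCurve] = []
    for author, works in groups.items():
        if len(works) < 2:
            continue
        pool_other = np.vstack(
            [m for a, ws in groups.items() if a != author for m in ws.values()]
        )
        for work, X in works.items():
            rest = np.vstack([m for w, m in works.items() if w != work])
            take = min(len(X), len(rest))
            sub_rest = rest[rng.choice(len(rest), size=take, replace=False)]
            curves.append(
                degradation_curve(X, sub_rest, config, rng=rng, label=SAME)
            )
            take = min(len(X), len(pool_other))
            idx = rng.choice(len(pool_other), size=take, replace=False)
            curves.append(
                degradation_curve(X, pool_other[idx], config, rng=rng, label=DIFFERENT)
            )
    return curves


def train_meta_learner(
    curves: list[DegradationCurve], config: UnmaskingConfig
) -> Pipeline:
    """Linear-SVM meta-classifier over curve features, Platt-calibrated.

    Classes are the curve labels; predicted probability of ``same_author``
    is the calibrated authorship-match confidence.
    """
    labeled = [c for c in curves if c.label in (SAME, DIFFERENT)]
    if len(labeled) < 10:
        raise ValueError("need at least 10 labeled curves")
    labels = {c.label for c in labeled}
    if labels != {SAME, DIFFERENT}:
        raise ValueError("both curve labels must be present")
    X = np.vstack([c.feature_vector() for c in labeled])
    y = np.array([c.label for c in labeled])
    # canonical order: verdicts should not depend on curve list order
    order = np.lexsort(np.vstack([X.T[::-1], (y == SAME).astype(float)]))
    X, y = X[order], y[order]
    n_min = int(min(np.sum(y == SAME), np.sum(y == DIFFERENT)))
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", CalibratedClassifierCV(
                SVC(kernel="linear", C=config.C, random_state=config.seed),
                method="sigmoid", ensemble=False, cv=min(5, n_min),
            )),
        ]
    )
    model.fit(X, y)
    return model


def match_probability(model: Pipeline, curve: DegradationCurve) -> float:
    """Calibrated P(same author) for one curve."""
    classes = list(model.classes_)
    p = model.predict_proba(curve.feature_vector()[None, :])[0]
    return float(p[classes.index(SAME)])


def attribute_work(
    questioned_segments: np.ndarray | pd.DataFrame,
    candidate_segments: np.ndarray | pd.DataFrame,
    model: Pipeline,
    config: UnmaskingConfig,
    questioned_doc: str = "questioned",
    candidate_author: str = "candidate",
) -> AttributionResult:
    """Classify a questioned work against one candidate author.

    Builds the questioned-vs-candidate degradation curve and averages the
    meta-learner's match probability over ``n_randomized_iterations``
    reseeded repetitions (the CV fold shuffling is re-randomized each
    time).
    """
    rng = np.random.default_rng(config.seed)
    q = np.asarray(
        questioned_segments[variable_columns(questioned_segments)]
        if isinstance(questioned_segments, pd.DataFrame) else questioned_segments,
        dtype=float,
    )
    cand = np.asarray(
        candidate_segments[variable_columns(candidate_segments)]
        if isinstance(candidate_segments, pd.DataFrame) else candidate_segments,
        dtype=float,
    )
    q, cand = _canonical_order(q), _canonical_order(cand)
    take = min(len(q), len(cand))
    probs = []
    for _ in range(config.n_randomized_iterations):
        # balance the comparison; the subsample is re-randomized per iteration
        a = q if len(q) == take else q[rng.choice(len(q), take, replace=False)]
        b = cand if len(cand) == take else (
            cand[rng.choice(len(cand), take, replace=False)]
        )
        curve = degradation_curve(a, b, config, rng=rng)
        probs.append(match_probability(model, curve))
    p_same = float(np.mean(probs))
    verdict = "Match" if p_same >= 0.5 else "Different"
    return AttributionResult(
        questioned_doc=questioned_doc, candidate_author=candidate_author,
        verdict=verdict, probability=max(p_same, 1.0 - p_same),
    )


def evaluate(predictions, truths) -> dict[str, float]:
    """Accuracy, class-balanced accuracy and Cohen's kappa."""
    predictions, truths = list(predictions), list(truths)
    if not predictions or len(predictions) != len(truths):
        raise ValueError("predictions and truths must be equal-length, non-empty")
    return {
        "accuracy": float(accuracy_score(truths, predictions)),
        "balanced_accuracy": float(balanced_accuracy_score(truths, predictions)),
        "kappa": float(cohen_kappa_score(truths, predictions)),
    }


def holdout_benchmark(
    seg_table: pd.DataFrame,
    config: UnmaskingConfig,
    test_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Train/evaluate the meta-learner on held-out curves from one corpus.

    Curves are built leave-one-work-out, split into train/test stratified
    by label, and the held-out verdicts scored with :func:`evaluate`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    curves = build_training_curves(seg_table, config, rng=rng)
    by_label: dict[str, list[int]] = {SAME: [], DIFFERENT: []}
    for i, c in enumerate(curves):
        by_label[c.label].append(i)
    test_idx: list[int] = []
    for idxs in by_label.values():
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_test = max(1, int(round(test_fraction * len(idxs))))
        test_idx.extend(idxs[:n_test])
    test_set = set(test_idx)
    train = [c for i, c in enumerate(curves) if i not in test_set]
    test = [curves[i] for i in sorted(test_set)]
    model = train_meta_learner(train, config)
    preds = [SAME if match_probability(model, c) >= 0.5 else DIFFERENT for c in test]
    truths = [c.label for c in test]
    return evaluate(preds, truths)
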