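"""Core mental-profile-map computation.

A mental profile map treats an author's documents as repeated multivariate
measurements of the same person.  Language variables are grouped into 13
clusters of psychological processes (style, emotion, cognition, ...); for
each cluster the author's "psychological center" is estimated as a
bootstrap mean, and each document's squared Mahalanobis distance D^2 from
that center is mapped through the upper tail of a chi-square distribution
(df = cluster dimensionality) onto a 0-100 score:

    score = 100 * P(chi2_df > D^2)

so a document exactly at the center scores 100 and scores fall
monotonically toward 0 with distance.  The median of a document's 13
cluster scores is its grand score; low grand scores flag documents whose
psychological composition is atypical of the author.  Documents being
scored are included in the center/covariance estimation (leave-in), which
matches the insertion workflow this method is built for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .lexicon import variable_columns

__all__ = [
    "ClusterScheme",
    "CenterModel",
    "ConsistencyReport",
    "MPMResult",
    "DEFAULT_CLUSTERS",
    "build_cluster_matrices",
    "fit_center_model",
    "fit_center_models",
    "mahalanobis_d2",
    "distance_scores",
    "grand_score",
    "cronbach_alpha",
    "internal_consistency",
    "project_map",
    "decompose",
    "run_mpm",
]

logger = logging.getLogger(__name__)

#: The 13 default clusters of psychological processes and their member
#: variables (LIWC2015 variable names).  Analytic belongs to both Style
#: and Complexity.
DEFAULT_CLUSTERS: list[tuple[str, list[str]]] = [
    ("Style", ["Analytic", "Clout", "Authentic", "Tone"]),
    ("Complexity", ["Analytic", "Sixltr"]),
    ("Function Words", ["i", "we", "you", "shehe", "they", "ipron", "article",
                        "prep", "auxverb", "adverb", "conj", "negate",
                        "interrog"]),
    ("Emotional", ["affect", "posemo", "negemo", "anx", "anger", "sad"]),
    ("Social", ["social", "family", "friend", "female", "male"]),
    ("Cognitive", ["cogproc", "insight", "cause", "discrep", "tentat",
                   "certain", "differ"]),
    ("Perceptual", ["percept", "see", "hear", "feel"]),
    ("Biological", ["bio", "body", "health", "sexual", "ingest"]),
    ("Motivational", ["drives", "affiliation", "achieve", "power", "reward",
                      "risk"]),
    ("Temporal", ["focuspast", "focuspresent", "focusfuture"]),
    ("Relational", ["relative", "motion", "space", "time"]),
    ("Personal", ["work", "leisure", "home", "money", "relig", "death"]),
    ("Utterances", ["informal", "swear", "assent", "nonflu"]),
]

#: Eigenvalues below this (relative) tolerance are treated as zero when
#: inverting a cluster covariance.
COV_EIG_TOL = 1e-8


class SchemeError(ValueError):
    """Raised when a cluster scheme cannot be applied to a feature table."""


@dataclass
class ClusterScheme:
    """An ordered grouping of feature variables into named clusters."""

    clusters: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.clusters]
        if len(set(names)) != len(names):
            raise SchemeError("duplicate cluster names")
        for name, members in self.clusters:
            if len(members) < 2:
                raise SchemeError(f"cluster {name!r} has fewer than 2 variables")

    @classmethod
    def default(cls) -> "ClusterScheme":
        return cls([(n, list(v)) for n, v in DEFAULT_CLUSTERS])

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.clusters]

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for _, members in self.clusters:
            for v in members:
                if v not in seen:
                    seen.append(v)
        return seen

    def members(self, name: str) -> list[str]:
        for n, m in self.clusters:
            if n == name:
                return list(m)
        raise KeyError(name)

    def restrict(self, available: list[str] | set[str]) -> "ClusterScheme":
        """Drop variables absent from ``available`` (with a logged warning).

        Raises :class:`SchemeError` if any cluster is left with fewer than
        two member variables.
        """
        available = set(available)
        out: list[tuple[str, list[str]]] = []
        for name, members in self.clusters:
            kept = [v for v in members if v in available]
            dropped = [v for v in members if v not in available]
            if dropped:
                logger.warning(
                    "cluster %r: dropping missing variables %s", name, dropped
                )
            if len(kept) < 2:
                raise SchemeError(
                    f"cluster {name!r} left with {len(kept)} variable(s) "
                    f"after dropping {dropped}"
                )
            out.append((name, kept))
        return ClusterScheme(out)


@dataclass
class CenterModel:
    """Per-cluster center and covariance for one author's map.

    The center is the mean over ``bootstrap_iterations`` bootstrap
    resamples of the resample mean; the covariance is the plain sample
    covariance (n-1 denominator) of the original rows.
    """

    center: np.ndarray
    covariance: np.ndarray
    n_docs: int
    bootstrap_iterations: int
    seed: int
    _pinv: np.ndarray | None = field(default=None, repr=False)

    def precision(self, ridge: float = 0.0) -> np.ndarray:
        """Moore-Penrose pseudo-inverse of the (optionally ridged) covariance."""
        if ridge:
            p = self.covariance.shape[0]
            sigma = self.covariance + ridge * np.trace(self.covariance) / p * np.eye(p)
            return np.linalg.pinv(sigma, hermitian=True, rcond=COV_EIG_TOL)
        if self._pinv is None:
            self._pinv = np.linalg.pinv(
                self.covariance, hermitian=True, rcond=COV_EIG_TOL
            )
        return self._pinv


@dataclass
class ConsistencyReport:
    """Internal consistency of the per-cluster distance scores."""

    alpha: float
    alpha_standardized: float
    mean_median_r: float
    item_correlations: pd.DataFrame


@dataclass
class MPMResult:
    """Output of a full map run: per-document profiles plus fitted models."""

    scheme: ClusterScheme
    models: dict[str, CenterModel]
    profiles: pd.DataFrame  # doc_id, author, <cluster scores>, grand_score, pc1, pc2
    d2: pd.DataFrame  # doc_id plus squared Mahalanobis distances per cluster

    def score_matrix(self) -> pd.DataFrame:
        return self.profiles.set_index("doc_id")[self.scheme.names]


def build_cluster_matrices(
    features: pd.DataFrame, scheme: ClusterScheme
) -> dict[str, np.ndarray]:
    """Slice a feature table into one documents x members matrix per cluster.

    Missing variables are dropped from the scheme first (logged); a
    cluster reduced below two variables is a configuration error.  All
    matrices share the feature table's document ordering.
    """
    cols = set(variable_columns(features))
    scheme = scheme.restrict(cols)
    return {
        name: features[members].to_numpy(dtype=float)
        for name, members in scheme.clusters
    }


def fit_center_model(
    cluster_matrix: np.ndarray, B: int = 1000, seed: int = 0
) -> CenterModel:
    """Fit one cluster's center (bootstrap mean of means) and covariance.

    Rows are resampled with replacement at the original size ``n_docs``
    for each of ``B`` bootstrap iterations; the center is the average of
    the resample means, which is deterministic given ``seed`` and equals
    the plain column mean in expectation.
    """
    X = np.asarray(cluster_matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 documents to fit a center, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    center = X[idx].mean(axis=1).mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return CenterModel(center=center, covariance=cov, n_docs=n,
                       bootstrap_iterations=B, seed=seed)


def fit_center_models(
    matrices: dict[str, np.ndarray], B: int = 1000, seed: int = 0
) -> dict[str, CenterModel]:
    """Fit every cluster, with independent seeded bootstrap streams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(matrices))
    return {
        name: fit_center_model(X, B=B, seed=int(child.generate_state(1)[0] % (2**31)))
        for (name, X), child in zip(matrices.items(), children)
    }


def mahalanobis_d2(
    X: np.ndarray, model: CenterModel, ridge: float = 0.0
) -> np.ndarray:
    """Squared Mahalanobis distances of rows of ``X`` from a fitted center."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[1]} variables, "
            f"model has {model.center.shape[0]}"
        )
    diff = X - model.center
    d2 = np.einsum("ij,jk,ik->i", diff, model.precision(ridge), diff)
    if np.any(d2 < 0):
        warnings.warn("negative squared distances clamped to 0 (numerical)",
                      RuntimeWarning, stacklevel=2)
        d2 = np.clip(d2, 0.0, None)
    return d2


def distance_scores(
    matrices: dict[str, np.ndarray],
    models: dict[str, CenterModel],
    ridge: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map squared distances to 0-100 scores, cluster by cluster.

    ``score = 100 * (1 - F_chi2(D^2; df))`` with df equal to the number of
    member variables, so the center scores 100 and the score decreases
    strictly with distance.  Returns ``(d2, scores)`` frames with one
    column per cluster.
    """
    if set(matrices) != set(models):
        raise ValueError("matrices and models cover different clusters")
    d2_cols, score_cols = {}, {}
    for name, X in matrices.items():
        model = models[name]
        d2 = mahalanobis_d2(X, model, ridge=ridge)
        df_ = X.shape[1]
        d2_cols[name] = d2
        score_cols[name] = 100.0 * stats.chi2.sf(d2, df_)
    return pd.DataFrame(d2_cols), pd.DataFrame(score_cols)


def grand_score(scores, scheme: ClusterScheme | None = None) -> float:
    """Median of the per-cluster scores (7th order statistic of 13).

    ``scores`` may be a mapping/Series of cluster -> score or a plain
    sequence.  With a scheme given, every cluster must be present.
    """
    if scheme is not None:
        missing = [n for n in scheme.names
                   if n not in scores or pd.isna(scores[n])]
        if missing:
            raise ValueError(f"missing cluster scores: {missing}")
        values = [float(scores[n]) for n in scheme.names]
    elif isinstance(scores, (dict, pd.Series)):
        values = [float(v) for v in dict(scores).values()]
    else:
        values = [float(v) for v in scores]
    if not values:
        raise ValueError("no scores")
    return float(np.median(values))


def cronbach_alpha(X: np.ndarray, standardized: bool = False) -> float:
    """Cronbach's alpha over item columns.

    Raw (covariance-based) by default: ``k/(k-1) * (1 - sum(item
    variances) / var(row sums))`` with n-1 variances.  The standardized
    variant uses the mean inter-item correlation instead.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if standardized:
        R = np.corrcoef(X, rowvar=False)
        rbar = (R.sum() - k) / (k * (k - 1))
        return float(k * rbar / (1 + (k - 1) * rbar))
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def internal_consistency(score_matrix: pd.DataFrame | np.ndarray) -> ConsistencyReport:
    """Alpha, mean-vs-median correlation, and the inter-item correlation matrix."""
    if isinstance(score_matrix, pd.DataFrame):
        cols = list(score_matrix.columns)
        X = score_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(score_matrix, dtype=float)
        cols = [f"item{i + 1}" for i in range(X.shape[1])]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 documents")
    alpha = cronbach_alpha(X)
    alpha_std = cronbach_alpha(X, standardized=True)
    row_mean = X.mean(axis=1)
    row_median = np.median(X, axis=1)
    r = float(np.corrcoef(row_mean, row_median)[0, 1])
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=cols, columns=cols)
    return ConsistencyReport(alpha=alpha, alpha_standardized=alpha_std,
                             mean_median_r=r, item_correlations=corr)


def project_map(score_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """2-D map coordinates: PCA of the column-standardized score matrix.

    Component signs are fixed so that each component's largest-magnitude
    loading is positive.  Perfectly collinear documents get a zero second
    coordinate; a matrix with no variation at all cannot be projected.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 documents")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if np.allclose(Z, 0.0):
        raise ValueError("score matrix has no variation; no 2-D projection")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Z)
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def decompose(
    scores, scheme: ClusterScheme | None = None, threshold: float = 20.0
) -> list[str]:
    """Clusters on which a document is highly discrepant (score <= threshold).

    Returned in scheme order; ``scores`` is a mapping cluster -> score.
    """
    scheme = scheme or ClusterScheme.default()
    return [n for n in scheme.names if n in scores and scores[n] <= threshold]


def run_mpm(
    features: pd.DataFrame,
    scheme: ClusterScheme | None = None,
    B: int = 1000,
    seed: int = 0,
    ridge: float = 0.0,
) -> MPMResult:
    """Full map pipeline on a feature table.

    Builds cluster matrices, fits centers/covariances (leave-in: every
    document in the table contributes), computes distance scores, grand
    scores and the 2-D projection.  Deterministic given ``seed``.
    """
    scheme = scheme or ClusterScheme.default()
    scheme = scheme.restrict(set(variable_columns(features)))
    matrices = build_cluster_matrices(features, scheme)
    models = fit_center_models(matrices, B=B, seed=seed)
    d2, scores = distance_scores(matrices, models)
    scores = scores[scheme.names]
    grand = scores.median(axis=1)
    coords = project_map(scores)
    profiles = pd.DataFrame({"doc_id": features["doc_id"].to_numpy()})
    if "author" in features.columns:
        profiles["author"] = features["author"].to_numpy()
    for name in scheme.names:
        profiles[name] = scores[name].to_numpy()
    profiles["grand_score"] = grand.to_numpy()
    profiles["pc1"] = coords[:, 0]
    profiles["pc2"] = coords[:, 1]
    d2.insert(0, "doc_id", features["doc_id"].to_numpy())
    return MPMResult(scheme=scheme, models=models, profiles=profiles, d2=d2)
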