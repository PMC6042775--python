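"""Seeded validation experiments for the map and the unmasking baseline.

These are the package's standing checks of its own statistical behavior:
bogus-insertion recovery, the null distribution of cluster scores under a
single-author model, and the separation/meta-learning performance of
unmasking on the synthetic benchmark.  They are used by the test suite
and the reproduction script, and are available to users who want to
re-run them at other sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ClusterScheme, run_mpm
from .insertion import insert_and_score
from .lexicon import variable_columns
from .synth import AuthorProfile, gen_author_feature_table, make_unmasking_benchmark
from .unmasking import UnmaskingConfig, degradation_curve, holdout_benchmark

__all__ = [
    "single_author_table",
    "shifted_candidate",
    "bogus_insertion_rate",
    "null_uniformity_ks",
    "unmasking_separation_rate",
    "benchmark_meta_metrics",
]


def single_author_table(
    n_docs: int,
    seed: int,
    within_sd: float = 5.0,
    rho: float = 0.3,
    scheme: ClusterScheme | None = None,
) -> pd.DataFrame:
    """One author's feature table: all cluster means at 50, exchangeable
    within-author covariance (sd ``within_sd``, correlation ``rho``)."""
    scheme = scheme or ClusterScheme.default()
    means = {n: np.full(len(m), 50.0) for n, m in scheme.clusters}
    covs = {
        n: within_sd**2
        * ((1 - rho) * np.eye(len(m)) + rho * np.ones((len(m), len(m))))
        for n, m in scheme.clusters
    }
    prof = AuthorProfile("author", means, covs, doc_length=26000)
    return gen_author_feature_table([prof], docs_per_author=n_docs, seed=seed,
                                    scheme=scheme)


def shifted_candidate(
    base: pd.DataFrame, offset_sd: float, doc_id: str = "inserted"
) -> pd.DataFrame:
    """A candidate work offset ``offset_sd`` pooled SD per variable from
    the base corpus mean."""
    cand = base.iloc[[0]].copy()
    cand["doc_id"] = doc_id
    cols = variable_columns(base)
    shift = base[cols].mean() + offset_sd * base[cols].std(ddof=1)
    cand[cols] = shift.to_numpy()[None, :]
    return cand


def bogus_insertion_rate(
    n_runs: int = 100,
    offset_sd: float = 3.0,
    n_docs: int = 16,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of seeded runs in which a far-shifted insertion ranks lowest.

    Each run draws a fresh 16-work single-author corpus, inserts a
    candidate offset ``offset_sd`` pooled SD on every variable, and checks
    whether its grand score is the map's minimum.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        s1, s2 = (int(x) for x in rng.integers(2**31, size=2))
        base = single_author_table(n_docs, seed=s1)
        cand = shifted_candidate(base, offset_sd)
        run = insert_and_score(base, cand, B=B, seed=s2)
        hits += run.inserted_rank == 1
    return hits / n_runs


def null_uniformity_ks(
    n_docs: int = 500, B: int = 1000, seed: int = 0
) -> dict[str, float]:
    """KS p-values of per-cluster scores against Uniform(0, 100).

    Under a single multivariate-normal author, each cluster's chi-square
    mapped scores should be approximately uniform in large samples.
    """
    table = single_author_table(n_docs, seed=seed)
    result = run_mpm(table, B=B, seed=seed)
    out = {}
    for name in result.scheme.names:
        s = result.profiles[name].to_numpy() / 100.0
        out[name] = float(stats.kstest(s, "uniform").pvalue)
    return out


def _work_pair(
    rng: np.random.Generator,
    same_author: bool,
    n_seg: int = 16,
    n_feat: int = 48,
    within_sd: float = 5.0,
    between_sd: float = 10.0,
    superficial_offset: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    author_a = 50 + rng.normal(0, between_sd, size=n_feat)
    author_b = author_a if same_author else 50 + rng.normal(0, between_sd,
                                                            size=n_feat)

    def work(mean):
        offset = np.zeros(n_feat)
        chosen = rng.choice(n_feat, size=4, replace=False)
        offset[chosen] = rng.choice([-1.0, 1.0], size=4) * superficial_offset
        return rng.normal(mean + offset, within_sd, size=(n_seg, n_feat))

    return work(author_a), work(author_b)


def unmasking_separation_rate(
    n_runs: int = 50, seed: int = 0, config: UnmaskingConfig | None = None
) -> float:
    """Fraction of runs where a same-author pair degrades more than a
    different-author pair (first-to-last accuracy drop)."""
    config = config or UnmaskingConfig(seed=seed)
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_runs):
        a1, a2 = _work_pair(rng, same_author=True)
        b1, b2 = _work_pair(rng, same_author=False)
        same = degradation_curve(a1, a2, config, rng=rng)
        diff = degradation_curve(b1, b2, config, rng=rng)
        drop_same = same.accuracies[0] - same.accuracies[-1]
        drop_diff = diff.accuracies[0] - diff.accuracies[-1]
        wins += drop_same > drop_diff
    return wins / n_runs


def benchmark_meta_metrics(
    n_iterations: int = 20, seed: int = 0, config: UnmaskingConfig | None = None
) -> dict[str, float]:
    """Held-out meta-learner performance on the synthetic benchmark.

    Each randomized iteration regenerates the 6-author benchmark corpus,
    builds leave-one-work-out curves, trains on a stratified 75% and
    scores the held-out 25%; metrics are averaged over iterations.
    """
    rng = np.random.default_rng(seed)
    acc, bacc, kap = [], [], []
    for _ in range(n_iterations):
        s = int(rng.integers(2**31))
        seg = make_unmasking_benchmark(seed=s)
        cfg = config or UnmaskingConfig(seed=s)
        m = holdout_benchmark(seg, cfg, rng=np.random.default_rng(s))
        acc.append(m["accuracy"])
        bacc.append(m["balanced_accuracy"])
        kap.append(m["kappa"])
    return {
        "accuracy": float(np.mean(acc)),
        "balanced_accuracy": float(np.mean(bacc)),
        "kappa": float(np.mean(kap)),
    }
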