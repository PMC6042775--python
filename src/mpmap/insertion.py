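"""Insertion workflows for single-candidate verification.

A questioned (or deliberately bogus) work is inserted into a candidate
author's corpus and the full map is recomputed over the union, so the
inserted work participates in center and covariance estimation exactly
like the verified works.  Its rank by grand score (1 = lowest, i.e. the
worst fit) and the full profile table are returned.  A base-only
reference analysis is always computed alongside so that averaging of the
base works' scores across several insertion runs can be compared against
the no-insertion analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClusterScheme, MPMResult, run_mpm

__all__ = ["InsertionRun", "insert_and_score", "average_runs"]


@dataclass
class InsertionRun:
    """One insertion analysis: base corpus plus a single inserted work."""

    base_author: str
    inserted_doc_id: str
    result: MPMResult  # joint map over base + inserted work
    base_only: MPMResult  # reference map over the base corpus alone
    inserted_rank: int  # 1 = lowest grand score; ties rank the insertion last
    base_features: pd.DataFrame | None = None  # the base corpus itself

    @property
    def inserted_grand_score(self) -> float:
        prof = self.result.profiles
        return float(
            prof.loc[prof["doc_id"] == self.inserted_doc_id, "grand_score"].iloc[0]
        )


def insert_and_score(
    base_features: pd.DataFrame,
    candidate: pd.DataFrame,
    scheme: ClusterScheme | None = None,
    B: int = 1000,
    seed: int = 0,
    ridge: float = 0.0,
) -> InsertionRun:
    """Insert one candidate work into a base corpus and run the map.

    ``candidate`` is a one-row feature table sharing the base table's
    variables.  Rank ties are broken by listing the inserted work last
    (after any base work with an equal grand score), which never inflates
    apparent detection.
    """
    if len(candidate) != 1:
        raise ValueError("candidate must be a single-row feature table")
    cand_id = str(candidate["doc_id"].iloc[0])
    if cand_id in set(base_features["doc_id"].astype(str)):
        raise ValueError(f"candidate doc_id {cand_id!r} collides with a base work")
    if len(base_features) < 3:
        raise ValueError("base corpus must contain at least 3 works")
    joint = pd.concat([base_features, candidate], ignore_index=True)
    result = run_mpm(joint, scheme=scheme, B=B, seed=seed, ridge=ridge)
    base_only = run_mpm(base_features, scheme=scheme, B=B, seed=seed, ridge=ridge)
    prof = result.profiles
    cand_grand = float(prof.loc[prof["doc_id"] == cand_id, "grand_score"].iloc[0])
    base_grands = prof.loc[prof["doc_id"] != cand_id, "grand_score"].to_numpy()
    rank = 1 + int(np.sum(base_grands <= cand_grand))
    author = ""
    if "author" in base_features.columns:
        authors = base_features["author"].unique()
        author = str(authors[0]) if len(authors) == 1 else "|".join(map(str, authors))
    return InsertionRun(base_author=author, inserted_doc_id=cand_id,
                        result=result, base_only=base_only, inserted_rank=rank,
                        base_features=base_features.reset_index(drop=True))


def average_runs(runs: list[InsertionRun]) -> tuple[pd.Series, float]:
    """Average base-work grand scores across insertion runs.

    Returns the per-base-work mean grand score (indexed by doc_id) and
    its Pearson correlation with the base-only (no insertion) analysis.
    All runs must share the same base corpus.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to average")
    base_ids = list(runs[0].base_only.profiles["doc_id"])
    ref = runs[0].base_features
    for r in runs[1:]:
        same_ids = list(r.base_only.profiles["doc_id"]) == base_ids
        same_feats = (
            ref is None or r.base_features is None or ref.equals(r.base_features)
        )
        if not (same_ids and same_feats):
            raise ValueError("runs cover different base corpora")
    per_run = []
    for r in runs:
        prof = r.result.profiles
        g = prof.loc[prof["doc_id"] != r.inserted_doc_id].set_index("doc_id")[
            "grand_score"
        ]
        per_run.append(g.loc[base_ids])
    means = pd.concat(per_run, axis=1).mean(axis=1)
    base_g = runs[0].base_only.profiles.set_index("doc_id")["grand_score"].loc[base_ids]
    r_val = float(np.corrcoef(means.to_numpy(), base_g.to_numpy())[0, 1])
    return means, r_val
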