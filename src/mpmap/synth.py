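"""Synthetic authors, corpora and packaged fixtures.

Every stage of the pipeline is testable without external data:

* multivariate-normal author profiles produce document-level feature
  tables for the map (each author's works scatter around a stable
  per-cluster center);
* a work/segment generator produces segment-level tables with the
  structure unmasking exploits — works by one author share the author's
  profile but carry superficial per-work offsets on a few features,
  while different authors differ persistently across many features;
* a token-level generator emits plain-text corpora whose dictionary
  scores recover specified category percentages within binomial error;
* the published 21-play score matrix (16 verified plays by Aphra Behn
  plus 5 questioned plays, 13 cluster scores and a grand median each)
  ships as a transcription-checked fixture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusterScheme
from .lexicon import Lexicon

__all__ = [
    "AuthorProfile",
    "Table7Fixture",
    "make_author_profiles",
    "gen_author_feature_table",
    "make_unmasking_benchmark",
    "gen_toy_corpus",
    "load_table7_fixture",
    "toy_dictionary_path",
]

#: sha256 of the packaged 21-play score fixture; guards against silent edits.
TABLE7_SHA256 = "1e805577688e0e73d4f97871ca9a6a033e4ce4fbd62b8c1b7c8172c96fbc310e"

BEHN_LABEL = "Behn"
QUESTIONED_LABEL = "Questioned"


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its validation checks."""


@dataclass
class AuthorProfile:
    """Generative model of one synthetic author.

    Each cluster has a mean vector and covariance in feature-score units
    (0-100 scale); documents are independent draws per cluster, clipped
    to [0, 100].  ``doc_length`` is recorded as the nominal word count of
    generated documents (full-length plays average tens of thousands of
    words).
    """

    author_id: str
    cluster_means: dict[str, np.ndarray]
    cluster_covs: dict[str, np.ndarray]
    doc_length: int = 26000

    def __post_init__(self) -> None:
        for name, cov in self.cluster_covs.items():
            cov = np.asarray(cov, dtype=float)
            if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
                raise ValueError(f"cluster {name!r}: covariance not PSD")
            mean = np.asarray(self.cluster_means[name], dtype=float)
            if np.any(mean < 0) or np.any(mean > 100):
                raise ValueError(f"cluster {name!r}: means outside [0, 100]")


def _exchangeable_cov(dim: int, sd: float, rho: float) -> np.ndarray:
    return sd**2 * ((1 - rho) * np.eye(dim) + rho * np.ones((dim, dim)))


def make_author_profiles(
    n_authors: int = 6,
    scheme: ClusterScheme | None = None,
    between_sd: float = 10.0,
    within_sd: float = 5.0,
    rho: float = 0.3,
    base_mean: float = 50.0,
    doc_length: int = 26000,
    seed: int = 0,
) -> list[AuthorProfile]:
    """Draw author profiles around a common population mean.

    Cluster means are N(base_mean, between_sd^2) per variable (clipped to
    [5, 95]); within-author covariance is exchangeable with standard
    deviation ``within_sd`` and correlation ``rho``.  The default keeps
    between-author spread at twice the within-author spread.
    """
    scheme = scheme or ClusterScheme.default()
    rng = np.random.default_rng(seed)
    profiles = []
    for a in range(n_authors):
        means, covs = {}, {}
        for name, members in scheme.clusters:
            d = len(members)
            means[name] = np.clip(
                rng.normal(base_mean, between_sd, size=d), 5.0, 95.0
            )
            covs[name] = _exchangeable_cov(d, within_sd, rho)
        profiles.append(
            AuthorProfile(author_id=f"author{a:02d}", cluster_means=means,
                          cluster_covs=covs, doc_length=doc_length)
        )
    return profiles


def gen_author_feature_table(
    profiles: list[AuthorProfile],
    docs_per_author: int = 15,
    seed: int = 0,
    scheme: ClusterScheme | None = None,
) -> pd.DataFrame:
    """Document-level feature table drawn from author profiles.

    For each document, every cluster's values are one multivariate-normal
    draw from the author's profile, clipped to [0, 100].  A variable
    appearing in more than one cluster takes its value from the first
    cluster that contains it.  Deterministic given ``seed``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    scheme = scheme or ClusterScheme.default()
    rng = np.random.default_rng(seed)
    rows = []
    for prof in profiles:
        for j in range(docs_per_author):
            values: dict[str, float] = {}
            for name, members in scheme.clusters:
                draw = rng.multivariate_normal(
                    np.asarray(prof.cluster_means[name], dtype=float),
                    np.asarray(prof.cluster_covs[name], dtype=float),
                    method="svd",
                )
                draw = np.clip(draw, 0.0, 100.0)
                for var, val in zip(members, draw):
                    values.setdefault(var, float(val))
            rows.append(
                {"doc_id": f"{prof.author_id}_doc{j:03d}",
                 "author": prof.author_id,
                 "word_count": prof.doc_length, **values}
            )
    return pd.DataFrame(rows)


def make_unmasking_benchmark(
    n_authors: int = 6,
    works_per_author: int = 8,
    segments_per_work: int = 12,
    n_features: int = 48,
    within_sd: float = 5.0,
    between_sd: float = 10.0,
    superficial_features: int = 4,
    superficial_offset: float = 12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment-level corpus with same/different-author curve structure.

    Author means differ persistently across all features (N(0,
    between_sd^2) per feature around 50); each work additionally carries
    a superficial offset of ±``superficial_offset`` on
    ``superficial_features`` randomly chosen features, emulating themes
    and characters that distinguish works by the same author only
    shallowly.  Segments are N(work mean, within_sd^2 I) draws.
    """
    rng = np.random.default_rng(seed)
    feats = [f"f{i:02d}" for i in range(n_features)]
    rows = []
    for a in range(n_authors):
        author_mean = 50.0 + rng.normal(0.0, between_sd, size=n_features)
        for w in range(works_per_author):
            offset = np.zeros(n_features)
            chosen = rng.choice(n_features, size=superficial_features, replace=False)
            offset[chosen] = rng.choice([-1.0, 1.0], size=superficial_features) * (
                superficial_offset
            )
            work_mean = author_mean + offset
            segs = rng.normal(work_mean, within_sd,
                              size=(segments_per_work, n_features))
            for s in range(segments_per_work):
                rows.append(
                    {"author": f"author{a:02d}",
                     "doc_id": f"author{a:02d}_work{w:02d}",
                     "seg_id": s,
                     **dict(zip(feats, segs[s]))}
                )
    return pd.DataFrame(rows)


def gen_toy_corpus(
    targets: dict[str, float],
    lexicon: Lexicon,
    n_docs: int,
    doc_length: int = 2000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[list[str]]:
    """Generate documents whose category scores hit specified targets.

    ``targets`` maps category names to expected percent-of-words rates.
    Tokens are i.i.d.: with probability target/100 a word belonging
    exclusively to that category is emitted (disjoint targets must sum to
    <= 100), otherwise a filler token matching no dictionary entry.
    Scoring the output recovers the targets within binomial error.  With
    ``out_dir`` set, writes one ``doc_###.txt`` per document plus a
    ``_metadata.json`` sidecar recording all parameters; byte-identical
    for identical seeds.
    """
    name_to_id = {name: cid for cid, name in lexicon.categories}
    unknown = set(targets) - set(name_to_id)
    if unknown:
        raise ValueError(f"targets name unknown categories: {sorted(unknown)}")
    total = sum(targets.values())
    if total > 100:
        raise ValueError(f"targets sum to {total} > 100")
    from .lexicon import match_categories

    emit_words: dict[str, list[str]] = {}
    for name, pct in targets.items():
        cid = name_to_id[name]
        # candidate tokens must score as exactly this category under the
        # full matching rules (literal precedence, prefixes, multi-membership)
        words = sorted(
            {e.pattern for e in lexicon.entries if cid in e.category_ids}
        )
        words = [w for w in words if match_categories(w, lexicon) == {cid}]
        if pct > 0 and not words:
            raise ValueError(f"no single-membership words for category {name!r}")
        emit_words[name] = words
    cats = sorted(t for t in targets if targets[t] > 0)
    probs = np.array([targets[c] / 100.0 for c in cats])
    filler = [f"zz{chr(ord('a') + i % 26)}{i // 26}" for i in range(40)]
    rng = np.random.default_rng(seed)
    docs: list[list[str]] = []
    for _ in range(n_docs):
        u = rng.random(doc_length)
        edges = np.concatenate([[0.0], np.cumsum(probs)])
        tokens = []
        for x in u:
            j = int(np.searchsorted(edges, x, side="right")) - 1
            if j < len(cats) and x < edges[-1]:
                pool = emit_words[cats[j]]
            else:
                pool = filler
            tokens.append(pool[int(rng.integers(len(pool)))])
        docs.append(tokens)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, toks in enumerate(docs):
            lines = [" ".join(toks[j : j + 12]) for j in range(0, len(toks), 12)]
            (out_dir / f"doc_{i:03d}.txt").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )
        meta = {
            "generator": "gen_toy_corpus",
            "targets": targets,
            "n_docs": n_docs,
            "doc_length": doc_length,
            "seed": seed,
        }
        (out_dir / "_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return docs


@dataclass
class Table7Fixture:
    """The published 21-play score matrix, validated on load."""

    table: pd.DataFrame  # author, title, grand_score, 13 cluster columns
    cluster_names: list[str] = field(default_factory=list)

    def behn_rows(self) -> pd.DataFrame:
        return self.table[self.table["author"] == BEHN_LABEL]

    def questioned_rows(self) -> pd.DataFrame:
        return self.table[self.table["author"] == QUESTIONED_LABEL]

    def score_matrix(self, behn_only: bool = False) -> pd.DataFrame:
        t = self.behn_rows() if behn_only else self.table
        return t.set_index("title")[self.cluster_names]

    def row_scores(self, title: str) -> pd.Series:
        row = self.table[self.table["title"] == title]
        if row.empty:
            raise KeyError(title)
        return row.iloc[0][self.cluster_names]


def toy_dictionary_path() -> Path:
    """Path of the bundled toy category dictionary (.dic)."""
    return Path(resources.files("mpmap").joinpath("data/toy.dic"))


def load_table7_fixture() -> Table7Fixture:
    """Load and validate the packaged 21-play score matrix.

    Checks the file checksum, the row counts (21 total, 16 verified), that
    every grand score equals the median of its 13 cluster scores at the
    printed 2-decimal precision, and the published mean/SD (48.56/16.41)
    of the verified plays' grand scores.
    """
    raw = resources.files("mpmap").joinpath("data/table7.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE7_SHA256:
        raise FixtureError(
            f"table7.csv checksum mismatch ({digest}); fixture corrupted"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    clusters = [c for c in df.columns if c not in ("author", "title", "grand_score")]
    if len(df) != 21 or len(clusters) != 13:
        raise FixtureError("fixture must have 21 rows x 13 cluster scores")
    if (df["author"] == BEHN_LABEL).sum() != 16:
        raise FixtureError("fixture must contain 16 verified rows")
    med = df[clusters].median(axis=1)
    if not np.allclose(med, df["grand_score"], atol=0.005):
        raise FixtureError("a grand score does not equal its row median")
    g = df.loc[df["author"] == BEHN_LABEL, "grand_score"]
    if round(float(g.mean()), 2) != 48.56 or round(float(g.std(ddof=1)), 2) != 16.41:
        raise FixtureError("verified grand-score mean/SD do not match 48.56/16.41")
    return Table7Fixture(table=df, cluster_names=clusters)
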