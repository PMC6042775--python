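"""Dictionary-based feature extraction for psychological text analysis.

Implements the word-counting model used by LIWC-style tools: a category
dictionary maps literal words and prefix stems (``happ*``) to named
categories, and a document's score on each category is the percentage of
its tokens that match a member of that category.  Documents can also be
split into fixed-length segments for segment-level analyses.

The proprietary LIWC2015 dictionary is not distributed here; any
dictionary in the standard ``.dic`` dialect can be loaded, and a small
toy dictionary ships with the package for testing and demonstration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Lexicon",
    "FeatureVector",
    "Segment",
    "LexiconError",
    "read_dic",
    "write_dic",
    "tokenize",
    "match_categories",
    "score_text",
    "segment_text",
    "score_corpus",
    "read_feature_table",
    "write_feature_table",
    "FEATURE_FLOAT_DECIMALS",
]

#: Columns that identify a row in a feature table; everything else is a variable.
ID_COLUMNS = ("doc_id", "author", "word_count")

#: Feature tables round-trip exactly at this many decimal places.
FEATURE_FLOAT_DECIMALS = 6


class LexiconError(ValueError):
    """Raised for malformed .dic files or inconsistent lexicons."""


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    is_prefix: bool
    category_ids: frozenset[int]


@dataclass
class Lexicon:
    """A category dictionary: named categories plus word/stem entries.

    ``categories`` is an ordered list of ``(id, name)`` pairs; ``entries``
    maps lowercase patterns to category-id sets, with ``is_prefix`` set
    for trailing-``*`` stems.
    """

    categories: list[tuple[int, str]]
    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {cid for cid, _ in self.categories}
        if len(ids) != len(self.categories):
            raise LexiconError("duplicate category ids")
        seen: set[tuple[str, bool]] = set()
        for e in self.entries:
            if not e.pattern or e.pattern != e.pattern.lower():
                raise LexiconError(f"invalid pattern {e.pattern!r}")
            key = (e.pattern, e.is_prefix)
            if key in seen:
                raise LexiconError(f"duplicate entry {e.pattern!r}")
            seen.add(key)
            unknown = e.category_ids - ids
            if unknown:
                raise LexiconError(
                    f"entry {e.pattern!r} references unknown category ids {sorted(unknown)}"
                )

    @property
    def category_names(self) -> list[str]:
        return [name for _, name in self.categories]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FeatureVector:
    """Per-document scores: category percentages plus summary variables.

    Category scores are 100 x (matching tokens) / (total tokens), hence in
    [0, 100].  ``degenerate`` flags an empty document (all scores zero by
    convention, no division performed).
    """

    doc_id: str
    word_count: int
    values: dict[str, float]
    degenerate: bool = False


@dataclass
class Segment:
    """A contiguous chunk of a tokenized document."""

    parent_doc_id: str
    segment_index: int
    tokens: list[str]


# Letters (any script) with internal apostrophes; digits/punct separate.
_TOKEN_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: maximal letter runs with internal apostrophes.

    Hyphens, digits and all punctuation act as separators, so the token
    count is the word count used as the percentage denominator.
    """
    text = text.replace("’", "'").lower()
    return _TOKEN_RE.findall(text)


def read_dic(path: str | Path) -> Lexicon:
    """Read a LIWC-format ``.dic`` dictionary.

    The format is a ``%``-delimited header of ``id<TAB>name`` lines
    followed by ``word<TAB>id [id ...]`` entry lines; a trailing ``*`` on
    a word marks a prefix stem.  Whitespace other than tabs is tolerated
    as a separator.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    # locate header delimiters
    delim = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delim) < 2:
        raise LexiconError(f"{path}: missing %% header delimiters")
    categories: list[tuple[int, str]] = []
    for i in range(delim[0] + 1, delim[1]):
        ln = lines[i].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise LexiconError(f"{path}:{i + 1}: malformed header line {ln!r}")
        try:
            cid = int(parts[0])
        except ValueError as exc:
            raise LexiconError(f"{path}:{i + 1}: category id not an integer") from exc
        categories.append((cid, parts[1]))
    known = {cid for cid, _ in categories}
    entries: list[LexiconEntry] = []
    for i in range(delim[1] + 1, len(lines)):
        ln = lines[i].strip()
        if not ln:
            continue
        parts = ln.split()
        word, id_parts = parts[0], parts[1:]
        if not id_parts:
            raise LexiconError(f"{path}:{i + 1}: entry {word!r} lists no categories")
        try:
            cids = frozenset(int(p) for p in id_parts)
        except ValueError as exc:
            raise LexiconError(f"{path}:{i + 1}: non-integer category id") from exc
        if not cids <= known:
            raise LexiconError(
                f"{path}:{i + 1}: entry {word!r} references unknown id "
                f"{sorted(cids - known)}"
            )
        is_prefix = word.endswith("*")
        pattern = word[:-1] if is_prefix else word
        if not pattern:
            raise LexiconError(f"{path}:{i + 1}: empty pattern")
        entries.append(LexiconEntry(pattern.lower(), is_prefix, cids))
    if not categories and not entries:
        raise LexiconError(f"{path}: empty lexicon")
    return Lexicon(categories=categories, entries=entries)


def write_dic(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon in ``.dic`` format (inverse of :func:`read_dic`)."""
    out = ["%"]
    out += [f"{cid}\t{name}" for cid, name in lexicon.categories]
    out.append("%")
    for e in lexicon.entries:
        word = e.pattern + ("*" if e.is_prefix else "")
        out.append(word + "\t" + "\t".join(str(c) for c in sorted(e.category_ids)))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def _build_matchers(
    lexicon: Lexicon,
) -> tuple[dict[str, frozenset[int]], dict[str, frozenset[int]]]:
    literal: dict[str, frozenset[int]] = {}
    prefix: dict[str, frozenset[int]] = {}
    for e in lexicon.entries:
        target = prefix if e.is_prefix else literal
        target[e.pattern] = target.get(e.pattern, frozenset()) | e.category_ids
    return literal, prefix


def _match_one(
    tok: str,
    literal: Mapping[str, frozenset[int]],
    prefix: Mapping[str, frozenset[int]],
) -> set[int]:
    cats: set[int] = set()
    has_literal = tok in literal
    if has_literal:
        cats |= literal[tok]
    for i in range(1, len(tok) + 1):
        stem = tok[:i]
        if stem in prefix:
            if stem == tok and has_literal:
                continue  # exact literal takes precedence over the same-string stem
            cats |= prefix[stem]
    return cats


def match_categories(token: str, lexicon: Lexicon) -> set[int]:
    """Category ids a single token counts toward under the matching rules."""
    literal, prefix = _build_matchers(lexicon)
    return _match_one(token, literal, prefix)


def score_text(
    tokens: Sequence[str], lexicon: Lexicon, doc_id: str = ""
) -> FeatureVector:
    """Score a token list against a lexicon.

    Each category's score is 100 x matched / total tokens.  A token
    matches a literal entry on equality and a prefix entry when the stem
    is a prefix of the token; when a literal entry and a prefix stem share
    the same pattern string and the token equals it, the literal wins.  A
    token may count toward several categories.  ``Sixltr`` (percentage of
    tokens longer than six letters) is always included.
    """
    if not lexicon.categories and not lexicon.entries:
        raise LexiconError("empty lexicon")
    literal, prefix = _build_matchers(lexicon)
    counts: dict[int, int] = {cid: 0 for cid, _ in lexicon.categories}
    n = len(tokens)
    long_words = 0
    for tok in tokens:
        if len(tok) > 6:
            long_words += 1
        for cid in _match_one(tok, literal, prefix):
            counts[cid] += 1
    if n == 0:
        values = {name: 0.0 for name in lexicon.category_names}
        values["Sixltr"] = 0.0
        return FeatureVector(doc_id=doc_id, word_count=0, values=values, degenerate=True)
    values = {name: 100.0 * counts[cid] / n for cid, name in lexicon.categories}
    values["Sixltr"] = 100.0 * long_words / n
    return FeatureVector(doc_id=doc_id, word_count=n, values=values)


def segment_text(
    tokens: Sequence[str], target: int = 250, parent_doc_id: str = ""
) -> list[Segment]:
    """Split tokens into consecutive chunks of ``target`` tokens.

    A final remainder shorter than ``target / 2`` is merged into the
    previous chunk (when one exists); otherwise it is kept as its own
    segment.  Concatenating the segments restores the token sequence.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    tokens = list(tokens)
    if not tokens:
        return []
    chunks = [tokens[i : i + target] for i in range(0, len(tokens), target)]
    if len(chunks) > 1 and len(chunks[-1]) < target / 2:
        tail = chunks.pop()
        chunks[-1] = chunks[-1] + tail
    return [
        Segment(parent_doc_id=parent_doc_id, segment_index=i, tokens=c)
        for i, c in enumerate(chunks)
    ]


def score_corpus(
    corpus_dir: str | Path,
    lexicon: Lexicon,
    segment: int | None = None,
) -> pd.DataFrame:
    """Score a corpus laid out as one directory per author, one .txt per document.

    Returns a feature table with columns ``doc_id, author, word_count``
    followed by the lexicon's variables.  With ``segment`` set, each
    document is split into ~``segment``-token chunks scored separately,
    with ``doc_id`` of the form ``<stem>#<index>`` and an extra
    ``parent_doc`` column.
    """
    corpus_dir = Path(corpus_dir)
    rows: list[dict] = []
    for author_dir in sorted(p for p in corpus_dir.iterdir() if p.is_dir()):
        for txt in sorted(author_dir.glob("*.txt")):
            tokens = tokenize(txt.read_text(encoding="utf-8"))
            if segment is None:
                fv = score_text(tokens, lexicon, doc_id=txt.stem)
                rows.append(
                    {"doc_id": fv.doc_id, "author": author_dir.name,
                     "word_count": fv.word_count, **fv.values}
                )
            else:
                for seg in segment_text(tokens, target=segment, parent_doc_id=txt.stem):
                    fv = score_text(seg.tokens, lexicon,
                                    doc_id=f"{txt.stem}#{seg.segment_index}")
                    rows.append(
                        {"doc_id": fv.doc_id, "author": author_dir.name,
                         "parent_doc": txt.stem, "word_count": fv.word_count,
                         **fv.values}
                    )
    if not rows:
        raise FileNotFoundError(f"no author/*.txt documents under {corpus_dir}")
    return pd.DataFrame(rows)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a documents x variables feature table (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "doc_id" not in df.columns:
        raise ValueError(f"{path}: feature table must have a doc_id column")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table; floats at 6 dp so tables round-trip exactly."""
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False,
              float_format=f"%.{FEATURE_FLOAT_DECIMALS}f")


def variable_columns(df: pd.DataFrame) -> list[str]:
    """Names of the variable (non-identifier) columns of a feature table."""
    skip = set(ID_COLUMNS) | {"parent_doc", "seg_id"}
    return [c for c in df.columns if c not in skip]
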