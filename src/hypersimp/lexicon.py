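"""Hypernym knowledge base with fuzzy character 3-gram term matching.

A lexicon maps lowercased terms (possibly multi-word) to candidate
hypernym phrases, each tagged with its source: a semantic-type label, a
lexical database ("wordnet"), or a custom entry. Term lookup from free
text goes through a character 3-gram TF-IDF index with cosine similarity,
so near-miss surface forms ("histamin") still resolve to their entry.

The TSV interchange format is::

    term<TAB>hypernym<TAB>source<TAB>semantic_type

with a mandatory header row; '#' lines are comments. This keeps licensed
terminology resources out of the package: any importer that emits this
format can feed the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

__all__ = [
    "SOURCE_TAGS",
    "LexiconError",
    "TermNotFoundError",
    "LexiconEntry",
    "HypernymLexicon",
    "CharNgramIndex",
    "load_lexicon",
    "build_lexicon",
    "write_lexicon",
    "build_ngram_index",
    "match_term",
    "select_hypernym",
    "char_ngrams",
]

SOURCE_TAGS = frozenset({"semantic_type", "wordnet", "custom"})

#: boundary padding: two marker characters per side, so 3-grams capture
#: one- and two-character prefixes/suffixes of the term.
_PAD = "##"
_N = 3


class LexiconError(ValueError):
    """Malformed lexicon input."""


class TermNotFoundError(KeyError):
    """A term was looked up that has no lexicon entry."""


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    hypernyms: tuple[tuple[str, str], ...]  # (hypernym_phrase, source_tag)
    semantic_type_label: str | None = None

    def __post_init__(self) -> None:
        if not self.hypernyms:
            raise LexiconError(f"entry {self.term!r} has no hypernym candidates")
        for phrase, source in self.hypernyms:
            if not phrase:
                raise LexiconError(f"entry {self.term!r} has an empty hypernym")
            if phrase.lower() == self.term:
                raise LexiconError(
                    f"entry {self.term!r}: hypernym equals its own term"
                )
            if source not in SOURCE_TAGS:
                raise LexiconError(
                    f"entry {self.term!r}: unknown source tag {source!r}"
                )


@dataclass(frozen=True)
class HypernymLexicon:
    entries: dict[str, LexiconEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.entries

    def __getitem__(self, term: str) -> LexiconEntry:
        try:
            return self.entries[term.lower()]
        except KeyError:
            raise TermNotFoundError(term) from None

    @property
    def terms(self) -> list[str]:
        return sorted(self.entries)


def build_lexicon(rows: Iterable[tuple[str, str, str, str]]) -> HypernymLexicon:
    """Build a lexicon from (term, hypernym, source, semantic_type) rows,
    collapsing duplicate (term, hypernym) pairs."""
    grouped: dict[str, list[tuple[str, str]]] = {}
    labels: dict[str, str | None] = {}
    for term, hypernym, source, semtype in rows:
        key = term.strip().lower()
        if not key:
            raise LexiconError("empty term")
        cand = (hypernym.strip(), source.strip())
        bucket = grouped.setdefault(key, [])
        if cand not in bucket:
            bucket.append(cand)
        if semtype.strip():
            labels.setdefault(key, semtype.strip())
    entries = {
        term: LexiconEntry(
            term=term,
            hypernyms=tuple(cands),
            semantic_type_label=labels.get(term),
        )
        for term, cands in grouped.items()
    }
    return HypernymLexicon(entries=entries)


_HEADER = ("term", "hypernym", "source", "semantic_type")


def load_lexicon(path: str | Path) -> HypernymLexicon:
    """Load the TSV lexicon format; errors name the offending line."""
    path = Path(path)
    rows: list[tuple[str, str, str, str]] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if not header_seen:
                if tuple(c.strip().lower() for c in cols) != _HEADER:
                    raise LexiconError(
                        f"{path}: line {lineno}: expected header "
                        f"'term\\thypernym\\tsource\\tsemantic_type'"
                    )
                header_seen = True
                continue
            if len(cols) != 4:
                raise LexiconError(
                    f"{path}: line {lineno}: expected 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            term, hypernym, source = (c.strip() for c in cols[:3])
            if not term:
                raise LexiconError(f"{path}: line {lineno}: empty term")
            if not hypernym:
                raise LexiconError(f"{path}: line {lineno}: empty hypernym")
            if hypernym.lower() == term.lower():
                raise LexiconError(
                    f"{path}: line {lineno}: hypernym equals its own term"
                )
            if source not in SOURCE_TAGS:
                raise LexiconError(
                    f"{path}: line {lineno}: unknown source tag {source!r}"
                )
            rows.append((cols[0], cols[1], cols[2], cols[3]))
    if not header_seen:
        raise LexiconError(f"{path}: empty lexicon file")
    if not rows:
        raise LexiconError(f"{path}: lexicon has a header but no entries")
    try:
        return build_lexicon(rows)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


def write_lexicon(lex: HypernymLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for term in lex.terms:
            entry = lex.entries[term]
            for phrase, source in entry.hypernyms:
                fh.write(
                    f"{term}\t{phrase}\t{source}\t{entry.semantic_type_label or ''}\n"
                )


# --------------------------------------------------------------------------
# Character 3-gram TF-IDF index
# --------------------------------------------------------------------------


def char_ngrams(s: str, n: int = _N) -> list[str]:
    """Padded character n-grams of a lowercased string; internal spaces of
    multi-word terms are retained."""
    padded = _PAD + s.lower() + _PAD
    return [padded[i : i + n] for i in range(len(padded) - n + 1)]


@dataclass(frozen=True)
class CharNgramIndex:
    """L2-normalized TF-IDF profiles over character 3-grams.

    Lexicon terms play the role of documents: IDF = ln(N/df). When every
    IDF is zero (a single-term lexicon, where TF-IDF degenerates to the
    zero vector) the index falls back to raw term-frequency profiles.
    """

    terms: tuple[str, ...]
    profiles: tuple[dict[str, float], ...] = field(repr=False)
    idf: dict[str, float] = field(repr=False)
    tf_fallback: bool = False

    def query_profile(self, query: str) -> dict[str, float]:
        """Profile for a free-text query under the index's weighting;
        grams unseen in the lexicon get zero weight (they cannot match)."""
        tf: dict[str, int] = {}
        for g in char_ngrams(query):
            tf[g] = tf.get(g, 0) + 1
        if self.tf_fallback:
            raw = {g: float(c) for g, c in tf.items()}
        else:
            raw = {
                g: c * self.idf[g] for g, c in tf.items() if self.idf.get(g, 0.0) > 0.0
            }
        return _l2_normalize(raw)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(self.terms),
                "profiles": [p for p in self.profiles],
                "idf": self.idf,
                "tf_fallback": self.tf_fallback,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CharNgramIndex":
        obj = json.loads(payload)
        return cls(
            terms=tuple(obj["terms"]),
            profiles=tuple(obj["profiles"]),
            idf=obj["idf"],
            tf_fallback=obj["tf_fallback"],
        )


def _l2_normalize(vec: dict[str, float]) -> dict[str, float]:
    norm = math.sqrt(sum(w * w for w in vec.values()))
    if norm == 0.0:
        return {}
    return {g: w / norm for g, w in vec.items()}


def build_ngram_index(lex: HypernymLexicon) -> CharNgramIndex:
    """Index every lexicon term by its padded character 3-gram profile."""
    if len(lex) == 0:
        raise LexiconError("cannot index an empty lexicon")
    terms = tuple(lex.terms)
    tfs: list[dict[str, int]] = []
    df: dict[str, int] = {}
    for term in terms:
        tf: dict[str, int] = {}
        for g in char_ngrams(term):
            tf[g] = tf.get(g, 0) + 1
        tfs.append(tf)
        for g in tf:
            df[g] = df.get(g, 0) + 1
    n = len(terms)
    idf = {g: math.log(n / d) for g, d in df.items()}
    tf_fallback = all(v == 0.0 for v in idf.values())
    profiles = []
    for tf in tfs:
        if tf_fallback:
            raw = {g: float(c) for g, c in tf.items()}
        else:
            raw = {g: c * idf[g] for g, c in tf.items() if idf[g] > 0.0}
        profiles.append(_l2_normalize(raw))
    return CharNgramIndex(
        terms=terms, profiles=tuple(profiles), idf=idf, tf_fallback=tf_fallback
    )


def _cosine(a: dict[str, float], b: dict[str, float]) -> float:
    if len(b) < len(a):
        a, b = b, a
    return sum(w * b.get(g, 0.0) for g, w in a.items())


def match_term(
    query: str,
    index: CharNgramIndex,
    k: int = 5,
    min_sim: float = 0.4,
) -> list[tuple[str, float]]:
    """Rank lexicon terms by cosine similarity to ``query``.

    Returns up to ``k`` terms with similarity >= ``min_sim``, in
    descending similarity; ties break lexicographically. A query sharing
    no indexed 3-gram with the lexicon yields an empty list.
    """
    if not query or not query.strip():
        raise ValueError("match_term requires a non-empty query")
    qp = index.query_profile(query)
    if not qp:
        return []
    scored = []
    for term, profile in zip(index.terms, index.profiles):
        sim = _cosine(qp, profile)
        if sim >= min_sim:
            scored.append((term, sim))
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored[:k]


def select_hypernym(
    term: str,
    lex: HypernymLexicon,
    counter: Callable[[str], int],
) -> str:
    """Choose the candidate hypernym with the fewest total syllables.

    Syllables are summed over the words of each candidate phrase with
    ``counter``; ties break by fewer characters, then lexicographically.
    Raises :class:`TermNotFoundError` for terms outside the lexicon.
    """
    entry = lex[term]

    def sort_key(cand: tuple[str, str]) -> tuple[int, int, str]:
        phrase = cand[0]
        syllables = sum(counter(w) for w in phrase.split())
        return (syllables, len(phrase), phrase)

    return min(entry.hypernyms, key=sort_key)[0]
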