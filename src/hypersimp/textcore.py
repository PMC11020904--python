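"""Deterministic text segmentation, tokenization and syllable counting.

Every readability formula downstream consumes the word / sentence /
character / syllable counts produced here, so the conventions are fixed
and documented rather than delegated to a linguistic toolkit:

* sentences are split on runs of terminal punctuation (``.``, ``!``, ``?``);
* word tokens are maximal alphanumeric runs, so hyphenated compounds
  ("non-covalently") split into separate word tokens and punctuation never
  enters a word count;
* syllables are counted as maximal vowel groups (``aeiouy``), minus one for
  a terminal silent "e" (unless that would leave zero), plus one for a
  terminal consonant+"le"; tokens without vowel letters (e.g. "h4") count
  as one syllable.

Published grade-level numbers for the same text can differ under other
tokenizer/syllabifier conventions; results from this module are only
comparable with themselves.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "EmptyTextError",
    "Token",
    "TokenizedText",
    "TextStats",
    "tokenize",
    "detokenize",
    "count_syllables",
    "text_stats",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]

_VOWELS = frozenset("aeiouy")
_WORD_RE = re.compile(r"[A-Za-z0-9]+")
# a sentence chunk ends at a run of terminal punctuation (or end of text)
_SENTENCE_END_RE = re.compile(r"[.!?]+")


class EmptyTextError(ValueError):
    """Raised when a text contains no word tokens."""


@dataclass(frozen=True)
class Token:
    """A word token with its position in the raw text."""

    text: str
    start: int  # character offset into raw_text, inclusive
    end: int  # exclusive
    sentence_index: int
    syllable_count: int

    @property
    def char_count(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class TokenizedText:
    """A definition segmented into sentences of word tokens.

    ``sentences`` holds the same Token objects as ``tokens``, grouped by
    sentence; punctuation is never tokenized, so every token is a word
    token and contributes to word counts.
    """

    raw_text: str
    sentences: tuple[tuple[Token, ...], ...]
    tokens: tuple[Token, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.tokens:
            object.__setattr__(
                self, "tokens", tuple(t for s in self.sentences for t in s)
            )

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class TextStats:
    """Aggregate counts feeding the readability formulas.

    ``n_chars`` counts letters+digits inside word tokens only;
    ``n_complex_words`` counts tokens with >= 3 syllables.
    """

    n_words: int
    n_sentences: int
    n_chars: int
    n_syllables: int
    n_complex_words: int

    def __add__(self, other: "TextStats") -> "TextStats":
        return TextStats(
            self.n_words + other.n_words,
            self.n_sentences + other.n_sentences,
            self.n_chars + other.n_chars,
            self.n_syllables + other.n_syllables,
            self.n_complex_words + other.n_complex_words,
        )


def count_syllables(word: str) -> int:
    """Count syllables of a single word token by vowel-group counting.

    Maximal runs of ``aeiouy`` each count one syllable; a terminal silent
    "e" is subtracted (unless that leaves zero) and a terminal
    consonant+"le" adds one back ("table" -> 2). Tokens without any vowel
    letter ("h4", "mm") count as 1. Digits contribute characters but no
    vowel groups.
    """
    w = word.lower()
    if not w:
        raise ValueError("count_syllables requires a non-empty token")
    groups = 0
    prev_vowel = False
    for ch in w:
        is_vowel = ch in _VOWELS
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    if groups == 0:
        return 1
    if w.endswith("e") and groups > 1:
        groups -= 1
    if len(w) >= 3 and w.endswith("le") and w[-3] not in _VOWELS:
        groups += 1
    return max(groups, 1)


def tokenize(text: str) -> TokenizedText:
    """Segment ``text`` into sentences of word tokens.

    Raises :class:`EmptyTextError` on empty/whitespace-only input or input
    with no alphanumeric content. Deterministic: the same raw text always
    yields an identical structure.
    """
    if text is None or not text.strip():
        raise EmptyTextError("input text is empty or whitespace-only")

    sentences: list[tuple[Token, ...]] = []
    cursor = 0
    chunks: list[tuple[int, int]] = []
    for m in _SENTENCE_END_RE.finditer(text):
        chunks.append((cursor, m.start()))
        cursor = m.end()
    if cursor < len(text):
        chunks.append((cursor, len(text)))

    for lo, hi in chunks:
        sent_tokens = []
        for wm in _WORD_RE.finditer(text, lo, hi):
            sent_tokens.append(
                Token(
                    text=wm.group(),
                    start=wm.start(),
                    end=wm.end(),
                    sentence_index=len(sentences),
                    syllable_count=count_syllables(wm.group()),
                )
            )
        if sent_tokens:
            sentences.append(tuple(sent_tokens))

    if not sentences:
        raise EmptyTextError("input text contains no word tokens")
    return TokenizedText(raw_text=text, sentences=tuple(sentences))


def detokenize(t: TokenizedText) -> str:
    """Render a canonical surface string: tokens joined by single spaces,
    each sentence terminated by a period."""
    return " ".join(" ".join(tok.text for tok in sent) + "." for sent in t.sentences)


def text_stats(t: TokenizedText) -> TextStats:
    """Aggregate a :class:`TokenizedText` into the counts the formulas use."""
    return TextStats(
        n_words=len(t.tokens),
        n_sentences=len(t.sentences),
        n_chars=sum(tok.char_count for tok in t.tokens),
        n_syllables=sum(tok.syllable_count for tok in t.tokens),
        n_complex_words=sum(1 for tok in t.tokens if tok.syllable_count >= 3),
    )


def read_corpus_jsonl(path: str | Path) -> list[dict]:
    """Read a JSONL corpus of ``{"id": ..., "text": ...}`` records."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: line {lineno}: invalid JSON ({exc})") from exc
            if "id" not in rec:
                raise ValueError(f"{path}: line {lineno}: record missing 'id'")
            records.append(rec)
    return records


def write_corpus_jsonl(records: Iterable[dict], path: str | Path) -> int:
    """Write records as JSONL; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            n += 1
    return n
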