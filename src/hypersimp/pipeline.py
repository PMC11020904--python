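"""The hypernym-substitution simplification method.

A definition is scanned for token spans that are simultaneously
*biomedical* (they fuzzy-match a lexicon term through the character
3-gram index) and *complex* (their maximum per-token complexity score
reaches the decision threshold, default 0.65). Each flagged span is
replaced by the matched term's fewest-syllable hypernym, with light
surface repairs (a/an agreement, sentence-initial capitalization).

The complexity scorer and the biomedical recognizer are pluggable: the
original method used a pretrained sequence-labeling complexity model and
a biomedical named-entity recognizer, which are external trained
artifacts. The package ships a deterministic default scorer (a
syllable/length heuristic with a common-word list) and a gazetteer
recognizer (lexicon membership via the fuzzy matcher); any callable
``word -> score in [0, 1]`` can stand in for the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .lexicon import (
    CharNgramIndex,
    HypernymLexicon,
    match_term,
    select_hypernym,
)
from .textcore import TokenizedText, count_syllables, tokenize

__all__ = [
    "DEFAULT_COMMON_WORDS",
    "PipelineConfig",
    "TargetSpan",
    "SubstitutionRecord",
    "SimplifiedText",
    "SimplifyRun",
    "OverlappingSpansError",
    "score_complexity",
    "identify_targets",
    "substitute",
    "simplify_corpus",
]

# 100 common English monosyllables. Serves two roles: the default scorer's
# common-word list (these always score 0.0) and the synthetic generator's
# filler vocabulary, keeping the simple/complex boundary crisp in tests.
DEFAULT_COMMON_WORDS: frozenset[str] = frozenset(
    """
    the of and a to in is it as at
    be by on or an if up so no do
    go we he she me my was for are with
    his they this from had not but what all were
    when can said there use each which how will that
    then them these some her him has have more one
    time two who did get may day our out new
    now old see way could than been call its long
    down side made part work first well such here take
    through much back good just know place year most still
    """.split()
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the simplification pipeline.

    ``threshold`` is the complexity-probability cutoff for flagging a word
    (default 0.65); ``min_sim`` the minimum 3-gram cosine for the
    biomedical gate; ``max_ngram`` caps candidate span length in tokens.
    """

    threshold: float = 0.65
    min_sim: float = 0.4
    top_k: int = 5
    max_ngram: int = 3
    common_words: frozenset[str] = DEFAULT_COMMON_WORDS

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not (0.0 <= self.min_sim <= 1.0):
            raise ValueError(f"min_sim must be in [0, 1], got {self.min_sim}")
        if self.max_ngram < 1:
            raise ValueError("max_ngram must be >= 1")


@dataclass(frozen=True)
class TargetSpan:
    """A flagged complex-and-biomedical token span (token indices are
    sentence-relative, half-open, 0-based)."""

    sentence_index: int
    token_start: int
    token_end: int
    surface: str
    complexity_score: float
    matched_term: str
    chosen_hypernym: str


@dataclass(frozen=True)
class SubstitutionRecord:
    """Provenance of one substitution, concrete enough to replay: applying
    all records (right-to-left) to the original text reproduces the
    output."""

    original_surface: str
    replacement: str
    repairs: tuple[str, ...]
    start: int  # character offsets into the original text
    end: int
    article_start: int | None = None
    article_end: int | None = None
    article_replacement: str | None = None


@dataclass(frozen=True)
class SimplifiedText:
    output_text: str
    substitutions: tuple[SubstitutionRecord, ...]


class OverlappingSpansError(ValueError):
    """Substitution requires sorted, non-overlapping spans."""


def score_complexity(word: str, config: PipelineConfig | None = None) -> float:
    """Deterministic default word-complexity score in [0, 1].

    Common words score 0; otherwise the score grows with syllable count
    and length: ``0.25 * max(0, syllables - 1) + 0.05 * max(0, length - 4)``,
    clamped to [0, 1].
    """
    cfg = config or PipelineConfig()
    w = word.lower()
    if w in cfg.common_words:
        return 0.0
    raw = 0.25 * max(0, count_syllables(w) - 1) + 0.05 * max(0, len(w) - 4)
    return min(1.0, max(0.0, raw))


def _find_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> int | None:
    """Offset of ``needle`` as a contiguous run inside ``haystack``, or None."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return None
    for off in range(n - m + 1):
        if list(haystack[off : off + m]) == list(needle):
            return off
    return None


def identify_targets(
    t: TokenizedText,
    lex: HypernymLexicon,
    index: CharNgramIndex,
    scorer: Callable[[str], float] | None = None,
    config: PipelineConfig | None = None,
) -> list[TargetSpan]:
    """Flag complex-and-biomedical spans and attach their hypernyms.

    Candidate spans are token n-grams up to ``max_ngram`` long, resolved
    longest-leftmost and non-overlapping. A candidate passes the
    biomedical gate when its fuzzy match into the lexicon reaches
    ``min_sim`` *and* the match is well-formed: either the matched term's
    tokens occur contiguously inside the candidate — the span then snaps
    to exactly those tokens, so a trigram around an exact term does not
    swallow its neighbors — or the candidate is a same-token-count fuzzy
    variant of the term (a misspelling). The resulting span passes the
    complexity gate when its maximum per-token score reaches
    ``threshold``.
    """
    cfg = config or PipelineConfig()
    if scorer is None:
        scorer = lambda w: score_complexity(w, cfg)  # noqa: E731

    spans: list[TargetSpan] = []
    for si, sent in enumerate(t.sentences):
        n = len(sent)
        i = 0
        while i < n:
            emitted = False
            for length in range(min(cfg.max_ngram, n - i), 0, -1):
                cand = sent[i : i + length]
                cand_lower = [tok.text.lower() for tok in cand]
                query = " ".join(cand_lower)
                matches = match_term(query, index, k=cfg.top_k, min_sim=cfg.min_sim)
                # take the best match whose span is well-formed: either the
                # term's tokens occur contiguously inside the candidate (the
                # span snaps to them), or the candidate is a pure fuzzy
                # variant with the same token count as the term
                term = None
                for cand_term, _sim in matches:
                    term_tokens = cand_term.split()
                    off = _find_subsequence(cand_lower, term_tokens)
                    if off is None:
                        # pure fuzzy variant: token counts must agree and the
                        # span must not edge on a common word (entities never
                        # start or end with an article/stopword)
                        if (
                            len(term_tokens) != length
                            or cand_lower[0] in cfg.common_words
                            or cand_lower[-1] in cfg.common_words
                        ):
                            continue
                    term = cand_term
                    break
                if term is None:
                    continue
                if off is None:
                    start, end = i, i + length
                else:
                    start = i + off
                    end = start + len(term.split())
                span_tokens = sent[start:end]
                score = max(scorer(tok.text) for tok in span_tokens)
                if score < cfg.threshold:
                    continue
                surface = t.raw_text[span_tokens[0].start : span_tokens[-1].end]
                spans.append(
                    TargetSpan(
                        sentence_index=si,
                        token_start=start,
                        token_end=end,
                        surface=surface,
                        complexity_score=score,
                        matched_term=term,
                        chosen_hypernym=select_hypernym(term, lex, count_syllables),
                    )
                )
                i = end
                emitted = True
                break
            if not emitted:
                i += 1
    return spans


def _capitalize(phrase: str) -> str:
    return phrase[0].upper() + phrase[1:] if phrase else phrase


def substitute(t: TokenizedText, spans: Sequence[TargetSpan]) -> SimplifiedText:
    """Replace each span with its hypernym, right-to-left, repairing the
    surface: a preceding "a"/"an" is re-agreed with the replacement's
    initial letter (case preserved) and sentence-initial capitalization is
    transferred. Raises :class:`OverlappingSpansError` on overlap.
    """
    ordered = sorted(spans, key=lambda sp: (sp.sentence_index, sp.token_start))
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.sentence_index == nxt.sentence_index and nxt.token_start < prev.token_end:
            raise OverlappingSpansError(
                f"spans {prev.token_start}:{prev.token_end} and "
                f"{nxt.token_start}:{nxt.token_end} overlap in sentence "
                f"{prev.sentence_index}"
            )

    records: list[SubstitutionRecord] = []
    for sp in ordered:
        sent = t.sentences[sp.sentence_index]
        first_tok, last_tok = sent[sp.token_start], sent[sp.token_end - 1]
        start, end = first_tok.start, last_tok.end
        replacement = sp.chosen_hypernym
        repairs: list[str] = []

        if sp.token_start == 0 and sp.surface[:1].isupper():
            replacement = _capitalize(replacement)
            repairs.append("capitalize")

        art_start = art_end = None
        art_repl = None
        if sp.token_start > 0:
            prev_tok = sent[sp.token_start - 1]
            if prev_tok.text.lower() in ("a", "an"):
                desired = "an" if replacement[:1].lower() in "aeiou" else "a"
                if prev_tok.text.lower() != desired:
                    art_repl = (
                        _capitalize(desired)
                        if prev_tok.text[:1].isupper()
                        else desired
                    )
                    art_start, art_end = prev_tok.start, prev_tok.end
                    repairs.append("article")

        records.append(
            SubstitutionRecord(
                original_surface=sp.surface,
                replacement=replacement,
                repairs=tuple(repairs),
                start=start,
                end=end,
                article_start=art_start,
                article_end=art_end,
                article_replacement=art_repl,
            )
        )

    out = t.raw_text
    for rec in reversed(records):
        out = out[: rec.start] + rec.replacement + out[rec.end :]
        if rec.article_start is not None:
            out = (
                out[: rec.article_start]
                + rec.article_replacement
                + out[rec.article_end :]
            )
    return SimplifiedText(output_text=out, substitutions=tuple(records))


@dataclass(frozen=True)
class SimplifyRun:
    """Corpus-level result: per-definition outputs, a failure log (records
    are never silently dropped), and summary counts."""

    results: tuple[dict, ...]
    failures: tuple[dict, ...]

    @property
    def summary(self) -> dict:
        return {
            "n_input": len(self.results) + len(self.failures),
            "n_output": len(self.results),
            "n_failed": len(self.failures),
            "n_substitutions": sum(len(r["substitutions"]) for r in self.results),
        }


def simplify_corpus(
    corpus: Iterable[dict],
    lex: HypernymLexicon,
    index: CharNgramIndex,
    config: PipelineConfig | None = None,
    scorer: Callable[[str], float] | None = None,
) -> SimplifyRun:
    """Run the pipeline over JSONL-style records ``{"id", "text"}``.

    Per-record failures (malformed records, empty text) are logged with
    their reason; successes carry full substitution provenance.
    """
    cfg = config or PipelineConfig()
    results: list[dict] = []
    failures: list[dict] = []
    for rec in corpus:
        rid = rec.get("id")
        try:
            text = rec.get("text")
            if not isinstance(text, str):
                raise ValueError("record has no usable 'text' field")
            t = tokenize(text)
            spans = identify_targets(t, lex, index, scorer=scorer, config=cfg)
            simplified = substitute(t, spans)
            results.append(
                {
                    "id": rid,
                    "text": simplified.output_text,
                    "substitutions": [
                        {
                            "from": r.original_surface,
                            "to": r.replacement,
                            "repairs": list(r.repairs),
                        }
                        for r in simplified.substitutions
                    ],
                }
            )
        except Exception as exc:  # per-record isolation is the contract
            failures.append({"id": rid, "reason": f"{type(exc).__name__}: {exc}"})
    return SimplifyRun(results=tuple(results), failures=tuple(failures))
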