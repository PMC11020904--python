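"""Seeded generators for definition-like corpora, matched hypernym
lexicons, dependency-parse fixtures and rating tables.

The generator emulates the *shape* of short biomedical definitions
(about 3 sentences and 31 words per definition) without any licensed
terminology resource: pseudo-biomedical complex terms are built by
consonant-vowel syllable concatenation and embedded among common
monosyllabic filler words, and every complex term gets a lexicon entry
whose hypernym has a controlled, strictly smaller syllable count. That
construction makes the expected direction of every readability delta
algebraically checkable, which is what the fixtures are for — the
generated text is not meaningful medical language.

Generated words use only the vowels a/i/o/u and always start syllables
with a consonant, so the vowel-group syllable counter recovers the
constructed syllable count exactly (no silent-e or terminal-le edge
cases).

Each artifact (term pool, corpus, failure injection, trees) draws from
its own RNG stream spawned from the master seed, so adding one fixture
never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import HypernymLexicon, build_lexicon
from .pipeline import DEFAULT_COMMON_WORDS

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "ConlluFixture",
    "FILLER_WORDS",
    "gen_corpus",
    "gen_conllu",
    "sample_corpus",
]

#: filler vocabulary: the default scorer's common-word list, sorted for
#: deterministic indexing.
FILLER_WORDS: tuple[str, ...] = tuple(sorted(DEFAULT_COMMON_WORDS))

_TERM_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aiou"
_SEMANTIC_TYPES = (
    "Process", "Substance", "Structure", "Finding", "Disorder", "Function",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic corpus.

    Defaults target the characteristic shape of short curated biomedical
    definitions: ~3 sentences and ~31 words per definition.
    ``complex_term_density`` is the per-word probability of emitting a
    complex term (default 0.25, several terms per definition — definition
    text is jargon-dense); ``hypernym_syllable_gap`` is how many syllables
    each hypernym saves over its term (default 1, the classic
    lymphoma→cancer reduction).
    """

    seed: int = 0
    n_definitions: int = 100
    mean_sentences: float = 3.0
    mean_words_per_sentence: float = 10.0
    complex_term_density: float = 0.25
    hypernym_syllable_gap: int = 1
    failure_injection_rate: float = 0.0
    n_terms: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.complex_term_density <= 1.0):
            raise ValueError("complex_term_density must be in [0, 1]")
        if not (0.0 <= self.failure_injection_rate <= 1.0):
            raise ValueError("failure_injection_rate must be in [0, 1]")
        if self.mean_sentences < 1 or self.mean_words_per_sentence < 1:
            raise ValueError("means must be >= 1")
        if self.hypernym_syllable_gap < 1:
            raise ValueError("hypernym_syllable_gap must be >= 1")
        if self.n_definitions < 1 or self.n_terms < 1:
            raise ValueError("n_definitions and n_terms must be >= 1")


@dataclass(frozen=True)
class SyntheticCorpus:
    records: tuple[dict, ...]  # {"id", "text"}; injected failures have text ""
    lexicon: HypernymLexicon
    term_syllables: dict[str, int]  # constructed syllable count per term
    hypernym_of: dict[str, str]  # the designed fewest-syllable hypernym
    failed_ids: tuple[str, ...]


def _make_word(rng: np.random.Generator, n_syllables: int, cvc: bool) -> str:
    """A pronounceable pseudo-word of exactly ``n_syllables`` vowel groups."""
    parts = []
    for _ in range(n_syllables):
        c1 = _TERM_CONSONANTS[rng.integers(len(_TERM_CONSONANTS))]
        v = _VOWELS[rng.integers(len(_VOWELS))]
        if cvc:
            c2 = _TERM_CONSONANTS[rng.integers(len(_TERM_CONSONANTS))]
            parts.append(c1 + v + c2)
        else:
            parts.append(c1 + v)
    return "".join(parts)


def _build_term_pool(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[dict[str, int], dict[str, str], list[tuple[str, str, str, str]]]:
    """Complex terms (3-6 CVC syllables, all above the default complexity
    gate) with hypernyms of ``syllables - gap`` CV syllables (floored at 1)."""
    term_syllables: dict[str, int] = {}
    hypernym_of: dict[str, str] = {}
    rows: list[tuple[str, str, str, str]] = []
    used: set[str] = set(FILLER_WORDS)
    while len(term_syllables) < cfg.n_terms:
        s = int(rng.integers(3, 7))
        term = _make_word(rng, s, cvc=True)
        if term in used:
            continue
        s_h = max(1, s - cfg.hypernym_syllable_gap)
        hypernym = _make_word(rng, s_h, cvc=False)
        if hypernym in used or hypernym == term:
            continue
        used.update({term, hypernym})
        term_syllables[term] = s
        hypernym_of[term] = hypernym
        semtype = _SEMANTIC_TYPES[rng.integers(len(_SEMANTIC_TYPES))]
        rows.append((term, hypernym, "semantic_type", semtype))
        # some terms get a longer wordnet alternative, exercising the
        # fewest-syllable selection without changing the designed choice
        if rng.random() < 0.3:
            alt = _make_word(rng, s_h + 1, cvc=False)
            if alt not in used and alt != term:
                used.add(alt)
                rows.append((term, alt, "wordnet", semtype))
    return term_syllables, hypernym_of, rows


def gen_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Generate a definition corpus and its matched hypernym lexicon.

    Deterministic under ``cfg.seed``. Exactly
    ``ceil(failure_injection_rate * n_definitions)`` records are malformed
    (empty text) to emulate per-definition processing loss.
    """
    ss = np.random.SeedSequence(cfg.seed)
    term_rng, corpus_rng, fail_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    term_syllables, hypernym_of, rows = _build_term_pool(term_rng, cfg)
    lexicon = build_lexicon(rows)
    terms = list(term_syllables)

    records: list[dict] = []
    for i in range(cfg.n_definitions):
        n_sent = max(1, int(corpus_rng.poisson(cfg.mean_sentences)))
        sentences = []
        for _ in range(n_sent):
            n_words = max(3, int(corpus_rng.poisson(cfg.mean_words_per_sentence)))
            words = []
            for _ in range(n_words):
                if corpus_rng.random() < cfg.complex_term_density:
                    words.append(terms[corpus_rng.integers(len(terms))])
                else:
                    words.append(FILLER_WORDS[corpus_rng.integers(len(FILLER_WORDS))])
            words[0] = words[0][0].upper() + words[0][1:]
            sentences.append(" ".join(words) + ".")
        records.append({"id": f"def-{i:04d}", "text": " ".join(sentences)})

    n_fail = math.ceil(cfg.failure_injection_rate * cfg.n_definitions)
    failed_ids: tuple[str, ...] = ()
    if n_fail > 0:
        fail_idx = fail_rng.choice(cfg.n_definitions, size=n_fail, replace=False)
        for i in sorted(fail_idx):
            records[i] = {"id": records[i]["id"], "text": ""}
        failed_ids = tuple(records[i]["id"] for i in sorted(fail_idx))

    return SyntheticCorpus(
        records=tuple(records),
        lexicon=lexicon,
        term_syllables=term_syllables,
        hypernym_of=hypernym_of,
        failed_ids=failed_ids,
    )


# --------------------------------------------------------------------------
# Dependency-parse fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConlluFixture:
    """CoNLL-U text with sidecar ground-truth MDD values computed directly
    from the generated arcs (independently of any parser/reader)."""

    conllu: str
    true_mdd: dict[str, float]  # per newdoc id, pooled over its sentences


def _random_projective_tree(
    rng: np.random.Generator, lo: int, hi: int
) -> tuple[int, list[tuple[int, int]]]:
    """Random projective tree over positions lo..hi (inclusive, 1-based).

    Returns (subtree head, arcs as (head, dependent)); each side of the
    chosen head is an independent projective subtree attached to it.
    """
    h = int(rng.integers(lo, hi + 1))
    arcs: list[tuple[int, int]] = []
    if lo <= h - 1:
        lh, larcs = _random_projective_tree(rng, lo, h - 1)
        arcs.extend(larcs)
        arcs.append((h, lh))
    if h + 1 <= hi:
        rh, rarcs = _random_projective_tree(rng, h + 1, hi)
        arcs.extend(rarcs)
        arcs.append((h, rh))
    return h, arcs


def gen_conllu(cfg: GeneratorConfig) -> ConlluFixture:
    """Random projective dependency trees over filler-word sentences.

    Each definition becomes a ``# newdoc`` block; every sentence gets a
    trailing period token tagged PUNCT and attached to the root word, so
    readers must honor the punctuation exclusion to reproduce the sidecar
    values.
    """
    ss = np.random.SeedSequence(cfg.seed)
    tree_rng = np.random.default_rng(ss.spawn(4)[3])
    lines: list[str] = []
    true_mdd: dict[str, float] = {}
    for i in range(cfg.n_definitions):
        doc_id = f"def-{i:04d}"
        lines.append(f"# newdoc id = {doc_id}")
        n_sent = max(1, int(tree_rng.poisson(cfg.mean_sentences)))
        distances: list[int] = []
        for _ in range(n_sent):
            n_tok = max(2, int(tree_rng.poisson(cfg.mean_words_per_sentence)))
            root, arcs = _random_projective_tree(tree_rng, 1, n_tok)
            head_of = {dep: head for head, dep in arcs}
            head_of[root] = 0
            distances.extend(abs(h - d) for h, d in arcs)
            for pos in range(1, n_tok + 1):
                form = FILLER_WORDS[tree_rng.integers(len(FILLER_WORDS))]
                rel = "root" if pos == root else "dep"
                lines.append(
                    f"{pos}\t{form}\t_\tX\t_\t_\t{head_of[pos]}\t{rel}\t_\t_"
                )
            lines.append(f"{n_tok + 1}\t.\t_\tPUNCT\t_\t_\t{root}\tpunct\t_\t_")
            lines.append("")
        true_mdd[doc_id] = sum(distances) / len(distances)
    return ConlluFixture(conllu="\n".join(lines) + "\n", true_mdd=true_mdd)


def sample_corpus(
    corpus: Sequence[dict],
    n: int,
    seed: int,
    exclude_ids: set | None = None,
) -> list[dict]:
    """Uniform sample of ``n`` records without replacement, optionally
    excluding ids (e.g. records already used for training)."""
    pool = [
        rec for rec in corpus if not (exclude_ids and rec.get("id") in exclude_ids)
    ]
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from {len(pool)} available records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]
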