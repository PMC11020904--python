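"""Text-complexity measures: FKS, FKG, ARI, GFI, MTLD and MDD.

Four classic readability formulas operate on :class:`~hypersimp.textcore.TextStats`
aggregates; two sentence-complexity measures operate on the token sequence
(MTLD) and on dependency parses (MDD). Readability is always computed per
definition, never on pooled corpus counts, so that paired pre/post deltas
are well defined.

Undefined values (e.g. MTLD on an all-distinct sequence, MDD with no
qualifying arc) are represented by ``value=None`` in :class:`MetricResult`,
not by NaN, and are excluded from corpus means with an exclusion count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .textcore import TextStats, text_stats, tokenize

__all__ = [
    "MetricResult",
    "Arc",
    "SentenceParse",
    "DependencyGraph",
    "fks",
    "fkg",
    "ari",
    "gfi",
    "mtld",
    "mdd",
    "read_conllu",
    "read_conllu_documents",
    "definition_metrics",
    "round_grade",
    "MTLD_TTR_THRESHOLD",
]

#: type-token-ratio threshold at which an MTLD factor completes (the
#: standard published parameterization).
MTLD_TTR_THRESHOLD = 0.72


@dataclass(frozen=True)
class MetricResult:
    """A metric value with the number of units (tokens or arcs) it used.

    ``value`` is ``None`` when the metric is undefined on the input. FKS is
    reported on its nominal 0-100 scale but never clamped: the formula may
    exceed either bound on extreme inputs.
    """

    metric_name: str  # one of FKS, FKG, ARI, GFI, MTLD, MDD
    value: float | None
    n_units: int


# --------------------------------------------------------------------------
# Readability formulas
# --------------------------------------------------------------------------


def fks(s: TextStats) -> MetricResult:
    """Flesch-Kincaid Reading Ease: higher is easier (nominal 0-100)."""
    if s.n_words < 1 or s.n_sentences < 1:
        return MetricResult("FKS", None, 0)
    value = (
        206.835
        - 1.015 * (s.n_words / s.n_sentences)
        - 84.6 * (s.n_syllables / s.n_words)
    )
    return MetricResult("FKS", value, s.n_words)


def fkg(s: TextStats) -> MetricResult:
    """Flesch-Kincaid Grade Level: estimated US school grade."""
    if s.n_words < 1 or s.n_sentences < 1:
        return MetricResult("FKG", None, 0)
    value = (
        0.39 * (s.n_words / s.n_sentences)
        + 11.8 * (s.n_syllables / s.n_words)
        - 15.59
    )
    return MetricResult("FKG", value, s.n_words)


def ari(s: TextStats) -> MetricResult:
    """Automated Readability Index: grade estimate from characters/word
    and words/sentence."""
    if s.n_words < 1 or s.n_sentences < 1:
        return MetricResult("ARI", None, 0)
    value = (
        4.71 * (s.n_chars / s.n_words)
        + 0.5 * (s.n_words / s.n_sentences)
        - 21.43
    )
    return MetricResult("ARI", value, s.n_words)


def gfi(s: TextStats) -> MetricResult:
    """Gunning Fog Index: years of formal education, driven by the
    fraction of words with >= 3 syllables."""
    if s.n_words < 1 or s.n_sentences < 1:
        return MetricResult("GFI", None, 0)
    value = 0.4 * (
        (s.n_words / s.n_sentences) + 100.0 * (s.n_complex_words / s.n_words)
    )
    return MetricResult("GFI", value, s.n_words)


def round_grade(value: float) -> int:
    """Half-up rounding for grade-level display (3.5 -> 4)."""
    import math

    return math.floor(value + 0.5)


# --------------------------------------------------------------------------
# MTLD
# --------------------------------------------------------------------------


def _mtld_one_direction(tokens: Sequence[str], threshold: float) -> float:
    """Factor count for one scan direction; 0.0 means no factor accrued."""
    factors = 0.0
    types: set[str] = set()
    n_in_factor = 0
    ttr = 1.0
    for tok in tokens:
        types.add(tok)
        n_in_factor += 1
        ttr = len(types) / n_in_factor
        if ttr < threshold:
            factors += 1.0
            types.clear()
            n_in_factor = 0
            ttr = 1.0
    if n_in_factor > 0 and ttr < 1.0:
        factors += (1.0 - ttr) / (1.0 - threshold)
    return factors


def mtld(tokens: Sequence[str], threshold: float = MTLD_TTR_THRESHOLD) -> MetricResult:
    """Measure of Textual Lexical Diversity (bidirectional).

    Scans the lowercased token sequence accumulating a running type-token
    ratio; each time the TTR drops below ``threshold`` a factor completes
    and the scan resets. A trailing partial factor contributes
    ``(1 - TTR)/(1 - threshold)``. The score is ``n_tokens / factors``,
    averaged over the forward and reverse passes. With zero factors in
    both directions (e.g. all-distinct tokens) the measure is undefined.
    """
    if not tokens:
        raise ValueError("mtld requires at least one token")
    toks = [t.lower() for t in tokens]
    n = len(toks)
    fwd = _mtld_one_direction(toks, threshold)
    rev = _mtld_one_direction(toks[::-1], threshold)
    if fwd == 0.0 and rev == 0.0:
        return MetricResult("MTLD", None, n)
    vals = []
    if fwd > 0.0:
        vals.append(n / fwd)
    if rev > 0.0:
        vals.append(n / rev)
    return MetricResult("MTLD", sum(vals) / len(vals), n)


# --------------------------------------------------------------------------
# Dependency parses and MDD
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Arc:
    head: int  # 1-based position; 0 for the root arc
    dependent: int  # 1-based position
    relation: str


@dataclass(frozen=True)
class SentenceParse:
    forms: tuple[str, ...]
    upos: tuple[str, ...]
    arcs: tuple[Arc, ...]

    def __post_init__(self) -> None:
        n = len(self.forms)
        roots = 0
        for a in self.arcs:
            if not (0 <= a.head <= n) or not (1 <= a.dependent <= n):
                raise ValueError(
                    f"arc ({a.head}->{a.dependent}) out of bounds for {n} tokens"
                )
            if a.head == 0:
                roots += 1
        if self.arcs and roots != 1:
            raise ValueError(f"expected exactly one root arc, found {roots}")


@dataclass(frozen=True)
class DependencyGraph:
    """Dependency parses for the sentences of one definition."""

    sentences: tuple[SentenceParse, ...]


def mdd(g: DependencyGraph) -> MetricResult:
    """Mean Dependency Distance: mean |head - dependent| position gap,
    pooled over all sentences of the definition.

    Root arcs and arcs whose dependent is tagged ``PUNCT`` are excluded;
    with no qualifying arc the measure is undefined. Relation labels do
    not influence the value.
    """
    distances = []
    for sent in g.sentences:
        for a in sent.arcs:
            if a.head == 0:
                continue
            if sent.upos[a.dependent - 1] == "PUNCT":
                continue
            distances.append(abs(a.head - a.dependent))
    if not distances:
        return MetricResult("MDD", None, 0)
    return MetricResult("MDD", sum(distances) / len(distances), len(distances))


_ID_SKIP_RE = re.compile(r"^\d+[-.]\d+$")  # multiword-token and empty-node lines


def _parse_conllu_sentence(lines: list[str], where: str) -> SentenceParse:
    forms, upos, heads, rels = [], [], [], []
    for line in lines:
        cols = line.split("\t")
        if len(cols) != 10:
            raise ValueError(f"{where}: expected 10 tab-separated columns: {line!r}")
        if _ID_SKIP_RE.match(cols[0]):
            continue
        forms.append(cols[1])
        upos.append(cols[3])
        heads.append(int(cols[6]))
        rels.append(cols[7])
    arcs = tuple(
        Arc(head=h, dependent=i + 1, relation=r)
        for i, (h, r) in enumerate(zip(heads, rels))
    )
    return SentenceParse(forms=tuple(forms), upos=tuple(upos), arcs=arcs)


def read_conllu(path: str | Path) -> DependencyGraph:
    """Read a CoNLL-U file as one :class:`DependencyGraph` (all sentences
    pooled into a single document)."""
    docs = read_conllu_documents(path)
    sentences = tuple(s for g in docs.values() for s in g.sentences)
    return DependencyGraph(sentences=sentences)


def read_conllu_documents(path: str | Path) -> dict[str, DependencyGraph]:
    """Read a CoNLL-U file grouped into documents by ``# newdoc id = X``
    comments; files without newdoc markers yield one document ``"_all"``.
    """
    path = Path(path)
    docs: dict[str, list[SentenceParse]] = {}
    current_doc = "_all"
    sent_lines: list[str] = []
    n_sent = 0

    def flush() -> None:
        nonlocal sent_lines, n_sent
        if sent_lines:
            n_sent += 1
            docs.setdefault(current_doc, []).append(
                _parse_conllu_sentence(sent_lines, f"{path}: sentence {n_sent}")
            )
            sent_lines = []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*newdoc\s+id\s*=\s*(\S+)", line)
                if m:
                    flush()
                    current_doc = m.group(1)
                    docs.setdefault(current_doc, [])
                continue
            sent_lines.append(line)
        flush()
    if not docs:
        raise ValueError(f"{path}: no sentences found")
    return {doc: DependencyGraph(sentences=tuple(sents)) for doc, sents in docs.items()}


# --------------------------------------------------------------------------
# Per-definition convenience
# --------------------------------------------------------------------------


def definition_metrics(text: str, graph: DependencyGraph | None = None) -> dict[str, MetricResult]:
    """Compute all applicable metrics for one definition text.

    MDD is included only when a dependency parse is supplied.
    """
    t = tokenize(text)
    s = text_stats(t)
    out = {
        "FKS": fks(s),
        "FKG": fkg(s),
        "ARI": ari(s),
        "GFI": gfi(s),
        "MTLD": mtld([tok.text for tok in t.tokens]),
    }
    if graph is not None:
        out["MDD"] = mdd(graph)
    return out
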