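# hypersimp

Lexical simplification of biomedical text by **hypernym substitution**,
with a complete readability evaluation harness.

Short biomedical definitions — the kind curated in clinical
terminologies — are written at a reading level far above what most
patients can use. One transparent, auditable way to simplify them is to
replace a complex biomedical term with its *hypernym*, a superordinate
umbrella term: "lymphoma is a type of cancer", so "Lymphoma was found"
becomes "Cancer was found". `hypersimp` implements that method
end-to-end for anyone studying text simplification for health literacy:

- a pipeline that flags token spans that are simultaneously *complex*
  (a pluggable word-complexity scorer with decision threshold 0.65) and
  *biomedical* (fuzzy lookup into a hypernym lexicon via character
  3-gram TF-IDF cosine matching), substitutes the fewest-syllable
  hypernym, and repairs a/an agreement and capitalization;
- the six text-complexity measures used to benchmark it: Flesch-Kincaid
  Reading Ease (FKS) and Grade (FKG), Automated Readability Index (ARI),
  Gunning Fog Index (GFI), the Measure of Textual Lexical Diversity
  (MTLD, bidirectional, TTR threshold 0.72), and Mean Dependency
  Distance (MDD) over CoNLL-U parses;
- evaluation statistics: per-definition paired deltas with IQRs and
  bootstrap CIs, two-sided Wilcoxon signed-rank tests (exact by full
  sign enumeration for n ≤ 25), Cohen's kappa with agreement bands, and
  pairwise Likert rating comparisons;
- a seeded synthetic generator that emulates the shape of definition
  corpora (~3 sentences, ~31 words per definition) with matched
  lexicons, dependency trees with ground-truth MDD sidecars, and
  controlled failure injection — so the whole method is testable
  without licensed terminology resources or trained models.

The formulas, in the standard notation (W words, S sentences,
Y syllables, C characters, X words with ≥ 3 syllables):

    FKS = 206.835 − 1.015 (W/S) − 84.6 (Y/W)
    FKG = 0.39 (W/S) + 11.8 (Y/W) − 15.59
    ARI = 4.71 (C/W) + 0.5 (W/S) − 21.43
    GFI = 0.4 ((W/S) + 100 X/W)

See `docs/methods.md` for the tokenization/syllable conventions these
are computed under, and every other methodological choice.

## Worked example

```python
from hypersimp import tokenize, text_stats, fks, fkg, ari, gfi
from hypersimp.lexicon import build_lexicon, build_ngram_index
from hypersimp.pipeline import identify_targets, substitute

text = "Interacting selectively and non-covalently with a h4 histamine receptor."
lex = build_lexicon([
    ("histamine receptor", "organ", "semantic_type", "Structure"),
    ("lymphoma", "cancer", "wordnet", ""),
])
index = build_ngram_index(lex)

t = tokenize(text)
spans = identify_targets(t, lex, index)     # complex AND biomedical spans
out = substitute(t, spans)
print(out.output_text)
for name, m in [("FKS", fks), ("FKG", fkg), ("ARI", ari), ("GFI", gfi)]:
    pre = m(text_stats(tokenize(text))).value
    post = m(text_stats(tokenize(out.output_text))).value
    print(f"{name}: {pre:.2f} -> {post:.2f}")
```

prints

```
Interacting selectively and non-covalently with a h4 organ.
FKS: -6.35 -> 9.70
FKG: 16.63 -> 14.14
ARI: 12.77 -> 9.24
GFI: 24.00 -> 16.93
```

"histamine receptor" is the only span that passes both gates (its
tokens score 0.75 and 0.70 against the 0.65 threshold, and the phrase
matches the lexicon exactly); replacing it with "organ" raises the
reading-ease score by 16 points and drops every grade-level estimate —
FKG by 2.5 grades, GFI by 7 — because the text now has three fewer
syllables and eleven fewer characters in the same number of words.

## Command line

```sh
hypersimp simplify  --lexicon lexicon.tsv --input corpus.jsonl --output post.jsonl
hypersimp evaluate  --pre corpus.jsonl --post post.jsonl --output report \
                    --conllu-pre pre.conllu --conllu-post post.conllu
hypersimp benchmark --seed 17 --n 200 --outdir bench/
hypersimp kappa     --ratings ratings.csv
```

Corpora are JSONL (`{"id", "text"}`); lexicons are TSV
(`term  hypernym  source  semantic_type`, `#` comments allowed); parses
are CoNLL-U grouped by `# newdoc id =` comments; ratings are CSV
(`id, rater, system, metric, score` with Likert scores 1–5). Every
command is deterministic under a fixed seed; per-record failures go to
a failure log, never abort a run.

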