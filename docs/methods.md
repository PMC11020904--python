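# Methods

## The simplification method

`hypersimp` implements lexical simplification of short biomedical
definitions by hypernym substitution: a word or phrase that is both
*complex* and *biomedical* is replaced by a superordinate term
("lymphoma" → "cancer"), trading specificity for readability.

The pipeline runs per definition:

1. **Candidate spans.** Token n-grams up to 3 tokens long are scanned
   longest-leftmost within each sentence, non-overlapping.
2. **Biomedical gate.** A candidate passes when it fuzzy-matches a
   lexicon term: its padded character 3-gram TF-IDF profile has cosine
   similarity ≥ `min_sim` (default 0.4) with the term's profile. Two
   well-formedness rules keep fuzzy matching from swallowing context:
   if the matched term's tokens occur contiguously inside the candidate,
   the span *snaps* to exactly those tokens; otherwise the candidate is
   accepted only when it has the same token count as the matched term
   and does not start or end with a common word (entity spans never edge
   on an article or stopword).
3. **Complexity gate.** The span's maximum per-token complexity score
   must reach `threshold` (default 0.65). The original method used a
   pretrained sequence-labeling complexity model; such a model is an
   external trained artifact, so the scorer is a pluggable callable
   `word -> [0, 1]`. The shipped default is deterministic:
   `0` for words on a 100-word common-monosyllable list, else
   `clamp(0.25·max(0, syllables−1) + 0.05·max(0, length−4))`.
   Taking the span *maximum* favors recall, consistent with a
   sensitivity-driven threshold choice.
4. **Hypernym selection.** Among all candidate hypernym phrases for the
   matched term (semantic-type labels, lexical-database entries, custom
   rows), the one with the fewest total syllables wins; ties break by
   fewer characters, then lexicographically. Candidate phrases are
   compared directly; no hypernym-chain traversal is attempted.
5. **Substitution and repair.** Spans are replaced right-to-left on
   character offsets, so recorded provenance replays exactly. Repairs
   are deliberately minimal — a preceding "a/an" is re-agreed with the
   replacement's initial letter (case preserved) and sentence-initial
   capitalization is transferred. No verb re-inflection or determiner
   insertion is attempted: programmatic hypernym substitution
   characteristically leaves such artifacts, and the evaluation is
   designed around the surface operation actually performed.

Per-definition failures (empty or malformed records) are logged with a
reason and never abort the corpus run; evaluation aligns on the
surviving intersection and reports every drop.

## Text conventions

The readability formulas are only comparable under fixed tokenization
and syllabification conventions, so these are pinned rather than
delegated:

- sentences split on runs of `.` `!` `?`; no abbreviation handling
  (definitions are short, fixtures avoid ambiguous periods);
- word tokens are maximal alphanumeric runs; hyphenated compounds split;
  punctuation never counts as a word;
- syllables = maximal `aeiouy` runs, − 1 for terminal silent "e" (unless
  that leaves 0), + 1 for terminal consonant+"le", floor 1; vowel-free
  tokens ("h4") count 1; digits contribute characters but no vowel
  groups.

Published grade levels for the same text computed under other
conventions (different syllabifiers, abbreviation-aware splitters) will
differ; all pre/post comparisons here use the same conventions on both
sides, which is what makes the paired deltas meaningful.

## Metrics

Per definition (never pooled over the corpus):

- **FKS** `206.835 − 1.015·(W/S) − 84.6·(Y/W)` — reported on its nominal
  0–100 scale, not clamped.
- **FKG** `0.39·(W/S) + 11.8·(Y/W) − 15.59`
- **ARI** `4.71·(C/W) + 0.5·(W/S) − 21.43`
- **GFI** `0.4·((W/S) + 100·(X/W))`, X = words with ≥ 3 syllables

with W words, S sentences, Y syllables, C in-token characters. Grades
are reported unrounded; `round_grade` (half-up) exists for display.

- **MTLD** is bidirectional with the standard TTR threshold 0.72: factors
  complete when the running type–token ratio of the lowercased sequence
  drops below 0.72, a trailing partial factor adds `(1−TTR)/(1−0.72)`,
  the score is tokens/factors averaged over forward and reverse passes.
  Zero factors (e.g. an all-distinct sequence) yields *undefined*, not
  infinity; undefined values are excluded from corpus means with the
  exclusion counted.
- **MDD** is the mean |head − dependent| position gap pooled over all
  sentences of a definition (pooling is robust to one-arc sentences,
  unlike a mean of sentence means), excluding the root arc and arcs
  whose dependent is tagged `PUNCT`. Parses arrive as standard CoNLL-U
  (column 7 = head, column 4 = UPOS); the package bundles no parser.

## Statistics

- **Wilcoxon signed-rank**, two-sided, on post − pre: zeros discarded
  (the classical treatment, not Pratt's), average ranks on tied
  |differences|, W = positive-rank sum. For n ≤ 25 the p-value is exact:
  the null distribution over all 2^n sign assignments is tabulated by a
  subset-sum recursion over the (doubled, hence integral) ranks. Larger
  n uses the normal approximation with continuity correction and the
  standard tie correction; at the n = 25 boundary the two agree within
  0.01.
- **Star tiers** are `*` p < 0.05, `**` p < 0.01, `***` p < 0.005.
- **CIs** for mean deltas are seeded percentile bootstrap (10,000
  resamples); the choice of interval method is free here and bootstrap
  makes no distributional assumption.
- **Cohen's kappa** is unweighted, with the conventional agreement bands
  (0.61–0.80 "substantial", etc.). κ is undefined (returned as `None`)
  when chance agreement is exactly 1.
- **Likert comparisons** average scores over raters per text, then run
  pairwise signed-rank tests per metric between systems; identical
  rating vectors are flagged degenerate rather than tested.

## Synthetic study conditions

The generator emulates the *shape* of curated biomedical definitions —
about 3 sentences and 31 words per definition — with matched lexicons,
so every stage is testable without licensed terminology or trained
models. Defaults (fixed once as the package's study conditions):

- `mean_sentences = 3`, `mean_words_per_sentence = 10` (truncated
  Poisson); measured mean words/definition ≈ 30.5, sentences ≈ 3.1.
- `complex_term_density = 0.25`: per-word probability of a complex term,
  giving ~7–8 terms per definition (definition text is jargon-dense).
- Terms are 3–6 CVC syllables drawn from consonants + `aiou` (the vowel
  restriction makes the constructed syllable count exact under the
  vowel-group counter). A 3-syllable CVC term is 9 characters and scores
  0.75 under the default scorer, so every generated term clears the 0.65
  gate by construction.
- `hypernym_syllable_gap = 1`: each hypernym has `syllables − 1` CV
  syllables (floored at 1) — the classic lymphoma(3)→cancer(2) step.
  CV construction means fewer syllables also means strictly fewer
  characters, which forces the ARI direction as well.
- Failure injection blanks exactly `⌈rate·n⌉` records, emulating
  per-definition processing loss; at rate 0.257 on 1000 definitions the
  aligned evaluation set is exactly 743.

Each artifact (term pool, corpus, failure mask, dependency trees) draws
from its own RNG stream spawned from the master seed, so adding one
fixture never perturbs another. Dependency fixtures are random
projective trees with a sidecar of true MDD values computed from the
in-memory arcs at generation time, independent of the CoNLL-U reader
they are later checked through; each sentence carries a PUNCT token
attached to the root word so the punctuation exclusion is exercised.

What the generator does *not* emulate: real medical vocabulary,
grammaticality, polysemy, abbreviation phenomena, or the character
length of real definitions (monosyllabic fillers make generated
definitions ≈170 characters rather than the ≈230 of curated ones).
Passing tests therefore demonstrate the correctness and the direction
of the method's effect under controlled conditions, not the magnitude
of improvement achievable on real clinical text — magnitudes depend on
the lexicon's coverage and on the external scorer/recognizer used.

## Numerical and degenerate-input choices

- Undefined metric values are `None`, never NaN, and are excluded with
  counts — silent NaN propagation would corrupt corpus means.
- A single-term lexicon makes every IDF zero; the index then falls back
  to raw TF profiles so self-matching still returns similarity 1.
- Query 3-grams unseen in the lexicon get zero weight (they cannot
  contribute to any match); a query sharing no gram with any term
  returns an empty match list.
- Matcher ties break lexicographically; hypernym ties break by character
  count then lexicographically — all orderings are total, so runs are
  reproducible to the byte.
- Substitution refuses overlapping spans rather than resolving them.

## Known limitations

- The default complexity scorer is a transparent heuristic, not a model
  of human word-complexity judgments; it exists to make the gate
  deterministic and the pipeline testable. Real deployments should plug
  in a trained scorer via the scorer callable.
- Simplification can change MTLD in either direction (substituting
  distinct terms with one shared hypernym lowers type counts), so no
  direction is asserted for it.
- a/an and capitalization are the only grammar repairs; number
  agreement and verb inflection artifacts remain by design.
- Sentence splitting has no abbreviation list; texts with "e.g." or
  "i.e." will over-split.
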