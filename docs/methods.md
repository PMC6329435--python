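# Methods

## The cleaning model

`facetclean` treats a column of semistructured report values as draws from a
small closed vocabulary of correct terms contaminated by data-entry noise.
Cleaning is cast as clustering on the column's *text facet* — the table of
distinct values with occurrence counts — followed by *value-merging*: every
member of a cluster is rewritten to the cluster's canonical value, and the
facet is rebuilt before the next stage. The central assumption is
**frequency dominance**: the correct spelling of a term occurs far more often
than any of its corruptions, so the most frequent member of a cluster is its
canonical value (ties break to the lexicographically smallest value; facet
values are distinct, so this is always decisive).

Stages run in a fixed order, cheap and precise first:

1. fingerprint key (case/punctuation/token-order variants),
2. n-gram fingerprint, n=2,
3. n-gram fingerprint, n=1 (anagram classes — catches adjacent
   transpositions),
4. Metaphone-family English phonetic key,
5. Kölner Phonetik key,
6. nearest neighbour at normalised Levenshtein radius 0.23,

with an optional compression-distance stage off by default. Merging between
stages (rather than collecting all proposals first) mirrors the interactive
merge-then-recluster workflow the pipeline automates, and makes the pipeline
a fixed point: a second run over a cleaned facet proposes nothing.

Nearest-neighbour clusters are connected components at the radius
(single linkage), so a typo of a typo still reaches the canonical. The two
clustering families are deliberately complementary: keys unite variants that
normalise identically regardless of edit count, while the radius search
unites small edits that change every key.

## Parameters that matter

- **Radius 0.23** (normalised Levenshtein, edits / longer length). Chosen so
  that two-edit errors on long words fall inside (2/9 ≈ 0.222) while
  two-edit errors on short words fall outside (2/8 = 0.25): exactly the
  boundary between the recoverable dropped-letter errors and the short-word
  near-misses (`native`, `negaitve`) that a radius search must *not* chase —
  widening the radius past 0.25 would start merging distinct short terms.
  Raw (unnormalised) Levenshtein with an integer radius cannot express this
  boundary — both error kinds sit at distance 2 — which is why it is provided
  but not the default.
- **Two distance normalisations.** Clustering divides by the *longer* string
  (required for the separation above); the reported `inconsistency_rate`
  divides by the *shorter* (the natural "share of the word's characters that
  disagree": `native` vs `negative` = 2/6 → 33%). Both are intentional and
  documented at the call sites.
- **Blocking** (`block_chars`, default 6). Facets up to 2000 distinct values
  are compared exhaustively; above that, candidate pairs must share a
  substring of `block_chars` characters. Two strings within the default
  radius and at least ~9 characters long always share a 3-gram (at most
  ⌊0.23·L⌋ edits cut the longer string into at most e+1 intact runs), so the
  desk-scale equivalence of blocked and exhaustive clustering is a tested
  property; 6 is a faster production default that can in principle miss
  extreme multi-edit pairs on mid-length strings.
- **`auto_accept`**. On by default; with it off the pipeline writes a review
  CSV (cluster id, stage, method, member, count, proposed canonical,
  editable decision and canonical override) and applies nothing until the
  edited file is passed back — the batch stand-in for an interactive merge
  UI. Proposals are computed under provisional acceptance so later stages
  see the facet a full acceptance would produce; a rejection therefore
  invalidates later proposals only rarely (when a rejected merge would have
  changed a later cluster's membership).

## Phonetic coders

Metaphone3-style coding is proprietary and version-sensitive, so the English
coder implements the classic Metaphone rule set (documented, self-contained:
initial-letter exceptions, digraph collapsing, soft/hard C and G, vowels
kept only word-initially). The pair behaviour on the packaged fixtures —
uniting `negaitve`/`negative` while separating `etamoeba`/`entamoeba`,
`lamdlia`/`lamblia` and `glamblia`/`lamblia` — is the binding contract, and
is pinned by tests rather than by bit-compatibility with any particular
implementation. The Kölner Phonetik follows the published code table
(context-sensitive letter→digit rules, adjacent-duplicate collapse, interior
zeros deleted). Multi-token values are keyed token-by-token and joined with
spaces by both coders.

Accent folding uses a fixed Latin-1/Latin-Extended table shipped with the
package; characters outside it pass through, keeping keys reproducible
across platforms and locales.

A note on idempotence: the fingerprint, n=1 n-gram and Cologne keys are
fixed points of themselves (the Cologne coder returns digit-only tokens
unchanged for this reason). The n-gram key at n≥2 is not — the key of a key
enumerates different n-grams by construction — and a Metaphone code is not a
meaningful coder input; both are deterministic, which is what clustering
requires.

## Compression distance

The optional stage uses normalized compression distance
`d(a,b) = (C(ab) + C(ba)) / (C(aa) + C(bb))` against a pluggable
deterministic byte compressor (any object with `cost_bits(bytes)`). The
built-in reference is an order-2 adaptive context model scored by ideal
arithmetic-code length (Σ −log₂ p, additive smoothing α = 1/16 over the byte
alphabet; no bitstream is emitted). The formula is exactly symmetric and its
floor is 1.0 (`d(a,a) = 1`), so thresholds for this stage sit slightly above
1. It is off by default: on short medical terms the edit-distance stage
dominates it, and it exists mainly as the contract point for
partial-matching compressors.

## Evaluation definitions

- A wrong string is **corrected** only if the plan's resolved mapping
  (cross-stage chains followed) sends it to exactly its gold correct string;
  landing in any other cluster counts as uncorrected.
- A **pattern** is a class of wrong strings for one correct term (default:
  each distinct wrong string is its own pattern; the grouping is explicit
  gold input, never inferred). The pattern rate is the share of patterns all
  of whose wrong strings were corrected.
- **Words** are occurrences: the word rate weights each wrong string by its
  facet count. **Accuracy** is the share of all occurrences (correct and
  wrong) that resolve to a correct string after cleaning.
- Rates are percentages rounded to two decimals; merging onto
  frequency-dominant canonicals makes both rates monotone non-decreasing as
  stages are appended (a tested property).

## Synthetic corpus generator

The generator emulates a parasite-screening result column: 30 correct terms
("Negative" plus Latin binomials of common stool parasites), Zipf-distributed
(exponent 1.0) with "Negative" at rank 1 — mirroring a screening archive
where most reports are negative. Each record is one term, corrupted with
probability `typo_fraction` (default 0.02). Error channels and default
weights: substitution 0.30, deletion 0.20, insertion 0.15, adjacent
transposition 0.15, punctuation/spacing variant 0.10, case variant 0.10; a
corrupted record receives a second single-character edit with probability
0.1, reflecting the strong dominance of single-slip errors in real typing.
Token-drop and genus-abbreviation channels (`Giardia lamblia` →
`G.lamblia`) exist but default to 0: they produce deliberately
hard-to-recover variants outside any radius. Corruption is redrawn if it
reproduces the source term, collides with another vocabulary term, or
collides with a wrong string already attributed to a different term, so the
emitted gold standard is closed and unambiguous. Only the handful of terms
appearing in the packaged fixtures is authoritative; the rest of the default
vocabulary is plausible filler.

What the generator does *not* model: free-text context around the term
(records are bare values; the extraction step is exercised separately),
non-Latin scripts, OCR noise, and field-swap errors. Passing the synthetic
recovery benchmark therefore demonstrates the pipeline's behaviour on
isolated-value typo noise, not end-to-end performance on raw clinical
narratives.

## Problem sizes and numerical choices

The packaged fixtures are desk-scale by design (11 and 6 distinct values);
the synthetic benchmark uses 10,000 records (~200 distinct wrong strings),
where the exhaustive nearest-neighbour stage runs in well under a second.
Cluster output is invariant under permutation of the input records; stage
output ordering is made deterministic by sorting clusters on their leading
member. All randomness flows through a single integer seed on `TypoModel`.

## Known limitations

- Frequency dominance fails in columns where an error is more common than
  its correct form; the review workflow (not a different statistic) is the
  intended remedy.
- The n=1 n-gram stage is aggressive by design; on vocabularies containing
  true anagram pairs it would merge distinct terms (the default vocabulary
  is verified anagram-free by a test).
- Thresholds are tuned for short clinical vocabulary terms; very long values
  (whole sentences) would need a larger radius or the compression stage.
- The dictionary extraction gate (normalised distance 0.35) is deliberately
  loose so typos survive extraction; it can pull in unrelated short tokens
  and relies on the downstream pipeline to leave them unmerged.
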