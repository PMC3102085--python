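# Methods

## Data model

All annotation is standoff: a `SourceDocument` holds an immutable unicode
string, and every `Token` and `EntitySpan` carries 0-based, half-open
character offsets into exactly that string.  The invariant
`text[start:end] == surface` is enforced at construction, at standoff read
and write time, and asserted globally in the test suite.  Offsets are
half-open for slice-arithmetic simplicity.

Readers NFC-normalise text at construction.  This is where normalisation
must happen: normalising later would re-index the string under existing
offsets.  The tokeniser's `unicode_nfc` flag normalises its own input view
and is therefore the identity on reader-produced documents; it matters only
when tokenising raw strings from other sources.

Markup extraction (XML via `lxml.etree`, HTML via `lxml.html`) concatenates
text nodes and inserts a single newline after block-level elements
(`p`, `div`, `li`, `td`, headings, `br`, ...), never inside inline markup,
so `<p>Metallo-<i>β</i>-lactamase</p>` extracts as one unbroken name.
Conversion chains between markup dialects are a classic source of offset
noise in NER pipelines; direct extraction to one canonical string avoids
the problem by construction.

## Tokenisation

The chemistry tokeniser applies a fixed rule order:

1. split on unicode whitespace;
2. iteratively detach leading/trailing sentence punctuation
   `. , ; : ! ? " ' ( ) [ ]` as single-character tokens;
3. exceptions during step 2:
   * an edge bracket is retained when its mate lies inside the same
     whitespace chunk (checked per chunk only — linear time, and sufficient
     because chemical bracketing is local: `C2(MONO)`, `(ii)`);
   * commas flanked by digits are interior characters and are never edge
     characters in practice, so locants (`1,2-diol`) survive;
   * `+` and `−` are not sentence punctuation, so charges (`Cu2+`) survive;
   * hyphens (U+002D, U+2212, U+2010 treated identically — chemical prose
     mixes them) are never split.

The rules are reverse-engineered from the canonical failure examples in the
chemistry NER literature rather than copied from any published rule table;
the fixture suite pins each rule to the example that motivates it.
Sentence segmentation is deliberately absent: the tagger conditions on the
previous label only, so document-level token sequences suffice.

`naive_tokenise` is pure whitespace splitting.  It is not a strawman: it
stands in for any general-purpose tokeniser that leaves sentence
punctuation attached, and it is the baseline arm of the ablation
experiments.

## MEMM

Per position, a single multinomial logistic model over {O, B-CM, I-CM}
shares one weight vector across previous-label contexts, with the previous
label injected as features (`prev_label=...` and a label/shape
conjunction).  At this label-set size this is as expressive as one model
per previous label with far fewer parameters.  Features are binary:
character n-grams of orders {1,2,3,4} over `^word$`, collapsed
character-class shape, 3-character prefix/suffix, lowercased neighbours
with edge sentinels, and a bias.  Unknown features at tag time contribute
zero weight.

Training builds one instance per token with the *gold* previous label
(teacher forcing), then minimises the negative penalised log-likelihood
with L-BFGS (`scipy.optimize.minimize`, analytic gradient, zero
initialisation, `ftol` 1e-8, max 300 iterations).  Defaults: L2 strength
1.0 — a conventional weakly-informative ridge for binary indicator features;
the objective is convex, so the seed recorded in `training_meta` documents
provenance rather than influencing the optimum.  Training refuses a corpus
with zero boundary-aligned entities: the degenerate all-O model would train
"successfully" and be silently useless.

Decoding is Viterbi over the position-conditional distributions; ties break
by the fixed label order O < B-CM < I-CM for reproducibility.  Entity
confidence is the probability of the event "B-CM at the first token, I-CM
through the last, no I-CM continuation", summed by a forward pass with
per-position admissible-label masks.  A Viterbi path score is *not* used as
confidence because a single path's probability is neither calibrated nor
monotone in entity quality; the constrained-forward mass is a true
probability in [0, 1].  Both dynamic programs are verified against
exhaustive enumeration over all 3ⁿ label sequences in the test suite
(n ≤ 6, hundreds of random models, tolerance 1e-9 on log-probabilities).

The default confidence threshold is 0.3, the conventional operating point
for MEMM-based chemical NER; `select_threshold` on a sweep of a development
split picks a corpus-specific point (a test split should not be used to
tune it).

Model files are JSON: feature list in index order, weight matrix, label
order, feature template version, training metadata.  Floats serialise via
`repr` shortest round-trip, so weights reload bit-exactly; loading a file
whose template version differs from the build is an error, because weights
are meaningless under a different feature template.

## Pattern recogniser

Three knowledge sources, no fitted classifier:

* **dictionary**: longest match of whitespace-normalised token windows
  (window ≤ 5 tokens — bounds matching cost and covers multiword names like
  `ruthenium (ii) diimine`) against a word list; case-sensitive with a
  case-insensitive fallback for initial-capital forms, to catch
  sentence-position capitalisation;
* **rules**: named finite-state patterns over token surfaces — locant
  prefixes, charged formulas, Greek-hyphenated stems, metal + bracketed
  oxidation state (+ ligand).  Each match records its rule name in
  `provenance`;
* **scorer**: two add-α-smoothed character n-gram models (order 4,
  α = 0.01) trained on chemical and non-chemical word lists; a token is a
  candidate when the length-normalised log-likelihood ratio is positive.
  The threshold is fixed at zero — the likelihood-ratio sign — keeping the
  recogniser parameter-free.  The normaliser counts emission events
  (word length + end symbol), making scores comparable across lengths and
  exactly antisymmetric under swapping the training lists.

Stop words suppress scorer candidates only; dictionary and rule matches are
assertions of knowledge and always stand.  Overlaps resolve longest-first,
then leftmost, then dictionary > rule > scorer — the standard deterministic
choice, and the full order is total so output never depends on iteration
incidentals.

## Workflows

Pipelines are linear lists of registered components, each declaring
consumed/produced annotation kinds from {document, tokens, entities}.
Validation checks that every consumed kind has an earlier producer and
warns when a kind is produced twice (later wins — explicit overwrite rather
than implicit merge).  Any two components with equal signatures are
interchangeable, which is the point: the tokenisation ablation is a one
component swap around an unchanged tagger.  Execution is per document;
a component failure aborts that document with a recorded diagnostic and the
corpus continues (or `fail_fast` raises).  Linear pipelines, not DAGs:
every workflow in scope is a chain, and the simpler contract is easier to
validate and reproduce.

## Synthetic corpora

The generator emulates the regime of a manually annotated chemistry corpus
— a few thousand mention annotations over prose — without reproducing any
licensed text.  Documents are English template sentences; mention slots are
filled from five name-family grammars (systematic, charged formula,
Greek-hyphenated, multiword metal complex, trivial names) with default
weights 0.30/0.20/0.15/0.15/0.20.  Mentions per sentence are drawn
Binomial(3, density/3) so the mean is exactly `entity_density` (default 1.0
per sentence, capped at 3) and corpus totals follow a closed-form binomial
law the tests check against.  Default split: 250 documents, 80% train.
The formula family always carries a charge suffix so the family is
uniformly tokenisation-fragile.  All generation flows from one
`numpy.random.default_rng(seed)` stream; identical configs give
byte-identical corpora.

`adversarial_corpus` restricts the family weights to the four
tokenisation-fragile families and uses templates that place nearly every
slot flush against sentence punctuation.  Under the chemistry tokeniser
every gold boundary aligns; under naive whitespace splitting the attached
`.` or `,` puts the gold end-boundary strictly inside a token, which
surfaces as a counted boundary-mismatch diagnostic in BIO encoding and as
unmatchable spans at evaluation.  That asymmetry is the engine of the
ablation experiments.

What passing on these corpora shows — and does not.  The generated names
are morphologically chemistry-like but lexically narrow; real chemistry
prose has ambiguous trivial names, acronyms, line-broken hyphenation and
annotator disagreement, none of which the generator emulates.  Near-perfect
F on the default corpus therefore demonstrates that the machinery is wired
correctly (features reach the optimiser, decoding matches enumeration,
offsets survive every transformation), not that comparable F is attainable
on curated corpora.  The ablation direction — chemistry tokenisation
strictly beating naive splitting when names abut punctuation — is the
transferable finding, and it is asserted as a direction, never as a magnitude.

## Evaluation

Exact span+label matching; a partial overlap is one false positive plus one
false negative, consistent with treating partial entities as errors.
Empty-denominator conventions: precision 1 with no predictions, recall 1
with no gold, F 0 when both P and R are 0.  Threshold sweeps re-evaluate at
every distinct confidence (plus 0 and 1); recall is non-increasing along
the grid by construction, and the ROC of threshold tuning is reported as
P/R/F rather than a true-/false-positive *rate* pair, because span-level
NER has no negative-instance count to normalise false positives by.
Single-split evaluation only; cross-validation orchestration is out of
scope.

## Problem sizes

The test suite and acceptance script use 250-document default corpora
(200/50 split), 150-document adversarial corpora (120/30), and
30-document corpora for retraining-determinism checks — sizes chosen so a
full run of everything completes in well under a minute of training time
while keeping several hundred test mentions per experiment.

## Known limitations

* The MEMM suffers from the usual label-bias caveats; a CRF would be the
  natural next component behind the same workflow signature.
* The feature template is a faithful-in-kind reconstruction of
  character-n-gram MEMM taggers, not a replica of any published template.
* The pattern rule inventory is illustrative, not exhaustive; real
  deployments should extend `PatternRuleSet`.
* The tokeniser does not repair hyphenation across line breaks and performs
  no sentence segmentation.
* Confidence computation is exact but O(n·L²) per entity; for very long
  documents batching per-document lattices (as `tag` does) matters.
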