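# chemner

Modular chemical named-entity recognition (NER) for chemistry text mining.

Chemical names break ordinary NLP tokenisation: hyphens, locant commas,
balanced brackets, charge signs and Greek letters are *intra*-token
characters in names like `Metallo-β-lactamase`, `1,2-diol`, `C2(MONO)` and
`Cu2+`, while the same characters are token delimiters in ordinary prose.
A tagger fed badly tokenised text sees partial entities and accumulates both
false positives (Type I) and false negatives (Type II). `chemner` makes
this mechanism measurable: it provides a chemistry-aware tokeniser, a
trainable maximum-entropy Markov model (MEMM) recogniser with per-entity
confidence, a deterministic pattern recogniser, and a workflow layer in
which any component can be swapped for another with the same input/output
signature — so a tokenisation ablation is literally a one-line change to a
pipeline configuration.

It is aimed at text-mining researchers and cheminformaticians who want a
small, fully inspectable NER stack whose every probability can be checked
against brute-force enumeration, plus a seeded synthetic-corpus generator so
experiments run with no external data.

## The model

Tokens are labelled with BIO tags over a single mention class `CM`
(chemical mention): `B-CM` begins an entity, `I-CM` continues one, `O` is
outside.  The MEMM factorises the sequence probability as

P(y₁..yₙ | x) = ∏ᵢ P(yᵢ | yᵢ₋₁, x, i)

where each factor is a multinomial logistic model over the three labels with
binary features of the observation (character n-grams of orders 1–4 with
word-boundary sentinels, token shape, 3-character prefix/suffix, neighbour
words) and of the previous label (identity and a label/shape conjunction).
Training maximises the L2-penalised conditional log-likelihood with L-BFGS;
decoding is Viterbi.

The confidence of a predicted entity spanning tokens a..b is the exact
probability, under the model's sequence distribution, of the event
{y_a = B-CM, y_{a+1..b} = I-CM, y_{b+1} ≠ I-CM}, computed by a constrained
forward pass.  Filtering entities below a confidence threshold (default
0.3) trades recall for precision; `chemner.evaluation.sweep` maps the whole
operating curve and `select_threshold` picks the max-F point.

The pattern recogniser is the statistical model's deterministic foil:
dictionary longest-match over token windows, finite-state name-morphology
rules, and a two-class character n-gram scorer, with overlaps resolved
longest-first / leftmost / dictionary > rule > scorer.

## Worked example

```python
from chemner import (GeneratorConfig, generate_corpus, train, tag,
                     tokenise, evaluate, TrainingConfig)

train_docs, test_docs = generate_corpus(GeneratorConfig(n_documents=250, seed=1))
model = train(train_docs, config=TrainingConfig(seed=1))

doc = test_docs[0]
for e in tag(model, tokenise(doc.document), threshold=0.3,
             text=doc.document.text)[:4]:
    print(f"[{e.start:4d},{e.end:4d})  conf={e.confidence:.3f}  {e.surface}")

gold = [d.entities for d in test_docs]
pred = [tag(model, tokenise(d.document), 0.3, text=d.document.text)
        for d in test_docs]
res = evaluate(gold, pred)
print(f"P={100*res.precision:.2f}%  R={100*res.recall:.2f}%  "
      f"F={100*res.f_score:.2f}%")
```

prints

```
[  80,  89)  conf=0.998  meropenem
[  91, 114)  conf=0.979  platinum (iv) porphyrin
[ 136, 164)  conf=0.981  platinum (iv) phenanthroline
[ 179, 184)  conf=0.997  Ru12+
P=100.00%  R=100.00%  F=100.00%
```

Each line is a predicted chemical mention: its half-open character span in
the document, the model's probability that exactly this span is an entity,
and its surface.  The final line is exact-span precision/recall/F over the
50 held-out documents — the generated corpus is morphologically regular, so
a correctly wired MEMM separates it essentially perfectly; the interesting
experiments degrade it deliberately (see the tokenisation ablation below).

The same pipeline is available from the shell:

```
chemner generate --seed 1 --out corpus/
chemner train --corpus corpus/train --out model.chemner
chemner tag --model model.chemner --in paper.txt --threshold 0.3 --out pred/
chemner evaluate --gold corpus/test --pred pred/ --report report.json
```

## Layout

| module                 | contents                                            |
|------------------------|-----------------------------------------------------|
| `chemner.annotations`  | documents, tokens, entity spans, BIO, standoff I/O  |
| `chemner.tokeniser`    | chemistry-aware + naive whitespace tokenisers       |
| `chemner.memm`         | features, training, Viterbi, confidence, tagging    |
| `chemner.pattern`      | lexicon, n-gram scorer, finite-state rules          |
| `chemner.workflow`     | typed component pipelines, validation, execution    |
| `chemner.evaluation`   | exact-span P/R/F, threshold sweeps                  |
| `chemner.synthetic`    | seeded annotated-corpus generator                   |
| `chemner.cli`          | `chemner` command-line interface                    |

See `docs/methods.md` for the modelling details, numerical choices and
known limitations.
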