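# Methods

This note documents the model implemented by `nervote`, its
assumptions, the parameters that matter, the numerical and design
choices that were genuinely open, and what the synthetic test bed does
and does not establish about real corpora.

## The ensemble model

Given N base sequence labelers over an output alphabet of O BIO labels,
the ensemble is defined by a real matrix `V ∈ [0,1]^{N×O}` of vote
weights. For token *t*, the combined score of class *c* is

```
f(c, t) = Σ_{m : op(t,m) = c}  V(m, c) · F_m
```

where `op(t, m)` is the hard label output by classifier *m* and `F_m`
its overall strict-match F-measure from K-fold cross-validation. The
joint decision is the argmax over classes, taken independently per
token; span-boundary conflicts between classifiers are resolved
implicitly by this per-token rule, and decoded sequences are *not*
repaired (an orphan `I-X` is left in place — the evaluator's chunker
handles it).

Assumptions worth stating explicitly:

- classifiers vote with **hard labels only** — no marginals, no
  calibration of posteriors;
- `F_m` is a classifier-level constant, so it scales all of a
  classifier's votes alike; the class-specific part of the weighting
  lives entirely in `V`;
- the decision is invariant to scaling all `V` entries and/or all
  `F_m` by one positive constant, so restricting genes to `[0,1]`
  loses no expressiveness.

### Tie-breaking and label order

The label alphabet is fixed as B-/I- labels sorted by entity type, with
`O` last. Argmax ties resolve to the earliest column. Two consequences:
the decision is deterministic and reproducible, and an all-zero score
vector (no weighted vote at all) can never *invent* an `O` override of
a real vote — nor can `O` win a tie against an entity label. The order
is recorded in every serialized weight matrix.

### The O column

Whether the `O` label should receive a learned weight column is a
genuinely open design point: weighting `O` lets the optimizer trade
precision against recall globally, but it also doubles as a knob for
degenerate all-`O` solutions. The default (`include_o=True`) learns an
`O` column like any other. With `include_o=False` the `O` votes carry
fixed weight `1 · F_m` and only entity columns are searched; this mode
is also what makes exhaustive grid verification tractable (see
"Verification" below).

## Fitness

The fitness of a weight matrix is the **mean over the K folds** of the
ensemble's overall strict-match F-measure on that fold's held-out
tokens (percent scale). All classifiers share identical sentence-level
folds — fold construction is part of the bank, not of the individual
classifier — otherwise the fitness would compare predictions made on
different data.

The landscape is piecewise constant in `V`: only the relative order of
the products `V(m,c)·F_m` matters. The evaluator therefore caches
fitness twice, by gene bytes and by the decoded-label signature; the
second cache is what makes population-scale GA runs and exhaustive
grids cheap.

## The genetic algorithm

Real-coded, generational, single-objective:

| parameter | default | meaning |
|---|---|---|
| P | 100 | population size |
| G | 50 | generations |
| k1, k3 | 1.0 | adaptive crossover constants |
| k2, k4 | 0.5 | adaptive mutation constants |
| δ | 0.1 | Laplace mutation scale (gene units) |
| K | 5 | cross-validation folds |

Genes initialize i.i.d. uniform on `[0,1]`. Selection is
roulette-wheel, proportional to fitness (uniform if every fitness is
zero). P/2 parent pairs are drawn with replacement; each pair crosses
with probability

```
μc = k1 · (f_max − f′) / (f_max − f_avg)   if f′ ≥ f_avg,  else k3
```

where `f′` is the larger parent fitness and `f_max`, `f_avg` are the
population maximum and mean (fitness mapped to `[0,1]` for these
formulas; the mapping is monotone so selection pressure is unchanged).
Crossover is single-point with a uniform cut in `[1, L−1]`. Each
offspring then mutates with per-chromosome probability

```
μm = k2 · (f_max − f) / (f_max − f_avg)    if f ≥ f_avg,  else k4
```

each selected gene being replaced by a Laplace(gene, δ) draw clamped to
`[0,1]`. The Laplace choice concentrates perturbations near the old
value while keeping every point of the domain reachable
(`E|X−μ| = δ`, median = μ — both verified empirically in the suite).
The population best has `μm = 0` and, when paired with itself, `μc = 0`:
good solutions are protected, poor ones are churned.

Numerical edge cases, fixed once:

- **converged population** (`f_max = f_avg`): the adaptive quotient is
  0/0; the rate falls back to k1 (crossover) or k2 (mutation);
- **μm timing**: μm depends on the chromosome's *own* fitness, so each
  offspring is evaluated once before mutation (the decode-signature
  cache absorbs the extra evaluations);
- **clamping**: mutation output is clipped to `[0,1]`; by scale
  invariance of the argmax this loses nothing;
- **elitism**: the best-ever chromosome lives in a slot outside the
  population and replaces the current worst individual each
  generation; the reported per-generation trace is the elite's fitness
  and is non-decreasing by construction.

The solution is the best-ever chromosome after G generations, returned
with its full fitness trace and the `F_m` vector used.

## Base classifiers

The ensemble consumes only a prediction bank — per-fold held-out hard
labels plus `F_m` per classifier — so the learners are deliberately
pluggable behind a two-method contract (`fit`, `predict`). Shipped
backends:

- `memorize` — maps each word to its most frequent training label
  (ties lexicographic, unseen words → `O`). Dependency-free; exists so
  tests and examples have a fast, perfectly predictable learner.
- `maxent` — multinomial logistic regression over the extracted
  feature dicts (scikit-learn, one-hot via `DictVectorizer`), greedy
  left-to-right decoding when dynamic (previous-tag) features are on.
- `svm-poly` — polynomial-kernel SVC (degree 2, one-vs-one),
  the margin-classifier configuration used for this task family.

Heterogeneity across ensemble members comes from varying the
`FeatureTemplate` (context radii, n-gram order, affix length, feature
family switches), not from hyperparameter search.

Per fold, feature resources (frequencies, head nouns, triggers,
informative words, content vocabulary) are rebuilt on that fold's
training portion only, so held-out predictions never leak gold
statistics. Test-time ensembles retrain every backend on 100% of the
training corpus while `V` and `F_m` come from the CV phase.

## Features

Fifteen families, all derived from the training corpus or the token's
own orthography — no external lexicons, by design. Parameters with
defaults:

- context windows: ±2 words (0–3 per column), n-grams up to n = 2;
- affixes: prefixes/suffixes up to 3 characters (0–4);
- word length indicator: fires above 5 characters;
- infrequent-word indicator: fires below 10 training occurrences;
- head nouns: final unigram/bigram of entity mentions with training
  frequency ≥ 2;
- trigger verbs: words immediately preceding mentions, frequency ≥ 2;
- dynamic features: up to 3 previous output tags (gold at training
  time, model predictions at decode time — never the current or future
  gold label, so decoding-time extraction is causally valid).

Three definitions the sources leave open were fixed as follows:

- **NEweight** — the share of a word's training occurrences that fall
  inside entity mentions: `inside_count / total_count ∈ [0,1]`.
  Candidates are words inside *multiword* mentions (digit/symbol
  tokens excluded); words with fewer than 2 in-mention occurrences are
  dropped; survivors are binned into five equal-width weight classes
  over (0,1]. Equal-width binning is the simplest reproducible rule
  for "five classes"; the edges are configurable.
- **Content words** — the 10 most frequent lower-cased unigrams
  (stopwords, numbers and symbols removed; ties lexicographic) within
  ±3 tokens of entity-labeled tokens over the linearized training
  corpus. The *feature* is pure window containment: indicator *i* fires
  iff vocabulary word *i* occurs within the window of the current
  token. Containment needs no label information at prediction time, so
  no second labeling pass is required; only the vocabulary is
  entity-derived, and from training data alone. At extraction time the
  window is clipped to the sentence (the vocabulary builder does cross
  sentence boundaries).
- **Stemming** — lower-case, strip one of `ing/ed/es/s`, collapse
  digit runs. Deliberately approximate: it exists to merge inflected
  variants, not to be linguistically correct.

The unknown-token indicator is randomized during training (every
training word is trivially "seen"): a deterministic hash of (run seed,
position, surface) yields an unbiased bit, so features are reproducible
regardless of extraction order. At prediction time the bit is simply
"not in the training vocabulary".

## Evaluation

Strict boundary matching: a predicted chunk is correct iff its
sentence, start, end and type all equal a gold chunk's. Recall =
correct/gold, precision = correct/predicted, F = harmonic mean, percent
scale, reported to two decimals, per class and overall. Orphan `I-X`
labels start a new chunk (conlleval-compatible); a flag switches to
dropping them. Chunk spans are closed intervals `[start, end]` over
0-based token positions.

## Synthetic test bed

`generate_corpus` emulates the corpus properties the method actually
depends on: sentences of 8–25 filler tokens; entity mentions of 1–4
tokens at a Poisson-distributed rate per sentence (default density 1.0,
thinned only when a sentence physically cannot hold a drawn mention);
entity tokens carrying capital/digit/hyphen orthographic patterns with
probability 0.8; trigger verbs immediately preceding mentions with
probability 0.3; PoS-like and chunk-like auxiliary columns. Defaults
were chosen once to resemble gene/protein corpora at small scale
(mention lengths around the ~2-token averages of gene-mention corpora,
most entity tokens orthographically marked) and are not tuned per test.

`simulate_classifier_outputs` instantiates the hypothesis the ensemble
is built on — per-classifier, per-class reliability: classifier *m*
emits the gold label with probability `a(m, j)` and otherwise an error
drawn uniformly over other labels, always `O`, or a B↔I boundary
jitter. Corruption is per token, so BIO validity breaks exactly as it
does for real taggers.

What passing tests show: the decoder, scorer and optimizer are correct
against independent oracles, the GA recovers grid-search optima, and
weighted per-class voting exploits complementary reliability. What
they do not show: performance on real biomedical text. Synthetic
fillers carry no semantics, reliability profiles are stationary and
class-conditional only (real classifier errors correlate with context),
and entity/filler vocabularies are disjoint across types. Improvements
of the ensemble over individuals are therefore larger here than the
~2-point gains typical on real corpora — the complementarity is
engineered rather than emergent — and absolute F values have no
real-corpus meaning.

## Verification scales

The suite verifies the method at sizes chosen for a desk-scale machine:
scorer oracle on 500 random sequence pairs, decoder oracle on 1,000
tokens × 4 classifiers × 7 labels, GA-vs-grid on a 300-sentence
two-classifier bank (single-token entities, O-column excluded, so the
0.05-step grid over the 2×2 entity-weight matrix — 194,481 points,
deduplicated through induced decision tables — is exhaustive), ensemble
dominance on a 200-sentence five-classifier bank over 10 seeds, and
byte-level rerun identity of the full pipeline on a 60-sentence corpus.
GA runs in the suite use P = 50, G = 30 (optimum recovery) and P = 40,
G = 20 (dominance); the package defaults stay P = 100, G = 50.

## Known limitations

- No linear-chain CRF backend is shipped; the registry accepts one,
  and the greedy maxent labeler with dynamic features is the stand-in
  sequence-aware learner. Both shipped learners are token classifiers;
  global sequence decoding (Viterbi) is out of scope.
- `F_m` is a single overall number per classifier, as the voting rule
  requires; per-class F enters only through what the GA learns in `V`.
- The informative-word binning treats the two-parameter selection
  ("weight" and "count") as a count cutoff followed by weight binning;
  other readings are possible and the bin edges are exposed.
- Roulette selection assumes non-negative fitness, which F-measure
  guarantees.
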