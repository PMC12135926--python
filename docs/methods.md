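# Methods

## Features

Each document contributes six features: the Shannon entropy, in bits, of its
word uni-, bi- and tri-gram distributions and of its POS uni-, bi- and
tri-gram distributions. The estimator is the plug-in (maximum-likelihood)
form H = −Σ p(i) log₂ p(i) with p(i) = f(i)/N over the N = L − n + 1
contiguous n-grams of a length-L stream. Three choices matter:

- **No bias correction.** The plug-in estimator is biased downward by
  roughly (types − 1)/(2N ln 2); with every document truncated to the same
  500-token window the bias is shared across classes, so between-class
  contrasts are unaffected and the value keeps its direct reading as the
  empirical average information content of the window. Miller–Madow or
  coverage-adjusted estimators would change absolute values without
  changing any comparison the pipeline makes.
- **No sentence-boundary resets.** N-grams run across the whole truncated
  stream; the document is treated as one production episode.
- **Counting conventions.** Word tokens are case-folded and punctuation
  tokens are excluded before counting, and hyphen/dash compounds stay
  single tokens. These conventions are forced by the worked example in the
  README: 22 tokens with p(the) = 3/22 only obtains when `The` and `the`
  merge and the comma and final period are not tokens.

Truncation to the first 500 word tokens (post punctuation removal) controls
length bias, since plug-in entropy grows with window length. Shorter
documents are kept and flagged by default; a `drop_short` switch removes
them, because no principled exclusion rule dominates and the choice is
exposed rather than hidden.

## Annotation

The POS tagger is an injected function `tokens -> tags`, so any external
tagger can be plugged in and deterministic fixtures or sidecar `.tags`
files can bypass tagging entirely (the synthetic generator always writes
sidecars). The built-in default is a lexicon-plus-suffix rule tagger
emitting Penn-style tags, mapped to twelve coarse categories (Det, Num,
Noun, Aux, Verb, Adj, Prep, Conj, Pron, Adv, Part, Other). Its coverage is
shallow by design — closed-class lookup plus ordered suffix rules with an
`NN` default — which is adequate for coarse POS *distributional* features
but not for token-level tagging accuracy; analyses of real corpora should
inject a trained tagger. The coarse tagset is the default because the
entropy features need distributional stability more than fine distinctions,
and a 36-tag fine mode inflates POS n-gram type counts in 500-token windows.

## Synthetic corpus generator

The generator emulates a three-class news-editorial study design — native
(L1), learner (L2) and translated (TL) English, 420 documents of 500 tokens
per class — at the level of distributional structure only. Per class:

- **Word stream:** i.i.d. draws from a vocabulary of `vocab_size` ranked
  types with Zipf law p(rank) ∝ rank^(−s). Larger vocabularies and smaller
  exponents raise all three word n-gram entropies; this single dial yields
  the designed word ordering L1 > L2 > TL (defaults: 2400/0.90, 1800/1.05,
  1550/1.12).
- **POS stream:** concatenation of tag templates drawn with fixed
  probabilities, truncated to length, then per-position substitution by a
  uniformly random tag of the class tagset with probability
  `template_noise`. Template *marginals* steer POS uni-gram entropy while
  template *diversity and noise* steer POS bi-/tri-gram entropy, so the two
  can be ordered independently: L1 uses many heterogeneous noun-heavy
  templates with the highest noise (0.17) — skewed marginal, lowest POS h1,
  but the richest transitions, highest POS h2/h3; L2 uses three templates
  at noise 0.03 (middle h1, lowest h2/h3); TL shares L2's frames plus one
  extra rare template at noise 0.05, sitting just above L2 on all POS
  features. The resulting orderings are POS h1: L1 < L2 < TL and POS
  h2/h3: L1 > TL > L2.

Word and POS streams are generated jointly but independently: no downstream
feature crosses the streams, so coupling them would add nothing testable.
All randomness flows through one explicit `numpy` Generator seeded from the
corpus spec; identical spec and seed give byte-identical corpora.

Effect sizes were calibrated once with the `monte_carlo_expected_entropy`
oracle so that all six group-mean orderings hold with at least 3 standard
errors of separation at the default sample size (the realised separations
are 15–170 SE), and so that TL stays close to L2 while L1 is distant on
most features — the geometry in which the learner class sits between the
native and translated extremes. Because the emulated study reports
orderings and significance rather than effect magnitudes, the absolute
entropy gaps are a design choice, not an estimate; classification
accuracies near 1.0 on the default design reflect that deliberate
separation, and passing tests demonstrate that the pipeline *recovers
built-in structure*, not that real L1/L2/TL corpora are this separable.
What the generator does not emulate: lexical content, syntax–lexicon
coupling, topic drift, document-length variation, or any dependence between
adjacent words beyond what Zipf marginals induce.

## Classification harness

Every pair of classes is split 75/25 (stratified, seeded) once, as a
single-split design; a `--repeats` option reports mean ± SD over
independent split seeds because single-split scores are seed-sensitive.
Five families run with documented defaults: linear-kernel SVM (C = 1),
logistic regression, k-NN (k = 5), random forest (100 trees), decision
tree; tree/forest seeds derive from the split seed. Features are
standardized with training-split statistics for the margin/distance-based
families (SVM, logistic, k-NN) and left raw for the axis-aligned trees —
distance-based methods are scale-sensitive and the six entropies live on
different scales, so unstandardized margins would be dominated by the
widest-ranging feature. AUC uses each family's continuous score (decision
value, class probability, or tree-vote fraction) with the lexicographically
first label of the pair as the positive class; that same label is the one
predicted by positive SVM coefficients. The linear kernel is required for
the interpretation step: signed per-feature coefficients exist only for
linear decision functions. Coefficient importance ranks order |coefficient|
descending with ties broken by the fixed feature order (word_h1 … pos_h3).
The boundary distance |w·x + b|/‖w‖ is averaged over *all* documents of
the pair (train and test) in the standardized space the SVM was fit in; it
is invariant to rescaling (w, b) by a positive constant.

## Group analysis

Per feature, a classical equal-variance one-way ANOVA (Welch is not the
default, matching the common spreadsheet-statistics workflow this mirrors;
the pairwise stage is configurable) with pairwise mean differences reported
for all ordered class pairs — exactly antisymmetric by construction — and
post-hoc p values from Tukey's HSD by default. Tukey was chosen over
unadjusted ("LSD") pairwise t tests because the procedure behind the
emulated workflow is unknown and family-wise control is the conservative
default; `method="lsd"` switches it off. Significance is starred at 0.05.
Group ranking orders classes by descending feature mean, with exact ties
broken lexicographically and flagged.

t-SNE embeds the standardized six-feature table in 2-D (perplexity 30,
auto-reduced and logged for small tables; PCA initialisation; 1,000
iterations; fixed seed). Coordinates are deterministic for a fixed seed on
a fixed platform; only neighbourhood structure, not axes or distances, is
interpretable.

## Numerical choices and degenerate inputs

- Entropy requires probabilities summing to 1 within 1e-9 and all p > 0;
  streams shorter than n are rejected (the feature is undefined), and
  documents shorter than 3 tokens cannot produce the six-feature vector.
- A single-type stream has H = 0 exactly; all-distinct streams attain the
  upper bound log₂ N, where float rounding can overshoot by ~1e-15.
- ANOVA rejects the degenerate case of zero within-group variance with
  unequal means (F undefined); equal-mean zero-variance groups return F = 0.
- Splits require at least 4 rows per class so both subsets contain both
  classes.
- `vocab_size = 1` profiles are rejected at construction but accepted by
  the sampling routine for explicit zero-entropy fixtures.

## Problem sizes

Tests and the acceptance script run the full designed corpus (1,260
documents × 500 tokens) for the structure-recovery checks, 20 two-class
null corpora at the same per-class size for classifier calibration, and
1,000 three-group normal replicates (n = 20 per group) for ANOVA type-I
calibration; unit tests use a reduced 3 × 30 × 200 corpus. These sizes keep
the statistical checks well-powered (binomial SE ≈ 0.005–0.007 at the
calibration sample sizes) while the whole suite completes in a few minutes.

## Known limitations

- The built-in tagger is heuristic; real-corpus POS entropies depend on the
  injected tagger's quality and tagset.
- Plug-in entropy bias is uncorrected (deliberate, see above), so absolute
  values are not comparable across different window lengths.
- The generator's i.i.d. word model cannot express collocational structure;
  word bi-/tri-gram entropies differ between classes only through marginal
  repetition rates.
- Single-split evaluation is seed-sensitive; use `--repeats` for error bars.
- t-SNE determinism holds per platform/library version, not across them.
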