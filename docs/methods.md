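# Methods

This note documents the models, parameters and design choices behind
`semharm`, and what the test suite's synthetic corpora do and do not show
about real questionnaire data.

## Scoring model

Item texts are mapped to fixed-length vectors by an embedding backend; the
similarity of an item pair is the cosine of their vectors (the
sentence-embedding score, SES). Vectors are unit-normalized by default so
that cosine reduces to a dot product and inner-product k-NN coincides with
cosine k-NN; cosine itself is normalization-invariant, so this choice never
changes a score. Cosine with a zero vector is defined as 0 with a warning
rather than an error, keeping exhaustive pairing total on degenerate texts.
Scores are clipped to [−1, 1] against floating-point drift.

### The hash n-gram backend

The built-in backend hashes the character trigrams of the lower-cased,
whitespace-normalized text into 256 signed buckets (BLAKE2b hash; the
bucket is `h mod dim`, the ±1 sign an independent high bit) and
L2-normalizes the count vector. It is a lexical-overlap model, not a
semantic one: near-paraphrases that share most of their wording score high,
but true synonymy and cross-lingual equivalence are invisible to it. Its
role is to make every pipeline stage deterministic and testable offline;
production scoring should use a sentence-transformer or comparable model
behind the same backend contract. Defaults `dim=256, n=3`: trigrams are the
shortest n-grams that respect word-internal structure, and 256 buckets keep
the collision mass low at desk scale (tested bound: unrelated fixed strings
with disjoint trigram sets stay below |cos| = 0.3).

## Pair model

All C(n, 2) unordered pairs are enumerated; a pair is stored canonically
with `item_a < item_b` under lexicographic id order, so the same physical
pair has the same identity under any item ordering. Within-instrument pairs
are kept and flagged (`cross_instrument=False`); coverage and
ground-truth evaluation use cross-instrument pairs only, because
within-instrument similarity is not a harmonization opportunity between
questionnaires. Score summaries use the population SD (ddof = 0): the pair
set is the complete population being described, not a sample. The histogram
spans [−1, 1] with equal-width bins, right edge inclusive in the last bin.

Exact top-k retrieval is the reference path, with deterministic
tie-breaking (higher score first, then smaller item id). The approximate
mode is an IVF-style coarse-quantizer search (k-means cells, probing the
`n_probe` nearest cells); it is an efficiency device excluded from
correctness guarantees, and `approximate_recall` measures it against the
exact path.

## Thresholding and confidence bands

Candidate filtering keeps pairs with SES **strictly** greater than τ;
default τ = 0.751, the lower confidence bound on positive candidates from
an expert pre-test. Classification bands are closed intervals supplied as
configuration — they derive from an expert study, not from the corpus, so
the package ships them as presets rather than recomputing them. Under the
`exclusive_bands` rule a score inside exactly one band takes that class;
inside both or neither it is *uncertain* and goes to human review. The
shipped default bands (positive 0.676–0.912, negative 0.737–0.800) are
nested, so their overlap is non-empty; routing the overlap to "uncertain"
is the conservative reading — ambiguity should cost automation, not invent
it. Only a positive band is published for the second reference model, so no
second preset is shipped.

## Coverage

An item is covered at τ iff it participates in ≥ 1 cross-instrument pair
with score > τ; instrument coverage is the covered percentage of its items.
Coverage and candidate counts are non-increasing in τ by construction
(tested over a τ grid). The inter-instrument matrix counts above-τ
cross-instrument pairs per instrument pair; it is symmetric with a zero
diagonal.

## Topics

Topic building is a defined deterministic pipeline: k-means on the
embedding vectors (fixed seed, `n_init=10`) followed by class-based TF-IDF
over the clustered texts,

    weight(t, c) = (count(t, c) / tokens(c)) × log(1 + A / f_t),

with f_t the total corpus count of t and A the average token count per
cluster. Density-based topic models over reduced embeddings are common
here, but they leave cluster counts unspecified and seed-sensitive; a
centroid model with an explicit formula gives a testable specification
instead. Tokenization: lower-case, split on non-alphanumerics, drop
single-character tokens; no stop-word list by default, since the
inverse-frequency factor already sinks ubiquitous terms (configurable).
Term ties are broken alphabetically. Empty clusters yield empty term lists
with a warning. The 2-D projection reference method is PCA (deterministic,
distance-preserving on planar data); UMAP is available as an optional
seed-controlled alternative with no correctness claims.

## Expert rating study

Pair eligibility for an instrument: at least one member item belongs to it.
The three groups per instrument are the `group_size` highest-score eligible
pairs, the `group_size` pairs closest to the *instrument's* mean eligible
score (the per-instrument mean, since groups are built per instrument), and
the `group_size` lowest. Groups are constructed in priority order
top > bottom > middle: each later group excludes already-claimed pairs and
refills, so group sizes are always `min(group_size, remaining)` and with
fewer than 3 × group_size eligible pairs the union is exactly the eligible
set. All ties break by smaller pair id.

Sampling: one group per instrument chosen uniformly at random, the chosen
groups concatenated into the preselected pool (counted with multiplicity —
full groups over m instruments give exactly 5m entries), and the final
sample drawn uniformly without replacement from the pool's distinct pairs,
keeping each pair's group provenance. One seed drives both stages.

Statistics: per-pair agreement is the percentage of raters whose binary
suitability vote matches the model class (model class: positive iff
SES > τ, the same τ as filtering). Class-level means carry t-based
confidence intervals on the mean (sample SD, df = n−1), reported
untruncated — an interval on a percentage may exceed 100, as untruncated
t-intervals do. Spearman's ρ between per-pair mean PSS and SES uses average
ranks for ties and the t-approximation p = 2·P(T_{n−2} > |ρ|√((n−2)/(1−ρ²)));
|ρ| = 1 reports p = 0 (below machine resolution). Pairs with PSS
SD ≥ 1 are flagged as harder to rate.

## Synthetic corpora

The generator emulates a multi-instrument health-survey corpus: filler
items instantiate one of twelve survey-style sentence frames ("how often
during the past year did you … about … or …") with slot words from a
generated 300-word vocabulary; paraphrase links copy a source item into
another instrument, substituting `round(intensity × n_tokens)` token
positions through a designated synonym dictionary that covers frame words
and vocabulary alike (so intensity 1 with the disjoint synonym set shares
no token). Each item joins at most one link. The optional second "language"
maps all tokens of chosen instruments through a bijective token dictionary —
deterministic pseudo-translation that exercises language codes and link
bookkeeping; the hash backend is not cross-lingual, so such links are only
recoverable by model backends.

Default study conditions, fixed once: 31 instruments × 15 items, 30
paraphrase links, intensity 0.3 — the instrument count of a realistic
multi-cohort pool at roughly one-third the item count, sized so the full
C(465, 2) = 107,880-pair pipeline runs in seconds. Under these conditions
and the default backend, planted links score ≈ 0.2–0.4 above the filler
mean (the regression-tested separation margin is ≥ 0.2), and verbatim
(intensity-0) links score exactly 1.0 and are fully recalled at τ = 0.99.

What passing these tests shows: the bookkeeping — enumeration, canonical
identity, thresholds, bands, coverage arithmetic, sampling design,
statistics — is correct, and the pipeline separates lexical paraphrases
from fillers. What it does not show: that any particular embedding model
separates *semantic* paraphrases in a real corpus; that remains an
empirical property of the model and data, which is exactly what the expert
rating study machinery is for.

## Numerical and degenerate-input choices

- Thresholds use strict inequality; bands use closed intervals.
- Texts empty after trimming are dropped at ingestion (counted);
  texts shorter than the n-gram length embed to the flagged zero vector.
- `classify_bands` on an empty pair table yields an all-zero report;
  empty pair lists are errors for summaries and group building.
- k-means and the final draw take explicit seeds; the pipeline derives
  named substream seeds (< 2³¹) from the single run seed, so stages stay
  reproducible independently.
- CSV artifacts are written in a fixed column order and, for pair exports,
  sorted by descending score with pair-id tie-break, making reruns
  byte-identical.

## Known limitations

- The hash backend measures lexical, not semantic, similarity; its scores
  are not comparable across backends, so τ and bands must be calibrated per
  backend.
- The synthetic generator plants one-to-one links only and does not model
  response scales, item order effects, or real multilingual wording.
- The approximate k-NN path trades recall for speed and is not used by any
  correctness test.
- Band endpoints are taken as given; the package provides no procedure to
  estimate them from ratings beyond the agreement statistics themselves.
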