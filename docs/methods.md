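# Methods

This note documents the models, the synthetic study design, the
numerical choices, and the limits of what the package's tests can show.

## The analysis chain

The pipeline audits how profile attributes relate to content exposure.
Its unit of analysis is a *document*: one video's title and description
concatenated.  Stages are strictly sequential, each consuming only the
previous stage's declared outputs:

synth → preprocess → cluster → gcn → metrics → profnet.

### Preprocessing

Tokenization NFKC-normalizes, strips diacritics, lowercases, and keeps
alphabetic runs (numeric tokens are dropped by default; configurable).
Stop words come from a fixed list shipped in the package so output is
identical across installations.  Stemming is the Porter (1980)
five-step suffix stripper, implemented here directly; it maps
inflectional families (vape/vaped/vaping) to a common base.  A
lemmatizer hook exists but defaults to the identity — stemming alone
already provides the base-form conflation the analysis needs, and any
specific lemma dictionary would be an arbitrary extra choice.  The
corpus operation is exactly the composition of the three atomic steps,
and the test suite enforces this equivalence.

### TF-IDF and clustering

TF-IDF uses the unsmoothed textbook definition
`w(d, t) = tf(d, t) · ln(N / df(t))` with natural log and no row
normalization; a term present in every document is weighted zero
everywhere.  Documents that are empty after preprocessing are excluded
from vector-space stages and logged.

Cosine-geometry k-means is realized as Euclidean k-means on
L2-normalized rows (the spherical-k-means equivalence).  We run
scikit-learn's `KMeans` with `init="random"` and `n_init` restarts,
keeping the best restart by SSE; determinism comes from the seeded
`random_state`.  The elbow rule is formalized (rather than judged
visually) as the smallest k whose relative SSE drop to k+1 falls below
a threshold, default 0.15; a constant curve therefore selects k=1, and
a never-stabilizing curve returns the largest k evaluated.  The 2-D
map of the corpus is classical (Torgerson) MDS of the cosine-distance
matrix: double-center the squared distances, take the top-2 eigenpairs,
clip negative eigenvalues at zero.  Sign of each coordinate axis is
fixed by making its largest-magnitude entry positive; raw stress is
reported alongside.

### Text-graph GCN

The corpus becomes one heterogeneous graph with a node per document and
per unique stem.  Document–word edges carry the same TF-IDF weights as
the clustering stage (one implementation, shared).  Word–word edges
carry pointwise mutual information over fixed-length sliding windows
(default 20 tokens; a shorter document is a single window), kept only
when positive.  Every node has a unit self-loop.  With identity
features (X = I), a two-layer graph convolution

    Z = softmax( Â · relu(Â W₀) · W₁ ),   Â = D^(−1/2) A D^(−1/2)

is trained by full-batch Adam (learning rate 0.02, weight decay 5·10⁻⁴
on W₀, hidden width 200, at most 200 epochs) on the cross-entropy of
labeled document nodes, with early stopping on validation loss
(patience 10) and restoration of the best weights.  No dropout is used:
the tasks here are small enough that early stopping regularizes
adequately, and omitting it keeps training exactly deterministic for a
given seed.  Labeled documents are split stratified-by-class into
60% train / 10% validation / 30% test by default; training raises if
any theme class has no training document.

### Metrics

Cohen's κ is computed on the full multi-class table, unweighted.
Precision/recall/F1 are reported per class and macro-averaged
(unweighted class means), since a single summary triple is otherwise
ambiguous; undefined ratios (class never predicted) are reported as 0
with a log note.  Metrics are rounded to 2 decimals and shares to 1
decimal in reports; share tables use largest-remainder rounding so each
row sums to exactly 100.0.

### Profile networks

A demographic group's video set is the union of unique ids over its
profiles' result lists (a video counts once per group no matter how
often it surfaced).  Edge weight between two groups is the intersection
cardinality; zero-weight edges are omitted.  Two networks are built:
marginal groups {male, female, age16, age24} and conjunction groups
{16F, 16M, 24F, 24M}.  Weighted degree centrality is the sum of
incident edge weights.  Race tags are carried through grouping
functions but no race-level network is built by default: with one or
two profiles per race × age × sex cell there are too few data points
for that comparison to mean anything.

## The synthetic study design

The generator emulates the audit that motivates the package, and its
defaults are the study conditions; they are not tuned per experiment.

* **Cohort** — 16 profiles: 4 African American, 4 Hispanic, 8 White
  (two blocks), each block balanced over age {16, 24} × sex
  {female, male}.
* **Search design** — 18 e-cigarette search terms; 7 pages × 20 results
  = 140 results per profile × term.  Collected totals are emergent
  (they depend on pool size and overlap); only the dedup identity
  `unique + duplicates = collected` is contractual.
* **Themes and text** — four content themes (product review, health
  information, instructional, other).  Each theme owns a 150-word
  vocabulary, there is a 100-word shared vocabulary, and word draws are
  Zipf-weighted (exponent 1.05).  Title and description lengths are
  Poisson with means 12 and 40.  Vocabulary words are generated as
  random letter strings filtered to be Porter fixed points outside the
  stop list, so separability is controlled here and not altered by
  preprocessing.
* **Theme mixing (ambiguity)** — each video draws an off-theme word
  rate uniformly from [0, 0.8]; each word then comes from a uniformly
  chosen *other* theme with that probability.  This emulates real
  videos whose text spans themes (a review that includes instructions)
  and is what keeps the classification task honest: with fully disjoint
  vocabularies a ~50-token document is trivially separable and every
  classifier saturates at accuracy 1.0, which no real corpus of this
  kind exhibits.  With the default ceiling of 0.8, GCN test accuracy
  lands in the low-to-mid 0.8s across seeds — above, but in the
  neighborhood of, the accuracy level reported for human-labeled
  corpora of this type (~0.72).
* **Demographic gradients** — per-(age, sex) theme mixtures are
  anchored at the prevalence pattern reported for such audits:
  instructional content is modal for 16-year-old profiles (16F 42.5%,
  16M 30.9%) and product reviews for 24-year-olds (24M 39.4%,
  24F 38.0%); the unreported cells spread the remaining mass.
* **Overlap structure** — each (age, sex) group can access a sub-pool
  whose *total* size is an age-dependent fraction of the video pool
  (0.25 for age 16, 0.45 for age 24 — emulating age-restriction of
  this content) and whose *per-theme composition* follows the group's
  theme mixture.  Sizing the slice by the mixture matters: group
  prevalence tables are computed over unique videos, and if sub-pools
  mirrored the pool's own theme composition, coverage saturation at
  realistic budgets would erase the configured group differences.
  The age-dependent total reproduces the qualitative network topology
  of interest: the 24M–24F common-video edge is the strongest and
  16M–16F the weakest, with cross-age pairs in between.  Within a group, each profile's
  accessible sub-pool copies each group slot with probability
  `overlap_kappa` (default 0.7) and substitutes a random same-theme
  video otherwise, so κ=1 gives identical supports and κ=0 independent
  ones; expected common-video counts are monotone in κ.
* **Simulated raters** — two independent coders who report the true
  theme with probability 0.975 each (uniform error otherwise), putting
  two-rater Cohen's κ near the "almost perfect" 0.93 level typical of
  trained human coding of this content.
* **Randomness** — every stochastic operation draws from a numpy
  Generator derived deterministically from `config.seed` and a
  per-operation stream id, so artifacts are bit-reproducible and
  operations may be called in any order.

### What the generator does *not* emulate

Real scraped metadata has skewed document lengths, named entities,
URLs, emoji, multilingual text, spam, and topic drift over time; search
rankings are not exchangeable within a page; duplicates cluster by
channel.  None of that is modeled.  Passing tests therefore demonstrate
that the *methods* are implemented correctly and recover planted
structure under the stated statistical assumptions — not that the
pipeline would achieve any particular accuracy on a live platform
corpus.

## Experiment problem sizes

The canned experiments use ~1000-document corpora for cluster-count
recovery and ~1500-document corpora for GCN label recovery, with 20
seeds each — sizes at which the multinomial noise on recovered
quantities is small relative to the effects being checked, while a full
multi-seed experiment remains a desk-scale (minutes, one CPU) run.
The paper-scale corpus (4201 uniques) runs through the same code path
via `vapexposure run`.

## Degenerate inputs and numerical conventions

* All-zero TF-IDF rows: excluded from clustering, similarity 0 by
  convention in cosine matrices; both logged.
* Empty clusters / assignment ties in k-means: delegated to
  scikit-learn's internal handling; results remain deterministic for a
  given seed.
* PMI: pairs never co-windowed have no edge; non-positive PMI edges are
  dropped.
* κ with degenerate marginals (p_e = 1): defined as 1.0 for identical
  labelings, else 0.0.
* F1 with p = r = 0: defined as 0, logged.
* MDS negative eigenvalues (non-Euclidean distance matrices): clipped
  to zero, which is the classical-MDS convention.
* Elbow with SSE = 0 at some k: that k is returned (a perfect fit is
  stable by definition).

## Known limitations

* The GCN is transductive: the model is tied to the graph it was
  trained on, and classifying new documents requires rebuilding the
  graph and retraining (as in the underlying method).
* The elbow threshold (0.15) formalizes a judgment call; on corpora
  whose themes blend heavily (high contamination), the rule can settle
  at k=1 because the SSE curve genuinely has no elbow.
* Bag-of-words generation cannot test tokenization robustness against
  real-world noise (handled only by the unit tests' adversarial
  strings).
* Race/ethnicity is a carried tag only; the design has too few
  profiles per race cell to support race-level analysis.
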