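# Methods

## Problem and model

The package classifies biomedical publications as relevant or irrelevant
to a curated database, combining three per-document representations:

* **d_IMG** — the binary occurrence vector of *Figure-words* over a
  2^K vocabulary, K being the number of panel-type classes in the image
  taxonomy. A Figure-word is the K-bit presence indicator of panel types
  within one figure: it abstracts a compound figure to *which kinds of
  evidence it shows together* (e.g. "fluorescence + histogram"), ignoring
  panel counts and layout. The default taxonomy has K = 11 classes —
  histogram, line chart, other diagram, macromolecule sequence, 3D
  structure, fluorescence microscopy, gel/blot, plate, light microscopy,
  other, and "separation residual" (non-informative fragments produced
  when compound-figure segmentation over-splits) — in that fixed order,
  giving a 2048-word vocabulary. Taxonomies are configurable; some
  taxonomies in circulation add a whole-mount class, and the vocabulary
  doubles with each added class.
* **d_CAP / d_TA** — embedding-mean vectors of the concatenated figure
  captions and of the title-and-abstract. Both use one fixed, externally
  trained word-embedding table (word2vec text format, 200-dimensional by
  default).

Two integration schemes:

* **CombV** concatenates [d_IMG | d_CAP | d_TA] and trains a single
  calibrated linear SVM. Because binary indicators and unbounded
  embedding means live on different scales, every feature is standardized
  to mean 0 / sd 1 — with parameters fit on the training fold only and
  applied unchanged to test documents. Constant training columns would
  have sd 0; their sd is clamped to 1 so they transform to exact zeros.
* **CombC** stacks a meta-SVM on the 6-vector
  ⟨L_IMG, P_IMG, L_CAP, P_CAP, L_TA, P_TA⟩ of per-modality base-classifier
  labels and relevant-class probabilities. Meta-features for *training*
  documents are produced by internal stratified 5-fold out-of-fold
  prediction: base outputs on their own training data are optimistically
  biased, and a meta-classifier trained on them learns to over-trust the
  bases (in-sample stacking is a classic leakage bug). At predict time the
  bases are refit on the full training set.

Labels follow probabilities through the fixed threshold L = [P ≥ 0.5]
everywhere, so label and probability outputs can never disagree.

## Text preprocessing

Pipeline order: named-entity substitution → lowercase → tokenize on
non-alphanumeric boundaries → Porter stemming → stop-word removal.
Details that matter:

* **NER** is a static surface-form → generic-term map (gene, disease,
  chemical, species, mutation, cell-line), applied longest-match-first and
  case-insensitively. Any external annotation service can be adapted by
  materializing its output as such a map; keeping the map static makes
  every run hermetic and reproducible.
* **Stemming** is the original five-step Porter algorithm, implemented
  in-package and validated against the algorithm's canonical worked
  examples. Note the genuine algorithm is *not* idempotent
  (agreed → agre → agr); no second pass is applied.
* **Stop words** use the standard English information-retrieval stop list
  frozen into the package data. Because the pipeline stems before
  removing stop words, and stemming can carry a stop word off the list
  ("this" → "thi"), a token is dropped when *either* its surface form or
  its stem is on the list.
* **Distinct-word mean**: d_CAP and d_TA average each distinct
  in-vocabulary token once, regardless of its frequency; the divisor n is
  the number of distinct in-vocabulary tokens. The more common
  frequency-weighted mean is available behind `distinct=False`.
  Out-of-vocabulary tokens are skipped and excluded from n; a document
  with no in-vocabulary tokens maps to the zero vector, which keeps
  downstream standardization well-defined.

## Degenerate inputs

Documents with no figures (or no classified panels) keep the all-zero
d_IMG rather than being dropped — real extraction pipelines yield more
figures than captions and some documents yield nothing, and a missing
modality should not exclude a document from triage. Figures with empty
panel-label lists are skipped from d_IMG with a logged warning.
Precision/recall with empty denominators return 0 with a warning.
The Figure-word index convention is taxonomy position 1 ↔ least
significant bit (index = Σ cᵢ·2^(i−1)); any fixed bijection would serve,
but this one is documented and stable across runs.

## Classifiers

All SVMs share one config: linear kernel, C = 1, Platt-style sigmoid
calibration (implemented as a calibrated linear SVM with internal
cross-validated calibration; non-linear kernels fall back to libsvm with
its built-in probability estimation), and a seed that fully determines
training. These defaults are deliberately plain — the representations,
not the classifier, are the object of study — and are config-driven.
Each base classifier standardizes its own feature block before the
margin fit (harmless for the binary image block, necessary for the
embedding blocks).

## Evaluation protocol

Repeated stratified k-fold CV: default five rounds of 5-fold CV, each
round with a distinct partition (one derived seed per round), giving 25
(round, fold) evaluations per scheme. Stratification keeps both classes
in every fold. Representations are computed once per corpus — they
involve no fitting — while standardizers, base classifiers and stacking
are refit inside every training fold. `run_cv` accepts a fit-listener
callback and announces each held-out fold to it, so tests *prove* (not
assume) that no component is ever fit on test-fold documents.

System comparisons use Welch's unequal-variance two-sample t-test on the
25 per-fold scores (round-mean pooling available by flag; fold-level is
the default because it reflects the protocol's actual replication unit).
Degenerate cases are pinned: identical score lists → (t=0, p=1); two
zero-variance samples with different means → (±inf, 0).

## Figure-word ranking

Counting is per figure, not per document — a Figure-word occurring in
three figures of one document contributes three counts — so the counts
match the scale of corpus figure totals. The two-proportion z uses the
pooled form; the pooled-degenerate cases (a word in every figure or no
figure) return z = 0 with a warning since they carry no contrast. Ranking
is by |z| descending with deterministic tie-breaks (total count
descending, then index ascending). No multiple-testing correction is
applied over the 2048-word vocabulary; the ranking is exploratory, and
consumers needing error control should apply their own correction.

## Synthetic data

The generator emulates exactly the structure the representations are
sensitive to: class-conditional Bernoulli panel-type inclusion per figure
(empty draws resampled — real figures contain at least one panel), and
class-conditional unigram token mixtures (topic words vs shared
background) for captions and titles-and-abstracts. Defaults mirror a
mid-sized curation corpus: 400 balanced documents, 5–12 figures each,
captions of 40–120 tokens, abstracts of 100–250, vocabulary 2000 with 50
topic words per class, moderate text signal (0.3), and a
fluorescence-microscopy panel contrast (inclusion 0.6 in relevant vs 0.05
in irrelevant documents) of the magnitude observed in real curation data.
Embeddings are unit-norm Gaussian vectors — near-orthogonal in 200
dimensions, so class topic sets are not collinear by construction.

Not emulated: syntax and discourse, Zipfian token frequencies, correlation
between a document's figures and its caption wording beyond the shared
class label, and panel-classification noise. Passing tests therefore show
the pipeline's statistical machinery is sound, not that real corpora are
this separable; real-data F-scores depend on upstream extraction and
panel-classifier quality that this package deliberately treats as inputs.

A `complementary` mode assigns each document exactly one informative
modality (uniformly img/cap/ta) and holds the other two at
class-independent null distributions. A single-modality classifier can
then identify only its own third of the relevant documents, while the
integration schemes can recover nearly all — the qualitative pattern that
motivates multimodal triage — and the generated manifest records each
document's informative modality so tests can assert recovery.

## Self-check experiments and problem sizes

`figword.experiments` fixes three canned experiments used by the test
suite and `scripts/acceptance.py`:

* **Null calibration** — 400 zero-signal documents, 5×5 CV, all five
  schemes; every pooled accuracy must land in the central 95% binomial
  band around 0.5. The band is computed at n = 400 (the corpus size),
  not 400 × rounds: repeated rounds re-predict the same documents, so
  treating rounds as independent draws would shrink the band below the
  statistic's true dispersion.
* **Signal recovery** — 600 complementary-signal documents, 5×5 CV;
  integration mean F-scores must be ≥ every single-modality mean F-score,
  with positive Welch t for each integration-vs-single comparison.
* **Ranking recovery** — 20 replicates of 400 documents with the
  0.6-vs-0.05 fluorescence contrast; the fluorescence-only Figure-word
  must top the |z| ranking in ≥ 95% of replicates.

These sizes give comfortable statistical margins (the planted ranking
signal sits near z ≈ 18 where the runner-up is ≈ 7) while keeping each
experiment to minutes on a single CPU.

## Known limitations

* The panel-type labels are trusted inputs; classification noise in them
  propagates directly into d_IMG and is not modeled.
* Figure-word vectors are strictly binary — no count weighting — and the
  vocabulary grows exponentially in taxonomy size, so taxonomies much
  beyond ~15 classes need a sparser downstream treatment than the dense
  d_ALL concatenation used here.
* The exact tokenizer/stop list of any particular upstream system will
  differ in detail; results are robust to this only insofar as the
  embedding table covers the resulting tokens.
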