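# Methods

## The model

`bioword` treats a protein sequence as a sentence in an unknown language.
Its words — recurrent multi-residue substrings — are not fixed a priori but
discovered from data, and the sequence's meaning (here: its interaction
behaviour) is predicted from the distributional semantics of those words.
The pipeline has three statistical components.

### Unigram-language-model segmentation

A tokenization s = (s1, ..., sN) of a sequence has probability
P(s) = ∏ p(si), with word probabilities summing to 1 over a vocabulary Φ.
Two inference problems arise:

* **Decoding.** The most probable segmentation s* = argmax P(s) is found by
  the Viterbi algorithm over the segment lattice of the sequence (nodes =
  inter-residue positions, edges = vocabulary words matching a substring).
  Cost is O(L · m) for sequence length L and maximum word length m.
* **Estimation.** With Φ fixed, the probabilities are estimated by EM on the
  marginal corpus likelihood F = Σx log Σ_{s ∈ X(Dx)} P(s), where X(D) is
  the set of all segmentations of sentence D.  Both F and the E-step's
  expected word counts are computed **exactly** by sum-product
  forward–backward over the lattice — no n-best approximation — which makes
  EM monotone in F and testable against brute-force enumeration.

The vocabulary itself is learned by iterative shrinkage:

1. **Seeding.** All observed residues plus frequent residue strings obtained
   by repeatedly merging the most frequent adjacent token pair (BPE-style)
   until the seed size is reached or no pair repeats.  Ties are broken
   toward the lexicographically smallest pair and merges are applied
   left-to-right without overlap, so seeding is deterministic.  Substring
   counting is a plain hash count capped at the maximum word length; at
   desk scale this is equivalent to suffix-array enumeration.
2. **EM** re-estimation of p(si) (2 inner iterations per round by default —
   the probabilities only need to be roughly right for ranking).
3. **Pruning.** Each removable word w is scored by the likelihood drop
   loss(w) = Σ_{D ∋ w} [log P(D | Φ) − log P(D | Φ∖{w})], holding the
   remaining probabilities fixed.  Holding them fixed (rather than
   renormalizing) makes the score exactly zero for words absent from every
   lattice and lets it be computed touching only the sentences that contain
   the word.  The top α% of removable words by loss are kept (α = 70),
   never dropping below the target size; single-residue words are never
   pruned and carry a probability floor of 1e-8 (1e-12 for multi-residue
   words) before renormalization, so every sequence always remains
   segmentable and all probabilities stay positive.

Steps 2–3 repeat until the vocabulary reaches the target size.  Viterbi
ties are broken toward fewer tokens, then the longest final word —
arbitrary but fixed, for reproducibility.

The **k-mer baseline** splits a sequence into overlapping fixed-length
substrings with a sliding window (⌊(L−k)/stride⌋ + 1 tokens).  Asking for
k > L is an error, not an empty list: an empty token list would silently
poison downstream vector averaging.

### Skip-gram embeddings and Bio2Vec

Word vectors are trained with skip-gram: maximize the average log
probability of the words within a window of c positions around each center
word, P(wO | wI) = softmax(v′_wO · v_wI).  The full softmax is replaced by
negative sampling — logistic discrimination of each true (center, context)
pair against k noise words drawn from unigram^(3/4) — optimized by
sequential SGD with a linearly decaying learning rate.  Input vectors start
uniform in [−0.5/n, 0.5/n], output vectors at zero; all randomness flows
from one seed, so training is bit-reproducible.  Gradients are hand-derived
and verified against central finite differences in the test suite.

A sequence segmented into N words is represented by the **mean** of its
word input vectors.  (The defining formula carries the 1/N factor even
though the surrounding convention often says "sum"; the mean is used here
because it makes the representation scale length-invariant.)  The mean is
permutation-invariant: word order within a sequence does not affect its
vector, only co-occurrence statistics during embedding training do.
Unknown words at vectorization time are skipped; a sequence with no known
word is an error.  Persisted embedding files store the input table in the
word2vec text dialect; the output table is training state and is not
persisted.

### The pair classifier

A protein pair is the concatenation of two sequence vectors (2K
components).  A convolution filter of window h produces the feature map
c_i = F(w · S_{i:i+h−1}) + b (nonlinearity inside, bias outside — applied
exactly as the defining formula is written), of length K − h + 1, which is
max-pooled to a single scalar per filter.  Three parallel subnetworks
process the pair vector: the first applies two convolution+pooling stages
(windows 3/3, 32 then 16 filters), the second and third one stage each
(windows 5 and 7, 32 filters).  Because pooling alone cannot hit exact
widths, a trainable linear projection (plus ReLU) brings the subnet outputs
to 64, 32 and 128 features; their 224-dimensional concatenation passes
through dropout (rate 0.5) and a fully connected sigmoid unit.  Kernel
windows and filter counts are configuration — the architecture's hard
constraints are the 64/32/128 subnet widths, the 224-wide penultimate
layer, and the two-stage first subnet.

Training minimizes binary cross-entropy with the Nadam optimizer (Adam
with Nesterov momentum, lr 0.002, β1 0.9, β2 0.999), mini-batches of 64,
dropout active during training only, early stopping on validation loss
with patience 10 (200 epochs maximum), returning the best-validation
snapshot.  The decision threshold is 0.5.  Pair order (A,B) vs (B,A) is
not symmetrized: pairs are used in dataset order.

## Evaluation

Accuracy, sensitivity TP/(TP+FN), precision and MCC are computed from the
confusion matrix.  (One published rendering of the sensitivity formula
reads TP/(TN+TP); that is not sensitivity, and the standard definition is
used.)  A metric with a zero denominator is reported as NaN with a stated
reason, never as silent zero.  The ROC sweeps all thresholds
(scikit-learn's `roc_curve` without intermediate dropping) and the AUC is
the trapezoidal integral, which equals the tie-aware normalized
Mann–Whitney U statistic — asserted against a brute-force pairwise oracle.

The split protocol reads the usual "nine tenths for model fitting, split
80/20 into train and validation, one tenth held out" as fractions
0.72/0.18/0.10, stratified by label with largest-remainder rounding, so
realized counts are within one pair per stratum.

## Synthetic data: what it emulates and what it does not

The generator realizes exactly the assumptions the pipeline makes, so each
stage can be scored against planted truth:

* **Planted vocabulary** — n words (default 50) of length 2–6 over the
  20-letter amino-acid alphabet, occurrence probabilities from a symmetric
  Dirichlet (concentration 5).  Rejection sampling guarantees no word is a
  substring of another, making recovery scoring unambiguous.
* **Sequences** — i.i.d. word draws concatenated (the unigram assumption),
  with 5% probability mass on single residues as noise; 25 words per
  sequence by default.
* **Interaction rule** — the words are split into 2 latent modules; each
  protein draws 95% of its non-singleton words from its own module, and a
  pair interacts iff both members contain ≥ 4 words of the same module.
  Pairs are sampled half within- and half across-module so both classes
  appear (realized prevalence ≈ 50%); every label is recomputed from the
  predicate, never assigned.  The defaults (purity 0.95, threshold 4,
  25 words/sequence) give a clean, near-deterministic rule whose signal is
  carried entirely by word content — which is what the method claims to
  exploit.

What the generator does **not** emulate: realistic protein evolution,
homology and shared domain architecture, length variation, compositional
bias, or label noise from imperfect interaction assays.  Passing the
synthetic acceptance tests therefore shows the machinery is correct and
can learn a word-content-driven interaction signal; it does not predict
performance on curated PPI benchmarks.

## Problem sizes and numerical choices

The acceptance experiments run at desk scale: 2000 pairs over 800
synthetic proteins, a 50-word planted vocabulary learned at target size
100 from a 300-sequence subsample (word statistics saturate well before
that), seed vocabulary 400, 32-dimensional embeddings (window 5, 5
negatives, 5 epochs).  Likelihoods are accumulated in log space with
`log1p`-based log-add-exp; `math.fsum` is used for corpus sums; the
sigmoid is branch-stabilized.  Per-stage pipeline seeds derive from the
master seed by `(master · 1009 + stage_index) mod 2^31`.

## Known limitations

* EM's M-step floors make F monotone only up to ~1e-9; assertions allow
  that slack.
* The word-loss computation scores words one at a time; interactions
  between simultaneously pruned words are ignored (standard practice).
* Skip-gram training is a sequential Python/numpy loop — fine for
  desk-scale corpora (hundreds of thousands of updates), not for
  proteome-scale runs.
* The classifier convolves over vector components of the learned
  representation; kernel windows/filter counts beyond the fixed widths are
  unconstrained configuration, and different choices will shift accuracy.
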