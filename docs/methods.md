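# Methods

## Model

`bacner` tags bacteria mentions with a linear-chain conditional random
field over IOB2 label sequences. For a tokenized sentence x of length n and
labels y ∈ {O, B-BAC, I-BAC}ⁿ, the unnormalized log-score is the sum of
state terms (one weight per active feature string and label) over positions
1..n and transition terms (one weight per active feature string and label
pair) over edges between consecutive positions. The conditional probability
is this score minus the log-partition log Z(x), computed by the forward
recursion.

Assumptions worth stating explicitly:

* **First-order Markov labels.** Only adjacent labels interact; the model
  cannot express longer-range label constraints directly (contextual
  evidence enters through the observation features, whose windows span
  −2..+2 by default).
* **Boundary handling.** No transition factor enters position 1. The
  begin-of-sentence context is instead carried by state feature strings
  containing the `_BOS_` sentinel, which is equivalent to a virtual BOS
  label whose fixed transition weights are folded into first-position state
  scores. End of sentence is symmetric via `_EOS_` valued features.
* **Label-free features.** Template expansion is a function of the
  observation sequence and position only. Conjoining with labels happens in
  the weight table, mirroring CRF++ template semantics: a `U` template
  string carries L weights, a `B` template string L² weights, and the bare
  `B` line is the observation-independent transition bias.

## Features

Eighteen attribute functions per token: surface word, lowercased word,
prefixes and suffixes of lengths 1–4 (absent when the token is shorter),
word shape (capitals→X, lowercase→x, digits→d, other kept) both verbatim and
run-compressed, six orthographic flags (initial capital, all caps, contains
digit, contains hyphen, single character, all punctuation), and a dictionary
flag. The dictionary flag is case-sensitive exact word membership: a token
matches if it equals any whitespace-separated word of any gazetteer entry.
Longest-match phrase tagging was considered and rejected: word membership is
the simplest rule that lets a model combine dictionary evidence with
context, and it naturally fires on the species epithet of abbreviated
writings ("coli" in "E. coli").

The default template file (31 lines) crosses these attributes with context
offsets: word unigrams at −2..+2, two word bigrams, affixes/shapes/flags at
the current position, shape and dictionary flags at ±1, one
dictionary×capitalization conjunction, and the transition bias. The template
file is plain text and user-editable, so any alternative feature
configuration is expressible without code changes. Feature strings observed
fewer than `min_count` times (default 1 — corpora here are small) are
dropped; ids are assigned in lexicographic order so retraining is
reproducible, and the index is frozen afterwards: unseen strings at
prediction time contribute zero score.

## Training

The penalized objective is NLL(w) = Σⱼ [log Z(xⱼ) − score(xⱼ, yⱼ)] +
‖w‖²/(2σ²), convex in w. Defaults: Gaussian prior σ = 1.0, start at w = 0,
stop when the gradient infinity-norm falls below 1e−4 or after 200
iterations. Gradients are exact (expected minus empirical feature counts,
plus w/σ²) from forward–backward in log space; no scaling-factor variant is
used — log-sum-exp is simpler and stable at these sentence lengths.

Optimizers: L-BFGS (scipy, default), full-batch Adam (lr 0.1, β₁ 0.9,
β₂ 0.999) and AdaGrad (lr 0.5), and per-sentence SGD with seeded shuffling
and 1/(1+0.05·t) step decay. Because the objective is convex, the
full-batch methods agree at convergence (the tests assert agreement within
1e−3 of NLL); SGD is provided for completeness and converges more loosely.
`max_iter = 0` returns the zero-weight model, whose Viterbi output is the
tie-break label at every position — label order fixes O first, then
B-BAC, I-BAC, so that degenerate model predicts all-O rather than inventing
entities.

Viterbi tie-breaking is toward the lowest label id at every backpointer
decision, making outputs fully deterministic. Models serialize to a single
self-describing JSON file carrying the label order, feature strings,
weights, template text, dictionary, and training config; loading a file with
a newer format version fails loudly. JSON float round-tripping is exact, so
save → load → predict is bit-identical.

## Tokenization

Rule-based and documented rather than learned: sentences split at
sentence-final punctuation followed by whitespace and a capital letter,
except after single-letter abbreviations ("E." in "E. coli" never ends a
sentence); tokens split on whitespace with leading/trailing punctuation
detached as separate tokens, keeping internal periods ("7.0") and
single-letter abbreviations intact. Determinism matters more here than
coverage of every edge case in real prose; the rules are exercised by a
sentence-level idempotence property and a detokenize/retokenize round trip.

## Synthetic corpora

No manually annotated bacteria corpus is redistributable, so the generator
plants known entities into template sentences and keeps the gold spans. It
emulates: multi-token Latin binomials (a shipped list of ~50 real names),
abbreviated writings (genus initial + species, 30% of multi-token mentions
by default), out-of-dictionary mentions (plausible Latin-shaped names
absent from the gazetteer, 10% of mentions), surface nesting (the name list
contains pairs like *Escherichia coli* / *Escherichia coli O157*; IOB2
cannot encode overlapping gold spans, so only the planted span is
annotated), and light context noise (one casing flip or character swap in
2% of sentences). An entity slot receives an entity with probability 0.7,
otherwise a filler noun phrase. These defaults are meant to resemble
abstract sentences about bacteria at a difficulty where dictionary,
affix and shape features all matter; they are fixed, not fitted.

Two template groups with fully disjoint context vocabulary ("train" and
"eval") support held-out experiments in which no context word seen at
training time recurs at evaluation: performance then rests on the shared
gazetteer and token-internal features. What passing these tests does *not*
show: real abstracts have far richer context distributions, genuinely novel
morphology, nested and discontinuous mentions, and annotation
inconsistencies; synthetic F-Measures (which reach 100% here) are an upper
bound and say nothing about absolute accuracy on real corpora.

## Evaluation

Entities are decoded from tags as maximal `B-BAC (I-BAC)*` runs; a stray
`I-BAC` is repaired as if it began an entity (evaluation never crashes on
decoder output). Matching is exact on sentence, boundaries and type — the
strictest defensible criterion; partial-overlap credit is out of scope. F
is the harmonic mean 2PR/(P+R), reported as percentages to three decimals;
zero denominators yield 0 with a degenerate flag rather than NaN.

## Parallel prediction

Decoding is a pure function of (model, sentence), so the batch predictor
guarantees bit-identical output for every (workers, chunk size) partition
plan — asserted exactly in tests, including the sequential path. Chunks are
contiguous and ordered; workers (joblib/loky processes) receive the model
read-only and never mutate shared state; a failing chunk aborts the run
with an error naming the chunk. The timing harness reports mean wall time
over 5 repeats per plan and derived sentences/second; timings are
informational only and never asserted against fixed values, since they are
a property of the host, not of the method.

## Problem sizes and numerical choices

Property tests compare the dynamic programming against brute-force
enumeration on random models with n ≤ 6 positions and L ≤ 4 labels
(tolerance 1e−10 in the log domain) and the analytic gradient against
central finite differences (step 1e−6, relative tolerance 1e−5). The
held-out experiment uses 1000 training / 300 evaluation sentences; the
separable-fit and optimizer-agreement checks use a 10-sentence corpus.
These sizes were chosen so the full suite and the acceptance script each
complete in a few minutes on one core while leaving the measured quantities
stable across seeds.

## Known limitations

First-order chain only (no semi-Markov or neural potentials); no L1
sparsity; single-machine worker-pool parallelism rather than a cluster
scheduler; dictionary matching is word-level, not phrase-level; the
tokenizer is heuristic; IOB2 cannot represent nested or discontinuous
entities, so nesting is emulated only at surface level.
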