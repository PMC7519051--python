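# Methods

## Problem and approach

The package studies how a sequence-to-sequence reaction-product predictor
trained on a large corpus of generic reactions can be specialized to a
small corpus of reactions whose outcome depends on stereochemistry and
functional-group context.  A reaction is written as a SMILES translation
task: the precursor fragments (reactants and reagents, undifferentiated,
joined by `.`) are the source sequence, the product fragments the target.
An encoder–decoder transformer learns the mapping; a prediction counts as
correct only if its canonicalized, fragment-sorted product multiset equals
the reference's.

Two transfer routes are implemented and compared against single-corpus
baselines:

* **multitask** — one model trained from scratch on a weighted mixture of
  the two corpora: each training example is drawn from the general corpus
  with probability `w_a / (w_a + w_b)` (so weights 9:1 show one
  specialized reaction per nine generic ones), each corpus cycling in
  reshuffled epochs;
* **sequential fine-tuning** — pretrain on the general corpus only, then
  continue training briefly on the specialized corpus alone.  Because the
  general corpus contains no stereo descriptors, the pretrained
  vocabulary lacks the stereocenter tokens (`[C@H]`, `[C@@H]`); before
  fine-tuning, the embedding table is extended to the union vocabulary,
  copying rows of shared tokens exactly and drawing rows for new tokens
  from the initializer distribution.

A model whose vocabulary lacks a token assigns it probability zero;
since every specialized reference product contains a stereocenter token,
the pretrained model's top-1 accuracy on the specialized test set is
*exactly* 0% — the transfer experiments measure how much of that is
recovered, and at what cost, by each route.

## The transformer

A deliberately small pre-layer-norm transformer implemented in NumPy with
explicit forward/backward passes (verified against finite differences in
the test suite):

| parameter | default | notes |
|---|---|---|
| layers (enc = dec) | 2 | |
| attention heads | 4 | |
| model width `d` | 64 | embedding and residual stream |
| feed-forward width | 128 | ReLU |
| dropout | 0.1 | attention weights, residual branches, embeddings |
| label smoothing | 0.0 | kept off so token probabilities stay interpretable |
| batch size | 24 examples | |
| optimizer | Adam (β = 0.9/0.998, ε = 1e-9) | gradient norm clipped to 1.0 |
| learning rate | `2.0 · d^-1/2 · min(s^-1/2, s · w^-3/2)` | warmup `w` = 500 steps |
| positions | sinusoidal | |
| embeddings | shared source/target, tied output projection | |

The width was chosen by measuring convergence at fixed step budgets:
at a few thousand optimizer steps a 64-wide model reaches substantially
higher exact-match accuracy than 96- or 128-wide ones, which are still
far from converged when the budget ends.  `ModelConfig.full_scale()`
exposes a GPU-scale profile for completeness; nothing in the tests uses
it.  Training is seeded and repeatable on one machine in single-threaded
mode; across BLAS builds results agree only to numerical tolerance.

Fine-tuning uses its own adaptation protocol, every element of which
serves fast convergence within a small step budget on a small clean
corpus: the learning-rate schedule is restarted with a fresh 200-step
warmup (shorter than pretraining's 500: with a 1,000-step budget a long
warmup would consume half of it) and the optimizer state is reset;
dropout is turned off (regularization noise costs more than it buys in a
short adaptation — measured desk-scale accuracy is markedly higher
without it); the batch size is doubled and the learning-rate factor
raised 1.5×, since larger batches reduce gradient noise enough to
support the higher rate.  All of these are overridable;
`restart_schedule=False` continues the pretraining schedule instead.
Label smoothing stays off by default because the confidence score — the
product of the decoder's probabilities of the emitted tokens, end token
included, accumulated in log space — is a headline mechanism and should
be a raw probability.  Out-of-vocabulary tokens are rejected loudly
during training; at inference they map to the unknown token (logged).

## The synthetic grammar

The generator emulates the study's two-corpus setting with a grammar
whose products are a pure deterministic function of the precursors, so
the data are solvable by construction and accuracy ceilings are clean.

**General domain** (default 8,000 train / 500 test): random alkyl
scaffolds with optional methyl branches, an optional ether oxygen and an
optional secondary hydroxyl, pushed through three templates — O-acylation
by an acyl chloride, bromide→amine substitution, and ester hydrolysis
(two-fragment product).  The token inventory contains no `@` and no
bracket atoms.  Crucially, scaffolds with several oxygen sites teach the
*base regiochemical rule*: acyl chlorides acylate the terminal hydroxyl.

**Specialized domain** (default 1,000 train / 500 test): acylation of
chiral diols `R–[C@H](OH)–(CH₂)ₙ–OH` whose prefix `R` is drawn from the
same alkyl/ether scaffold distribution as the general domain.  The site
is context-dependent: `@` directs the acyl group to the secondary
hydroxyl, `@@` to the primary one, and a methyl-blocked secondary site
diverts to the primary regardless of the descriptor.  Two substrates
identical except for `@` vs `@@` therefore yield different products, and
every reference product retains a stereocenter token after
canonicalization.

Publication years are drawn uniformly from 2005–2020 for time-split
experiments.  `noise_rate` replaces that fraction of products with the
wrong-but-valid alternative outcome (the non-selected site); it defaults
to 0.  Duplicate reactions are permitted (the rate is logged); at the
default sizes the specialized train set covers under a tenth of the
reachable reaction space and roughly three quarters of the test
reactions never occur in training, so test performance requires
compositional generalization, not lookup.

What the grammar does *not* emulate: reagent/condition effects,
stoichiometry, yields, competing pathways, noisy or inconsistent
literature data, and the heavy-tailed molecule-size distribution of real
corpora.  Passing the desk-scale experiments therefore demonstrates the
*mechanisms* (vocabulary closure and recovery, transfer gain over
single-corpus training, mixture weighting, confidence calibration), not
real-world accuracy levels.

## Study conditions and problem sizes

The experiment suite (shared by the acceptance tests and
`scripts/acceptance.py`) uses: general 8,000 train / 500 test,
specialized 1,000 train (from a 2,000-record pool for the size series) /
500 test; pretraining 3,000 steps; fine-tuning 1,000 steps; the
specialized-only baseline at the matched 4,000-step total budget of the
sequential recipe; fine-tune size series 250/500/1,000/2,000 with nested
subsamples (a fixed seeded permutation, prefix of length n), which makes
the size–accuracy curve monotone-comparable.

The multitask run (weights 9:1) trains for 20,000 steps.  Its budget is
set by *specialized exposure*, not total steps: at 9:1 one example in
ten is specialized, so 10,000 steps would match the fine-tune budget's
1,000 specialized batches; this is doubled because the mixture must
learn the general task inside the same run rather than inheriting it
from a pretrained checkpoint.  The full-scale protocol has the same
shape — multitask training runs roughly fifty times longer than
fine-tuning.  Training corpora are canonicalized before training, as in
full-scale practice; error analysis shows that emitting RDKit-canonical
spellings of diverse scaffolds is precisely the data-hungry skill that
pretraining transfers (a specialized-only model makes almost no
selectivity-rule errors but many canonical-serialization errors on
scaffolds it has not seen).

These budgets mirror the full-scale asymmetry of long pretraining versus
an order-of-magnitude shorter adaptation, at sizes a single CPU core
trains in minutes.

## Numerical and design choices

* Canonicalization is RDKit's, isomeric (stereo preserved); fragments on
  each side are sorted lexicographically afterwards, so exact-match
  comparison is order-invariant.  Records whose products fail
  canonicalization are dropped from training corpora with a logged count.
* The tokenizer is the standard atom-wise SMILES regular expression:
  bracket atoms, `Cl`/`Br` and `%NN` ring closures are single tokens;
  `detokenize ∘ tokenize` is the identity on every tokenizable string.
* The multitask mixture is a per-example Bernoulli draw, not strict
  interleaving: the weight ratio holds in expectation (tested against the
  99% binomial interval over 10,000 draws), batches stay homogeneous in
  size, and both corpora still cycle exhaustively per epoch.
* Deduplication keys on the full canonical reaction string, keeps first
  occurrences, and passes uncanonicalizable records through (logged).
  Cross-corpus deduplication is available but off by default.
* Time splits place `year < cutoff` in train+validation and
  `year ≥ cutoff` in test; undated records are excluded and counted.  A
  validation set is carved from train+validation by a seeded random 5%
  when needed.
* Beam search ranks candidates by the sum of token log-probabilities
  (equal to log confidence; no length penalty), so ranks are
  non-increasing in confidence; beam size 1 reproduces greedy decoding
  exactly, and batched greedy decoding is used for bulk evaluation.
* Cross-entropy and log-softmax are computed in float64 regardless of the
  parameter dtype; confidences are products of per-token probabilities in
  log space, so 500-token products do not underflow.
* An invalid (non-canonicalizable) top-1 prediction counts as incorrect
  and increments the invalid-SMILES fraction; it never raises.
  Calibration bins are left-open/right-closed with default edges
  0/0.2/0.4/0.6/0.8/1.0; the 0.8 edge is highlighted in reports because
  correct predictions cluster above it.

## Known limitations

* The transformer is CPU-sized; absolute accuracies on real corpora are
  out of reach by design, and no attempt is made to reproduce them.
* The scenario orderings are budget-bound statements.  At full scale a
  small specialized corpus is *fundamentally* insufficient to learn
  general chemistry, whatever the step count; the toy grammar is simple
  enough that a specialized-only model keeps improving beyond the
  matched budget and eventually closes the gap.  The desk-scale
  experiments therefore demonstrate the transfer advantage at the
  protocol's budgets, not an asymptotic data limitation.
* Beam search recomputes the decoder per step (no key/value cache); fine
  for desk-scale sequence lengths, wasteful beyond them.
* Fine-tuning on the specialized corpus alone erodes general-corpus
  accuracy (catastrophic forgetting); the multitask route avoids this at
  the cost of much longer training — the same trade-off the full-scale
  setting exhibits.
* The grammar's selectivity rule is binary (secondary vs primary site);
  real regio-/stereoselectivity is graded and condition-dependent.
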