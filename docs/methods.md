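# Methods

## Model

`prunebm` works with Bernoulli Boltzmann machines: stochastic binary
networks of a visible layer **v** and one or two hidden layers **h¹**,
**h²**, coupled by symmetric weights between consecutive layers only.
The energy of a joint configuration is

    E(v, h; φ) = − Σᵢ bᵢᵛ vᵢ − Σⱼ bⱼʰ hⱼ − Σᵢⱼ wᵢⱼ vᵢ hⱼ

(with the analogous additional bias and pairwise terms for a second
hidden layer), and states are distributed as p = e^{−E}/Z at unit
temperature.  Units are binary (firing/silent); conditional on the
neighbouring layers, each unit fires independently with probability
σ(bias + weighted input).  Every weight matrix carries a binary mask:
pruning a synapse zeroes its mask entry while the stored value is kept,
so retraining resumes from unaltered surviving parameters.  Networks of
at most 24 units are enumerated exactly (joint table, partition function,
visible marginal); this enumeration is the oracle for every sampled
quantity in the test suite.

## Importance estimates

The Fisher information matrix of a Boltzmann machine is the covariance of
the per-parameter energy-gradient statistics (vᵢhⱼ for weights, unit
values for biases) under the model distribution.  Its diagonal is locally
available at each synapse: because units are binary,

    F_w = ⟨vh⟩ (1 − ⟨vh⟩),

the variance of the pre–post coincidence ("variance FI").  A second,
fully local estimate replaces the tracked coincidence by a mean-field
expression in the synaptic weight and the two mean rates,

    ⟨vh⟩ ≈ ⟨v⟩⟨h⟩ / (⟨v⟩ + (1 − ⟨v⟩) e^{−w(1−⟨h⟩)}),

("heuristic FI"); at w = 0 it reduces exactly to independence ⟨v⟩⟨h⟩.
Rates are clipped to [1e−6, 1−1e−6] before use because the implicit
log-odds inversion is undefined at the boundary; the clipped value
returns the analytic limit rather than raising.  For small networks the
full FIM is computed exactly and the magnitude each weight receives in
the leading eigenvector is a third criterion; the FIM's strong rank-1
structure makes the diagonal a faithful proxy (for an exactly rank-1
matrix, diag ∝ u², an identity the tests assert).

Activity statistics come from three protocols: free-running thinned Gibbs
chains (model distribution), clamped sampling (one hidden sample per data
instance, exact for an RBM), and a clamped *expectation* estimator that
uses conditional probabilities (mean-field means for DBMs) in place of
binary samples.  The expectation estimator is a Rao-Blackwellisation: it
estimates the same ⟨vh⟩ with far lower variance at the same instance
count.  The prune loop uses it by default because the criterion ranks
~10³ weights whose importances differ by factors of only 2–5 in the
relevant tail; at desk-scale sample sizes the single-sample estimators'
Poisson noise scrambles that ranking, while the expectation estimator
preserves it.  Both sampling modes remain available and are verified
against the enumeration oracle.

## Pruning

Each iteration ranks the live weights of a layer pair by the chosen
criterion and removes the lowest-ranked so that exactly
floor((100−p)/100 · n_live) survive — iterated halving of 910 weights
therefore yields 455 → 227 → 113.  Ties are broken by (importance, row,
column) so runs are bit-reproducible.  Two overrides: if more
zero-importance live weights exist than the percentile would remove, all
of them are removed at once (FI criteria only); the Anti-FI control
inverts the variance-FI ranking and removes the *most* important weights.
The random-unit control removes whole hidden units chosen uniformly,
keeping the smallest unit count whose total fan reaches the matched
weight budget (ceil(budget / fan)).

Hidden units whose incoming — or, in DBMs, outgoing — weights are all
masked are deleted, cascading until stable, so the deleted-weight total
can exceed the percentile specification.  Visible units left without
live synapses are reported as disconnected but retained, preserving data
column indexing.  After pruning, the model retrains for a configured
number of epochs from the surviving values (no re-initialisation, no
weight rewinding).

## Training

RBMs are fit by k-step contrastive divergence (positive statistics from
the data with p(h|v), negative statistics from a k-step alternating Gibbs
reconstruction), per-instance updates, learning rate decaying
logarithmically (default 0.1 → 0.01 over 2 epochs), momentum 0.9, weights
initialised N(0, 0.1²), hidden biases −2 (encouraging sparse codes),
visible biases at the data log-odds log[p/(1−p)].  DBMs are built by
greedy pretraining of two RBMs (the second trained on sampled hidden
codes of the first, the shared layer's biases merged by averaging) and
then trained jointly: mean-field variational inference provides the
positive phase (damped fixed-point iteration, default damping 0.8) and
100 persistent free-running Gibbs chains the negative phase, with each
weight matrix's spectral norm clipped to 6 after every update.  The
damping coefficient does not change the fixed point, only the approach —
a property the tests check — and non-convergence is flagged rather than
raised.

## Synthetic data

The patch-mixture generator emulates binarized circular image patches.
Latent causes are prototype pairs — a random pixel subset and its
complement at equal frequency — so every pixel's mixture marginal is
exactly 1/2, the signature of thresholding at the median.  Pair
frequencies decay geometrically (default 0.65 per rank, six pairs),
giving a sloppy spectrum of common and rare causes; samples flip each bit
independently with probability 0.05.  The default 13 pixels match the
radius-2 discrete disk, keeping the full pattern distribution enumerable.
This design is deliberate: rare-cause detectors develop large, selective
weights yet fire rarely, which is the regime where weight magnitude and
activity-based importance genuinely disagree.  An equal-frequency
mixture with unbalanced pixel marginals does not produce that
dissociation — importance then has no between-unit spread in its tail —
and the criterion comparison degenerates.

What the generator does *not* emulate: spatial smoothness and
translation structure of natural images, long-range pixel correlations,
and continuous grey-level statistics.  Passing results therefore show
that the pruning machinery orders criteria correctly when the latent
cause spectrum is sloppy and marginals are balanced, not that it
reproduces any particular natural-image experiment.

The labeled fixture (`toy_digits`) draws block/bar/frame shapes on a
12×12 grid with a one-pixel border forced to zero in every sample, so
border pixels carry no class information and importance-guided pruning
should disconnect them.

## Study protocol and problem sizes

The canonical experiment (`cli_io.rbm_patch_experiment`) trains a fully
connected 13×70 RBM (910 weights) on 10,000 mixture samples and prunes
four iterations at the 50th percentile (455 → 227 → 113 → 56 surviving
weights) with two retraining epochs per iteration, recording remaining
weights, remaining units, and generative fit at each step.  Generative
fit is KL(data ‖ model) between the empirical pattern distributions of
the training data and of 2,000 model samples (parallel Gibbs chains,
thinning 20 — mixing on these 13-unit models is fast; the thinning-200
storage default remains for larger models), with model-side probabilities
floored at 1/(10·n_samples) and renormalised.  The criterion comparison
aggregates hidden-unit counts over the whole matched weight-count grid
(the per-iteration counts are directly comparable because survivor
counts are deterministic), which is less noise-sensitive than any single
iteration.

## Numerical choices

* Enumeration guard at 24 units; exact FIM built from the joint table in
  covariance form and symmetrised; PSD up to 1e−9.
* Percentile removal is count-based with deterministic index tie-breaks,
  not value-thresholding, so halving sequences are exact integers.
* The epsilon floor for unseen patterns is 1/(10·n_model_samples)
  (Laplace-style smoothing scaled to sample size).
* The encoding-quality classifier is multinomial logistic regression
  (lbfgs, C = 1.0, seeded) on an 80/20 stratified split; it is an
  instrument, not part of the model.
* One master seed fans out through CRC-derived named streams (data,
  init, train, prune, eval), so stages can be re-run in isolation and
  whole runs are byte-reproducible.

## Known limitations

* Exact generative evaluation is limited to ≤ 24 visible units; larger
  models are compared only through sampled pattern distributions.
* The mean-field positive phase underestimates correlations between
  hidden layers; the expectation estimator for (h¹,h²) coincidences
  inherits that factorisation.
* Random-unit matching uses the average live fan per unit, which is only
  exact for fully connected layers.
* CD/PCD training at these sizes is per-instance and sequential; the
  implementation favours reproducibility over throughput.
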