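# Methods

This note documents the models and procedures implemented in
`ratsearch`, the assumptions behind them, the parameters that matter,
and what the synthetic test conditions do and do not show.

## Neural simulation core

Vectors are represented by populations of leaky integrate-and-fire
(LIF) neurons following the standard encoding/decoding scheme: neuron
*i* receives current `J_i = alpha_i * e_i . x + J_i^bias` where `e_i`
is its unit preferred-direction vector, and fires according to the LIF
nonlinearity.  In normalised units the membrane evolves as
`dV/dt = (J - V)/tau_rc`, spikes at `V = 1`, resets, and is clamped
for the refractory period `tau_ref`.  The steady-state rate is

    r(J) = 1 / (tau_ref - tau_rc * ln(1 - 1/J))   for J > 1, else 0.

Defaults are `tau_rc = 20 ms`, `tau_ref = 2 ms`, timestep `dt = 1 ms`,
feedforward synapse `tau = 5 ms`; all configurable.  Maximum rates are
sampled uniformly in [200, 400] Hz and intercepts uniformly in [-1, 1)
(for multidimensional ensembles the intercept distribution is adjusted
to the cosine distribution of random directions, so that a useful
fraction of neurons is active for any represented unit vector).

Numerical choices worth knowing:

* The discrete LIF step back-interpolates threshold crossings, so the
  refractory period starts at the true (sub-step) spike time.  Spike
  counts over 10 s match the closed-form rate to well under 1% at
  `dt = 1 ms`; the test suite verifies 2% against an independent
  brute-force integration of the membrane ODE at `dt = 10 us`.
* Decoders are solved from rate-model activities by regularised least
  squares (ridge term `(0.1 * max rate)^2` on the Gram diagonal by
  default).  Unregularised solves raise on ill-conditioned activity
  matrices rather than returning garbage.
* Connections always run in factored form (decode, transform,
  re-encode); the full weight matrix `W_ji = alpha_j e_j^T (T d_i)` can
  be materialised for inspection and is verified to produce identical
  currents to machine precision.
* Inhibitory gating connections deliver a current scaled per neuron by
  its maximum drive (`gain + bias`), so a unit gating signal silences a
  population outright regardless of its tuning; a decoded negative
  input cannot guarantee that.

## Word vectors and the association transform

Words are quasi-orthogonal random unit vectors ("semantic pointers"),
drawn by rejection sampling under a pairwise absolute-dot-product bound
(default 0.1 at the production scale of 5018 words in 2048 dimensions;
the bound is enforced on the absolute value because sign-symmetric
cross-talk is what corrupts clean-up).  Only the offending candidate is
redrawn, so generation is deterministic per seed.  Exhausting the
per-slot attempt budget raises a capacity error naming N, D and the
bound.

Associations are retrieved by one linear map.  With word-vector matrix
`V` (N x D) and association matrix `A` (`A[i, j]` = strength from word
i to word j), the transform `A~ = V^T A^T V` sends `w_i` to the
superposition of its associates' vectors.  Retrieval fidelity is
limited by the Gram matrix `V V^T = I + E`: at the scaled-down test
size (N = 50, D = 256) the off-diagonal cross-talk (~1/16 per pair)
caps the raw correlation between association rows and retrieved
similarity profiles at about 0.85.  The clean-up memory's
representation threshold (0.1) suppresses this sub-threshold
cross-talk, restoring the correlation to above 0.95; the acceptance
test measures fidelity this way, i.e. as the architecture actually
reads the profile.  At the production dimensionality the raw profile
itself is clean.

## Association data

Norms tables (cue, target, strength) load into a labelled sparse CSR
matrix; co-occurrence matrices are built by summing bigram counts
("fire fly") and compound-word counts ("firefly") over a word list.
Three transformations produce model variants:

* binarise - keep only link existence (1 for any non-zero strength);
* symmetrise - `A + A^T`, making associations reciprocal;
* prune - remove exactly `round(fraction * nnz)` links uniformly at
  random (optionally coupled across directions), modelling individual
  differences in associative networks.

The generation pipeline for the search model is load -> binarise ->
prune, with the pruned fraction drawn uniformly from [0.6, 0.8] per
simulation.  Binarising first makes "associations" a set, which is
what removing a fraction of associations presumes.  Symmetrisation is
used only when building symmetric filter matrices, never for the
generation matrix.

## The search model

The model searches for a word related to three cue words by
alternating two processes in spiking neurons:

* **Cue selection.**  Each cue vector passes through gating neurons
  into a primary-cue ensemble.  Three scalar selection ensembles race
  under white noise (std 0.01, with the 1/sqrt(dt) power convention)
  with mutual inhibition; the winner silences its inversion group
  (biased to represent 1), which stops inhibiting the winner's gate.
  The three selection ensembles share identical tuning curves so the
  race is decided by the noise process, not by frozen tuning
  asymmetries.  A periodic reset signal (default every 1 s, 150 ms
  pulse) silences the selection ensembles and forces a fresh race.
* **Response generation.**  A clean-up memory holds one small neuron
  group per vocabulary word, with the group's preferred direction on
  its word's axis and intercepts at or above the representation
  threshold 0.1.  Its input is the superposition of the associates of
  all three cues (weight `cue_strength = 0.1` each), of the primary cue
  (`primary_cue_strength = 0.7`) and of the current response
  (`wta_feedback_strength = 0.5`, producing local chain-like search),
  each through `A~`; input currents below the cut-off
  `assoc_th = 0.05` are zeroed.  The cut-off (0.05) and the
  representation threshold (0.1) are deliberately distinct parameters.
* **Response inhibition.**  A leaky integrator (recurrent gain 0.95
  through a 150 ms synapse) accumulates recent winners and inhibits
  the clean-up memory in proportion, so the active word is subject to
  growing suppression until a new word displaces it.

Winner-take-all details that proved essential at scaled-down size:

* Lateral inhibition is transmitted through a steep *step* decode (a
  group inhibits rivals only once clearly active, then at full
  strength).  With linear lateral inhibition, several equally driven
  groups rise together, their summed delayed inhibition crashes
  everyone, and the network bursts at ~12 Hz instead of settling.
* The identity decode of the similarity groups saturates at 1, so a
  winner pushed past the represented range by self-excitation still
  transmits clean values.
* The response-inhibition integrator is represented in the same
  word-axis basis as the clean-up memory.  A dense D-dimensional
  mixture representation lets older words' suppression rotate away
  under cross-talk; per-word integrator groups decay independently.
  Threshold-style intercepts make it leak faster near zero, damping
  decode-noise accumulation; input and output cut-offs
  (`integrator_input_cutoff`, `integrator_output_cutoff`) keep noise
  from charging it and residual charge from inhibiting.

The lateral inhibition (2.5), self-excitation (1.5), integrator input
strength (0.12) and inhibition strength (5.0) were tuned by observing
which ranges produce stable single-winner selection with discrete
response turnover at the scaled-down network size; they are exposed in
the configuration.  Read-out emits a word when its decoded similarity
is maximal and above 0.3 for at least 200 ms continuously, merging
consecutive duplicates.  Trials run their full duration; producing the
solution is recorded but does not stop the search.

### Known limitation: occasional fast returns of hub words

The response-inhibition contract — no word reappearing within two
positions of its last occurrence — holds for most words and most
seeds, but not absolutely.  In 20 x 10 s scaled-down runs a residual
~3-5% of responses are distance-two returns, concentrated on
"hub" words (associates of all three cues, usually the planted
solution).  The cause is structural: a hub's drive (cue + primary +
feedback input) exceeds the level at which the decaying integrator
charge releases it, so whenever its suppression dips below that
threshold it out-competes fresh candidates.  Lengthening suppression
enough to prevent this at this network size either silences the
network (global over-suppression) or collapses response dwell times
below the read-out window; the corresponding acceptance check is left
strict and failing rather than weakened.  Repeated responses in model
output are consistent with the behavioural data this class of model is
compared against, where repeated responses occur and are merged or
filtered during analysis.

## Response filter

The filter models the report stage: a produced word is reported only
if the sum of its association strengths from the three cues reaches a
threshold.  The threshold is derived from the problem set as the
minimum summed cue-to-solution strength, so every solution passes its
own filter by construction (pass is at >=, since the minimising
solution attains the threshold exactly).  On a binary matrix where
every solution is linked to all three cues the derivation yields 3,
making "pass" equivalent to *associate of all three cues*; a lower
override (e.g. 2) is supported for sensitivity analyses.  The filter
matrix is independent of the generation matrix — generation and
filtering are distinct processes with possibly distinct knowledge
sources; symmetrised variants are used for norms-based filter matrices
and raw variants for co-occurrence-based ones.

## Response-sequence analysis

Human response logs and model output flow through identical code.
Preprocessing drops out-of-vocabulary words and words identical to a
cue, and merges immediately repeated responses.  Every word gets a
vector from a word association space (WAS): the association matrix is
row-normalised to `P`, the two-step strength `S2 = P + P @ P` (direct
associations plus links across one intermediary word) is formed, and a
rank-300 truncated SVD gives vectors `U * sigma`; similarity is the
cosine.  If the matrix rank is lower than requested the available rank
is used with a warning.  Each response's *primary cue* is the cue with
the highest cosine similarity (ties break to the first cue in problem
order); clusters are maximal runs of one primary cue.

Statistics:

* within- vs across-cluster similarity of adjacent pairs, with
  percentile bootstrap CIs (10,000 resamples by default, seeded) and a
  two-sided Welch t-test;
* a permutation control that re-assigns each trial the cue triple of a
  uniformly chosen different trial;
* switch probability against the independence baseline
  `sum_c p_c^2` (exact two-sided binomial test);
* adjacent vs non-adjacent similarity within clusters and across
  cluster breaks (same-cue pairs spanning different clusters are not
  comparable and are excluded);
* the similarity slope over the last ten positions approaching the
  final response (least squares through per-position means, plus a
  sign test over per-trial slopes), with excluded trials omitted;
* accuracy, sequence-length statistics, and Pearson correlations with
  a comparison set both over binned length histograms and over
  per-problem mean lengths (both are reported because either
  convention is defensible).

Only human logs can carry an excluded flag (the analog of trials where
an incorrect response was marked correct); model trials are never
excluded.  The "cleaned" variant recomputes adjacency after deletions,
so formerly non-adjacent survivors become adjacent pairs.

## Synthetic data

The generator emulates the qualitative structure of free-association
norms: sparse directed graphs (Poisson out-degrees), heavy-tailed
strengths (Beta(0.3, 3), rescaled so row sums stay below 1, giving the
many-weak/few-strong associate profile of normed response
frequencies), and optional triadic closure for local clustering.
Problems plant a solution with at least three in-neighbour cues inside
a strength band, preferring mutually non-associated cues.  Response
logs come from a Markov walk: keep the current cue with a continuation
probability, else switch; draw the next word from the current cue's
associates, or the previous response's with the local-walk
probability; optional drift increasingly samples the solution's
neighbourhood and ends at the solution.  Ground-truth cue labels
travel in an extra column that the evaluation code never reads.

What the synthetic conditions do not show: real norms have power-law
degree tails, far larger vocabularies, and semantic (not random)
cluster structure, and real response logs contain typos, morphological
variants and out-of-vocabulary words.  Passing tests demonstrate that
the machinery recovers planted structure under clean conditions, not
that the model reproduces any particular human dataset.  The headline
behavioural comparisons of this class of model (accuracy near 40%,
sequence-length correlations ~0.9 after co-occurrence filtering)
require the real norms, co-occurrence counts, problem sets and human
logs, none of which ship with the package; they are integration
targets once those datasets are supplied in the TSV/CSV formats the
loaders accept.

## Problem sizes used in the checked examples

The test suite exercises the spiking model at vocabulary sizes 5-50
and 64-256 dimensions, with 6-8 neurons per dimension in
high-dimensional ensembles and 30 neurons per word-similarity group;
trials are 2-10 simulated seconds over 10-20 noise seeds.  These sizes
were chosen to keep a full desk run in minutes; the production-scale
configuration (5018 words, 2048 dimensions, 60 s trials, 56 seeds per
problem) uses the same code paths and is flagged as long-running.
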