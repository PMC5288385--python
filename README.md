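# ratsearch

A spiking-neuron model of semantic memory search on three-cue word
association problems (the Remote Associates Test), together with the
response filtering and response-sequence analysis needed to compare
its behaviour with human search data.

In the task, a subject sees three cue words (*fish*, *mine*, *rush*)
and must find a fourth word related to all three (*gold*).  People
solve it by generating a stream of candidate words: runs of responses
related to one cue, occasional switches between cues, and local chains
where each response primes the next.  This package implements a model
of that search process in which every component is a population of
leaky integrate-and-fire neurons, wired using the Neural Engineering
Framework (NEF):

* words are quasi-orthogonal unit vectors **w** in a D-dimensional
  space, represented by distributed spiking activity;
* a neuron's activity is `a_i = G_i[alpha_i e_i^T x + J_i^bias]`, and a
  population's represented value is read out with least-squares linear
  decoders through exponential synapses;
* associations live in one linear transform
  `A~ = V^T A^T V`, where `A[i, j]` is the associative strength from
  word i to word j (from free-association norms or co-occurrence
  counts) and `V` stacks the word vectors: applied to **w**, `A~` yields
  the superposition of its associates;
* the model itself couples a noise-driven *cue selection* network
  (which gates one of the three cues through to a primary-cue
  ensemble, reselecting at intervals), a *response network* (a
  winner-take-all clean-up memory over all words, driven by the
  associates of the cues and of the current response), and a
  *response inhibition* integrator that suppresses recent responses;
* a second, separate process filters the generated words: a word is
  reported only if its summed association strength to the three cues
  reaches a threshold derived from the problem set (the minimum summed
  cue-to-solution strength, which guarantees every solution passes).

The analysis suite mirrors the standard treatment of human response
logs: word vectors from a truncated-SVD word association space built
on `S2 = P + P^2` (direct plus one-intermediary associations),
primary-cue assignment, cluster/switching statistics with bootstrap
CIs and permutation controls, adjacent/non-adjacent similarity, and
the similarity slope approaching the final response.  Model output and
human logs flow through identical code.

Everything is testable offline: a synthetic-data module generates
FAN-like sparse heavy-tailed association norms, three-cue problems
planted in them, and ground-truth-labelled response sequences.

## Worked example

`examples/run_search_model.py` builds a 30-word synthetic vocabulary,
wires the spiking model for one planted problem and runs 10 seconds of
simulated search:

```
problem: cues ('w0009', 'w0029', 'w0015') -> solution 'w0026'
28 responses in 10 s of simulated search:
   0.01s  w0026  (primary cue ?) <- solution
   0.38s  w0019  (primary cue w0029)
   0.73s  w0007  (primary cue w0029)
   1.05s  w0026  (primary cue ?) <- solution
   1.37s  w0017  (primary cue w0029)
   1.65s  w0016  (primary cue w0029)
   ...
```

Each line is one decoded response with the cue that was driving the
search at its onset (`?` marks onsets during a reselection window,
when no cue dominates the primary-cue ensemble).  Responses are
associates of the concurrent primary cue, the primary cue changes
after the periodic reselection, and recently produced words are held
back for a couple of seconds by the response-inhibition integrator.  The other examples demonstrate the NEF core
(`lif_tuning_and_decoding.py`), the association transform
(`word_vectors_and_associations.py`), and the filter + analysis
pipeline on synthetic logs (`filter_and_analyse.py`).

## Command line

A thin CLI wraps the library for batch use:

```bash
ratsearch gen norms --seed 1 --out norms.tsv
ratsearch gen problems --norms norms.tsv --n 5 --seed 2 --out problems.csv
ratsearch run --problems problems.csv --norms norms.tsv --seeds 4 --out responses.csv
ratsearch filter --responses responses.csv --problems problems.csv \
    --filter-norms norms.tsv --binary --out filtered.csv
ratsearch eval --responses filtered.csv --problems problems.csv \
    --norms norms.tsv --out report.json
```

Model parameters are read from a plain-text `key = value` config
(`--config`), using the conventional names: `d`, `th`, `assoc_th`,
`cue_strength`, `primary_cue_strength`, `wta_feedback_strength`,
`noise_std`, `integrator_feedback`, plus the engineering fields of
`ratsearch.rat_model.ModelConfig`.

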