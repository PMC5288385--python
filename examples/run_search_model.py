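"""Run the spiking search model on one synthetic three-cue problem.

Builds a scaled-down network (30 words, 256-dimensional vectors), runs a
10-second trial and prints the decoded response sequence together with
the primary cue that was driving the search at each response onset.
Expect a few seconds of simulation time per simulated second.
"""

from ratsearch import rat_model as rm
from ratsearch import semantic_vectors as sv
from ratsearch import synthetic_data as sd
from ratsearch.association_data import binarize

norms = sd.gen_norms(
    sd.GeneratorSpec(n_words=30, mean_out_degree=7, clustering=0.3, seed=5)
)
matrix = binarize(norms)
problem = sd.gen_problems(matrix, 1, seed=3)[0]
print(f"problem: cues {problem.cues} -> solution {problem.solution!r}")

vocab = sv.generate_pointers(
    30, 256, max_similarity=0.15, seed=11, words=matrix.labels
)
config = rm.ModelConfig(
    d=256, neurons_per_dim=6, neurons_per_group=30, seed=42, trial_duration=10.0
)
network = rm.build_network(vocab, matrix, problem, config)
result = rm.run_trial(network, seed=0)

print(f"{len(result.responses)} responses in 10 s of simulated search:")
for word, onset, offset in result.responses:
    cue_idx = result.primary_cue_at(onset)
    cue = problem.cues[cue_idx] if cue_idx is not None else "?"
    mark = " <- solution" if word == problem.solution else ""
    print(f"  {onset:5.2f}s  {word}  (primary cue {cue}){mark}")

# Responses should be associates of the concurrent primary cue; the
# primary cue changes after the periodic reset of the selection network,
# and no word reappears within the last couple of responses because the
# response-inhibition integrator suppresses recent winners.
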