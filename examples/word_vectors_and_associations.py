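"""Quasi-orthogonal word vectors and linear association retrieval.

Generates a 50-word vocabulary of random unit vectors under a pairwise
similarity bound, builds the association transform A~ = V^T A^T V from a
synthetic norms matrix, and shows that applying A~ to a word's vector
produces a superposition whose strongest similarities are that word's
associates.
"""

import numpy as np

from ratsearch import semantic_vectors as sv
from ratsearch import synthetic_data as sd

norms = sd.gen_norms(sd.GeneratorSpec(n_words=50, mean_out_degree=5, seed=1))
vocab = sv.generate_pointers(
    50, 256, max_similarity=0.15, seed=1, words=norms.labels
)
print(f"max pairwise |dot| over {len(vocab)} vectors: "
      f"{vocab.max_pairwise_similarity():.3f} (bound 0.15)")

tf = sv.association_transform(norms, vocab)
word = norms.labels[0]
retrieved = tf(vocab[word])
profile = vocab.vectors @ retrieved
top = np.argsort(-profile)[:5]
print(f"associates of {word!r} in the norms: {norms.associates(word)}")
print("strongest similarities of A~ w:",
      [(norms.labels[i], round(float(profile[i]), 3)) for i in top])

# The top similarity entries should coincide with the word's associates;
# entries below ~0.1 are cross-talk from the quasi-orthogonal vectors,
# which the model's clean-up memory thresholds away.
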