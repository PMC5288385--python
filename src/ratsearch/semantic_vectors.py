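"""Quasi-orthogonal word vectors and the association transform.

Words are represented as random unit vectors ("semantic pointers") in a
D-dimensional space, generated under the constraint that no pair exceeds
a small dot-product bound.  Near-orthogonality is what lets a clean-up
memory decide unambiguously *which* word a noisy spiking representation
holds; similarity-structured embeddings would let an associate drown out
the represented word itself.

Associations are retrieved through a single linear map: given the word
matrix ``V`` (rows are word vectors) and an association matrix ``A``
(``A[i, j]`` = strength from word i to word j), the transform
``A_tilde = V^T A^T V`` sends word vector ``w_i`` to a superposition of
its associates' vectors.  Because it is linear it can be installed
directly as a connection transform between two neural ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Vocabulary",
    "AssocTransform",
    "CapacityError",
    "generate_pointers",
    "similarity",
    "association_transform",
]


class CapacityError(Exception):
    """Raised when no new vector satisfying the similarity bound is found."""


@dataclass
class Vocabulary:
    """An ordered word list with an N x D matrix of unit word vectors.

    Invariants: every row has unit norm, all pairwise absolute dot
    products are at most ``max_similarity``, and words are unique.
    """

    words: list
    vectors: np.ndarray
    max_similarity: float = 0.1
    seed: Optional[int] = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.words = [str(w) for w in self.words]
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.words) != self.vectors.shape[0]:
            raise ValueError("word list and vector matrix sizes differ")
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in vocabulary")
        norms = np.linalg.norm(self.vectors, axis=1)
        if len(self.words) and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("word vectors must have unit norm")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def index(self, word: str) -> int:
        return self._index[word]

    @property
    def dimensions(self) -> int:
        return self.vectors.shape[1]

    def max_pairwise_similarity(self, block: int = 512) -> float:
        """Largest absolute dot product over all distinct vector pairs."""
        n = len(self.words)
        if n < 2:
            return 0.0
        best = 0.0
        for start in range(0, n, block):
            rows = self.vectors[start : start + block]
            dots = np.abs(rows @ self.vectors.T)
            for k in range(rows.shape[0]):
                dots[k, start + k] = 0.0
            best = max(best, float(dots.max()))
        return best

    def save(self, words_path: Union[str, Path], vectors_path: Union[str, Path]) -> None:
        Path(words_path).write_text("\n".join(self.words) + "\n")
        np.savetxt(vectors_path, self.vectors, delimiter=",")

    @classmethod
    def load(
        cls,
        words_path: Union[str, Path],
        vectors_path: Union[str, Path],
        max_similarity: float = 0.1,
    ) -> "Vocabulary":
        words = Path(words_path).read_text().split()
        vectors = np.atleast_2d(np.loadtxt(vectors_path, delimiter=","))
        vocab = cls(words=words, vectors=vectors, max_similarity=max_similarity)
        worst = vocab.max_pairwise_similarity()
        if worst > max_similarity + 1e-9:
            raise ValueError(
                f"loaded vocabulary violates the similarity bound: "
                f"max pairwise |dot| = {worst:.4f} > {max_similarity}"
            )
        return vocab


@dataclass
class AssocTransform:
    """The dense D x D association transform ``V^T A^T V``."""

    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("association transform must be a square matrix")

    def __call__(self, w: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(w, dtype=float)


def generate_pointers(
    n_words: int,
    dimensions: int,
    max_similarity: float = 0.1,
    seed: Optional[int] = None,
    max_attempts: int = 100,
    words: Optional[list] = None,
) -> Vocabulary:
    """Generate quasi-orthogonal unit vectors by rejection sampling.

    Candidates are drawn as normalised Gaussian vectors (uniform on the
    hypersphere).  A candidate is accepted iff its absolute dot product
    with every previously accepted vector stays within ``max_similarity``;
    otherwise only that candidate is redrawn, so the procedure is
    deterministic for a given seed.  ``max_attempts`` bounds the redraws
    per slot; exhausting it raises :class:`CapacityError`, since it means
    the requested number of vectors does not fit in the space at the
    requested bound.

    Parameters
    ----------
    n_words, dimensions
        Number of vectors N and space dimensionality D.
    max_similarity
        Pairwise absolute dot-product bound (default 0.1).
    words
        Optional explicit word labels; defaults to ``w0000, w0001, ...``.
    """
    if n_words < 1 or dimensions < 1:
        raise ValueError("n_words and dimensions must be at least 1")
    rng = np.random.default_rng(seed)
    V = np.empty((n_words, dimensions))
    for i in range(n_words):
        for attempt in range(max_attempts):
            v = rng.standard_normal(dimensions)
            v /= np.linalg.norm(v)
            if i == 0 or np.max(np.abs(V[:i] @ v)) <= max_similarity:
                V[i] = v
                break
        else:
            raise CapacityError(
                f"could not place vector {i + 1} of {n_words} in "
                f"{dimensions} dimensions under the similarity bound "
                f"{max_similarity} after {max_attempts} attempts"
            )
    if words is None:
        width = max(4, len(str(n_words - 1)))
        words = [f"w{i:0{width}d}" for i in range(n_words)]
    elif len(words) != n_words:
        raise ValueError("explicit word list length must equal n_words")
    return Vocabulary(
        words=list(words), vectors=V, max_similarity=max_similarity, seed=seed
    )


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Dot-product similarity (cosine for unit vectors)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(u @ v)


def association_transform(matrix, vocab: Vocabulary) -> AssocTransform:
    """Collapse an association matrix into the transform ``V^T A^T V``.

    Applied to word vector ``w_i`` the result approximates the
    superposition ``sum_j A[i, j] w_j`` of word i's associates, with
    cross-talk bounded by the vocabulary's pairwise-similarity leakage.

    ``matrix`` may be an :class:`~ratsearch.association_data.AssociationMatrix`
    (labels are checked against the vocabulary order) or a plain N x N
    array aligned to the vocabulary.
    """
    labels = getattr(matrix, "labels", None)
    A = getattr(matrix, "strengths", matrix)
    if labels is not None and list(labels) != list(vocab.words):
        offending = [
            (a, b) for a, b in zip(labels, vocab.words) if a != b
        ][:5] or [("<length mismatch>", "<length mismatch>")]
        raise ValueError(
            "association matrix labels are not aligned with the vocabulary; "
            f"first mismatches (matrix, vocab): {offending}"
        )
    V = vocab.vectors
    if sp.issparse(A):
        if A.shape != (len(vocab), len(vocab)):
            raise ValueError("association matrix shape does not match vocabulary")
        At_V = A.T @ V
    else:
        A = np.asarray(A, dtype=float)
        if A.shape != (len(vocab), len(vocab)):
            raise ValueError("association matrix shape does not match vocabulary")
        At_V = A.T @ V
    return AssocTransform(matrix=V.T @ At_V, source=getattr(matrix, "provenance", "array"))
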