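"""Synthetic association norms, three-cue problems and response logs.

Real free-association norms are sparse directed graphs with heavy-tailed
strength distributions (each cue has many weak associates and a few
strong ones, row sums bounded by 1 because strengths are normed response
frequencies) and strong local clustering.  This module generates
matrices with that qualitative structure, plants three-cues-one-solution
problems in them, and emits ground-truth-labelled response sequences
that mimic the known properties of human memory search on such
problems: runs of responses driven by one cue, occasional cue switches,
and a local walk where the next response is drawn from the associates of
the previous one.

Everything is deterministic given a seed, and the emitted response logs
use the same schema the evaluation pipeline reads for real data; the
planted ground-truth cue travels in an extra column that the evaluation
code never consults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .association_data import AssociationMatrix

__all__ = [
    "GeneratorSpec",
    "PlantedSequenceSpec",
    "RATProblem",
    "GenerationError",
    "gen_norms",
    "gen_problems",
    "gen_response_sequences",
]


class GenerationError(Exception):
    """Raised when a generator cannot satisfy its constraints."""


@dataclass(frozen=True)
class RATProblem:
    """Three cue words and the solution word relating to all of them."""

    cues: tuple
    solution: str

    def __post_init__(self) -> None:
        if len(self.cues) != 3:
            raise ValueError("a problem has exactly three cues")
        words = set(self.cues) | {self.solution}
        if len(words) != 4:
            raise ValueError("cues and solution must be four distinct words")


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic norms generator.

    mean_out_degree
        Expected number of associates per cue word (Poisson distributed).
    clustering
        Probability that a new associate is drawn from the associates of
        existing associates (triadic closure), producing the local
        clustering typical of semantic networks.
    strength_a, strength_b
        Beta-distribution shape parameters for associative strengths; the
        default Beta(0.3, 3) gives the many-weak / few-strong profile of
        normed response frequencies.  Row sums are rescaled to stay <= 1.
    """

    n_words: int = 50
    mean_out_degree: float = 5.0
    clustering: float = 0.0
    strength_a: float = 0.3
    strength_b: float = 3.0
    seed: Optional[int] = None


@dataclass
class PlantedSequenceSpec:
    """Parameters of the planted response-sequence generator.

    continuation_prob
        Per-step probability of keeping the current true cue rather than
        switching to one of the other two.
    local_walk_prob
        Probability of drawing the next response from the associates of
        the previous response instead of from the current cue's.
    drift_strength
        0 disables; otherwise the probability of stepping toward the
        solution grows linearly to this value over the sequence, and the
        final response is the solution, producing a positive
        final-approach similarity slope.
    mean_length
        Mean sequence length (Poisson, at least 2).
    """

    continuation_prob: float = 0.7
    local_walk_prob: float = 0.3
    drift_strength: float = 0.0
    mean_length: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("continuation_prob", "local_walk_prob", "drift_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _word_labels(n: int) -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"w{i:0{width}d}" for i in range(n)]


def gen_norms(spec: GeneratorSpec) -> AssociationMatrix:
    """Generate a sparse, heavy-tailed, row-sub-stochastic norms matrix."""
    n = spec.n_words
    if n < 4:
        raise ValueError("need at least 4 words")
    if spec.mean_out_degree >= n:
        raise GenerationError(
            f"mean out-degree {spec.mean_out_degree} infeasible for "
            f"{n} words"
        )
    rng = np.random.default_rng(spec.seed)
    targets_of: List[set] = [set() for _ in range(n)]
    degrees = rng.poisson(spec.mean_out_degree, size=n)
    degrees = np.minimum(degrees, n - 1)
    for i in range(n):
        chosen = targets_of[i]
        while len(chosen) < degrees[i]:
            candidate = -1
            if spec.clustering > 0 and chosen and rng.random() < spec.clustering:
                # triadic closure: associate of an existing associate
                via = int(rng.choice(sorted(chosen)))
                second = sorted(targets_of[via] - chosen - {i})
                if second:
                    candidate = int(rng.choice(second))
            if candidate < 0:
                candidate = int(rng.integers(n))
            if candidate != i:
                chosen.add(candidate)
    rows, cols, vals = [], [], []
    for i in range(n):
        if not targets_of[i]:
            continue
        js = sorted(targets_of[i])
        strengths = rng.beta(spec.strength_a, spec.strength_b, size=len(js))
        total = strengths.sum()
        if total > 1.0:
            strengths = strengths / total
        rows.extend([i] * len(js))
        cols.extend(js)
        vals.extend(strengths.tolist())
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return AssociationMatrix(
        labels=_word_labels(n), strengths=mat, kind="raw",
        provenance=f"synthetic(seed={spec.seed})",
    )


def gen_problems(
    matrix: AssociationMatrix,
    n_problems: int,
    strength_band: tuple = (0.0, np.inf),
    seed: Optional[int] = None,
) -> List[RATProblem]:
    """Plant three-cue problems whose solutions lie in a strength band.

    For each problem a solution word is chosen that has at least three
    in-neighbours whose cue->solution strength falls inside
    ``strength_band``; three such cues are drawn, preferring mutually
    non-associated ones when enough candidates exist.  Solutions are
    distinct across problems.
    """
    rng = np.random.default_rng(seed)
    lo, hi = strength_band
    csc = matrix.strengths.tocsc()
    candidates = []
    for j in range(len(matrix)):
        col = csc.getcol(j).tocoo()
        cue_idx = [i for i, v in zip(col.row, col.data) if lo <= v <= hi and i != j]
        if len(cue_idx) >= 3:
            candidates.append((j, cue_idx))
    if len(candidates) < n_problems:
        raise GenerationError(
            f"only {len(candidates)} of the requested {n_problems} problems "
            "are possible with the given matrix and strength band"
        )
    order = rng.permutation(len(candidates))
    problems = []
    for k in order[:n_problems]:
        j, cue_idx = candidates[k]
        cue_idx = list(cue_idx)
        rng.shuffle(cue_idx)
        # greedily prefer mutually non-associated cues
        picked: List[int] = []
        for c in cue_idx:
            if all(
                matrix.strengths[c, d] == 0 and matrix.strengths[d, c] == 0
                for d in picked
            ):
                picked.append(c)
            if len(picked) == 3:
                break
        for c in cue_idx:  # fall back to associated cues if needed
            if len(picked) == 3:
                break
            if c not in picked:
                picked.append(c)
        problems.append(
            RATProblem(
                cues=tuple(matrix.labels[c] for c in picked[:3]),
                solution=matrix.labels[j],
            )
        )
    return problems


def _associates(matrix: AssociationMatrix, word: str) -> tuple:
    i = matrix.index(word)
    row = matrix.strengths.getrow(i).tocoo()
    return row.col, row.data


def gen_response_sequences(
    matrix: AssociationMatrix,
    problem: RATProblem,
    spec: PlantedSequenceSpec,
    n_trials: int = 1,
    trial_offset: int = 0,
    response_interval: float = 1.0,
) -> pd.DataFrame:
    """Generate ground-truth-labelled response logs for one problem.

    A Markov walk over the association graph: at each step the true cue
    is kept with ``continuation_prob`` (else resampled uniformly from the
    other two); the response is drawn from the associates of the current
    cue, or of the previous response with ``local_walk_prob`` (the local
    search strategy).  A cue with no associates is resampled.  Output
    columns: trial, seed, position, word, onset_s, true_cue -- the same
    schema as recorded model/human responses plus the ground-truth
    column.
    """
    for w in (*problem.cues, problem.solution):
        if w not in matrix:
            raise ValueError(f"problem word {w!r} missing from the matrix")
    rng = np.random.default_rng(spec.seed)
    records = []
    for trial in range(n_trials):
        length = max(2, int(rng.poisson(spec.mean_length)))
        cue = problem.cues[int(rng.integers(3))]
        prev_word: Optional[str] = None
        for pos in range(length):
            if pos > 0 and rng.random() >= spec.continuation_prob:
                others = [c for c in problem.cues if c != cue]
                cue = others[int(rng.integers(2))]
            drift_p = spec.drift_strength * (pos / max(length - 1, 1))
            if spec.drift_strength > 0 and pos == length - 1:
                word = problem.solution
            elif spec.drift_strength > 0 and rng.random() < drift_p:
                cols, data = _associates(matrix, problem.solution)
                word = (
                    matrix.labels[int(rng.choice(cols))]
                    if len(cols)
                    else problem.solution
                )
            else:
                source = cue
                if (
                    prev_word is not None
                    and rng.random() < spec.local_walk_prob
                ):
                    source = prev_word
                cols, data = _associates(matrix, source)
                if len(cols) == 0 and source != cue:
                    cols, data = _associates(matrix, cue)
                while len(cols) == 0:
                    cue = problem.cues[int(rng.integers(3))]
                    cols, data = _associates(matrix, cue)
                probs = data / data.sum()
                word = matrix.labels[int(rng.choice(cols, p=probs))]
            records.append(
                {
                    "trial": trial_offset + trial,
                    "seed": spec.seed if spec.seed is not None else -1,
                    "position": pos,
                    "word": word,
                    "onset_s": pos * response_interval,
                    "true_cue": cue,
                }
            )
            prev_word = word
    return pd.DataFrame.from_records(
        records, columns=["trial", "seed", "position", "word", "onset_s", "true_cue"]
    )
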