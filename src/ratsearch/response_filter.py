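"""Association-strength filtering of generated responses.

Memory search produces many words that a person would never write down
as an answer attempt -- priming artefacts and weakly related words.  The
filter models the report stage as a second cognitive process: a word is
reported only if the sum of its association strengths from the three
problem cues reaches a threshold.

The threshold is not a free parameter.  It is derived from the problem
set itself as the minimum, over problems, of the summed cue-to-solution
strength, which guarantees that every problem's solution passes its own
filter; accuracy is therefore unaffected by filtering, only the volume
of reported responses changes.  On a binary matrix where every solution
is linked to all three of its cues this derivation yields a threshold of
3: "pass" then means *associate of all three cues*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

from .association_data import AssociationMatrix
from .synthetic_data import RATProblem

__all__ = [
    "FilterSpec",
    "cue_similarity",
    "derive_threshold",
    "filter_responses",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """A filter matrix (any norms variant) plus its pass threshold."""

    matrix: AssociationMatrix
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be non-negative, got {self.threshold}")


def cue_similarity(
    word: str, cues: Sequence[str], matrix: AssociationMatrix
) -> float:
    """Summed association strength from each cue to the word.

    Words missing from the matrix contribute 0 (and are logged), so the
    measure is defined for every response.
    """
    total = 0.0
    word = str(word).lower()
    if word not in matrix:
        logger.debug("word %r not in filter matrix; similarity 0", word)
        return 0.0
    for cue in cues:
        if str(cue).lower() not in matrix:
            logger.debug("cue %r not in filter matrix; contributes 0", cue)
            continue
        total += matrix.strength(cue, word)
    return total


def derive_threshold(
    problems: Iterable[RATProblem], matrix: AssociationMatrix
) -> float:
    """Lowest summed cue-to-solution strength over the problem set.

    Using this minimum as the filter threshold ensures that every
    problem's solution passes its own filter (pass is at >=, and the
    minimising solution attains the threshold exactly).
    """
    problems = list(problems)
    if not problems:
        raise ValueError("cannot derive a threshold from an empty problem list")
    return min(
        cue_similarity(p.solution, p.cues, matrix) for p in problems
    )


def filter_responses(
    sequence: Sequence[str],
    cues: Sequence[str],
    spec: FilterSpec,
) -> Tuple[List[str], pd.DataFrame]:
    """Keep responses whose summed cue similarity reaches the threshold.

    Returns the kept words in their original order together with a
    per-word log of the summed strength and the verdict.
    """
    rows = []
    kept = []
    for word in sequence:
        s = cue_similarity(word, cues, spec.matrix)
        passed = s >= spec.threshold
        rows.append({"word": word, "summed_strength": s, "kept": passed})
        if passed:
            kept.append(word)
    log = pd.DataFrame(rows, columns=["word", "summed_strength", "kept"])
    return kept, log
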