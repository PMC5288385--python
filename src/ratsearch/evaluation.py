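"""Response-sequence analysis for three-cue association search.

Analyses a set of trials -- each a sequence of words produced while
searching for the solution to a three-cue problem -- the same way for
human logs and model output:

1. preprocess: drop out-of-vocabulary words and words identical to a
   cue, merge immediately repeated responses;
2. embed every word in a low-dimensional Word Association Space (WAS):
   row-normalise the association matrix to ``P``, form the two-step
   measure ``S2 = P + P @ P`` (direct associations plus links across one
   intermediary word), and keep the top singular directions;
3. assign each response a *primary cue* -- the problem cue whose WAS
   vector is most cosine-similar -- and segment the sequence into
   clusters (maximal runs of one primary cue);
4. compute the search statistics: within- vs across-cluster similarity
   of adjacent responses (with bootstrap CIs, t-tests and a cue
   permutation control), the probability of switching primary cues
   against an independence baseline, adjacent vs non-adjacent response
   similarity, the similarity slope approaching the final response, and
   accuracy / sequence-length summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "TrialAnalysis",
    "WASSpace",
    "MetricsReport",
    "preprocess_trial",
    "was_vectors",
    "assign_primary_cues",
    "cluster_similarity",
    "permutation_test",
    "switch_probability",
    "adjacency_analysis",
    "final_approach_slope",
    "summary",
    "bootstrap_ci",
    "load_response_log",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class TrialAnalysis:
    """One preprocessed trial: responses plus analysis annotations."""

    trial_id: int
    cues: tuple
    solution: str
    responses: List[str]
    dropped: List[tuple] = field(default_factory=list)
    vectors: Optional[np.ndarray] = None  # (n_responses, dims)
    primary_cues: Optional[List[int]] = None  # index into cues, per response
    solved: bool = False
    excluded: bool = False

    def clusters(self) -> List[Tuple[int, int]]:
        """Maximal runs of equal primary cue as half-open (start, end)."""
        if self.primary_cues is None:
            raise ValueError("assign primary cues before segmenting clusters")
        out = []
        start = 0
        for i in range(1, len(self.primary_cues)):
            if self.primary_cues[i] != self.primary_cues[i - 1]:
                out.append((start, i))
                start = i
        if self.primary_cues:
            out.append((start, len(self.primary_cues)))
        return out


@dataclass
class WASSpace:
    """Low-dimensional word vectors from an association matrix."""

    words: list
    vectors: np.ndarray  # (N, dims)
    rank: int
    provenance: str = ""
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("WAS vectors contain non-finite entries")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def cosine(self, w1: str, w2: str) -> float:
        return _cosine(self.vector(w1), self.vector(w2))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# Preprocessing and embedding
# ---------------------------------------------------------------------------


def preprocess_trial(
    raw_sequence: Sequence[str],
    cues: Sequence[str],
    vocabulary: Iterable[str],
    solution: str = "",
    trial_id: int = 0,
    excluded: bool = False,
) -> TrialAnalysis:
    """Clean one raw response sequence.

    Words not in the vocabulary and words identical to a cue are dropped
    (logged with a reason); immediately repeated responses are merged
    into one.  ``solved`` records whether the solution appears anywhere
    in the raw sequence.
    """
    vocab = {str(w).lower() for w in vocabulary}
    cue_set = {str(c).lower() for c in cues}
    solution = str(solution).lower()
    responses: List[str] = []
    dropped: List[tuple] = []
    solved = False
    for raw in raw_sequence:
        word = str(raw).lower()
        if solution and word == solution:
            solved = True
        if word in cue_set:
            dropped.append((word, "cue"))
            continue
        if word not in vocab:
            dropped.append((word, "out-of-vocabulary"))
            continue
        if responses and responses[-1] == word:
            dropped.append((word, "repeat"))
            continue
        responses.append(word)
    return TrialAnalysis(
        trial_id=trial_id,
        cues=tuple(str(c).lower() for c in cues),
        solution=solution,
        responses=responses,
        dropped=dropped,
        solved=solved,
        excluded=excluded,
    )


def was_vectors(matrix, dims: int = 300) -> WASSpace:
    """Build WAS word vectors from an association matrix.

    Rows of the matrix are normalised to a stochastic ``P`` (zero rows
    stay zero), the two-step strength ``S2 = P + P @ P`` is formed, and a
    rank-``dims`` truncated SVD gives vectors ``U * sigma``.  If the
    matrix rank is below ``dims`` the available rank is used and a
    warning is issued.  Word similarity is the cosine of the vectors,
    which is invariant to the truncation when ``dims`` reaches full rank.
    """
    labels = getattr(matrix, "labels", None)
    A = getattr(matrix, "strengths", matrix)
    A = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("association matrix must be square")
    if A.size and A.min() < 0:
        raise ValueError("association matrix must be non-negative")
    n = A.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    row_sums = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, A / np.where(row_sums == 0, 1.0, row_sums), 0.0)
    S2 = P + P @ P
    U, s, _ = np.linalg.svd(S2, full_matrices=False)
    tol = max(S2.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    k = min(dims, n)
    if rank < dims:
        warnings.warn(
            f"association matrix rank {rank} is below the requested "
            f"{dims} dimensions; using rank {rank}",
            stacklevel=2,
        )
        k = min(k, max(rank, 1))
    vectors = U[:, :k] * s[:k]
    return WASSpace(
        words=list(labels), vectors=vectors, rank=rank,
        provenance=getattr(matrix, "provenance", "array"),
    )


def assign_primary_cues(trial: TrialAnalysis, space: WASSpace) -> TrialAnalysis:
    """Attach WAS vectors and per-response primary cues to a trial.

    Each response is assigned the problem cue with the highest cosine
    similarity; exact ties break toward the first cue in problem order.
    """
    for cue in trial.cues:
        if cue not in space:
            raise ValueError(f"cue {cue!r} missing from the WAS space")
    cue_vecs = np.stack([space.vector(c) for c in trial.cues])
    vectors = np.zeros((len(trial.responses), space.vectors.shape[1]))
    primary: List[int] = []
    for i, word in enumerate(trial.responses):
        if word not in space:
            raise ValueError(f"response {word!r} missing from the WAS space")
        v = space.vector(word)
        vectors[i] = v
        sims = [_cosine(v, cv) for cv in cue_vecs]
        primary.append(int(np.argmax(sims)))  # argmax takes the first maximum
    return replace(trial, vectors=vectors, primary_cues=primary)


# ---------------------------------------------------------------------------
# Statistics helpers
# ---------------------------------------------------------------------------


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _adjacent_pairs(trials: Iterable[TrialAnalysis]):
    """Yield (cos, same_cue) for every within-trial adjacent response pair."""
    for trial in trials:
        if trial.vectors is None or trial.primary_cues is None:
            raise ValueError("trials must have primary cues assigned")
        for i in range(len(trial.responses) - 1):
            yield (
                _cosine(trial.vectors[i], trial.vectors[i + 1]),
                trial.primary_cues[i] == trial.primary_cues[i + 1],
            )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def cluster_similarity(
    trials: Sequence[TrialAnalysis],
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> Dict:
    """Within- vs across-cluster similarity of adjacent response pairs.

    Adjacent pairs are split by whether the two responses share a primary
    cue; reports means, 95% bootstrap CIs and a two-sided unpooled
    (Welch) t-test.  With no across-cluster pairs the across statistics
    are reported as missing.
    """
    within, across = [], []
    for cos, same in _adjacent_pairs(trials):
        (within if same else across).append(cos)
    if not within and not across:
        raise ValueError("no adjacent response pairs in the trial set")
    out: Dict = {
        "within_mean": float(np.mean(within)) if within else None,
        "across_mean": float(np.mean(across)) if across else None,
        "within_ci": bootstrap_ci(within, n_boot, seed=seed) if within else None,
        "across_ci": bootstrap_ci(across, n_boot, seed=None if seed is None else seed + 1)
        if across
        else None,
        "n_within": len(within),
        "n_across": len(across),
        "t": None,
        "p": None,
    }
    if len(within) >= 2 and len(across) >= 2:
        t, p = stats.ttest_ind(within, across, equal_var=False)
        out["t"], out["p"] = float(t), float(p)
    return out


def permutation_test(
    trials: Sequence[TrialAnalysis],
    space: WASSpace,
    seed: Optional[int] = None,
    n_boot: int = 10000,
) -> Dict:
    """Cluster similarity after swapping each trial's cues for another's.

    Every trial is re-analysed with the cue triple of a uniformly chosen
    *different* trial; conservation of the within > across trend under
    this reassignment shows the trend is not an artefact of the
    particular cue labels.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("permutation test requires at least two trials")
    rng = np.random.default_rng(seed)
    permuted = []
    for i, trial in enumerate(trials):
        j = int(rng.integers(len(trials) - 1))
        if j >= i:
            j += 1
        donor = trials[j]
        swapped = replace(trial, cues=donor.cues, vectors=None, primary_cues=None)
        permuted.append(assign_primary_cues(swapped, space))
    return cluster_similarity(permuted, n_boot=n_boot, seed=seed)


def switch_probability(trials: Sequence[TrialAnalysis]) -> Dict:
    """Primary-cue switching rate against an independence baseline.

    Actual: fraction of adjacent pairs sharing a primary cue (and its
    complement, the switch rate).  Baseline: ``sum_c p_c**2`` where
    ``p_c`` are the empirical primary-cue frequencies -- the same-cue
    probability if successive cue assignments were independent.  The
    two-sided exact binomial test compares the same-cue count with the
    baseline probability.
    """
    pairs = list(_adjacent_pairs(trials))
    if not pairs:
        raise ValueError("no adjacent response pairs in the trial set")
    same = sum(1 for _, s in pairs if s)
    n = len(pairs)
    counts = np.zeros(3)
    for trial in trials:
        for c in trial.primary_cues or []:
            counts[c] += 1
    freqs = counts / counts.sum() if counts.sum() else counts
    baseline = float(np.sum(freqs**2))
    test = stats.binomtest(same, n, p=baseline, alternative="two-sided")
    return {
        "same_cue_pct": 100.0 * same / n,
        "switch_pct": 100.0 * (n - same) / n,
        "baseline_same_cue_pct": 100.0 * baseline,
        "cue_frequencies": freqs.tolist(),
        "n_pairs": n,
        "p": float(test.pvalue),
    }


def adjacency_analysis(
    trials: Sequence[TrialAnalysis],
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> Dict:
    """Adjacent vs non-adjacent response similarity, within and across.

    Within a cluster, adjacent (consecutive) pairs are compared with
    non-adjacent pairs of the same cluster (needs cluster length >= 3).
    Across, consecutive pairs at cluster breaks are compared with
    non-consecutive pairs of responses holding different primary cues.
    Cells with no pairs are reported as missing.
    """
    cells: Dict[str, list] = {
        "within_adjacent": [],
        "within_nonadjacent": [],
        "across_adjacent": [],
        "across_nonadjacent": [],
    }
    for trial in trials:
        if trial.vectors is None or trial.primary_cues is None:
            raise ValueError("trials must have primary cues assigned")
        cues = trial.primary_cues
        n = len(trial.responses)
        cluster_id = np.zeros(n, dtype=int)
        for cid, (a, b) in enumerate(trial.clusters()):
            cluster_id[a:b] = cid
        for i in range(n):
            for j in range(i + 1, n):
                cos = _cosine(trial.vectors[i], trial.vectors[j])
                adjacent = j == i + 1
                if cluster_id[i] == cluster_id[j]:
                    key = "within_adjacent" if adjacent else "within_nonadjacent"
                elif cues[i] != cues[j]:
                    key = "across_adjacent" if adjacent else "across_nonadjacent"
                else:
                    continue  # same cue, different clusters: not comparable
                cells[key].append(cos)
    out: Dict = {}
    for k, (key, vals) in enumerate(cells.items()):
        if vals:
            out[key] = {
                "mean": float(np.mean(vals)),
                "ci": bootstrap_ci(vals, n_boot, seed=None if seed is None else seed + k),
                "n": len(vals),
            }
        else:
            out[key] = None
    return out


def final_approach_slope(trials: Sequence[TrialAnalysis], k: int = 10) -> Dict:
    """Similarity to the final response over the last ``k`` positions.

    For positions -k..-1 relative to the final response, the mean cosine
    similarity to the final response is computed; a least-squares line
    through the per-position means gives the slope (positive slope =
    responses converge toward the final answer).  Trials flagged as
    excluded and trials with fewer than two responses before the final
    one are ignored; a sign test over per-trial slopes accompanies the
    pooled estimate.
    """
    by_position: Dict[int, list] = {p: [] for p in range(-k, 0)}
    trial_slopes = []
    used = 0
    for trial in trials:
        if trial.excluded or trial.vectors is None:
            continue
        n = len(trial.responses)
        if n < 3:  # final plus at least two approach positions
            continue
        used += 1
        final = trial.vectors[-1]
        pos, sims = [], []
        for p in range(max(-k, -(n - 1)), 0):
            cos = _cosine(trial.vectors[n - 1 + p], final)
            by_position[p].append(cos)
            pos.append(p)
            sims.append(cos)
        if len(pos) >= 2 and np.ptp(sims) > 0:
            trial_slopes.append(float(np.polyfit(pos, sims, 1)[0]))
    if used == 0:
        raise ValueError("no trial has at least two responses before the final one")
    positions = sorted(p for p in by_position if by_position[p])
    means = [float(np.mean(by_position[p])) for p in positions]
    slope = float(np.polyfit(positions, means, 1)[0]) if len(positions) >= 2 else 0.0
    n_pos = sum(1 for s in trial_slopes if s > 0)
    n_eff = len(trial_slopes)
    sign_p = (
        float(stats.binomtest(n_pos, n_eff, 0.5, alternative="two-sided").pvalue)
        if n_eff
        else None
    )
    return {
        "positions": positions,
        "mean_similarity": means,
        "slope": slope,
        "n_trials": used,
        "sign_test_p": sign_p,
        "positive_trial_slopes": n_pos,
        "trial_slopes_n": n_eff,
    }


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Accuracy and sequence-length statistics, optionally vs a comparison."""

    accuracy: float
    n_trials: int
    min_length: int
    max_length: int
    mean_length: float
    length_r: Optional[float] = None
    length_r_p: Optional[float] = None
    per_problem_r: Optional[float] = None
    per_problem_r_p: Optional[float] = None
    kde_grid: Optional[list] = None
    kde_density: Optional[list] = None

    def to_dict(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summary(
    trials: Sequence[TrialAnalysis],
    comparison_lengths: Optional[Sequence[int]] = None,
    problem_of_trial: Optional[Sequence] = None,
    comparison_problem_means: Optional[Dict] = None,
) -> MetricsReport:
    """Accuracy, sequence-length statistics and comparison correlations.

    Accuracy is the fraction of trials whose raw response sequence
    contained the solution.  Length correlations with a comparison set
    are reported two ways: over binned length histograms
    (``length_r``) and over per-problem mean lengths
    (``per_problem_r``) when a trial-to-problem map and comparison
    per-problem means are supplied.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to summarise")
    lengths = np.array([len(t.responses) for t in trials])
    accuracy = float(np.mean([t.solved for t in trials]))
    report = MetricsReport(
        accuracy=accuracy,
        n_trials=len(trials),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        mean_length=float(lengths.mean()),
    )
    positive = lengths[lengths > 0]
    if positive.size >= 2 and np.ptp(positive) > 0:
        kde = stats.gaussian_kde(positive)  # Scott's rule bandwidth by default
        grid = np.linspace(0, positive.max() + 5, 200)
        report.kde_grid = grid.tolist()
        report.kde_density = kde(grid).tolist()
    if comparison_lengths is not None:
        comp = np.asarray(comparison_lengths)
        hi = int(max(lengths.max(), comp.max()))
        bins = np.arange(0.5, hi + 1.5)
        h1, _ = np.histogram(lengths, bins=bins, density=True)
        h2, _ = np.histogram(comp, bins=bins, density=True)
        if h1.size >= 2:
            r, p = stats.pearsonr(h1, h2)
            report.length_r, report.length_r_p = float(r), float(p)
    if problem_of_trial is not None and comparison_problem_means is not None:
        frame = pd.DataFrame({"problem": list(problem_of_trial), "length": lengths})
        means = frame.groupby("problem")["length"].mean()
        shared = [p for p in means.index if p in comparison_problem_means]
        if len(shared) >= 3:
            ours = means.loc[shared].to_numpy()
            theirs = np.array([comparison_problem_means[p] for p in shared])
            r, p = stats.pearsonr(ours, theirs)
            report.per_problem_r, report.per_problem_r_p = float(r), float(p)
    return report


# ---------------------------------------------------------------------------
# Response-log IO
# ---------------------------------------------------------------------------


def load_response_log(source) -> pd.DataFrame:
    """Read a responses.csv table (path or DataFrame) and validate columns."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"trial", "position", "word"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response log is missing columns: {sorted(missing)}")
    return df.sort_values(["trial", "position"]).reset_index(drop=True)
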