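"""Tests for the response-sequence analysis suite."""

import numpy as np
import pytest
import scipy.sparse as sp

from ratsearch import evaluation as ev
from ratsearch.association_data import AssociationMatrix


def make_trial(vectors, primary_cues, trial_id=0, cues=("c1", "c2", "c3"),
               solution="sol", solved=False, excluded=False):
    vectors = np.asarray(vectors, dtype=float)
    responses = [f"r{i}" for i in range(len(vectors))]
    return ev.TrialAnalysis(
        trial_id=trial_id, cues=cues, solution=solution, responses=responses,
        vectors=vectors, primary_cues=list(primary_cues), solved=solved,
        excluded=excluded,
    )


def axis_vectors(indices, dims=8, noise=0.0, rng=None):
    """Unit vectors near coordinate axes, optionally jittered."""
    out = np.zeros((len(indices), dims))
    for k, i in enumerate(indices):
        out[k, i] = 1.0
    if noise and rng is not None:
        out = out + rng.normal(0, noise, out.shape)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


class TestPreprocess:
    def test_consecutive_duplicates_merged(self):
        trial = ev.preprocess_trial(
            ["water", "water", "coal"], ("fish", "mine", "rush"),
            ["water", "coal", "gold"], solution="gold",
        )
        assert trial.responses == ["water", "coal"]

    def test_cue_responses_dropped(self):
        trial = ev.preprocess_trial(
            ["fish", "water"], ("fish", "mine", "rush"), ["fish", "water"],
        )
        assert trial.responses == ["water"]
        assert ("fish", "cue") in trial.dropped

    def test_out_of_vocabulary_dropped(self):
        trial = ev.preprocess_trial(
            ["zzz", "water"], ("a", "b", "c"), ["water"],
        )
        assert trial.responses == ["water"]
        assert ("zzz", "out-of-vocabulary") in trial.dropped

    def test_empty_sequence(self):
        trial = ev.preprocess_trial([], ("a", "b", "c"), ["x"])
        assert trial.responses == []
        assert not trial.solved

    def test_solution_detected_in_raw_sequence(self):
        trial = ev.preprocess_trial(
            ["gold"], ("fish", "mine", "rush"), ["gold"], solution="gold",
        )
        assert trial.solved


class TestWASVectors:
    def test_identity_matrix_gives_orthogonal_words(self):
        # each word only self-associated: no shared structure, zero cosines
        matrix = np.eye(5)
        space = ev.was_vectors(matrix, dims=5)
        for i in range(5):
            for j in range(i + 1, 5):
                assert space.cosine(str(i), str(j)) == pytest.approx(0.0, abs=1e-9)

    def test_two_block_matrix_separates_cliques(self):
        # two 5-word cliques with no cross links: within-clique cosines must
        # exceed every cross-clique cosine (dense SVD oracle at full rank)
        n = 10
        dense = np.zeros((n, n))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        dense[i, j] = 1.0
        space = ev.was_vectors(dense, dims=n)
        within, across = [], []
        for i in range(n):
            for j in range(i + 1, n):
                c = space.cosine(str(i), str(j))
                (within if (i < 5) == (j < 5) else across).append(c)
        assert min(within) > max(across)

    def test_full_rank_truncation_is_lossless(self):
        rng = np.random.default_rng(0)
        dense = rng.random((6, 6)) * (rng.random((6, 6)) < 0.6)
        np.fill_diagonal(dense, 0.0)
        row = dense.sum(axis=1, keepdims=True)
        P = np.where(row > 0, dense / np.where(row == 0, 1, row), 0.0)
        S2 = P + P @ P
        space = ev.was_vectors(dense, dims=6)
        for i in range(6):
            for j in range(i + 1, 6):
                ni, nj = np.linalg.norm(S2[i]), np.linalg.norm(S2[j])
                expected = S2[i] @ S2[j] / (ni * nj) if ni > 0 and nj > 0 else 0.0
                # S2 rows live in the right singular basis; cosines between
                # word vectors (U * s rows) match cosines between S2 rows
                assert space.cosine(str(i), str(j)) == pytest.approx(expected, abs=1e-9)

    def test_rank_deficiency_warns(self):
        dense = np.zeros((4, 4))
        dense[0, 1] = 1.0
        with pytest.warns(UserWarning, match="rank"):
            ev.was_vectors(dense, dims=4)

    def test_labels_from_association_matrix(self):
        matrix = AssociationMatrix(
            labels=["a", "b"], strengths=sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        )
        space = ev.was_vectors(matrix, dims=2)
        assert "a" in space and "b" in space


class TestAssignPrimaryCues:
    @pytest.fixture()
    def space(self):
        # cues on axes 0,1,2; responses near those axes
        words = ["c1", "c2", "c3"] + [f"r{i}" for i in range(6)]
        vecs = axis_vectors([0, 1, 2, 0, 0, 1, 1, 2, 2], dims=4,
                            noise=0.05, rng=np.random.default_rng(3))
        return ev.WASSpace(words=words, vectors=vecs, rank=4)

    def test_assigns_nearest_cue(self, space):
        trial = ev.TrialAnalysis(
            trial_id=0, cues=("c1", "c2", "c3"), solution="",
            responses=["r0", "r2", "r4"],
        )
        out = ev.assign_primary_cues(trial, space)
        assert out.primary_cues == [0, 1, 2]

    def test_tie_breaks_to_first_cue(self):
        words = ["c1", "c2", "c3", "mid"]
        vecs = np.array([
            [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0],
            [np.sqrt(0.5), np.sqrt(0.5)],  # equidistant from c1 and c2
        ])
        space = ev.WASSpace(words=words, vectors=vecs, rank=2)
        trial = ev.TrialAnalysis(0, ("c1", "c2", "c3"), "", ["mid"])
        assert ev.assign_primary_cues(trial, space).primary_cues == [0]

    def test_missing_cue_rejected(self, space):
        trial = ev.TrialAnalysis(0, ("c1", "c2", "nope"), "", ["r0"])
        with pytest.raises(ValueError, match="nope"):
            ev.assign_primary_cues(trial, space)

    def test_planted_cluster_recovery(self):
        # responses generated near cue c1's axis are assigned c1
        rng = np.random.default_rng(7)
        words = ["c1", "c2", "c3"] + [f"r{i}" for i in range(30)]
        planted = [0, 1, 2] + [0] * 30
        vecs = axis_vectors(planted, dims=6, noise=0.25, rng=rng)
        space = ev.WASSpace(words=words, vectors=vecs, rank=6)
        trial = ev.TrialAnalysis(
            0, ("c1", "c2", "c3"), "", [f"r{i}" for i in range(30)]
        )
        out = ev.assign_primary_cues(trial, space)
        assert np.mean(np.array(out.primary_cues) == 0) >= 0.8


class TestClusterSegmentation:
    def test_clusters_partition_sequence(self):
        trial = make_trial(np.eye(6), [0, 0, 1, 1, 1, 2])
        clusters = trial.clusters()
        assert clusters == [(0, 2), (2, 5), (5, 6)]
        assert sum(b - a for a, b in clusters) == 6


class TestClusterSimilarity:
    def test_planted_two_cluster_gap_detected(self):
        rng = np.random.default_rng(1)
        trials = []
        for t in range(40):
            cues = [0] * 3 + [1] * 3
            vecs = axis_vectors(cues, dims=8, noise=0.2, rng=rng)
            trials.append(make_trial(vecs, cues, trial_id=t))
        out = ev.cluster_similarity(trials, n_boot=2000, seed=0)
        assert out["within_mean"] > out["across_mean"]
        assert out["p"] < 0.01
        lo, hi = out["within_ci"]
        assert lo <= out["within_mean"] <= hi

    def test_all_same_cue_has_no_across_pairs(self):
        trial = make_trial(np.eye(4), [0, 0, 0, 0])
        out = ev.cluster_similarity([trial], n_boot=100, seed=0)
        assert out["across_mean"] is None
        assert out["n_across"] == 0

    def test_identical_vectors_null_case(self):
        vecs = np.tile(np.array([1.0, 0.0]), (6, 1))
        trial = make_trial(vecs, [0, 0, 1, 1, 0, 0])
        out = ev.cluster_similarity([trial], n_boot=100, seed=0)
        assert out["within_mean"] == pytest.approx(out["across_mean"])


class TestPermutationTest:
    def _space_and_trials(self):
        rng = np.random.default_rng(2)
        words = ["c1", "c2", "c3"] + [f"r{i}" for i in range(8)]
        vecs = axis_vectors([0, 1, 2, 0, 0, 0, 0, 1, 1, 1, 1], dims=5,
                            noise=0.1, rng=rng)
        space = ev.WASSpace(words=words, vectors=vecs, rank=5)
        trial = ev.TrialAnalysis(
            0, ("c1", "c2", "c3"), "", [f"r{i}" for i in range(8)]
        )
        return space, ev.assign_primary_cues(trial, space)

    def test_identical_trials_reproduce_unpermuted_result(self):
        space, trial = self._space_and_trials()
        from dataclasses import replace
        twin = replace(trial, trial_id=1)
        base = ev.cluster_similarity([trial, twin], n_boot=500, seed=3)
        perm = ev.permutation_test([trial, twin], space, seed=3, n_boot=500)
        assert perm["within_mean"] == pytest.approx(base["within_mean"])
        assert perm["across_mean"] == pytest.approx(base["across_mean"])

    def test_single_trial_rejected(self):
        space, trial = self._space_and_trials()
        with pytest.raises(ValueError):
            ev.permutation_test([trial], space, seed=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        words = ["c1", "c2", "c3", "x1", "x2", "y1", "y2"]
        vecs = axis_vectors([0, 1, 2, 0, 0, 1, 1], dims=4, noise=0.2, rng=rng)
        space = ev.WASSpace(words=words, vectors=vecs, rank=4)
        trials = []
        for t, resp in enumerate((["x1", "x2", "y1"], ["y2", "y1", "x1"],
                                  ["x2", "y2", "x1"])):
            tr = ev.TrialAnalysis(t, ("c1", "c2", "c3"), "", resp)
            trials.append(ev.assign_primary_cues(tr, space))
        a = ev.permutation_test(trials, space, seed=9, n_boot=200)
        b = ev.permutation_test(trials, space, seed=9, n_boot=200)
        assert a["within_mean"] == b["within_mean"]
        assert a["across_mean"] == b["across_mean"]


class TestSwitchProbability:
    def test_equal_frequencies_give_one_third_baseline(self):
        trial = make_trial(np.eye(6), [0, 1, 2, 0, 1, 2])
        out = ev.switch_probability([trial])
        assert out["baseline_same_cue_pct"] == pytest.approx(100.0 / 3.0)

    def test_single_cue_everywhere(self):
        trial = make_trial(np.eye(5), [1, 1, 1, 1, 1])
        out = ev.switch_probability([trial])
        assert out["same_cue_pct"] == 100.0
        assert out["baseline_same_cue_pct"] == 100.0
        assert out["switch_pct"] == 0.0

    def test_baseline_is_sum_of_squared_frequencies(self):
        trial = make_trial(np.eye(4), [0, 0, 0, 1])
        out = ev.switch_probability([trial])
        expected = (3 / 4) ** 2 + (1 / 4) ** 2
        assert out["baseline_same_cue_pct"] == pytest.approx(100 * expected)

    def test_switch_and_same_sum_to_hundred(self):
        trial = make_trial(np.eye(6), [0, 1, 1, 2, 2, 2])
        out = ev.switch_probability([trial])
        assert out["same_cue_pct"] + out["switch_pct"] == pytest.approx(100.0)


class TestAdjacencyAnalysis:
    def test_cluster_of_two_contributes_only_adjacent_within(self):
        trial = make_trial(np.eye(2), [0, 0])
        out = ev.adjacency_analysis([trial], n_boot=100, seed=0)
        assert out["within_adjacent"]["n"] == 1
        assert out["within_nonadjacent"] is None
        assert out["across_adjacent"] is None

    def test_markov_chain_gives_adjacent_advantage(self):
        # each response is a small perturbation of its predecessor: adjacent
        # pairs are more similar than non-adjacent in both conditions
        rng = np.random.default_rng(5)
        trials = []
        for t in range(30):
            v = rng.normal(0, 1, 12)
            vecs, cues = [], []
            for i in range(10):
                v = v + rng.normal(0, 0.35, 12)
                vecs.append(v / np.linalg.norm(v))
                cues.append(0 if i < 5 else 1)
            trials.append(make_trial(np.array(vecs), cues, trial_id=t))
        out = ev.adjacency_analysis(trials, n_boot=500, seed=1)
        assert out["within_adjacent"]["mean"] > out["within_nonadjacent"]["mean"]
        assert out["across_adjacent"]["mean"] > out["across_nonadjacent"]["mean"]


class TestFinalApproachSlope:
    def test_constant_repetition_gives_zero_slope(self):
        vecs = np.tile(np.array([0.0, 1.0]), (8, 1))
        trial = make_trial(vecs, [0] * 8)
        out = ev.final_approach_slope([trial])
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert all(m == pytest.approx(1.0) for m in out["mean_similarity"])

    def test_planted_drift_gives_positive_slope(self):
        rng = np.random.default_rng(6)
        trials = []
        target = np.zeros(10)
        target[0] = 1.0
        for t in range(25):
            vecs = []
            for i in range(11):
                w = (i + 1) / 11
                v = w * target + (1 - w) * rng.normal(0, 1, 10)
                vecs.append(v / np.linalg.norm(v))
            trials.append(make_trial(np.array(vecs), [0] * 11, trial_id=t))
        out = ev.final_approach_slope(trials)
        assert out["slope"] > 0
        assert out["sign_test_p"] < 0.05

    def test_reversed_drift_gives_negative_slope(self):
        rng = np.random.default_rng(6)
        trials = []
        target = np.zeros(10)
        target[0] = 1.0
        for t in range(25):
            vecs = []
            for i in range(11):
                w = 1.0 - i / 11
                v = w * target + (1 - w) * rng.normal(0, 1, 10)
                vecs.append(v / np.linalg.norm(v))
            # final response is far from the earlier, target-like ones
            trials.append(make_trial(np.array(vecs), [0] * 11, trial_id=t))
        assert ev.final_approach_slope(trials)["slope"] < 0

    def test_excluded_trials_ignored(self):
        vecs = np.tile(np.array([0.0, 1.0]), (8, 1))
        good = make_trial(vecs, [0] * 8)
        bad = make_trial(np.eye(8), [0] * 8, excluded=True)
        out = ev.final_approach_slope([good, bad])
        assert out["n_trials"] == 1

    def test_all_short_trials_rejected(self):
        trial = make_trial(np.eye(2), [0, 0])
        with pytest.raises(ValueError):
            ev.final_approach_slope([trial])


class TestSummary:
    def test_no_solution_found_gives_zero_accuracy(self):
        trials = [make_trial(np.eye(3), [0, 1, 2], solved=False)]
        assert ev.summary(trials).accuracy == 0.0

    def test_single_trial_length_stats(self):
        trial = make_trial(np.eye(7), [0] * 7, solved=True)
        report = ev.summary([trial])
        assert report.min_length == report.max_length == 7
        assert report.mean_length == 7.0
        assert report.accuracy == 1.0

    def test_identical_length_distributions_correlate_perfectly(self):
        rng = np.random.default_rng(8)
        lengths = rng.integers(2, 15, size=50)
        trials = [
            make_trial(np.eye(int(n)), [0] * int(n), trial_id=i)
            for i, n in enumerate(lengths)
        ]
        report = ev.summary(trials, comparison_lengths=lengths)
        assert report.length_r == pytest.approx(1.0)

    def test_per_problem_correlation(self):
        trials, problems = [], []
        for i, n in enumerate([3, 3, 8, 8, 12, 12]):
            trials.append(make_trial(np.eye(n), [0] * n, trial_id=i))
            problems.append(i // 2)
        comparison = {0: 3.0, 1: 8.0, 2: 12.0}
        report = ev.summary(
            trials, problem_of_trial=problems, comparison_problem_means=comparison
        )
        assert report.per_problem_r == pytest.approx(1.0)


class TestBootstrapCI:
    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0.5, 0.2, 100)
        lo, hi = ev.bootstrap_ci(values, n_boot=2000, seed=0)
        assert lo <= values.mean() <= hi

    def test_seeded_reproducibility(self):
        values = np.arange(20.0)
        assert ev.bootstrap_ci(values, 500, seed=4) == ev.bootstrap_ci(values, 500, seed=4)

    def test_empty_input_gives_nan(self):
        lo, hi = ev.bootstrap_ci([], 100, seed=0)
        assert np.isnan(lo) and np.isnan(hi)


class TestLoadResponseLog:
    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "r.csv"
        pd.DataFrame({"trial": [0], "word": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="position"):
            ev.load_response_log(path)

    def test_sorts_by_trial_and_position(self):
        import pandas as pd

        df = pd.DataFrame({
            "trial": [1, 0, 0], "position": [0, 1, 0], "word": ["c", "b", "a"],
        })
        out = ev.load_response_log(df)
        assert out["word"].tolist() == ["a", "b", "c"]
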