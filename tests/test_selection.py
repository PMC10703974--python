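"""Objective evaluation and the random-restart greedy optimizer."""

from __future__ import annotations

import numpy as np
import pytest

from poseconsensus.pose_model import LigandPoseSet, Pose
from poseconsensus.selection import (
    ObjectiveConfig,
    SelectionState,
    greedy_sweep,
    hypothesis_gap,
    objective_value,
    optimize_selection,
)
from poseconsensus.similarity import PairFeatureTensor

from oracles import exhaustive_best_selection


def make_sets(score_lists, rmsds=None):
    sets = []
    for i, scores in enumerate(score_lists):
        poses = [
            Pose(
                ligand_id=f"l{i}",
                pose_index=p,
                pose_score=float(s),
                rmsd_to_truth=None if rmsds is None else float(rmsds[i][p]),
            )
            for p, s in enumerate(scores)
        ]
        sets.append(LigandPoseSet(ligand_id=f"l{i}", molecule=None, poses=poses))
    return sets


def make_tensor(score_lists, sim_blocks, rmsds=None):
    """sim_blocks[(i,j)] -> dict kind -> matrix of similarity values."""
    n = len(score_lists)
    return PairFeatureTensor(
        ligand_ids=[f"l{i}" for i in range(n)],
        pose_counts=[len(s) for s in score_lists],
        inter=sim_blocks,
        mcss_ok={k: "mcss" in v for k, v in sim_blocks.items()},
        pose_scores=[np.asarray(s, float) for s in score_lists],
        rmsd_to_truth=None if rmsds is None else [np.asarray(r) for r in rmsds],
        targets=["t"] * n,
    )


@pytest.fixture
def step_dists():
    """Densities making the log-ratio an affine, monotone function of the
    similarity value (native mass high, reference mass low)."""
    from poseconsensus.stats import SimilarityDistributions, fit_distribution

    rng = np.random.default_rng(0)
    native = {}
    reference = {}
    for kind in ("hbond", "saltbridge", "hydrophobic"):
        native[kind] = fit_distribution(rng.uniform(0.7, 0.95, 200), 0.03, (0, 1))
        reference[kind] = fit_distribution(rng.uniform(0.05, 0.55, 200), 0.03, (0, 1))
    native["mcss"] = fit_distribution(rng.uniform(0.0, 2.0, 200), 0.18, (0, 6))
    reference["mcss"] = fit_distribution(rng.uniform(2.0, 6.0, 200), 0.18, (0, 6))
    return SimilarityDistributions(native=native, reference=reference)


def random_instance(rng, n_ligands=3, n_poses=4):
    score_lists = [rng.random(n_poses) for _ in range(n_ligands)]
    blocks = {}
    for i in range(n_ligands):
        for j in range(i + 1, n_ligands):
            blocks[(i, j)] = {
                "hydrophobic": rng.uniform(0.05, 0.95, (n_poses, n_poses))
            }
    return score_lists, blocks


class TestObjectiveValue:
    def test_single_ligand_is_score_only(self, step_dists):
        sets = make_sets([[0.3, 0.9]])
        tensor = make_tensor([[0.3, 0.9]], {})
        cfg = ObjectiveConfig(c=2.0, restarts=1)
        assert objective_value(np.array([1]), sets, tensor, step_dists, cfg) == (
            pytest.approx(1.8)
        )

    def test_no_features_sums_scores(self):
        sets = make_sets([[0.4], [0.7]])
        tensor = make_tensor([[0.4], [0.7]], {(0, 1): {"hydrophobic": np.array([[0.5]])}})
        cfg = ObjectiveConfig(c=1.0, features=(), restarts=1)
        assert objective_value(np.array([0, 0]), sets, tensor, None, cfg) == (
            pytest.approx(1.1)
        )

    def test_two_ligand_pair_counted_twice(self, step_dists):
        from poseconsensus.stats import log_likelihood_ratio

        sim = 0.8
        sets = make_sets([[0.4], [0.7]])
        tensor = make_tensor(
            [[0.4], [0.7]], {(0, 1): {"hydrophobic": np.array([[sim]])}}
        )
        cfg = ObjectiveConfig(c=1.0, features=("hydrophobic",), restarts=1)
        r = log_likelihood_ratio(step_dists, "hydrophobic", sim)
        expected = 1.0 * (0.4 + 0.7) + 2 * r
        assert objective_value(np.array([0, 0]), sets, tensor, step_dists, cfg) == (
            pytest.approx(expected)
        )

    def test_empty_objective_errors(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(c=0.0, features=())

    def test_permutation_invariance(self, step_dists):
        rng = np.random.default_rng(7)
        score_lists, blocks = random_instance(rng)
        sets = make_sets(score_lists)
        tensor = make_tensor(score_lists, blocks)
        cfg = ObjectiveConfig(features=("hydrophobic",), restarts=1)
        sel = np.array([1, 2, 0])
        base = objective_value(sel, sets, tensor, step_dists, cfg)
        perm = [2, 0, 1]  # relabel ligands
        p_sets = [sets[i] for i in perm]
        p_tensor = tensor.subset(perm)
        p_sel = sel[perm]
        assert objective_value(p_sel, p_sets, p_tensor, step_dists, cfg) == (
            pytest.approx(base, abs=1e-10)
        )


class TestGreedySweep:
    def test_score_only_picks_max_score(self):
        score_lists = [[0.2, 0.9, 0.4], [0.8, 0.1, 0.3]]
        sets = make_sets(score_lists)
        tensor = make_tensor(score_lists, {(0, 1): {"hydrophobic": np.full((3, 3), 0.5)}})
        cfg = ObjectiveConfig(features=(), restarts=1)
        state = SelectionState(np.array([0, 1]), objective=-np.inf)
        out = greedy_sweep(state, sets, tensor, None, cfg, order=[0, 1])
        assert list(out.selected) == [1, 0]

    def test_fixed_point_unchanged(self, step_dists):
        rng = np.random.default_rng(11)
        score_lists, blocks = random_instance(rng)
        sets = make_sets(score_lists)
        tensor = make_tensor(score_lists, blocks)
        cfg = ObjectiveConfig(features=("hydrophobic",), restarts=1, seed=1)
        state = optimize_selection(sets, tensor, step_dists, cfg)
        again = greedy_sweep(state, sets, tensor, step_dists, cfg, order=[2, 1, 0])
        assert np.array_equal(again.selected, state.selected)

    def test_never_decreases_objective(self, step_dists):
        rng = np.random.default_rng(13)
        for _ in range(10):
            score_lists, blocks = random_instance(rng)
            sets = make_sets(score_lists)
            tensor = make_tensor(score_lists, blocks)
            cfg = ObjectiveConfig(features=("hydrophobic",), restarts=1)
            sel = np.array([rng.integers(4) for _ in range(3)])
            state = SelectionState(
                sel, objective_value(sel, sets, tensor, step_dists, cfg)
            )
            out = greedy_sweep(
                state, sets, tensor, step_dists, cfg, order=rng.permutation(3)
            )
            assert out.objective >= state.objective - 1e-12

    def test_constructed_pair_selected(self, step_dists):
        # only pose pair (0, 0) is strongly similar; the sweep must find it
        sim = np.full((2, 2), 0.1)
        sim[0, 0] = 0.9
        score_lists = [[0.5, 0.5], [0.5, 0.5]]
        sets = make_sets(score_lists)
        tensor = make_tensor(score_lists, {(0, 1): {"hydrophobic": sim}})
        cfg = ObjectiveConfig(features=("hydrophobic",), restarts=1)
        state = SelectionState(np.array([1, 1]), objective=-np.inf)
        out = greedy_sweep(state, sets, tensor, step_dists, cfg, order=[0, 1])
        assert list(out.selected) == [0, 0]
        _, best = exhaustive_best_selection(
            score_lists,
            {(0, 1): np.vectorize(
                lambda v: __import__("poseconsensus.stats", fromlist=["x"]
                                     ).log_likelihood_ratio(step_dists, "hydrophobic", v)
            )(sim)},
            c=1.0,
        )
        assert list(best) == [0, 0]


class TestOptimizeSelection:
    def test_single_ligand_argmax(self, step_dists):
        sets = make_sets([[0.1, 0.7, 0.3]])
        tensor = make_tensor([[0.1, 0.7, 0.3]], {})
        cfg = ObjectiveConfig(restarts=5, seed=3)
        state = optimize_selection(sets, tensor, step_dists, cfg)
        assert state.selected[0] == 1

    def test_deterministic_under_seed(self, step_dists):
        rng = np.random.default_rng(17)
        score_lists, blocks = random_instance(rng, 4, 5)
        sets = make_sets(score_lists)
        tensor = make_tensor(score_lists, blocks)
        cfg = ObjectiveConfig(features=("hydrophobic",), restarts=25, seed=9)
        s1 = optimize_selection(sets, tensor, step_dists, cfg)
        s2 = optimize_selection(sets, tensor, step_dists, cfg)
        assert np.array_equal(s1.selected, s2.selected)
        assert s1.objective == s2.objective

    def test_attains_exhaustive_maximum(self, step_dists):
        from poseconsensus.selection import pair_llr_matrices

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            score_lists, blocks = random_instance(rng)
            sets = make_sets(score_lists)
            tensor = make_tensor(score_lists, blocks)
            cfg = ObjectiveConfig(
                features=("hydrophobic",), restarts=500, seed=seed
            )
            state = optimize_selection(sets, tensor, step_dists, cfg)
            llr = pair_llr_matrices(tensor, step_dists, cfg.features)
            best_obj, _ = exhaustive_best_selection(
                score_lists, {(0, 1): llr[(0, 1)], (0, 2): llr[(0, 2)],
                              (1, 2): llr[(1, 2)]}, c=cfg.c
            )
            if state.objective >= best_obj - 1e-9:
                hits += 1
        assert hits >= 19


class TestHypothesisGap:
    def _labelled_instance(self, rng):
        n_poses = 4
        rmsds = [rng.uniform(0.5, 6.0, n_poses) for _ in range(3)]
        for r in rmsds:
            r[rng.integers(n_poses)] = rng.uniform(0.3, 1.5)
        score_lists = [rng.random(n_poses) for _ in range(3)]
        _, blocks = random_instance(rng)
        return make_sets(score_lists, rmsds), make_tensor(score_lists, blocks, rmsds)

    def test_score_only_gap_is_argmax_bound(self, step_dists):
        rng = np.random.default_rng(19)
        sets, tensor = self._labelled_instance(rng)
        cfg = ObjectiveConfig(features=(), restarts=10, seed=2)
        restricted, free, diff = hypothesis_gap(sets, tensor, step_dists, cfg)
        expected = sum(
            max(s.pose_scores()) - s.pose_scores()[np.argmin([p.rmsd_to_truth
                                                              for p in s.poses])]
            for s in sets
        )
        assert diff == pytest.approx(expected, abs=1e-9)
        assert diff >= 0

    def test_free_at_least_restricted(self, step_dists):
        rng = np.random.default_rng(23)
        sets, tensor = self._labelled_instance(rng)
        cfg = ObjectiveConfig(features=("hydrophobic",), restarts=200, seed=5)
        restricted, free, diff = hypothesis_gap(sets, tensor, step_dists, cfg)
        assert free >= restricted - 1e-9
        assert diff == pytest.approx(free - restricted)

    def test_missing_labels_error(self, step_dists):
        sets = make_sets([[0.5, 0.6]])
        tensor = make_tensor([[0.5, 0.6]], {})
        cfg = ObjectiveConfig(restarts=1)
        with pytest.raises(ValueError, match="rmsd_to_truth"):
            hypothesis_gap(sets, tensor, step_dists, cfg)
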