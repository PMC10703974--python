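"""Consensus pose selection by random-restart greedy coordinate ascent.

One pose ℓ_i is chosen per ligand so as to maximize

    Σ_i [ C·score(ℓ_i) + (1/(n−1)) Σ_{s∈S} Σ_{j≠i} log f(s(ℓ_i,ℓ_j)|Native)
                                                     / f(s(ℓ_i,ℓ_j)|Reference) ]

— a per-ligand reward for the docking engine's own pose score plus a
consensus reward for inter-ligand pose-pair similarity under the pre-fitted
native/reference densities.  The landscape is combinatorial, so selections
are optimized by repeated greedy sweeps (each ligand in random order set to
the argmax holding the others fixed) from many random initializations; the
best selection across restarts is returned.  All randomness flows from one
seeded generator, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .pose_model import LigandPoseSet, NATIVE_RMSD_THRESHOLD
from .similarity import ALL_PAIR_KINDS, PairFeatureTensor
from .stats import SimilarityDistributions, log_likelihood_ratio

__all__ = [
    "ObjectiveConfig",
    "SelectionState",
    "objective_value",
    "greedy_sweep",
    "optimize_selection",
    "hypothesis_gap",
    "pair_llr_matrices",
]


@dataclass
class ObjectiveConfig:
    """Objective weights and optimizer settings.

    ``verbatim_sign`` flips the score term to a penalty (the literal printed
    form of the objective); the default treats the pose score as a reward,
    which is the semantically consistent reading given that higher scores
    mean more likely native.
    """

    c: float = 1.0
    features: tuple[str, ...] = ("hbond", "saltbridge", "hydrophobic", "mcss")
    restarts: int = 500
    max_sweeps: int = 100
    seed: int = 0
    verbatim_sign: bool = False

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("C must be >= 0")
        unknown = set(self.features) - set(ALL_PAIR_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
        if self.c == 0 and not self.features:
            raise ValueError("objective undefined: no score term and no features")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    @property
    def score_sign(self) -> float:
        return -1.0 if self.verbatim_sign else 1.0


@dataclass
class SelectionState:
    """Selected pose index per ligand plus the cached objective value."""

    selected: np.ndarray  # (n_ligands,) pose indices
    objective: float

    @property
    def n(self) -> int:
        return len(self.selected)


def pair_llr_matrices(
    tensor: PairFeatureTensor,
    dists: SimilarityDistributions,
    features: Sequence[str],
) -> dict[tuple[int, int], np.ndarray]:
    """Per ligand pair, the summed log-likelihood-ratio matrix over features.

    A ligand pair without a valid MCSS contributes 0 for the mcss feature
    (the neutral log-ratio).  These matrices are what every sweep consults,
    so they are computed once up front.
    """
    out = {}
    for (i, j), block in tensor.inter.items():
        total = np.zeros_like(next(iter(block.values())))
        for kind in features:
            if kind not in block:
                continue  # absent MCSS: neutral contribution
            total += log_likelihood_ratio(dists, kind, block[kind].ravel()).reshape(
                block[kind].shape
            )
        out[(i, j)] = total
    return out


def _scores(sets: Sequence[LigandPoseSet]) -> list[np.ndarray]:
    return [s.pose_scores() for s in sets]


def objective_value(
    state: SelectionState | np.ndarray,
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: Optional[SimilarityDistributions],
    cfg: ObjectiveConfig,
    llr: Optional[dict] = None,
) -> float:
    """Evaluate the objective for a fixed selection.

    With a single ligand the pairwise term is defined as 0, so the method
    degrades gracefully to score-only selection.
    """
    selected = state.selected if isinstance(state, SelectionState) else np.asarray(state)
    n = len(selected)
    if n < 1:
        raise ValueError("need at least one ligand")
    scores = _scores(sets)
    total = cfg.score_sign * cfg.c * sum(
        float(scores[i][selected[i]]) for i in range(n)
    )
    if n == 1 or not cfg.features:
        return total
    if llr is None:
        if dists is None:
            raise ValueError("distributions required when features are enabled")
        llr = pair_llr_matrices(tensor, dists, cfg.features)
    pair_sum = 0.0
    for (i, j), mat in llr.items():
        pair_sum += float(mat[selected[i], selected[j]])
    # each unordered pair appears in both endpoints' brackets
    return total + 2.0 * pair_sum / (n - 1)


def greedy_sweep(
    state: SelectionState,
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: Optional[SimilarityDistributions],
    cfg: ObjectiveConfig,
    order: Sequence[int],
    llr: Optional[dict] = None,
) -> SelectionState:
    """One pass over the ligands in the given order.

    Each visited ligand's pose is replaced by the argmax of the (global)
    objective with all other selections held fixed; ties break to the lowest
    pose index.  The objective never decreases.
    """
    if llr is None and cfg.features:
        llr = pair_llr_matrices(tensor, dists, cfg.features)
    selected = state.selected.copy()
    n = len(selected)
    scores = _scores(sets)
    for i in order:
        cand = cfg.score_sign * cfg.c * scores[i]
        if n > 1 and cfg.features:
            pair_part = np.zeros_like(cand)
            for j in range(n):
                if j == i:
                    continue
                key = (i, j) if i < j else (j, i)
                mat = llr[key]
                pair_part += mat[:, selected[j]] if i < j else mat[selected[j], :]
            cand = cand + (2.0 / (n - 1)) * pair_part
        selected[i] = int(np.argmax(cand))  # argmax ties -> lowest index
    obj = objective_value(selected, sets, tensor, dists, cfg, llr=llr)
    return SelectionState(selected=selected, objective=obj)


def optimize_selection(
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: Optional[SimilarityDistributions],
    cfg: ObjectiveConfig,
) -> SelectionState:
    """Random-restart greedy coordinate ascent over pose selections.

    Each restart draws a uniform-random initial selection and sweeps (fresh
    random ligand order every sweep) until a sweep changes nothing or the
    sweep cap is hit; the best state across restarts is returned.  Fully
    reproducible from ``cfg.seed``.
    """
    n = len(sets)
    if n == 0:
        raise ValueError("need at least one ligand")
    counts = np.array([len(s.poses) for s in sets])
    if np.any(counts < 1):
        raise ValueError("every ligand needs at least one pose")
    rng = np.random.default_rng(cfg.seed)
    llr = (
        pair_llr_matrices(tensor, dists, cfg.features)
        if (cfg.features and n > 1)
        else {}
    )
    best: Optional[SelectionState] = None
    for _ in range(cfg.restarts):
        selected = rng.integers(0, counts)
        state = SelectionState(
            selected=selected,
            objective=objective_value(selected, sets, tensor, dists, cfg, llr=llr),
        )
        for _ in range(cfg.max_sweeps):
            order = rng.permutation(n)
            new_state = greedy_sweep(state, sets, tensor, dists, cfg, order, llr=llr)
            changed = not np.array_equal(new_state.selected, state.selected)
            state = new_state
            if not changed:
                break
        if best is None or state.objective > best.objective:
            best = state
    return best


def hypothesis_gap(
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: SimilarityDistributions,
    cfg: ObjectiveConfig,
    native_threshold: float = NATIVE_RMSD_THRESHOLD,
) -> tuple[float, float, float]:
    """Objective at the best-RMSD selection vs. free optimization.

    Only ligands possessing at least one pose below the native threshold are
    included.  Returns (objective with each ligand pinned to its lowest-RMSD
    pose, best objective over all poses, difference free − pinned).  If
    distinct ligands truly bound alike, the two would coincide; a positive
    gap quantifies how far the consensus objective prefers non-native
    ensembles.
    """
    rmsds = []
    for s in sets:
        r = []
        for p in s.poses:
            if p.rmsd_to_truth is None:
                raise ValueError(
                    f"pose {p.pose_index} of {s.ligand_id} lacks rmsd_to_truth"
                )
            r.append(p.rmsd_to_truth)
        rmsds.append(np.array(r))
    keep = [i for i, r in enumerate(rmsds) if r.min() < native_threshold]
    if not keep:
        raise ValueError("no ligand has a pose below the native threshold")
    sub_sets = [sets[i] for i in keep]
    sub_tensor = tensor.subset(keep)
    pinned = np.array([int(np.argmin(rmsds[i])) for i in keep])
    llr = (
        pair_llr_matrices(sub_tensor, dists, cfg.features)
        if (cfg.features and len(keep) > 1)
        else {}
    )
    restricted = objective_value(pinned, sub_sets, sub_tensor, dists, cfg, llr=llr)
    free_state = optimize_selection(sub_sets, sub_tensor, dists, cfg)
    return restricted, free_state.objective, free_state.objective - restricted
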