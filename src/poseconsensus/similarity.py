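"""Pairwise inter-pose similarity.

Residue-level interaction fingerprints are compared with a smoothed
("pseudo") Tanimoto ratio

    TS(i, j) = (1 + Σ_r √f_i^r √f_j^r) / (2 + Σ f_i + Σ f_j + Σ_r √f_i^r √f_j^r)

where f^r are the per-residue summed scores of one feature kind and the
cross-term runs over the residues of the docking protein.  The additive 1/2
constants regularize sparse fingerprints: two empty fingerprints score
exactly 0.5, and any non-empty disjoint pair scores below 0.5.  Values are
always inside the open interval (0, 1).

:class:`PairFeatureTensor` assembles these similarities (plus the MCSS RMSD
where the ligand pair has a valid MCSS) for every inter-ligand pose pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .featurize import FEATURE_KINDS, ResidueFeatureMap
from .mcss import MCSSResult, mcss_rmsd_matrix
from .pose_model import LigandPoseSet, NATIVE_RMSD_THRESHOLD

__all__ = [
    "pseudo_tanimoto",
    "PairFeatures",
    "PairFeatureTensor",
    "build_pair_tensor",
    "ALL_PAIR_KINDS",
]

#: feature kinds carried per pose pair (MCSS RMSD is optional per ligand pair)
ALL_PAIR_KINDS: tuple[str, ...] = FEATURE_KINDS + ("mcss",)


def pseudo_tanimoto(
    fi: Mapping[tuple, float] | Mapping[str, float],
    fj: Mapping[tuple, float] | Mapping[str, float],
) -> float:
    """Pseudo-Tanimoto similarity of two same-kind residue score maps."""
    sum_i = 0.0
    for v in fi.values():
        if v < 0:
            raise ValueError("negative fingerprint value")
        sum_i += v
    sum_j = 0.0
    for v in fj.values():
        if v < 0:
            raise ValueError("negative fingerprint value")
        sum_j += v
    cross = 0.0
    smaller, larger = (fi, fj) if len(fi) <= len(fj) else (fj, fi)
    for r, v in smaller.items():
        w = larger.get(r)
        if w:
            cross += np.sqrt(v) * np.sqrt(w)
    return (1.0 + cross) / (2.0 + sum_i + sum_j + cross)


@dataclass(frozen=True)
class PairFeatures:
    """Similarity values for one pose pair."""

    ligand_i: str
    pose_i: int
    ligand_j: str
    pose_j: int
    values: dict  # kind -> similarity (in (0,1)); "mcss" -> RMSD Å, may be absent

    def __post_init__(self) -> None:
        for kind, v in self.values.items():
            if kind == "mcss":
                if v < 0:
                    raise ValueError("mcss_rmsd must be >= 0")
            elif not 0.0 < v < 1.0:
                raise ValueError(f"{kind} similarity {v} outside (0, 1)")


@dataclass
class PairFeatureTensor:
    """Feature-major container of all pairwise pose similarities.

    ``inter[(i, j)][kind]`` (i < j, ligand indices) is an (n_i, n_j) array.
    ``mcss_ok[(i, j)]`` records whether the MCSS feature is available for the
    pair.  Optional per-ligand arrays (pose scores, RMSD labels, native
    flags, target ids) travel with the tensor so the statistics module can
    fit native/reference distributions from it directly.
    """

    ligand_ids: list[str]
    pose_counts: list[int]
    inter: dict[tuple[int, int], dict[str, np.ndarray]]
    mcss_ok: dict[tuple[int, int], bool]
    intra: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    pose_scores: Optional[list[np.ndarray]] = None
    rmsd_to_truth: Optional[list[np.ndarray]] = None
    targets: Optional[list[str]] = None

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    def native_flags(self, threshold: float = NATIVE_RMSD_THRESHOLD) -> list[np.ndarray]:
        if self.rmsd_to_truth is None:
            raise ValueError("tensor carries no RMSD-to-truth labels")
        return [r < threshold for r in self.rmsd_to_truth]

    def pair(self, i: int, j: int) -> dict[str, np.ndarray]:
        """Symmetric access: (i, j) with i > j returns transposed arrays."""
        if i == j:
            return self.intra[i]
        key = (min(i, j), max(i, j))
        block = self.inter[key]
        if i < j:
            return block
        return {k: v.T for k, v in block.items()}

    def pair_features(self, i: int, pi: int, j: int, pj: int) -> PairFeatures:
        block = self.pair(i, j)
        values = {k: float(v[pi, pj]) for k, v in block.items()}
        return PairFeatures(
            self.ligand_ids[i], pi, self.ligand_ids[j], pj, values
        )

    def subset(self, indices: Sequence[int]) -> "PairFeatureTensor":
        """Tensor restricted to the given ligand indices (reindexed)."""
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        inter = {}
        mcss_ok = {}
        for (a, b), block in self.inter.items():
            if a in remap and b in remap:
                na, nb = remap[a], remap[b]
                if na < nb:
                    inter[(na, nb)] = block
                else:
                    inter[(nb, na)] = {k: v.T for k, v in block.items()}
                mcss_ok[tuple(sorted((na, nb)))] = self.mcss_ok[(a, b)]
        return PairFeatureTensor(
            ligand_ids=[self.ligand_ids[i] for i in indices],
            pose_counts=[self.pose_counts[i] for i in indices],
            inter=inter,
            mcss_ok=mcss_ok,
            intra={remap[i]: v for i, v in self.intra.items() if i in remap},
            pose_scores=None
            if self.pose_scores is None
            else [self.pose_scores[i] for i in indices],
            rmsd_to_truth=None
            if self.rmsd_to_truth is None
            else [self.rmsd_to_truth[i] for i in indices],
            targets=None if self.targets is None else [self.targets[i] for i in indices],
        )


def _similarity_matrix(
    fps_i: Sequence[ResidueFeatureMap],
    fps_j: Sequence[ResidueFeatureMap],
    kind: str,
) -> np.ndarray:
    """Vectorized pseudo-Tanimoto between two fingerprint lists.

    Builds dense (pose × residue) score matrices over the union of residues
    touched by either ligand; the cross-term is then one matrix product.
    """
    residues = sorted(
        {r for fp in fps_i for r in fp[kind]} | {r for fp in fps_j for r in fp[kind]}
    )
    if not residues:
        return np.full((len(fps_i), len(fps_j)), 0.5)
    index = {r: c for c, r in enumerate(residues)}

    def dense(fps):
        mat = np.zeros((len(fps), len(residues)))
        for p, fp in enumerate(fps):
            for r, v in fp[kind].items():
                if v < 0:
                    raise ValueError("negative fingerprint value")
                mat[p, index[r]] = v
        return mat

    fi = dense(fps_i)
    fj = dense(fps_j)
    cross = np.sqrt(fi) @ np.sqrt(fj).T
    sums = fi.sum(axis=1)[:, None] + fj.sum(axis=1)[None, :]
    return (1.0 + cross) / (2.0 + sums + cross)


def build_pair_tensor(
    sets: Sequence[LigandPoseSet],
    fingerprints: Sequence[Sequence[ResidueFeatureMap]],
    mcss_results: Mapping[tuple[int, int], MCSSResult],
    include_intra: bool = False,
) -> PairFeatureTensor:
    """Assemble the full pair-feature tensor across ligands.

    ``fingerprints[i][p]`` is the fingerprint of pose p of ligand i; it must
    exist for every retained pose.  ``mcss_results[(i, j)]`` (i < j) is the
    MCSS between ligands i and j; the MCSS RMSD channel is filled only where
    that result is valid.  Intra-ligand pairs (used when fitting statistics,
    never for selection) are populated on request.
    """
    n = len(sets)
    for i, pose_set in enumerate(sets):
        if len(fingerprints[i]) != len(pose_set.poses):
            missing = len(pose_set.poses) - len(fingerprints[i])
            raise ValueError(
                f"ligand {pose_set.ligand_id}: {missing} pose(s) lack fingerprints"
            )
    coords = [
        np.stack([p.coords for p in s.poses]) if s.molecule is not None else None
        for s in sets
    ]
    inter: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    mcss_ok: dict[tuple[int, int], bool] = {}
    for i in range(n):
        for j in range(i + 1, n):
            block = {
                kind: _similarity_matrix(fingerprints[i], fingerprints[j], kind)
                for kind in FEATURE_KINDS
            }
            result = mcss_results.get((i, j)) or mcss_results.get((j, i))
            ok = result is not None and result.valid
            if ok:
                mats = mcss_rmsd_matrix(coords[i], coords[j], result)
                block["mcss"] = mats
            inter[(i, j)] = block
            mcss_ok[(i, j)] = ok
    intra: dict[int, dict[str, np.ndarray]] = {}
    if include_intra:
        for i in range(n):
            block = {
                kind: _similarity_matrix(fingerprints[i], fingerprints[i], kind)
                for kind in FEATURE_KINDS
            }
            result = mcss_results.get((i, i))
            if result is not None and result.valid:
                block["mcss"] = mcss_rmsd_matrix(coords[i], coords[i], result)
            intra[i] = block
    rmsds = []
    have_rmsd = all(
        all(p.rmsd_to_truth is not None for p in s.poses) for s in sets
    )
    return PairFeatureTensor(
        ligand_ids=[s.ligand_id for s in sets],
        pose_counts=[len(s.poses) for s in sets],
        inter=inter,
        mcss_ok=mcss_ok,
        intra=intra,
        pose_scores=[s.pose_scores() for s in sets],
        rmsd_to_truth=[
            np.array([p.rmsd_to_truth for p in s.poses], dtype=float) for s in sets
        ]
        if have_rmsd
        else None,
        targets=[s.target for s in sets],
    )
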