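"""End-to-end orchestration: poses in, consensus selection report out.

The full chain is: read pose ensembles → re-rank and truncate by pose score
→ add hydrogens → interaction fingerprints → pairwise MCSS → pair-feature
tensor → load (or fit) similarity distributions → optimize selection →
report.  Stage timings and counts are logged; the assembled tensor is cached
on disk keyed by a hash of the inputs, so unchanged reruns skip
featurization.

Docking itself is outside this package: poses either arrive pre-docked as
SDF files or are produced by a user-supplied external command template
(placeholders ``{receptor}``, ``{ligand}``, ``{autobox}``, ``{out}``); only
the output SDF is ever parsed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import subprocess
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import FEATURE_KINDS, FeaturizeConfig, add_pose_hydrogens, featurize_pose
from .mcss import strict_mcss
from .pose_model import (
    LigandPoseSet,
    ReceptorStructure,
    rank_and_truncate,
    read_pose_ensemble,
    read_receptor,
)
from .selection import (
    ObjectiveConfig,
    SelectionState,
    optimize_selection,
    pair_llr_matrices,
)
from .similarity import PairFeatureTensor, build_pair_tensor
from .stats import SimilarityDistributions, fit_similarity_statistics

logger = logging.getLogger("poseconsensus")

__all__ = [
    "PipelineConfig",
    "prepare_tensor",
    "run_pipeline",
    "run_ablation",
    "selection_report",
    "ABLATION_TOKENS",
]


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run."""

    receptor: Path
    pose_files: list[Path]
    distributions: Optional[Path] = None
    top_k: int = 100
    score_property: str = "CNNscore"
    featurize: FeaturizeConfig = field(default_factory=FeaturizeConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    relaxed_mcss: bool = False
    mcss_timeout: int = 60
    cache_dir: Optional[Path] = None
    docking_cmd: Optional[str] = None  # None = pre-docked

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
            else:
                logger.info("stage %s done in %.2fs", name, dt)
            return False

    return _Timer()


def run_external_docking(
    template: str, receptor: Path, ligand: Path, autobox: Path, out: Path
) -> None:
    """Invoke a user-supplied docking command; only its output SDF is read."""
    cmd = template.format(
        receptor=receptor, ligand=ligand, autobox=autobox, out=out
    )
    logger.info("external docking: %s", cmd)
    subprocess.run(cmd, shell=True, check=True)
    if not Path(out).exists():
        raise FileNotFoundError(f"external docking produced no output at {out}")


def _inputs_digest(cfg: PipelineConfig, extra: str = "") -> str:
    sha = hashlib.sha256()
    for path in [cfg.receptor, *sorted(cfg.pose_files)]:
        sha.update(Path(path).read_bytes())
    sha.update(
        repr(
            (
                cfg.top_k,
                cfg.score_property,
                asdict(cfg.featurize),
                cfg.relaxed_mcss,
                extra,
            )
        ).encode()
    )
    return sha.hexdigest()[:24]


def _save_tensor(tensor: PairFeatureTensor, path: Path) -> None:
    arrays = {}
    for (i, j), block in tensor.inter.items():
        for kind, mat in block.items():
            arrays[f"inter|{i}|{j}|{kind}"] = mat
    for i, block in tensor.intra.items():
        for kind, mat in block.items():
            arrays[f"intra|{i}|{kind}"] = mat
    if tensor.rmsd_to_truth is not None:
        for i, arr in enumerate(tensor.rmsd_to_truth):
            arrays[f"rmsd|{i}"] = arr
    for i, arr in enumerate(tensor.pose_scores):
        arrays[f"score|{i}"] = arr
    meta = {
        "ligand_ids": tensor.ligand_ids,
        "pose_counts": tensor.pose_counts,
        "mcss_ok": {f"{i}|{j}": ok for (i, j), ok in tensor.mcss_ok.items()},
        "targets": tensor.targets,
        "has_rmsd": tensor.rmsd_to_truth is not None,
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def _load_tensor(path: Path) -> PairFeatureTensor:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    inter: dict = {}
    intra: dict = {}
    for key in data.files:
        parts = key.split("|")
        if parts[0] == "inter":
            i, j, kind = int(parts[1]), int(parts[2]), parts[3]
            inter.setdefault((i, j), {})[kind] = data[key]
        elif parts[0] == "intra":
            i, kind = int(parts[1]), parts[2]
            intra.setdefault(i, {})[kind] = data[key]
    n = len(meta["ligand_ids"])
    return PairFeatureTensor(
        ligand_ids=meta["ligand_ids"],
        pose_counts=meta["pose_counts"],
        inter=inter,
        mcss_ok={
            (int(k.split("|")[0]), int(k.split("|")[1])): v
            for k, v in meta["mcss_ok"].items()
        },
        intra=intra,
        pose_scores=[data[f"score|{i}"] for i in range(n)],
        rmsd_to_truth=[data[f"rmsd|{i}"] for i in range(n)]
        if meta["has_rmsd"]
        else None,
        targets=meta["targets"],
    )


def prepare_sets(cfg: PipelineConfig) -> list[LigandPoseSet]:
    """Read, re-rank, truncate and protonate every ligand's ensemble."""
    sets = []
    with _stage("read+rank"):
        for path in cfg.pose_files:
            pose_set = read_pose_ensemble(path, score_property=cfg.score_property)
            pose_set = rank_and_truncate(pose_set, cfg.top_k)
            sets.append(pose_set)
        logger.info(
            "read %d ligands, %s poses", len(sets), [len(s) for s in sets]
        )
    with _stage("protonate"):
        sets = [add_pose_hydrogens(s) for s in sets]
    return sets


def prepare_tensor(
    receptor: ReceptorStructure,
    sets: Sequence[LigandPoseSet],
    cfg: PipelineConfig,
    include_intra: bool = False,
) -> PairFeatureTensor:
    """Fingerprint every pose, compute pairwise MCSS and build the tensor."""
    with _stage("featurize"):
        fingerprints = [
            [featurize_pose(receptor, p, cfg.featurize) for p in s.poses]
            for s in sets
        ]
    with _stage("mcss"):
        mcss_results = {}
        for i in range(len(sets)):
            lo = i if include_intra else i + 1
            for j in range(lo, len(sets)):
                mcss_results[(i, j)] = strict_mcss(
                    sets[i].molecule,
                    sets[j].molecule,
                    timeout=cfg.mcss_timeout,
                    relaxed=cfg.relaxed_mcss,
                )
    with _stage("pair tensor"):
        tensor = build_pair_tensor(
            sets, fingerprints, mcss_results, include_intra=include_intra
        )
    return tensor


def prepare_tensor_cached(
    receptor: ReceptorStructure,
    sets: Sequence[LigandPoseSet],
    cfg: PipelineConfig,
    include_intra: bool = False,
) -> PairFeatureTensor:
    if cfg.cache_dir is None:
        return prepare_tensor(receptor, sets, cfg, include_intra)
    cache_dir = Path(cfg.cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _inputs_digest(cfg, extra=f"intra={include_intra}")
    cache_path = cache_dir / f"tensor-{key}.npz"
    if cache_path.exists():
        logger.info("tensor cache hit: %s", cache_path.name)
        return _load_tensor(cache_path)
    tensor = prepare_tensor(receptor, sets, cfg, include_intra)
    _save_tensor(tensor, cache_path)
    return tensor


def selection_report(
    state: SelectionState,
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: Optional[SimilarityDistributions],
    cfg: ObjectiveConfig,
) -> pd.DataFrame:
    """Per-ligand report: selected pose, score and per-feature contributions."""
    n = len(sets)
    rows = []
    per_feature = {kind: np.zeros(n) for kind in cfg.features}
    if n > 1 and cfg.features and dists is not None:
        for kind in cfg.features:
            llr_k = pair_llr_matrices(tensor, dists, [kind])
            for (i, j), mat in llr_k.items():
                v = float(mat[state.selected[i], state.selected[j]])
                per_feature[kind][i] += v / (n - 1)
                per_feature[kind][j] += v / (n - 1)
    for i, s in enumerate(sets):
        pose = s.poses[int(state.selected[i])]
        row = {
            "ligand_id": s.ligand_id,
            "selected_pose_index": pose.pose_index,
            "original_index": pose.original_index,
            "pose_score": pose.pose_score,
        }
        for kind in cfg.features:
            row[f"llr_{kind}"] = per_feature[kind][i]
        if pose.rmsd_to_truth is not None:
            row["rmsd_to_truth"] = pose.rmsd_to_truth
            row["native"] = bool(pose.rmsd_to_truth < 2.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["objective"] = state.objective
    return df


def run_pipeline(
    cfg: PipelineConfig,
    receptor: Optional[ReceptorStructure] = None,
    dists: Optional[SimilarityDistributions] = None,
) -> tuple[pd.DataFrame, SelectionState, list[LigandPoseSet]]:
    """Execute the full chain and return (report, selection, pose sets)."""
    if receptor is None:
        with _stage("receptor"):
            receptor = read_receptor(cfg.receptor)
    sets = prepare_sets(cfg)
    tensor = prepare_tensor_cached(receptor, sets, cfg)
    if dists is None:
        if cfg.distributions is None:
            raise ValueError("no similarity distributions provided")
        dists = SimilarityDistributions.from_json(cfg.distributions)
    with _stage("selection"):
        state = optimize_selection(sets, tensor, dists, cfg.objective)
    report = selection_report(state, sets, tensor, dists, cfg.objective)
    return report, state, sets


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

#: component tokens as used in ablation figures: G = pose score, HB/SB/C =
#: hydrogen bond / salt bridge / hydrophobic contact similarity, MCSS = MCSS RMSD
ABLATION_TOKENS = {
    "G": "score",
    "HB": "hbond",
    "SB": "saltbridge",
    "C": "hydrophobic",
    "MCSS": "mcss",
}


def parse_subset(label: str) -> tuple[bool, tuple[str, ...]]:
    """Parse an ablation label like ``"G,HB,MCSS"`` or ``"full"``."""
    label = label.strip()
    if label.lower() == "full":
        return True, ("hbond", "saltbridge", "hydrophobic", "mcss")
    use_score = False
    features = []
    for token in label.split(","):
        token = token.strip().upper()
        if not token:
            continue
        if token not in ABLATION_TOKENS:
            raise ValueError(f"unknown ablation token '{token}'")
        if token == "G":
            use_score = True
        else:
            features.append(ABLATION_TOKENS[token])
    return use_score, tuple(features)


def run_ablation(
    sets: Sequence[LigandPoseSet],
    tensor: PairFeatureTensor,
    dists: SimilarityDistributions,
    subsets: Sequence[str],
    base: Optional[ObjectiveConfig] = None,
) -> pd.DataFrame:
    """Selection accuracy (fraction of ligands whose chosen pose is native)
    for each requested component subset."""
    if not subsets:
        raise ValueError("empty subset list")
    base = base or ObjectiveConfig()
    flags = [s.native_flags() for s in sets]
    rows = []
    for label in subsets:
        use_score, features = parse_subset(label)
        c = base.c if use_score else 0.0
        if c == 0 and not features:
            warnings.warn(f"subset '{label}' enables no objective term; skipped")
            continue
        cfg = ObjectiveConfig(
            c=c,
            features=features,
            restarts=base.restarts,
            max_sweeps=base.max_sweeps,
            seed=base.seed,
            verbatim_sign=base.verbatim_sign,
        )
        state = optimize_selection(sets, tensor, dists, cfg)
        accuracy = float(
            np.mean([flags[i][state.selected[i]] for i in range(len(sets))])
        )
        rows.append(
            {"subset": label, "accuracy": accuracy, "objective": state.objective}
        )
    return pd.DataFrame(rows)
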