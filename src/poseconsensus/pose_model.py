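"""Domain types for docked poses, ligands and receptors, plus ensemble I/O.

A *pose* is one candidate placement of a ligand in the receptor frame, as
produced by a docking engine and re-scored by a pose-correctness model
(``pose_score`` in [0, 1]; higher means more likely near-native).  Pose
ensembles arrive as multi-record SDF files whose records carry the score as a
tagged numeric property.  All downstream similarity computations assume every
pose of every ligand lives in one shared receptor coordinate frame, so RMSDs
here are computed *without* superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem

__all__ = [
    "Pose",
    "LigandPoseSet",
    "ReceptorAtom",
    "ReceptorResidue",
    "ReceptorStructure",
    "read_pose_ensemble",
    "read_receptor",
    "rank_and_truncate",
    "heavy_atom_rmsd",
    "label_native",
    "NATIVE_RMSD_THRESHOLD",
]

#: Heavy-atom RMSD below which a docked pose counts as native (strict "<").
NATIVE_RMSD_THRESHOLD = 2.0


@dataclass
class Pose:
    """One docked ligand conformation.

    ``mol`` holds an RDKit molecule with a single conformer in the receptor
    frame.  It may be ``None`` for feature-level workflows (synthetic feature
    tensors) where only scores and labels matter.
    """

    ligand_id: str
    pose_index: int
    pose_score: float
    mol: Optional[Chem.Mol] = None
    affinity_score: Optional[float] = None
    rmsd_to_truth: Optional[float] = None
    native: Optional[bool] = None
    original_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pose_score <= 1.0:
            raise ValueError(
                f"pose_score must lie in [0, 1], got {self.pose_score} "
                f"for {self.ligand_id} pose {self.pose_index}"
            )
        if self.rmsd_to_truth is not None and self.rmsd_to_truth < 0:
            raise ValueError("rmsd_to_truth must be >= 0")
        if self.original_index is None:
            self.original_index = self.pose_index

    @property
    def hydrogens_present(self) -> bool:
        if self.mol is None:
            return False
        return any(a.GetAtomicNum() == 1 for a in self.mol.GetAtoms())

    @property
    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    @property
    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates (Å), ordered as the heavy atoms appear."""
        conf = self.mol.GetConformer()
        pos = conf.GetPositions()
        return pos[self.heavy_atom_indices]

    @property
    def all_coords(self) -> np.ndarray:
        return self.mol.GetConformer().GetPositions()


@dataclass
class LigandPoseSet:
    """All retained docked poses of one ligand.

    Every pose shares one molecular graph (``molecule``, heavy atoms only);
    poses differ only in conformer coordinates.  ``truth`` optionally holds a
    ground-truth (crystallographic) pose used for native labelling.
    """

    ligand_id: str
    molecule: Optional[Chem.Mol]
    poses: list[Pose]
    truth: Optional[Pose] = None
    target: str = "default"

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.molecule.GetAtoms() if a.GetAtomicNum() > 1)

    def pose_scores(self) -> np.ndarray:
        return np.array([p.pose_score for p in self.poses], dtype=float)

    def native_flags(self, threshold: float = NATIVE_RMSD_THRESHOLD) -> np.ndarray:
        flags = []
        for p in self.poses:
            if p.rmsd_to_truth is None:
                raise ValueError(
                    f"pose {p.pose_index} of {self.ligand_id} has no rmsd_to_truth"
                )
            flags.append(p.rmsd_to_truth < threshold)
        return np.array(flags, dtype=bool)


# ---------------------------------------------------------------------------
# Receptor
# ---------------------------------------------------------------------------

@dataclass
class ReceptorAtom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å


@dataclass
class ReceptorResidue:
    chain: str
    resnum: int
    resname: str
    atoms: list[ReceptorAtom]
    icode: str = ""

    @property
    def residue_id(self) -> tuple[str, str]:
        return (self.chain, f"{self.resnum}{self.icode}")


@dataclass
class ReceptorStructure:
    residues: list[ReceptorResidue]
    protonated: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for res in self.residues:
            rid = res.residue_id
            if rid in seen:
                raise ValueError(f"duplicate residue id {rid}")
            seen.add(rid)
            for atom in res.atoms:
                if not np.all(np.isfinite(atom.coords)):
                    raise ValueError(f"non-finite coordinates in residue {rid}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


def read_receptor(path: str | Path) -> ReceptorStructure:
    """Read a (protonated) receptor from PDB."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    residues: list[ReceptorResidue] = []
    has_h = False
    model = structure[0]
    for chain in model:
        for res in chain:
            atoms = []
            for atom in res:
                elem = atom.element.name
                if elem == "H":
                    has_h = True
                atoms.append(
                    ReceptorAtom(
                        name=atom.name,
                        element=elem,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
            residues.append(
                ReceptorResidue(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    resname=res.name,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
    return ReceptorStructure(residues=residues, protonated=has_h)


def write_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor to PDB (one chain per stored chain id)."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = "receptor"
    model = gemmi.Model("1")
    chains: dict[str, "gemmi.Chain"] = {}
    for res in receptor.residues:
        chain = chains.get(res.chain)
        if chain is None:
            chain = gemmi.Chain(res.chain)
            chains[res.chain] = chain
        gres = gemmi.Residue()
        gres.name = res.resname
        gres.seqid = gemmi.SeqId(res.resnum, res.icode or " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Pose ensemble I/O
# ---------------------------------------------------------------------------

def read_pose_ensemble(
    path: str | Path,
    score_property: str = "CNNscore",
    affinity_property: str = "minimizedAffinity",
    ligand_id: Optional[str] = None,
    rmsd_property: str = "rmsd_to_truth",
) -> LigandPoseSet:
    """Read a docked pose ensemble from a multi-record SDF file.

    Every record must parse and carry a numeric ``score_property`` tag; the
    affinity and RMSD tags are optional.  Record order is preserved and
    ``pose_index`` is the record ordinal from 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise ValueError(f"no poses in {path}: {exc}") from exc
    poses: list[Pose] = []
    lig_id = ligand_id or path.stem
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record {i} in {path}")
        if not mol.HasProp(score_property):
            raise ValueError(
                f"record {i} of {path} lacks required property '{score_property}'"
            )
        try:
            score = float(mol.GetProp(score_property))
        except ValueError as exc:
            raise ValueError(
                f"record {i} of {path}: property '{score_property}' is not numeric"
            ) from exc
        affinity = None
        if mol.HasProp(affinity_property):
            affinity = float(mol.GetProp(affinity_property))
        rmsd = None
        if mol.HasProp(rmsd_property):
            rmsd = float(mol.GetProp(rmsd_property))
        poses.append(
            Pose(
                ligand_id=lig_id,
                pose_index=i,
                pose_score=score,
                mol=mol,
                affinity_score=affinity,
                rmsd_to_truth=rmsd,
            )
        )
    if not poses:
        raise ValueError(f"no poses in {path}")
    template = Chem.RemoveHs(Chem.Mol(poses[0].mol))
    return LigandPoseSet(ligand_id=lig_id, molecule=template, poses=poses)


def write_pose_ensemble(
    pose_set: LigandPoseSet,
    path: str | Path,
    score_property: str = "CNNscore",
    rmsd_property: str = "rmsd_to_truth",
) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for pose in pose_set.poses:
            mol = Chem.Mol(pose.mol)
            mol.SetProp("_Name", f"{pose_set.ligand_id}_pose{pose.pose_index}")
            mol.SetProp(score_property, repr(pose.pose_score))
            if pose.affinity_score is not None:
                mol.SetProp("minimizedAffinity", repr(pose.affinity_score))
            if pose.rmsd_to_truth is not None:
                mol.SetProp(rmsd_property, repr(pose.rmsd_to_truth))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Ranking / RMSD / native labelling
# ---------------------------------------------------------------------------

def rank_and_truncate(pose_set: LigandPoseSet, k: int) -> LigandPoseSet:
    """Sort poses by pose_score (desc) and keep the top ``k``.

    Ties are broken by affinity_score ascending (missing affinities last),
    then by original input order, so reruns are deterministic.  ``pose_index``
    is reassigned 0..k-1; the original record ordinal survives in
    ``original_index``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")

    def key(pose: Pose):
        affinity = pose.affinity_score if pose.affinity_score is not None else math.inf
        return (-pose.pose_score, affinity, pose.original_index)

    ranked = sorted(pose_set.poses, key=key)[:k]
    new_poses = [replace(p, pose_index=i) for i, p in enumerate(ranked)]
    return LigandPoseSet(
        ligand_id=pose_set.ligand_id,
        molecule=pose_set.molecule,
        poses=new_poses,
        truth=pose_set.truth,
        target=pose_set.target,
    )


def heavy_atom_rmsd(
    a: Pose | np.ndarray,
    b: Pose | np.ndarray,
    mapping: Sequence[tuple[int, int]],
) -> float:
    """RMSD over mapped heavy-atom pairs, in the shared frame (no fitting).

    ``mapping`` pairs indices into the heavy-atom coordinate arrays of ``a``
    and ``b`` respectively.
    """
    if len(mapping) == 0:
        raise ValueError("empty atom mapping")
    ca = a.coords if isinstance(a, Pose) else np.asarray(a, dtype=float)
    cb = b.coords if isinstance(b, Pose) else np.asarray(b, dtype=float)
    ia = [m[0] for m in mapping]
    ib = [m[1] for m in mapping]
    diff = ca[ia] - cb[ib]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _graph_matches(template: Chem.Mol, other: Chem.Mol, max_matches: int = 4096):
    """All isomorphisms of ``other``'s heavy-atom graph onto ``template``'s."""
    matches = template.GetSubstructMatches(
        other, uniquify=False, useChirality=False, maxMatches=max_matches
    )
    if not matches or len(matches[0]) != other.GetNumAtoms():
        return ()
    return matches


def label_native(
    pose_set: LigandPoseSet,
    truth: Pose,
    threshold: float = NATIVE_RMSD_THRESHOLD,
    use_automorphisms: bool = True,
) -> LigandPoseSet:
    """Fill ``rmsd_to_truth`` for every pose and flag natives.

    The RMSD to the ground-truth pose is minimised over all graph
    automorphisms of the molecule (symmetry-corrected), or computed with the
    identity mapping when ``use_automorphisms`` is False.  A pose is native
    iff rmsd < threshold (strict).
    """
    template = pose_set.molecule
    truth_heavy = Chem.RemoveHs(Chem.Mol(truth.mol))
    if Chem.MolToSmiles(template) != Chem.MolToSmiles(truth_heavy):
        raise ValueError(
            f"ground-truth molecular graph does not match ligand {pose_set.ligand_id}"
        )
    matches = _graph_matches(template, truth_heavy)
    if not matches:
        raise ValueError(
            f"could not map ground-truth atoms onto ligand {pose_set.ligand_id}"
        )
    if not use_automorphisms:
        matches = matches[:1]
    truth_coords = truth.coords
    new_poses = []
    for pose in pose_set.poses:
        pc = pose.coords
        best = math.inf
        for match in matches:
            mapping = [(match[q], q) for q in range(len(match))]
            rmsd = heavy_atom_rmsd(pc, truth_coords, mapping)
            best = min(best, rmsd)
        new_poses.append(replace(pose, rmsd_to_truth=best, native=best < threshold))
    return LigandPoseSet(
        ligand_id=pose_set.ligand_id,
        molecule=pose_set.molecule,
        poses=new_poses,
        truth=truth,
        target=pose_set.target,
    )
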