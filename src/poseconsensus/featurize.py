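"""Protein–ligand interaction fingerprints.

Each docked pose is profiled for hydrogen bonds, salt bridges and hydrophobic
contacts with the receptor; contact scores are summed per protein residue and
per feature kind, giving the residue-level fingerprint that pose-pair
similarities are computed from.

Scoring uses piecewise-linear distance (and, for hydrogen bonds, angle) ramps:
a contact scores 1 at ideal geometry and decays linearly to 0 at the cutoff.
All cutoffs are exposed in :class:`FeaturizeConfig`.  Ionizable ligand groups
are found by SMARTS substructure matching (formal charges on docked ligands
are unreliable); the pattern set ships as an editable data file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .pose_model import LigandPoseSet, Pose, ReceptorStructure

__all__ = [
    "FeatureKind",
    "FEATURE_KINDS",
    "Contact",
    "ResidueFeatureMap",
    "FeaturizeConfig",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_hydrophobic",
    "build_fingerprint",
    "featurize_pose",
    "add_pose_hydrogens",
    "load_ion_patterns",
]

FeatureKind = Literal["hbond", "saltbridge", "hydrophobic"]
FEATURE_KINDS: tuple[str, ...] = ("hbond", "saltbridge", "hydrophobic")

HALOGENS = {9, 17, 35, 53}


@dataclass(frozen=True)
class Contact:
    """One scored protein–ligand interaction (before residue summation)."""

    feature_kind: str
    residue_id: tuple[str, str]
    ligand_atom_index: int
    score: float
    pose: Optional[tuple[str, int]] = None  # (ligand_id, pose_index)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("contact score must be >= 0")


@dataclass
class ResidueFeatureMap:
    """Per-feature, per-residue summed interaction scores for one pose."""

    maps: dict[str, dict[tuple[str, str], float]]
    ligand_id: Optional[str] = None
    pose_index: Optional[int] = None

    def __getitem__(self, kind: str) -> dict[tuple[str, str], float]:
        return self.maps.get(kind, {})

    @classmethod
    def empty(cls, ligand_id=None, pose_index=None) -> "ResidueFeatureMap":
        return cls(maps={k: {} for k in FEATURE_KINDS},
                   ligand_id=ligand_id, pose_index=pose_index)


@dataclass
class FeaturizeConfig:
    """Geometric cutoffs for contact detection (Å, degrees)."""

    hbond_dist_ideal: float = 2.0
    hbond_dist_max: float = 3.0
    hbond_angle_min: float = 120.0
    saltbridge_dist_ideal: float = 3.0
    saltbridge_dist_max: float = 4.0
    hydrophobic_dist_ideal: float = 3.5
    hydrophobic_dist_max: float = 4.5
    ion_patterns_path: Optional[str] = None


def _ramp(d: float, ideal: float, cutoff: float) -> float:
    return float(np.clip((cutoff - d) / (cutoff - ideal), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Receptor atom typing
# ---------------------------------------------------------------------------

_NEG_RES_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_POS_RES_ATOMS = {
    ("LYS", "NZ"),
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
}
_HIS_RING_N = {"ND1", "NE2"}


class _ReceptorView:
    """Flat typed arrays over a receptor, built once per featurization run."""

    def __init__(self, receptor: ReceptorStructure):
        coords, elements, names, resids, resnames = [], [], [], [], []
        for res in receptor.residues:
            for atom in res.atoms:
                coords.append(atom.coords)
                elements.append(atom.element)
                names.append(atom.name)
                resids.append(res.residue_id)
                resnames.append(res.resname)
        self.coords = np.asarray(coords, dtype=float)
        self.elements = np.array(elements)
        self.names = names
        self.resids = resids
        self.resnames = resnames
        n = len(coords)

        # bonds by distance (small pocket structures; 1.9 Å covers heavy-heavy)
        self._neighbors: list[list[int]] = [[] for _ in range(n)]
        if n > 1:
            from scipy.spatial import cKDTree

            tree = cKDTree(self.coords)
            for i, j in tree.query_pairs(1.95):
                if self.elements[i] == "H" and self.elements[j] == "H":
                    continue
                dmax = 1.3 if ("H" in (self.elements[i], self.elements[j])) else 1.95
                if np.linalg.norm(self.coords[i] - self.coords[j]) <= dmax:
                    self._neighbors[i].append(j)
                    self._neighbors[j].append(i)

        is_h = self.elements == "H"
        self.h_idx = np.where(is_h)[0]
        # donors: N/O with an attached hydrogen -> list of (donor, hydrogen)
        self.donor_pairs: list[tuple[int, int]] = []
        for h in self.h_idx:
            for nb in self._neighbors[h]:
                if self.elements[nb] in ("N", "O"):
                    self.donor_pairs.append((nb, h))
        # acceptors: any O; N without attached hydrogen
        self.acceptors: list[int] = []
        for i in range(n):
            if self.elements[i] == "O":
                self.acceptors.append(i)
            elif self.elements[i] == "N" and not any(
                self.elements[nb] == "H" for nb in self._neighbors[i]
            ):
                self.acceptors.append(i)
        # charged atoms by residue/atom-name convention
        self.cations: list[int] = []
        self.anions: list[int] = []
        for i in range(n):
            key = (self.resnames[i], self.names[i])
            if key in _POS_RES_ATOMS:
                self.cations.append(i)
            elif key in _NEG_RES_ATOMS:
                self.anions.append(i)
            elif self.resnames[i] in ("HIS", "HIP", "HID", "HIE") and self.names[
                i
            ] in _HIS_RING_N:
                # protonated ring nitrogen only
                if any(self.elements[nb] == "H" for nb in self._neighbors[i]):
                    self.cations.append(i)
        # apolar carbons: C not bonded to N or O
        self.apolar: list[int] = [
            i
            for i in range(n)
            if self.elements[i] == "C"
            and not any(self.elements[nb] in ("N", "O") for nb in self._neighbors[i])
        ]


# ---------------------------------------------------------------------------
# Ligand atom typing
# ---------------------------------------------------------------------------

def load_ion_patterns(path: str | Path | None = None):
    """Load (sign, compiled SMARTS) pairs; first pattern atom is the ion site."""
    if path is None:
        source = resources.files("poseconsensus") / "data" / "salt_bridge_patterns.smarts"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sign, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"invalid SMARTS pattern: {smarts}")
        patterns.append((sign, query))
    return patterns


_ION_PATTERN_CACHE: dict[str, list] = {}


def _ion_patterns(config: FeaturizeConfig):
    key = config.ion_patterns_path or "__default__"
    if key not in _ION_PATTERN_CACHE:
        _ION_PATTERN_CACHE[key] = load_ion_patterns(config.ion_patterns_path)
    return _ION_PATTERN_CACHE[key]


def _ligand_ion_atoms(mol: Chem.Mol, config: FeaturizeConfig):
    cations, anions = set(), set()
    for sign, query in _ion_patterns(config):
        for match in mol.GetSubstructMatches(query):
            (cations if sign == "+" else anions).add(match[0])
    return sorted(cations), sorted(anions)


def _ligand_apolar_atoms(mol: Chem.Mol) -> list[int]:
    """Carbons and halogens with no N/O neighbour."""
    out = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z != 6 and z not in HALOGENS:
            continue
        if any(nb.GetAtomicNum() in (7, 8) for nb in atom.GetNeighbors()):
            continue
        out.append(atom.GetIdx())
    return out


def _ligand_donor_pairs(mol: Chem.Mol) -> list[tuple[int, int]]:
    pairs = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    pairs.append((atom.GetIdx(), nb.GetIdx()))
    return pairs


def _ligand_acceptors(mol: Chem.Mol) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 8:
            out.append(atom.GetIdx())
        elif z == 7:
            has_h = any(nb.GetAtomicNum() == 1 for nb in atom.GetNeighbors())
            if not has_h and atom.GetFormalCharge() <= 0 and atom.GetTotalDegree() <= 3:
                out.append(atom.GetIdx())
    return out


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def _require_view(receptor) -> _ReceptorView:
    if isinstance(receptor, _ReceptorView):
        return receptor
    view = getattr(receptor, "_featurize_view", None)
    if view is None:
        view = _ReceptorView(receptor)
        receptor._featurize_view = view
    return view


def detect_hbonds(
    receptor: ReceptorStructure,
    pose: Pose,
    config: FeaturizeConfig | None = None,
) -> list[Contact]:
    """Hydrogen bonds, both protein→ligand and ligand→protein directions.

    score = dist_ramp(H···acceptor) × angle_ramp(∠ donor–H···acceptor).
    """
    config = config or FeaturizeConfig()
    if not pose.hydrogens_present:
        raise ValueError(
            f"pose {pose.pose_index} of {pose.ligand_id} has no hydrogens; "
            "run add_pose_hydrogens first"
        )
    view = _require_view(receptor)
    mol = pose.mol
    lig_coords = pose.all_coords
    provenance = (pose.ligand_id, pose.pose_index)
    contacts: list[Contact] = []

    d_ideal, d_max, a_min = (
        config.hbond_dist_ideal,
        config.hbond_dist_max,
        config.hbond_angle_min,
    )

    def score(donor_xyz, h_xyz, acc_xyz) -> float:
        d = float(np.linalg.norm(h_xyz - acc_xyz))
        if d > d_max:
            return 0.0
        theta = _angle_deg(donor_xyz, h_xyz, acc_xyz)
        if theta < a_min:
            return 0.0
        return _ramp(d, d_ideal, d_max) * float(
            np.clip((theta - a_min) / (180.0 - a_min), 0.0, 1.0)
        )

    # protein donor -> ligand acceptor
    lig_acceptors = _ligand_acceptors(mol)
    for donor, hyd in view.donor_pairs:
        for la in lig_acceptors:
            s = score(view.coords[donor], view.coords[hyd], lig_coords[la])
            if s > 0:
                contacts.append(
                    Contact("hbond", view.resids[donor], la, s, provenance)
                )
    # ligand donor -> protein acceptor
    for donor, hyd in _ligand_donor_pairs(mol):
        for pa in view.acceptors:
            s = score(lig_coords[donor], lig_coords[hyd], view.coords[pa])
            if s > 0:
                contacts.append(
                    Contact("hbond", view.resids[pa], donor, s, provenance)
                )
    return contacts


def detect_salt_bridges(
    receptor: ReceptorStructure,
    pose: Pose,
    config: FeaturizeConfig | None = None,
) -> list[Contact]:
    """Opposite-charge atom pairs within the salt-bridge cutoff."""
    config = config or FeaturizeConfig()
    view = _require_view(receptor)
    mol = pose.mol
    lig_coords = pose.all_coords
    provenance = (pose.ligand_id, pose.pose_index)
    lig_cations, lig_anions = _ligand_ion_atoms(mol, config)
    contacts: list[Contact] = []
    d_ideal, d_max = config.saltbridge_dist_ideal, config.saltbridge_dist_max
    for lig_atoms, prot_atoms in ((lig_cations, view.anions), (lig_anions, view.cations)):
        for la in lig_atoms:
            for pa in prot_atoms:
                d = float(np.linalg.norm(lig_coords[la] - view.coords[pa]))
                if d <= d_max:
                    s = _ramp(d, d_ideal, d_max)
                    if s > 0:
                        contacts.append(
                            Contact("saltbridge", view.resids[pa], la, s, provenance)
                        )
    return contacts


def detect_hydrophobic(
    receptor: ReceptorStructure,
    pose: Pose,
    config: FeaturizeConfig | None = None,
) -> list[Contact]:
    """Apolar ligand atom / apolar protein carbon pairs within the cutoff."""
    config = config or FeaturizeConfig()
    view = _require_view(receptor)
    lig_coords = pose.all_coords
    provenance = (pose.ligand_id, pose.pose_index)
    lig_apolar = _ligand_apolar_atoms(pose.mol)
    contacts: list[Contact] = []
    d_ideal, d_max = config.hydrophobic_dist_ideal, config.hydrophobic_dist_max
    if not lig_apolar or not view.apolar:
        return contacts
    pc = view.coords[view.apolar]
    for la in lig_apolar:
        dists = np.linalg.norm(pc - lig_coords[la], axis=1)
        for k in np.where(dists <= d_max)[0]:
            s = _ramp(float(dists[k]), d_ideal, d_max)
            if s > 0:
                contacts.append(
                    Contact(
                        "hydrophobic", view.resids[view.apolar[k]], la, s, provenance
                    )
                )
    return contacts


def build_fingerprint(
    contacts: Sequence[Contact],
    ligand_id: Optional[str] = None,
    pose_index: Optional[int] = None,
) -> ResidueFeatureMap:
    """Sum contact scores by protein residue, per feature kind."""
    provenances = {c.pose for c in contacts if c.pose is not None}
    if len(provenances) > 1:
        raise ValueError(f"contacts from multiple poses: {sorted(provenances)}")
    if provenances:
        ligand_id, pose_index = next(iter(provenances))
    maps: dict[str, dict[tuple[str, str], float]] = {k: {} for k in FEATURE_KINDS}
    for c in contacts:
        if c.score <= 0:
            continue
        kind_map = maps.setdefault(c.feature_kind, {})
        kind_map[c.residue_id] = kind_map.get(c.residue_id, 0.0) + c.score
    return ResidueFeatureMap(maps=maps, ligand_id=ligand_id, pose_index=pose_index)


def featurize_pose(
    receptor: ReceptorStructure,
    pose: Pose,
    config: FeaturizeConfig | None = None,
) -> ResidueFeatureMap:
    """Full residue-level interaction fingerprint for one pose."""
    config = config or FeaturizeConfig()
    contacts = (
        detect_hbonds(receptor, pose, config)
        + detect_salt_bridges(receptor, pose, config)
        + detect_hydrophobic(receptor, pose, config)
    )
    return build_fingerprint(contacts, pose.ligand_id, pose.pose_index)


# ---------------------------------------------------------------------------
# Hydrogen placement
# ---------------------------------------------------------------------------

def add_pose_hydrogens(pose_set: LigandPoseSet) -> LigandPoseSet:
    """Add explicit hydrogens to every pose and relax only their positions.

    Docking engines commonly drop hydrogens; they are rebuilt here with
    standard valence geometry and relaxed with UFF while every heavy atom is
    held fixed, so heavy-atom coordinates are bit-identical before and after.
    Poses that already carry hydrogens are returned unchanged.
    """
    new_poses = []
    for pose in pose_set.poses:
        if pose.hydrogens_present:
            new_poses.append(pose)
            continue
        try:
            molh = Chem.AddHs(Chem.Mol(pose.mol), addCoords=True)
            Chem.SanitizeMol(molh)
        except Exception as exc:
            raise ValueError(
                f"cannot protonate pose {pose.pose_index} of {pose_set.ligand_id}: {exc}"
            ) from exc
        before = np.array(pose.coords)
        ff = AllChem.UFFGetMoleculeForceField(molh)
        if ff is not None:
            for atom in molh.GetAtoms():
                if atom.GetAtomicNum() > 1:
                    ff.AddFixedPoint(atom.GetIdx())
            ff.Minimize(maxIts=500)
        new_pose = replace(pose, mol=molh)
        after = new_pose.coords
        if not np.array_equal(before, after):  # contract: heavy atoms pinned
            raise AssertionError(
                f"heavy atoms moved while protonating pose {pose.pose_index} "
                f"of {pose_set.ligand_id}"
            )
        new_poses.append(new_pose)
    return LigandPoseSet(
        ligand_id=pose_set.ligand_id,
        molecule=pose_set.molecule,
        poses=new_poses,
        truth=pose_set.truth,
        target=pose_set.target,
    )
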