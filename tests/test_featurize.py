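"""Interaction-fingerprint scoring: geometry ramps and residue summation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from poseconsensus.featurize import (
    Contact,
    FeaturizeConfig,
    add_pose_hydrogens,
    build_fingerprint,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
    featurize_pose,
)
from poseconsensus.pose_model import (
    LigandPoseSet,
    Pose,
    ReceptorAtom,
    ReceptorResidue,
    ReceptorStructure,
)

from conftest import embedded


def _receptor(atoms_per_res):
    """atoms_per_res: list of (resname, [(name, element, xyz), ...])."""
    residues = [
        ReceptorResidue(
            chain="A",
            resnum=i + 1,
            resname=name,
            atoms=[ReceptorAtom(n, e, np.array(c, float)) for n, e, c in atoms],
        )
        for i, (name, atoms) in enumerate(atoms_per_res)
    ]
    return ReceptorStructure(residues=residues, protonated=True)


def _mol_pose(smiles, coords, ligand_id="lig"):
    """Build a pose with hydrogens and explicit coordinates per atom index."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    conf = mol.GetConformer()
    for idx, xyz in coords.items():
        conf.SetAtomPosition(idx, [float(v) for v in xyz])
    return Pose(ligand_id=ligand_id, pose_index=0, pose_score=0.5, mol=mol)


def _water_like_pose(o_xyz, h_xyz):
    """Methanol oxygen/hydroxyl-H placed exactly; rest of the atoms far away."""
    mol = Chem.AddHs(Chem.MolFromSmiles("CO"))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    conf = mol.GetConformer()
    o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
    h_idx = next(
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(o_idx).GetNeighbors()
        if nb.GetAtomicNum() == 1
    )
    # park every other atom 50 Å away to isolate the O-H pair
    for atom in mol.GetAtoms():
        if atom.GetIdx() not in (o_idx, h_idx):
            conf.SetAtomPosition(atom.GetIdx(), [50.0, 50.0, 50.0])
    conf.SetAtomPosition(o_idx, [float(v) for v in o_xyz])
    conf.SetAtomPosition(h_idx, [float(v) for v in h_xyz])
    return Pose(ligand_id="w", pose_index=0, pose_score=0.5, mol=mol), o_idx, h_idx


class TestHbond:
    def _score_at(self, d, theta_deg):
        """Ligand O-H donor pointing at a receptor backbone-style O acceptor."""
        # donor O at origin, H along +x at 1.0 Å; acceptor placed to realize
        # the requested H...A distance and D-H...A angle
        theta = math.radians(theta_deg)
        h = np.array([1.0, 0.0, 0.0])
        acc = h + d * np.array([-math.cos(theta), math.sin(theta), 0.0])
        pose, _, _ = _water_like_pose((0, 0, 0), h)
        receptor = _receptor([("GLY", [("O", "O", tuple(acc))])])
        contacts = detect_hbonds(receptor, pose)
        return sum(c.score for c in contacts)

    def test_ideal_geometry_scores_one(self):
        assert self._score_at(2.0, 180.0) == pytest.approx(1.0)

    def test_beyond_distance_cutoff(self):
        assert self._score_at(3.2, 180.0) == 0.0

    def test_intermediate_ramp_product(self):
        assert self._score_at(2.5, 150.0) == pytest.approx(0.25)

    def test_angle_below_minimum(self):
        assert self._score_at(2.0, 100.0) == 0.0

    def test_requires_hydrogens(self):
        mol = Chem.MolFromSmiles("CO")
        AllChem.Compute2DCoords(mol)
        pose = Pose(ligand_id="x", pose_index=0, pose_score=0.5, mol=mol)
        receptor = _receptor([("GLY", [("O", "O", (0, 0, 0))])])
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(receptor, pose)


class TestSaltBridge:
    def _carboxylate_pose(self, o_xyz):
        mol = Chem.AddHs(Chem.MolFromSmiles("CC(=O)O"))
        AllChem.EmbedMolecule(mol, randomSeed=1)
        conf = mol.GetConformer()
        for atom in mol.GetAtoms():
            conf.SetAtomPosition(atom.GetIdx(), [50.0, 50.0, 50.0])
        o_ids = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O"]
        conf.SetAtomPosition(o_ids[0], [float(v) for v in o_xyz])
        return Pose(ligand_id="a", pose_index=0, pose_score=0.5, mol=mol)

    def _lys(self, xyz=(0.0, 0, 0)):
        return _receptor([("LYS", [("NZ", "N", xyz)])])

    def test_ideal_distance_scores_one(self):
        pose = self._carboxylate_pose((3.0, 0, 0))
        contacts = detect_salt_bridges(self._lys(), pose)
        assert len(contacts) == 1
        assert contacts[0].score == pytest.approx(1.0)

    def test_beyond_cutoff(self):
        pose = self._carboxylate_pose((4.5, 0, 0))
        assert detect_salt_bridges(self._lys(), pose) == []

    def test_linear_ramp_midpoint(self):
        pose = self._carboxylate_pose((3.5, 0, 0))
        contacts = detect_salt_bridges(self._lys(), pose)
        assert contacts[0].score == pytest.approx(0.5)

    def test_neutral_ligand_no_matches(self):
        pose = _mol_pose("c1ccccc1", {})
        assert detect_salt_bridges(self._lys(), pose) == []


class TestHydrophobic:
    def _methane_pose(self, c_xyz):
        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        AllChem.EmbedMolecule(mol, randomSeed=1)
        conf = mol.GetConformer()
        shift = np.asarray(c_xyz, float) - conf.GetPositions()[0]
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, (conf.GetPositions()[i] + 0).tolist())
        pos = mol.GetConformer().GetPositions() + shift
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, pos[i].tolist())
        return Pose(ligand_id="m", pose_index=0, pose_score=0.5, mol=mol)

    def _leu(self):
        return _receptor([("LEU", [("CD1", "C", (0.0, 0, 0))])])

    @pytest.mark.parametrize(
        "d,expected", [(3.0, 1.0), (4.0, 0.5), (4.5, None)]
    )
    def test_distance_ramp(self, d, expected):
        contacts = detect_hydrophobic(self._leu(), self._methane_pose((d, 0, 0)))
        if expected is None:
            assert contacts == []
        else:
            assert contacts[0].score == pytest.approx(expected)

    def test_polar_bonded_carbon_excluded(self):
        # methanol carbon is bonded to O -> not apolar
        pose, o_idx, _ = _water_like_pose((50, 50, 50), (50, 51, 50))
        c_idx = next(a.GetIdx() for a in pose.mol.GetAtoms() if a.GetSymbol() == "C")
        pose.mol.GetConformer().SetAtomPosition(c_idx, [3.5, 0.0, 0.0])
        assert detect_hydrophobic(self._leu(), pose) == []


class TestBuildFingerprint:
    def test_sums_by_residue(self):
        contacts = [
            Contact("hbond", ("A", "45"), 0, 0.4),
            Contact("hbond", ("A", "45"), 1, 0.25),
        ]
        fp = build_fingerprint(contacts)
        assert fp["hbond"][("A", "45")] == pytest.approx(0.65)

    def test_kinds_kept_separate(self):
        contacts = [
            Contact("hbond", ("A", "1"), 0, 0.4),
            Contact("hydrophobic", ("A", "2"), 0, 0.3),
        ]
        fp = build_fingerprint(contacts)
        assert set(fp["hbond"]) == {("A", "1")}
        assert set(fp["hydrophobic"]) == {("A", "2")}

    def test_empty_contacts_empty_map(self):
        fp = build_fingerprint([])
        assert all(fp[k] == {} for k in ("hbond", "saltbridge", "hydrophobic"))

    def test_mixed_provenance_errors(self):
        contacts = [
            Contact("hbond", ("A", "1"), 0, 0.4, pose=("a", 0)),
            Contact("hbond", ("A", "1"), 0, 0.4, pose=("a", 1)),
        ]
        with pytest.raises(ValueError, match="multiple poses"):
            build_fingerprint(contacts)


class TestFrameInvariance:
    def test_rigid_translation_preserves_fingerprint(self, toy_system):
        receptor, sets = toy_system
        pose = sets[0].poses[0]
        fp0 = featurize_pose(receptor, pose)
        shift = np.array([13.0, -7.0, 4.0])
        import copy

        moved = copy.deepcopy(receptor)
        del moved._featurize_view
        for res in moved.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + shift
        mol = Chem.Mol(pose.mol)
        conf = mol.GetConformer()
        pos = conf.GetPositions() + shift
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, pos[i].tolist())
        moved_pose = Pose(ligand_id=pose.ligand_id, pose_index=pose.pose_index,
                          pose_score=pose.pose_score, mol=mol)
        fp1 = featurize_pose(moved, moved_pose)
        for kind in ("hbond", "saltbridge", "hydrophobic"):
            assert set(fp0[kind]) == set(fp1[kind])
            for key in fp0[kind]:
                assert fp0[kind][key] == pytest.approx(fp1[kind][key], abs=1e-9)

    def test_scores_in_unit_interval(self, toy_system):
        receptor, sets = toy_system
        for s in sets:
            for pose in s.poses[:3]:
                fp = featurize_pose(receptor, pose)
                for kind in ("hbond", "saltbridge", "hydrophobic"):
                    for v in fp[kind].values():
                        assert v > 0 and np.isfinite(v)


class TestAddHydrogens:
    def _heavy_set(self, smiles="C"):
        mol = embedded(smiles, 13)
        heavy = Chem.RemoveHs(Chem.Mol(mol))
        pose = Pose(ligand_id="h", pose_index=0, pose_score=0.5, mol=heavy)
        return LigandPoseSet(ligand_id="h", molecule=Chem.Mol(heavy), poses=[pose])

    def test_methane_gains_four_hydrogens_at_bond_length(self):
        out = add_pose_hydrogens(self._heavy_set("C"))
        mol = out.poses[0].mol
        hs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1]
        assert len(hs) == 4
        pos = mol.GetConformer().GetPositions()
        for h in hs:
            assert np.linalg.norm(pos[h] - pos[0]) == pytest.approx(1.09, abs=0.05)

    def test_heavy_atoms_bit_identical(self):
        pose_set = self._heavy_set("OC(=O)c1ccccc1")
        before = pose_set.poses[0].coords.copy()
        out = add_pose_hydrogens(pose_set)
        assert np.array_equal(before, out.poses[0].coords)

    def test_already_protonated_unchanged(self):
        mol = embedded("CCO", 4)
        pose = Pose(ligand_id="p", pose_index=0, pose_score=0.5, mol=mol)
        pose_set = LigandPoseSet(ligand_id="p", molecule=Chem.RemoveHs(Chem.Mol(mol)),
                                 poses=[pose])
        out = add_pose_hydrogens(pose_set)
        assert out.poses[0].mol is mol
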