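from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem


def embedded(smiles: str, seed: int = 7) -> Chem.Mol:
    """A 3D-embedded molecule with explicit hydrogens."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    return mol


@pytest.fixture(scope="session")
def toy_system():
    """Small labelled 3D synthetic system shared across tests."""
    from poseconsensus.synthetic import SyntheticConfig, generate_system

    cfg = SyntheticConfig(
        n_ligands=4, poses_per_ligand=6, n_native_per_ligand=2,
        consensus_strength=1.0, score_informativeness=0.5, seed=11,
    )
    receptor, sets = generate_system(cfg)
    return receptor, sets


@pytest.fixture(scope="session")
def toy_tensor(toy_system):
    from poseconsensus.pipeline import PipelineConfig, prepare_tensor

    receptor, sets = toy_system
    cfg = PipelineConfig(receptor="unused", pose_files=[])
    return prepare_tensor(receptor, sets, cfg, include_intra=True)


@pytest.fixture(scope="session")
def toy_dists(toy_tensor):
    from poseconsensus.stats import fit_similarity_statistics

    return fit_similarity_statistics(toy_tensor)


def write_sdf(path, records):
    """Write simple SDF records: (smiles, properties dict, seed)."""
    writer = Chem.SDWriter(str(path))
    try:
        for smiles, props, seed in records:
            mol = embedded(smiles, seed)
            for key, val in props.items():
                mol.SetProp(key, str(val))
            writer.write(mol)
    finally:
        writer.close()
    return path
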