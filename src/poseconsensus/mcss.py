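"""Strict maximum-common-substructure (MCSS) computation and MCSS RMSD.

Two ligands of a congeneric series typically share a scaffold; whether two
docked poses place that scaffold in the same part of the pocket is measured
by the RMSD between their MCSS atoms (no superposition — poses share the
receptor frame).  The matching is deliberately strict: elements must be equal
(except halogens, which are mutually interchangeable), bond orders must be
identical (aromatic only matches aromatic), ring bonds only match ring bonds
and any matched ring must be complete in both molecules.  An MCSS covering
less than half of the smaller ligand's heavy atoms is considered
uninformative and flagged invalid, and callers drop the MCSS feature for
that ligand pair.

A "relaxed" mode (any element, any bond order, no ring constraints) is
available for ablation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .pose_model import Pose, heavy_atom_rmsd

__all__ = [
    "MCSSResult",
    "strict_mcss",
    "mcss_rmsd",
    "mcss_rmsd_matrix",
    "shared_scaffold_fraction",
]

_HALOGENS = {9, 17, 35, 53}


@dataclass
class MCSSResult:
    """Outcome of an MCSS search between two molecules.

    ``mappings`` holds every distinct atom-index correspondence realizing a
    maximum-size common substructure: tuples of (index in A, index in B)
    pairs over heavy atoms.  ``valid`` applies the half-heavy-atom rule.
    """

    atom_count: int
    bond_count: int
    mappings: tuple[tuple[tuple[int, int], ...], ...]
    valid: bool
    smarts: str = ""
    timed_out: bool = False

    def __post_init__(self) -> None:
        for m in self.mappings:
            if len(m) != self.atom_count:
                raise ValueError("mapping length does not equal atom_count")


class _HalogenAwareAtomCompare(rdFMCS.MCSAtomCompare):
    """Element equality with F/Cl/Br/I treated as one equivalence class."""

    def __call__(self, parameters, mol1, atom1, mol2, atom2) -> bool:  # noqa: D102
        z1 = mol1.GetAtomWithIdx(atom1).GetAtomicNum()
        z2 = mol2.GetAtomWithIdx(atom2).GetAtomicNum()
        if not (z1 == z2 or (z1 in _HALOGENS and z2 in _HALOGENS)):
            return False
        if parameters.RingMatchesRingOnly and not self.CheckAtomRingMatch(
            parameters, mol1, atom1, mol2, atom2
        ):
            return False
        return True


def _heavy(mol: Chem.Mol) -> Chem.Mol:
    return Chem.RemoveHs(Chem.Mol(mol))


def _enumerate_mappings(
    a: Chem.Mol, b: Chem.Mol, query: Chem.Mol, max_mappings: int = 720
) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Compose substructure matches of the MCS query in both molecules.

    Distinct (match-in-A, match-in-B) pairs can induce the same atom
    correspondence; duplicates are removed.  Enumeration is capped to bound
    the cost on highly symmetric molecules.
    """
    matches_a = a.GetSubstructMatches(query, uniquify=False, maxMatches=256)
    matches_b = b.GetSubstructMatches(query, uniquify=False, maxMatches=256)
    seen = set()
    out = []
    for ma in matches_a:
        for mb in matches_b:
            corr = tuple(sorted(zip(ma, mb)))
            if corr not in seen:
                seen.add(corr)
                out.append(corr)
                if len(out) >= max_mappings:
                    return tuple(out)
    return tuple(out)


def strict_mcss(
    a: Chem.Mol,
    b: Chem.Mol,
    timeout: int = 60,
    relaxed: bool = False,
) -> MCSSResult:
    """Maximum common substructure of two heavy-atom molecular graphs.

    A common substructure with no bonds (isolated matched atoms) counts as
    empty.  On timeout the result is flagged invalid rather than returning a
    partial answer.
    """
    a = _heavy(a)
    b = _heavy(b)
    n_a = a.GetNumAtoms()
    n_b = b.GetNumAtoms()
    if n_a == 0 or n_b == 0:
        raise ValueError("empty molecule in MCSS computation")

    params = rdFMCS.MCSParameters()
    params.Timeout = timeout
    params.StoreAll = True  # enumerate every degenerate maximal substructure
    if relaxed:
        params.AtomTyper = rdFMCS.AtomCompare.CompareAny
        params.BondTyper = rdFMCS.BondCompare.CompareAny
    else:
        params.AtomTyper = _HalogenAwareAtomCompare()
        params.BondTyper = rdFMCS.BondCompare.CompareOrderExact
        params.AtomCompareParameters.RingMatchesRingOnly = True
        params.BondCompareParameters.RingMatchesRingOnly = True
        params.BondCompareParameters.CompleteRingsOnly = True
    result = rdFMCS.FindMCS([a, b], params)

    min_heavy = min(n_a, n_b)
    if result.canceled:
        return MCSSResult(0, 0, (), valid=False, timed_out=True)
    queries = dict(result.degenerateSmartsQueryMolDict)
    if result.numBonds == 0 or not queries:
        return MCSSResult(0, 0, (), valid=False)

    seen = set()
    mappings: list[tuple[tuple[int, int], ...]] = []
    for qmol in queries.values():
        for corr in _enumerate_mappings(a, b, qmol):
            if corr not in seen:
                seen.add(corr)
                mappings.append(corr)
    atom_count = result.numAtoms
    valid = 2 * atom_count >= min_heavy and len(mappings) > 0
    return MCSSResult(
        atom_count=atom_count,
        bond_count=result.numBonds,
        mappings=tuple(mappings),
        valid=valid,
        smarts="|".join(sorted(queries)),
    )


def mcss_rmsd(a: Pose, b: Pose, m: MCSSResult) -> float:
    """Minimum RMSD over all MCSS atom mappings, in the shared frame."""
    if not m.valid:
        raise ValueError("MCSS is invalid for this ligand pair; skip the feature")
    best = math.inf
    for mapping in m.mappings:
        best = min(best, heavy_atom_rmsd(a, b, mapping))
    return best


def mcss_rmsd_matrix(
    coords_a: np.ndarray, coords_b: np.ndarray, m: MCSSResult
) -> np.ndarray:
    """RMSD matrix over two pose stacks.

    ``coords_a``: (Pa, n_atoms_a, 3); ``coords_b``: (Pb, n_atoms_b, 3).
    Returns (Pa, Pb) of per-pair minimum-over-mappings RMSD.
    """
    if not m.valid:
        raise ValueError("MCSS is invalid for this ligand pair; skip the feature")
    pa = coords_a.shape[0]
    pb = coords_b.shape[0]
    best = np.full((pa, pb), np.inf)
    for mapping in m.mappings:
        ia = [p[0] for p in mapping]
        ib = [p[1] for p in mapping]
        diff = coords_a[:, ia, :][:, None, :, :] - coords_b[:, ib, :][None, :, :, :]
        rmsd = np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))
        np.minimum(best, rmsd, out=best)
    return best


def shared_scaffold_fraction(query: Chem.Mol, cognate: Chem.Mol, **kwargs) -> float:
    """Fraction of the query ligand's heavy atoms inside the MCSS with the
    cognate ligand.

    Benchmark curation drops a docking ligand when this fraction exceeds 0.5
    (the pocket is then presumably pre-shaped for it).
    """
    q = _heavy(query)
    if q.GetNumAtoms() == 0:
        raise ValueError("empty query molecule")
    result = strict_mcss(query, cognate, **kwargs)
    return result.atom_count / q.GetNumAtoms()


def curation_excluded(query: Chem.Mol, cognate: Chem.Mol, threshold: float = 0.5) -> bool:
    """True when the query shares more than ``threshold`` of its atoms with
    the cognate ligand and should be excluded from a benchmark."""
    return shared_scaffold_fraction(query, cognate) > threshold
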