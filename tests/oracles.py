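"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the MCSS oracle is an
exhaustive connected-common-edge-subgraph search over networkx, the
selection oracle enumerates every possible pose selection, and the
density/score-weight oracles use closed forms.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism
from rdkit import Chem

HALOGENS = {9, 17, 35, 53}


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    mol = Chem.RemoveHs(Chem.Mol(mol))
    g = nx.Graph()
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        label = "X" if z in HALOGENS else atom.GetSymbol()
        g.add_node(atom.GetIdx(), label=label, ring=atom.IsInRing())
    for bond in mol.GetBonds():
        if bond.GetIsAromatic():
            order = "ar"
        else:
            order = bond.GetBondTypeAsDouble()
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=order,
            ring=bond.IsInRing(),
        )
    return g


def _sssr_bond_sets(mol: Chem.Mol):
    mol = Chem.RemoveHs(Chem.Mol(mol))
    out = []
    for ring_bonds in mol.GetRingInfo().BondRings():
        bonds = frozenset(
            frozenset(
                (mol.GetBondWithIdx(b).GetBeginAtomIdx(),
                 mol.GetBondWithIdx(b).GetEndAtomIdx())
            )
            for b in ring_bonds
        )
        out.append(bonds)
    return out


def _ring_complete(edge_set: set[frozenset], rings) -> bool:
    """Every ring is either fully inside or fully outside the edge set."""
    for ring in rings:
        inter = len(ring & edge_set)
        if 0 < inter < len(ring):
            return False
    return True


def _connected_edge_subsets(g: nx.Graph, rings):
    """All connected, ring-complete edge subsets of g, by decreasing size."""
    edges = [frozenset(e) for e in g.edges()]
    subsets = []
    for r in range(len(edges), 0, -1):
        for combo in itertools.combinations(edges, r):
            edge_set = set(combo)
            sub = nx.Graph(tuple(e) for e in edge_set)
            if not nx.is_connected(sub):
                continue
            if not _ring_complete(edge_set, rings):
                continue
            subsets.append(edge_set)
    return subsets


def brute_force_mcss(mol_a: Chem.Mol, mol_b: Chem.Mol):
    """Exhaustive strict MCSS: returns (atom_count, bond_count, mappings).

    Maximizes bond count (atoms as tie-break), enforcing element equality
    with halogen interchange, exact bond order (aromatic only with
    aromatic), ring bonds matching only ring bonds, and ring completeness of
    the matched subgraph in both molecules.  Mappings are tuples of
    (atom in A, atom in B) pairs.
    """
    ga, gb = mol_to_graph(mol_a), mol_to_graph(mol_b)
    rings_a = _sssr_bond_sets(mol_a)
    rings_b = _sssr_bond_sets(mol_b)

    node_match = isomorphism.categorical_node_match(["label", "ring"], [None, None])
    edge_match = isomorphism.categorical_edge_match(["order", "ring"], [None, None])

    best_bonds = 0
    best_atoms = 0
    best_mappings: set[tuple[tuple[int, int], ...]] = set()
    for edge_set in _connected_edge_subsets(ga, rings_a):
        n_bonds = len(edge_set)
        sub = ga.edge_subgraph([tuple(e) for e in edge_set])
        n_atoms = sub.number_of_nodes()
        if (n_bonds, n_atoms) < (best_bonds, best_atoms):
            continue
        matcher = isomorphism.GraphMatcher(
            gb, sub, node_match=node_match, edge_match=edge_match
        )
        for iso in matcher.subgraph_monomorphisms_iter():
            # iso maps gb nodes -> sub nodes; invert to A -> B
            mapping = tuple(sorted((a, b) for b, a in iso.items()))
            image_edges = {
                frozenset((b1, b2))
                for b1, b2 in itertools.combinations(iso.keys(), 2)
                if gb.has_edge(b1, b2)
                and sub.has_edge(iso[b1], iso[b2])
            }
            if not _ring_complete(image_edges, rings_b):
                continue
            if (n_bonds, n_atoms) > (best_bonds, best_atoms):
                best_bonds, best_atoms = n_bonds, n_atoms
                best_mappings = set()
            best_mappings.add(mapping)
    return best_atoms, best_bonds, best_mappings


def brute_force_min_rmsd(coords_a, coords_b, mappings) -> float:
    """Minimum RMSD across mappings, straight from the definition."""
    best = math.inf
    for mapping in mappings:
        sq = 0.0
        for ia, ib in mapping:
            d = coords_a[ia] - coords_b[ib]
            sq += float(np.dot(d, d))
        best = min(best, math.sqrt(sq / len(mapping)))
    return best


def exhaustive_best_selection(score_lists, llr_matrices, c):
    """Enumerate every selection; return (best objective, best selection).

    Implements the objective from its definition: per-ligand score reward
    plus, for each unordered ligand pair, twice the pair's log ratio divided
    by (n - 1).
    """
    n = len(score_lists)
    best_obj, best_sel = -math.inf, None
    for sel in itertools.product(*[range(len(s)) for s in score_lists]):
        obj = c * sum(score_lists[i][sel[i]] for i in range(n))
        if n > 1:
            for i in range(n):
                for j in range(i + 1, n):
                    obj += 2.0 * llr_matrices[(i, j)][sel[i], sel[j]] / (n - 1)
        if obj > best_obj:
            best_obj, best_sel = obj, sel
    return best_obj, best_sel


def logistic_bin_slope(scores, prob_native, bin_size=100):
    """Score-weight oracle from exact per-bin native probabilities."""
    order = np.argsort(-scores, kind="stable")
    n_bins = len(scores) // bin_size
    xs, ys = [], []
    for b in range(n_bins):
        idx = order[b * bin_size : (b + 1) * bin_size]
        xs.append(scores[idx].mean())
        ys.append(-math.log(prob_native[idx].mean()))
    slope, _ = np.polyfit(xs, ys, 1)
    return abs(float(slope))
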