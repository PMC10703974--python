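"""Pairwise pose similarity: pseudo-Tanimoto fingerprints and MCSS RMSD.

Compares a native-native pose pair against a native-decoy pair from two
different ligands of a congeneric series.  Native pairs share the consensus
interaction pattern, so their fingerprint similarity is high and their
shared scaffold sits in the same place (small MCSS RMSD).
"""

import numpy as np

from poseconsensus import featurize_pose, mcss_rmsd, pseudo_tanimoto, strict_mcss
from poseconsensus.synthetic import SyntheticConfig, generate_system

receptor, sets = generate_system(
    SyntheticConfig(n_ligands=2, poses_per_ligand=8, n_native_per_ligand=2,
                    consensus_strength=1.0, seed=3)
)
a, b = sets
nat_a = a.poses[int(np.argmin([p.rmsd_to_truth for p in a.poses]))]
nat_b = b.poses[int(np.argmin([p.rmsd_to_truth for p in b.poses]))]
dec_b = b.poses[int(np.argmax([p.rmsd_to_truth for p in b.poses]))]

mcss = strict_mcss(a.molecule, b.molecule)
print(f"MCSS between the two ligands: {mcss.atom_count} atoms "
      f"({len(mcss.mappings)} mapping(s), valid={mcss.valid})")

for label, pose_b in (("native-native", nat_b), ("native-decoy", dec_b)):
    fa = featurize_pose(receptor, nat_a)
    fb = featurize_pose(receptor, pose_b)
    sim = pseudo_tanimoto(fa["hydrophobic"], fb["hydrophobic"])
    rmsd = mcss_rmsd(nat_a, pose_b, mcss)
    print(f"{label:14s} hydrophobic similarity {sim:.3f}   MCSS RMSD {rmsd:6.2f} Å")
print("The native pair scores clearly higher and places the shared scaffold")
print("within ~1 Å; the decoy pair shares no residues and sits many Å away.")
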