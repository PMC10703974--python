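# Methods

## Model

The package treats pose selection for n ligands docked to one receptor as a
combinatorial optimization over one pose index ℓ_i per ligand. The
objective is

Σ_i [ C·score(ℓ_i) + (1/(n−1)) Σ_{s∈S} Σ_{j≠i} log f(s(ℓ_i,ℓ_j)|Native) / f(s(ℓ_i,ℓ_j)|Reference) ]

with S the enabled pairwise features (hydrogen-bond, salt-bridge and
hydrophobic fingerprint similarities; MCSS RMSD). The model assumes (a)
pose scores are calibrated so that higher means more likely native, (b) all
poses of all ligands live in one receptor frame, so inter-pose RMSDs need no
superposition, and (c) native poses of distinct ligands express more similar
interaction patterns than arbitrary pose pairs — the consensus hypothesis
the likelihood ratio encodes. The score term is implemented as a reward
(+C·score) under maximization; `ObjectiveConfig(verbatim_sign=True)` flips
it for anyone wanting the literal penalty form, which empirically destroys
selection quality. With a single ligand the pairwise term is defined as 0,
so the method degrades to score-only docking.

## Featurization choices

Contact scores use piecewise-linear ramps, a standard interaction-
fingerprint convention; the underlying functional forms are only loosely
constrained by precedent, so all cutoffs sit in `FeaturizeConfig`:

| feature | ideal | cutoff | extra condition |
|---|---|---|---|
| hydrogen bond (H···acceptor) | 2.0 Å | 3.0 Å | donor–H···acceptor angle ≥ 120°, linearly ramped to 180° |
| salt bridge (ion pair) | 3.0 Å | 4.0 Å | opposite formal sign |
| hydrophobic (apolar C/halogen pairs) | 3.5 Å | 4.5 Å | carbon not bonded to N/O |

The hydrogen-bond score is the product of the distance and angle ramps.
Ligand ionizable groups come from a SMARTS pattern file
(`data/salt_bridge_patterns.smarts`, editable): protonatable aliphatic
amines, explicit charges, amidinium/guanidinium; carboxylate, phosphate,
sulfonate and tetrazole sites. Protein charge sites use residue/atom-name
conventions (Asp/Glu carboxylate O, Lys NZ, Arg guanidinium N, protonated
His ring N). Docked poses usually arrive without hydrogens; they are
rebuilt with standard valence geometry and relaxed with UFF while every
heavy atom is held fixed, which keeps heavy-atom coordinates bit-identical.

## MCSS

The strict matcher requires element equality (F/Cl/Br/I form one
equivalence class), identical bond orders (aromatic only with aromatic),
ring bonds matching only ring bonds, and per-SSSR-ring completeness. All
degenerate maximal substructures are kept and the MCSS RMSD minimizes over
every atom mapping of every one of them, which favours the consensus
reading when a scaffold is symmetric. A common substructure with no bonds
counts as empty. The half-heavy-atom validity rule (2·|MCSS| ≥ smaller
ligand's heavy count) gates the feature per ligand pair; an invalid or
timed-out (default 60 s) search drops the feature rather than returning a
partial answer. Mapping enumeration is capped (256 embeddings per molecule,
720 composed mappings) to bound cost on highly symmetric molecules. A
relaxed mode (any element, any bond, no ring constraints) exists for
ablations.

## Densities and numerical choices

Similarity densities are Gaussian KDEs with data reflected across both
support endpoints, zero outside the support, and normalized by the exact
Gaussian-CDF mass, so the integral over the support is 1 to machine
precision. Bandwidths are 0.03 for the (0, 1) similarities and 0.18 Å for
MCSS RMSD on [0, 6] Å; MCSS values above 6 Å are set to 6 Å before fitting,
which produces the expected boundary spike in the reference density. Exact
evaluation is O(n) per query; for high-volume queries a 4096-point grid is
cached (built by histogram + kernel convolution when the sample exceeds
2000 points) and linearly interpolated. The log ratio floors both densities
at 1e−9 to stay finite where the reference density underflows. In the score-
weight fit, per-bin native fractions are floored at 1/(2·bin size) so empty
bins keep a finite negative log likelihood; C is the magnitude of the OLS
slope (a flat fit yields C = 0 with a warning). Ranking ties break by
affinity ascending then input order; greedy argmax ties break to the lowest
pose index; the ligand visiting order is redrawn every sweep; all
randomness flows from a single seeded generator.

Native labelling uses the strict "< 2 Å" convention everywhere and
minimizes the RMSD over graph automorphisms (symmetry correction); the
identity-mapping RMSD is available as an option. A native *pair* requires
both poses to be native — the conservative reading of the distribution
definition.

## Synthetic data

The generator has two tiers. The 3D tier builds a ~12-residue toy pocket
(apolar leucine/alanine carbons ringing a consensus site, two serines, an
aspartate and a lysine; three distant apolar decoy sub-pockets) and a
congeneric series of benzene-scaffold ligands. A designated native pose
reproduces the canonical consensus-site placement (small rigid jitter) with
probability `consensus_strength`, otherwise it falls to a decoy sub-pocket;
decoys always go to sub-pockets with random orientation. RMSD labels come
from the actual geometry. The feature-map tier skips geometry and samples
pair similarities directly: pairs whose poses both express the shared
pattern draw from higher-mean Beta laws (hydrophobic 0.83 vs 0.69,
following the shift observed in cross-docked data; hydrogen bond 0.43 vs
0.25; salt bridge 0.55 vs 0.45; MCSS RMSD |N(1.2, 0.6)| vs U(0.5, 9) Å),
with concentration 12. Pose scores are Beta with concentration 10 and means
0.5 ± 0.3·`score_informativeness`. Default conditions are 16 ligands × 50
poses, 5 native poses per ligand, consensus 0.9, informativeness 0.3.

What the synthetic tiers do *not* emulate: receptor flexibility and
side-chain rearrangement, water-mediated contacts, correlated decoy
clusters from a real sampler, realistic pose-score miscalibration, and
chemically diverse (non-congeneric) helper sets. Passing recovery tests
therefore demonstrates the machinery — featurization, statistics,
optimization — under the consensus assumption, not prospective accuracy on
real cross-docking, where the consensus hypothesis itself is only partially
true (the hypothesis-gap experiment quantifies this tension: free
optimization typically attains a higher objective than the best-RMSD
ensemble).

## Problem sizes

Tests and the acceptance script run at desk scale by design: statistics and
selection experiments use the 16 × 50 feature-map tier across 20 seeds; the
3D tier runs at 2–4 ligands × 6–12 poses, which already exercises every
code path (fingerprints, MCSS, hydrogens, tensor assembly, CLI round
trips). The optimizer's exhaustive-enumeration checks use 3 ligands × 4
poses where the 64-selection ground truth is computable. Reproducing
published-scale cross-docking benchmarks would require hundreds of external
crystal structures and a docking engine, both outside this package's scope
(docking is reachable only through the external command hook).

## Known limitations

- Hydrogen placement ignores the receptor, so donor hydrogens need not
  point at acceptors; hydrogen-bond similarities are correspondingly weak
  discriminators.
- SMARTS-based charge detection cannot see receptor-induced protonation
  changes.
- The greedy optimizer is stochastic; 500 restarts make small instances
  effectively exact but give no global guarantee at scale.
- π–π stacking, cation–π and water-mediated contacts are not featurized.
- Protein preparation (alignment, repair, minimization) and conformer
  generation quality are the caller's responsibility.
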