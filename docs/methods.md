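# Methods

`caaxbind` predicts whether a C-terminal Cxxx tetrapeptide can bind protein
farnesyltransferase (FTase), using a fixed-template, minimization-based
threading protocol. This note documents the model, its assumptions, the
tunable parameters, and what the synthetic benchmark does and does not show.

## The protocol

Binding of a Cxxx peptide to FTase is highly constrained: the cysteine
thiolate coordinates the catalytic zinc, the C-terminal carboxylate accepts
a hydrogen bond from a glutamine of the alpha subunit, and the a2 backbone
carbonyl accepts one from an arginine of the beta subunit. Because these
three contacts pin the peptide backbone, a single-conformation protocol
suffices: thread the query sequence onto a template peptide backbone, pack
its side chains, minimize in torsion space under distance restraints
encoding the three conserved contacts, and read off a peptide energy.

Pipeline stages for one sequence:

1. **Threading** (`conformers.thread_sequence`). Backbone heavy atoms
   (N, CA, C, O, OXT) are copied bitwise from the template; side chains are
   rebuilt at ideal geometry in the first library rotamer. The pose carries
   a torsion-space chart (phi/psi/omega, all chi, 6-DOF rigid body, receptor
   interface chi, ligand chain dihedrals) whose internal coordinates are
   measured from the actual structure, so an unchanged torsion state rebuilds
   the input coordinates exactly.
2. **Packing** (`conformers.pack_sidechains`). Peptide side chains only; the
   receptor is fixed at this stage. Energies decompose over rotamer
   single/pair tables, so exhaustive enumeration is exact when the
   combination count is below `exhaustive_limit` (default 1e5); above it a
   seeded simulated annealing on the same tables is used. `extra_chi` adds
   +-10 degree sub-rotamers on chi1/chi2. Equal-energy ties break toward the
   lowest library index.
3. **Minimization** (`minimize.minimize_pose`). DFP quasi-Newton in the
   selected torsion space with an Armijo backtracking line search;
   forward-difference gradients for poses, central differences in the
   generic core. Convergence when the absolute energy change drops below
   `tolerance` (default 1e-4). Free degrees of freedom: all peptide
   torsions, peptide rigid body, receptor side-chain chi for residues whose
   C-beta (C-alpha for Gly) lies within 8 A of the peptide, and ligand chain
   dihedrals. The receptor backbone never moves. The constraint term enters
   the objective with weight 1.0 (configurable).
4. **Scoring** (`energy.score_pose` + `energy.peptide_score`). The
   classification score is the sum of the four peptide residues' per-residue
   energies, minus a per-amino-acid reference constant (all zeros by
   default). Five schemes are exposed: total, interface
   (complex-minus-parts), peptide, peptide-no-reference, and buried
   interface surface area (Shrake-Rupley, probe 1.4 A).

## Energy model

The energy function is self-contained and deliberately simple; its absolute
values are NOT comparable to any published force field, and the classical
-0.4 / -1.1 thresholds shipped as defaults are interface conventions, not
transferable calibrations — calibrate on labeled data via
`evaluation.calibrate_thresholds` for any new template or parameter set.

Pairwise terms (8 A cutoff, C1-smooth switching from 5.5 A):

- **Lennard-Jones 6-12**, well depth `sqrt(eps_i eps_j)` at `r_i + r_j`,
  split into attractive and repulsive branches; the repulsion is linearized
  below 0.6 of the contact distance so deep clashes have bounded gradients.
- **Hydrogen bond**: Gaussian well in donor-acceptor heavy-atom distance
  (optimum 2.9 A, sigma 0.35 A) modulated by donor and acceptor
  directionality derived from covalent-neighbor geometry (crystal-style
  heavy-atom-only structures carry no hydrogens; polar-H directions are
  inferred).
- **Implicit solvation**: Gaussian-exclusion pair term; each atom type
  carries a desolvation density (positive for polar/charged = burial
  penalty, negative for carbon = hydrophobic effect) and an occlusion
  volume.
- **Electrostatics**: Coulomb with distance-dependent dielectric (4r),
  formal charges only (carboxylates, Lys, Arg).

Pair energies are attributed half/half to the two residues, which makes the
decomposition identity (sum of per-residue energies + constraint total =
total) exact by construction. Atom pairs joined by a constraint — the
sulfur-triad coordination and the two conserved hydrogen bonds — are
excluded from the nonbonded terms together with their 1-3 neighbors across
the pseudo-bond, exactly as covalent bonds are: a 2.3 A coordination
contact would otherwise sit deep on the repulsive wall and fight the
constraints throughout minimization.

Constraints are pure harmonics `((d - d0)/sd)^2` with `d0` measured in the
template and `sd = 0.1` A by default (0.25 A is a documented alternative
that is slightly softer). No flat bottom is used.

## Template preparation

`structio.prepare_template` truncates the bound peptide to its last four
residues, keeps the co-crystallized lipid analog as a rigid (optionally
dihedral-flexible) unit, strips waters and metal ions (the zinc is replaced
by the three coordination constraints), and builds a missing C-terminal OXT
at ideal sp2 carboxylate geometry. Anchor atoms are addressed by
configuration (`chain:seqpos:atom`), never hard-coded, so any template with
equivalent conserved contacts can be used. The carboxylate constraint uses
whichever terminal oxygen is nearer the glutamine anchor in the template.

## The synthetic template and benchmark

`synthetic.make_toy_template` builds a deterministic miniature pocket with
the same logic as the real site: solvent-facing a1; a buried a2 pocket
whose floor is a leucine tip placed so that Ile/Leu/Val side chains make
ideal contact and anything longer clashes; a deeper, narrow X channel
(fits Met/Gln); a polar rim serine; the two hydrogen-bond donors and the
sulfur triad at configured distances (2.8 A and 2.3 A); a hydrophobic
8-carbon chain ligand along the pocket floor; and an ellipsoidal shell of
single-carbon pseudo-residues that stands in for the bulk protein burying
the site (open over the a1 face and the X channel). Wall placements are
checked for steric clearance at build time, so threading always starts from
finite energies.

`synthetic.make_labeled_peptides` draws binders from binder-biased pools
(a1 from AST, a2 from ILV, X from MQTC) and non-binders from the same
background with at least one charged defect at a buried position (a2 from
RD and/or X = D, each with probability 0.7). The `separability` parameter
(default 1.0) mixes pool draws with uniform draws. This is synthetic, not
biological, truth: it encodes the qualitative profile (aliphatic a2
favored, charged burial disfavored) that the toy pocket can express through
sterics and desolvation. The defect alphabet is deliberately narrow, for
reasons the pocket's size makes unavoidable: acidic X residues are
non-binders in the synthetic truth even though real FTase accepts a CxxD/E
substrate class (the toy pocket has no stabilization network for a buried
carboxylate); aromatic side chains are absent from the non-binder pools
because a pocket this small cannot reliably reject a planar ring that can
lie against an open face; and lysine/glutamate are absent because their
long aliphatic stems collect favorable contacts while the charged tip
snorkels to the open solvent face. These are limitations of the miniature
fixture, not of the pipeline contract.

Passing the synthetic benchmark therefore shows that the pipeline
end-to-end (threading, packing, constrained minimization, per-residue
scoring, ROC, calibration) behaves correctly and discriminates the designed
signal; it does not show that the energy function reproduces real FTase
specificity profiles or published AUC values, which were obtained with a
different, full-featured macromolecular force field on experimental
peptide libraries.

## Numerical choices

- Problem sizes: the end-to-end benchmark scores 25 binders + 25
  non-binders on the toy template (about 120 atoms, ~45 degrees of
  freedom), with `max_iter = 200` minimization steps per sequence in the
  pipeline default; the DFP core itself defaults to `max_iter = 500`.
  Minimization rarely reaches the 1e-4 convergence tolerance within the
  pipeline's step cap; the residual descent is in the receptor side-chain
  tail and contributes per-sequence score noise of order one energy unit.
- Packing tables are exact for the pairwise-decomposable energy; the
  brute-force equivalence is asserted in tests.
- Gradient steps: 2e-3 degrees/A forward differences for pose objectives;
  central differences (exact for quadratics) in `dfp_minimize` by default.
- Classification boundary rule: a score exactly at a threshold takes the
  more favorable class ("<= passes"); ties at a ROC threshold count as
  positive calls, consistently.
- The ROC implementation is lower-score-is-positive throughout; AUC is
  computed by trapezoid and cross-checked against the tie-adjusted
  concordant-pair statistic at run time (a mismatch raises).
- Batch scoring derives a per-sequence RNG seed from CRC32 of
  `(seed, sequence)`, making results independent of evaluation order.
- Proline: the ring is built at fixed torsions without ring-closure
  refinement and carries no sampled chi angles.
- Omega angles are minimized freely (no planarity restraint by default; an
  optional restraint flag was considered and rejected as the template
  backbone barely moves under the three constraints).

## Known limitations

- The energy model has no explicit hydrogens, no polarization, and a
  two-parameter-per-type solvation model; absolute energies are
  template-specific.
- The kinematic chart roots at the peptide N-terminus; severe distortions
  far from the template geometry are outside the protocol's intended regime
  (it is a refinement, not a folding method).
- Receptor side chains respond only through chi rotations; backbone
  plasticity (which rescues bulky X residues in more aggressive sampling
  protocols) is out of scope.
- The toy receptor is ~40 residues with a pseudo-atom shell; buried surface
  areas and interface statistics are of toy magnitude.
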