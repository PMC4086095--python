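# Generic coarse-grained docking parameter set shipped with pepsurf.
#
# SYNTHETIC STAND-IN: this is a self-consistent generic parameter set in
# the spirit of reduced protein docking force fields (backbone heavy atoms
# kept, side chains as up to two pseudo-beads, soft 8-6 Lennard-Jones plus
# screened electrostatics).  It is NOT a published parameterization; users
# with access to a published reduced force-field table can drop in their
# own file with the same schema (sections: types, groups, charges,
# repulsive_pairs, plus scalar settings).
#
# sigma: Angstrom, per-pair sigma = (sigma_i + sigma_j) / 2
# epsilon: kcal/mol, per-pair epsilon = sqrt(epsilon_i * epsilon_j)
# Pairs listed under repulsive_pairs use the sign-inverted (purely
# repulsive) form of the soft potential.

dielectric: 15.0        # eps(r) = dielectric * r  (distance-dependent)
coulomb_constant: 332.0636   # kcal*A/(mol*e^2)
surface_bead_radius: 0.0     # A; surface = bead centers (see docs)

types:
  # backbone heavy atoms (one bead per atom)
  N_bb:  {sigma: 2.9, epsilon: 0.60}
  CA_bb: {sigma: 3.3, epsilon: 0.60}
  C_bb:  {sigma: 3.3, epsilon: 0.60}
  O_bb:  {sigma: 2.9, epsilon: 0.60}
  # side-chain pseudo-bead classes
  APO_S: {sigma: 3.8, epsilon: 1.00}   # small apolar group
  APO_M: {sigma: 4.4, epsilon: 1.20}   # medium apolar group
  POL:   {sigma: 3.6, epsilon: 0.80}   # polar uncharged group
  ARO:   {sigma: 4.6, epsilon: 1.30}   # aromatic ring
  POS:   {sigma: 3.8, epsilon: 0.70}   # amine / guanidinium group
  NEG:   {sigma: 3.6, epsilon: 0.70}   # carboxylate group

# Like-charged bead pairs interact through the purely repulsive form.
repulsive_pairs:
  - [POS, POS]
  - [NEG, NEG]

# Side-chain heavy-atom groups per residue: each group becomes one
# pseudo-bead at the centroid of its atoms.  Residues with more than four
# side-chain heavy atoms are split at the first branch point into two
# groups (proximal, distal).
groups:
  GLY: []
  ALA: [{type: APO_S, atoms: [CB]}]
  SER: [{type: POL,   atoms: [CB, OG]}]
  CYS: [{type: POL,   atoms: [CB, SG]}]
  THR: [{type: POL,   atoms: [CB, OG1, CG2]}]
  VAL: [{type: APO_S, atoms: [CB, CG1, CG2]}]
  PRO: [{type: APO_S, atoms: [CB, CG, CD]}]
  LEU: [{type: APO_M, atoms: [CB, CG, CD1, CD2]}]
  ILE: [{type: APO_M, atoms: [CB, CG1, CG2, CD1]}]
  MET: [{type: APO_M, atoms: [CB, CG, SD, CE]}]
  ASP: [{type: NEG,   atoms: [CB, CG, OD1, OD2]}]
  ASN: [{type: POL,   atoms: [CB, CG, OD1, ND2]}]
  GLU: [{type: APO_S, atoms: [CB, CG]},
        {type: NEG,   atoms: [CD, OE1, OE2]}]
  GLN: [{type: APO_S, atoms: [CB, CG]},
        {type: POL,   atoms: [CD, OE1, NE2]}]
  LYS: [{type: APO_S, atoms: [CB, CG, CD]},
        {type: POS,   atoms: [CE, NZ]}]
  ARG: [{type: APO_S, atoms: [CB, CG, CD]},
        {type: POS,   atoms: [NE, CZ, NH1, NH2]}]
  HIS: [{type: APO_S, atoms: [CB, CG]},
        {type: ARO,   atoms: [ND1, CD2, CE1, NE2]}]
  PHE: [{type: APO_S, atoms: [CB, CG]},
        {type: ARO,   atoms: [CD1, CD2, CE1, CE2, CZ]}]
  TYR: [{type: APO_S, atoms: [CB, CG]},
        {type: ARO,   atoms: [CD1, CD2, CE1, CE2, CZ, OH]}]
  TRP: [{type: APO_M, atoms: [CB, CG, CD1, CD2]},
        {type: ARO,   atoms: [NE1, CE2, CE3, CZ2, CZ3, CH2]}]

# Formal charge per residue, carried by the LAST side-chain pseudo-bead.
# Backbone beads and unlisted residues carry zero; histidine is neutral
# by default; terminal charges are off by default.
charges:
  ASP: -1.0
  GLU: -1.0
  LYS: 1.0
  ARG: 1.0
  HIS: 0.0
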