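# Default fragment/charge configuration.
#
# Continuum-electrostatics (PARSE-style) radii and charges for a minimal set
# of standard residues, plus the SF4 cubane hetero group (per-atom integer
# formal charges: Fe +2/+3, bridging sulfide -2) and the single-atom toy
# residues emitted by the synthetic-structure generator.  Titration
# parameters: pk_sol (solution pKa), em_sol (solution midpoint, mV), m
# (acid/base indicator), n (electrons bound in the reduced form).

radii:
  C: 1.70
  N: 1.50
  O: 1.40
  S: 1.85
  H: 1.00
  FE: 1.30

lj:
  C:  {rmin: 2.00, eps: 0.110}
  N:  {rmin: 1.85, eps: 0.170}
  O:  {rmin: 1.77, eps: 0.120}
  S:  {rmin: 2.10, eps: 0.250}
  H:  {rmin: 1.10, eps: 0.020}
  FE: {rmin: 1.45, eps: 0.050}

backbone_charges:
  N: -0.40
  H: 0.40
  CA: 0.00
  C: 0.55
  O: -0.55

residues:
  GLY:
    kind: residue_sidechain
    states:
      - {name: "0", charge: 0, m: 0, n: 0}
  ALA:
    kind: residue_sidechain
    states:
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {CB: 0.0}}
  CYS:
    kind: residue_sidechain
    states:
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {CB: 0.0, SG: 0.0}}
      - {name: "-1", charge: -1, m: -1, n: 0, pk_sol: 9.1,
         atom_charges: {CB: -0.08, SG: -0.92}}
  LYS:
    kind: residue_sidechain
    states:
      - {name: "+1", charge: 1, m: 1, n: 0, pk_sol: 10.4,
         atom_charges: {CE: 0.0, NZ: 1.0}}
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {CE: 0.0, NZ: 0.0}}
  ARG:
    kind: residue_sidechain
    states:
      - {name: "+1", charge: 1, m: 1, n: 0, pk_sol: 12.0,
         atom_charges: {CZ: 0.4, NH1: 0.3, NH2: 0.3}}
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {CZ: 0.0, NH1: 0.0, NH2: 0.0}}

  # single-atom toy residues written by the synthetic generator -----------
  SHL:  # Lys/Arg-like charged shell site, titrating charged <-> neutral
    kind: residue_sidechain
    sidechain_atoms: [NZ]
    states:
      - {name: "+1", charge: 1, m: 1, n: 0, pk_sol: 10.4, atom_charges: {NZ: 1.0}}
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {NZ: 0.0}}
  SHM:  # Asp/Glu-like negative shell site
    kind: residue_sidechain
    sidechain_atoms: [OD]
    states:
      - {name: "-1", charge: -1, m: -1, n: 0, pk_sol: 4.0, atom_charges: {OD: -1.0}}
      - {name: "0", charge: 0, m: 0, n: 0, atom_charges: {OD: 0.0}}
  CYL:  # thiolate-like ligand sulfur
    kind: residue_sidechain
    sidechain_atoms: [SG]
    states:
      - {name: "-1", charge: -1, m: 0, n: 0, atom_charges: {SG: -1.0}}
  BBD:  # rigid backbone-like dipole (zero conformational degrees of freedom)
    kind: backbone
    atom_charges: {NP: 0.40, OM: -0.40}
  MTX:  # neutral matrix filler defining the low-dielectric region
    kind: backbone
    atom_charges: {}

hetero:
  SF4:
    fe:
      radius: 1.30
      states:
        - {name: red, charge: 2, m: 0, n: 1, em_sol: -170.0}
        - {name: ox, charge: 3, m: 0, n: 0}
    s:
      radius: 1.80
      charge: -2
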