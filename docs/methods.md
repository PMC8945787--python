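# Methods

## Physical model

`redoxmc` treats a protein with embedded metal clusters as a set of
*fragments*, the smallest units that carry an integer charge and can change
state independently: each Fe ion of a cubane (+2 reduced / +3 oxidized),
each bridging sulfide (fixed −2), each cysteine thiolate ligand (−1), and
each titratable side chain. A fragment is represented by discrete
conformers — alternate geometries (taken from altloc records or supplied
externally; no rotamer search is performed) crossed with ionization states
from the charge configuration. Backbone atoms have zero conformational
degrees of freedom and enter only as a fixed partial-charge set.

The microstate energy is the standard multi-conformer continuum expression
(see README): a pH term `2.303·m·kT·(pH − pK_sol)`, a redox term
`n·F·(Eh − Em_sol)`, the desolvation and backbone terms from the PB solver,
and pairwise conformer–conformer energies. Conventions that matter:

* `n` counts electrons bound in the **reduced** conformer, so raising Eh
  penalizes reduced states and drives oxidation; the oxidized conformer of
  a couple carries `n = 0`. The equivalent convention with the term
  attached to the oxidized conformer differs only by a constant per
  fragment, which cancels in occupancies.
* The pairwise sum counts each unordered pair **once**. Reading the
  double sum of the usual printed form literally would double-count every
  interaction; the once-per-pair convention is what makes the two-site
  closed forms below come out exactly.
* Energies are kcal/mol, lengths Å, potentials mV. `kT = 0.5922` kcal/mol
  at 298 K, `F = 23.061` kcal mol⁻¹ V⁻¹, Coulomb constant
  `332.0636` kcal Å mol⁻¹ e⁻².
* Em values sit on the Eh scale anchored by the fragment's solution
  reference `Em_sol`; for Fe couples the default is −170 mV, the value
  that calibrates a deeply buried inter-polypeptide cluster in the
  photosystem I benchmark against its measured potential. pH defaults
  to 7 (the pH term is implemented and active for acid/base conformers;
  coupled pH×Eh surfaces are out of scope).

## Poisson–Boltzmann solver

The linearized PB equation `∇·(ε∇φ) − κ̄²(r)φ = −4πρ` is discretized on a
regular grid with dielectric values on grid links and Debye–Hückel
screening (`κ̄² = 8π k_c c / kT`, c the ion density of the 0.15 M default
1:1 salt) on solvent nodes; for water at 298 K this reproduces a ~7.9 Å
Debye length. The solution uses red-black successive over-relaxation with
the over-relaxation factor `2/(1+sin(π/N))` and a convergence criterion of
max potential update < 1e-6 kcal/mol/e; non-convergence raises with the
residual. Dirichlet boundary values come from the Debye–Hückel monopole
sum. Charges are spread trilinearly to the eight surrounding nodes.

The low-dielectric region is the inflated van der Waals surface eroded by
the solvent probe (1.4 Å): a point is protein if inside an atom sphere, or
inside the probe-inflated surface and unreachable by a probe — resolved
with a Euclidean distance transform on a 0.4 Å auxiliary grid. For a
single sphere this reproduces the solvent-excluded surface exactly; for
multi-atom solutes the re-entrant surface is approximate at the auxiliary
grid's resolution.

Grid self-energies are never reported: every energy is either a
*difference* of two solutions with identical charge layout and grid
(desolvation), or an interaction evaluated through the split
`φ = φ_reaction-field + analytic Coulomb/ε_protein`, where the grid
supplies only the smooth reaction-field part. This makes uniform-medium
interactions exact and keeps pairwise/backbone terms accurate at coarse
spacing.

Default grid: 0.5 Å spacing, 8 Å padding, one focusing level. With
focusing, coarser levels cover the full box and the fine level a
`max(8h, 6 Å)` margin around the charges; potentials requested outside a
focus box fall back to the coarser level. Verified behaviors: Born-sphere
reaction field within 2% of the analytic value at 0.25 Å; two-level
focusing within 1% of the equally fine unfocused solution; salt screening
monotone in ionic strength.

Desolvation is defined as (reaction field in the protein cavity) minus
(reaction field of the conformer alone in water), which is ≥ 0 for buried
net charge — the sign convention under which the published decompositions
report desolvation as "always positive and unfavorable". Both solves use
the same grid and salt so self-energy and reference terms cancel exactly.

Lennard-Jones 12-6 terms use per-element `Rmin/2, ε` parameters from the
charge configuration with Lorentz–Berthelot combining, evaluated
analytically off-grid, with interatomic distances floored at 0.5 Å to keep
pathological overlaps finite.

## Clash preselection

A conformer is discarded when some atom pair overlaps by more than
`overlap_tol` (default 0.1 Å; no published threshold exists) against the
backbone, or against *every* conformer of another fragment (a clash the
sampler could never avoid). The rule is iterated to a fixed point, which
makes the filter idempotent; the last surviving conformer of a fragment is
never removed, so degenerate inputs (e.g. two rigid fragments placed on
top of each other) keep one conformer each rather than emptying the model.

## Sampling and midpoints

Exact enumeration marginalizes the full microstate tensor (feasible to
~1e6 states) and is the oracle for the Metropolis sampler. The sampler
does single-conformer flips plus, with 10% probability, correlated double
flips of two random fragments; default schedule 2000 burn-in + 10000
sampling sweeps, occupancies as visit fractions, standard errors by batch
means over 25 batches. Runs are bit-reproducible for a fixed seed; a run
with zero accepted state-changing proposals emits a non-ergodicity
warning.

Per-site midpoints are the 0.5-crossing of the oxidized fraction on the Eh
grid (linear interpolation; 5 mV default step). The cluster Em for the
2+/1+ couple is defined as the Eh where the expected number of oxidized Fe
crosses 1.5 — the operational form of the "second oxidized iron"
convention, chosen here because it is well defined even when the two
lowest oxidation events mix. For two *distinct* sites far apart in Em the
1.5-crossing equals `Em_2 + 1000·W/F` mV exactly under an ox–ox coupling
W; for two *equal* sites it sits at `Em + 1000·W/F + (kT/F)·ln 2 + O(e^{−W/kT})`
— the degeneracy term, ≈17.8 mV at 298 K, is a property of the statistics,
not an artifact, and the tests pin it against the exact two-site partition
function.

## Mean-field decomposition

Each term of `F·Em_MFE = nF·Em_sol + ΔG_bkbn + ΔΔG_rxn + ΔG_res^MFE` is
the **oxidized-minus-reduced** difference of the corresponding energy over
the site's conformers (occupancy-weighted within each redox state when a
state has geometric variants); the residue term weights pair energies by
partner occupancies at the condition of interest, normally the site's own
Em. The identity defines `Em_MFE` and holds to machine precision by
construction. The shift realized by the sampled titration,
`F·(Em_calc − Em_sol)`, is reported separately as `dEm`; the two differ by
exactly the content of the mean-field approximation, and published
decomposition tables are themselves internally inconsistent at the
~0.2 kcal/mol level between these two definitions, so the package labels
both rather than reconciling them.

Interaction tables (probe columns × partner rows) use the electrostatic
part of the pair matrix only; display output blanks entries below
0.5 kcal/mol (the smallest magnitude printed in the benchmark tables) but
totals always use full-precision values.

## Geometry

Cubane descriptors pair each Fe with its three nearest bridging sulfides
(12 Fe–S bonds), the nearest thiolate SG, and all six Fe–Fe pairs. The
ligand summary of a designated oxidized Fe averages its four sulfur
distances. Which Fe is "second oxidized" is an input — from titration
ordering or the user — never guessed from geometry. Report rounding is
half-away-from-zero to 2 decimals with a 1e-9 representation-error guard
(so decimal ties from averaged 2-decimal values round as by hand);
internal values keep full precision.

## Synthetic data

`make_toy_cluster` builds the study conditions the analysis assumes: an
ideal cubane (Fe–S bond = cube edge, default 2.3 Å as in the benchmark
structures) with per-atom integer formal charges, thiolate-like ligands at
2.3 Å, optional Lys/Arg-like ±1 shell sites at 4–8 Å with charged/neutral
conformer pairs, rigid ±0.4 e backbone dipoles, and an optional neutral
atom-filled sphere that creates a contiguous ε=4 interior. Default Fe/S²⁻
radii are 1.3/1.8 Å (no published values exist for the per-atom-charge
reading of the cluster; these are configurable). Shell placement is the
only randomness and is fully seeded; generators are pure functions of
spec + seed and the PDB text round-trips through the parser losslessly.

What the toys do *not* emulate: real rotamer distributions, the ~10⁵-atom
scale of a full reaction-center complex, MD-relaxed geometries, and
electronic delocalization over the cubane (per-atom integer charges make
individual energy terms larger than the spread-charge reality; observable
midpoints arise as near-cancellations, which is also true of the real
systems). Passing tests therefore validate the energy machinery and its
identities, not absolute midpoint predictions for any particular protein.

`make_titration_system` bypasses the PB stage entirely, building energy
tables with prescribed site references, ox–ox couplings and self-energy
shifts whose titration behavior has closed forms — these back the
midpoint, Nernst-slope, coupling-shift and parameter-recovery tests.

Published benchmark tables (per-sulfur interaction energies, bold ligand
distances, decomposition terms, midpoint values for the three photosystem
I clusters) are transcribed once into checksummed data files; the loader
fails loudly on checksum mismatch.

## Problem sizes

Unit and acceptance tests run PB solves on single- to 20-conformer systems
at 0.25–0.9 Å spacing (seconds each), the MC-vs-enumeration comparison on
100 random ≤10-conformer systems, and the full synthetic pipeline at
0.6 Å with two-level focusing — sizes chosen so the whole suite completes
in about a minute while every analytic check retains its stated tolerance.

## Known limitations

* Linearized PB only; fine for 0.15 M 1:1 salt, not for highly charged
  surfaces in divalent salt. No ion-exclusion (Stern) layer.
* The dielectric boundary is the EDT-eroded inflated vdW surface, not a
  triangulated molecular surface; re-entrant regions are approximate.
* Reaction-field energies of sub-ångström cavities need ≲0.3 Å (focused)
  grids; at ≳0.9 Å spacing symmetric sites can disagree by tens of
  kcal/mol in their (huge) raw desolvation terms.
* Conformer generation is limited to supplied geometries × ionization
  states; no rotamer machinery.
* Spin–spin and spin–orbit effects are absent — the model is classical
  electrostatics throughout, with electron delocalization reduced to
  integer formal charges.
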