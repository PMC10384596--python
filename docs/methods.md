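# Methods

This note documents the models, conventions and numerical choices behind
`lyotraj`, and what its synthetic-fixture tests do and do not demonstrate
about real freeze-drying simulations.

## The stage model

The pipeline treats freeze-drying as five consecutive preparation
operators, each consuming the final configuration of the previous stage:

| stage | operator | geometric rule |
|-------|----------|----------------|
| RT    | solvation-box definition | cubic box, protein-to-face margin 15 Å |
| F     | ice covering | hexagonal ice-Ih slabs on the +x, +y, +z box faces |
| 1D    | bulk-water stripping | water kept iff its oxygen is ≤ 3 Å from any protein atom; vacuum box margin 50 Å |
| 2D    | residual-water selection | water kept iff its oxygen is within 1.5 Å of a crystal-water position |
| REC   | re-solvation | fresh cubic box at 15 Å margin, grid-placed waters |

Coarse-grained multimer systems for aggregation statistics use a 2×2×2
replication grid at 85 Å centre-of-mass spacing and a 7.5 Å box margin.

All of these rules are *geometric*: the package deliberately contains no
force field, thermostat or integrator.  Where a production workflow would
relax inserted molecules by energy minimisation, `lyotraj` substitutes
deterministic clash pruning (molecules closer than 2.4 Å to existing atoms
are deleted).  This preserves the combinatorial content of each stage —
which molecules exist, where the boxes are — without pretending to sample
dynamics.

### Conventions the pipeline fixes

Several rules are stated loosely in common laboratory practice; the
package fixes one interpretation each and makes it configurable:

* **Water–protein distance** is measured from the water *oxygen* to any
  protein atom, and the stripping boundary is inclusive (≤ 3 Å retained).
* **% w/w basis** is excipient mass over (excipient + water) mass.
* **Residual waters** are "placed similarly to crystal waters" when the
  oxygen lies within 1.5 Å of a crystal-water position, after the caller
  superposes the system onto the reference protein frame.
* **Ice covering**: one slab per axis on the positive box face.  Proton
  disorder is emulated by randomised rigid-water orientations without
  Bernal–Fowler ring constraints — downstream analysis is geometry-only,
  so hydrogen-bond topology inside the ice has no consumers.
* **Protein net charge is an input** (default −1 in the examples), not
  computed from pKa; counterion arithmetic follows from it exactly.
* **Excipient arginine** shares the ARG residue name with the amino acid;
  in-memory it is told apart by its role label and its own chain, so PDB
  round-trips require declaring ARG an excipient residue name explicitly
  when reading mixed systems.

## Observables

* **RMSD** uses Kabsch superposition (SVD with a determinant correction,
  so reflections are never returned) against the first frame of the first
  stage; the default atom selection is Cα.  The test suite checks it
  against an independent quaternion (Horn) implementation.
* **Radius of gyration** is mass-weighted.
* **SASA** is Shrake–Rupley with a golden-section spiral point grid
  (default 960 points, probe 1.4 Å) and a fixed per-element van der Waals
  radius table (H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å).  A fixed point
  grid makes the result very slightly orientation-dependent (< ~2 % at the
  default resolution); tests that require exact invariance supply
  accessibilities directly.  The non-polar ratio classifies carbon and
  sulfur as non-polar, with hydrogens inheriting their bonded heavy atom's
  class.
* **β-sheet content** detects backbone hydrogen bonds with the
  Kabsch–Sander electrostatic energy
  E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol (bond if
  E < −0.5), reconstructing amide hydrogens from the planar sp² geometry
  when absent, then marks residues matched by the parallel or antiparallel
  bridge patterns.  Bridges require a sequence separation ≥ 3 within a
  chain.  Only the bridge-level assignment is reported; sheet topology
  classes are not distinguished.
* **Hydrogen-bond counts** use a geometric criterion — donor–acceptor
  heavy-atom distance ≤ 3.5 Å and D–H···A deviation from linearity
  ≤ 30° — because published counts rarely state their criterion.  Counts
  from microsecond trajectories are therefore not numeric targets here;
  the package asserts only the criterion's own semantics.
* **PPI counting** records one count per unique inter-monomer residue pair
  per frame (minimum atom–atom distance strictly < 4 Å, minimum-image on
  orthorhombic boxes), summed over frames; a per-trajectory-unique mode is
  also exposed.  Normalisation divides by the smallest positive
  per-condition count, so ties all map to 1.0 and the output is
  scale-invariant.  Heatmap cells below 25 % of the reference condition's
  strongest pair are removed; cells exactly at the threshold are retained.
* **APR scores** are a transparent stand-in for external
  aggregation-propensity programs: score_i = Σ_j w(d_ij)·h_j·rsa_j over
  residues j with Cα within 10 Å of residue i, where h is the
  Kyte–Doolittle hydropathy rescaled to [0, 1], rsa the residue SASA over
  its theoretical maximum, and w(d) = 1 − d/R.  Higher = more
  aggregation-prone; difference maps record operand order explicitly
  because subtraction-order conventions in the literature are
  inconsistent.  No numeric equivalence with any external program is
  claimed.

## Synthetic fixtures

The generator produces the *study conditions* for the test suite:

* **Ideal fragments.**  Helices and extended strands are built from ideal
  torsions (φ/ψ = −57/−47 and −139/135) by natural-extension-reference-frame
  placement with Engh–Huber-like bond geometry.  The hairpin is built from
  explicit flat-pleated coordinates with exact mutual N–H···O=C register
  (H···O 1.97 Å, N···O 2.97 Å), so its Kabsch–Sander energies (≈ −2.7
  kcal/mol) are controlled by construction rather than by torsion
  propagation.
* **Solvated fixtures** place water oxygens at stated minimum distances
  from the protein (± 0.05 Å), by rejection sampling from random surface
  directions; deterministic under a seed.
* **Aggregation scripts** start 8 monomers on the 85 Å grid and rigidly
  translate scheduled pairs into contact.  The approaching monomer is first
  re-placed collinearly beyond the target's +x extent so a scheduled event
  produces exactly one closest residue pair; scheduled distances must
  differ from the contact cutoff by ≥ 0.5 Å so ground truth is never a
  floating-point coin flip.  Ground-truth counts are recomputed by direct
  all-pairs enumeration at build time.
* **Excipient populations** are single-bead molecules on a non-clashing
  grid carrying the formulation charge logic (ARG +1, TXA 0, SUC 0).

Problem sizes are deliberately small — 10–12-residue fragments, tens of
waters, 8 three-bead monomers, ten-frame trajectories — chosen so every
check is exact or brute-force verifiable.  Passing tests therefore
demonstrate that the *operators and statistics* are correct, not that any
particular protein behaves a particular way: fixtures have no dynamics, no
energetics and no realistic sequence, and headline magnitudes from
microsecond simulations (fold-changes in PPIs, hydrogen-bond averages,
occupancy percentages) are structural analogues here, not reproduced
measurements.

## Numerical choices

* Coordinates are Å throughout; PDB serialisation truncates to 3 decimals,
  and round-trip tests assert at that precision.
* Boxes are orthorhombic; the hexagonal ice lattice is generated in its
  native cell and clipped to an orthorhombic slab region.
* Contact detection uses kd-trees (periodic kd-trees for boxed systems);
  the strict `< cutoff` inequality matches the counting rule, and the
  brute-force O(N²) oracle in the tests uses the same inequality.
* `normalize_ppi` raises on all-zero inputs rather than returning NaN.
* Degenerate inputs are errors where silence would corrupt downstream
  statistics (empty trajectories, empty reference record sets, residue
  mismatches in difference maps) and no-ops where the physical reading is
  clear (stripping a system with no waters).

## Known limitations

* No energetics: clash pruning stands in for minimisation, and ice slabs
  are geometric blocks, not equilibrated interfaces.
* The PDB dialect is the subset needed by the pipeline
  (ATOM/HETATM/MODEL/ENDMDL/CRYST1/TER, first altloc only, ≤ 62 chains).
* The β detector reports bridge participation only; isolated β-bridges and
  ladder topology are not separated.
* The APR score is a documented proxy; it ranks hydrophobic exposure, not
  validated aggregation propensity.
* Re-solvation places oxygen-only grid waters, sufficient for counting,
  distance and box semantics but not for hydrogen-bond analysis of the
  solvent itself.
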