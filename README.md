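# lyotraj

Freeze-drying (lyophilization) simulation-pipeline construction and
trajectory analysis for protein formulations.

Lyophilized protein drugs are prepared by freezing a solvated formulation,
subliming the bulk ice (primary drying), desorbing most of the remaining
water (secondary drying) and later re-dissolving the solid
(reconstitution).  Each of those steps stresses the protein — ice
interfaces, loss of the hydration shell, hydrophobic exposure, domain
collapse — and excipients such as arginine (ARG), tranexamic acid (TXA) and
sucrose (SUC) are added to protect it.  `lyotraj` implements the
*computational* side of studying this process: the deterministic
system-preparation operators that turn one stage's final configuration into
the next stage's starting system, and the structural statistics used to
judge what the process did to the protein.  It is aimed at formulation
scientists and simulation practitioners who want the stage bookkeeping and
the analysis to be reproducible, testable code rather than one-off scripts.

## What it computes

**Stage construction** (`lyotraj.stage_builder`) — the five-stage protocol
RT → F → 1D → 2D → REC:

* cubic solvation boxes with an exact protein-to-face margin (15 Å for
  solvated stages, 50 Å for vacuum drying, 7.5 Å for the coarse-grained
  multimer systems);
* monomer replication on a 2×2×2 grid at 85 Å centre-of-mass spacing for
  coarse-grained aggregation systems;
* excipient loading by molarity, `N = round(C·V·N_A)`, or by mass fraction,
  `N = round(f/(1−f) · n_w · M_w / M_e)` with the basis
  excipient/(excipient+water);
* neutralisation: a solute of net charge q gets q Cl⁻ (q > 0) or |q| Na⁺
  (q < 0), never both;
* freezing by covering the box faces with hexagonal ice-Ih slabs
  (a = 4.497 Å, c = 7.322 Å, 4 molecules per unit cell, clash-pruned);
* primary drying: a water survives iff its oxygen is ≤ 3 Å from the
  protein; secondary drying: a water survives iff it sits within 1.5 Å of a
  crystal-water position; reconstitution: grid re-solvation in a fresh
  15 Å box.

**Trajectory observables** (`lyotraj.traj_analysis`) — Kabsch superposition
and RMSD time courses against the starting structure, mass-weighted radius
of gyration `Rg = sqrt(Σ mᵢ|rᵢ−r_com|²/Σ mᵢ)`, Shrake–Rupley SASA and the
non-polar/total SASA ratio (hydrophobic exposure), β-sheet content from
Kabsch–Sander backbone hydrogen-bond energies
(`E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol`, bond if
E < −0.5), geometric hydrogen-bond counts (3.5 Å / 30°), and the
kringle-2–catalytic domain-separation distance.

**Aggregation statistics** (`lyotraj.ppi_analysis`) — inter-monomer
protein–protein interactions (PPIs): a residue pair on two different
monomers counts when its minimum atom–atom distance is < 4 Å (minimum-image
convention under periodic boxes); totals are normalised to the weakest
condition; contact heatmaps drop cells below 25 % of the reference
condition's strongest pair; oligomer sizes are connected components of the
monomer contact graph; and excipient-contact occupancy reports the fraction
of frames a residue (e.g. a lysine binding site) touches an excipient.

**APR scoring** (`lyotraj.apr_analysis`) — a transparent aggregation-prone
residue score (exposure-weighted hydrophobicity with linear spatial decay
over a 10 Å neighbourhood) and stage-to-stage difference maps with explicit
operand order.

**Synthetic fixtures** (`lyotraj.synthetic_data`) — ideal helices, strands
and hydrogen-bond-registered β-hairpins, solvated systems with waters at
controlled distances, multi-monomer trajectories with scripted contact
events and known ground truth, and excipient populations with the
formulation charge logic.

## Worked example

```python
import lyotraj as lt

# a hydrogen-bond-registered hairpin, solvated with 8 waters at 2.5 A and 8 at 5.0 A
protein = lt.make_ideal_fragment("hairpin", 12)
solvated = lt.make_solvated_fixture(protein, [(2.5, 8), (5.0, 8)], seed=3)
crystal = solvated.coords[solvated.water_oxygen_indices()][:3]

result = lt.run_pipeline(solvated, crystal_waters=crystal, seed=3)
for stage in result.stages:
    system = result.system(stage)
    print(stage, len(system.atoms),
          len(system.select(role="water")), len(system.select(role="ice")))
```

prints

```
RT 74 16 0
F 5870 16 5796
1D 66 8 0
2D 61 3 0
REC 4127 4069 0
```

— freezing adds 5796 ice atoms on the box faces; primary drying removes the
8 waters beyond 3 Å; secondary drying keeps only the 3 waters matching the
crystal-water positions; reconstitution re-solvates the dried system.

The coarse-grained aggregation readout, on scripted fixtures in which the
no-excipient condition spends twice as many frames in contact:

```python
mono = lt.make_cg_monomer()
none = lt.AggregationScript(n_monomers=8, n_frames=10, schedule=[((0, 9), (0, 1), 3.5)])
comp = lt.AggregationScript(n_monomers=8, n_frames=10, schedule=[((0, 4), (0, 1), 3.5)])
seg_none, _ = lt.make_aggregation_trajectory(mono, none)
seg_comp, _ = lt.make_aggregation_trajectory(mono, comp)
counts = {"no_excipient": lt.ppi_count(seg_none, 4.0),
          "with_excipient": lt.ppi_count(seg_comp, 4.0)}
print(counts, lt.normalize_ppi(counts))
# {'no_excipient': 10, 'with_excipient': 5} {'no_excipient': 2.0, 'with_excipient': 1.0}

print(lt.neutralize(-1 + 284 * 1))   # protein -1 with 284 arginine(+1)
# IonInventory(n_na=0, n_cl=283)
```

A command-line interface mirrors the library:

```sh
lyotraj prepare --stage freeze --in rt.pdb --out frozen.pdb
lyotraj analyze --traj traj.pdb --observables rmsd,rg --out series.tsv
lyotraj ppi --traj multimer.pdb --cutoff 4.0 --out heatmap.tsv
lyotraj apr --structure dried.pdb --minus rt.pdb --out apr_diff.tsv
```

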