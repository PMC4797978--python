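# Methods

## Protocol

Given a family of co-crystallized complexes of one target, all superposed
into a single coordinate frame beforehand, the harness runs the full
ligand × receptor grid. For each ordered pair (ligand *i*, receptor *j*):

1. the grid box is centered on the unweighted heavy-atom centroid of
   receptor *j*'s **own** co-crystallized ligand — in the shared frame that
   centroid marks the binding site for any incoming ligand (the alternative,
   centering on the incoming ligand, differs only by the alignment residual
   and couples the box to the molecule being docked);
2. ligand *i* is randomized (seeded rigid transform, or the engine's
   randomize-only mode for Vina) so the search cannot start from the
   crystal conformation;
3. the engine docks it, returning up to `num_modes` poses sorted by
   predicted binding energy (kcal/mol);
4. each pose is scored by in-place symmetry-corrected heavy-atom RMSD
   against ligand *i*'s crystal pose.

Failures of single cells are recorded with their diagnostic and skipped by
the statistics (with the failed count reported); only a run in which every
cell fails is an error.

## RMSD: assumptions and numerical choices

* **No superposition.** The RMSD is computed in the shared frame. This is
  an assumption about the inputs (they were aligned once, structurally) and
  a deliberate choice: fitting pose onto reference would cancel exactly the
  placement errors cross-docking is meant to measure.
* **Heavy atoms only.** Engine pose files usually omit nonpolar hydrogens,
  making an all-atom correspondence ill-defined. Hydrogens are parsed and
  retained in `Molecule` but excluded from mapping and from the box-center
  centroid.
* **Positional correspondence.** Pose row *k* corresponds to reference
  heavy atom *k*, because the pose is the engine's transform of the ligand
  we submitted. Engines that reorder atoms need a name-based matcher ahead
  of scoring.
* **Symmetry correction.** The reported value is the minimum over all
  element- and bond-preserving automorphisms of the reference heavy-atom
  graph, enumerated with VF2 (networkx). Bonds come from the mol2 bond
  section when available, otherwise from distance-based perception: a bond
  where the interatomic distance is at most 1.3 × the sum of Cordero
  covalent radii. The 1.3 factor passes normal single bonds (C–C at 1.5 Å
  against a 1.98 Å cutoff) while rejecting 1,3-neighbors (≈2.45 Å for
  tetrahedral geometry).
* **Enumeration cap.** Pathologically symmetric graphs can have huge
  automorphism groups; after 10,000 mappings (configurable) the identity
  mapping is used, the result is flagged `symmetry_corrected=False`, and a
  warning is logged. Ties between mappings resolve to the first enumerated.
* The whole-molecule-translation identity (a rigid shift of *d* Å has RMSD
  exactly *d* under any automorphism, since permutation displacements sum
  to zero) is what makes the planted fixtures exact, and is asserted as a
  property test.

## Selections and aggregates

Per cell, two poses are singled out: the **best-RMSD** pose (minimum RMSD;
ties to the lower mode index) and the **best-energy** pose (minimum
energy; its RMSD is reported, since a prospective screen only ever sees
this pose). `best_rmsd ≤ rmsd(best_energy)` by construction.

Per receptor column: arithmetic mean of best RMSDs and the count with
RMSD strictly below the success threshold (default 2.0 Å; the boundary
value counts as failure). Means are taken over non-failed cells only.
Self-docks are included by default — they sit in the same matrix, only
typographically bolded — with a switch to exclude them. Ranking is
ascending in mean RMSD (or descending in success count) with the
complementary criterion, then the lexicographic root, as tie-breaks.

## Reports

Matrices put receptors in columns, ligands in rows, with footer rows for
the column average and success count. Cells are colored by nearest-rank
percentiles of the pooled matrix values: at or below the 10th percentile
green, at or below the 50th yellow, at or above the 90th red, with green
taking precedence when degenerate data collapse the thresholds. Pooling is
per matrix by default (`band_scope = column` switches to per-column
thresholds). Spreadsheets render to two decimals; the CSV mirrors carry
full precision and, together with the band sidecar, are the
machine-readable source of truth. Files are replaced atomically
(write-then-rename).

## Synthetic families and the mock engine

The fixture generator emulates exactly what the pipeline consumes: a
pre-aligned family of receptor/ligand PDB pairs following the naming
convention, with binding sites that nearly coincide (as after structural
alignment). Ligands have 3–12 heavy atoms in three topology classes —
an asymmetric chain (trivial automorphism group), a carboxylate-like
swap-pair head (one nontrivial swap), and an all-carbon ring (full
dihedral group) — so symmetry handling is exercised at known group orders.
Receptors are 20-atom carbon cages on an 8 Å Fibonacci sphere around the
site, plus two waters so loading exercises water stripping. Defaults
(3 pairs, 5 heavy atoms, ±0.05 Å coordinate jitter) keep geometry generic
without perturbing bond perception.

The mock engine plants each pose as the crystal conformation rigidly
translated by a chosen offset, so its ground-truth RMSD is the offset
itself; unplanted cells draw offsets uniformly from [0, 4) Å with energy
−10 + offset, a monotone map that ties the energy ranking to displacement.
Everything is a pure function of the seed; per-cell seeds are derived by
hashing (global seed, ligand root, receptor root), so grids are
reproducible and cells independent of execution order.

What passing tests on these families shows: the bookkeeping — pairing,
randomization, scoring, selection rules, aggregation, banding, file
layout — is exact. What it cannot show: anything about docking accuracy on
real proteins, which lives entirely in the external engine; conformational
(torsional) pose differences, since planted poses are rigid translations;
or pdbqt atom-ordering quirks of engines other than Vina.

## Problem sizes

The test suite and the acceptance script run grids up to 4×4 with ligands
of ≤8 heavy atoms and validate the symmetry RMSD against brute-force
bijection enumeration at ≤7 heavy atoms (≤5040 permutations per molecule,
hundreds of trials), sizes at which the oracle is exact and instant.
Production grids are bounded by the docking engine, not the harness: the
scoring and reporting of an 18×18 grid take seconds.

## Known limitations

* Ligands are compared only to their own crystal pose; ligands with
  different heavy-atom counts across files (partial occupancy, alternate
  locations) are a correspondence error, and maximum-common-substructure
  RMSD is out of scope.
* No chain subsetting, protonation, or charge assignment — preparation
  belongs to external tools, and receptors are used whole.
* The Vina adapter trusts the engine's atom order and converts non-pdbqt
  inputs through Open Babel; exotic residues may need manual preparation.
* Published cross-docking tables from other tools may differ systematically
  where their RMSDs are not symmetry-corrected or include hydrogens.
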