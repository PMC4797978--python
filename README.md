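# crossdock

A cross-docking harness for receptor-ensemble selection in structure-based
drug discovery.

When several crystal structures of the same target exist, the best one for
pose prediction and virtual screening is rarely the one with the best
resolution: flexible binding sites adapt to their co-crystallized ligand,
and a pocket molded around a small ligand may not accommodate a larger one.
Cross-docking answers this empirically — dock every co-crystallized ligand
of the family into **every** receptor of the family and see which receptor
reproduces the most crystal binding modes.

`crossdock` automates the whole protocol: it pairs receptor and ligand
files by naming convention (`<root>-p.*` / `<root>-l.*`), strips waters
(keeping cofactors and coenzymes), centers the docking grid box on each
receptor's own native ligand, randomizes each incoming ligand before
docking, drives a pluggable docking engine over the full ligand × receptor
grid, and scores every pose against its crystal reference.

## The statistic at the core

All structures must be pre-aligned in one coordinate frame (e.g. with
PyMOL's `align`). Pose quality is then the **in-place, symmetry-corrected
heavy-atom RMSD** — no superposition, which would hide binding-mode errors:

```
RMSD = min over σ ∈ Aut(G)  sqrt( (1/N) Σᵢ ‖ r_ref(i) − r_pose(σ(i)) ‖² )
```

where `Aut(G)` is the set of element- and bond-preserving automorphisms of
the ligand's heavy-atom graph, so topologically equivalent atoms (the two
oxygens of a carboxylate, the carbons of a phenyl ring) are never
over-penalized. A dock "succeeds" when its best RMSD is strictly below
2.0 Å, the conventional cutoff for reproducing a crystal binding mode.

Per receptor, the harness reports the column mean of the best RMSDs and the
count of successful docks; receptors with low mean RMSD and/or high success
count are the ones to carry forward into virtual screening. Because a real
screen keeps only the lowest-energy pose, the RMSD carried by each cell's
best-*energy* pose is reported alongside the best-*RMSD* pose — the two
routinely disagree, and the paired tables make the disagreement visible.

## Engines

Docking itself is delegated through one small interface:

* **Vina adapter** — shells out to an AutoDock Vina executable
  (exhaustiveness defaults to 8), converting inputs to pdbqt via Open
  Babel, and parses the multi-model `REMARK VINA RESULT` output.
* **Mock engine** — a deterministic engine with planted pose offsets and
  energies, used by the test suite and the synthetic fixture families; its
  ground-truth RMSDs are exact by construction.

## Worked example

Generate a synthetic aligned 3-pair family and cross-dock it with the mock
engine:

```
$ crossdock fixtures demo/family --n-pairs 3 --ligand-size 6 --symmetry swap-pair --seed 42
wrote 3 pairs under demo/family (receptors/, ligands/); roots: a, b, c

$ crossdock run --receptor-dir demo/family/receptors --ligand-dir demo/family/ligands \
      --output-dir demo/out --engine mock --seed 7 --num-modes 5
INFO crossdock: library: 3 pairs: a, b, c
INFO crossdock: receptor a: mean best RMSD 0.58 A, 3/3 docks < 2.0 A
INFO crossdock: receptor b: mean best RMSD 1.57 A, 2/3 docks < 2.0 A
INFO crossdock: receptor c: mean best RMSD 0.84 A, 2/3 docks < 2.0 A
receptors ranked by mean best RMSD: a, c, b
wrote 13 report files to demo/out
```

Receptor `a` accommodated all three ligands below 2.0 Å (column mean
0.58 Å) and would be the structure to pick. The best-RMSD matrix shows the
per-cell values behind those summaries:

```
$ head -6 demo/out/Table_the_best_RMSD.csv
ligand,a,b,c
a,0.1637198191996206,0.9614489416150431,0.025201675068128065
b,1.440822149531178,1.7150765622008879,0.3375707994910506
c,0.13475625827346963,2.027273511508593,2.166106925973638
average,0.5797660756680894,1.5679330051081746,0.8429598001776055
n(RMSD<2),3.0,2.0,2.0
```

Six report files are written, as spreadsheets with traffic-light
conditional formatting (green/yellow/red at the 10th/50th/90th percentiles,
self-docking diagonal in bold) plus full-precision CSV mirrors:
`Output`, `Output_the_best_RMSD`, `Table_the_best_RMSD`,
`Table_the_best_energy`, `Table_RMSD_for_the_best_energy`,
`Table_energy_for_the_best_RMSD`. Receptors are in columns, co-crystallized
ligands in rows. A `run_manifest.json` (config echo, seed, versions) and a
saved grid (`crossdock_result.json`) make every run reproducible;
`crossdock report` rebuilds the tables from a saved grid without
re-docking.

For a real run, put pre-aligned receptors and ligands in two directories,
write a `config.txt` (`receptor_dir`, `ligand_dir`, optional grid sizes,
`num_modes`, `exhaustiveness`, `engine = vina`) and call
`crossdock run --config config.txt`.

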