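# shapedock

Shape-space analysis tools for antioxidant-mechanism studies and docking
preparation:

- **`shapedock.shape_core`** — Riemannian shape distances between
  atom-matched molecular conformers (e.g. a parent compound and its
  deprotonated anion), globally and per chemical-element subspace, with a
  brute-force rotation-search oracle for verification.  Distances are
  angles in [0, π/2] between preshapes (centered, unit-size
  configurations), computed by SVD Procrustes alignment over proper
  rotations (default) or with reflections allowed.
- **`shapedock.thermo`** — the five antioxidant thermodynamic descriptors
  (BDE, PA, ETE, IP, PDE, kcal/mol) from species enthalpies, with
  thermodynamic-cycle consistency checks, deprotonation-site ranking,
  favored-mechanism classification (HAT / SPLET / SET-PT) and PA-vs-shape
  rank-concordance reports.
- **`shapedock.ligand_frame`** — a similarity-invariant canonical ligand
  orientation (variability-ordered axes with reflection-safe sign
  conventions fixed by the farthest atom pair) plus the 10-member
  rotation ensemble (template + 90/180/270° rotations in the xy/xz/yz
  planes) and AutoDock-Vina grid-box/config emission and result
  collation.
- **`shapedock.mol_io`** — XYZ / PDB / SDF / PDBQT coordinate I/O (PDBQT
  preserves all non-coordinate columns byte-exactly) and atom
  correspondence between a parent and a variant missing one hydrogen.
- **`shapedock.synth`** — seeded synthetic fixtures: random molecules,
  parent/anion pairs, and enthalpy tables constructed to reproduce chosen
  descriptor values exactly.
- **`shapedock.datasets`** — small published reference tables for the four
  betalain study compounds (betanin, betanidin and their C15-epimers).

## Command line

```sh
# shape distances between a parent structure and anion conformers
shapedock rd parent.xyz anionC17.xyz anionC15.xyz --mode proper_rotation

# descriptors + mechanism verdict from a species-enthalpy table
# (TSV/CSV/JSON with columns: compound, site, role, H, unit)
shapedock descriptors species.tsv

# canonical invariant ligand orientation
shapedock template ligand.pdb -o template.pdb

# template + rotation ensemble + Vina configs (default grid box:
# 20x20x20 Å centered at 26, 10, 118)
shapedock dock-prep ligand.pdbqt --receptor receptor.pdbqt --outdir job/

# collate best affinities from Vina logs or docked PDBQTs
shapedock collate job/result_*.log
```

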