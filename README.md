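# symstack

A screw-symmetry stacking toolkit for docking ligands to amyloid fibrils.

Fibrils relate consecutive protein monomers by a screw motion — a small
rotation (twist) about the fibril axis plus a translation (rise) along it —
and a ligand bound at one monomer is implicitly repeated at every other.
`symstack` provides the machinery this implies:

- **geometry** — represent the screw motion as an affine operator
  (`x' = R·x + t`), derive it from a multi-monomer structure by
  least-squares superposition of consecutive monomers, and decompose it
  into axis / twist / rise / axis point.
- **stacking** — generate symmetry images of a ligand pose, reject poses
  whose nearest image comes within a cutoff (2 Å by default) of the
  original, and measure stack geometry (interplanar separation, RMSD).
- **scoring** — united-atom 12-6 Lennard-Jones ligand–ligand stacking
  energy for poses that pass the filter, optionally combined with
  externally supplied protein-interaction scores, plus pose ranking.
- **refine** — rigid-body Metropolis–Hastings Monte Carlo optimization of
  the stack under a per-monomer energy estimated from the three-pose
  stack; the energy backend is the builtin LJ sum or any external command
  (e.g. a neural-network potential) via a simple XYZ/stdout contract.
- **fibril** — periodic blockwise extension of fibril structures by the
  operator (5 monomers → 15 with one copy in each direction) and export
  of ligand-stack heavy atoms as dielectric-boundary pseudo-atoms.
- **metrics** — virtual-screening enrichment: EF at a top fraction and
  adjusted semilog logAUC (random-curve reference 14.462% at λ = 0.001).
- **fixtures** — seeded generators for synthetic helical fibrils, planar
  ring ligands, and labeled screen lists; no downloads needed anywhere.

## CLI

All functionality is reachable through the `symstack` command:

```sh
symstack fixtures --preset tau-like --seed 1 --out demo/   # synthetic inputs
symstack derive-operator --fibril demo/fibril.pdb --out op.json
symstack check  --poses demo/ligand.sdf --operator op.json --cutoff 2.0 --out verdicts.csv
symstack score  --poses demo/ligand.sdf --operator op.json --out report.csv
symstack refine --pose demo/ligand.sdf --operator op.json --steps 1000 \
                --tsigma 0.2 --rsigma 2.0 --kt 0.593 --seed 17 --out mc.json
symstack extend --fibril demo/fibril.pdb --operator op.json --copies 1 --out extended.pdb
symstack boundary --pose demo/ligand.sdf --operator op.json --images 2 --out stack.xyzr
symstack enrich --scores demo/screen.csv --fraction 0.01 --out enrich.json
```

Exit codes: 0 success, 1 usage error, 2 data error. Identical invocations
with the same seed produce byte-identical outputs.

## File formats

PDB for structures and multi-model stacks; SDF/MOL2 for ligand poses
(SYBYL atom types from MOL2 are preserved and used as vdW type labels);
JSON for operators (4×4 homogeneous matrix, row-major, column-vector
convention) and reports; CSV for verdicts and screens; `x y z radius`
text for boundary pseudo-atoms. The vdW parameter table is a
whitespace-delimited text file (`type epsilon rmin_half`, plus
`default element type` fallbacks); see
`src/symstack/data/vdw_params.txt`.
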