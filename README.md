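# tmrepack

Structural-analysis toolkit for comparing transmembrane-transporter
ensembles: helix-bundle repacking descriptors, water-occupancy cavity
volumes, interdomain contact and hydrogen-bond statistics, probe-grid
binding-pocket characterization, docking-pose site assignment, and pairwise
sequence identity — exercised end-to-end on synthetic structures and
trajectories with analytically known ground truth.

## Modules

| Module | Purpose |
| --- | --- |
| `tmrepack.structure_io` | Multi-MODEL PDB read/write, named residue selections (YAML/JSON), backbone phi/psi with rectangular-region classification |
| `tmrepack.synthetic_data` | Fixture generators: ideal helices/bundles with calibrated per-helix tilt/shift overrides, cavity waters of known count, perturbed trajectories, docking pose sets, mutated sequences |
| `tmrepack.helix_bundle` | Per-helix axis fit (PCA + cylinder refinement), bundle descriptors (distance, length, z-shift, total/radial/lateral tilt), Welch block-mean ensemble comparison with BH adjustment |
| `tmrepack.cavity_volume` | Cavity region (membrane slab ∩ shrunk convex hull), water counting, volume = n_waters × v_water, volume distributions P(V) |
| `tmrepack.interface_contacts` | Atom-pair contact counts, residue-pair contact frequencies with the ≥0.5 / >10% significance rule, H-bond detection, lifetime τ and ΔG = −RT ln(τ/τ₀) |
| `tmrepack.pocket_sites` | Probe-grid pocket detection (clash-free + burial), lining atoms, polarity (N+O+S)/(N+O+S+C), residue-class distributions, pose→site assignment and per-site best-ΔG tables |
| `tmrepack.seq_tools` | Needleman–Wunsch global alignment (BLOSUM62, affine gaps), percent identity/similarity over both-non-gap columns |
| `tmrepack.cli_pipeline` | `tmrepack` CLI and the end-to-end WT-vs-variant demo with manifest |

## CLI

```sh
tmrepack demo --outdir out/ --seed 0          # synthetic WT vs variant, full report
tmrepack bundle --trajectory traj.pdb --selections sel.yaml --out bundle.tsv
tmrepack compare --wt bundle_wt.tsv --variant bundle_var.tsv --out comparison.tsv
tmrepack volume --trajectory traj.pdb --selections sel.yaml --out volumes.tsv
tmrepack contacts --trajectory traj.pdb --selections sel.yaml \
    --group-a ICH1 --group-b NBD1 --out contacts.tsv
tmrepack hbonds --trajectory traj.pdb --selections sel.yaml \
    --donors ICH4 --acceptors NBD1 --dt 10 --out hbonds.tsv
tmrepack pockets --structure frame.pdb --out pockets.tsv --box 0,0,0,32.25,26.25,37.5
tmrepack dock-assign --poses-pdb poses.pdb --scores poses.tsv \
    --sites sites.yaml --out assignments.tsv
tmrepack seqid --fasta-a human.fasta --fasta-b mouse.fasta --out identity.json
```

All tables are TSV with `#`-comment parameter headers; `demo` writes a
`manifest.json` recording every tunable parameter, the seed and stage status,
and is byte-reproducible for a fixed (config, seed).

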