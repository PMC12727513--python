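# rsk — catalytic-motif scaffolding & evaluation toolkit

`rsk` implements the bespoke computational stages of a catalytic-motif
scaffolding workflow for de novo enzyme design, together with the full
design-evaluation and kinetics metric suite used to rank and
characterize the resulting designs.  The external deep-learning and
force-field stages (sequence design, relax, structure prediction,
backbone diffusion) are *not* bundled: they are pluggable adapter
contracts with deterministic offline stubs, so the whole package
builds, runs and tests without network access or GPUs.

## What's inside

| module | role |
| --- | --- |
| `rsk.structio` | structure data model, PDB I/O (multi-model, altloc resolution), Kabsch superposition, RMSD, neighbor counting |
| `rsk.motiflib` | artificial motif libraries: rotamer inversion (functional groups fixed, backbone solved), phi/psi-compatible rotamer selection, helical-fragment placement, exact clash-free combinatorial assembly, probability/abundance ranking, multi-model PDB + JSON serialization |
| `rsk.pocket` | entry-channel placeholder helix placement, flat-bottom pocket potential with analytic gradients (usable as a per-step guiding-potential callback), ligand burial and backbone–ligand clash metrics, placeholder stripping |
| `rsk.refine` | deterministic refinement-loop skeleton: harmonic coordinate-constraint records (text round trip), stage adapters + stubs, z-score composite top-k selection |
| `rsk.evaluate` | motif RMSDs with symmetric-naming resolution, SAP (Shrake–Rupley SASA), core contacts, OLS stability regression, composite active-site metric, ensemble RMSF / H-bond / functional-group metrics, Michaelis–Menten and two-pKa fits, kinetic-resolution selectivity relations, SAXS descriptors |
| `rsk.fixtures` | seeded synthetic generators for every input: toy rotamer library, ideal helical fragments, constructed catalytic arrays (retro-aldolase tetrad, MBH triad), jittered ensembles, synthetic metric/kinetics tables |

## CLI

Everything is reachable through the `rsk` entry point; each command
prints JSON.

```bash
rsk fixtures make ra_tetrad --seed 0 --out demo/      # motif library from the toy tetrad
rsk motiflib build --array mbh_triad --out library.pdb
rsk pocket place-helix --out complex.pdb              # assembly + placeholder helix
rsk pocket burial complex.pdb --ligand Z:500 --cutoff 8
rsk pocket check-grad --n 100 --seed 1                # gradient vs central differences
rsk refine run --n-designs 8 --n-cycles 3 --stub jitter --seed 7
rsk eval mm-fit rates.csv                             # concentration,rate columns
rsk eval ph-fit profile.csv                           # pH,rate columns
rsk eval selectivity --e-value 4 --conversion 0.3
rsk eval stability-fit metrics.csv                    # + midpoint column
rsk eval sap model.pdb
rsk eval saxs model.pdb
rsk rmsd reference.pdb model.pdb --selection backbone
```

Input formats: PDB for coordinates (multi-model for ensembles and
libraries), TSV for rotamer libraries
(`identity phi psi probability chi1..chi4`) and fragment sets
(`fragment_id residue_index atom_name x y z phi psi anchor_index
abundance`), two-column CSV for kinetics tables.

## Notes on conventions

- Distance-cutoff boundaries are inclusive (d ≤ cutoff).
- Clash criterion: d < γ·(r_i + r_j) with γ = 0.75 and standard vdW
  radii (configurable).
- Altlocs resolve to the highest-occupancy conformer (tie → first in
  file); hydrogens are parsed but excluded from heavy-atom metrics.
- Assembly ranking: `w_rot·mean(log p) + w_abund·mean(log(abundance+1))`,
  ties broken by insertion order; all pipelines are deterministic given
  a seed.
- The pocket potential is a flat-bottom quadratic
  `E = w·Σ max(0, d−r₀)²` of backbone-atom distances to a centre point
  on the placeholder helix (r₀ = 12 Å, w = 1 by default).
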