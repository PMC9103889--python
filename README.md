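# cosolvmap

Analysis tooling for cosolvent ("mixed-solvent") MD trajectories of a protein
plus many copies of a small probe molecule. Instead of asking which probes a
given protein binds, it profiles which *protein residue environments* a given
probe prefers:

1. **PMAP** — probe heavy atoms from every snapshot of a run are binned into
   1 Å voxels; values outside a 5 Å shell around the protein are discarded and
   the rest scaled to unit total.
2. **max-PMAP** — the per-voxel maximum of the PMAPs across independent runs
   (compensates under-sampling of deep pockets; its shell sum is ≥ 1).
3. **Preferable surface** — voxels where max-PMAP ≥ 0.2 (inclusive).
4. **Residue environments** — for every snapshot, each probe copy with a
   heavy atom on the preferable surface is extracted along with all residues
   having at least one heavy atom within 4 Å of any probe heavy atom.
5. **Interaction profile** — every environment is rigidly superposed onto a
   reference probe (minimum RMSD over the probe's symmetry-equivalent atom
   orderings; proper rotations only) and the Cβ atoms (or any chosen atom) of
   surrounding residues are binned per residue type (acidic / basic /
   hydrophilic / hydrophobic / aromatic; glycine excluded) into 1 Å grids.
6. **Stability filter** (optional) — keeps only poses whose heavy-atom
   centroid moved strictly less than 3 Å over the preceding 500 ps
   (minimum-image corrected).

Grids are exported as OpenDX text files (readable by PyMOL/VMD/Chimera) with
JSON geometry sidecars. A synthetic-data module generates toy protein+probe
trajectories with planted hotspots and known residue geometry, so the entire
pipeline is testable without running MD.

## CLI

One entry point, `cosolvmap`, with subcommands `simulate`, `fit`, `pmap`,
`maxpmap`, `surface`, `profile`, `filter`, and `run-all`. A typical
synthetic end-to-end session:

```bash
# generate 20 pseudo-runs with a planted hotspot + truth.json + config.yaml
cosolvmap simulate --outdir sim --seed 1

# full pipeline: fit -> PMAPs -> max-PMAP -> surface -> environments -> profile
cosolvmap run-all --config sim/config.yaml --outdir out
```

`out/` then holds `pmap_run*.dx`, `max_pmap.dx`, `surface.tsv` (+ a voxel
pseudo-PDB), one `profile_<type>.dx` per residue type, a reference-probe PDB
for superposition in viewers, and `manifest.json` with parameters and
per-stage counts. Exit codes: 0 success, 2 configuration error, 3 data error.

Real trajectories are supplied as multi-model PDB files (MODEL/ENDMDL; probe
copies identified by residue name, orthorhombic CRYST1 box, pre-imaged).
Probe presets (template geometry, alignment atoms, symmetry mappings) ship
for benzene, catechol, and benzamidine; custom probes go in the YAML config.

Configuration is YAML; an empty file gives the protocol defaults (1 Å
spacing, 5 Å shell, θ = 0.2, 4 Å environment cutoff, 500 ps / 3 Å stability
rule, 20–40 ns window every 10 ps, 20 runs). See `cosolvmap.config.RunConfig`.

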