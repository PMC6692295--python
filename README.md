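# filadyn

Analysis pipeline for helical protein filaments and their subunits:

- **Filament assembly** — build an N-subunit helical filament from a single
  protomer and rise/twist symmetry parameters (+Z screw axis), select axial
  slices, and validate construction by consecutive-interface RMSD.
- **Elastic-network normal modes** — anisotropic network model on C-alpha
  atoms (15 A cutoff default), low-frequency modes by dense or shift-invert
  sparse eigensolvers, mean-square-fluctuation profiles, per-subunit
  averages (excluding the first 24 residues by default), mode character
  classification (bend / twist / stretch) and a per-position significance
  test for fluctuation differences (t-test p < 0.001, effect > sigma,
  run length >= 3).
- **Ensemble comparison** — Kabsch superposition, per-residue RMSD profiles
  of model ensembles against a reference (or the iterative ensemble mean),
  and detection of residue regions with significant RMSD differences
  (p < 0.001, |dRMSD| > 0.5 A, run length >= 3).
- **NMR relaxation** — Lipari-Szabo model-free analysis of 15N T1/T2/NOE
  under a fully anisotropic rotational diffusion tensor (Woessner five-term
  spectral density), per-residue fitting over the m1-m4 model ladder,
  diffusion-tensor estimation from T1/T2 ratios of rigid residues, and
  weighted-average chemical-shift perturbations (15N weight 0.159).
- **HDX-MS** — deuterium-uptake forward model, relative fractional uptake
  (78.6% deuterium fraction for the default 15 uL + 55 uL mix, no
  back-exchange correction), two-state comparison with per-peptide Wald
  tests (BH-adjusted, alpha 0.01) and major/minor classification
  (>10% / 5-10% maximum uptake difference).
- **Synthetic data** — deterministic generators for every input: a
  pilin-like protomer (long N-terminal helix + compact head), perturbed
  coordinate ensembles, relaxation tables from known (S2, tau_e, Rex) and
  tensor, and replicate HDX uptake tables from per-residue exchange rates.

## Command-line usage

All stages are subcommands of a single entry point:

```sh
filadyn simulate protomer --seed 1 -o work/          # synthetic protomer PDB
filadyn build-filament --protomer work/protomer.pdb \
    --rise 10 --twist 85 --n 30 -o work/pilus.pdb
filadyn anm --model work/pilus.pdb --cutoff 15 --modes 3 -o work/msf.tsv
filadyn compare --ensemble-a a/*.pdb --ensemble-b b/*.pdb \
    --reference ref.pdb --select 27:130 -o work/regions.tsv
filadyn modelfree --relax relax.tsv --structure monomer.pdb \
    --tensor auto -o work/modelfree.tsv
filadyn csp --shifts-a a.tsv --shifts-b b.tsv -o work/csp.tsv
filadyn hdx --state-a hdx_A.tsv --state-b hdx_B.tsv --alpha 0.01 -o work/cmp.tsv
filadyn demo --seed 0 -o work/demo                   # full synthetic pipeline
```

`filadyn demo` runs every stage on synthetic data and writes a filament
PDB, global/local MSF tables, mode labels, a delta-RMSD region table, a
model-free fit table and tensor, a CSP table, HDX comparison tables, and
a manifest (seed + config hash). Outputs are byte-identical across runs
with the same seed.

### Input formats

- Coordinates: PDB (C-alpha level is sufficient; N/H atom pairs are used
  for N-H vectors when present).
- Relaxation: TSV with columns `residue, T1, T1_err, T2, T2_err, NOE, NOE_err`
  (T1/T2 in seconds).
- Chemical shifts: TSV with `residue, dH, dN` per state.
- HDX uptake: TSV with `start, end, sequence, time_min, replicate, uptake_Da`
  per state (flattened cluster-export dialect, one row per
  peptide x time x replicate).

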