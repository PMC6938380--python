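# homodel

Desk-scale homology modeling by satisfaction of spatial restraints.

`homodel` builds protein 3D models from target–template alignments using
Gaussian homology-derived distance restraints (HDDRs), and provides the
full experimental machinery to study how restraint parameters control
model quality:

- **Restraint building** for four atom groups (CA-CA, backbone N-O,
  side chain/main chain, side chain/side chain) from PIR or aligned-FASTA
  alignments plus PDB template coordinates, with per-template
  (distance, sigma, weight) mixture entries and uniform / similarity /
  only-lowest weighting schemes.
- **Optimal sigma theory**: when the native structure is known, the
  likelihood-maximizing sigma for each restraint is
  `|d_native − d_template|` (floored at 0.05 Å), and the optimal
  multi-template parameterization puts all mixture weight on the template
  with the smallest sigma ("only-lowest"). Both facts are verified by
  brute-force grid-search oracles in the test suite.
- **Controlled-noise estimator simulation**: Laplace-noise perturbation of
  signed deltas with a 5000-trial linear sweep of the scale parameter,
  selecting the trial whose Pearson correlation with the unperturbed values
  is closest to a requested target (typically within 0.003), followed by
  mean rescaling that interpolates between the pair's observed mean and a
  per-group global mean.
- **Composite objective** `F_TOT = F_PHYS + F_HOM + w_SP · F_SP` with
  analytic gradients: simplified stereochemical terms (harmonic bonds and
  angles, soft-sphere repulsion), the restraint mixture negative
  log-likelihood, and a cubic-spline pairwise statistical potential with an
  8 Å contact shell (a built-in toy potential is provided; real tables load
  from TSV).
- **Optimization**: conjugate gradients, seeded Metropolis annealing, and a
  final quench, with an objective ceiling that reproduces the failure mode
  of quasi-singular (unfloored) sigmas. Multi-decoy builds average scores
  over independently seeded decoys.
- **Evaluation**: GDT-HA (heuristic superposition search, oracle-bounded on
  toys), distance-only lDDT, and CA RMSD.
- **Synthetic data**: toy native/template pairs with controlled backbone
  divergence and alignment register errors, so the whole stack runs offline.

## CLI

All functionality is reachable through one entry point:

```bash
# generate a 20-target synthetic benchmark corpus
homodel simulate --n 20 --seed 1 --out corpus/

# build 16 decoys with optimal restraint parameters
homodel build --aln corpus/target000.pir \
    --templates corpus/target000_template1.pdb \
    --native corpus/target000_native.pdb \
    --sigma optimal --decoys 16 --seed 1 --out models/

# optimal sigma profile for a target/template pair
homodel optimal-sigma --native n.pdb --template t.pdb --aln a.pir --out sig/

# perturbed-sigma restraint sets across a PCC grid
homodel perturb-sweep --native n.pdb --template t.pdb --aln a.pir \
    --pcc-grid 0.0:0.9:10 --sets 5 --seed 1 --out perturbed/

# score decoys against a native
homodel score --models models/ --native n.pdb --out report/

# YAML-configured corpus experiment
homodel experiment --config exp.yaml --out results/
```

Every subcommand writes a `run_manifest.json` (version, resolved config,
seeds, output digests) into its `--out` directory.

An experiment YAML looks like:

```yaml
manifest: corpus/manifest.tsv
decoys: 2
seed: 11
conditions:
  - {name: uniform1, strategy: uniform, uniform_sigma: 1.0}
  - {name: optimal, strategy: optimal}
  - {name: pcc0.5, strategy: perturbed, pcc_sel: 0.5, n_sets: 5}
```

## Layout

```
src/homodel/
  io_formats.py      PDB / PIR / aligned-FASTA I/O, residue correspondence
  restraints.py      HDDR building, Gaussian mixtures, weighting schemes
  optimal_sigma.py   optimal sigma / only-lowest parameterization
  perturbation.py    Laplace b-sweep, mean rescaling, PCC_MODEL
  energy.py          F_PHYS / F_HOM / F_SP and analytic gradients
  optimizer.py       CG + annealing builds, decoy generation
  quality.py         superposition RMSD, GDT-HA, lDDT
  synthetic_data.py  toy fold generator and corpus writer
  experiments.py     corpus-level experiment orchestration
  cli_app.py         click CLI
```
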