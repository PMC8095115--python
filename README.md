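# ligprof

Trajectory-ensemble profiling of protein–ligand binding sites:
per-residue contact fingerprints, ligand selectivity, headgroup
minimum-distance series, symmetry-aware ligand RMSD, frame-averaged
atomic density maps with map–map correlation, and water-bridge
occupancy.

`ligprof` is aimed at structural biologists who have multi-frame
ensembles (molecular-dynamics trajectories, multi-model PDB files) of a
— possibly homo-multimeric — channel or receptor with a bound lipid or
small-molecule ligand, and want to answer questions like: *which
sidechains contact the phosphoinositide headgroup persistently? which of
them prefer one ligand over another? how stable is the bound pose per
subunit? does the computed ligand density match an experimental map? is
there a water-mediated hydrogen bond between a residue and the ligand?*

## The quantities it computes

For an ensemble of `T` frames over a tetramer with one bound ligand per
subunit `s`:

- **Contact frequency** of residue `r`:
  `f_s(r) = (1/T) Σ_t 1[ min_{i∈side(r), j∈head} ‖x_i − x_j‖ ≤ c ]`
  with cutoff `c = 5 Å` (closed boundary), sidechain heavy atoms versus
  ligand headgroup heavy atoms only; combined over subunits as
  `f(r) = mean_s f_s(r)`.
- **Selectivity** between ligands A and B at threshold 0.5: residue `r`
  is selective for A iff `f_A(r) ≥ 0.5 > f_B(r)`, shared iff both pass;
  the cumulative value `f_A(r) + f_B(r) ≤ 2` supports stacked-bar
  fingerprints.
- **Minimum-distance series** `d_s(r, t)` over the same atom pairs,
  subunit-averaged, with a report that flags residues whose mean
  separation exceeds a reference residue's by a margin (default 4 Å).
- **Ligand RMSD versus the initial configuration**: per frame and
  subunit, superpose on the local Cα cage (Kabsch, proper rotation),
  then `RMSD(t, s) = sqrt(mean_i ‖x_i(t) − x_i(0)‖²)` over ligand heavy
  atoms without further fitting.
- **Atomic density maps**: each heavy atom deposits an isotropic
  Gaussian (σ = 1.0 Å "atom size") on a 0.5 Å grid, normalised so its
  discrete integral equals its mass (or 1 in occupancy mode); frames are
  combined by averaging. Two maps are compared by correlation about zero
  after trilinear resampling (for two unit Gaussians offset by δ this is
  `exp(−δ²/4σ²)`); the about-mean Pearson coefficient is also reported.
- **Water bridges**: a frame counts as bridged when some water oxygen is
  within 3.5 Å of both a polar (N/O) sidechain atom of the residue and a
  polar atom of the ligand; the occupancy map variant deposits waters
  within 6 Å of both anchors.

A seeded synthetic-data module generates C4-symmetric tetramer
ensembles with *known* designed contact probabilities, pose-noise levels
and bridge occupancy, so every stage can be validated against ground
truth (see `docs/methods.md`).

## Worked example

```python
from ligprof import contact_frequencies, classify_selectivity, rmsd_series
from ligprof.synthetic import SyntheticSpec, generate_study, ligand_spec_for

spec = SyntheticSpec(n_frames=1000, seed=42)   # the default study design
ensembles, truth = generate_study(spec)

profiles = {
    label: contact_frequencies(ensembles[label], ligand_spec_for(spec, label))
    for label in spec.ligands
}
report = classify_selectivity(profiles["PI"], profiles["PIP2"], threshold=0.5)
print("selective for PI:", [f"{n}{s}" for s, n in report.selective_a])
print("shared:", [f"{n}{s}" for s, n in report.shared])

for label in spec.ligands:
    r = rmsd_series(ensembles[label], ligand_spec_for(spec, label))
    print(f"{label}: time-averaged ligand RMSD {r.time_average:.2f} A")
```

prints

```
selective for PI: ['LEU501', 'ILE502', 'VAL503', 'PHE504', 'MET505', 'SER506', 'THR507', 'ALA508']
shared: ['TYR509', 'TRP510', 'GLU511', 'ASP512', 'LYS513', 'ARG514', 'PRO517', 'GLN519']
PI: time-averaged ligand RMSD 0.86 A
PIP2: time-averaged ligand RMSD 3.44 A
```

The eight selective residues are exactly the designed p = 0.9 / 0.1
set; the shared list is the designed 0.9 / 0.9 set plus the pinned
near-probe and bridge residues; and the RMSD averages sit at
`σ·√3` for the designed pose noise (σ = 0.5 Å for PI, 2.0 Å for PIP2),
i.e. the "stable" species is correctly ranked below the "unstable" one.

The same analyses are available from the shell:

```bash
profiler simulate --out fixtures/                  # write study fixtures
profiler contacts --ensemble fixtures/PI.pdb \
    --ligand fixtures/PI.ligand.yaml --ligand-resnames PI --out PI.tsv
profiler selectivity --a PI.tsv --b PIP2.tsv --out selectivity.tsv
profiler run --config config.yaml                  # full pipeline
```

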