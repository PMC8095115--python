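# Methods

This note documents the models and procedures implemented in `ligprof`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not
demonstrate.

## Data model and conventions

An ensemble is `T` frames of `N × 3` Cartesian coordinates in Å over a
fixed topology; frame 0 is the reference ("initial") configuration.
Coordinates are used exactly as stored: no periodic-boundary imaging is
ever applied, so trajectories must be pre-imaged (the bounding-box
check `Ensemble.check_bounding_box` flags frames whose diagonal exceeds
a configurable limit, the usual symptom of an un-imaged frame).
Residue numbering is taken verbatim from the input (1-based PDB
convention). Hydrogens are kept in the data model but excluded from all
distance and density analyses; masses come from a built-in element
table, never from PDB occupancy/B-factor columns. Water residues are
recognised by name ({HOH, WAT, TIP3, SOL}, configurable). Protein atoms
split into backbone ({N, CA, C, O, OXT}) and sidechain by atom name —
consequently glycine has no sidechain heavy atom and can never register
a sidechain contact; this is deliberate and documented rather than
patched with backbone atoms.

Supported formats: multi-model PDB (biotite; all models must have
identical atom counts and order — violations abort with the offending
model named), a plain `frame atom_id x y z` table with a TSV topology
sidecar, and OpenDX scalar grids for density maps (gridDataFormats;
non-uniform spacing rejected). Binary trajectory codecs (DCD/XTC) are
out of scope; convert externally.

## Contact fingerprints and selectivity

A residue contacts the ligand in a frame iff the minimum distance
between its sidechain heavy atoms and the ligand's heavy headgroup
atoms is ≤ the cutoff (default 5.0 Å, closed boundary, so a pair at
exactly the cutoff counts). The headgroup must be named explicitly by
atom names — there is no chemical perception of "the polar part", and
for real systems the user must supply the atom list. The neighbor
search uses a k-d tree (scipy `cKDTree`) whose closed-ball query
matches the contact definition; its equivalence with brute-force O(N²)
enumeration is asserted in tests over seeded random frames.

Per-subunit frequencies are combined as the arithmetic mean over the
symmetry-related subunits (`subunit_mean`); `frame_pooled` (pool all
subunit-frames, then divide) is provided as an option, and the two
coincide whenever every subunit contributes every frame. Ligands pair
with protein subunits same-chain by default; inter-subunit sites need
an explicit pairing map. Selectivity classification applies the
threshold (default 0.5 — contact in at least half the frames) to the
*combined* frequencies of two profiles computed with the same cutoff
and combine mode, partitioning residues into selective-A, selective-B,
shared and neither; cumulative values `f_A + f_B ≤ 2` support stacked
fingerprint plots.

## Distances, superposition, RMSD

Minimum-distance series use the same sidechain-heavy × headgroup-heavy
pair minima per frame and subunit; a residue without sidechain heavy
atoms produces a per-residue error entry rather than a batch failure.
The mean-separation report sorts residues by time/subunit-averaged
distance and can flag residues more than a margin (default 4 Å) farther
than a reference residue — the screen for discarding apparently
contacting but actually remote residues.

Superposition is least-squares optimal (Kabsch) via scipy's
`Rotation.align_vectors`, which guarantees a proper rotation
(determinant +1, reflections corrected on the smallest singular axis).
Fewer than three points or near-collinear references (second singular
value ≤ 1e-8 of the largest) raise a degenerate-geometry error.
Superposition is unweighted by default; mass-weighting is available via
the `weights` argument.

Ligand RMSD versus frame 0 is computed per subunit: superpose the frame
onto the reference using that subunit's alignment atoms, then measure
heavy-atom RMSD of the target with no further fitting. The default
alignment selection is the subunit's Cα atoms within 15 Å of the target
in the reference frame — a local cage that removes global drift without
absorbing pose motion. A `global` mode (one whole-complex alignment per
frame) is provided because either convention is defensible for a
C4-symmetric complex; outputs record which was used, and per-subunit is
the default.

## Density maps, correlation, water bridges

"Resolution" is interpreted as the grid spacing (default 0.5 Å) and
"atom size" as the σ of an isotropic Gaussian kernel (default 1.0 Å),
truncated at 4σ and normalised per atom so that kernel sum × voxel
volume equals the atom's weight — atomic mass by default, 1 in
occupancy mode. The grid covers the selection's bounding box over *all*
frames, padded by 4σ, with the origin snapped to a spacing multiple;
because the grid is frame-independent, the `T`-frame map equals the
voxel-wise mean of per-frame maps exactly, and the single-frame map
integral equals the summed weight exactly (the 4σ truncation is
absorbed by the per-atom normalisation).

Map agreement resamples map B onto map A's grid by trilinear
interpolation and reports two statistics. The primary `correlation` is
computed about zero, `∫AB / sqrt(∫A²∫B²)` (with `∫B²` on B's native
grid so density outside A's extent still normalises), which is the
default convention of volume-comparison tools and has the closed form
`exp(−δ²/4σ²)` for two equal Gaussians offset by δ — the package's
quantitative oracle. The secondary `correlation_about_mean` is the
Pearson coefficient over voxels where `max(A,B)` exceeds the mask
threshold; it reaches −1 for a map reflected about its mean, but its
value depends strongly on how much empty space the mask admits, which
is why it is not the primary score.

The water-bridge criterion is purely distance-based: a frame (per
subunit) is bridged iff some water oxygen lies within `d_bridge`
(default 3.5 Å, a conventional heavy-atom donor–acceptor distance) of
both a polar (N/O) sidechain heavy atom of the residue and a polar
heavy atom of the ligand. No angular term is applied; with coordinates
but no explicit hydrogen-bond geometry this is the robust choice, and
angular refinement is out of scope. The water occupancy map instead
uses a 6 Å shell around *all* heavy atoms of both anchors and deposits
qualifying water oxygens with weight 1, so the map integral estimates
the mean number of simultaneously-near waters per frame.

## The synthetic study generator

The generator emulates the study design the analyses exist for: a
C4-symmetric homotetramer (subunits are 90° rotations about z) with one
ligand per subunit, two ligand species with contrasting pose stability,
designed residue–ligand contact statistics, and a water bridge of known
occupancy. Geometry is deliberately schematic — each residue is a
4-atom backbone proxy on a fixed scaffold plus a 3-atom sidechain
proxy, the ligand a 3-atom polar headgroup (P1/O1/O2) plus an apolar
tail — because the analyses are purely geometric and what matters is
exact, known ground truth.

Key mechanisms:

- **Exact Bernoulli contacts.** Per frame/subunit, each residue's
  sidechain is placed along its own direction `u_r` at a drawn distance
  `d` from the headgroup atom with the largest projection onto `u_r`
  *after* ligand jitter. This anchor choice guarantees the designed `d`
  *is* the pairwise minimum distance, so with `d ~ U(2.8, 4.2)` inside
  the 5 Å shell (probability `p`) and `d ~ U(6.8, 10.0)` outside,
  empirical contact frequencies are exact Bernoulli(`p`) samples at any
  ligand noise level.
- **Distance probes.** Selected residues instead draw
  `d ~ N(mean, 0.3 Å)` (defaults 3 Å and 8 Å), giving designed mean
  separations the distance report must recover.
- **Pose noise.** Ligand atoms receive i.i.d. per-coordinate Gaussian
  jitter of the species' σ for frames ≥ 1; frame 0 is the clean
  reference, so `E[RMSD²] = 3σ²` and the time-averaged RMSD is `σ√3`
  up to chi-distribution corrections. Defaults: σ = 0.5 Å ("stable"
  species PI) versus 2.0 Å ("unstable" species PIP2).
- **Water bridge.** One water per subunit toggles with designed
  occupancy (default 0.7) between the midpoint of the bridge residue's
  sidechain oxygen and a headgroup oxygen (≤ 2.3 Å from each, so the
  3.5 Å criterion always fires) and a remote position 9 Å away (so it
  never fires). The bridge residue is pinned inside the contact shell
  (effective contact probability 1) to keep the bridging geometry
  feasible in every frame; the ground truth records it as such.
- **Determinism.** All randomness derives from one seed through
  per-(species, frame, subunit) `SeedSequence` substreams with a fixed
  draw order, so fixtures are byte-identical across runs and
  independent of generation order.

Defaults are the study conditions: T = 1000 frames, 4 subunits, 24
residues per subunit, 8 residues selective for PI (p = 0.9 vs 0.1), 6
shared (0.9/0.9), 2 selective for PIP2, background p = 0.1, protein
scaffold noise 0.05 Å, bridge occupancy 0.7.

What passing tests on this generator show — and what they do not: they
validate the *measurement machinery* (search correctness, estimator
consistency at the O(T^-1/2) binomial rate, closed-form RMSD and
density behaviour, determinism) under known ground truth. They do not
show that real trajectories are well sampled, that 5 Å/50% thresholds
are optimal for a given system, or anything about force-field quality;
the proxy residues have no covalent connectivity between sidechain
positions in consecutive frames, and real sidechains move continuously.

## Problem sizes and numerical choices

Test and acceptance runs use T = 1000 frames for statistical recovery
(binomial 3σ envelopes at the per-trajectory frame count), 500 frames
with a 100-heavy-atom ligand for the RMSD noise law, 100 seeded
replicates of T = 30 for the stability-ordering contrast, and 100
random ≤200-atom frames for brute-force equivalence — sizes at which
every designed effect is resolved with wide margins while the full
suite runs in well under a minute. Ties at the contact cutoff count as
contact (closed boundary); all analysis thresholds are echoed into
pipeline outputs; stage wall-times are logged to `pipeline.log`, which
is excluded from byte-determinism comparisons since timing is the one
legitimately non-reproducible output.

## Known limitations

- Contact fingerprints are sidechain-only and per-residue; per-atom
  fingerprints and interaction typing (beyond the water bridge) are out
  of scope.
- The bridge criterion has no angular term and treats all N/O atoms as
  polar regardless of protonation.
- BRIX-format reference maps are not ingested; convert to OpenDX
  externally. Pocket-geometry (pore-profile) analysis is not provided.
- The about-mean Pearson map score is sensitive to the mask threshold;
  comparisons should fix it explicitly when reporting that statistic.
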