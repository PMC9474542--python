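# Methods

## Scope and model

`fibrilsite` quantifies how a small planar ligand (the built-in topology
is anle138b, 3-(1,3-benzodioxol-5-yl)-5-(3-bromophenyl)-1H-pyrazole,
21 heavy atoms: 16 C, 2 N, 2 O, 1 Br) engages the tubular cavity of a
cross-beta protofilament. The fibril is represented as a stack of
beta-strand layers ("rungs"); all analyses are expressed in terms of
that layer structure. The package analyses coordinate series
(MD-trajectory-like input); it does not run dynamics itself, and it
treats the protein as rigid in the ligand-centric analyses (contacts,
bonds, depth) while protein-coordinate ensembles are used for RMSF.

Lengths are nanometres everywhere inside the package; PDB/XYZ I/O
converts from/to Angstrom at the boundary. Times are nanoseconds,
energies kJ/mol, temperatures K.

## Geometry

**Protofilament axis.** The stacking axis is the normalised mean of
backbone N->H unit vectors of every second residue in the folded
N-terminal part of the fold (defaults: start residue 36, stride 2,
span 36-56), oriented from layer 0 toward the last layer. In a parallel
in-register cross-beta stack these amide vectors point along the
stacking direction; the stride skips the alternating residues whose NH
points the other way. The exact endpoint of the "folded N-terminal part"
is a free choice; 36-56 covers the contiguous N-terminal beta region and
is configurable.

**Insertion depth x.** Euclidean distance between the mass-weighted
centre of mass of the ligand pyrazole ring and the mass-weighted COM of
the tip (edge) beta-strand layer. Mass weighting uses standard atomic
masses; hydrogens are included when present (whether the original
analysis used mass-weighted or geometric centroids is not determinable
from the inputs; the two differ negligibly for these rigid groups). The
tip defaults to layer 0; profiles from either tip are mirror images.

**Equilibration trimming.** `discard_equilibration` removes the first
`floor(fraction * n_frames)` frames of each trajectory independently;
the default fraction 0.25 keeps the last 75% of the data.

**RMSF.** Per-atom RMSF is the root time-mean squared deviation from the
time-mean position, computed after (optional) least-squares Kabsch
superposition of the non-edge-layer backbone onto the first retained
frame. Deviations are accumulated relative to the first frame so a
static trajectory yields exactly zero. Per-residue values average the
residue's backbone heavy atoms (N, CA, C, O); strand-class averages
("contact" vs "non_contact" layers) exclude the two edge layers, whose
fraying is an end artefact. SEM is across independent trajectories.
For independent isotropic Gaussian jitter of width sigma the per-atom
RMSF closed form is sigma * sqrt(3), used as a calibration check.

## Contacts and polar bonds

Two contact rules are implemented, both with defaults matching the
standard fibril-ligand mapping protocol:

* heavy-atom contact: any ligand heavy atom within **0.40 nm** of any
  heavy atom of a residue ("heavy" is decided by element, never by atom
  name). The per-frame count of ligand heavy atoms in contact feeds the
  binding-mode classifier.
* pyrazole-nitrogen rule: either pyrazole N within **0.50 nm** of any
  backbone carbon or nitrogen of a residue (mirrors an NMR isotope
  labelling scheme). CA counts as a backbone carbon by default
  (`include_ca=False` restricts to C and N; the narrower reading of
  "backbone carbon" cannot be excluded).

Contact probabilities are averaged over time first, then over the
independent trajectories (so trajectories of unequal length weigh
equally). Edge layers are excluded by default.

**Hydrogen bonds** are geometric: donor-acceptor heavy-atom distance
<= 0.35 nm and D-H...A angle >= 150 deg (both configurable). Ligand
donors are the declared donor hydrogens (pyrazole N-H); ligand acceptors
are the pyrazole nitrogens and benzodioxole oxygens; protein donors and
acceptors are backbone N-H and C=O, plus sidechain O/N acceptors behind
a flag. HB *energies* are reported through a pluggable model whose
default is an explicitly non-canonical smooth surrogate
(E = -V0 cos^2(180 - theta) exp(-(r - r0)/rho), V0 = 20 kJ/mol,
r0 = 0.28 nm, rho = 0.06 nm, clamped at -V0); classification never
consumes the energy, only bond presence.

**Halogen bonds**: Br...O(carbonyl) distance <= 0.36 nm and C-Br...O
angle at the bromine >= 150 deg, where 180 deg is perfectly linear (the
only convention under which a ">= 150 deg" near-linearity criterion is
meaningful).

Neighbour searches use a k-d tree; the test suite checks exact agreement
with an all-pairs brute force. Inputs are assumed whole/unwrapped; no
minimum-image handling is applied.

## Binding modes

Per frame: **I** unbound (zero heavy-atom contacts), **II** partially
bound (fewer than half of the 21 ligand heavy atoms in contact, i.e.
<= 10), **III** bound without polar bonds (>= 11 atoms in contact, no
HB/XB), **IV** polar (>= 1 HB or XB), subtyped IVa (pyrazole HB), IVb
(benzodioxole HB), IVc (bromophenyl XB). The presence of a polar bond
dominates: a frame with a bond is IV even below the half-contact
threshold, since mode IV is defined by bond presence without a
contact-count qualifier. Populations are trajectory means of
per-trajectory frame fractions; the four major modes always sum to 1.

## Free-energy profile

Pooled insertion-depth samples are binned (default width 0.05 nm, about
a tenth of the 0.48 nm layer spacing, resolving per-layer minima; the
upstream protocol states 1-d bins without a width) and Boltzmann
inverted: G_i = -RT ln(n_i / n_total) with T = 300 K
(RT = 2.4943 kJ/mol). The profile is shifted so its minimum over
populated bins is zero; zero-count bins are masked (NaN), never reported
as G = 0. SEM is across per-trajectory profiles referenced to the pooled
minimum bin (block averaging is not used; the independent trajectories
are the natural replicates). A trajectory that does not populate a bin
is excluded from that bin's SEM.

Note on binned estimators: within a bin the estimator returns the
Boltzmann average of the potential, not its value at the bin centre, so
sharp kinks are softened by up to ~(slope * width)^2 / (24 RT). Round-
trip validations therefore either use plateau-aligned potentials or
reference both curves to the same populated-minimum bin.

## Dwell-time kinetics

The ligand's axial position (projection of the pyrazole-ring COM on the
fibril axis; the scalar depth can be substituted) is registered to a
lattice of sites one layer spacing apart. A hop is committed only when
the signal lies within the inner `core_fraction` (default 0.5) of the
new site's cell for at least `min_residence_frames` (default 1)
consecutive frames — a hysteresis rule that prevents boundary jitter
from fragmenting dwells. Dwells are the intervals between committed
hops; the first and last dwell of each trajectory are flagged censored
and excluded from means by default (they are truncated by the
observation window and bias the mean downward; a flag includes them).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the real inputs with exact
ground truth, not their physics:

* `build_toy_fibril`: layers are translated copies along +z at the
  canonical cross-beta rise (0.48 nm default); each residue carries
  N, H, CA, C, O and one sidechain pseudo-atom, with amide N-H parallel
  to the axis and N/O lining a channel of the requested radius. No
  twist, no realistic side chains, no sequence.
* `simulate_hopping`: a continuous-time Markov jump process over layer
  sites, sampled exactly (Gillespie), discretised at the frame interval
  (default 0.1 ns), then dressed with isotropic Gaussian jitter of the
  rigid ligand body. Because jitter is applied after discretisation, the
  returned dwell ground truth is exact, and dwell durations (censored
  tails included) tile the trajectory length exactly. Boundaries are
  rejection-style reflecting: at the end sites the outward rate is zero.
  This makes the stationary occupancy exactly uniform for symmetric
  rates, at the cost of a halved exit rate at the two end sites, so the
  event-mean dwell is 1/k + (2/k)/(n_sites - 1) rather than 1/k.
  Dwell-oracle validations therefore run on a long lattice (32 sites),
  where the edge term is ~3% against a 10% tolerance. Validations of
  transition-count recovery use a 0.02 ns frame interval: at a 0.5/ns
  exit rate, ~5% of jump pairs would fall inside a single 0.1 ns frame
  and be invisible to any detector (aliasing of the observation, not a
  detector property); at 0.02 ns the aliased fraction is ~0.5%.
* `sample_boltzmann_depths`: inverse-CDF sampling on a 4096-point grid
  of density proportional to exp(-G(x)/RT) for a piecewise-linear G.
* `generate_peak_tables`: free-state shifts are per-nucleus baselines
  (HN 8.3, N 119, CA 55, CB 35 ppm) with reproducible scatter; bound
  shifts add the configured per-nucleus CSP offsets on perturbed
  residues plus Gaussian noise; bound intensities are scaled by the
  attenuation factor and multiplicative lognormal noise (mean-one).
  Glycine-like residues omit CB rows. No peak overlap, no linewidth
  effects, no assignment errors.

All generators are bit-reproducible under a fixed seed. Passing tests
on these inputs demonstrate that the analysis transforms are correct
and self-consistent; they do not demonstrate force-field accuracy,
convergence of real trajectories, or spectral quality of real NMR data.

## NMR perturbation analysis

CSP per residue is the unweighted mean of |delta shift| over the nuclei
present in both states among HN, N, CA, CB (absolute values; a
nucleus-weighted variant is available behind `weights` but is not the
default, following the plain-average convention). Attenuation is the
bound/free intensity ratio per matched peak, averaged over nuclei; a
bound peak that disappeared while the free peak exists counts as ratio 0
(attenuated beyond detection, the physically meaningful reading), while
a missing or zero free peak makes the value undefined. The smoothing is
a missing-aware trailing moving average over consecutive residue numbers
(window 2 by default, reported at the first residue of the window;
sequence gaps count as missing).

## Validation problem sizes

The bundled validation suite and `scripts/acceptance.py` use: 120 random
frames of 25-100 atoms per side for the contact oracle; 1000 random
geometries each for the HB and XB criteria; 2x10^5 Boltzmann samples for
the profile round trip; 4 x 30000-frame hopping trajectories (0.02 ns
frames, 32 sites) yielding >= 1000 uncensored dwells; 10^4 frames for
the RMSF closed form; 64-residue paired peak tables. These sizes put
sampling error well below the assertion tolerances while keeping the
whole suite inside a couple of minutes on one CPU.

## Known limitations

* No periodic-boundary handling: trajectories must be whole/unwrapped.
* The protein is static in contact/bond/depth analyses; induced-fit
  effects are invisible.
* The HB energy scale is a labelled surrogate, not a validated
  empirical potential.
* No helical twist in the toy fibril; axis construction on strongly
  twisted polymorphs will average over the twist.
* Binary trajectory formats (XTC/TRR/DCD) are not read; convert to
  multi-model PDB or XYZ upstream.
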