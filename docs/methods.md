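# Methods

## Coordinate conventions and units

All coordinates are nanometres.  oxDNA-format files are converted at the I/O
boundary (1 oxDNA length unit = 0.8518 nm) and converted back on writing;
orientation versors are dimensionless and never scaled.  Configuration
timestamps are stored in microseconds via the coarse-grained time mapping
(τ_LJ = 0.7 ns per intrinsic unit); this is metadata only — no analysis
depends on the time scale.  Internally everything is 0-based; reports
(site ids, base-pair numbering) are 1-based.

The coarse-grained nucleotide is a rigid body: a stored position (treated as
the backbone interaction centre, 0.6 nm radially off the helix axis in the
ideal helix), a backbone→base versor `a1`, and a base-normal versor `a3`.
The base interaction centre is placed 0.56 nm from the position along `a1`,
i.e. essentially on the axis.  Paired strands of the ideal helix sit at
opposite azimuth, making the duplex pseudo-dyad an exact symmetry of the
construction.  Only the *relative* rigid geometry of the 20 anchor points
enters the docking superpositions, so deviations from the finer published
coarse-grained geometry cancel.

Pairing is not present in oxDNA topology files.  It is taken from the design
(`DesignMap.staple_topology_indices`) when available; otherwise a geometric
fallback pairs mutually nearest antiparallel, complementary base sites
within 0.15 nm, inferred from one configuration.

## Steric accessibility

**Docking template.**  `build_docking_template` superposes the crystal
duplex (one anchor per nucleotide: C1′, else P, else the residue centroid;
the central 10 bp if longer) onto the ideal 10-bp helix with the Kabsch
algorithm and applies the same transform to the enzyme's heavy atoms.  A
superposition RMSD above 0.5 nm triggers a warning (not an error): it
usually means the duplex chain assignment is wrong.

**Per-frame docking.**  For each site and frame the helix anchor set is
superposed onto the 10-bp window's nucleotide positions.  Side = scaffold
maps helix strand A onto the scaffold strand read 5′→3′; side = staple uses
the strand-swapped correspondence (A_i ↔ staple partner of scaffold bp
9−i), which is the pseudo-dyad flip of the duplex — verified in tests
against an explicitly constructed 180° flip matrix.

**Distance maps.**  Each particle (placed enzyme or environment) is
assigned to a cell (i, θ): i is the nearest window base-pair centre along
the site axis — particles beyond the 10-bp extent are clamped to the end
rows, so near-window clashes still count — and θ its azimuth in the site's
local frame, discretised into 72 bins of 5° (≈0.4 nm of arc at typical
helix–helix distances, finer than the particle spacing; configurable).
Distances are Euclidean from the assigned base-pair centre rather than from
a global axis line, which keeps rows meaningful when the site helix bends.
The site frame itself comes from the window: axis = principal direction of
the 10 bp centres oriented along the scaffold 5′→3′, origin = their
centroid, in-plane reference = the designated nucleotide's `a1` component
perpendicular to the axis.  Which nucleotide defines the reference is an
explicit argument (default: the first motif nucleotide) since any choice is
a convention.

**Environment.**  Every oxDNA interaction centre (backbone + base site) of
all nucleotides outside the site window plus a 2-bp margin along both
strands of the same duplex.  The margin exists because the window's own
helix must not self-block; 2 bp covers the clamped end rows.

**Classification and aggregation.**  A frame is accessible from a side iff
max < min in every cell; cells with no enzyme particle (max = −∞) or no
environment particle (min = +∞) never block.  Particles are points — the
criterion compares point distances, and adding radii would double-count
excluded volume.  Frames whose window contains an unpaired nucleotide are
skipped and counted separately, not scored inaccessible: scoring them would
conflate a structural defect with sterics.  Fractions (scaffold, staple,
and *both sides in the same frame*) are means of the per-frame booleans over
scored frames.

## Global mechanics

Alignment superposes every frame onto the **first frame** over the particle
selection (scaffold-only by default, so different structures are compared
with the same particle count); the mean structure is computed in a single
pass after alignment, not iteratively re-aligned — with ~10³–10⁴ frames the
iterate moves far less than the fluctuation scale.  RMSF is
√⟨‖r_i(t) − ⟨r_i⟩‖²⟩ per nucleotide.

The covariance spectrum is computed through the thin SVD of the (T, 3N)
deviation matrix, exact for the nonzero spectrum (rank ≤ T − 1) and far
cheaper than assembling C when 3N ≫ T; a brute-force dense-eigendecomposition
oracle checks it in the tests.  Eigenvector signs are fixed so each mode's
largest-magnitude component is positive, making collinearity patterns and
projections reproducible across platforms.  The total mean-square
fluctuation is the covariance trace = Σλ_n.

Cross-structure projection (e.g. a triangle trapezoid onto the isolated
trapezoid's first mode) requires a caller-supplied nucleotide index map;
nothing is matched automatically, to avoid silently misaligned selections.

**Free energy.**  F(bin) = −ln(count/total) in k_BT, offset so min F = 0,
over `n_bins` equal bins spanning the sample range (default 100 for ~10³-
frame projections; configurable).  Zero-count bins are masked, never
interpolated.  No kernel smoothing is applied anywhere — profiles are raw
histograms.

**Two-state statistics.**  Wells are strict minima of the masked profile
with prominence ≥ 0.5 k_BT (scipy `find_peaks`; the threshold suppresses
single-bin noise minima and is configurable); with fewer than two wells a
single-state result is returned.  The divider is the highest-F bin between
the two deepest wells; barriers are F(divider) − F(well); frames are
labelled by the side of the divider, giving populations, mean residence run
lengths, and divider-crossing counts.  An explicit divider can be supplied
to do the bookkeeping without well detection (used for planted or reference
coordinates).  Because well depths and the barrier top are read from single
bins, the estimate carries extreme-value noise ∝ 1/√(count per bin); with
5 × 10⁴ samples, ~50 bins keep the barrier-top counts ≳150 and the read-off
stable to ≲0.2 k_BT for barriers of a few k_BT.

## Synthetic scenes: what they emulate, and what they do not

*Duplex scenes* are ideal B-form helices (rise 0.34 nm, twist 360/10.5°)
with isotropic Gaussian jitter — no sequence-dependent structure, no base
breathing.  *Raft scenes* stand in for the local environment of an origami
site: a motif-bearing central duplex flanked by rigid parallel duplexes
whose surface-to-surface gap follows a per-frame schedule exactly.  Because
the helices are rigid rods, the block/clear label per frame is analytic —
a frame is clear iff (gap + 2·helix radius − 0.6 nm environment-particle
radius) ≥ probe radial extent — and the default geometry (gaps 0.5 / 10 nm
vs a 3-nm probe) leaves >1 nm of slack on both sides of that threshold, so
map discretisation cannot flip a label.  The central helix defaults to
14 bp so the 10-bp window plus the 2-bp exclusion margin covers it
completely: a site's own duplex must not occlude the enzyme.  *Two-state
scenes* plant a single collective coordinate from an overdamped
Euler–Maruyama double well U(s) = B((s²−a²)/a²)² (defaults B = 3 k_BT,
a = 2 nm; dt = 0.005 natural units, small against the stiffest curvature
8B/a²; recording every 30 steps ≈ one intra-well relaxation time, so frames
are roughly independent within a well) on top of a static structure, with
optional isotropic noise; the mode is orthogonalised against the six
rigid-body directions so superposition cannot absorb it.

Passing on these scenes demonstrates the correctness of the machinery —
format round-trips, superposition, spectra, Boltzmann inversion, docking
geometry, steric classification — not the realism of any force field: real
origami fluctuations are anharmonic, correlated across modes, and sequence
dependent, and real enzymes are flexible.

## Numerical choices

- Superposition degeneracy: second-smallest singular value of the centred
  reference < 1e-9 nm raises an error (collinear point sets have no unique
  rotation).  Reflections are excluded throughout.
- The attained RMSD is recomputed from residuals after the rotation;
  library-reported residual norms lose precision to cancellation near exact
  fits.
- θ values exactly on a bin edge go to the upper bin (floor of the scaled
  angle, clamped).
- Eigenvalues below 1e-10 nm² are treated as numerically zero in invariance
  comparisons.
- Synthetic-scene randomness uses `numpy.random.default_rng(seed)`
  exclusively; identical (parameters, seed) reproduce outputs byte-for-byte.

## Known limitations

- Enzyme flexibility, induced fit, energetic scoring, and kinetic rate
  constants beyond the accessible fraction r are out of scope; the enzyme is
  a rigid particle cloud.
- The cadnano reader handles the square-lattice dialect only and recovers
  routing/crossovers/sequence, not 3D coordinates (building coordinates from
  a design is an external converter's job).
- Pairing inference (geometric fallback) assumes duplex geometry close to
  the ideal construction; heavily distorted frames may need design-based
  pairing.
- Free-energy errors are histogram-level; no reweighting or enhanced-
  sampling estimators, and no error bars beyond bootstrap on profiles.
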