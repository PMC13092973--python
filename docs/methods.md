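# Methods

## The model

A particle field is a set of rigid bodies (ribosomes) in a tomogram
volume: positions in Angstrom, orientations as ZYZ intrinsic Euler angles
`(rot, tilt, psi)` in degrees, with the rotation mapping particle-frame
vectors into the lab frame.  This matches the STAR-dialect ecosystem the
package reads and writes; the quaternion interconversion is documented in
`ribotopo.geometry` and unit-tested against the Euler path.

The object of study is the *relative transform* of neighbor `j` in
particle `i`'s frame, `t_rel = R_i^T(x_j − x_i)`, `R_rel = R_i^{-1}R_j`.
Relative transforms are invariant under any global rigid motion of the
field (an equivariance the test suite asserts end-to-end), so everything
downstream — clustering, symmetry detection, classification — inherits
that invariance.

### Transform metric

Translations and rotations are made commensurate by scaling:
`d² = |Δt|²/σ_t² + Δθ²/σ_θ²` with defaults σ_t = 25 Å, σ_θ = 10°, i.e. a
25 Å displacement "costs" the same as a 10° rotation — both roughly 10%
of a ribosome diameter at its surface.  The metric is *symmetrized* by
minimizing over `{T2, T2^{-1}}`: each physical pair is deliberately
emitted in both orientations, and a C2 dimer's two halves see each other
through mutually inverse transforms, so the symmetrization makes both
identifications automatic.  The symmetrized form is not a true metric
(triangle inequality can fail), which DBSCAN does not require.

### Clustering and classification

DBSCAN with eps = 3.0 (metric units) and min_samples = 10 on the sparse
radius graph, built blockwise so that a 5000-particle field (~25k ordered
pairs) needs no dense distance matrix.  Cluster centroids are **medoids**
(the member minimizing summed distance to the rest, subsampled to 1500
members for large clusters): quaternion averaging near a C2 orbit is
ill-defined, a medoid is always a legal transform.  Noise pairs stay
unassigned, and unclassified clusters are retained in all outputs — in
realistic fields the named classes cover only about half of the
particles, and the remainder must stay visible.

Cluster medoids are matched against the packaged template library
(`data/motif_templates.yaml`) under per-template tolerances
(tol_t = 50 Å, tol_theta = 20°), checking each template generator and its
inverse.  Particles inherit the class of their pairs' clusters; conflicts
resolve by template priority `collided > disome2 > disome3 > disome1 >
membrane_planar > cyto_helical`, so a specific dimer interface is never
absorbed into an extendable lattice it happens to touch.

The template transforms are synthetic stand-ins — the source structures
for these motifs are published as density maps, not numeric transforms —
designed under four constraints (all machine-checked): mutual symmetrized
separations ≥ 6.5 metric units (no merging at eps = 3), disome2 exactly
C2 while disome1/3 are not, dimer self-composition clashes while
helix/plane generators extend, and every dimer partner within 60° of the
+x axis used as the mRNA-exit-side proxy.  They must not be read as
measured inter-ribosome geometries.

### C2 symmetry and extendability

`detect_c2` tests `d(T, T^{-1}) < tol` on the medoid with tol = 3.0.
The threshold sits between the noise scale of a genuinely C2 cluster
medoid under the default pose noise (empirically ≲ 2.5) and the smallest
non-C2 template's self-distance (≥ 5): below it only transforms whose
square returns to the identity — a ~180° rotation with in-plane offset —
qualify.

`extendability` composes a transform with itself k = 6 times: if any two
generated centers approach within twice the clash radius (100 Å, the
ribosome hard-core radius) the putative oligomer is sterically blocked
(`terminal`; a C2 transform trivially returns onto the origin at step 2).
Otherwise the centers lie on a constant-rise screw — any repeated rigid
step does — and the motif extends (`helical`).  `planar` is reserved for
templates carrying an in-plane second generator; the medoid (orientation-
canonicalized toward its matched generator) and the other generator are
composed into a lattice and checked for clashes the same way.

### Stalled-collided detection

Collided dimers are planted at 1.2% — far below the density-clustering
comfort zone — so they are re-detected at pair level: a pair is collided
if its transform lies within `strict_eps` of the collided template under
the symmetrized metric.  Default `strict_eps = 0.75·eps = 2.25`: tight
enough that the surrounding transform space contributes essentially no
false positives (the acceptance volume is a tiny fraction of the
reachable space), wide enough to cover the bulk of the default pose-noise
deviation (pairs displaced by twice this radius are rejected, which the
tests pin).  The fraction 0.75 is a design choice of this package derived
from the noise model, not a measured value.

## The synthetic generator

The generator *defines* the study conditions; its defaults are not
tuning knobs.

* **Conditions.** Two packaged configs.  `untreated`: 81.7% of particles
  in the four elongation-cycle states (decoding predominant, POST
  low-abundance), 15.4% idle.  `treated` (puromycin): 31.7% elongating,
  64.8% idle — an approximately four-fold idle increase.  The source
  percentages for dissociated subunits are quoted against a different
  denominator than the 80S state percentages; here the residual
  (100 − elongating − idle: 2.9% / 3.5%) is carried by subunit labels so
  each condition's state vector sums to exactly 1.
* **Motif mixtures.** Treated: the five topology classes cover 56% of
  particles (helical 20, planar 15, disome1 9, disome2 8, disome3 4),
  with the two LSU-mediated hibernating dimers at 12% combined;
  untreated plants fewer dimers (52% total coverage).  Collided dimers
  sit at 1.2% in both conditions.
* **Motif-conditional states.** Disome2/3 particles are exclusively
  idle; collided particles sit in the hybrid (rotated-PRE) state;
  polysome lattices carry a condition-dependent idle fraction.  The
  free-monomer state vector is solved as the residual that makes the
  planted mixture reproduce the global composition exactly (negative
  residuals are a config error).
* **Geometry.** Box 18000×18000×2500 Å (a lamella-like slab; at n = 5000
  the packing fraction is ~0.16, far from the random-sequential-adsorption
  jam).  Hard-core d_min = 200 Å enforced by rejection sampling against a
  uniform hash grid, capped at 10⁴ attempts per group before a
  placement-failure error.  Helical chains are 4–9 particles, planar
  patches 3×3; remainders are absorbed so no planted particle is
  stranded without a partner.
* **Pose noise.** σ_t = 15 Å per axis on positions; orientation noise is
  a rotation by an angle ~N(0, σ_θ = 5°) about a uniformly random axis
  (σ_θ is the std of the *total* angle — the convention matters when
  comparing to per-axis rotation-vector noise).
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw; identical config (seed included) gives a bitwise-identical
  table.  The pipeline forks a master seed into named per-stage
  substreams (SHA-256 of `seed:stage`, < 2³¹), so adding a stage never
  perturbs earlier draws.

## Composition, NN distances, occupancy

Composition tables are exact frequency tables; the "all" row equals the
class rows mixed by size (conserved totals, asserted).  Fold-changes with
a zero denominator are reported as undefined, never infinite.  The
nearest-neighbor distance comparison uses the two-sample
Kolmogorov–Smirnov test — no particular test is canonical for this
contrast, and KS is distribution-free over the plain distance sample.
Occupancy declares the mRNA entry/exit directions as unit vectors in the
ribosome frame (defaults ±x, cone 60°, reach 400 Å), matching the frame
in which the packaged templates place dimer partners; real entry/exit
exit-site geometry would be supplied by the user per reference frame.

## RNA layer

Folding is Nussinov base-pair maximization (WC + GU wobble, hairpin loop
≥ 3) rather than thermodynamic folding: the questions asked — is there a
stem-loop, how GC-rich is the terminal loop, can two loops pair — depend
only on the combinatorics of nested pairing, and the DP is exactly
testable against explicit enumeration of all nested structures (the test
suite does this for all lengths ≤ 12 over seeded random samples).  The
terminal stem-loop is the hairpin closed by the longest contiguous helix
in the traceback (ties: 5'-most).  Kissing registers are contiguous,
antiparallel, and bulge-free; the score is the longest complementary run
over all sliding registers, GU off by default (whether wobble pairs
participate in such interfaces is not established; it is a flag).  A loop
scoring ≥ 0.75 of its length against itself is flagged self-complementary
— capable of the reciprocal loop–loop contact of a C2 homodimer.  Note an
interplay with the DP: a *long* self-complementary loop is folded
intramolecularly (pairs ≥ min_loop apart are legal), so robust flagged
cases are short loops whose self-pairing is entirely close-range (e.g. a
4-mer like `ACGU`); the synthetic panel is built accordingly.  No real
expansion-segment sequences ship with the package — the panel in
`analysis/data/` is clearly labelled synthetic, and `species_scan` takes
any user FASTA (T coerced to U with a logged warning; ambiguity codes
rejected).

## Problem sizes and what passing shows

Tests and the acceptance script run fields of n = 5000 (the headline
recovery checks), with unit and property tests at n ≈ 100–2000; these
sizes give 3-binomial-SE bands of about ±1.6 points on the composition
fractions and keep the full suite to a few minutes.  Passing them shows
that the pipeline recovers *planted* structure under Gaussian pose noise,
excluded volume, and realistic class imbalance.  It does not show
robustness to what the generator omits: missing/false particles from
picking, anisotropic (missing-wedge) localisation error, curved membrane
patches, heterogeneous dimer geometries, or density-level ambiguity in
state assignment — state labels enter the simulator as labels, standing
in for a map-space classification this package deliberately does not
perform.

## Known limitations

* Template transforms are plausible inventions; on real data the library
  should be re-derived (e.g. from medoids of a reference dataset).
* The symmetrized metric's non-metricity means DBSCAN results can depend
  mildly on eps near cluster boundaries; eps/min_samples are exposed in
  every config.
* Pair-level collided detection assumes the pose-noise scale of the
  generator; for other noise regimes `strict_eps` should be recalibrated
  (e.g. to a high quantile of the planted deviation distribution).
* The planar motif is a flat lattice; membrane curvature is out of scope.
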