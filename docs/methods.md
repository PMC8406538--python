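# Methods

## Coordinate and unit conventions

Array axes (0, 1, 2) map to (AP = x, DV = y, ML = z).  Physical units are
µm throughout; voxel indices are 0-based with voxel centres at
`(index + 0.5) · h` for voxel size `h`.  Anterior is at low x.

## Shape metrics

* **Volume** is voxel count × voxel volume.  An independent route — the
  enclosed volume of the raw marching-cubes isosurface — agrees within 2%
  and is used as a cross-check in the tests, never as the implementation.
* **Surface area** is the area of a marching-cubes mesh of the mask after a
  light Gaussian smoothing (σ = 0.7 voxels).  Smoothing suppresses the
  staircase artefact that otherwise inflates the area of binary
  isosurfaces; σ = 0.7 keeps a voxelised radius-10 µm sphere at sphericity
  ≥ 0.99 while preserving strict monotonicity of area in the generator's
  flare sweep.  The triangle count of the same mesh is reported as a legacy
  surface proxy (`n_triangles`); the physical area in µm² is the primary
  metric.
* **Ellipsoid semi-axes** come from the eigen-decomposition of the voxel
  second-moment matrix, scaled by √5 so a uniform solid ellipsoid is
  recovered exactly; `h²/12` is added per axis to account for the finite
  voxel extent (this makes a discrete cuboid match its continuous
  counterpart).  Cells with < 4 voxels are flagged `degenerate` with
  missing metrics; cells whose top two eigenvalues differ by < 5% are
  flagged `isotropic` because their major-axis orientation is unstable.
* **Oriented bounding box** extents are max − min of the voxel-centre
  projections on the eigenvectors, plus one voxel.
* **Transverse cross-sectional area `A`** is the area of the binary
  projection of the mask onto the DV–ML plane.  A projection (rather than
  `V/l_AP`, which would make the length model circular, or a single slice,
  which is noisy) captures the cell's full transverse spreading footprint,
  including flared margins.
* **AP anisotropy** is the dimensionless `l_AP/√A`.
* **Cuboidness** `V/(o₁o₂o₃)` and **sphericity**
  `π^{1/3}(6V)^{2/3}/SA` are clipped at 1: discretisation can push either
  marginally above the theoretical bound.
* **Prolate/oblate ellipticity** use `2(a−b)/(2a−b−c)` and
  `2(b−c)/(a+b−2c)` with a zero fallback when the denominator vanishes
  (perfect sphere).
* **DV layer inference** (when annotations do not provide it): within AP
  windows of 0.1 normalised length, the most dorsal and most ventral cells
  are labelled Müller rows and the remainder central.  AP regions use
  half-open bins [0, 0.15) anterior, [0.15, 0.40) pharynx, [0.40, 0.60)
  trunk, [0.60, 1.0] posterior.

## Morphospace

The default feature set is the 15-parameter suite (orientations, surface
area, volume, three aspect ratios, AP anisotropy, three nuclear
displacements, cuboidness, sphericity, flatness).  Spatial position and
stage are never features.  The redundancy screen removes one member of any
pair with |Pearson r| ≥ 0.95 (most-correlated pair first), keeping the
feature ranked earlier in a documented priority order that prefers derived,
dimensionless descriptors over raw lengths; the threshold and order are
package choices, recorded in the model output.  Cells with missing metrics
are excluded listwise.  PCA is an SVD of the z-scored matrix (sample SD,
ddof = 1); component signs are fixed so the largest-|loading| feature loads
positively, making embeddings reproducible.  Contributions are squared
loadings scaled to % per component.

## Trajectory inference

Cluster centres in the first three components are joined by a Euclidean
minimum spanning tree; each start→end tree path defines a lineage.
Clusters that end up as MST spurs (off every path) contribute their cells
to the lineages containing their attachment node, so a stage whose centre
hangs off the main path is still fitted.  Each lineage is an iterated
principal curve: initialise on the densified centre polyline, then repeat
{project, order by arc length, smooth each coordinate against arc length,
rebuild} until the mean projection distance improves by < 1e-4 (relative)
or 50 iterations; the best iterate is kept and non-convergence is a warning
flag, not an error.  The smoother is lowess with span 0.6 (configurable) —
the default family of reference principal-curve implementations.  Curves
are linearly extended beyond their end vertices so no cell projects onto a
bare endpoint.  Pseudotime is arc length of the projection scaled to
[0, 1] per lineage (the measured quantity is unitless "pseudotemporal
distance"; rescaling makes lineages comparable).  Cells take the lineage of
minimal projection distance, ties to the lower branch index.  Per-stage
pseudotime densities use a Gaussian KDE (Silverman bandwidth) renormalised
to integrate to 1 on [0, 1].

## Geometric model

Per-stage mean cells are arithmetic means with SEMs; the prism
approximation `l ≈ V/A` is exact for prisms and its relative error is
reported per stage as a model diagnostic (it grows for flared, bowtie-like
cells whose projection area exceeds the mean cross-section) rather than
silently absorbed.  Scenario definitions: constant-volume shape change
`l(s) = V(s₀)/A(s)`; isotropic growth `l(s) = l(s₀)(V(s)/V(s₀))^{1/3}`;
AP-directed growth `l(s) = V(s)/A(s₀)`.  Neighbourhood scenarios couple a
length rule with an intercalation index: growth-only scenarios hold β at
β(s₀) (growth "alone" means intercalation frozen), while shape and
intercalation scenarios apply the measured β(s).  β > 1 from measurement
noise on small groups is clipped to 1 with a warning.  Per-cent changes are
`100·(l(s) − l(s₀))/l(s₀)`.

## Proliferation landscapes

Nucleus positions are normalised per embryo by its anterior/posterior
references; values beyond [0, 1] by ≤ 2% are clipped (warning), larger
excursions are errors.  Densities are Gaussian KDEs with reflective
boundaries at 0 and the stage mean axis length, Silverman bandwidth, scaled
so each (stage, marker) curve integrates to the mean labelled count per
embryo ("mean frequency", not a probability density).  Groups with < 5
nuclei are skipped with a warning.

## Synthetic generator

The generator encodes the study conditions the pipeline is validated
against; its defaults are fixed, not tuning knobs.

* **Shape family.**  A cell is a superellipse prism along AP (squareness
  exponent 4 for central cells, 2 for Müller) with optional end flanges
  occupying 15% of the AP length at each face, radially widened by the
  flare factor.  Flanges imitate the bowtie: at fixed projection area,
  flaring narrows the waist, which strictly lowers cuboidness and strictly
  raises surface area.  Programmed volume follows analytically from
  (l_AP, A, flare); programs can be evaluated "on the raster", where AP
  length snaps to whole voxels and the flange slab splits at voxel-slice
  resolution, so ground truth matches the voxelised realisation.  AP cell
  faces are snapped to voxel boundaries with half-open voxel ownership:
  stacked cells abut without gaps or collisions, and measured AP lengths
  and group extents are grid-exact.
* **Programs.**  Central cells: l_AP 8 → 4 → 9 µm, A 30 → 120 → 130 µm²,
  DV:ML 0.5 → 1.2 → 2.0, flare 0 → 0.35 → 0 across maturity 6 → 10 → 14
  (knots extend down to maturity 2 for gradient-delayed cells).  Müller
  cells elongate to 20 µm while A falls to 12 µm²; the ventral row runs a
  12% shorter variant so the two sub-rows differ in AP anisotropy.  Both
  programs share the progenitor morphology up to maturity 6, so the
  branching point of the two trajectories is explicit.  Magnitudes are
  embryonic-cell scale (hundreds of µm³); the transitions, not absolute
  sizes, are what downstream stages must recover.
* **Maturity gradient.**  `m = s − γ·|p − 0.5|` with γ = 4 stage units per
  unit normalised AP distance: a linear mid-to-tips delay, the simplest
  form consistent with a qualitative bidirectional gradient.
* **Intercalation.**  Centre-to-centre spacings are solved by regularised
  least squares so every 10-cell window has extent β·10·l̄, then DV rows
  are assigned by greedy interval colouring so x-overlapping cells never
  collide; β = 1 degenerates to a perfect single-file stack.
* **Noise.**  Multiplicative lognormal (CV 0.05 by default) on length,
  area and DV:ML ratio, plus a uniform ±5° roll about the AP axis.
  Rotations are restricted to the transverse plane so AP lengths stay
  grid-exact; the roll feeds realistic variation into the transverse
  orientation features.  With `noise_cv = 0` the generator is fully
  deterministic geometry.
* **Proliferation.**  A per-stage posterior fraction (1.0 at 6 ss — broad
  division — shrinking to 0.12 at 14 ss) gates which cells can carry
  EdU/PhH3 labels (55%/12% of eligible cells); the standalone
  nucleus-table generator uses the same schedule with 3 embryos × ~40
  labelled nuclei per stage and axes growing 250 → 610 µm.
* **Layout.**  Stages are parallel blocks along ML in one label volume;
  the default study is 5 stages × (60 central + 2 × 20 Müller) cells, and
  the trunk preset is 5 × 100 central cells at AP 0.40–0.60.  At 0.5 µm
  voxels these generate and measure in seconds, which keeps the full test
  suite and the acceptance script fast.

### What the generator does and does not emulate

It reproduces the *structure* the pipeline must recover: branching
type-specific shape trajectories, the two-step central-cell transition, a
spatial maturation gradient, a staged intercalation schedule and
posterior-restricted division.  It does not emulate microscopy (no PSF or
intensity noise), segmentation errors, cell–cell boundary deformation,
mechanical interactions, or biological cell-to-cell program variation
beyond lognormal size noise.  Passing tests therefore certify the
*computational* pipeline — metrics, embedding, curve fitting, model
algebra — on idealised geometry; they do not certify robustness to
segmentation artefacts in real data.

## Numerical choices and degenerate inputs

Voxel fidelity: a cell face falls between voxel centres, so any per-cell
length carries a ±h/2 quantisation; the generator's face snapping removes
it for AP lengths, and program-fidelity checks run at h = 0.25 µm against
raster targets.  The redundancy screen and PCA require ≥ 2 features and
≥ 3 cells; constant features are removed (screen) or an error
(standardisation).  Trajectories require ≥ 2 clusters with ≥ 3 cells each;
disconnected cluster graphs are errors.  Stage-pseudotime correlation on
zero-variance input is an explicit error.  Empty AP bins are reported as
missing (profiles) or merged with a warning (cluster bins).  All random
draws flow from explicit integer seeds (`numpy.random.default_rng`);
k-means uses a fixed `random_state`, so every pipeline output is
reproducible byte-for-byte.

## Known limitations

* The prism length model degrades for strongly flared cells (reported as
  the per-stage model-error diagnostic).
* Multi-lineage fits are independent principal curves; no
  shared-trunk shrinkage across branches.
* Pseudotime is cluster-guided; with severely overlapping stage clusters
  the MST can place a stage as a spur, which the anchor-attachment rule
  mitigates but does not eliminate.
* Surface area depends mildly on the smoothing σ; σ = 0.7 voxels is
  calibrated on analytic fixtures, and the raw (σ = 0) isosurface is
  available for oracle-style checks.
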