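# notomorph

Single-cell 3D morphometrics of notochord development: shape feature
extraction from labelled volumes, PCA morphospace embedding, cluster-guided
principal-curve pseudotime, a geometric model of cell and tissue elongation,
and proliferation landscapes — with a synthetic notochord generator that
makes the whole pipeline testable end to end.

## The problem

During early chordate development the notochord transforms from a loose
array of rounded cells into an elongated rod: a central "stack-of-coins"
column of flattened cells flanked (in amphioxus) by dorsal and ventral rows
of Müller cells.  Live imaging of this process is often impossible, so cell
behaviour must be inferred from static, stage-ordered 3D segmentations.
`notomorph` is for developmental biologists and image analysts who have
labelled cell volumes (one integer label per cell, known voxel size) across
developmental stages and want to reconstruct *trajectories of cell shape
change* and dissect what drives tissue elongation.

## The method

1. **Shape metrics** — per cell: volume `V`, marching-cubes surface area,
   axis-aligned and object-oriented bounding boxes, inertia-ellipsoid
   semi-axes `a ≥ b ≥ c` (`a = √(5λ₁)`), orientation cosines of the major
   axis, transverse projection area `A`, AP anisotropy `l_AP/√A`,
   cuboidness `V/(o₁o₂o₃)`, sphericity `π^{1/3}(6V)^{2/3}/SA`, flatness
   `c/b`, prolate/oblate ellipticity, nuclear displacement.
2. **Morphospace** — screen redundant features (|Pearson r| ≥ 0.95),
   z-score, PCA; each cell becomes a point in the space of principal
   components, with per-component variance fractions and feature
   contributions.
3. **Trajectory** — clusters (somite stage, AP bins, or k-means) guide a
   minimum spanning tree; start→end paths are fitted with iterated
   principal curves; pseudotime is normalised arc length of each cell's
   projection.
4. **Geometric model** — a mean cell per stage obeys `l_AP(s) ≈ V(s)/A(s)`.
   Counterfactual scenarios isolate transformations: constant-volume shape
   change `l = V(s₀)/A(s)`, isotropic growth `l = l(s₀)(V/V₀)^{1/3}`,
   AP-directed growth `l = V(s)/A(s₀)`.  Neighbourhood length couples cell
   length to an intercalation index `β(s) = l⁽ⁿ⁾/(n·l̄_AP)` via
   `l⁽ⁿ⁾ = β·n·l̄_AP` (β = 1 is a perfect stack-of-coins).
5. **Proliferation landscapes** — EdU/PhH3 nucleus positions normalised per
   embryo, pooled per stage, smoothed into densities whose integral is the
   mean labelled count per embryo.

The synthetic generator (`notomorph.synthetic`) realises parameterised
shape programs — a central-cell program with two sequential transitions
(transverse spreading + AP shortening + bowtie flare + growth, then AP
elongation + flare loss) and Müller programs that elongate along AP — as
superellipse prisms with flared end flanges, placed along the AP axis so
neighbourhood extents hit a per-stage β target, with a mid-to-tips maturity
gradient `m = s − γ·|p − 0.5|` and posterior-restricted division labels.

## Worked example

```bash
python examples/trajectory_pseudotime.py
```

```
stage-pseudotime Pearson r = 0.979
 stage  mean   std  count
   6.0 0.102 0.082    100
   8.0 0.389 0.013    100
  10.0 0.638 0.003    100
  12.0 0.748 0.021    100
  14.0 0.944 0.020    100
pseudotime vs ground-truth maturity: r = 0.979
```

Five hundred synthetic trunk cells are generated, measured, embedded into
morphospace and ordered along a principal curve.  The Pearson r of 0.979
between somite stage and pseudotime says the inferred shape trajectory
recapitulates developmental time; the per-stage means rise monotonically
from 0.10 to 0.94, and pseudotime also recovers each cell's hidden
ground-truth maturity (r = 0.979).

`examples/geometric_scenarios.py` decomposes elongation the same way:

```
               scenario  final_length_um  pct_change_6_to_14ss
     intercalation_only             79.3                 121.9
        shape_no_growth             18.1                 -49.3
  isotropic_growth_only             60.0                  67.8
anisotropic_growth_only            168.9                 372.5
                   full             87.6                 145.1
```

Shape change without growth *shrinks* a 10-cell neighbourhood by 49% while
the full programme elongates it by 145% — growth must counteract the AP
shortening that accompanies transverse spreading for intercalation to
lengthen the tissue.

The other examples cover dataset simulation, fixture-validated shape
metrics, morphospace diagnostics and proliferation landscapes.  A thin CLI
(`notomorph simulate|features|embed|trajectory|geomodel|proliferation|run`)
wraps the same API for shell use.

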