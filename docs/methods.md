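# Methods

## Model overview

The follicle transverse section is idealized as a 2-D plane-strain linear
elastic body. Plane strain is appropriate because the follicle is long and
axially confined; axial physiology enters only through the keratinization
eigenstrain. The section is partitioned into six compartments — medulla,
posterior/anterior cortex, posterior/anterior IRS, outer ring — each an
isotropic material (Young's modulus E, Poisson ratio ν). Stiffness units are
relative: only modulus **ratios** matter in eigenstrain-driven quasi-statics,
so the base epithelium is E = 1 and everything else is expressed against it.

Growth and keratinization are *eigenstrains* (imposed stress-free strains),
implemented through the thermal-expansion analogy: an element with
eigenstrain ε\* contributes the load f_e = A_e·Bᵀ·D·ε\*. A homogeneous,
unconstrained body under uniform eigenstrain therefore deforms exactly by
ε\* (the solver's patch test holds to machine precision).

Total process strains far exceed the small-strain regime, so the simulation
is quasi-static and incremental (updated-Lagrangian): pseudo-time τ ∈ [0, 1]
(≙ height along the follicle, base → keratinized shaft) is divided into
N = 50 increments; each increment applies the *multiplicative* strain ratio
of its process time course, assembles and solves on the current mesh, and
advances the node coordinates. Halving the step count moves the final cortex
fraction by ~0.1 percentage points.

**Boundary condition.** The outer boundary of the outer ring is fully fixed,
representing confinement by the ORS/Henle's layer and dermis. This conserves
total section area, which is consistent with the observed bookkeeping: the
cortex share falls 67% → 27% while its absolute preferred area falls by
1/λ_z ≈ 0.3, so the total section area must stay roughly constant, with the
vacated area absorbed by the (soft, actively enlarging) IRS. A traction-free
alternative (`bc="pinned"`) is available.

## Geometry

The section is *radially stratified*: every layer boundary is a
single-valued polar curve r(θ) about the section centre (anterior = −x).
This makes the domain star-shaped, so compartment polygons, the
posterior/anterior splits and a structured conforming mesh all derive from
the same analytic curves.

- **Medulla crescent.** The disc bounded by a circle of radius R_m whose
  centre is shifted a µm toward the anterior, minus a posterior *bite*
  circle carving the concavity between the two horn lobes. Both arcs are
  single-valued in θ from the origin. The offset a is derived from the
  cortex eccentricity e (the posterior:anterior apex thickness ratio) by
  requiring thickness_posterior(apex) = e·thickness_anterior(apex) with the
  bite carved; the bite circle passes through the horn tips (at the lobe
  half-angle) and through the bite floor on the posterior axis. At e = 1 the
  construction degenerates to concentric annuli (no offset, no bite).
- **IRS and protrusion.** The IRS is a band of constant base thickness whose
  anterior side carries a cos²-profile thickening (the Huxley's-layer
  protrusion) digging into the cortex; the protrusion must stay shallower
  than the local cortex (validated).
- **Thickness measurement.** Posterior/anterior cortex thickness is the mean
  radial extent of the cortex layer over rays within ±20° of the respective
  apex — the way the two sides are compared on micrographs. Defaults give a
  ratio of 3.1, inside the anatomical 3–4 band.
- **Defaults** (µm): follicle radius 100, medulla outer radius 36.26, lobe
  half-angle 48°, bite depth 0.4, eccentricity 3.5, IRS 6, protrusion depth 8
  (half-width 30°), ring 4. The medulla radius was fixed once so the cortex
  holds 67.0% of the base section; all values live in the shipped config.
  Compartment polygons sample the curves at 256 shared angles, so adjacent
  polygons share vertices bit-exactly and the areas telescope to the total
  (partition exact to ~1e-16 relative).

## Meshing

With analytic radius curves, a structured "onion" mesh is built directly:
rings of nodes on interpolated radius curves at a shared angle grid
(quadrant split meridians included exactly), quads between consecutive rings
split into alternating triangles, and a centre fan. The mesh is conforming
by construction, every element carries exactly one compartment label, and
per-compartment mesh area agrees with the polygon area to ≲0.03% at the
default 3.5 µm edge (~10–11k elements). The target edge must not exceed the
thinnest layer's mean thickness (4 µm, the ring). Geometries loaded from
GeoJSON are re-stratified by ray casting.

## The three processes (defaults and why)

| process | window (τ) | magnitude | moduli |
|---|---|---|---|
| anterior IRS growth | 0 → 0.85 | peak isotropic strain 0.18, cos² zone weight | growing zone 3× IRS |
| cortex keratinization | posterior onset 0.30, anterior 0.45, full 0.85 | λ_z: 1 → 3.2, in-plane ε\* = λ_z^(−1/2) − 1 | E: 1 → 50 with λ |
| medulla keratinization + collapse | stiffen 0.20–0.50; collapse 0.70–1.0 | cavity-collapse strain −0.75 | E: 1 → 35, then Gibson–Ashby drop to E·ρ_rel² (ρ_rel = 0.1) |

Materials at base: epithelium 1, IRS 0.5, outer ring 20, ν = 0.3 everywhere
(cortex ν configurable; the end state moves < 5 pp across ν ∈ [0.2, 0.4]).

Design rationale, where the design was genuinely open:

- **Sustained IRS growth.** The anterior IRS enlarges continuously from
  mid-follicle levels through keratinization, so the growth window extends
  to τ = 0.85 rather than stopping when the cortex starts keratinizing.
  Mechanically this matters: only a maintained growth pressure keeps the
  protrusion pressed into the shrinking shaft; a bulge that stops growing is
  released as the stiff cortex contracts around it, and the groove vanishes.
- **λ_z = 3.2 and the stiffness contrast.** Under the area-conserving BC the
  cortex cannot fully realize its preferred 1/λ_z area factor — the
  stretched IRS pulls back elastically — so the axial stretch and the
  keratinized modulus (50× the living epithelium; real keratin is orders of
  magnitude stiffer still) were calibrated once, with the package's own
  `calibrate()`, to land the final cortex fraction at ~26–27%.
- **Collapse = crush + delayed softening.** The foam collapse combines a
  negative eigenstrain (cavities closing as medulla cells shrink and die)
  with the Gibson–Ashby modulus drop, the drop lagging the strain
  (geometric interpolation in the squared collapse phase). A pure modulus
  drop cannot shrink the medulla: under area conservation a soft inclusion
  with no volume loss is stretched by its neighbours, not crushed. With the
  lag, the still-stiffish collapsing medulla drags the thin keratinized
  anterior cortex inward, deepening the furrow.

## Shape metrics

- **Furrow depth**: largest distance from a vertex of the shaft outline
  (cortex + medulla region boundary) to the boundary of its convex hull —
  0 for a convex shaft. The full default run ends at ~5.2 µm and exceeds
  every single-process ablation (3.9 / 4.6 / 2.1 µm for growth /
  keratinization / collapse disabled respectively, recomputed by the test
  suite). A literal "furrow present yes/no" threshold cannot separate the
  runs — a growth bulge pressed into a never-keratinizing soft cortex always
  leaves some concavity — so "the furrow needs both growth and
  keratinization" is checked as this strict dominance plus two trend
  signatures: the concavity deepens *before* keratinization onset only when
  growth is enabled, and the medulla fraction strictly decreases after
  collapse onset only when collapse is enabled.
- **Medulla convexity deficit**: 1 − area/hull-area of the medulla region.

## Synthetic data

The generator emulates the annotated micrographs statistically, not
visually: per-region homogeneous Poisson counts placed uniformly inside the
region polygons, markers drawn per-point from region-specific Bernoulli
probabilities, every marker point coinciding with a Hoechst nucleus.
Regions derive from the parametric section: DP = crescent scaled 0.75 about
its centroid, medulla = the band around it, matrix counting areas split by
distance to the DP (posterior signaling range 25 µm, anterior 35 µm — the
anterior matrix lies almost wholly in range, the posterior only partially),
IRS areas as-is. Mean counts anchor on the printed 1,093 DP and 80 medulla
cells per section (the DP figure is used directly as the per-section mean);
the other regions' means are plausible absolute counts, not measured
densities. BrdU probability fades (τ 0.3 → 0.9) and TUNEL rises
(τ 0.4 → 0.95, to 0.25) along the stack as linear ramps.

What passing tests therefore do **not** show about real data: no cell–cell
exclusion (a hard-core pattern would lower local density maxima), no
segmentation error, no section-to-section registration error, and no
empirical per-region densities. The quantification stage is exact on this
null model (verified against brute-force oracles); on real annotations its
accuracy is limited by the annotations themselves.

## Numerical choices

- Direct sparse factorization (`spsolve`); relative residual tolerance 1e-8.
- Eigenstrain increments are multiplicative ratios of the process courses;
  an increment that inverts any element raises an error instructing more
  steps rather than silently continuing.
- Point-in-region tests count boundary points as inside; overlapping regions
  warn and resolve first-match in declared region order (determinism).
- DP distances use the polygon boundary (0 inside), not the centroid.
- Density maps: square grid, spacing = radius/4, radius = 3% of the image
  diagonal (diagonal = √(w² + h²) of the stated frame), normalized per-map.
- Degenerate inputs raise typed errors (`ParameterError`, `GeometryError`,
  `MeshError`, `UndefinedValueError` for empty denominators — never a silent 0).

## Problem sizes

Default runs use ~10.6k elements and 50 increments (seconds per run); the
test suite's trend/ablation/robustness checks re-run the full model at that
resolution and use a 4 µm / 8-step configuration for loop-level unit tests.
Synthetic-data statistics use 20–100 seeded sections (~1.9k nuclei each).

## Known limitations

- Linear elasticity with incremental updates approximates a finite-strain
  path; there is no contact, viscoelasticity or growth–stress feedback.
- The outer ring is rigidly fixed; real follicle outlines deform somewhat.
- The 2-D section sequence stands in for a 3-D structure; pseudo-time is a
  modelling identification, not a measured mapping to follicle height.
- Ablation contrasts in furrow depth are O(1 µm) at default magnitudes;
  they are stable at the default resolution but not large.
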