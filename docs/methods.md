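# Methods

`voxcanopy` reproduces, on fully synthetic data, the processing chain that
turns terrestrial laser scans of a closed broad-leaved stand into a voxel
canopy model, perturbs that model structurally, and measures the spectral
consequences at the top of the canopy. This note documents the models,
their assumptions, the free design choices, and what the synthetic results
can and cannot say about real forests.

## The synthetic stand

The generator emulates a closed, even-aged beech stand: 223 trees/ha,
mean DBH 0.404 m, mean height 32.3 m, crown base 14.3 m, target LAI
2.32 m²/m² on a square core plot (default 30 m).
Trees are placed uniformly at random with a minimum spacing (default 4 m;
the horizontal tree pattern of such a stand is rarely reported, so a random
pattern with spacing was chosen and is configurable). Heights and DBH get
small relative Gaussian scatter (4% / 8%).

Crowns are prolate ellipsoids between crown base and tree top; the
foliage envelope starts `crown_lift` (default 1 m) above the measured
crown base, since the lowest leaves of a closed-canopy broadleaf sit on
branches that arch upward from the bole rather than on the bole itself
(this also keeps trunk and crown from fusing into one connected component
in occlusion-free ground-truth clouds). The
vertical leaf density follows a beta distribution over the crown span with
its mode at the center of `lad_peak_height_range` (default 20–25 m), which
reproduces the characteristic upper-canopy LAD bulge of a closed beech
stand. Horizontal positions are uniform inside the ellipsoid cross
section; crowns overhanging the plot edge wrap toroidally so the core tile
clones into a seamless homogeneous forest.

Leaves are sampled as **distinct cells of the 2 cm voxel lattice** and
stored as cell centers. This makes the leaf count exact:
`N = round(LAI · area / 4·10⁻⁴ m²)`, so the reference canopy's LAI is
2.32 by construction, and voxelizing the ground truth reproduces the stand
cell for cell. Physically this asserts only that no two leaves sit within
the same 2 cm cube, which is innocuous at the realized within-crown
density (≈0.5% lattice occupancy).

Crown radius is the one free parameter that controls clumping and hence
canopy openness. At fixed LAI the simulated hemispherical openness (from
1.3 m at the plot center, uniform solid-angle sampling) ranges from ≈24%
for compact crowns (3.4 m) down to a ≈21% plateau as crowns interlock.
The default of 5.5 m — plausible for mature beech at this density — gives
≈22% openness against the 18.7% reference value of the emulated stand. The residual gap reflects
details our leaf model does not carry (within-crown clumping, a leaf
inclination *distribution* rather than the fixed plagiophile angle), and
is accepted rather than tuned away with unrealistic geometry.

Material spectra are analytic synthetic templates (green peak, red edge,
NIR plateau, liquid-water absorption at 1450/1940 nm; leaf ρ+τ ≤ 0.9 at
all bands) standing in for field spectroradiometer measurements, defined
on 350–2500 nm at 10 nm. They are not a leaf optical model; measured
spectra can be substituted as two-column CSV.

## Scan simulation and ghost points

Scans are organized azimuth × elevation rasters (default 0.036°, the
resolution class of a phase-shift scanner; test fixtures use coarser
grids). Each ray records the first surface hit within the 76 m maximum
range — a z-buffer contract that produces realistic occlusion. Reference
spheres (icosphere meshes) yield dense front-hemisphere returns for
registration.

Mixed-pixel "ghost" returns are injected on rays whose 8-neighborhood
spans a depth discontinuity (> 0.5 m): the true return at range r₀ with a
neighbor surface at r₁ is replaced by a return uniform in (r₀, r₁),
mimicking the range-mixing mechanism of phase-shift scanners at silhouette
edges. Every synthetic point carries a ground-truth class (leaf, trunk,
soil, sphere, ghost), so the filter can be scored exactly.

The ghost filter follows the printed rule: a return survives iff at least
75% of the valid neighbors in a kernel box differ in range by strictly
less than 0.02 m. The kernel size is a free parameter;
5×5 (half-width 2) is the default — large enough for the 75% allocation
rule to be meaningful. Range difference (not 3-D distance) is the metric,
matching the 2-D re-projection formulation; boundary kernels truncate; a
return whose neighborhood holds no other valid return is removed. On
labeled synthetic scans the defaults achieve ghost recall ≈ 1.0 and
kept-point precision ≈ 1.0 while removing most isolated single-leaf
returns — deliberately intensive filtering whose losses voxelization (and
here, the ground-truth canopy path) absorbs.

## Registration and classification

Sphere centers are fitted algebraically and refined by geometric
Gauss–Newton; scans are aligned with the Kabsch/orthogonal-Procrustes
solution over matched centers, with exhaustive correspondence search when
the pairing is unknown. Classification bins points into 0.25 m cells
(26-connectivity; both configurable), labels a connected component a trunk
when its bounding box satisfies dz ≥ 3·min(dx,dy) and 0.66 ≤ dx/dy ≤ 1.5,
and everything else foliage. Cell size was chosen so a 0.4 m trunk forms
one slender component; a degenerate horizontal extent classifies as
foliage. An optional pre-step drops points within 0.2 m of a fitted
ground plane. Classification runs in a single pass at one octree depth.

## Voxel canopy and structural manipulation

Voxelization uses 2 cm half-open cubic cells; a filled cell is trunk if
any trunk point falls in it, else leaf. Each leaf voxel carries a fixed
one-sided leaf area quantum of 400 mm², so LAI and the 1 m-layer LAD
profile are exact counting:
`LAD(z) = n_leaf(z)·quantum / (ground_area·Δz)`.

* `reduce_lai(f)` empties `round(f·n)` leaf voxels per layer (uniform,
  seeded), scaling the LAD profile by (1−f) within one quantum per layer.
  From the 2.32 reference, f = 0.10 yields LAI printing as 2.09. (Note
  that a printed L5 value of 2.22 is not 0.95 × 2.32 at two decimals;
  voxel-removal semantics give 2.20 and no attempt is made to force 2.22.)
* `translate_lad(0.5, 17 m, 1.3 m)` removes exactly `round(0.5·n_upper)`
  leaf voxels with center z ≥ 17 m and creates the same number in empty
  cells with center z in (1.3, 17) m. Receiving layers are weighted by
  their existing leaf counts (largest-remainder rounding, residue on the
  most populated layer) and new cells are drawn inside the convex
  horizontal footprint of each layer's leaves — the one genuinely free
  choice in this operator, and the one that most shapes the LRT spectra.
  Total leaf count, hence LAI, is conserved exactly.

Thresholds compare against voxel-center z. All randomized operators are
bit-reproducible under a fixed seed.

## Scene building and cloning

Each leaf voxel becomes one equilateral triangle of exactly 400 mm²
centered on the voxel, normal at 42.5° zenith (plagiophile average for
beech) with i.i.d. uniform azimuth; normals point upward and leaves are
two-sided in the renderer, so the sign is radiometrically neutral. Trunks
are open-ended triangle tubes: parametric cylinders when trunk geometry is
known, or ball-pivoting reconstruction from trunk points (ball radius 3×
the mean nearest-neighbor spacing) with a fitted-cylinder fallback when
more than 20% of edges remain on the boundary. Soil is a Lambertian plane
at z = 0.

The core tile is cloned on a centered 5×5 grid (24 added instances,
150×150 m) to provide lateral context. Clones are exact translates,
realized by instancing: the renderer translates rays per tile, so memory
holds one copy of the core geometry.

## Radiative transfer

The integrator is a forward path tracer from a nadir orthographic sensor
over a 21×21 m footprint centered on the core tile (avoiding lateral-flux
error at the domain edge). Per band it estimates the
hemispherical-directional reflectance factor π·L_nadir / E_horizontal.

* Illumination: a directional sun (default 30° zenith, 180° azimuth) plus
  an isotropic diffuse sky, both defined on 350–2500 nm at 10 nm; the
  sensor senses 400–2500 nm or any subset (the index band set in the
  default experiment).
* Leaf interaction is bi-Lambertian: reflect with probability ρ, transmit
  with probability τ into the cosine-weighted hemisphere on either side,
  absorb otherwise; trunks and soil are opaque Lambertian. Sampling the
  scattering event by albedo keeps path throughput at 1 until absorption.
* The sun is sampled by next-event estimation with binary visibility
  (diffuse transmission does not propagate a collimated beam); the sky is
  collected when a path escapes the scene. Rays leaving the 150×150 m
  domain escape to sky — no cyclic boundary.
* Path length is bounded by Russian roulette (survival 0.8 after depth 8)
  with a hard cap of 48. A cap of 16 — a common renderer default — would
  truncate visibly in the NIR, where leaf single-scattering albedo is
  ≈0.9 and mean chain length approaches ten scattering events, so the
  deeper cap was chosen; the roulette keeps the estimator unbiased.
* Bands are rendered independently, single-threaded, with a per-band seed
  derived from the sensor seed; runs are bit-reproducible. The same
  sensor seed is used for every canopy configuration, so configuration
  differences benefit from common random numbers.

Geometry is held in float32 inside a median-split BVH (node bounds
inflated past the rounding slack; traversal arithmetic in float64), tiles
are visited nearest-first, and occlusion queries exit on any hit. The
renderer was validated against closed forms: a Lambertian plane returns
its albedo, an opaque slab hides the soil, ρ=1 reaches unity (white
furnace), and a translucent Lambertian layer over soil matches the
adding formula ρ₁ + τ₁²ρ_s/(1−ρ₁ρ_s) within Monte Carlo error; BVH
traversal is tested identical to brute-force intersection.

Canopy openness is estimated by simulated hemispherical photography:
uniform solid-angle rays from 1.3 m, the unobstructed fraction reported
with its binomial standard error.

## The experiment and its scale

`run_experiment` drives: stand synthesis → (optionally scan → filter →
register → classify) → voxelize → LR / L5 / L10 / LRT → scene → render →
vegetation indices. Stage seeds derive from one master seed via
`SeedSequence([master, stage_index])` with a fixed stage table, so a
configuration re-runs bit-identically and a different master seed
re-randomizes all stages coherently.

By default the reference canopy is voxelized from the stand's ground
truth rather than from simulated scans: at LAI 2.32, occlusion makes any
finite scan set lose leaf area, and the experiment is defined on a canopy
*tuned to* LAI 2.32. The TLS chain is exercised and scored on its own
fixtures (`canopy_source: "tls"` runs it end to end).

The default experiment runs at the full stand geometry — 30 m core,
5.22 million leaf voxels, 25 tiles — with the Monte Carlo sample count as
the only scaled quantity. Because the NDVI sensitivity statistic reads
only the 670 and 800 nm bands, the sensor supports per-band sample
budgets: the acceptance script renders those two bands with 100 000 paths
(20 000 elsewhere) so the reported statistic reflects canopy structure
rather than estimator noise, and the test suite uses 40 000 / 4 000 with
a dedicated 150 000-path render for the single-band NIR ordering check.
Standard errors are reported alongside every reflectance.

## Vegetation indices

Six indices are computed from the rendered spectra: NDVI
(R800−R670)/(R800+R670), ZM R750/R710, CM R695/R760, RDVI
(R800−R670)/√(R800+R670), TVI, and NDII (R850−R1650)/(R850+R1650). Band
requests resolve to the nearest band center with ties toward the lower
wavelength, and the matching is recorded. The configured TVI form,
0.5·(120·(R750−R550) − 200·(R670+R550)), is evaluated verbatim by
default; the canonical Broge–Leblanc variant with (R670−R550) is
available behind a flag, since the plus sign in the configured form is at
odds with the index's original definition and the intent is not guessed.
Percent differences versus the LR reference are reported as magnitudes
with the sign retained in a secondary column; a zero reference is flagged
undefined, never silently zero.

## What the synthetic results show — and what they do not

On the emulated stand (dark soil, ≈22% openness), thinning LAI lowers NIR
reflectance monotonically (LR > L5 > L10 beyond two standard errors at
850 nm), NDVI is the least responsive of the six indices, and its maximum
absolute change across L5/L10/LRT stays under 0.7%. These are the
qualitative behaviors the experiment was designed to expose. Two caveats
are structural: absolute reflectance levels and percent deltas measured on
a real canopy depend on its actual architecture and field spectra, which
no synthetic stand reproduces; and in this synthetic canopy the LRT
translation *raises* NIR reflectance (leaf area moved to sparsely
occupied lower layers intercepts extra light above a dark floor), where a
real canopy with the same bulk manipulation can instead track the
10%-thinned configuration — the receiving-layer allocation rule is the
free choice this behavior is most sensitive to.

## Known limitations

Leaves are rigid fixed-area triangles with one global inclination angle —
no leaf angle distribution, curvature, petioles, or branch architecture;
spectra are templates without within-canopy variation; the sky is
isotropic; radiometric intensity, multi-return waveforms and wind are out
of scope. The ball-pivoting implementation targets trunk-scale point sets
(10³–10⁴ points), not full scans.
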