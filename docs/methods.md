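# Methods

This note documents the models, algorithms and design decisions behind
`atlasforge`, in the order the pipeline runs. Wherever the underlying
methodology leaves a numerical or procedural choice open, the choice made
here is stated explicitly together with its rationale.

## Scope and model of the data

The package builds a cellular-resolution gene expression atlas of an early
(blastula/gastrula-stage) embryo from 3D multichannel fluorescence volumes.
The biological model is a spherical embryo whose blastoderm is a thin cap of
near-contact cells; every specimen carries a nuclear counterstain channel
and one or two gene channels, one of which is a shared reference gene (a
*gsc*-like dorsal organizer marker) used to anchor registration. Whole
embryos imaged at low magnification serve as per-stage *templates*; partial
dorsal views at higher magnification are *analyzed* specimens mapped onto
the template, "virtually multiplexing" stains across individuals. Expression
is binarized per cell, consistent with Boolean gene-regulatory-network
modelling; graded levels are available only as an optional per-specimen
relative quantification.

World coordinates are continuous, right-handed and in µm; a voxel index
`(ix, iy, iz)` (0-based) maps to the world position of its centre,
`world = (index + 0.5) · spacing`. This voxel-centre convention makes point
sets and grids round-trip without half-voxel ambiguity and is applied
consistently across I/O, detection, segmentation and registration
(SimpleITK images are given an origin of `spacing/2` to match).

## Synthetic-data generator

Real acquisitions are not required: `synthetic.generate_embryo` renders a
ground-truthed stand-in with the geometry and noise structure the pipeline
must cope with.

* **Geometry.** Nuclei lie on a spherical cap (default radius 120 µm,
  cap fraction 0.4 of the sphere — a scaled-down blastoderm chosen so the
  default volumes stay around 10⁶ voxels). The scale-down affects only
  compute cost; all rules are expressed in units of the internuclear
  distance (IND), so properties measured here transfer to full-size volumes.
* **Placement.** Nuclei are placed quasi-uniformly by dart throwing:
  proposals are spherical Fibonacci-lattice sites jittered tangentially by
  a Gaussian of 0.08 lattice constants and rejected when closer than
  2·σ_nucleus (6 µm) to an accepted centre; a site is re-proposed until it
  fits, and the generator rejects specs whose separation constraint is not
  met within 10·n proposals. The jittered-lattice proposal (rather than
  uniform random darts) reproduces the near-regular epithelial packing of a
  real blastoderm; with the default jitter the realized mean
  nearest-neighbour distance tracks the unjittered scaffold's spacing
  (`EmbryoSpec.nominal_spacing`) within 10%. Defaults give IND ≈ 13 µm,
  matching the 10–14 µm range of early-gastrula internuclear distances.
* **Rendering.** Each nucleus is an isotropic Gaussian blob (σ = 3 µm,
  peak 200 a.u.); gene channels are smooth plateaus (the binary angular-cap
  domain mask smoothed by σ_nucleus) over the blastoderm shell. Noise is
  additive Gaussian after rendering, clipped at zero (default SD 10, i.e.
  20:1 peak SNR); an optional `attenuation_lambda` applies exponential
  depth decay `exp(-depth/λ)` to both channels for quantification tests.
  Voxels are anisotropic, 1.5 × 1.5 × 3 µm, as in confocal stacks.
* **Gene domains** are angular caps (axis + half-angle) on the shell;
  ground-truth positivity is the exact point-in-cap test per nucleus. The
  default pair is a gsc-like reference domain near the dorsal margin plus
  one broader private gene.
* **Cohorts.** `generate_cohort` renders one whole-cap template and J
  analyzed specimens sharing the template's nuclear layout, each rescaled in
  radius by a draw from N(1, 0.05) truncated to ±10% (so the stated "95%
  within 10% of the mean radius" envelope holds by construction), rigidly
  jittered (default ≤8°, ≤10 µm, recorded in the ground truth), re-rendered
  with a fresh noise realization, and cropped to a dorsal sub-volume: the
  bounding box of the reference domain dilated by 25% of the radius,
  widened toward the full grid as `view_fraction → 1`. Sharing the layout
  (rather than re-placing nuclei per specimen) keeps a known point-to-point
  correspondence in the ground truth; inter-individual variability is
  expressed through the radius scaling and pose jitter. What the generator
  deliberately omits: optics (PSF, z-blur), yolk and EVL anatomy,
  per-embryo pattern variability beyond rigid motion + scaling, and
  Poisson photon statistics. Passing tests therefore demonstrate the
  correctness and stability of the algorithms under controlled geometry and
  additive noise — not performance on arbitrary real acquisitions.

## Nuclear centre detection

A difference-of-Gaussians band-pass: the image is convolved with two
Gaussians (σ_small, σ_large, both physical µm converted to per-axis voxel σ
through the spacing), their difference is taken, and values below
`threshold_fraction · max` of the difference image are zeroed. Centres are
the local maxima of the result: voxels not exceeded in their
26-neighbourhood, with positive value; candidates closer than σ_small
collapse to their highest-valued member, ties resolved to the lowest linear
voxel index (this also reduces equal-valued plateaus to a single centre).

Parameters are supervised. The config defaults are σ_small = 2.8 µm,
σ_large = 12 µm and a 7% threshold — the expert values for a low-noise
acquisition — with sweep ranges σ_small ∈ [2, 4] µm, σ_large ∈ [8, 16] µm
and thresholds 1–15% (the upper σ bounds are a config choice; they are
exposed rather than hard-coded). Defining the threshold as a fraction of
the *filtered* image's maximum makes the 1–15% range scale-free. The
supervised choice must track the noise floor: at peak SNR 5 the
post-filter noise sits just below 15% of the band-pass maximum, so the
benchmark at that SNR uses the top of the range; at the default 20:1 SNR
the error rate is flat (±1 threshold point moves it by far less than 2
points). Near-contact nuclei closer than about twice the effective blur
√(σ_blob² + σ_small²) merge into one maximum; at the default packing a
σ_small of 2 µm keeps all nuclei resolved, which is what the noise-free
exactness test uses.

Scoring against ground truth uses greedy globally-closest one-to-one
matching under a 4.2 µm radius (the approximate radius of the smallest
nucleus). Greedy matching (not Hungarian) is deterministic, reproducible
and adequate when the match radius is far below the IND; unmatched
detections are false positives, unmatched truth centres false negatives,
and the error rate is (FP+FN)/GT. The internuclear distance is the mean
over centres of the nearest-other-centre distance.

## Gene-domain segmentation and positive cells

Segmentation is threshold + morphology: binarize at a supervised fraction
of the channel maximum (default 0.5, per-gene overrides in config), then
morphological **closing followed by opening** with a digital Euclidean ball
whose *diameter* equals the IND — one typical cell — built in world units so
anisotropic voxels get anisotropic radii. The largest 26-connected
component is kept; an all-background result is a flagged empty domain, not
an error. The domain boundary is the set of mask voxels with a background
6-neighbour.

A cell is **positive** when its centre lies inside the mask or within
`0.5 · IND` (config: `radius_factor`) of the nearest boundary voxel —
equivalently, inside the mask dilated by half a cell. The dilation reading
was chosen deliberately: a literal "distance to the border" rule would
exclude deep-interior cells, which contradicts how positive template cells
are selected in practice. `radius_factor = 0` reduces to strict membership.

Optional relative quantification per cell: mean gene intensity in a ball of
radius IND about the centre, minus the background (mean intensity outside
the embryo mask, itself derived by thresholding the smoothed nucleus
channel at 10% of max), divided by a depth factor f(z) — the embryo-masked
per-slice mean of the nucleus channel normalized to its z-maximum — then
min-max normalized per specimen (the pre-normalization values are available
via `normalize=False`). f(z) assumes the nucleus channel's per-slice mean
is depth-independent apart from attenuation; that holds for slab-like
geometry and only approximately for a spherical cap, which is a documented
limitation of this estimator.

## Referential extraction and rigid mapping

Mapping is initialization-by-anatomy followed by intensity refinement.

1. **Sphere.** An algebraic least-squares sphere fit to the outer nuclei —
   the half of the nuclei farthest from the provisional centroid (the
   "outer 50% shell" heuristic; the fraction is configurable).
2. **Margin plane.** Total-least-squares plane through the 5% of nuclei
   lowest along the provisional animal–vegetal axis (default +z: specimens
   are mounted dorsal-up; the axis is a config value because "southernmost"
   presupposes a mounting convention). The normal is re-oriented
   animal-ward and becomes **u**.
3. **Dorso-ventral axis.** **v** is the unit projection of
   (gsc centroid − sphere centre) onto the margin plane's direction space;
   a gsc centroid collinear with u is a hard error ("degenerate dorsal
   direction"). **w = u × v** completes the right-handed trihedron; the
   bilateral symmetry plane spans {u, v} through the sphere centre.
4. **Origin.** The sphere centre is projected onto the margin plane and
   advanced along v to the sphere surface: margin latitude, gsc longitude.
5. **Initialization.** The unique rigid map carrying one frame's
   (O; u, v, w) onto another's.
6. **Refinement.** Embryo shapes are compared as distance-weighted maps:
   the nuclear mask (union of balls of radius 0.5·IND about the centres)
   has an external contour a further 0.5·IND out; each voxel inside that
   envelope is weighted `1/(1 + d/IND)` with d its distance to the contour
   (1 on the contour, decaying inward, 0 outside). The exact functional
   form of the inverse-distance weighting is a package choice and is
   isolated in `shape_weight_map`. Registration maximizes normalized
   cross-correlation between the two weight maps under a rigid transform,
   using SimpleITK's registration framework (correlation metric,
   Euler-angle rigid transform, regular-step gradient descent with
   parameter scaling from physical shift; defaults: initial step 6 µm ≈
   0.5·IND, minimum step 0.05 µm, 200 iterations, relaxation 0.5, weight
   maps at 3–4 µm isotropic). The refined transform is accepted only if its
   correlation is at least the initialization's (monotone acceptance);
   badly initialized runs surface through the returned correlation rather
   than failing silently. Manual offsets — the replayable equivalent of
   interactive correction — are config-supplied post-transforms, never
   interactive.

Transforms map moving (analyzed) world points into the fixed (template)
frame, are stored as a row-major 3×3 rotation plus µm translation, and are
re-projected to the nearest proper rotation on construction so orthogonality
invariants hold exactly.

## Atlas assembly

Mapped domain masks are resampled into the template grid and the same
half-IND rule selects positive template cells, giving per-gene counts n_e
(analyzed) and n_t (template) whose discrepancy, together with the
analyzed/template IND ratio, is reported per mapping. With J specimens of
one gene, each template cell's repetition count V ∈ 0..J is the number of
specimens calling it positive; the **mean domain** is V ≥ majority with
majority defaulting to ⌈J/2⌉ (the binarization of V is not uniquely
determined by the underlying methodology, so the majority is exposed in
config and the monotone sweep over majorities is testable).

Domains live at the cell level; a cell-level boundary is the set of
positive cells with a negative neighbour within 1.5·IND. Boundary
variability uses a leave-one-out protocol: specimen j's boundary points are
assigned the distance to the nearest boundary point of the mean domain
rebuilt from the other J−1 specimens, reported per specimen (mean ± SD),
pooled, and binned at IND/2 with the fractions within one and two cell rows.
Distances are directed point-to-nearest-point; repetition-count profiles
along the frame's lateral/radial/sagittal lines are sampled every IND/2 by
nearest-nucleus (Voronoi) lookup.

## Atlas analytics

* **Coexpression.** For a gene pair, n_ab cells coexpress; fractions are
  n_ab/n_a and n_ab/n_b and Dice is 2·n_ab/(n_a+n_b). Cells flagged "not
  observed" (outside every imaged analyzed volume) are excluded from
  denominators, since absence of coverage is not negativity. Topology
  trajectories plot (n_ab/n_a, n_ab/n_b) per stage and classify identity /
  inclusion / exclusion / intersection with a one-cell tolerance per
  denominator.
* **WPGMA.** Cells (per stage) and genes (columns concatenated across
  stages) are clustered by weighted pair-group averaging on Euclidean
  distances between binary profiles: merge the closest pair, then
  d(k, i∪j) = (d(k,i)+d(k,j))/2. Ties break toward the lexicographically
  smallest pair of current node indices, so trees are reproducible;
  inversions are possible and not corrected. Cutting to k clusters removes
  the k−1 largest-height merges (ties toward later merges). Cell clustering
  excludes all-zero profiles by default (configurable) and internally sorts
  cells by (profile, position) so the result is invariant to table row
  order. A brute-force dictionary recurrence (`evaluation.wpgma_reference`)
  and SciPy's `weighted` linkage serve as independent cross-checks in the
  test suite; the pipeline always uses the in-package implementation.
* **Entropy.** Per-cell profiles over N genes are one of 2^N N-bit words;
  the plug-in estimate H = −Σ p̂_k log₂ p̂_k (p̂_k = n_k/C, 0·log 0 = 0) is
  reported in bits per cell with no bias correction, together with each
  profile's contribution −p̂_k log₂ p̂_k and the number of profiles needed
  for 60/75/90% of H. H is bounded by N bits, attained exactly at
  uniformity over all 2^N profiles.
* **Robustness.** Perturbation experiments rerun segmentation → positivity
  for ±10% threshold changes on two genes (one coexpressed with the
  reference, one spread over a larger area), plus controls: one flipped
  cell-gene value, one third of entries re-randomized, a fully random
  table. Each perturbed atlas is compared to the original by ΔH, by the
  Pearson correlation of the original tree's cophenetic distances against
  the *perturbed* pairwise distances (the original tree is kept fixed, as
  the comparison is defined), and by the correlation of the two distance
  matrices. Flipping one cell among C can move two profile counts by one,
  bounding |ΔH| ≤ 2·log₂(C)/C + 2/C bits.
* **Expansion rates.** Per consecutive stage pair,
  (n_g(t+1)/n_g(t)) / (n_roi(t+1)/n_roi(t)): 1 means the domain grows with
  proliferation, <1 down-regulation, >1 recruitment.

## Benchmark problem sizes

The `evaluation` module fixes desk-scale problem sizes: 400-nucleus embryos
(300 for registration), 20 registration seeds, a J=9 leave-one-out cohort
with ≤2.5° domain-axis jitter (≈0.4·IND of boundary displacement), a
9-gene standard atlas for robustness, 5 planted disjoint domains for
clustering recovery, and 100 random ≤7-leaf tables for the WPGMA
cross-check. Registration benchmarks run from ground-truth centres so they
measure the mapping machinery in isolation (detection accuracy has its own
benchmark), and cohorts for rigid-recovery measurement disable radius
scaling, since a rigid estimate cannot (and should not) absorb a scale
change. Clustering recovery is scored against the rule-based truth — the
planted cap widened by the half-IND calling margin — i.e. exactly the cells
the positivity rule is designed to select.

## Known limitations

* The depth-attenuation factor assumes per-slice nucleus statistics are
  depth-independent apart from attenuation (see above).
* Greedy detection matching can differ from optimal assignment when
  detections are denser than half the match radius; at IND ≫ 4.2 µm this
  does not occur.
* WPGMA with many exact ties (binary profiles) yields one canonical tree
  out of several valid ones; all reported statistics are computed on that
  canonical tree.
* The rigid model ignores per-specimen scale; radius variability shows up
  in the positive-count discrepancy table rather than being corrected.
* The synthetic cohort shares one nuclear layout across specimens; true
  inter-individual pattern variability beyond pose, scale and domain-axis
  jitter is not modelled.
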