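# atlasforge

Construction and quantitative analysis of **cellular-resolution gene
expression atlases** from 3D fluorescence volumes of early embryos.

Early (blastula/gastrula-stage) embryos lack the morphological landmarks
that landmark-based registration needs, yet every in-situ experiment can
stain only one or two genes per specimen. `atlasforge` solves the resulting
integration problem: partial, high-resolution 3D views of individual
stained embryos ("analyzed" specimens) are mapped onto whole-embryo
"templates" through an anatomically defined referential plus rigid
refinement, so that expression patterns from many individuals are virtually
multiplexed onto one set of template cells. The result is a per-stage table
of cells × genes binary expression profiles that supports quantitative
analysis: coexpression, morphogenetic-domain clustering, synexpression
groups, and genetic entropy. A ground-truthed synthetic-embryo generator
makes the entire pipeline testable with no microscopy data.

The pipeline, stage by stage:

1. **Detection** — nuclear centres at the local maxima of a
   difference-of-Gaussians band-pass, `G(σ₁)∗I − G(σ₂)∗I`, thresholded at a
   fraction of its maximum; supervised parameters swept over
   σ₁ ∈ [2, 4] µm, σ₂ ∈ [8, 16] µm, thresholds 1–15%. The mean
   nearest-neighbour distance of the centres (the internuclear distance,
   IND) is the pipeline's cell-diameter yardstick.
2. **Segmentation** — per gene: threshold, morphological closing then
   opening with a ball one cell in diameter, largest connected component.
   A cell is *positive* iff its centre lies within the domain or within
   ½·IND of its border.
3. **Mapping** — fit a sphere to the outer nuclei; fit the blastoderm
   margin plane to the 5% southernmost nuclei; take the bilateral symmetry
   plane through the sphere centre and the reference-gene (gsc) centroid;
   the two planes define a right-handed trihedron (u, v, w) and origin O
   whose alignment initializes a rigid registration that maximizes
   normalized cross-correlation between distance-weighted embryo-shape
   maps.
4. **Atlas** — per template cell and gene, the repetition count
   V ∈ 0..J over J mapped specimens; mean domains by majority on V;
   leave-one-out boundary-distance statistics quantify mapping accuracy
   plus biological variability.
5. **Analytics** — pairwise coexpression fractions and Dice coefficients;
   topology trajectories; WPGMA hierarchical clustering of cells
   (morphogenetic domains) and of genes across stages (synexpression
   groups) with cophenetic diagnostics; Shannon entropy of the profile
   distribution, H = −Σ p̂ₖ log₂ p̂ₖ, in bits per cell (≤ N bits for N
   genes); robustness of all of it under segmentation-threshold
   perturbations.

## Worked example

```python
import numpy as np
from atlasforge import *

spec = EmbryoSpec(seed=0)
nucleus, genes, truth = generate_embryo(spec)
print(f"volume {nucleus.shape} at {nucleus.spacing} um, {len(truth.true_centers)} nuclei")

params = DetectionParams(sigma_small=2.8, sigma_large=12.0, threshold_fraction=0.07)
detected = detect_centers(dog_filter(nucleus, params), params)
score = evaluate_detection(detected, truth.true_centers, match_radius=4.2)
print(f"detected {len(detected)} centres, error rate {100*score.error_rate:.1f}% "
      f"(FP={score.n_fp}, FN={score.n_fn})")
ind = detected.ind
print(f"internuclear distance {ind:.1f} um")

domain = segment_domain(genes["gsc"], threshold_fraction=0.5, ind=ind, gene="gsc")
call = call_positive_cells(detected, domain, radius_factor=0.5)
print(f"gsc domain: {domain.mask.sum()} voxels, {call.n_positive} positive cells "
      f"(ground truth {truth.true_positive_flags['gsc'].sum()})")

frame = build_frame(detected, call)
print(f"sphere radius {frame.sphere_radius:.1f} um, dorsal axis v = {np.round(frame.v, 3)}")
```

prints

```
volume (173, 173, 40) at (1.5, 1.5, 3.0) um, 400 nuclei
detected 400 centres, error rate 0.5% (FP=1, FN=1)
internuclear distance 11.5 um
gsc domain: 6195 voxels, 27 positive cells (ground truth 25)
sphere radius 119.8 um, dorsal axis v = [-0.003  1.     0.004]
```

The synthetic embryo is a 120 µm-radius spherical cap of 400 near-contact
nuclei with a dorsal gsc-like domain. Detection with the expert band-pass
recovers all 400 centres at a 0.5% error rate; segmentation plus the
half-IND rule calls 27 cells positive against 25 in the ground truth (the
rule deliberately includes cells within half a cell of the border); the
fitted referential recovers the sphere radius to 0.2 µm and the
dorso-ventral axis to a fraction of a degree (the generator's dorsal axis
is +y).

The same flow runs end-to-end from a YAML config — generation, detection,
segmentation, frame extraction, registration, atlas assembly, analytics —
with per-stage artifacts and a replayable log of every supervised choice:

```sh
atlasforge run --config config.yaml --out artifacts/
```

Individual stages are exposed as `atlasforge
generate|detect|segment|callpos|frame|register|analyze`.

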