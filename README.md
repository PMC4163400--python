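# lungmorph

Automated morphometric analysis of fetal rat lung explants from stereo-microscope
images.

Lung branching morphogenesis studies culture fetal lung explants for several
days and quantify, from one image per day, the explant's **outer contour**,
the branched **inner epithelium**, and the number of **peripheral airway
buds** (terminal branch tips near the rim). Done by hand with generic curve
tools, this takes minutes per image and varies between researchers.
`lungmorph` automates the whole measurement chain and ships a synthetic
phantom generator with known ground truth, so every stage is testable without
microscope data.

## Method

Given an RGB image *f(x, y)* (768 × 576 px, 40 µm/px):

1. **Preprocessing** — channels are averaged and min–max normalized to
   [0, 255]; the image is denoised by Perona–Malik anisotropic diffusion with
   Tukey's biweight edge-stopping function
   g(x, σ) = ½[1 − (x/σ)²]² for |x| ≤ σ, else 0
   (defaults: 80 iterations, σ = 4.5), which flattens tissue while freezing
   flux across strong boundaries.
2. **Outer contour** — a global threshold *T* maximizes the total Shannon
   entropy E_B(T) + E_O(T) of the background/object histogram classes
   (Kapur's criterion). For low-contrast, rim-shadowed images, 8 rays cast at
   45° steps from the object centroid locate contour points C₁…C₈; a local
   entropy threshold is computed in a disc of radius D̄/4 at each, the eight
   levels are spread into a smooth per-pixel threshold surface by multilevel
   cubic B-spline approximation, and the image is re-thresholded against the
   surface. The contour is finally Gaussian-smoothed.
3. **Partitioning** — the gradient magnitude of the diffused image is treated
   as a relief; every pixel follows the steepest-descent flow line to a local
   minimum, and pixels draining to the same minimum form one primitive
   region, so region boundaries sit on gradient ridges.
4. **MDL clustering** — seeds are placed on each ray at the position of
   minimum mean intensity under a circular 8-px kernel (the epithelium is
   dark); clusters grow greedily from the seed regions by merging an adjacent
   region R_n into cluster C_i whenever the description-length gain

   G = nR_n·H(R_n) + nC_i·H(C_i) − nC_new·H(C_new) + b₁ + nb·b₂

   is positive and maximal — the pooled-intensity coding cost must be repaid
   by the b₁ + nb·b₂ bits saved on the vanished common boundary (b₁ bits per
   chain start, b₂ = 3 bits per 8-direction chain element, nb shared
   elements). Merging is evaluated inside a local circular window of at most
   100 primitive regions around the query region.
5. **Bud counting** — the epithelial mask is thinned to a 1-px skeleton;
   branched ends (degree-1 pixels) whose distance to the outer contour is
   below 25 % of the explant's vertical extent are counted by their distinct
   parent junctions.
6. **Morphometry** — areas (px² and µm²), traced-boundary perimeters
   (px and µm) and the bud count per explant; segmentations are scored with
   the Dice similarity coefficient DSC(A, B) = 2|A∩B| / (|A|+|B|), in percent.

## Worked example

Generate one day-2 phantom (with ground truth) and analyze it:

```sh
$ lungmorph phantom --days 2 --n 1 --seed 3 --out p2
wrote 1 phantoms to p2

$ lungmorph segment p2/phantom_d2_000.png --day 2 --out analysis
outer area 29216 px^2 (46745600 um^2), epithelial area 6225 px^2, epithelial perimeter 567.8 px, buds 3

$ lungmorph evaluate --manifest p2/manifest.json --out eval
             image  day  outer_dsc   epi_dsc  bud_error  n_buds  true_buds
phantom_d2_000.png    2  98.451539 90.644307          0       3          3
```

The segment line reports the explant's outer area (29 216 px² = 4.67 mm² at
40 µm/px), the epithelial area and perimeter, and 3 peripheral buds. The
evaluation row compares the masks against the phantom's ground truth: outer
contour DSC 98.5 %, epithelial DSC 90.6 %, and the bud count recovered
exactly (`bud_error` 0). `analysis/` also holds the binary masks, a color
overlay (outer contour yellow, epithelium red, skeleton white, branched ends
red, parents blue), the merge audit log and the resolved configuration.

The same operations are available as library calls:

```python
import lungmorph as lm
from lungmorph.phantom import PhantomSpec, generate_phantom

truth = generate_phantom(PhantomSpec(rng_seed=3, n_generations=3, n_buds_target=4))
result = lm.analyze_image(truth.rgb)
print(result.report.n_buds, lm.dsc(result.epi_mask, truth.epi_truth))
```

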