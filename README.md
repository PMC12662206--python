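# budoid-axis

Quantifying the proximal–distal axis of elongated organoid sections.

Limb-bud-like mesodermal organoids ("budoids") break symmetry and elongate,
forming a cartilage-forming (proximal) end and a fibroblast-rich (distal)
end. Sections profiled by targeted in situ transcriptomics yield a
segmentation mask, per-cell centroids and a cell-by-gene count matrix — but
no common spatial reference frame: every section has its own arbitrary
position, rotation and left/right handedness. `budoid-axis` turns each
section into a comparable one-dimensional expression profile:

1. **Structure segmentation** — morphological closing (disc r=50 px), hole
   filling, opening (disc r=20 px), largest connected component; masks near
   the image border are padded by 100 px first.
2. **Morphological midline** — the Euclidean distance transform of the mask
   is ridge-enhanced (Meijering neuriteness); the midline is the minimum-cost
   8-connected path over `1 − ridge` between the two Harris corners closest
   to the ends of the mask's major axis.
3. **Crowding-penalized cell projection** — cell *c* is assigned to the
   midline coordinate *i* minimizing `D_ic · exp(α·N_i)` where `D` is the
   Euclidean distance and `N_i` the number of cells already at *i*
   (α = 0.01); plain nearest-coordinate projection (α = 0) piles most cells
   onto a few coordinates.
4. **Orientation and polarization** — cells are binned into four equidistant
   arc-length bins; bin profiles are scored for a chondrogenic gene set
   (*Sox9, Acan, Col2a1, Col9a1, Col9a2, Col11a1*) and a fibroblast set
   (*Col1a1, Col3a1*) against expression-matched control genes. The half
   with the higher chondrogenic score is proximal; positions are scaled to
   [0, 1] with 0 = proximal. Both scores > 0.01 → *polarized*; both < 0.01 →
   *invalid*; otherwise *nonpolarized*.
5. **Domain analysis** — samples with < 180 detected genes are excluded;
   normalized expression is averaged per proximal/distal half; domain
   summaries are compared across conditions by the distance between
   proximal and distal centroids in PCA space (genes in < 1 % of cells
   dropped, mean imputation, per-gene standardization).

Mask morphometrics (area, moment-ellipse axes, elongation classes at axis
ratios 0.85/0.75, 200-bin major-axis intensity profiles) and a synthetic
organoid generator with known ground truth (bent-capsule masks, uniformly
scattered cells, Poisson/negative-binomial counts with opposing monotone
gradients) are included, so the whole pipeline is testable without any
external data.

## Worked example

Run the full pipeline on a simulated organoid (400×100 px capsule, 600
cells, opposing expression gradients with strength β = 4, Poisson noise,
seed 42):

```python
from budoid_axis import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(out_dir="demo_run"))
shape, scores = bundle["shape"], bundle["scores"]
print("elongation:", shape.elongation_class, "axis_ratio %.3f" % shape.axis_ratio)
print("midline length: %.1f px" % bundle["midline"].length)
print("proximal_score %.3f distal_score %.3f -> %s"
      % (scores.proximal_score, scores.distal_score, scores.polarization_class))
```

prints

```
elongation: long axis_ratio 0.259
midline length: 400.0 px
proximal_score 1.253 distal_score 0.888 -> polarized
```

The capsule is correctly called a long elongation (minor/major = 0.26 ≤
0.75); the extracted midline spans the full 400 px axis; both gene-set
scores clear the 0.01 threshold, so the section is *polarized*, and the
recovered proximal end matches the simulated ground truth
(`bundle["organoid"].true_orientation`). `demo_run/` holds every
intermediate artifact (structure mask, midline CSV, per-cell axis
positions, polarity JSON) plus a `manifest.json` recording all parameters.

The same stages are available as a CLI:

```sh
budoid-axis simulate --n-cells 600 --beta 4 --seed 42 --out sim/
budoid-axis midline --mask sim/mask.tif --out mid/
budoid-axis project --cells sim/cells.csv --midline mid/midline.csv \
    --mask mid/structure_mask.tif --out proj/
budoid-axis polarity --cells proj/assignment.csv --matrix sim/matrix \
    --midline mid/midline.csv --out pol/
```

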