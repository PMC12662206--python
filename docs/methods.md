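# Methods

## Problem setting

Each profiled organoid section provides three inputs: a binarized
cell-segmentation image, a table of cell centroids (pixels, row/col,
origin top-left), and a cell-by-gene count matrix from a targeted in situ
panel (~131 genes). Sections share no spatial reference frame, so
cross-section comparison requires (i) a per-section axis, (ii) a
projection of cells onto that axis, and (iii) a consistent
proximal→distal orientation. The package implements that chain plus the
mask-level morphometrics used to phenotype whole structures.

## Structure segmentation

The cell mask is closed with a disc of radius 50 px, hole-filled, opened
with a disc of radius 20 px, and reduced to its largest 8-connected
component. If any foreground pixel lies within 50 px of the image border,
the grid is padded by 100 px on all sides beforehand so the closing cannot
clip; the padding is kept and recorded as `pad_offset` so downstream cell
coordinates can be shifted consistently (removing it would force every
consumer to re-derive the shift). Disc morphology is computed via
exact Euclidean-distance-transform thresholding (`isotropic_closing` /
`isotropic_opening`), which is equivalent to an explicit disc footprint
and much faster at radius 50.

Defaults (50 / 20 / 100 / 50 px) assume images at roughly 0.3–1 µm/px
where an organoid section is several hundred pixels across; for other
magnifications they scale linearly and are exposed as parameters.

## Midline extraction

The midline is the ridge of the mask's Euclidean distance transform
(EDT): the crest of the EDT approximates the medial axis of an elongated
shape. Steps:

1. EDT of the segmented mask.
2. Meijering neuriteness filtering of the EDT (bright ridges), maximum
   response over scales σ ∈ {1, 3, 5, 7} px. The scale range covers crest
   widths from thin necks to ~15 px-wide plateaus; the response is min–max
   rescaled to [0, 1] so the routing cost `1 − ridge` is non-negative.
3. Candidate endpoints: Harris corner response of the binary mask
   (k = 0.05), peaks with relative threshold 0.01 and non-maximum
   suppression radius 10 px.
4. Anchor selection: the two candidates nearest (Euclidean) to the two
   *ends of the major axis*. The ends are taken as the mask pixels
   extremal along the moment-ellipse orientation. The alternative —
   centroid ± half the major-axis length along the orientation — is exact
   for straight shapes but drifts off (and outside) bent shapes, where it
   selects cap-rim corners ~20–30 px off-axis; the extremal-pixel form
   keeps the anchors on the structure for any curvature and is what makes
   midline recovery on bent capsules accurate to ~2 px.
5. Minimum-cost 8-connected path between the two anchors over `1 − ridge`
   (`route_through_array`, geometric step weighting: diagonal steps weigh
   √2× the mean of their endpoint costs). Pixels outside the mask carry a
   large finite cost (10⁶) so the path cannot leave the structure.
   Arc length accumulates 1 per axis step and √2 per diagonal step.

Degenerate inputs: an empty or multi-component mask, a constant ridge
response, or fewer than two corner candidates raise errors rather than
returning a guess.

## Cell projection

Cells whose rounded centroid falls outside the segmented structure are
removed (centroids out of grid bounds are dropped with a warning — they
indicate a coordinate-frame mismatch). Each remaining cell *c* is
assigned to midline coordinate `i* = argmin_i D_ic · exp(α·N_i)`, where
`D` is Euclidean pixel distance and `N_i` the current number of cells at
*i*; `N` is updated after each assignment. α = 0.01 by default; α = 0
reduces exactly to nearest-coordinate projection.

The sequential update makes the result depend on processing order, which
the scheme itself does not fix; cells are processed in ascending
`cell_id` order for determinism, and argmin ties break toward the smaller
index. Measured on a 200-cell clustered fixture, reversing the order
moves no cell more than 5 % of the axis length (mean ≤ 1 %): the penalty
can swap a cell between adjacent coordinates but not displace it
meaningfully, which is why the order convention is harmless for the
downstream 4-bin analysis. Exact same-index agreement under reordering
is low (~50 %), an intrinsic property of a 1 % multiplicative penalty
acting on near-tied adjacent-coordinate distances — not a numerical
defect.

## Normalization, gene-set scoring, orientation

Counts are per-cell total-count scaled to 10⁴ (the conventional target
for this normalization; configurable) and log1p-transformed.

A gene-set score is the mean normalized expression of the set minus the
mean of expression-matched controls: genes are ranked by average
expression and cut into 25 equal-size bins; for each set gene, up to 50
controls are drawn (seeded, without replacement, set members excluded)
from its bin. Consequences used as test oracles: a constant panel scores
0, additive shifts cancel, and a panel where set genes equal their
matched controls plus δ scores exactly δ.

Orientation: cells are partitioned into 4 equidistant arc-length bins and
the normalized expression is averaged per bin. The half (bins 1–2 vs 3–4)
with the higher mean chondrogenic score is proximal; positions
`s = arclen/total` are flipped if needed so s = 0 is proximal. The
proximal score is the chondrogenic score of the proximal half and the
distal score the fibroblast score of the distal half; computing both
scores on the whole-section profile instead is available via
`score_scope="whole"`. Empty axis bins are flagged and scores use the
available bins.

Polarization: both scores strictly > 0.01 → polarized; both strictly
< 0.01 → invalid; everything else — including scores exactly at the
threshold, which the three strict rules do not cover — nonpolarized.
Domain split: s < 0.5 proximal, s ≥ 0.5 distal (the boundary cell goes
distal).

## Domain analysis

Samples with fewer than 180 detected genes (count ≥ 1 in ≥ 1 cell) are
excluded. Domain summaries are per-domain means of the normalized layer.
For the cross-condition comparison, genes expressed in < 1 % of pooled
cells are dropped ("expressed" = count ≥ 1 in a cell), missing summary
values are mean-imputed per gene, each gene is standardized, and the
summaries are embedded by PCA; per condition, the separation statistic is
the Euclidean distance between the proximal and distal centroid in the
first 2 components (the full space is available via
`distance_components`). Per-gene proximal-vs-distal testing uses a
two-sided Wilcoxon rank-sum on per-sample domain means with
Benjamini–Hochberg correction (the correction method is this package's
choice).

## Synthetic organoids

The generator emulates an elongated, optionally bent section with a known
axis so every stage can be scored against ground truth:

* **Shape** — a capsule (stadium) of tip-to-tip length `length_px`
  (default 400) and width `width_px` (default 100), its spine bent along
  a circular arc of curvature `curvature` (1/px, default 0; must satisfy
  radius > width/2). The mask is the set of pixels within width/2 of the
  spine. The *true midline* is the spine extended straight along the end
  tangents to the cap tips, sampled at 0.5 px: the extracted midline is
  corner-anchored at the tips, so the recovery metric needs a reference
  spanning the full axis; over the central portion this coincides with
  the strict medial axis.
* **Cells** — `n_cells` (default 600) centroids uniform over mask pixels
  with sub-pixel jitter; each carries its true axial fraction `s_true`
  (nearest true-midline point, ties to the lower index).
* **Counts** — with p the axial position from the proximal end (the
  proximal end label is a fair coin drawn from the seed), chondrogenic
  genes have mean `base_rate·(1 + β(1−p))`, fibroblast genes
  `base_rate·(1 + β·p)`, and `n_background_genes` (default 123, panel
  size 131) flat background genes `base_rate` (default 2 counts/gene/cell,
  a typical targeted-panel depth). Noise is Poisson, or negative binomial
  with variance μ + d·μ² when `dispersion` d > 0. β (default 4) is a free
  parameter: the real gradients' effect size is not known, so β = 4 is
  chosen as a clearly detectable gradient (set-gene means differ 5× end
  to end) for recovery benchmarking, and β = 0 provides the null.
* **Intensity images** — in-mask intensity `0.5 + gradient·(s − 0.5)`
  (affine in axial position), zero outside.

All randomness flows from one seed through `numpy.random.SeedSequence`
sub-streams, so identical parameters give bit-identical output. What the
generator does *not* emulate: segmentation errors, optical blur, spot
decoding, irregular outlines, 3-D structure, or cell-density gradients.
Passing recovery tests therefore shows the algorithm chain is correct and
well-conditioned on idealized shapes — not that it is robust to imaging
artifacts of real sections.

## Benchmark problem sizes

Recovery rates are measured over 50 simulated organoids per condition at
the default parameters (β = 4 vs β = 0, 600 cells, base rate 2, Poisson);
midline recovery over curvatures {0, 0.001, 0.002}; the projection oracle
over 20 random 100-cell/50-coordinate instances. The PCA comparison uses
8 sections per condition: with 123 standardized pure-noise background
genes and only 2 retained components, fewer sections (e.g. 3) leave the
null condition's centroid distance dominated by sampling noise that can
exceed the gradient condition's signal; 8 sections — a realistic
per-condition section count for this kind of experiment — makes the
comparison stable.

## Known limitations

* The midline is a single path; branching or ring-like structures are out
  of scope by construction.
* Corner anchoring assumes the structure has two identifiable ends; near-
  circular masks (axis ratio → 1) have ill-defined orientation and may
  anchor arbitrarily.
* The sequential crowding penalty has no fixed-point iteration; results
  depend (boundedly, see above) on processing order.
* Intensity profiles sample a 1 px line through the centroid at the
  major-axis orientation; for strongly bent organoids the straight line
  can exit and re-enter the mask, and the profile covers only in-mask
  samples.
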