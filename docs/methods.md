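# Methods

## The grading model

A hemosiderophage's Golde grade is a five-level ordinal quantization of a
continuous quantity — the fraction of the cytoplasm occupied by hemosiderin
pigment. The package treats the grade in both forms: as a discrete class
(softmax classification, THS arithmetic) and as a continuous score (the
scaled-sigmoid regression heads, range [−0.5, 4.5], so that a rounded score
reproduces the five classes with half-unit guard bands at both ends).

Slide scoring follows the Doucet adaptation of the Golde system. The
canonical formulation grades exactly 300 cells and computes
Σ n_g·g / 3; this package generalizes to `THS = round(100 · mean grade)`
for any cell count, which is identical at N = 300, scale-invariant in the
counts, and reproduces the packaged reference table's score column for all
17 slides. Rounding is half-away-from-zero (the table prints 235 for
234.86). The diagnosis rule is strict: THS > 75. `grade_sd` uses the
population (n) denominator — this is what matches the reference table's SD
column — while the dataset summary of per-slide totals uses the sample
(n−1) denominator, which matches the printed "SD = 3,389". Three reference
rows print truncated rather than rounded values (slide 02's mean 0.72 for
0.7289, slides 08 and 15's SDs); the fixture flags them and the tests
accept "rounded or truncated" for exactly those rows.

## Synthetic slides

The generator emulates Prussian/Turnbull-blue-stained BALF cytospins: a
pale, faintly eosinophilic background; elliptical macrophages with a pale
cytoplasm and a light-red (nuclear-fast-red) nucleus; and dark-blue pigment
granules covering a per-grade fraction of the cell ellipse — defaults
(0, 0.15, 0.40, 0.70, 0.95) for grades 0–4, a monotone calibration chosen
once since no quantitative pigment-to-grade mapping is published. Granule
texture comes from thresholding a Gaussian-smoothed noise field at the
target quantile inside the cell mask, which pins the covered fraction
exactly (to rasterization error) while looking blobby-granular. Two
distractor types — hair streaks and extracellular pigment clumps — are
drawn *without* annotations to exercise false-positive behavior; both
stains look identical, so the staining enum is metadata only.

Default cell diameters are 60–140 px, matching macrophages of roughly
15–35 µm at 0.25 µm/px; the grade distribution defaults to the pooled
proportions of the packaged reference counts (0.372, 0.345, 0.173, 0.091,
0.019). `measure_pigment_fraction` inverts the generator with a fixed
color rule (blue-dominant, non-bright pixels within the inscribed ellipse)
and a threshold rule on that fraction recovers the true grade for ≥ 95% of
cells — this recoverability is what makes detector training on synthetic
slides meaningful.

What the generator does **not** emulate: real staining variability,
overlapping/touching cell clusters, out-of-focus regions, scanner color
profiles, and the ambiguity of intra- vs extracellular pigment. Passing
tests therefore demonstrate algorithmic correctness and end-to-end
trainability, not clinical-grade accuracy on real slides.

## Sampling

`random_hit_probability` is the area-ratio approximation
(patch area / slide area) for a uniformly placed patch covering one fixed
point. The two-stage cluster sampler picks a grade uniformly among grades
present, then a cell uniformly within that grade, then a patch offset
uniform among positions keeping the cell inside — every draw is guaranteed
a cell, and rare grades get 1/#grades of the draws regardless of their
frequency.

The quadtree sampler quarters the slide recursively. Two stopping rules
are supported: require ≥ `min_cells` (default 300) in every would-be child,
or split until a child's side equals the training patch size; the min-cells
rule is the default. Sibling probabilities are the module's own definition
(no published formula exists): a node's raw score is the sum over its cells
of `1/(global n_g + 1)` — inverse global grade frequency with additive
smoothing — floored at `min_prob` (default 0.01) of the sibling mass so
empty regions stay reachable, then normalized. The weight function is
injectable. Patch placement at the reached leaf is uniform over positions
*intersecting* the leaf (not contained in it), so cells on leaf boundaries
remain sampleable.

## Detector

A single-level RetinaNet-style design: a stack of stride-2
conv–batchnorm–ReLU stages downsamples the patch to one stride-32 feature
map (the "32 × 32 map" for 1024-px patches; for other patch sizes, the
stride-32 level), on which sit a shared 3×3 trunk and four heads:
6-way classification (five grades + background) under softmax focal loss
(α_t = 0.25, γ = 2 — the usual focal-loss convention), smooth-L1 box
regression in the standard center-offset/log-size parameterization, a
per-anchor cell-score head (scaled sigmoid, MSE against the matched cell's
grade), and a patch-score head on globally pooled backbone features (MSE
against the patch's mean grade, 0 for empty patches — the empty-patch
target being otherwise undefined). The training loss is the unweighted sum
of the four terms; the focal term averages over all non-ignored anchors,
the box and cell terms over positive anchors. The composite loss with two
MSE terms reflects the two grade-regression heads (cell-level and
patch-level); their weights default to 1 and are configurable.

Anchors are square by default (cells are round), three sizes per position.
Matching uses 0.5/0.4 positive/negative IoU thresholds plus a best-anchor
force match per truth. The force match matters geometrically: with anchor
centers on a stride-s grid, the worst-case center offset is s/2 per axis,
and a square cell of side d can only reach IoU 0.5 with *some* square
anchor if d ≳ 2.75·s; at stride 32 that is ~88 px, so cells of 60–88 px may
top out near IoU 0.42 and would go unsupervised without the force match.
The tiny preset (below) uses stride 16 with 44–64 px cells, where the 0.5
guarantee holds everywhere.

Training uses Adam (maximal learning rate 10⁻³, 100 epochs at full scale)
with geometric augmentation only — right-angle rotations and flips.
Intensity augmentation is **rejected by config validation**: shifting
staining intensity would change a cell's apparent hemosiderin content and
hence its grade label. Classification-head biases are initialized toward
background so early training is not swamped by false positives.

### Desk-scale preset

The `tiny_preset` runs the identical architecture at CPU scale: 128-px
patches, feature stride 16, anchors {44, 52, 60} px, four backbone stages
(8–64 channels), 60 epochs, box-term weight 2 (localization is the
binding constraint at this scale). The end-to-end demo trains on 240
cluster-sampled patches from two 512-px synthetic slides (40 cells each,
uniform grades, well-separated cells of 44–64 px) and evaluates on a
held-out slide; with the fixed demo seed it reaches mAP@0.5 ≈ 0.97 and a
THS within a few points of ground truth in under two minutes on one CPU.
These problem sizes are the package's chosen demonstration scale.

## Single-cell grading and baselines

The crop classifier/regressor share a small convolutional extractor and a
two-layer head, trained in two stages with Adam under a cosine decay from
the maximal learning rate (default 0.01): three epochs head-only (frozen
extractor), then twenty epochs fine-tuning everything. The regressor's
continuous score maps to a grade by round-then-clip — 2.49 → 2, 2.51 → 3 —
a discretization this package defines. Crop side defaults to 128 px (no
published value exists); crops are resized to 32 px for the compact nets.
Test-set construction mirrors the human-comparison design: a
representative set sampled uniformly from the pool and a balanced set with
exactly k cells per grade (defaults 1000 / 200).

The classical baseline concatenates three per-channel 32-bin intensity
histograms (bin count is this module's choice) and fits an RBF
support-vector regressor with complexity C = 0.1 against the patch's mean
grade (0 for empty patches); slide score = round(100 × mean patch
prediction). Predictions clip to [0, 4].

## Inference and evaluation

Slides are covered by overlapping tiles (default overlap 128 px ≥ one cell
diameter; desk scale 64 px) with the final tile per axis clamped inside the
slide. Per-tile detections shift to slide coordinates and merge with
class-agnostic greedy NMS at IoU 0.5 — cross-tile de-duplication is this
package's design, made testable by seam-straddling fixtures and a
tiling-invariance check. A detection's slide grade is its argmax class
(THS is defined on discrete grades); the continuous cell score is carried
alongside for interpretability. Detections below confidence 0.5 (the max
grade posterior) are dropped by default; the threshold is configurable. A
slide with no detections has an undefined score, reported as such rather
than 0.

AP follows the VOC definition with greedy confidence-ordered matching,
each truth matched at most once at IoU ≥ 0.5, duplicates counting as false
positives; the area under the precision envelope uses all-point
interpolation (the 11-point variant is available by flag). mAP averages
the five grades, excluding (and reporting) grades without ground truth.
Cohen's kappa, Fleiss' kappa and per-grade F1 wrap the standard
scikit-learn/statsmodels implementations with explicit degenerate-case
handling: kappa is NaN when expected agreement is 1, F1 is *absent* (not
0) for a grade with neither support nor predictions. `hypothetical_map`
formalizes "what mAP would perfect localization plus this grading
confusion give": with every cell detected at its true position with unit
confidence, a class's all-point AP reduces to precision × recall (the
conservative tie order with false positives first); classes without truth
are excluded.

THS error is the mean absolute per-slide THS difference (population SD
alongside); a per-patch aggregation is available by flag.

## Numerical and engineering choices

* `sideroscan.nn` is a float32 NCHW engine: im2col convolution, batchnorm
  (running stats, momentum 0.1, eps 1e-5), ReLU, linear, global average
  pooling, Adam. All backward passes are hand-derived and pinned by
  finite-difference tests (tolerance 5·10⁻³ relative, the float32 limit).
* Focal loss clamps p_t at 1e-12 before the log; p_t ≤ 0 is a domain
  error. Box decoding clamps log-size offsets at ±8.
* NMS ties in confidence break by input order (stable, deterministic).
* All randomness flows through `numpy.random.Generator`; the demo fans one
  global seed into per-stage 31-bit seeds via `SeedSequence.spawn`, so
  stages are reproducible in isolation and identical seeds give identical
  reports (and bit-identical synthetic slides).
* Checkpoints are self-describing `.npz` files embedding the config JSON.

## Known limitations

* Synthetic realism is deliberately limited (see above); mAP ≈ 0.97 on
  well-separated synthetic cells says nothing quantitative about real
  slides, which are substantially harder (touching cells, stain and focus
  variation, ambiguous extracellular pigment).
* The numpy engine targets compact models; the full-scale preset (stride
  32, 1024-px patches, five stages) is configured but impractical to train
  on one CPU.
* The quadtree probability formula reproduces the intended qualitative
  behavior (rare grades attract sampling mass) but is not a published
  formula; published worked percentages for specific slides are not
  reproducible without the original annotations and weighting.
* Reading proprietary scanner formats and the annotation database of the
  original tooling are out of scope; annotations exchange via this
  package's JSON/CSV schema and a COCO export.
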