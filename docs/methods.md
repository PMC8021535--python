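# Methods

`imic` implements immunofluorescence multichannel image cytometry (IMIC):
per-cell quantification of three antibody stains plus a DAPI nuclear
counterstain in FFPE tissue sections of upper-airway mucosa, and the
statistics built on top of it. This note records the model behind each
stage, the parameters that matter, what the synthetic phantoms do and do
not emulate, and the design choices made where the procedure was genuinely
open.

## The measurement model

A field is a 4-channel epifluorescence raster — DAPI, AF488
(pancytokeratin, epithelial cells), eFluor 570 (vimentin, connective
tissue), AF594 (CD45/CD18, leukocytes) — acquired with 14-bit camera
semantics (values in [0, 16383]) at a default pixel pitch of 0.25378 µm.
Epithelium and lamina propria (LP) are simple polygons in pixel
coordinates; artifact exclusions are polygons that override tissue
membership. Conventions: 0-based row-major arrays, pixel centres at
integer coordinates, closed polygon boundaries (an edge point is inside),
cells assigned to a region by nucleus centroid. Areas of polygons are
measured by rasterized pixel count, not the shoelace formula, so polygon
and mask areas agree exactly.

## Nuclear segmentation and the plausibility gate

Nuclei are detected in the DAPI master channel by Gaussian smoothing
(`smoothing_sigma_um`, default 0.4 µm), an Otsu or fixed intensity
threshold, hole filling and connected-component labeling. Components
large enough to be nucleus conglomerates (area above the gate's upper
bound) are split by a watershed on the Euclidean distance transform,
seeded at local maxima at least `min_split_distance_um` (default 4 µm)
apart. The *remove labels* gate then deletes nuclei with area outside the
closed interval [`area_min_um2`, `area_max_um2`] = [40, 100] µm²: below it
sit fragments of marginally cut nuclei, above it unsplit conglomerates.
The endpoints are retained because the exclusion is of areas *smaller*
than 40 and *larger* than 100 µm². The closed-interval test is exact, and
widening the gate can only grow the retained set.

The background sample is the complement of **all pre-gate** nuclear
pixels (gated-out nuclei are still nuclear material, so they stay
excluded), intersected with the analyzed tissue polygons. Background
"events" default to individual pixels; an optional tile mode averages
n×n pixel squares to tame camera noise.

## Cell-mask growing

Sectioning at 5 µm projects cytoplasmic staining both around and over the
nucleus, so each cell's mask grows outward *and* inward from the nuclear
margin, per channel, in rings of `step_width_um` (default 0.5 µm):

* outward: ring k is accepted while the ring's median intensity has not
  dropped by at least `step_drop_fraction` (default 0.5) relative to the
  previously accepted ring, and k ≤ `max_growing_steps` for that channel
  (AF488 2.0, eFluor 570 4.0, AF594 2.0). Fractional step counts mean
  fractional reach: the final ring is cut at
  `max_growing_steps × step_width_um` from the margin.
* inward: from the margin toward the centre under the same sudden-step
  rule until the centre is reached; the margin ring itself always belongs
  to the mask.

The "sudden step" needed a definition: a relative drop between
consecutive ring *medians*, because medians resist the single-pixel
outliers and partial neighbour overlaps that plague ring means. The
baseline for the first outward ring is the margin ring's median. Pixels
contested by several nuclei go to the nucleus with the nearer margin
(Euclidean distance), which makes the per-channel masks of different
cells disjoint by construction. The deeper eFluor 570 limit reflects
elongated fibroblast-like cells whose vimentin signal often starts away
from the nuclear membrane; on uniform images it makes every eFluor mask a
strict superset of the AF488 mask. The physical width of one growing
step is not a documented quantity anywhere we know of; `step_width_um` is
therefore an explicit free parameter.

## Intensity quantification

A cell record holds, per marker channel, the arithmetic mean m of the raw
pixel values over that channel's mask and the mask area; the background
statistic b is the per-channel median of the background events. No
normalization is applied by default: the downstream ratio gate is
invariant under any per-channel rescaling (multiplying a channel's pixels
by k multiplies every m and b by k and leaves every classification
unchanged), so a normalization step would be a no-op where it is correct
and harmful where it is not. An optional per-channel affine map is
available for users matching an external calibration. Cells with an
empty mask in any channel are flagged, excluded from threshold estimation
and classified negative.

## The positivity gate

For each channel, the threshold τ is the upper bound of the 95%
confidence interval of the median cell/background ratio, estimated on a
30% simple random sample of all cells (one sample, pooled across
specimens, reused for every channel; `floor(n × fraction)` cells, seeded,
at least 20). A cell is positive iff its own ratio **strictly** exceeds
τ. Two ratio definitions are supported:

* `quotient` (default): r = m / b;
* `printed_difference`: d = (m − b)/m = 1 − b/m.

They are linked by the strictly increasing map d = 1 − 1/r (for m, b >
0). Because the CI bound is an order statistic of the sampled ratios,
the two definitions classify every cell identically — a property the test
suite asserts exhaustively. The quotient is the default because realized
thresholds of the reference workflow exceed 1, which the difference form
cannot produce. The CI is distribution-free by default (binomial order-
statistic interval: bounds x(l), x(n−l+1) with l the largest rank whose
lower binomial tail is ≤ 2.5%; guaranteed ≥ 95% coverage with no
distributional assumption); a seeded percentile bootstrap is available
for comparison. Whether the original 95% CI was computed over cells,
patients or bootstrap replicates is not documented; both implemented
modes are labeled and neither is claimed to be the original.

A consequence worth knowing: an upper-CI-of-median cut marks just under
50% of any continuous unimodal sample positive. The gate is therefore
meaningful only where the marker-positive and -negative subpopulations
are separated and the threshold sample mixes them — which is why negative
controls must be gated with the thresholds of the matched *tissue* run
(see QC below), never with thresholds derived from the control itself.

The three per-channel booleans map bijectively onto 8 populations
(cytokeratin/vimentin/CD45-CD18 single positives, the three double
positives, triple positive, triple negative).

## Population analysis

Populations are cross-tabulated per (diagnosis group, region) stratum;
percentages use the stratum's own total as denominator, so each stratum's
8 percentages sum to 100 (epithelium and LP columns are only
interpretable per-stratum). Cells outside every tissue polygon are
reported separately and excluded. Comparisons: two-sided Wilcoxon
signed-rank for paired per-patient epithelium-vs-LP metrics (exact null
for ≤ 25 informative pairs, zeros discarded, normal approximation
beyond); pairwise pooled two-proportion z-tests across groups within a
population row, Bonferroni-corrected with m = number of pairs in the
row, flagging the larger-proportion group of each significant pair.
Quartile summaries use linear interpolation between order statistics.

## Quality controls

* **Isotype ROC** — per channel, tissue cell intensities vs isotype-
  control cell intensities through the Mann–Whitney construction
  (AUC = U/(n₁n₂), ties mid-ranked) with the Mann–Whitney p-value; the
  AUC is invariant under monotone intensity transforms. Control cells
  gated with the tissue run's thresholds should be almost entirely triple
  negative.
* **Spillover** — each single-stain slide runs through the full pipeline
  with the multiplexed run's thresholds; the report gives the fraction of
  cells called positive in the two off-target channels for each of the 6
  source→target pairs, against a configurable 1% bound. Spillover is
  measured, not corrected: no compensation is applied to pixel data.

## The synthetic tissue phantom

The generator emulates the tissue architecture the method was built for:
a pseudostratified epithelial band (default 10% of the field height,
giving an epithelium-to-LP area ratio close to the measured one) over a
lamina propria, at 3486 cells/mm², with lognormal nucleus areas (median
64 µm², log-sd 0.10, matching the reported quartiles), elliptical nuclei
with axis ratio uniform in [1, 2.5], and a cytoplasmic annulus of 2 µm
(fibroblast-like vimentin-single-positive cells get an elongated halo, +4
µm along the major axis, to exercise the deeper eFluor 570 growing
limit). Cell counts are Poisson in the field area; nuclei are placed by
rejection sampling with a 1 µm minimum border separation (an explicit
error names the achievable density if placement saturates). Half of the
cytokeratin-single-positive LP cells cluster into gland patches (8/mm²,
25 µm Gaussian spread) mimicking seromucous glands. The default lineage
mix in both regions is the all-patient mean population distribution (26 /
13 / 6 / 23 / 3 / 10 / 11 / 8% in the display order of the population
table).

Optics: expressing cells add specific signal on their annulus (defaults
600/800/500 camera units for AF488/eFluor 570/AF594, cell-level CV 0.2)
over a diffuse background (200 counts in marker channels, 100 in DAPI);
the three marker channels mix through a 3×3 spillover matrix (default
off-diagonals 0.005, i.e. the sub-1% crosstalk regime); additive Gaussian
noise (σ 20, DAPI 10) and clipping to [0, 16383] finish the image. The
signal levels are calibration knobs chosen to land realized
cell/background ratios in the 1.4–2.7 range of the reference workflow;
per-lineage intensity distributions are not documented anywhere, so these
are explicitly not claims about tissue.

Isotype-control and single-stain slides are generated from the same
seed with the random stream consumed identically, so DAPI content is
bit-identical and controls are pixel-aligned with their phantom.

What the phantom does **not** emulate: optical PSF and defocus, 3D
sectioning artifacts (partially cut nuclei appear only through the area
law's tails), shot noise (noise is additive Gaussian, adequate for gating
logic), realistic autofluorescence spectra, tile stitching, and nucleus
clumping beyond the contact the 1 µm separation allows. Passing tests on
phantoms therefore validate the *logic* of segmentation, growing, gating
and tabulation against known truth — not performance on real slides,
where touching nuclei and autofluorescence texture are harsher.

## Numerical choices and degenerate inputs

Blank DAPI yields an empty label map, not an error. A degenerate ratio
sample (all equal) gives a zero-width CI. Quotient ratios require b > 0
(enforced); printed-difference ratios flag cells with m ≤ 0. Ties in
sampled ratios are broken by stable sorted order. The exact Wilcoxon
null requires tie-free ranks; with ties the implementation falls back to
scipy's handling. Percentages of empty strata are reported missing, not
zero. All randomness (placement, noise, threshold sampling, bootstrap)
flows from explicit integer seeds; identical configuration and seed
reproduce byte-identical outputs.

## Problem sizes used in the shipped checks

The default phantom is a 1 mm² field (~3500 cells), used for the
segmentation-fidelity and density checks; the full-pipeline population-
recovery check runs a 2×2 mm field (~14,000 cells), the scale of a
typical per-patient scan region; QC and end-to-end tests use 0.06–0.35
mm² fields, enough for stable thresholds (threshold samples of 60+
cells). The acceptance script reruns the whole chain, controls included,
on a 1 mm² field.

## Known limitations

* Commercial tissue-cytometry packages keep their exact segmentation and
  growing parameters proprietary; the implemented smoothing + threshold +
  watershed family and the ring-median stopping rule reproduce the
  documented behaviour of such workflows, not any vendor's exact output.
* The gate's behaviour depends on the positive fraction per channel: if
  far more than half of all cells express a marker, the sample median —
  and hence τ — moves into the positive population and sensitivity
  drops. This is a property of the method, inherited by design.
* Region assignment by nucleus centroid misassigns cells straddling the
  epithelium–LP boundary by up to one cell diameter.
* Overlapping cytoplasmic annuli of adjacent cells leak signal into each
  other's masks and create spurious double positives — the same overlay
  artifact described for real tissue; on default phantoms it shifts
  population percentages by ≲ 2–3 points.
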