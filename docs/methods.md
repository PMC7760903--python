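# Methods

This note documents the statistical model behind `thermopattern`, the
choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Data model

An annotated thermogram is a pair (temperature grid, class map) of
identical shape; class labels 1–15 name regions of interest (ROIs) over
superficial muscles and 0 marks background. Pixels are addressed
row-major, 0-based, origin top-left; every extraction order derives
from that convention, which is what makes seeded subsampling
reproducible. Annotated temperatures must be finite and inside a
[−20, 60] °C sanity window; non-native grid shapes are accepted but
flagged. The portable on-disk format is plain CSV grids plus a YAML
manifest; temperatures are stored with six decimals so a round-trip is
exact to well below 1e-6 °C, and class maps round-trip bit-exactly.

Groups of ROIs (GORs) are named unions of ROI labels. The default ten
overlap by design (ROI 9 alone belongs to Hindquarter, Rump, Ventral
aspect and Legs); a pixel contributes to every group containing it and
is never deduplicated, within or across groups. Pooling over a species
concatenates animals' pixels, so animals contribute proportionally to
their annotated area — there is no per-animal reweighting.

## Testing scheme

All comparisons are two-sample, one-sided Mann–Whitney–Wilcoxon (MWW)
tests at α = 0.001 on equalised samples:

* **Equalisation** (`min_whole` rule): n = min of the two sizes; the
  smaller sample enters whole, the larger is subsampled uniformly
  without replacement. An alternative `subsample_both` rule draws both
  sides, for sensitivity analysis. Each comparison owns an RNG stream
  derived by SHA-256 hashing of (seed, species, scope, pair, animal),
  so results are bit-identical under a fixed seed and independent of
  evaluation order.
* **Direction**: the tested alternative is the sign of the observed
  mean difference — the score is for the observed ordering itself. On
  null data this roughly doubles the nominal one-sided level (to ≈
  2α); the type-I validation study measures the realised rate, which
  stays well under 0.005 because the normal approximation with
  continuity correction is conservative at α = 0.001.
* **Implementation**: for combined sizes ≤ 12 without ties, the exact
  U distribution (via `scipy.stats.mannwhitneyu(method="exact")`,
  checked in the tests against an independent brute-force enumeration
  of rank assignments); otherwise the tie-corrected normal
  approximation with continuity correction. Fully tied input carries no
  ordering evidence and returns p = 1.0 with a `tie` flag (the other
  defensible convention, p = 0.5, differs only in reporting; 1.0 was
  fixed once and documented).
* **No multiplicity correction** is applied over the 45 group pairs;
  the fixed p < 0.001 threshold is the decision rule, deliberately.

The difference matrix stores Δ(i,j) = mean(i) − mean(j) over pooled
pixels (exactly antisymmetric); global significance flags are computed
once per unordered pair and mirrored. Local counts test each animal in
the *global* direction, so an animal whose own contrast is reversed
never counts as support. Animals missing a group's pixels are skipped
for that pair and logged. Pairs with an exactly zero pooled difference
are non-significant by convention.

Cross-species classification works on the canonical cell (i < j): same
signs give SPS/SP, horse-positive/donkey-negative gives HWS/HW, the
reverse HCS/HC; the S-suffix requires global significance in *both*
species, and the class is defined on the unordered pair (the mirrored
cell gets the same tag). Minimum shared-animal counts are the minimum
of the two species' local counts, defined only for significant
classes. Compliance of one animal against a reference matrix requires
sign agreement *and* local significance in the reference direction;
references are built leave-one-out when the animal belongs to the
reference species.

## Synthetic generator

Pixel model: T = base + b_a + o_r + ε, with per-animal intercept
b_a ~ N(0, animal_sd²) shared across the whole animal, fixed per-ROI
offsets o_r, and pixel noise ε (Gaussian, or a mean-centred
two-component mixture for multimodal regions). The intercept cancels
exactly in within-animal group contrasts but widens pooled species
distributions — the decomposition the local/global test distinction
relies on. Layout is a 3×5 grid of equal rectangular ROI blocks
(native raster 240×320 → 76×60 px per ROI): pattern statistics depend
only on label sets, so anatomical shapes are unnecessary; equal block
sizes make every GOR mean a plain average of its member-ROI means.

The `study-like` preset encodes the published population it emulates:

* pooled levels 22.72 °C (horses) and 18.88 °C (donkeys) with pooled
  sds 2.46/2.30 °C. The pooled sd is decomposed as animal_sd = 1.5 °C
  (the between/within split is not published; this is a fixed,
  documented choice) plus the variance of the regional profile, with
  pixel_sd balancing the remainder (≈1.72 °C horses, ≈0.88 °C donkeys);
* regional GOR profiles with Rump/Legs coldest and Neck/Front quarter
  warmest, the horse Rump−Neck contrast at −2.12 °C, five horse group
  pairs and two donkey pairs with exactly equal means (the published
  non-significant exceptions), and exactly four pairs with opposite
  sign between species (three involving the Dorsal aspect);
* cross-species per-ROI differences anchored at 1.59 °C (ROI 4, the
  minimum) and 5.26 °C (ROI 7, the maximum), all others strictly
  between;
* metadata from truncated Gaussians: hair coat 1.78±0.38 cm (horses)
  vs 3.39±0.46 cm (donkeys); SF-Skin 8.80±0.87 vs 12.01±0.83 mm;
* optional outliers: D.17, uniformly 4 °C colder with a 7.6 cm hair
  coat, and D.18 with +3.5 °C patches over 60 % of Trunk/Rump/Legs;
  both flagged excluded from formal selections.

The GOR definitions impose a linear identity — Ventral aspect
{9,10,11,12,13} is the disjoint union of Legs {9,13}, Groins {10,12}
and Abdomen {11}, so 5·G7 = 2·G10 + 2·G9 + G8 holds for any offset
assignment — and the preset's target profiles respect it. Because
overlapping groups carry different target means, the profile cannot be
written as a per-GOR offset map; the preset therefore stores per-ROI
offsets (solved once from the target levels by a least-norm linear
solve and frozen as constants), while per-GOR offset maps remain
supported for custom configurations, with conflicting assignments to a
shared ROI rejected rather than averaged.

### What the synthetic data does and does not show

Passing on study-like data demonstrates that the machinery recovers
designed structure: contrast signs, tie pairs, the cross-species
taxonomy, outlier detectability, determinism and calibration. Two
caveats about realism:

* The additive model has no animal×region interaction, so any nonzero
  contrast is locally significant for essentially every animal at
  these pixel counts. Stable-pattern counts on synthetic data
  therefore equal the significant-pair counts (≈40/45 horses, 43/45
  donkeys) — real animals, whose regional contrasts vary individually,
  show far fewer stable patterns. Likewise the uniformly cold outlier
  stays compliant almost everywhere, because a level shift cannot
  change within-animal contrasts.
* Rank tests at pooled sizes of 10⁵ pixels detect *any* distributional
  asymmetry. Two groups with equal means but different mixture shapes
  (a heterogeneous group versus a single-ROI group) can still be
  declared significant; the preset's tie pairs were chosen so this
  effect stays below the threshold at the default geometry, but it is
  a property of the method worth remembering on real data.

## Visualization conventions

Thermal maps use a 256-entry violet→red lookup table (HSV hue 0.75→0 at
full saturation/value), linear over the common range ⟨8.8, 30.65⟩ °C —
the extreme annotated temperatures of the study population — with
values clamped at the endpoints and unannotated pixels black;
`per_animal` mode stretches to the animal's own annotated range. The
table approximates the published figures without claiming pixel parity.
Histogram heights follow the counts/total convention (heights sum to
one); `true_density` divides by bin width as well. Boxplots use
linear-interpolation quartiles; whiskers sit at the most extreme
observations within q1 − 1.5·IQR and q3 + 1.5·IQR (the standard Tukey
rule — the source description's upper fence contains an evident sign
slip), and points beyond them are outliers.

Feature vectors use one statistic per ROI (mean, sd, skewness, excess
kurtosis — normal = 0, a convention fixed here); minimum pixel counts
of 1/2/3/4 apply, with under-filled ROIs flagged missing and such
vectors excluded from embedding rather than imputed. t-SNE (perplexity
5, PCA initialisation) runs with a fixed seed for reproducibility — a
deliberate replacement of curated representative runs — and only
neighbourhood structure in the embedding is interpretable.

## Problem sizes and numerical choices

The test suite exercises the statistics at reduced rasters (60×100 and
30×50 grids, 324 and 64 px per ROI) chosen so every designed effect
retains power ≈ 1 while the full suite stays fast. The acceptance
script uses the native raster for the single "study" analysis, 48
reduced-raster replicates to average population scalars (pooled means
and per-ROI species differences carry the sampling noise of only 16
animal intercepts per species, about ±0.4 °C per dataset), and 200
null replicates for the type-I study, whose rejection rate is pooled
over the 45 pairs (200 replicates resolve a per-pair rate only to
1/200, so the pooled rate is the meaningful calibration estimate).
Comparisons of reloaded temperatures use an absolute tolerance of
1e-6 °C; matrix antisymmetry is exact by construction, not to
tolerance.

## Known limitations

* Geometry is schematic (rectangles); nothing about spatial adjacency,
  left/right symmetry or acquisition physics (emissivity, ambient
  reflection, camera calibration) is modelled.
* One record per animal; handling of multiple views per animal is left
  to the user at manifest level.
* The taxonomy's HW/HC labels for non-significant opposite pairs
  follow the same orientation rule as their significant counterparts;
  orientation for such pairs is sign-of-noise on near-tied data and
  should not be over-read.
* No effect sizes beyond Δ and no multiple-testing machinery, by
  design; add them downstream if needed.
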