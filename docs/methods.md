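# Methods

## Scope and data model

The package analyses single, isolated pachytene chromosomes. An input is a
multi-channel image (channel 0 = DAPI/PI counterstain; optional FISH or
antibody channels) with a μm/pixel calibration, or directly a 1-D axial
profile. All axial coordinates are μm from the short-arm terminus; image
pixel coordinates are 0-based `[row, col]`. Absent table values are kept
absent (`None`), never coerced to 0. The packaged karyotype and FISH-marker
tables are UTF-8 TSV transcriptions, with `mean±sd` kept in one cell and
split at parse time; both round-trip byte-identically through the canonical
writer, which is how fixture integrity is tested.

## Synthetic data generator

Real squash-preparation microscopy is emulated only to the degree the
downstream analysis is sensitive to it:

- **Axis**: line, circular arc, sinusoid, or polyline, parameterized by arc
  length; self-approach closer than a tube diameter is rejected because
  straightening would be ill-posed.
- **Axial intensity**: baseline 50 AU plus one Gaussian bump (σ = 0.15 μm,
  amplitude 100 AU) per chromomere. Heterochromatic blocks multiply bump
  amplitudes (default ×2). The centromeric constriction is a Gaussian dip
  in the baseline (depth 0.7, σ = 0.4 μm) — an intensity rendition of the
  primary constriction.
- **Image**: the axis becomes a tube of Gaussian cross-section
  (σ = 0.35 μm); FISH spots are 2-D Gaussians (σ = 0.3 μm) at their mapped
  axis coordinate; the camera adds Gaussian read noise (optional Poisson
  shot noise) last. Default calibration 0.1 μm/px — a repo convention, as
  no calibration is published for the original material.
- **Per-chromosome fixtures**: total length, centromere position and
  chromomere count come from the packaged karyotype table. For a published
  count of *n* the layout plants *n*+1 bumps: a pair flanking the
  centromere at ±0.5 μm (inside the ±1 μm merge window) and *n*−1 bumps
  spaced evenly along the arms (0.5 μm end margins, 1.5 μm clearance to the
  centromere), allocated to arms in proportion to arm length.
  Heterochromatic blocks follow the qualitative per-chromosome
  descriptions: whole short arm plus proximal long arm for chromosomes 4
  and 10, pericentromeric blocks for 5–8, long-arm blocks for 9 and 11, a
  short-arm block for 12, none for 1–3.
- **Dual-channel fixture**: 19 evenly spaced counterstain chromomeres on a
  20.07 μm chromosome (7 short + 12 long); 16 of them receive an antibody
  bump displaced by at most 0.1 μm. With 0.3 μm matching tolerance and
  ≈1 μm spacing the planted coincidence set is recovered for every seed.

What the generator does **not** model: overlapping or touching bivalents,
nucleoli and neighbouring chromosomes, 3-D defocus, photobleaching,
chromatic shift between channels, and spatially varying background. Passing
tests therefore demonstrate the correctness of the measurement chain on
idealized single chromosomes, not segmentation robustness on crowded real
slides.

Determinism: every generator takes an explicit seed; identical spec + seed
is bit-identical. The pipeline derives per-stage streams from one run seed
via `SeedSequence.spawn`.

## Straightening

The counterstain channel is Gaussian-blurred (0.3 μm) so the beaded
chromomere string thresholds as one object, thresholded by Otsu,
morphologically closed (radius 0.8 μm) so the dim centromeric constriction
cannot split the mask, reduced to its largest connected component and
hole-filled. The skeleton's longest endpoint-to-endpoint path (Dijkstra
over 8-connected skeleton pixels, ties broken by mean intensity) is
smoothed with a cubic spline whose smoothing factor is 0.05× the point
count, extended along the end tangents to the mask boundary, and trimmed at
each end by half the local tube radius (distance-transform value at the
skeleton endpoint). The extension compensates skeleton end-shortening; the
trim compensates the cap rounding the mask adds beyond the true terminus.
These three constants were fixed by validating recovered arc length against
analytic curves (line, semicircle, sinusoids) at zero and moderate noise;
across those cases the length error stays within ±1.2%, against the ±2%
acceptance band. Straightening resamples perpendicular cross-sections at
1-pixel arc-length stations with bilinear interpolation, identically for
all channels; orientation flips the column order so column 0 is the
short-arm terminus, with an arm-designating marker channel overriding the
lesser-arm-from-centromere rule (needed when the designated short arm is
physically longer, as for chromosome 3).

## Profiles and chromomere segmentation

Axial profiles aggregate each straightened column (mean by default, max
optional), subtract the modal off-axis level (median of the outer rows) and
floor at zero. Detection smooths with a 0.15 μm Gaussian, takes strict
local maxima, and keeps those whose topological prominence exceeds
`min_prominence_rel` (default 0.15) × the local baseline (median within
±`window_um`, default 2 μm) — all thresholds relative, so calls are
invariant under global intensity rescaling. Boundaries sit at the deepest
minima between adjacent kept peaks, ties resolved toward the midpoint. With
a centromere position given, the two flanking peaks within the ±1 μm merge
window fuse into one centromeric chromomere (reducing the count by exactly
one when both sides have a peak) and indices are assigned outward from it.
The exact prominence statistic of the original imaging software is not
published; only the relative-to-adjacent-regions principle is, so the
window, threshold and smoothing defaults are repo conventions, recorded in
every result, chosen so the published per-chromosome counts are recovered
exactly at zero noise and in ≥95% of seeds at SNR 10 (they recover in
100% of the 240 tested seed×chromosome combinations).

**Condensation classes.** A chromomere is condensed iff its mean intensity
exceeds the chromosome-wide mean by more than `k_sd` (default 0.5) standard
deviations, with both statistics taken across the chromosome's segment
means. Taking the statistics across segments rather than raw samples makes
the call a comparison of chromomeres with chromomeres; pointwise statistics
are dominated by the spiky intensity texture within chromomeres and would
make the stated examples (2× blocks flagged at k_sd = 1) unreachable.
Contiguous condensed segments merge into heterochromatic blocks.

**Centromere location.** `fish` takes the peak of the pericentromeric
repeat channel. `constriction` finds the deepest interior minimum (10% end
margins) of the baseline envelope: a grey erosion 0.7 μm wide first removes
chromomere bumps — including the tall pair flanking the constriction, which
would otherwise fill the dip under plain smoothing — followed by a 1 μm
median filter against noise-extreme minima and a light Gaussian. The two
methods agree within 0.3 μm on the image fixtures.

**Graygram.** Intensities are quantile-binned into `n_levels` gray levels
(ties share the lowest applicable level, so a constant trace is a single
level); higher level = darker ink = brighter fluorescence.

**Peak matching.** Two channels' peak lists are paired greedily by
nearest-neighbour distance; a pair counts iff |Δposition| ≤ tolerance and
each peak is used once. The count is symmetric in the two channels on all
fixtures.

## Karyotype metrics

Compaction, arm ratio, Levan class and marker-position conversions are
exact quotients of tabulated means, kept at full precision and rounded
half-up to two decimals only for reporting. Levan boundaries (1.7, 3.0,
7.0) follow the 1964 convention; ratios below 1 are reported as-is but
classified via the reciprocal. Two closure checks ship as first-class
results: all 36 compaction cells recompute within print precision except
the chromosome-4 short arm (9.86/4.87 = 2.0246 vs printed 2.03, consistent
only with the unrounded arm-length mean), and 11 of 12 marker rows convert
percent→μm within 0.02 μm, the 5S-rDNA row on 11S deviating by ≈0.11 μm.
Both are *flagged*, never forced: an internally inconsistent printed cell
is reported with its deviation.

Condensation dynamics divides a chromosome into regions by ordered
landmarks (region I = short arm, II–V on the long arm) and reports, per
region, the percent reduction from the stage where the region is longest to
the stage where it is shortest. Applied to the stage-series generator this
inverts the planted contraction vector exactly; the demo condition uses
contractions peaking at 65.6% (region III) with a 15.8% minimum
(region IV). No raw multi-stage image series is distributed with the
source material, so region-wise dynamics are validated by this inverse
property rather than by re-measuring archival images.

## Map integration

Each map is a per-arm column over the 24 arms. The nucleotide and pachytene
columns derive from the packaged karyotype table. The linkage, somatic,
repeat-count and gene-count columns are **synthetic stand-ins** (the cited
public resources publish no per-arm values in the source tables): generated
once with a fixed seed and frozen into `arms_synthetic.tsv`, constructed to
carry the documented qualitative structure — proportionality for the
somatic column (per-arm 0.09–0.18 μm/Mb), a clearly nonzero intercept for
linkage, repeats and genes. Their fixture header states this provenance.

Regression is OLS (statsmodels) with a two-sided intercept t-test at
α = 0.05; through-origin refits drop the intercept column (one fewer model
degree of freedom), and both 95% confidence and prediction bands come from
the adopted model's prediction machinery. Empirical prediction-interval
coverage is calibrated at 95% ± 2% over 10,000 simulated points (200
training fits × 50 fresh points). `MapColumn` carries a per-arm exclusion
flag (e.g. for the NOR-bearing 9S arm, whose tabulated μm length and Mb
content cover different extents), but the packaged pachytene comparison
keeps all 24 arms: with 9S included the intercept test does not reject
(p ≈ 0.15, through-origin adopted) and every arm lies inside the 95%
prediction band, whereas excluding it flips the intercept decision — the
all-arm fit is therefore the configuration under which the documented
statistical behaviour holds. Relative lengths (short% + long% = 100 per
chromosome) put all maps on one scale for the side-by-side rendering,
whose per-chromosome bar heights are adjusted to the pachytene ratios; SVG
output is byte-deterministic (fixed hash salt, no timestamp metadata).

## Pipeline, sizes and limitations

The demo pipeline (simulate → straighten → profile → metrics → integrate →
dynamics → immunostaining) runs in a few seconds on one CPU and writes a
JSON report that validates against a packaged schema and reproduces
byte-identically under a fixed configuration. Problem sizes throughout
(profiles of 170–390 samples at 0.1 μm, images up to ≈450×250 px, 20-seed
noise sweeps, 10,000-point coverage simulations) were chosen so the whole
suite exercises every claim in well under a minute while keeping every
statistical check comfortably powered.

Known limitations: the straightening geometry is validated on synthetic
tubes only and assumes a non-self-approaching axis; condensation classes
depend on the segment partition (no sub-chromomere structure); the
constriction caller assumes a single primary constriction and can be
distracted by an equally deep secondary constriction; and the synthetic
linkage/somatic/repeat/gene columns support method demonstrations, not
biological conclusions about those maps.
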