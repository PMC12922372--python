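# Methods

`nctquant` quantifies nucleocytoplasmic-transport (NCT) disruption in
multi-channel 2-D fluorescence images and tests group differences with
rank-based, cluster-robust statistics. This note documents the models,
conventions, defaults, and the deliberate design choices behind them.

## Compartment model

Each cell is represented by boolean masks on the image grid (0-based,
row-major, pixel centers at integer coordinates):

- **nucleus** — from the DNA stain (DAPI): global threshold (Otsu by
  default, fixed-value and percentile available), hole filling, removal of
  components below `min_nucleus_area_um2` (default 10 µm²).
- **whole cell** — from a cytosolic marker (ChAT/NeuN, Vimentin, ...):
  threshold, then each foreground component is assigned the nuclei it
  contains; components holding several nuclei are split by a geodesic
  nearest-nucleus partition (watershed constrained to the foreground). The
  nucleus is always union-enforced into its cell, so `nucleus ⊆ cell` holds
  by construction.
- **cytosol** — `cell AND NOT nucleus`, computed on construction (the same
  Boolean rule used by imaging flow cytometry mask logic).
- **laminar ring** — `dilate(nucleus, outer) AND NOT dilate(nucleus,
  inner)` with disk structuring elements; the default laminar ring is
  inner 0 µm, outer 1.3 µm. A 1-px **envelope band** and a configurable
  **perinuclear band** cover the post-mortem-tissue variants, where
  envelope signal is normalised by the nucleoplasm and cytoplasmic XPO1 is
  read in a narrow band around the nucleus rather than the full cytosol.
  The reported widths of those bands in the source protocols are mutually
  inconsistent at a single magnification (1 px ≈ 0.3 µm vs 1.5 px ≈ 4.5
  µm), so both are plain configuration values (`envelope_band_px`,
  `perinuclear_width_um`) and neither is treated as ground truth.

µm→px conversion is round-half-up everywhere (`um_to_px`). Background is
the median intensity outside the union of cell masks dilated by a 2-px
guard band; a manual value can be supplied instead.

## Intensity metrics

- **C/N ratio** `(mean_cytosol − bg) / (mean_nucleus − bg)`; the N/C
  gradient is its reciprocal orientation. Non-positive denominators make
  the cell's value undefined: it is excluded and logged, never clipped or
  imputed.
- **Laminar intensity** — ring mean minus background; negative values are
  returned as-is (flagged upstream).
- **Envelope/nucleoplasm ratio** — 1-px band mean over the mean of the
  nucleus eroded by the same width; the nucleoplasm is the normaliser, so
  no external background enters.
- **Normalisation to control** — values divided by the control group's
  mean within each independent experiment; afterwards the control mean is
  exactly 1 per experiment.

## Boundary walk, perimeter, circularity

One Moore-neighbour boundary trace backs both circularity and the
continuity index, so every quantity divides by the same perimeter. Arc
length uses Kulpa-calibrated step weights (0.948 axial, 1.340 diagonal)
rather than the naive 1/√2 weights: the naive weights overestimate smooth
contours by ~5.5% on average (a digital circle of radius 50 px measures
329.7 px against the true 314.16), which would bias circularity to ~0.91
for a perfect disk. With the calibrated weights the same disk gives 1.009.
Raw weights remain available (`calibrated=False`) for exact step-count
arithmetic on axis-aligned shapes. Circularity is `4π·area/perimeter²`
with area = pixel count × pixel area.

## Envelope profile and continuity index

The nucleus boundary is traced counter-clockwise from the
topmost-then-leftmost boundary pixel. At each boundary pixel the rim
intensity is the maximum of the image sampled bilinearly along the outward
normal (approximated by the ray from the nucleus centroid — exact for
circles, adequate for the bounded eccentricities generated and observed)
over the ring width. Radial sampling matters: a square max-window would
bleed rim signal tangentially into gaps and bias the continuity index
upward by roughly the window width per gap edge.

The continuity index binarizes the profile at a threshold and reports
supra-threshold arc length / perimeter (1 = unbroken rim); fragments and
gaps are maximal circular runs. Binarization is strict (`>`), so a
threshold equal to the background classifies pure-background rim positions
as gap. The default threshold is
`background + 0.5·(P90(rim intensity) − background)`. The 90th percentile,
not the median, estimates the rim signal level: the median of rim
intensities collapses onto the binarization boundary precisely when half
the rim is missing, making the half-way rule degenerate at gap fraction
0.5 — inside the range the index must resolve. P90 keeps the rule stable
for gap fractions up to ~0.9 while agreeing with the median rule on intact
rims.

## Puncta

Puncta are connected components (8-connectivity) of `image > threshold`
within a region mask, filtered by area in `[min, max]` µm², then optionally
by roundness (`4π·area/perimeter² ≥ 0.6` by default) and by centroid
distance to the nuclear boundary (≤ 2 µm default) — the rule used for
FG-Nup accumulations that are "round and near the envelope". Components
smaller than 4 px are round by convention (their digital perimeter is not
meaningful). Detection parameters are recorded in the returned set.

## Colocalization and line profiles

The colocalization ratio is `|A∩B| / |A|` on the two thresholded masks,
per image — the area-ratio statistic, deliberately not Pearson/Manders. It
is exactly invariant under any strictly monotone rescaling applied jointly
to intensities and thresholds. Line profiles sample channels bilinearly at
equally spaced points with distances in µm.

## Synthetic scenes

The generator emulates what the metrics consume: non-overlapping cells
(rejection placement), elliptical nuclei with axis ratio ≤ 1.3 (bounded
eccentricity keeps analytic shape truth meaningful; nuclear shape in the
motivating data is largely preserved), a circular cell boundary enforcing
≥ 2 µm of cytosolic rim, flat background (default 10), a DNA channel at
300 above background, and per-marker planted structure:

- compartment levels (`nucleus_level`, `cytosol_level`) — the planted C/N;
- an envelope ring of configurable width with 1–3 planted gap arcs whose
  angular extents sum to `gap_fraction`·2π; every gap and every rim
  segment spans at least 0.25 rad so planted counts survive pixel
  quantization;
- non-overlapping cytoplasmic puncta of known count/radius/level;
- an overlap channel whose thresholded mask covers an exact pixel fraction
  of a reference channel's mask (pixel-subset selection, plus disjoint
  filler so the channel is non-empty at fraction 0).

Channels compose additively; Poisson shot noise is applied to the composed
signal, then Gaussian read noise, then clipping at 0. A fixed seed fully
determines the output. Defaults: 256×256 px at 0.325 µm/px (a common 20×
CCD sampling, under which the 1.3 µm ring is exactly 4 px), nucleus radius
4.0 ± 0.4 µm, cell radius 8.0 ± 0.8 µm. The noisy test condition is SNR 10
(Gaussian sd = one tenth of the relevant planted level, Poisson on).

What the generator does **not** emulate: point-spread blur, 3-D structure,
autofluorescence, cell-type morphology, intensity gradients, or
segmentation-hostile cell crowding. Passing recovery tests therefore
demonstrates correctness of the measurement operators and statistics on
their own terms, not robustness to every real-tissue artifact.

Cohorts are groups → clusters → cells with additive group effects,
Gaussian cluster intercepts (sd `cluster_sd`) and residuals (sd
`cell_sd`), giving ICC = `cluster_sd²/(cluster_sd²+cell_sd²)`; a lognormal
option exponentiates the latent values. At least two clusters per group
are required (cluster-level variance is not estimable otherwise).

## Statistics

Responses are jointly mid-rank transformed, then regressed on group
indicators (cell-means coding: coefficients are group rank means).
Inference uses a cluster-robust sandwich covariance:

- **CR2** (default): per-cluster adjustment `A_g = (I − H_gg)^{−1/2}`,
  with Bell–McCaffrey/Satterthwaite degrees of freedom per contrast
  computed under the working independence model. CR0 and CR1 are available
  by configuration. CR2 is the default because the motivating designs have
  very few clusters (3–5 animals or lines per group), where uncorrected
  sandwich SEs are markedly anti-conservative.
- **Omnibus**: Wald F on the k−1 group differences with denominator df =
  n_clusters − n_groups (a cluster-count-based choice; under the validated
  design, 3×5 clusters, it yields empirical size ≈ 0.06–0.08 at α = 0.05).
- **Pairwise contrasts**: rank-mean differences with robust SEs; Tukey
  adjustment via the studentized range evaluated at each contrast's own
  robust df. Classical Tukey assumes homoskedastic equal-n statistics, so
  this is an approximation; Holm is available as an alternative.
- **Two-group case**: the rank two-sample t-test with the same machinery
  and no multiplicity adjustment; ranks are computed per pair.
- **Mann-Whitney U**: scipy's implementation (exact for both n ≤ 20
  without ties, tie-corrected normal approximation otherwise), validated
  against full enumeration for all group sizes ≤ 8.

All tests are two-sided at α = 0.05 by default, with the usual
significance ladder (* < 0.05, ** < 0.01, *** < 0.001). If every response
value is identical the statistic is 0/0; the package reports statistic 0
and p = 1 by convention. Rank-based tests are invariant under strictly
monotone transforms of the response, and with one observation per cluster
the robust t-test collapses to Welch's t on ranks.

Calibration is checked by simulation: under a clustered global null
(3 groups × 5 clusters × 40 cells, ICC 0.3, 1000 replicates) the
cluster-robust rank ANOVA rejects at ≈ 0.06–0.08 (α = 0.05) and the Tukey
family-wise error stays ≈ 0.05, while the cluster-ignoring rank ANOVA on
the same draws rejects at ≈ 0.8 — the anti-conservatism the clustered
procedure exists to remove.

## Pipeline and reproducibility

`run_pipeline` maps sample-sheet rows (image, group, cluster, experiment,
channel names) through segmentation and the requested metrics into one
tidy table, optionally normalises to the control group per experiment,
picks the rank ANOVA (≥3 groups) or rank t-test (2 groups) per metric, and
writes measurements, test results, a text report (median, quartiles,
10–90 range per group — matching the box/whisker convention of the
motivating figures, with linear-interpolation quantiles), an exclusion
log, and the effective configuration. Outputs are written atomically;
identical inputs + config + seed give byte-identical CSVs. Excluded cells
(undefined ratios) are always logged with reasons.

Problem sizes used in the validation suite and `scripts/acceptance.py`
(200 cells per planted C/N value, 60 cells per gap fraction, 100 cell
images for puncta, 1000 null replicates) were chosen as the package's own
validation conditions; all complete in a few minutes on one CPU.

## Known limitations

- Single 2-D planes only; the metrics operate on the plane they are given.
- The nearest-nucleus cell splitting is plumbing for touching cells, not a
  learned segmenter; heavily crowded tissue may need external masks.
- The outward-normal approximation in the envelope profile assumes
  near-convex nuclei; deeply lobed nuclei would need true normals.
- ImageJ's exact perimeter estimator is not replicated; the calibrated
  boundary walk is used consistently instead.
- Tukey-on-robust-contrasts and the omnibus df rule are small-sample
  approximations validated by simulation at the designs above, not exact
  distributional results.
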