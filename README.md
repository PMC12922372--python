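# nctquant

Quantification of **nucleocytoplasmic transport (NCT) disruption** in
fluorescence microscopy, with the clustered rank-based statistics such
data needs — plus a synthetic image/cohort generator that provides ground
truth for every stage.

In ALS models and patient tissue, transport factors such as RanGAP1,
XPO1 and the FG-repeat nucleoporins mislocalise from the nuclear envelope
and nucleus into the cytoplasm. The standard readouts are per-cell image
metrics; this package implements them as a tested, scriptable pipeline:

- **C/N ratio** — background-subtracted cytosol-to-nucleus mean intensity
  ratio (and its N/C reciprocal, e.g. for the Ran gradient),
- **laminar intensity** — mean marker intensity in the annulus between
  the nucleus edge and its 1.3 µm dilation,
- **envelope/nucleoplasm ratio** — the post-mortem-tissue variant using a
  1-px envelope band normalised by the nucleoplasm,
- **continuity index** — supra-threshold arc length of rim signal divided
  by nuclear perimeter (1 = unbroken envelope), with fragment/gap counts,
- **puncta calling** — thresholded connected components with area,
  roundness and envelope-proximity filters,
- **nuclear circularity** — 4π·area/perimeter² from a calibrated digital
  boundary walk,
- **colocalization ratio** — overlap area of two thresholded channels
  over the reference channel's area,
- **line profiles** and **per-experiment normalisation to control**.

Because cells from one animal or cell line are correlated, group
comparisons use **rank-based tests with cluster-robust (CR2) sandwich
standard errors**, Satterthwaite-style degrees of freedom, and Tukey
adjustment of all pairwise contrasts — the naive cell-level ANOVA is
badly anti-conservative at realistic intra-cluster correlations (see the
worked example below). A plain Mann-Whitney test is included.

Images travel as (OME-)TIFF with pixel size in µm/px; tables are tidy
CSV; everything is deterministic given a seed.

## Worked example

Cells within an animal share a random intercept; with no true group
effect and ICC 0.3, the two analyses disagree sharply
(`examples/04_clustered_rank_anova.py`):

```
global null (no group effect, ICC 0.3):
  cluster-robust rank ANOVA p = 0.760
  naive rank ANOVA p          = 0.0172  <- spuriously small

real shift in group2 (+2 SD):
cluster-robust rank ANOVA (CR2, alpha=0.05)
  groups: group0, group1, group2
  n cells: group0=200, group1=200, group2=200
  n clusters: group0=5, group1=5, group2=5
  omnibus: stat=52.19, df=(2, 12), p=1.202e-06 ***
  group0 vs group1: est=1.405, se=35.43, df=8, p_adj=0.9991 n.s.
  group0 vs group2: est=-266.7, se=34.31, df=8, p_adj=0.0001396 ***
  group1 vs group2: est=-268.1, se=29.36, df=8, p_adj=4.35e-05 ***
```

The naive test "finds" a group difference in pure noise (p = 0.017); the
cluster-robust test does not (p = 0.76), yet still detects a genuine
2-SD shift with the correct pair of significant contrasts (estimates are
rank-mean differences).

The imaging side is just as direct
(`examples/01_simulate_and_recover_cn_ratio.py` — planted C/N of 2.0 at
SNR 10, segmented and measured from the images alone):

```
background: 9.9 (median_outside_cells); planted C/N = 2.0
  cell 1: C/N = 2.016
  cell 2: C/N = 2.009
  ...
median C/N = 2.008 (planted 2.0)
```

The other example scripts cover envelope continuity (planted gap
fractions 0 / 0.25 / 0.5 recovered as indices 1.000 / 0.757 / 0.507),
puncta calling and colocalization, and the end-to-end pipeline
(`simulate → segment → quantify → normalise → test → report`).

## Command line

A thin CLI wraps the library:

```bash
nctquant simulate scene  --config scene.yaml  --out scenes/
nctquant simulate cohort --config cohort.yaml --out cohort.csv
nctquant quantify --images samples.csv --metrics cn_ratio,continuity_index --out results/
nctquant stats    --table cohort.csv --test anova --adjust tukey --out stats.csv
nctquant run      --images samples.csv --metrics cn_ratio --out results/
```

The sample sheet CSV maps each image to its group, cluster (animal /
line / experiment) and channel names; the YAML config exposes every
tunable (thresholds, ring offsets in µm, puncta bounds, variance
estimator, α, seed) and is dumped alongside every output directory.

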