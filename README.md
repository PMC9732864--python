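# ecogdist

Spatial analysis of intraoperative electrocorticography (ioECoG)
biomarkers relative to MRI lesions in focal epilepsy surgery.

During resective epilepsy surgery, electrode grids and strips placed on
the exposed cortex record interictal biomarkers — epileptiform spikes and
high-frequency oscillations (ripples, 80–250 Hz; fast ripples,
250–500 Hz) — whose rates help delineate epileptogenic tissue beyond the
radiographically visible lesion.  How those rates relate *spatially* to
the lesion depends on the underlying pathology: non-tumourous lesions
(focal cortical dysplasia, cavernoma) tend to generate discharges at
their border, whereas low-grade gliomas drive epileptogenicity in distant
peritumoural tissue.  `ecogdist` implements the full quantitative
machinery to study this relationship, and a synthetic-cohort generator so
every stage runs and is tested without access to clinical data.

## What it computes

**Geometry.**  Electrode positions partially observed on intraoperative
photographs are completed by marching the rigid 10 mm lattice across the
triangulated cortical surface.  For each bipolar channel (midpoint of two
adjacent electrodes) three distances to the binary lesion segmentation
are computed:

- `d_edge` — Euclidean distance to the closest lesion voxel,
- `d_com`  — Euclidean distance to the lesion's centre of mass (COM),
- `d_geo`  — straight segment from the COM to the cortical surface plus
  the shortest on-surface path to the electrode (Dijkstra on a k-ring
  chord graph of the mesh).

**Statistics.**  Per pathology group and distance family, distance is
regressed on the biomarker rate with heteroscedasticity-consistent HC3
(Davidson–MacKinnon) standard errors:

    d_i = β0 + β1 · rate_i + ε_i,     Var̂(β̂) = (XᵀX)⁻¹ Xᵀ diag(e_i²/(1−h_ii)²) X (XᵀX)⁻¹

with η² (= r² in simple regression) as effect size under Cohen's bins
(≤ 0.06 small, < 0.14 moderate, ≥ 0.14 large), percentile bootstrap CIs
(1000 case resamples), Welch's ANOVA for D_max comparisons, a binary
logistic model for fast-ripple occurrence (odds ratio per mm), and a
joint simple-slopes moderation model

    d ~ rate + pathology + volume + rate·pathology + rate·volume

testing whether pathology type (robust Wald F, k−1 df) or lesion volume
(1 df) changes the rate–distance slope.  No multiple-comparison
correction is applied; α = 0.05.

**Synthetic cohorts.**  The generator emulates a 33-patient surgical
cohort — per-pathology patient counts, lesion volumes, rate scales and
rate–distance slopes — writing NIfTI lesions, PLY surfaces, TSV
electrode tables (with hidden electrodes withheld) and CSV event logs,
exactly the formats the pipeline consumes.

## Worked example

`examples/03_regression_and_moderation.py` generates channels for two
pathologies with opposite injected slopes and runs the core analysis:

```
pathology            slope   95% CI            p        eta2  class
FCD                  -0.21  [-0.33, -0.11]    0.00092  0.05  small
low_grade_glioma     +0.68  [+0.50, +0.94]      8e-08  0.51  large

pathology moderation: F(1,645) = 46.50, p = 2.1e-11
  simple slope FCD                -0.21 (SE 0.06, p 0.00091)
  simple slope low_grade_glioma   +0.68 (SE 0.11, p 4.4e-09)
```

The FCD slope is negative: channels with higher spike rates sit closer
to the lesion edge (−0.21 mm per spike/min, small effect).  The
low-grade glioma slope is positive and large: spikes concentrate *away*
from the tumour.  The moderation test confirms the two pathologies
differ significantly in how rates map onto lesion distance.  The other
examples cover the three distance models (`01`), event-log handling and
D_max (`02`), and the file-level pipeline (`04`).

## Command line

The pipeline is also a CLI (`ecogdist simulate | localize | distances |
rates | fit | moderate | report | run-all`):

```
ecogdist run-all --seed 7 --out results/
```

simulates the default cohort and writes the report bundle
(`channels.csv`, `regressions.csv`, `family_comparison.csv`,
`moderation.json`, `dmax.csv`, `welch.json`, `logistic.json`,
`visual_slopes.csv`, `exclusions.csv`, `manifest.json`).

## Layout

- `src/ecogdist/geometry.py` — lesion volumes, surfaces, distances, grid extrapolation
- `src/ecogdist/events.py` — rates, montages, summaries, D_max
- `src/ecogdist/stats.py` — HC3 regression, Welch, logistic, moderation
- `src/ecogdist/cohort.py` — synthetic cohort generator
- `src/ecogdist/pipeline.py`, `src/ecogdist/cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
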