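# Methods

This note documents the models, conventions and numerical choices behind
`ecogdist`, and what the synthetic data do and do not establish.

## Coordinate conventions

All computations run in world millimetres.  A voxel index `i` (0-based)
maps to the *centre* of voxel `i` through the NIfTI affine.  Lesion
masks are binary; any nonzero voxel is foreground.

## The three distance models

A bipolar channel is located at the exact spatial midpoint of its two
adjacent electrodes (both on the cortex; the midpoint sits at most a few
tenths of a millimetre beneath it for 10 mm spacing on realistic
curvature).

- **Edge distance** is the minimum Euclidean distance from the channel
  to any foreground voxel centre, and 0 for a point inside the mask.
  Using voxel centres (rather than an iso-surface) keeps the quantity
  exactly checkable against brute-force enumeration; the discrepancy is
  at most half a voxel (0.5 mm at 1 mm resolution), well below the
  2–3 mm electrode-localization uncertainty inherent to
  photograph-based placement.
- **COM distance** is the Euclidean norm to the unweighted mean of
  foreground voxel-centre coordinates.
- **Geodesic distance** is `L1 + L2`: the straight segment from the COM
  to its nearest surface vertex `P` (vertex snapping keeps the two leg
  endpoints consistent; equidistant ties go to the lowest vertex index),
  plus the shortest on-graph path from `P` to the vertex nearest the
  channel.

### Geodesic graph

Shortest paths run on a *k-ring chord graph*: vertices at most `k` mesh
edges apart are joined by their straight chord (`k = 1` is exactly the
mesh edge graph).  Pure edge-graph Dijkstra carries a direction-dependent
stretch of up to sec 30° ≈ 15% on triangulated lattices that does not
vanish with refinement; with the default `k = 3` the worst-case stretch
falls to sec 10° − 1 ≈ 1.5%, and on a 10k-vertex icosphere the measured
error against the analytic great-circle value is ≤ 0.5%.  Chords cut
marginally through convexities (negligible at these edge lengths) and
may shortcut deep concavities; for strongly folded surfaces a smaller
`k` with a finer mesh is the conservative choice.  Electrodes must lie
within a snap tolerance of the surface (default: the longest mesh edge;
the pipeline uses 1.5 mm) — a distant point indicates a localization
failure and raises with the channel named.

## Grid extrapolation

Electrodes hidden under the skull are re-derived by sequential
constrained placement on the surface, marching outward from visible
electrodes with two rules: **in-line** continuation (two consecutive
known electrodes in a row/column fix the direction; the new point lies
on the surface at chord distance = 10 mm), and **corner** completion (an
L of three known electrodes is completed to a lattice quad with both new
chords equal to the spacing).  Corner completion has priority: it pins
each interior electrode to *both* lattice neighbours, which prevents
independently marched rows from drifting apart on curved surfaces.  Both
rules iterate projection onto the mesh against chord rescaling to
1e-10 mm; on a plane they reproduce the exact lattice, and on spheres
all adjacent chords equal the nominal spacing to machine precision.
Visible electrodes are never moved, making the operation idempotent.
Chord tolerance (0.2 mm default, 1.0 mm in the pipeline for bumpy
synthetic cortices) and snap tolerance are configurable; violations
raise rather than degrade silently.

Physical grids are rigid in the chord sense, so chord spacing (not
on-surface arc spacing) is the preserved quantity.

## Event rates and exclusions

Rates are `count / epoch_minutes` per channel and biomarker from
timestamped event logs (60 s epochs by default).  Artifact-flagged
channels are dropped before any rate is computed and never reappear
downstream; every exclusion is logged with its reason.  Multiple
recordings per patient are pooled without weighting, and channels from
different recordings are distinct even when they overlap spatially.
Summary tables report means/SDs over channels with at least one event of
that biomarker, with all-zero groups flagged as missing.  The bipolar
montage pairs layout-adjacent electrodes along rows by default
(configurable); D_max records each patient's maximal-rate channel per
biomarker, ties broken by lowest channel id, with its edge distance.

## Statistical conventions

- Regressions put *distance* on the left and *rate* on the right, per
  the analysis orientation; η² equals the squared Pearson correlation in
  this simple-regression setting and is invariant to orientation.
- HC3 robust t statistics use n − 2 df (small-sample conservatism,
  consistent with F(1, n−2) reporting).
- Bootstrap CIs are percentile intervals over 1000 case resamples with
  an exposed seed; degenerate resamples (constant predictor) are
  dropped.
- Effect-size bins resolve the boundary overlap by assigning exactly
  0.06 to "small" and exactly 0.14 to "large".
- Welch's ANOVA uses the Satterthwaite denominator df; it equals the
  classical F only asymptotically (the correction factor is 1 + O(1/n)).
- Logistic CIs are Wald-type on the log-odds scale; single-class
  outcomes and complete separation raise.
- Moderation at the cohort level fits pathology and lesion volume
  *jointly* (`d ~ rate + pathology + volume + rate·pathology +
  rate·volume`, HC3 covariance, robust Wald F per interaction block).
  The joint model is what makes the volume test meaningful here: volume
  differs systematically between pathologies, so an unadjusted volume
  moderation would partly re-test pathology.  When
  volume is collinear with pathology (one patient per level) the volume
  moderator is dropped with a note.  The single-moderator form
  (`moderation()`), probing continuous moderators at mean ± 1 SD, is
  available separately.
- No multiple-comparison correction anywhere; α = 0.05.

## Synthetic cohort generator

The generator's defaults are the study conditions of the emulated
33-patient cohort: patient counts per pathology (12 FCD, 9
ganglioglioma, 5 DNET, 3 low-grade glioma, 2 PXA, 2 cavernoma), lesion
volume means/SDs per pathology (drawn log-normally, matching the first
two moments, so volumes stay positive even where the SD exceeds the
mean), biomarker rate means/SDs per pathology, and rate–distance slopes
per pathology and biomarker (fast ripples absent for cavernoma, DNET and
low-grade glioma).  Between one and five recordings per patient, each
one 4×5, 4×4 or 1×8 array, a single 60 s epoch per recording, ~10% of
channels artifact-flagged, and a configurable fraction of hidden
electrodes.

**Rate model.**  Rates are generated conditionally on distance (the
causal direction) and analysed in the reverse orientation.  For target
slope `b` (mm per event/min), rate mean `λ0` and SD `σ_r`, the expected
rate is `max(0, λ0 + γ(d − d̄))` with `γ = b σ_r² / var(d)`, which makes
the distance-on-rate regression recover `b` in expectation.  Counts are
gamma-mixed Poisson over the epoch, the mixing variance chosen so the
marginal rate variance matches `σ_r²`; the strong overdispersion this
implies reproduces the zero-inflated character of real biomarker counts.
When a requested slope implies more correlation than the distance spread
can carry ((bσ_r)²/var(d) > 0.8), the realized slope saturates at the
attainable strength with the requested sign.  With the default
parameters this construction reproduces effect sizes of the expected
order (e.g. η² ≈ 0.05 for FCD spikes, ≈ 0.3 for cavernoma spikes)
without any η² entering the generator.

**Geometry.**  Surfaces are gently perturbed icospheres ("bumpy
spheres", 65 mm radius, ±3% smooth radial modulation) — curvature
without folding.  Lesions are connected voxel blobs grown beneath a
surface anchor by jittered-distance ordering; the realized volume equals
the voxel-quantized target.  Arrays are marched across the surface from
a seed near the lesion with the same placement primitives the
extrapolation uses, and the *trailing* columns are hidden — physically
the part of a grid slipped under the skull — so the localization stage
re-derives them through the same geometric constraints that generated
them.  Ground-truth distances are computed by the geometry module
itself, making generator/pipeline agreement a genuine file-round-trip
check (NIfTI/PLY/TSV/CSV) rather than a tautology of shared state.

**What the synthetic data do not emulate:** anatomically realistic
cortical folding, within-patient between-channel correlation beyond the
shared distance dependence, brain shift, propagation structure of
discharges, or raw-signal properties (detector behaviour, filter
settings).  Passing tests therefore establish the correctness of the
geometry, bookkeeping and statistics, and the internal consistency of
the generator/analysis pair — not clinical validity on real recordings.

## Problem sizes and determinism

The test suite and the acceptance script run the full default cohort (33
patients, ~1100–1400 included channels) for the headline analyses, 100
seeds for recovery/power properties, 2000 null simulations for test
calibration and 500 replicates for bootstrap coverage; these sizes give
stable empirical rates while keeping a full run in tens of seconds.  All
randomness flows from spawned `SeedSequence` children of a single seed;
same-seed runs are byte-identical (the run manifest records the seed,
config hash and library versions, and contains no timestamps).

## Known limitations

- Geodesics are graph-based, not exact polyhedral geodesics; the k-ring
  stretch floor (~0.5% mean on icospheres) does not vanish with mesh
  refinement alone.
- Grid extrapolation assumes the hidden region continues the visible
  lattice; it cannot recover from a grid physically folded over a sharp
  edge.
- The edge distance quantizes at half a voxel near the lesion boundary.
- Logistic and moderation models assume channel independence; clustered
  (per-patient) standard errors are not implemented.
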