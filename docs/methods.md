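# Methods note

This note records the model implemented by `cytoreg`, the numerical choices
made along the way, and the design rationale of the synthetic benchmarks used
to validate it.

## Data model and preprocessing

A `Sample` is an events × channels matrix with an explicit three-state
transform machine: `raw` → `compensated` (spillover unmixed) →
`transformed` (ArcSinh). Compensation multiplies fluorescence events by the
inverse of the spillover matrix; scatter channels (FSC/SSC/Time, matched by
name) are never compensated, transformed with a fixed linear scale
(divided by 10⁴) instead of ArcSinh, and excluded from registration. The
ArcSinh cofactor defaults to 150 for fluorescence and 5 for mass-cytometry
channels. FCS files are read and written natively (FCS 2.0/3.0/3.1 list
mode, `$DATATYPE` F/D, `$SPILLOVER`); registered output is written as FCS
3.0 float32 after inverse transformation back to linear scale.

All registration operates in transformed space, where technical shifts are
approximately additive.

## Cluster substrate

The subpopulation structure is a full-covariance Gaussian mixture
(`fit_template`, scikit-learn, k-means++ initialization, `reg_covar` 1e-6).
After the mixture converges, a polish loop iterates exact E-steps and
mean/weight M-steps with covariances frozen until the largest centroid update
falls below 1e-11. This makes the template an exact fixed point of soft
assignment: assigning the reference to its own template reproduces the
template centroids to machine precision, which in turn makes
self-registration a fixed point (acceptance requirement: event movement
< 1e-6). Posteriors are floored at 1e-8 and renormalized — identically in
fitting and assignment — so no event ever has exactly zero membership
anywhere and the fixed point is shared between both code paths.

Degenerate components (effective size below 2 events) are pruned after
fitting.

## Registration

Movement vectors always point from the sample toward the reference:
`v = reference_centroid − sample_centroid`.

**ICR** uses these per-cluster differences directly (restricted to registered
channels); clusters empty in the sample are masked to zero.

**NDCR** builds, per channel:

1. *Weights.* `ω(κ) = 1 − 2·T_cdf(−μ√κ/σ; df = max(1, κ−1))` with defaults
   μ = 1/15 (allowed range [1/20, 1/10]) and σ = 1; κ is the smaller of the
   sample and reference effective cluster sizes. ω(0) = 0, ω(4) ≈ 0.1,
   ω(10⁴) ≈ 1. The sign of the t-statistic is chosen so the weight *grows*
   with cluster size, matching the stated asymptotics (weight ≈ 1 for
   clusters above ~10,000 cells); this is the only reading under which the
   published weight range (~0.1 to 1) is reproducible.
2. *Bins.* `clamp(⌊0.75√N⌋, 2, 20)` bins, filled greedily in channel order
   until each reaches the weight quota `total/n_bins` (the crossing cluster
   stays in the closing bin; the last bin absorbs the remainder). At least
   two clusters are required, else the channel is unregistrable by NDCR.
3. *Curve.* A cubic smoothing spline (generalized cross-validation,
   `scipy.interpolate.make_smoothing_spline`, bin weights normalized to unit
   mean) through the weighted bin averages of (intensity, movement). With
   fewer than five bins — below the spline routine's minimum — a weighted
   piecewise-linear fit is used instead. The curve's support spans the
   centroid range of the participating clusters; queries inside the support
   are clipped to the outermost bin abscissae (the fit is never
   extrapolated), and beyond the support the boundary value ramps linearly
   to zero over one mean bin width, so empty regions of intensity space
   receive no correction.

Each cluster's NDCR movement in the channel is the curve at its sample
centroid.

**Iteration.** Events move by the posterior-weighted blend of their clusters'
vectors (`fraction · Σⱼ posterior·vⱼ`), then are re-assigned. The default
schedule is NDCR ×2 then ICR ×2 at full update fraction; a partial-update
preset (25%, 33%, 50%, 100%) is available for fragile data. Every iteration
is logged with per-channel and total centroid RMSE.

## Batch workflow

`build_batch_template` registers a batch's internal standard to the
reference template and freezes the per-iteration `(method, fraction,
vectors)` triples in a `BatchTemplate`. `apply_batch_template` replays them
on a sample: per captured iteration the sample is re-assigned to the
reference template (its *own* posteriors) but displaced along the *captured*
vectors — never vectors derived from the sample itself. Consequences:

* the reference batch's template is numerically all-zero and replay is the
  identity;
* within-batch differences between samples are preserved exactly up to the
  posterior reweighting, because all samples of a batch receive the same
  field of vectors;
* a batch without an internal standard falls back, with a warning, to a
  consensus concatenate of its samples — valid only when every batch
  contains a similar mix of experimental groups.

## Parameters and defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| μ (weight tolerance) | 1/15 | middle of the allowed [1/20, 1/10] band |
| σ (weight scale) | 1.0 | transformed-space units |
| bin factor / min / max | 0.75 / 2 / 20 | bin-count heuristic and clamps |
| update schedule | NDCR×2 + ICR×2, fraction 1 | channel drift first, residual snap second |
| posterior floor | 1e-8 | keeps assignment smooth and fixed points exact |
| fit polish threshold | 1e-11 | centroid fixed point to machine noise |
| ArcSinh cofactors | 150 (fluor) / 5 (mass) | standard community practice |
| taper span | mean bin width | curve dies off over one bin beyond support |

## Synthetic benchmarks

**Multi-batch study** (`gaussian_batch_study`): 18 subjects × 300 cells in 3
batches, 6 "old" / 12 "young", one 2-D Gaussian per subject (sd 0.15), plus
a 600-cell internal standard per batch. Batch shifts (≈0.5 transformed
units, about three cluster sd) clearly separate batches; the old-group
effect (0.35, 0.35) and subject jitter (sd 0.08) are smaller, so
registration has genuine biology to preserve. The magnitudes of shift,
jitter and group effect are this package's choices — picked to make batch
and biology visually distinct, not fitted to any dataset. Because each
subject is a single Gaussian, batch registration uses a k = 1 template with
an ICR-only schedule (NDCR is undefined below two clusters, and any k ≥ 2
split of one Gaussian is arbitrary and injects artifactual within-batch
variation).

**Semi-synthetic scaling series** (`make_semisynthetic`): starting from a
compensated linear-scale sample, target-channel values become
`(v − b)/f + b` for backgrounds `b` and a ladder of factors `f` (default 8
factors evenly spaced on [1, 10]) — either for all events (*channel* mode,
emulating a gain/staining change) or only for a tracked cluster's stable
cohort (*cluster* mode, emulating a biological subpopulation shift). The
tracked cohort is chosen by stability under repeated bootstrap template
refits: a cluster is *well resolved* if ≥ 80% of repeats retain ≥ 80% of its
members, and the *stable cohort* is the events staying with the cluster in
> 95% of repeats.

**Selectivity panel** (`panel_centroids`): 32 subpopulations over 8
channels — the two scaled channels carry a dim/mid/bright grid (sd 0.42),
the six lineage channels are bimodal (sd 0.12). 28 subpopulations have
unique lineage profiles; the tracked bright cluster shares its profile with
three static relatives, so scaling it produces realistic mis-assignment
within that family. This layout matters: in small panels (≤ ~16 clusters
over ≤ 4 channels) a single moved cluster dominates its own correction-curve
bin and NDCR "self-corrects" the very shift it should ignore, erasing the
ICR/NDCR contrast the benchmark measures. The 32-cluster/8-channel regime
mirrors realistic panel complexity, where each bin averages over many
clusters. The layout and σ values are fixture design choices; the benchmark
passes across all generator seeds tried (0–3), and seeds were not selected
on outcomes.

With this panel, cluster-scale series are recovered best by ICR, channel
-scale series essentially perfectly by NDCR, and the recommended NDCR→ICR
schedule stays within 2 capture-fraction points of the better pure method in
both regimes — the selectivity property the acceptance suite locks in.

## Numerical and scope limitations

* The mixture substrate assumes roughly Gaussian subpopulations in
  transformed space; heavily skewed or rare (< a few dozen events)
  populations blur into neighbors.
* Registration assumes the reference template contains every subpopulation
  present in test samples; unmatched novel populations are dragged toward
  their nearest template clusters.
* NDCR needs ≥ 2 clusters per registered channel and derives no correction
  in intensity regions without clusters (by design — the taper).
* The consensus-standard fallback confounds batch and biology when group
  composition differs across batches.
* Statistical comparison of groups (`group_comparison`) is a thin
  exploratory wrapper (rank-sum + Benjamini–Hochberg), not part of the
  validated core.
* Problem sizes in tests (hundreds of events per cluster, ≤ 32 clusters,
  ≤ 8 channels) are desk-scale choices; the algorithms are vectorized and
  scale linearly in events, quadratically in clusters × channels for
  template fitting.
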