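# cytoreg

Cluster registration for flow and mass cytometry data: removes technical
variability — including batch effects — by aligning cell subpopulations
across samples, while preserving the biological differences between them.

## The problem

Cytometry measurements of the same cell population drift between runs:
instrument settings, reagent lots, staining efficiency and operator handling
all move subpopulations around in marker space. When samples from a study are
acquired in batches, these shifts masquerade as (or mask) biology. `cytoreg`
corrects this at the level of *cell subpopulations* rather than whole-channel
histograms: a mixture-model template is fitted to a reference sample, every
other sample is softly assigned to it, and events are moved along per-cluster
**movement vectors** until the sample's clusters sit on the reference's.

## The model

All registration happens on compensated, ArcSinh-transformed data
(`asinh(x / cofactor)`, cofactor 150 for fluorescence, 5 for mass cytometry;
scatter channels are excluded from registration).

**Cluster template.** A Gaussian mixture with `k` components is fitted to the
reference sample (`fit_template`), then polished with a short exact
expectation/maximization loop so that the reference is a true fixed point of
registration. Test samples are soft-assigned (`assign`): each event gets a
posterior membership over the `k` clusters, and each cluster gets a sample
centroid (posterior-weighted mean) and an effective size.

**Two kinds of movement vectors.**

* **ICR** (independent cluster registration): each cluster's vector is simply
  `reference_centroid − sample_centroid`. Precise for well-resolved clusters,
  but happily "corrects" genuine biological shifts of individual
  subpopulations.
* **NDCR** (neighbor-dependent cluster registration): per channel, clusters
  are weighted by a Student-t confidence in their centroid,

  `ω(κ) = 1 − 2·T_cdf(−μ√κ / σ; df = max(1, κ−1))`,   μ = 1/15, σ = 1,

  where κ is the smaller of the sample and reference cluster sizes (ω(0) = 0,
  ω ≈ 0.1 at κ = 4, ω ≈ 1 at κ = 10,000). Clusters are then packed into
  `clamp(⌊0.75√N⌋, 2, 20)` weight-balanced bins along the channel, and a
  smooth curve of *movement vs. intensity* is fitted through the weighted bin
  averages. Each cluster's correction is the curve at its centroid — so the
  correction follows the consensus of neighboring clusters and ignores a
  single shifted subpopulation (which is presumably biology, not drift).

**Compound displacement.** Events move by the posterior-weighted blend of
their clusters' vectors, scaled by the iteration's update fraction. The
recommended schedule is two NDCR iterations (remove channel-wide drift)
followed by two ICR iterations (snap residual per-cluster offsets); each
iteration re-assigns events, letting initially mis-assigned cells recover.

**Batch registration.** A batch's technical shift is estimated once, by
registering its *internal standard* (an aliquot of one cryopreserved sample
run with every batch) to the reference template. The captured per-iteration
vectors are frozen in a `BatchTemplate` and replayed verbatim on every sample
of the batch — so the correction is batch-specific, never sample-specific,
and within-batch biological differences pass through untouched. Batches
without a standard can fall back to a consensus concatenate of their samples.

## Worked example: removing a batch effect

Simulate an 18-subject study acquired in 3 batches (6 "old" and 12 "young"
subjects; batches shifted by roughly three cluster standard deviations), then
register every batch to batch 0 via the internal standards:

```python
import numpy as np
from cytoreg.synthetic import SyntheticStudySpec, gaussian_batch_study
from cytoreg.batch import register_batches
from cytoreg.registration import RegistrationConfig

study = gaussian_batch_study(SyntheticStudySpec(seed=5))
cfg = RegistrationConfig(schedule=[("icr", 1.0), ("icr", 1.0)])
registered, templates, ref_template = register_batches(
    study.samples_by_batch, study.standards_by_batch,
    reference_batch=0, k=1, config=cfg,
)

def batch_means(samples_by_batch):
    return {b: np.mean([s.events.mean(axis=0) for s in mm.values()], axis=0)
            for b, mm in samples_by_batch.items()}

print("batch means before registration:")
for b, m in batch_means(study.samples_by_batch).items():
    print(f"  batch {b}: CD3 {m[0]:.3f}  CD4 {m[1]:.3f}")
print("batch means after registration:")
for b, m in batch_means(registered).items():
    print(f"  batch {b}: CD3 {m[0]:.3f}  CD4 {m[1]:.3f}")
for b in (1, 2):
    total = sum(f * v.masked() for _, f, v in templates[b].iterations)
    print(f"captured shift, batch {b}: {np.round(total[0], 3)}")
```

Output:

```text
batch means before registration:
  batch 0: CD3 2.093  CD4 2.100
  batch 1: CD3 2.630  CD4 1.692
  batch 2: CD3 1.680  CD4 2.612
batch means after registration:
  batch 0: CD3 2.093  CD4 2.100
  batch 1: CD3 2.125  CD4 2.080
  batch 2: CD3 2.116  CD4 2.106
captured shift, batch 1: [-0.505  0.388]
captured shift, batch 2: [ 0.435 -0.505]
```

The captured shifts recover the simulated batch offsets ((0.5, −0.4) and
(−0.45, 0.5)) to within sampling noise; the residual spread of the
batch means (~0.03) is the subjects' own biological jitter, which
registration preserves (within-batch subject differences change by < 0.1%).

Sample-to-reference registration works the same way on multi-cluster data:

```python
import cytoreg as cr
from cytoreg.synthetic import separated_centroids, gaussian_mixture_sample

centroids = separated_centroids(10, 3, seed=11)
channels = ["CD3", "CD4", "CD8"]
reference, _ = gaussian_mixture_sample(centroids, 0.12, 400, channels, seed=21)
test, _ = gaussian_mixture_sample(centroids, 0.12, 400, channels, seed=22)
template = cr.fit_template(reference, k=10, seed=0)

shifted = test.copy()
shifted.events[:, 0] += 0.5          # instrument drift in CD3
registered, log = cr.register(shifted, template)
print(f"centroid RMSE before: {log.iterations[0]['rmse_distance']:.4f}")
print(f"centroid RMSE after:  {log.final_rmse:.6f}")
```

```text
centroid RMSE before: 0.5027
centroid RMSE after:  0.000000
```

## Command line

```sh
cytoreg simulate --out study/                 # synthetic multi-batch study
cytoreg diagnose study/manifest.csv --out qc/ # correlation heatmaps, QC plots
cytoreg register study/manifest.csv --batch --out registered/
cytoreg batch-register study/manifest.csv --out registered/   # shortcut
```

Manifests are CSVs with columns `path,batch,subject,role` where `role` is
`sample`, `internal_standard`, or `reference` (the reference batch's
standard). Registered samples are written as FCS 3.0 files (`*_reg.fcs`,
inverse-transformed back to linear scale) next to per-batch template files
and JSON logs. Exit codes: 0 success, 2 configuration error, 3 data error.

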