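"""Ground-truthed synthetic and semi-synthetic cytometry data.

Three generators back the test and evaluation harness:

* :func:`gaussian_batch_study` — a multi-batch study in which each subject is
  one 2-D Gaussian subpopulation and batches differ by a common centroid
  shift; emits per-batch internal standards and full truth tables.
* :func:`make_semisynthetic` — the scaling protocol for semi-synthetic series:
  after background subtraction, linear intensities of either one tracked
  cluster (cluster mode) or all events (channel mode) are divided by a ladder
  of scale factors, backgrounds restored, and the result ArcSinh-transformed.
* :func:`gaussian_mixture_sample` — generic separated-mixture fixtures with
  true labels.

Stability utilities (:func:`well_resolved_clusters`, :func:`stable_cohort`)
identify clusters and event cohorts that are reproducibly recovered under
repeated template fits, so scaled cells can be tracked unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import ClusterTemplate, assign, fit_template
from .fcs import FLUOR_COFACTOR, Sample, arcsinh_transform

__all__ = [
    "SyntheticStudySpec",
    "StudyData",
    "SemisyntheticSeries",
    "gaussian_batch_study",
    "gaussian_mixture_sample",
    "separated_centroids",
    "linear_panel_sample",
    "make_semisynthetic",
    "well_resolved_clusters",
    "stable_cohort",
]


@dataclass
class SyntheticStudySpec:
    """Multi-batch single-cluster study: 18 subjects of 300 cells split over
    3 batches, 6 old / 12 young, one 2-D Gaussian per subject.

    Each subject's centroid is base + group effect (old only) + batch shift +
    subject jitter.  Batch shifts of ~0.5 transformed units (about three
    cluster standard deviations) visibly separate the batches; the old-group
    effect is smaller than the batch effect so that registration has something
    real to preserve.
    """

    n_subjects: int = 18
    cells_per_subject: int = 300
    n_batches: int = 3
    n_old: int = 6
    channels: tuple = ("CD3", "CD4")
    base_centroid: tuple = (2.0, 2.0)
    cluster_sd: float = 0.15
    subject_jitter_sd: float = 0.08
    group_effect: tuple = (0.35, 0.35)
    batch_shifts: tuple = ((0.0, 0.0), (0.5, -0.4), (-0.45, 0.5))
    standard_cells: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.cells_per_subject, self.n_batches, self.standard_cells) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.n_old > self.n_subjects:
            raise ValueError("more old subjects than subjects")
        if len(self.batch_shifts) != self.n_batches:
            raise ValueError("need one batch shift per batch")


@dataclass
class StudyData:
    samples_by_batch: dict          # batch id -> {subject id: Sample}
    standards_by_batch: dict        # batch id -> Sample
    truth: pd.DataFrame             # per-subject truth table
    spec: SyntheticStudySpec


def _transformed_sample(events: np.ndarray, channels, source_id: str) -> Sample:
    return Sample(
        events=events,
        channels=list(channels),
        transform_state="transformed",
        cofactor_map={c: FLUOR_COFACTOR for c in channels},
        source_id=source_id,
    )


def gaussian_batch_study(spec: SyntheticStudySpec) -> StudyData:
    """Generate the multi-batch Gaussian study with full ground truth.

    Batch/group assignment is balanced: subjects are dealt to batches round
    robin, and old subjects are spread evenly across batches.  Internal
    standards (aliquots of one notional sample, so base centroid + batch shift
    only) are emitted per batch.
    """
    rng = np.random.default_rng(spec.seed)
    C = len(spec.channels)
    base = np.asarray(spec.base_centroid, float)
    shifts = np.asarray(spec.batch_shifts, float)
    group_eff = np.asarray(spec.group_effect, float)

    # balanced assignment: old subjects spread evenly over batches
    batches = [i % spec.n_batches for i in range(spec.n_subjects)]
    old_flags = [False] * spec.n_subjects
    per_batch_old = [spec.n_old // spec.n_batches + (1 if b < spec.n_old % spec.n_batches else 0)
                     for b in range(spec.n_batches)]
    counts = [0] * spec.n_batches
    for i, b in enumerate(batches):
        if counts[b] < per_batch_old[b]:
            old_flags[i] = True
            counts[b] += 1

    samples_by_batch: dict = {b: {} for b in range(spec.n_batches)}
    rows = []
    for i in range(spec.n_subjects):
        b = batches[i]
        jitter = rng.normal(0.0, spec.subject_jitter_sd, size=C)
        centroid = base + shifts[b] + (group_eff if old_flags[i] else 0.0) + jitter
        events = rng.normal(centroid, spec.cluster_sd, size=(spec.cells_per_subject, C))
        sid = f"subject{i:02d}"
        s = _transformed_sample(events, spec.channels, f"{sid}_batch{b}")
        s.event_sources = np.array([sid] * spec.cells_per_subject)
        samples_by_batch[b][sid] = s
        rows.append({
            "subject": sid, "batch": b, "group": "old" if old_flags[i] else "young",
            "cluster": 0,
            **{f"centroid_{ch}": centroid[c] for c, ch in enumerate(spec.channels)},
        })

    standards_by_batch = {}
    for b in range(spec.n_batches):
        events = rng.normal(base + shifts[b], spec.cluster_sd, size=(spec.standard_cells, C))
        standards_by_batch[b] = _transformed_sample(events, spec.channels, f"standard_batch{b}")

    return StudyData(samples_by_batch, standards_by_batch, pd.DataFrame(rows), spec)


# ---------------------------------------------------------------------------
# Generic mixture fixtures


def separated_centroids(k: int, n_channels: int, lo: float = 0.5, hi: float = 4.0,
                        min_dist: float = 1.2, seed: int = 0) -> np.ndarray:
    """Rejection-sample k centroids with pairwise distance >= min_dist."""
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    for _ in range(100_000):
        cand = rng.uniform(lo, hi, size=n_channels)
        if all(np.linalg.norm(cand - c) >= min_dist for c in out):
            out.append(cand)
            if len(out) == k:
                return np.array(out)
    raise RuntimeError(f"could not place {k} centroids at min_dist={min_dist}")


def gaussian_mixture_sample(centroids: np.ndarray, sd, n_per_cluster,
                            channels, seed: int = 0,
                            source_id: str = "synthetic") -> tuple[Sample, np.ndarray]:
    """Transformed-space mixture sample with true labels.

    ``sd`` is a scalar (isotropic) or per-channel vector of standard
    deviations shared by all clusters.
    """
    rng = np.random.default_rng(seed)
    centroids = np.atleast_2d(np.asarray(centroids, float))
    k = centroids.shape[0]
    sizes = np.full(k, n_per_cluster) if np.isscalar(n_per_cluster) else np.asarray(n_per_cluster)
    sd = np.broadcast_to(np.asarray(sd, float), (centroids.shape[1],))
    chunks, labels = [], []
    for j in range(k):
        chunks.append(rng.normal(centroids[j], sd, size=(int(sizes[j]), centroids.shape[1])))
        labels.extend([j] * int(sizes[j]))
    events = np.vstack(chunks)
    return _transformed_sample(events, channels, source_id), np.array(labels)


#: transformed-space channel sd of the panel fixture: stained (scaled) markers
#: are broad, lineage (gating) markers tight
PANEL_SD = (0.42, 0.42, 0.12, 0.12, 0.12, 0.12, 0.12, 0.12)
PANEL_CHANNELS = ("CD3", "CD4", "CD8", "CD45RA", "CD19", "CD14", "CD56", "CD16")


def panel_centroids() -> np.ndarray:
    """Transformed-space centroids of the 32-subpopulation panel fixture.

    The first two channels (the ones the scaling protocol targets) carry a
    dim / mid / bright grid; the remaining six are bimodal lineage markers.
    Twenty-eight backbone subpopulations get distinct lineage profiles, so
    they stay identifiable under any shift of the first two channels.  Four
    subpopulations — three static plus the bright tracked one (last row) —
    share one lineage profile, so displacing the tracked cluster along the
    scaling path produces realistic mis-assignment within that family.
    """
    import itertools

    rng = np.random.default_rng(0)  # fixed layout, not a data seed
    pstar = (3.0, 3.0, 1.0, 1.0, 3.0, 1.0)
    others = [p for p in itertools.product([1.0, 3.0], repeat=6) if p != pstar]
    rng.shuffle(others)
    positions = [(a, b) for a in (0.7, 2.6, 4.8) for b in (0.7, 2.6, 4.8)]
    cents = [[*positions[i % 9], *others[i]] for i in range(28)]
    cents += [[0.9, 0.9, *pstar], [4.8, 0.9, *pstar], [0.9, 4.8, *pstar], [4.8, 4.8, *pstar]]
    return np.array(cents)


def linear_panel_sample(seed: int = 0, n_per_cluster: int = 250,
                        background: float = 100.0,
                        cofactor: float = FLUOR_COFACTOR) -> tuple[Sample, np.ndarray, np.ndarray]:
    """A compensated linear-scale sample for the scaling protocol.

    Events for the :func:`panel_centroids` layout are generated as Gaussians
    in transformed space and mapped back to linear intensities above a common
    background, emulating compensated data.  The tracked cluster is the last
    (bright) centroid row.

    Returns (linear sample, true labels, transformed-space centroids).
    """
    centroids = panel_centroids()
    sample, labels = gaussian_mixture_sample(
        centroids, PANEL_SD, n_per_cluster, PANEL_CHANNELS, seed=seed,
        source_id=f"panel(seed={seed})",
    )
    linear = sample.copy()
    linear.events = np.sinh(sample.events) * cofactor + background
    linear.transform_state = "compensated"
    linear.cofactor_map = {}
    return linear, labels, centroids


# ---------------------------------------------------------------------------
# Semi-synthetic scaling series


@dataclass
class SemisyntheticSeries:
    """One scaled sample per factor, plus the tracked cohort."""

    samples: list          # transformed Samples, one per factor
    factors: np.ndarray
    cohort_ids: np.ndarray  # event indices of the tracked stable cohort
    target_cluster: int
    mode: str
    channels: list[str] = field(default_factory=list)


def default_scale_factors(n: int = 8, lo: float = 1.0, hi: float = 10.0) -> np.ndarray:
    """The scaling ladder: n factors evenly spaced from lo (no change) to hi."""
    return np.linspace(lo, hi, n)


def make_semisynthetic(sample: Sample, template: ClusterTemplate, mode: str,
                       channels: list[str], scale_factors=None,
                       backgrounds: dict[str, float] | None = None,
                       cohort_ids=None, target_cluster: int | None = None,
                       cofactor_map: dict[str, float] | None = None,
                       n_reps: int = 5, seed: int = 0) -> SemisyntheticSeries:
    """Build a scaling series from a compensated linear-scale sample.

    Per factor f and target channel: values v become ``(v − b)/f + b`` with b
    the channel background — in cluster mode only for the tracked stable
    cohort of the target cluster, in channel mode for all events.  Factor 1
    leaves the sample unchanged.  Each scaled sample is ArcSinh-transformed
    and returned together with the tracked cohort's event indices.
    """
    if sample.transform_state != "compensated":
        raise ValueError("make_semisynthetic expects a compensated, linear-scale sample")
    if mode not in ("cluster", "channel"):
        raise ValueError(f"mode must be 'cluster' or 'channel', got {mode!r}")
    factors = default_scale_factors() if scale_factors is None else np.asarray(scale_factors, float)
    backgrounds = backgrounds or {}

    transformed = arcsinh_transform(sample, cofactor_map)
    if cohort_ids is None:
        if target_cluster is None:
            resolved = well_resolved_clusters(transformed, template, n_reps=n_reps, seed=seed)
            if not resolved:
                raise ValueError("no well-resolved cluster to track")
            a = assign(transformed, template)
            # moderate-sized: median effective size among resolved clusters
            sizes = a.sample_sizes[resolved]
            target_cluster = int(resolved[int(np.argsort(sizes)[len(sizes) // 2])])
        cohort_ids = stable_cohort(transformed, template, target_cluster,
                                   n_reps=n_reps, seed=seed)
    else:
        cohort_ids = np.asarray(cohort_ids, dtype=int)
        if target_cluster is None:
            a = assign(transformed, template)
            target_cluster = int(np.bincount(a.hard_labels[cohort_ids]).argmax())

    idxs = [sample.channel_index(c) for c in channels]
    bgs = np.array([float(backgrounds.get(c, 0.0)) for c in channels])
    for c, b, j in zip(channels, bgs, idxs):
        if b > sample.events[:, j].max():
            raise ValueError(f"background {b} exceeds all values in channel {c!r}")

    rows_all = np.arange(sample.n_events)
    rows = cohort_ids if mode == "cluster" else rows_all
    out = []
    for f in factors:
        scaled = sample.copy()
        for b, j in zip(bgs, idxs):
            vals = scaled.events[rows, j]
            scaled.events[rows, j] = (vals - b) / f + b
        scaled.source_id = f"{sample.source_id}|{mode}x{f:g}"
        out.append(arcsinh_transform(scaled, cofactor_map))
    return SemisyntheticSeries(
        samples=out, factors=factors, cohort_ids=np.asarray(cohort_ids, int),
        target_cluster=int(target_cluster), mode=mode, channels=list(channels),
    )


# ---------------------------------------------------------------------------
# Cluster / cohort stability under repeated template fits


def _repeat_labelings(sample: Sample, template: ClusterTemplate, n_reps: int,
                      seed: int) -> list[np.ndarray]:
    """Hard labels of the full sample under n_reps perturbed template refits
    (bootstrap-resampled events, different seeds)."""
    rng = np.random.default_rng(seed)
    labelings = []
    for r in range(n_reps):
        idx = rng.choice(sample.n_events, size=sample.n_events, replace=True)
        boot = sample.copy()
        boot.events = sample.events[idx]
        boot.event_sources = None
        refit = fit_template(boot, k=template.k, seed=int(rng.integers(2**31 - 1)))
        labelings.append(assign(sample, refit).hard_labels)
    return labelings


def _match_cluster(base_members: np.ndarray, labels: np.ndarray) -> tuple[int, float]:
    """Refit cluster capturing most of a base cluster's members, and the
    retained fraction."""
    sub = labels[base_members]
    counts = np.bincount(sub)
    best = int(counts.argmax())
    return best, counts[best] / len(sub)


def well_resolved_clusters(sample: Sample, template: ClusterTemplate,
                           n_reps: int = 5, seed: int = 0,
                           retention: float = 0.8, rep_fraction: float = 0.8) -> list[int]:
    """Clusters whose membership is reproducible under repeated fits.

    A cluster qualifies if, in at least ``rep_fraction`` of the repeat
    assignments, a single refit cluster retains at least ``retention`` of its
    original members (the 80%/80% criterion at the defaults).
    """
    if n_reps < 2:
        raise ValueError("need at least two repeats")
    base = assign(sample, template)
    labelings = _repeat_labelings(sample, template, n_reps, seed)
    out = []
    for j in range(template.k):
        members = np.nonzero(base.hard_labels == j)[0]
        if members.size == 0:
            continue
        hits = sum(
            1 for labels in labelings if _match_cluster(members, labels)[1] >= retention
        )
        if hits >= rep_fraction * n_reps:
            out.append(j)
    if not out:
        import warnings

        warnings.warn(
            f"no cluster met the {retention:.0%}/{rep_fraction:.0%} stability "
            f"criterion over {n_reps} repeats",
            stacklevel=2,
        )
    return out


def stable_cohort(sample: Sample, template: ClusterTemplate, cluster_id: int,
                  n_reps: int = 5, seed: int = 0, threshold: float = 0.95,
                  size_floor: int = 10) -> np.ndarray:
    """Event indices assigned with the cluster in more than ``threshold`` of
    repeat assignments (the >95%/>95% criterion at the default).

    The cohort is a subset of the cluster's baseline membership, so scaled
    cells can be tracked exactly across the semi-synthetic series.
    """
    base = assign(sample, template)
    members = np.nonzero(base.hard_labels == cluster_id)[0]
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} has no member events")
    labelings = _repeat_labelings(sample, template, n_reps, seed)
    stay = np.zeros(members.size)
    for labels in labelings:
        matched, _ = _match_cluster(members, labels)
        stay += labels[members] == matched
    cohort = members[stay / n_reps > threshold]
    if cohort.size < size_floor:
        import warnings

        warnings.warn(
            f"stable cohort of cluster {cluster_id} has only {cohort.size} events",
            stacklevel=2,
        )
    return cohort
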