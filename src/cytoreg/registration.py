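"""Cluster registration: movement vectors, ICR, NDCR, and the iteration driver.

Two registration modes operate on the soft assignment of a test sample to a
reference cluster template:

* **ICR** (independent cluster registration): each cluster is aligned to its
  reference counterpart by its own movement vector, the per-channel difference
  ``reference_centroid − sample_centroid``.

* **NDCR** (neighbor-dependent cluster registration): per channel, clusters
  are weighted by size (a Student-t confidence weight), binned by cumulative
  weight along the channel, and a smooth correction curve is fitted through
  the weighted bin averages of intensity vs. movement.  Each cluster's
  movement in that channel is the curve evaluated at its centroid, so the
  correction is driven by the local consensus of neighboring clusters and is
  robust to individual shifted subpopulations.

Events are displaced along compound vectors: each event moves by the
posterior-weighted combination of its clusters' vectors, scaled by the
iteration's update fraction.  Iterating re-assigns events after each move,
letting initially mis-assigned cells recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import make_smoothing_spline
from scipy.stats import t as student_t

from .clusters import Assignment, ClusterTemplate, assign
from .fcs import Sample, is_scatter_channel

__all__ = [
    "MovementVectors",
    "CorrectionCurve",
    "RegistrationConfig",
    "RegistrationLog",
    "ChannelUnregistrableError",
    "cluster_weight",
    "bin_count",
    "build_bins",
    "correction_curve",
    "movement_vectors",
    "ndcr_vectors",
    "displace_events",
    "register",
]

#: Eq.-style binning constants: bins = clamp(floor(BIN_FACTOR * sqrt(N)), BIN_MIN, BIN_MAX)
BIN_FACTOR = 0.75
BIN_MIN = 2
BIN_MAX = 20

#: default Student-t weight parameters; mu is the centroid-error tolerance in
#: units of sigma and must stay within [1/20, 1/10]
DEFAULT_MU = 1.0 / 15.0
DEFAULT_SIGMA = 1.0


class ChannelUnregistrableError(ValueError):
    """No positively weighted clusters in a channel: NDCR cannot proceed."""


@dataclass
class MovementVectors:
    """Per-cluster, per-channel displacement targets.

    Sign convention: ``displacement = reference_centroid − sample_centroid``,
    so applying a vector moves the sample toward the reference.  Rows where
    ``valid`` is False (clusters empty in the sample) are masked and
    contribute zero displacement.
    """

    vectors: np.ndarray  # K × C, zero in unregistered channels
    valid: np.ndarray    # K bool

    def masked(self) -> np.ndarray:
        out = np.where(self.valid[:, None], self.vectors, 0.0)
        return np.nan_to_num(out, nan=0.0)


# ---------------------------------------------------------------------------
# Cluster weights (Student-t confidence in the centroid estimate)


def cluster_weight(kappa, mu: float = DEFAULT_MU, sigma: float = DEFAULT_SIGMA):
    """Size-dependent cluster weight ω ∈ [0, 1].

    ω = 1 − 2·T_cdf(−μ√κ/σ; df = max(1, κ−1)) where κ is the smaller of the
    test-sample and reference-template cluster sizes (fractional effective
    sizes allowed) and T_cdf is the Student-t CDF.  ω(0) = 0 — an absent
    cluster has no influence; ω grows monotonically with κ and reaches 1 for
    large clusters (≈1.000 at κ = 10,000 with defaults), reflecting the
    shrinking uncertainty of a centroid estimated from more cells.
    """
    if mu <= 0 or sigma <= 0:
        raise ValueError("mu and sigma must be positive")
    kappa = np.asarray(kappa, dtype=float)
    if (kappa < 0).any():
        raise ValueError("cluster size kappa must be nonnegative")
    pos = kappa > 0
    out = np.zeros_like(kappa)
    if pos.any():
        kp = kappa[pos]
        stat = -(mu * np.sqrt(kp)) / sigma
        df = np.maximum(1.0, kp - 1.0)
        out[pos] = 1.0 - 2.0 * student_t.cdf(stat, df)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# NDCR binning


def bin_count(n_clusters: int, factor: float = BIN_FACTOR,
              lo: int = BIN_MIN, hi: int = BIN_MAX) -> int:
    """Number of NDCR bins: clamp(⌊factor·√N⌋, lo, hi)."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    return int(np.clip(math.floor(factor * math.sqrt(n_clusters)), lo, hi))


def build_bins(centroids_channel: np.ndarray, weights: np.ndarray,
               n_bins: int | None = None) -> list[np.ndarray]:
    """Partition clusters into weight-balanced bins along one channel.

    Clusters are sorted ascending by channel centroid (ties by index) and
    filled greedily; a bin closes once its cumulative weight reaches the quota
    ``total_weight / n_bins`` (the crossing cluster stays in the closing bin);
    the last bin absorbs any remainder.  Returns index arrays into the input.
    """
    x = np.asarray(centroids_channel, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size < 2:
        raise ChannelUnregistrableError(
            "neighbor-dependent correction needs at least two clusters"
        )
    if (w <= 0).all():
        raise ChannelUnregistrableError("all cluster weights are zero in this channel")
    total = w.sum()
    if n_bins is None:
        n_bins = bin_count(len(x))
    order = np.lexsort((np.arange(len(x)), x))
    quota = total / n_bins
    bins: list[list[int]] = [[]]
    acc = 0.0
    for idx in order:
        bins[-1].append(int(idx))
        acc += w[idx]
        if acc >= quota - 1e-12 and len(bins) < n_bins:
            bins.append([])
            acc = 0.0
    out = [np.array(b, dtype=int) for b in bins if b]
    if len(out) < 2 and len(x) >= 2:
        # weight concentrated at the top of the sort order: fall back to an
        # equal-count split so a curve can still be fitted
        k = min(n_bins, len(x))
        out = [np.array(c, dtype=int) for c in np.array_split(order, k)]
    return out


# ---------------------------------------------------------------------------
# Correction curves


@dataclass
class CorrectionCurve:
    """Smooth per-channel movement curve with tapered support.

    The support ``[x_lo, x_hi]`` spans the cluster centroids the curve was
    fitted on.  Inside it the fitted curve is evaluated (queries are clipped
    to the bin-point range, so the fit is never extrapolated); beyond the
    support the boundary value ramps linearly to zero over ``taper_span`` and
    is exactly zero past the taper, so regions with no clusters receive no
    correction.
    """

    bin_x: np.ndarray
    bin_y: np.ndarray
    bin_w: np.ndarray
    x_lo: float
    x_hi: float
    taper_span: float
    _spline: object = field(repr=False, default=None)

    def _inner(self, x: np.ndarray) -> np.ndarray:
        if self._spline is None:  # degenerate single-point support
            return np.full_like(x, self.bin_y[0])
        x = np.clip(x, self.bin_x[0], self.bin_x[-1])
        return np.asarray(self._spline(x), dtype=float)

    def __call__(self, x):
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.zeros_like(x)
        inside = (x >= self.x_lo) & (x <= self.x_hi)
        if inside.any():
            y[inside] = self._inner(x[inside])
        if self.taper_span > 0:
            y_lo = float(self._inner(np.array([self.x_lo]))[0])
            y_hi = float(self._inner(np.array([self.x_hi]))[0])
            left = (x < self.x_lo) & (x > self.x_lo - self.taper_span)
            y[left] = y_lo * (1.0 - (self.x_lo - x[left]) / self.taper_span)
            right = (x > self.x_hi) & (x < self.x_hi + self.taper_span)
            y[right] = y_hi * (1.0 - (x[right] - self.x_hi) / self.taper_span)
        return float(y[0]) if scalar else y


def correction_curve(bins: list[np.ndarray], centroids_channel: np.ndarray,
                     movements_channel: np.ndarray, weights: np.ndarray,
                     taper_span: float | None = None,
                     smoothing: float | None = None) -> CorrectionCurve:
    """Fit the NDCR correction curve for one channel.

    Bin abscissa is the weighted average cluster centroid, ordinate the
    weighted average movement (reference − sample).  A cubic smoothing spline
    is fitted through the bin points (weighted generalized cross-validation);
    with fewer than five bins a weighted piecewise-linear fit is used instead.
    """
    x = np.asarray(centroids_channel, float)
    yv = np.asarray(movements_channel, float)
    w = np.asarray(weights, float)
    bx, by, bw = [], [], []
    for b in bins:
        wb = w[b]
        ws = wb.sum()
        if ws <= 0:
            continue
        bx.append(float((wb * x[b]).sum() / ws))
        by.append(float((wb * yv[b]).sum() / ws))
        bw.append(float(ws))
    if not bx:
        raise ChannelUnregistrableError("no positively weighted bins")
    bx, by, bw = np.array(bx), np.array(by), np.array(bw)
    order = np.argsort(bx)
    bx, by, bw = bx[order], by[order], bw[order]
    # merge coincident abscissae with weight-sum
    keep_x, keep_y, keep_w = [bx[0]], [by[0] * bw[0]], [bw[0]]
    for xi, yi, wi in zip(bx[1:], by[1:], bw[1:]):
        if xi - keep_x[-1] < 1e-10:
            keep_y[-1] += yi * wi
            keep_w[-1] += wi
        else:
            keep_x.append(xi)
            keep_y.append(yi * wi)
            keep_w.append(wi)
    bx = np.array(keep_x)
    bw = np.array(keep_w)
    by = np.array(keep_y) / bw

    if taper_span is None:
        taper_span = (bx[-1] - bx[0]) / max(1, len(bx) - 1) if len(bx) > 1 else 1.0
        taper_span = taper_span if taper_span > 0 else 1.0

    spline = None
    if len(bx) >= 5:
        spline = make_smoothing_spline(bx, by, w=bw / bw.mean(), lam=smoothing)
    elif len(bx) >= 2:
        xs, ys = bx.copy(), by.copy()
        spline = lambda q: np.interp(q, xs, ys)  # noqa: E731
    pos = w > 0
    support = x[pos] if pos.any() else bx
    return CorrectionCurve(
        bin_x=bx, bin_y=by, bin_w=bw,
        x_lo=float(min(support.min(), bx[0])), x_hi=float(max(support.max(), bx[-1])),
        taper_span=float(taper_span), _spline=spline,
    )


# ---------------------------------------------------------------------------
# Vectors


def movement_vectors(assignment: Assignment, template: ClusterTemplate) -> MovementVectors:
    """ICR vectors: reference centroid − sample centroid, per cluster/channel."""
    vec = template.centroids - assignment.sample_centroids
    return MovementVectors(vectors=np.nan_to_num(vec, nan=0.0), valid=assignment.valid.copy())


@dataclass
class RegistrationConfig:
    """Parameters of the iterative registration driver.

    ``schedule`` is a list of (method, update fraction) pairs executed in
    order; the default is the recommended two NDCR cycles followed by two ICR
    cycles, all with full (fraction 1.0) position updates.
    """

    schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [("ndcr", 1.0), ("ndcr", 1.0), ("icr", 1.0), ("icr", 1.0)]
    )
    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA
    bin_factor: float = BIN_FACTOR
    bin_min: int = BIN_MIN
    bin_max: int = BIN_MAX
    channels: list[str] | None = None
    taper_span: float | None = None
    spline_smoothing: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 / 20 - 1e-12 <= self.mu <= 1 / 10 + 1e-12):
            raise ValueError(f"mu={self.mu} outside the allowed range [1/20, 1/10]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for method, frac in self.schedule:
            if method not in ("ndcr", "icr"):
                raise ValueError(f"unknown method {method!r}")
            if not 0 < frac <= 1:
                raise ValueError(f"update fraction {frac} outside (0, 1]")

    @classmethod
    def partial(cls, **kw) -> "RegistrationConfig":
        """Partial-update preset: 25%, 33%, 50%, 100% over the default schedule."""
        sched = [("ndcr", 0.25), ("ndcr", 1 / 3), ("icr", 0.5), ("icr", 1.0)]
        return cls(schedule=sched, **kw)

    @classmethod
    def make_schedule(cls, method: str, iterations: int, partial: bool = False) -> list[tuple[str, float]]:
        if method == "ndcr+icr":
            half = iterations // 2
            methods = ["ndcr"] * half + ["icr"] * (iterations - half)
        elif method in ("ndcr", "icr"):
            methods = [method] * iterations
        else:
            raise ValueError(f"unknown method {method!r}")
        n = len(methods)
        fracs = [1.0 / (n - i) for i in range(n)] if partial else [1.0] * n
        return list(zip(methods, fracs))

    @classmethod
    def from_yaml(cls, path) -> "RegistrationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "schedule" in raw:
            raw["schedule"] = [(str(m), float(f)) for m, f in raw["schedule"]]
        return cls(**raw)

    def registered_channel_indices(self, channels: list[str]) -> list[int]:
        if self.channels is not None:
            return [channels.index(c) for c in self.channels]
        return [i for i, c in enumerate(channels) if not is_scatter_channel(c)]


def ndcr_vectors(assignment: Assignment, template: ClusterTemplate,
                 config: RegistrationConfig | None = None) -> MovementVectors:
    """NDCR vectors: per channel, the correction curve evaluated at each
    cluster's sample centroid.  Channels are corrected one at a time; the
    per-channel movements are assembled into one K × C displacement set.
    """
    config = config or RegistrationConfig()
    K, C = template.centroids.shape
    vec = np.zeros((K, C))
    valid = assignment.valid
    idxs = np.nonzero(valid)[0]
    if idxs.size == 0:
        return MovementVectors(vectors=vec, valid=valid.copy())
    kappa = np.minimum(assignment.sample_sizes[idxs], template.sizes[idxs])
    weights = np.asarray(cluster_weight(kappa, config.mu, config.sigma))
    for c in config.registered_channel_indices(template.channels):
        cents = assignment.sample_centroids[idxs, c]
        moves = template.centroids[idxs, c] - cents
        nb = bin_count(len(idxs), config.bin_factor, config.bin_min, config.bin_max)
        bins = build_bins(cents, weights, n_bins=nb)
        curve = correction_curve(
            bins, cents, moves, weights,
            taper_span=config.taper_span, smoothing=config.spline_smoothing,
        )
        vec[idxs, c] = curve(cents)
    return MovementVectors(vectors=vec, valid=valid.copy())


# ---------------------------------------------------------------------------
# Event displacement and the iteration driver


def displace_events(sample: Sample, posteriors: np.ndarray,
                    vectors: MovementVectors, fraction: float) -> Sample:
    """Move each event along its compound vector.

    Displacement in channel c is ``fraction · Σ_j posterior[e,j]·vectors[j,c]``
    — the posterior-weighted blend of its clusters' vectors, which avoids
    discontinuities for events with split membership.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if posteriors.shape[0] != sample.n_events or posteriors.shape[1] != vectors.vectors.shape[0]:
        raise ValueError(
            f"dimension mismatch: posteriors {posteriors.shape}, "
            f"events {sample.events.shape}, vectors {vectors.vectors.shape}"
        )
    out = sample.copy()
    out.events = sample.events + fraction * (posteriors @ vectors.masked())
    return out


@dataclass
class RegistrationLog:
    """Per-iteration record: method, fraction, and centroid RMSE per channel."""

    iterations: list[dict] = field(default_factory=list)

    def add(self, iteration: int, method: str, fraction: float,
            assignment: Assignment, template: ClusterTemplate) -> None:
        diff = template.centroids - assignment.sample_centroids
        valid = assignment.valid
        per_channel = {}
        if valid.any():
            rms = np.sqrt(np.nanmean(diff[valid] ** 2, axis=0))
            per_channel = {c: float(r) for c, r in zip(template.channels, rms)}
            total = float(np.sqrt(np.nanmean(np.sum(diff[valid] ** 2, axis=1))))
        else:
            total = float("nan")
        self.iterations.append({
            "iteration": iteration,
            "method": method,
            "fraction": fraction,
            "rmse_per_channel": per_channel,
            "rmse_distance": total,
        })

    @property
    def final_rmse(self) -> float:
        return self.iterations[-1]["rmse_distance"] if self.iterations else float("nan")

    def to_json(self, path=None) -> str:
        text = json.dumps({"iterations": self.iterations}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def register(sample: Sample, template: ClusterTemplate,
             config: RegistrationConfig | None = None,
             capture: list | None = None) -> tuple[Sample, RegistrationLog]:
    """Iteratively register a transformed sample to a reference template.

    Each scheduled iteration re-assigns the (possibly already moved) events to
    the template, derives movement vectors by the iteration's method, and
    displaces every event along its compound vector scaled by the update
    fraction.  When ``capture`` is a list, the per-iteration
    (method, fraction, MovementVectors) triples are appended to it — this is
    how batch templates freeze a standard's registration trajectory.
    """
    config = config or RegistrationConfig()
    log = RegistrationLog()
    current = sample
    for i, (method, fraction) in enumerate(config.schedule):
        a = assign(current, template)
        log.add(i, method, fraction, a, template)
        if method == "icr":
            vec = movement_vectors(a, template)
            reg_idx = set(config.registered_channel_indices(template.channels))
            mask = np.array([j in reg_idx for j in range(template.n_channels)])
            vec.vectors = np.where(mask[None, :], vec.vectors, 0.0)
        else:
            vec = ndcr_vectors(a, template, config)
        if capture is not None:
            capture.append((method, fraction, vec))
        current = displace_events(current, a.posteriors, vec, fraction)
        if not np.isfinite(current.events).all():
            raise FloatingPointError(f"non-finite event values after iteration {i} ({method})")
    final = assign(current, template)
    log.add(len(config.schedule), "final", 0.0, final, template)
    return current, log
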