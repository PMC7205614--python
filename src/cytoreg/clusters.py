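"""Cluster templates and soft assignment.

A :class:`ClusterTemplate` is a frozen full-covariance Gaussian mixture fit on
a reference sample: centroids (means of transformed intensities), covariances
and relative sizes.  Test samples are soft-assigned to the template — every
event is allocated proportionally across clusters by its posterior membership
probability — and per-cluster sample centroids and effective sizes are the
posterior-weighted statistics that registration operates on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

__all__ = ["ClusterTemplate", "Assignment", "fit_template", "assign", "cluster_stats"]

#: posterior memberships below this are zeroed and rows renormalized
POSTERIOR_FLOOR = 1e-8
#: components whose effective size falls below this are pruned during fitting
SIZE_FLOOR = 2.0


@dataclass
class ClusterTemplate:
    """Frozen mixture model of a reference sample.

    ``sizes`` are reference cluster sizes in cells (mixture_weights × events);
    they may be fractional.
    """

    centroids: np.ndarray          # K × C
    covariances: np.ndarray        # K × C × C
    mixture_weights: np.ndarray    # K, sums to 1
    sizes: np.ndarray              # K, in cells
    channels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.k < 1:
            raise ValueError("template needs at least one cluster")
        if not np.isclose(self.mixture_weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if (self.mixture_weights < 0).any():
            raise ValueError("mixture weights must be nonnegative")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_channels(self) -> int:
        return self.centroids.shape[1]

    # -- serialization: JSON metadata + npz binary sidecar ------------------

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "format": "cytoreg-template",
            "version": 1,
            "channels": self.channels,
            "metadata": self.metadata,
        }
        path.write_text(json.dumps(meta, indent=1))
        np.savez(
            path.with_suffix(path.suffix + ".npz"),
            centroids=self.centroids,
            covariances=self.covariances,
            mixture_weights=self.mixture_weights,
            sizes=self.sizes,
        )

    @classmethod
    def load(cls, path) -> "ClusterTemplate":
        path = Path(path)
        meta = json.loads(path.read_text())
        if meta.get("format") != "cytoreg-template":
            raise ValueError(f"{path} is not a cytoreg template")
        arrays = np.load(path.with_suffix(path.suffix + ".npz"))
        return cls(
            centroids=arrays["centroids"],
            covariances=arrays["covariances"],
            mixture_weights=arrays["mixture_weights"],
            sizes=arrays["sizes"],
            channels=list(meta["channels"]),
            metadata=meta.get("metadata", {}),
        )


@dataclass
class Assignment:
    """Soft assignment of one sample to a template.

    ``sample_centroids`` rows are NaN (and ``valid`` False) for clusters with
    zero effective size in this sample.
    """

    posteriors: np.ndarray        # E × K
    hard_labels: np.ndarray       # E
    sample_centroids: np.ndarray  # K × C, NaN where undefined
    sample_sizes: np.ndarray      # K, effective sizes (posterior column sums)
    valid: np.ndarray             # K bool

    @property
    def n_events(self) -> int:
        return self.posteriors.shape[0]

    @property
    def k(self) -> int:
        return self.posteriors.shape[1]


def _log_component_densities(events: np.ndarray, template: ClusterTemplate) -> np.ndarray:
    """log[w_k N(x; mu_k, Sigma_k)] for all events and components, via the
    Cholesky factor of each covariance (stable for near-singular fits)."""
    E, C = events.shape
    out = np.empty((E, template.k))
    for k in range(template.k):
        cov = template.covariances[k]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(cov + 1e-9 * np.eye(C))
        dev = events - template.centroids[k]
        u = solve_triangular(chol, dev.T, lower=True).T
        maha = np.einsum("ij,ij->i", u, u)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, k] = (
            np.log(max(template.mixture_weights[k], 1e-300))
            - 0.5 * (C * np.log(2 * np.pi) + logdet + maha)
        )
    return out


def _posteriors(events: np.ndarray, template: ClusterTemplate) -> np.ndarray:
    """Floored, renormalized posterior membership matrix (E × K)."""
    logw = _log_component_densities(events, template)
    logw -= logsumexp(logw, axis=1, keepdims=True)
    post = np.exp(logw)
    post[post < POSTERIOR_FLOOR] = 0.0
    post /= post.sum(axis=1, keepdims=True)
    return post


def _weighted_stats(events: np.ndarray, post: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sizes = post.sum(axis=0)
    valid = sizes > 0
    centroids = np.full((post.shape[1], events.shape[1]), np.nan)
    if valid.any():
        centroids[valid] = (post[:, valid].T @ events) / sizes[valid, None]
    return centroids, sizes, valid


def fit_template(sample, k: int, seed: int = 0, size_floor: float = SIZE_FLOOR,
                 max_iter: int = 300) -> ClusterTemplate:
    """Fit a k-component full-covariance GMM on a transformed sample.

    After EM converges, a short exact E/M refinement (using the same floored
    posteriors as :func:`assign`) is run until the centroids are a fixed point
    of the assignment statistics, so that re-assigning the fitting sample
    reproduces the template centroids to numerical precision.
    """
    if sample.transform_state != "transformed":
        raise ValueError("fit_template requires a transformed sample")
    events = sample.events
    if not 1 <= k <= events.shape[0]:
        raise ValueError(f"k={k} out of range for {events.shape[0]} events")

    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        random_state=seed,
        init_params="k-means++",
        max_iter=max_iter,
        reg_covar=1e-6,
        n_init=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(events)

    means, covs, weights = gm.means_, gm.covariances_, gm.weights_

    # prune degenerate components
    eff = weights * events.shape[0]
    keep = eff >= min(size_floor, eff.max())
    if not keep.all():
        warnings.warn(
            f"pruned {int((~keep).sum())} degenerate component(s) with effective "
            f"size < {size_floor}",
            stacklevel=2,
        )
        means, covs, weights = means[keep], covs[keep], weights[keep]
        weights = weights / weights.sum()

    template = ClusterTemplate(
        centroids=means,
        covariances=covs,
        mixture_weights=weights,
        sizes=weights * events.shape[0],
        channels=list(sample.channels),
        metadata={"seed": seed, "k": int(k), "reference": sample.source_id,
                  "log_likelihood": float(gm.lower_bound_)},
    )

    # Fixed-point polish under the assignment conventions: iterate the E-step
    # and the mean/weight M-step with covariances frozen, so that the template
    # centroids are exactly the posterior-weighted means the assignment
    # statistics reproduce.  Covariances stay fixed, hence their Cholesky
    # factors are computed once.
    for _ in range(400):
        post = _posteriors(events, template)
        centroids, sizes, valid = _weighted_stats(events, post)
        if not valid.all():  # component starved: stop polishing
            break
        shift = np.nanmax(np.abs(centroids - template.centroids))
        template.centroids = centroids
        template.mixture_weights = sizes / sizes.sum()
        template.sizes = sizes
        if shift < 1e-11:
            break
    return template


def assign(sample, template: ClusterTemplate) -> Assignment:
    """Soft-assign a transformed sample to a template."""
    if sample.transform_state != "transformed":
        raise ValueError("assign requires a transformed sample")
    if list(sample.channels) != list(template.channels):
        raise ValueError(
            f"channel mismatch: sample {sample.channels} vs template {template.channels}"
        )
    post = _posteriors(sample.events, template)
    centroids, sizes, valid = _weighted_stats(sample.events, post)
    return Assignment(
        posteriors=post,
        hard_labels=post.argmax(axis=1),
        sample_centroids=centroids,
        sample_sizes=sizes,
        valid=valid,
    )


def cluster_stats(assignment: Assignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster posterior-weighted centroids and effective sizes."""
    return assignment.sample_centroids, assignment.sample_sizes
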