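import numpy as np
import pytest

import cytoreg as cr
from cytoreg.synthetic import gaussian_mixture_sample, separated_centroids

CHANNELS_3 = ["CD3", "CD4", "CD8"]


@pytest.fixture(scope="session")
def mixture10():
    """10 well-separated clusters in 3 channels: reference sample, a fresh
    draw from the same mixture, the true centroids, and the fitted template."""
    centroids = separated_centroids(10, 3, lo=0.5, hi=4.0, min_dist=1.2, seed=11)
    reference, ref_labels = gaussian_mixture_sample(
        centroids, 0.12, 400, CHANNELS_3, seed=21, source_id="reference"
    )
    test, test_labels = gaussian_mixture_sample(
        centroids, 0.12, 400, CHANNELS_3, seed=22, source_id="test"
    )
    template = cr.fit_template(reference, k=10, seed=0)
    return {
        "centroids": centroids,
        "reference": reference,
        "test": test,
        "template": template,
        "ref_labels": ref_labels,
        "test_labels": test_labels,
    }


@pytest.fixture(scope="session")
def two_cluster():
    """Two far-separated equal clusters in 2 channels plus fitted template."""
    centroids = np.array([[0.0, 0.0], [8.0, 8.0]])
    sample, labels = gaussian_mixture_sample(
        centroids, 0.3, 500, ["CD3", "CD4"], seed=7, source_id="two"
    )
    template = cr.fit_template(sample, k=2, seed=1)
    return {"centroids": centroids, "sample": sample, "labels": labels, "template": template}


def shifted_copy(sample, channel_idx, delta):
    out = sample.copy()
    out.events[:, channel_idx] += delta
    out.source_id = f"{sample.source_id}+shift"
    return out
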