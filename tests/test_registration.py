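"""Movement vectors, cluster weights, binning, correction curves, and the
iterative registration driver."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

import cytoreg as cr
from cytoreg.clusters import Assignment, ClusterTemplate
from cytoreg.registration import (
    ChannelUnregistrableError,
    MovementVectors,
    RegistrationConfig,
    bin_count,
    build_bins,
    cluster_weight,
    correction_curve,
    displace_events,
    movement_vectors,
    ndcr_vectors,
)

from conftest import shifted_copy


def _line_template(k=25, spacing=0.4, channels=("CD3", "CD4"), size=500.0):
    """k clusters evenly spaced along channel 0, constant channel 1."""
    cents = np.stack([np.arange(k) * spacing, np.full(k, 1.0)], axis=1)
    return ClusterTemplate(
        centroids=cents,
        covariances=np.stack([np.eye(2) * 0.01] * k),
        mixture_weights=np.full(k, 1.0 / k),
        sizes=np.full(k, size),
        channels=list(channels),
    )


def _assignment_for(template, sample_centroids, sizes=None, n_events=10):
    k = template.k
    sizes = np.full(k, 500.0) if sizes is None else np.asarray(sizes, float)
    post = np.full((n_events, k), 1.0 / k)
    return Assignment(
        posteriors=post,
        hard_labels=post.argmax(axis=1),
        sample_centroids=np.asarray(sample_centroids, float),
        sample_sizes=sizes,
        valid=sizes > 0,
    )


# ---------------------------------------------------------------------------
# Cluster weights


class TestClusterWeight:
    def test_absent_cluster_has_zero_weight(self):
        assert cluster_weight(0.0) == 0.0

    def test_large_cluster_weight_saturates_at_one(self):
        assert cluster_weight(10_000) == pytest.approx(1.0, abs=5e-4)
        assert round(cluster_weight(10_000), 3) == 1.0

    def test_small_cluster_weight_near_one_tenth(self):
        # a 4-cell cluster sits near the bottom of the useful weight range
        assert cluster_weight(4) == pytest.approx(0.1, abs=0.01)

    def test_against_quadrature_oracle(self):
        # independent oracle: omega = P(|T_df| < mu*sqrt(kappa)/sigma),
        # computed by numerically integrating the Student-t density written
        # out from its gamma-function definition
        from scipy.integrate import quad

        for kappa in (2.0, 4.0, 10.0, 100.0, 2500.0):
            df = max(1.0, kappa - 1.0)
            bound = (1.0 / 15.0) * math.sqrt(kappa) / 1.0

            def t_pdf(x, df=df):
                log_c = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
                         - 0.5 * math.log(df * math.pi))
                return math.exp(log_c - (df + 1) / 2 * math.log1p(x * x / df))

            expected, err = quad(t_pdf, -bound, bound)
            assert err < 1e-10
            assert cluster_weight(kappa) == pytest.approx(expected, abs=1e-9)

    def test_monotone_nondecreasing_in_kappa(self):
        kappas = np.concatenate([[0.0], np.geomspace(0.5, 1e4, 300)])
        w = cluster_weight(kappas)
        assert np.all(np.diff(w) >= -1e-12)
        assert np.all((w >= 0) & (w <= 1))

    def test_vectorized_matches_scalar(self):
        ks = np.array([0.0, 3.0, 50.0, 1e4])
        vec = cluster_weight(ks)
        for k, v in zip(ks, vec):
            assert cluster_weight(float(k)) == pytest.approx(v, abs=1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cluster_weight(10, mu=0.0)
        with pytest.raises(ValueError, match="positive"):
            cluster_weight(10, sigma=-1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            cluster_weight(-1.0)


# ---------------------------------------------------------------------------
# Binning


class TestBinCount:
    @pytest.mark.parametrize("n,expected", [
        (1, 2),        # floor(0.75) = 0, clamped up
        (4, 2),        # floor(1.5) = 1, clamped up
        (8, 2),        # floor(2.12) = 2
        (16, 3),
        (64, 6),
        (100, 7),      # floor(7.5)
        (712, 20),     # floor(20.01) = 20, at the cap
        (711, 19),
        (1000, 20),    # floor(23.7), clamped down
        (100_000, 20),
    ])
    def test_known_values(self, n, expected):
        assert bin_count(n) == expected

    def test_bounds_hold_over_full_range(self):
        ns = np.unique(np.concatenate([
            np.arange(1, 2000), np.geomspace(2000, 100_000, 200).astype(int)
        ]))
        counts = np.array([bin_count(int(n)) for n in ns])
        assert counts.min() == 2 and counts.max() == 20
        assert np.all(np.diff(counts) >= 0)  # monotone in N

    def test_zero_clusters_rejected(self):
        with pytest.raises(ValueError):
            bin_count(0)


class TestBuildBins:
    def test_equal_weights_split_evenly(self):
        x = np.arange(20.0)
        bins = build_bins(x, np.ones(20), n_bins=2)
        assert [len(b) for b in bins] == [10, 10]
        np.testing.assert_array_equal(bins[0], np.arange(10))
        np.testing.assert_array_equal(bins[1], np.arange(10, 20))

    def test_twenty_bins_of_five_percent(self):
        x = np.arange(20.0)
        bins = build_bins(x, np.ones(20), n_bins=20)
        assert len(bins) == 20
        assert all(len(b) == 1 for b in bins)

    def test_quota_crossing_cluster_stays_in_closing_bin(self):
        # 10 light (w=0.1) clusters at low x, 10 heavy (w=1.0) above them.
        # Total weight 11, quota 5.5: the first bin keeps filling until the
        # 15th cluster pushes it to 6.0 >= 5.5, so it holds 15 clusters.
        x = np.arange(20.0)
        w = np.array([0.1] * 10 + [1.0] * 10)
        bins = build_bins(x, w, n_bins=2)
        assert [len(b) for b in bins] == [15, 5]

    def test_bins_ordered_and_partition(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 37)
        w = rng.uniform(0.1, 1.0, 37)
        bins = build_bins(x, w)
        flat = np.concatenate(bins)
        assert sorted(flat) == list(range(37))
        # bins are ordered along the channel
        maxes = [x[b].max() for b in bins[:-1]]
        mins = [x[b].min() for b in bins[1:]]
        assert all(m <= n + 1e-12 for m, n in zip(maxes, mins))

    def test_all_zero_weights_unregistrable(self):
        with pytest.raises(ChannelUnregistrableError):
            build_bins(np.arange(5.0), np.zeros(5))

    def test_extreme_weight_concentration_still_two_bins(self):
        # nearly all weight on the last cluster: fallback keeps >= 2 bins
        w = np.array([1e-9] * 9 + [1.0])
        bins = build_bins(np.arange(10.0), w, n_bins=2)
        assert len(bins) >= 2


# ---------------------------------------------------------------------------
# Correction curves


class TestCorrectionCurve:
    def _curve(self, x, y, w=None, n_bins=None, **kw):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        w = np.ones_like(x) if w is None else np.asarray(w, float)
        bins = build_bins(x, w, n_bins=n_bins)
        return correction_curve(bins, x, y, w, **kw)

    def test_zero_movement_gives_zero_curve(self):
        c = self._curve(np.linspace(0, 5, 30), np.zeros(30))
        q = np.linspace(-2, 8, 100)
        np.testing.assert_allclose(c(q), 0.0, atol=1e-12)

    def test_constant_movement_recovered(self):
        c = self._curve(np.linspace(0, 5, 30), np.full(30, 0.4))
        inside = np.linspace(c.x_lo, c.x_hi, 50)
        np.testing.assert_allclose(c(inside), 0.4, atol=0.02)

    def test_exactly_zero_beyond_taper(self):
        c = self._curve(np.linspace(0, 5, 30), np.full(30, 0.4))
        assert c(c.x_lo - c.taper_span - 0.01) == 0.0
        assert c(c.x_hi + c.taper_span + 0.01) == 0.0
        assert c(c.x_hi + 10.0) == 0.0

    def test_taper_ramps_linearly_to_zero(self):
        c = self._curve(np.linspace(0, 5, 30), np.full(30, 0.4))
        edge = c(c.x_hi)
        mid = c(c.x_hi + c.taper_span / 2)
        assert mid == pytest.approx(edge / 2, rel=1e-6)

    def test_linear_fallback_with_two_bins(self):
        # 4 clusters, 2 bins -> weighted linear interpolation between the
        # two bin points (0.5, 0.1) and (2.5, 0.3)
        c = self._curve([0.0, 1.0, 2.0, 3.0], [0.1, 0.1, 0.3, 0.3], n_bins=2)
        assert c(0.5) == pytest.approx(0.1)
        assert c(2.5) == pytest.approx(0.3)
        assert c(1.5) == pytest.approx(0.2)

    def test_weighted_bin_average(self):
        # one bin of two clusters with weights 3 and 1: abscissa and ordinate
        # are the weighted means
        bins = [np.array([0, 1])]
        c = correction_curve(bins, np.array([0.0, 4.0]), np.array([1.0, -3.0]),
                            np.array([3.0, 1.0]))
        assert c.bin_x[0] == pytest.approx(1.0)   # (3*0 + 1*4)/4
        assert c.bin_y[0] == pytest.approx(0.0)   # (3*1 + 1*(-3))/4

    def test_spline_tracks_smooth_trend(self):
        x = np.linspace(0, 6, 40)
        y = 0.3 * np.sin(x / 2)
        c = self._curve(x, y)
        q = np.linspace(0.5, 5.5, 50)
        np.testing.assert_allclose(c(q), 0.3 * np.sin(q / 2), atol=0.03)


# ---------------------------------------------------------------------------
# Vectors


class TestMovementVectors:
    def test_icr_is_reference_minus_sample(self):
        t = _line_template(k=5)
        sample_cents = t.centroids + np.array([0.3, -0.2])
        a = _assignment_for(t, sample_cents)
        vec = movement_vectors(a, t)
        np.testing.assert_allclose(vec.vectors, np.tile([-0.3, 0.2], (5, 1)), atol=1e-12)

    def test_invalid_rows_masked_to_zero(self):
        vec = MovementVectors(
            vectors=np.array([[1.0, 2.0], [3.0, np.nan]]),
            valid=np.array([False, True]),
        )
        np.testing.assert_array_equal(vec.masked(), [[0.0, 0.0], [3.0, 0.0]])

    def test_ndcr_zero_for_aligned_sample(self):
        t = _line_template()
        a = _assignment_for(t, t.centroids.copy())
        vec = ndcr_vectors(a, t)
        np.testing.assert_allclose(vec.vectors, 0.0, atol=1e-9)

    def test_ndcr_recovers_global_shift(self):
        t = _line_template()
        a = _assignment_for(t, t.centroids + np.array([0.3, 0.0]))
        vec = ndcr_vectors(a, t)
        np.testing.assert_allclose(vec.vectors[:, 0], -0.3, atol=1e-6)
        np.testing.assert_allclose(vec.vectors[:, 1], 0.0, atol=1e-6)

    def test_ndcr_discounts_single_outlier(self):
        # one cluster moved against a static field: neighbors vote it down,
        # so |NDCR| is well below |ICR| for the outlier
        t = _line_template()
        cents = t.centroids.copy()
        cents[12, 0] += 0.8
        a = _assignment_for(t, cents)
        ndcr = ndcr_vectors(a, t)
        icr = movement_vectors(a, t)
        assert abs(icr.vectors[12, 0]) == pytest.approx(0.8)
        assert abs(ndcr.vectors[12, 0]) < 0.4

    def test_ndcr_skips_scatter_channels(self):
        t = _line_template(channels=("CD3", "FSC-A"))
        a = _assignment_for(t, t.centroids + np.array([0.2, 0.5]))
        vec = ndcr_vectors(a, t)
        np.testing.assert_array_equal(vec.vectors[:, 1], 0.0)
        assert not np.allclose(vec.vectors[:, 0], 0.0)


# ---------------------------------------------------------------------------
# Event displacement


class TestDisplaceEvents:
    def _sample(self, events, channels=("CD3", "CD4")):
        return cr.Sample(events=np.asarray(events, float), channels=list(channels),
                         transform_state="transformed")

    def test_full_membership_moves_by_vector(self):
        s = self._sample([[1.0, 1.0], [2.0, 2.0]])
        vec = MovementVectors(vectors=np.array([[0.5, -0.25]]), valid=np.array([True]))
        out = displace_events(s, np.ones((2, 1)), vec, fraction=1.0)
        np.testing.assert_allclose(out.events, [[1.5, 0.75], [2.5, 1.75]])
        np.testing.assert_allclose(s.events, [[1.0, 1.0], [2.0, 2.0]])  # input untouched

    def test_split_membership_blends_vectors(self):
        s = self._sample([[0.0, 0.0]])
        vec = MovementVectors(vectors=np.array([[1.0, 0.0], [0.0, 1.0]]),
                              valid=np.array([True, True]))
        out = displace_events(s, np.array([[0.4, 0.6]]), vec, fraction=1.0)
        np.testing.assert_allclose(out.events, [[0.4, 0.6]])

    def test_fraction_scales_linearly(self):
        rng = np.random.default_rng(0)
        s = self._sample(rng.normal(size=(20, 2)))
        post = rng.dirichlet(np.ones(3), size=20)
        vec = MovementVectors(vectors=rng.normal(size=(3, 2)), valid=np.ones(3, bool))
        full = displace_events(s, post, vec, 1.0).events - s.events
        half = displace_events(s, post, vec, 0.5).events - s.events
        np.testing.assert_allclose(half, full / 2, atol=1e-12)

    def test_fraction_out_of_range_rejected(self):
        s = self._sample([[0.0, 0.0]])
        vec = MovementVectors(vectors=np.zeros((1, 2)), valid=np.array([True]))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                displace_events(s, np.ones((1, 1)), vec, bad)

    def test_dimension_mismatch_rejected(self):
        s = self._sample([[0.0, 0.0]])
        vec = MovementVectors(vectors=np.zeros((2, 2)), valid=np.ones(2, bool))
        with pytest.raises(ValueError, match="mismatch"):
            displace_events(s, np.ones((1, 3)), vec, 1.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_displacement_inside_vector_hull(self, seed):
        # posterior rows are convex weights, so each event's displacement
        # must lie inside the per-channel range of the cluster vectors
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        post = rng.dirichlet(np.ones(k), size=8)
        vecs = rng.normal(size=(k, 2))
        mv = MovementVectors(vectors=vecs, valid=np.ones(k, bool))
        s = self._sample(np.zeros((8, 2)))
        d = displace_events(s, post, mv, 1.0).events
        for c in range(2):
            assert np.all(d[:, c] >= vecs[:, c].min() - 1e-9)
            assert np.all(d[:, c] <= vecs[:, c].max() + 1e-9)


# ---------------------------------------------------------------------------
# Configuration


class TestRegistrationConfig:
    def test_default_schedule(self):
        cfg = RegistrationConfig()
        assert cfg.schedule == [("ndcr", 1.0), ("ndcr", 1.0), ("icr", 1.0), ("icr", 1.0)]

    def test_mu_range_enforced(self):
        RegistrationConfig(mu=1 / 20)
        RegistrationConfig(mu=1 / 10)
        with pytest.raises(ValueError, match="mu"):
            RegistrationConfig(mu=1 / 25)
        with pytest.raises(ValueError, match="mu"):
            RegistrationConfig(mu=0.2)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError, match="method"):
            RegistrationConfig(schedule=[("quantile", 1.0)])
        with pytest.raises(ValueError, match="fraction"):
            RegistrationConfig(schedule=[("icr", 0.0)])

    def test_partial_preset_fractions(self):
        cfg = RegistrationConfig.partial()
        assert [f for _, f in cfg.schedule] == pytest.approx([0.25, 1 / 3, 0.5, 1.0])

    def test_make_schedule_combined(self):
        sched = RegistrationConfig.make_schedule("ndcr+icr", 4)
        assert sched == [("ndcr", 1.0), ("ndcr", 1.0), ("icr", 1.0), ("icr", 1.0)]
        sched = RegistrationConfig.make_schedule("icr", 3, partial=True)
        assert [f for _, f in sched] == pytest.approx([1 / 3, 1 / 2, 1.0])

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump({
            "schedule": [["ndcr", 0.5], ["icr", 1.0]],
            "mu": 1 / 12, "sigma": 1.5, "seed": 7,
        }))
        cfg = RegistrationConfig.from_yaml(p)
        assert cfg.schedule == [("ndcr", 0.5), ("icr", 1.0)]
        assert cfg.mu == pytest.approx(1 / 12)
        assert cfg.seed == 7

    def test_scatter_channels_excluded_by_default(self):
        cfg = RegistrationConfig()
        idx = cfg.registered_channel_indices(["FSC-A", "CD3", "SSC-H", "CD4", "Time"])
        assert idx == [1, 3]


# ---------------------------------------------------------------------------
# The iteration driver


class TestRegister:
    def test_self_registration_is_fixed_point(self, mixture10):
        reg, log = cr.register(mixture10["reference"], mixture10["template"])
        assert np.abs(reg.events - mixture10["reference"].events).max() < 1e-6
        assert log.final_rmse < 1e-6

    def test_recovers_constant_shift(self, mixture10):
        shifted = shifted_copy(mixture10["test"], 0, 0.5)
        reg, log = cr.register(shifted, mixture10["template"])
        assert log.iterations[0]["rmse_distance"] > 0.4
        assert log.final_rmse < 0.1
        # registered events land near the unshifted originals
        assert np.abs(reg.events - mixture10["test"].events).mean() < 0.1

    def test_icr_only_single_cluster(self, two_cluster):
        t = cr.fit_template(two_cluster["sample"], k=1, seed=0)
        shifted = shifted_copy(two_cluster["sample"], 0, 0.7)
        cfg = RegistrationConfig(schedule=[("icr", 1.0), ("icr", 1.0)])
        reg, log = cr.register(shifted, t, cfg)
        assert log.final_rmse < 1e-6

    def test_ndcr_single_cluster_unregistrable(self, two_cluster):
        t = cr.fit_template(two_cluster["sample"], k=1, seed=0)
        cfg = RegistrationConfig(schedule=[("ndcr", 1.0)])
        with pytest.raises(ChannelUnregistrableError):
            cr.register(two_cluster["sample"], t, cfg)

    def test_capture_records_every_iteration(self, two_cluster):
        captured = []
        cfg = RegistrationConfig(schedule=[("icr", 0.5), ("icr", 1.0)])
        cr.register(two_cluster["sample"], two_cluster["template"], cfg, capture=captured)
        assert [(m, f) for m, f, _ in captured] == [("icr", 0.5), ("icr", 1.0)]
        assert all(v.vectors.shape == (2, 2) for _, _, v in captured)

    def test_log_serializes_to_json(self, two_cluster, tmp_path):
        import json

        _, log = cr.register(two_cluster["sample"], two_cluster["template"])
        text = log.to_json(tmp_path / "log.json")
        data = json.loads(text)
        # 4 scheduled iterations + final evaluation entry
        assert len(data["iterations"]) == 5
        assert data["iterations"][-1]["method"] == "final"
        assert set(data["iterations"][0]["rmse_per_channel"]) == {"CD3", "CD4"}

    def test_partial_updates_converge_too(self, mixture10):
        shifted = shifted_copy(mixture10["test"], 1, 0.4)
        reg, log = cr.register(shifted, mixture10["template"], RegistrationConfig.partial())
        assert log.final_rmse < 0.1
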