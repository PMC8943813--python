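"""Distance datasets, histograms, mixture deconvolution, statistics."""

import itertools

import numpy as np
import pytest

from chromatinmc.chain import build_chain, initial_configuration
from chromatinmc.distances import (
    DistanceDataset,
    Histogram,
    MarkerPair,
    apply_cutoff,
    fit_mixture,
    histogram,
    marker_distance,
    max_extension,
    project_omit_z,
    random_projection_2d,
    rank_sum_compare,
    read_distance_table,
    rmse_hist,
    summary_stats,
    write_distance_table,
)


class TestMarkerDistance:
    def test_same_anchor_zero(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        # anchors at the same joint map to distance 0
        pair = MarkerPair(100, 101)
        assert marker_distance(cfg, topo, pair) < topo.seg_len0.max()

    def test_straight_chain_contour_distance(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        pair = MarkerPair(50, 929)  # first footprint start to last footprint end
        ja = topo.joint_index_for_bp(50)
        jb = topo.joint_index_for_bp(929)
        expected = topo.seg_len0[ja:jb].sum()
        assert marker_distance(cfg, topo, pair) == pytest.approx(expected)

    def test_rotation_invariance(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "random_walk", seed=1)
        pair = MarkerPair(100, 800)
        d0 = marker_distance(cfg, topo, pair)
        R = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
        cfg.pos[:] = cfg.pos @ R.T
        assert marker_distance(cfg, topo, pair) == pytest.approx(d0)

    def test_anchor_outside_interval(self, small_set):
        topo = build_chain(small_set)
        cfg = initial_configuration(topo, "straight")
        with pytest.raises(ValueError):
            marker_distance(cfg, topo, MarkerPair(100, 5000))


class TestMaxExtension:
    def test_5kb_is_243nm(self):
        assert max_extension(5000) == pytest.approx(5000 * 0.34 / 7)
        assert round(max_extension(5000)) == 243

    def test_7bp(self):
        assert max_extension(7) == pytest.approx(0.34)

    def test_zero_span_error(self):
        with pytest.raises(ValueError):
            max_extension(0)


class TestApplyCutoff:
    def test_all_below_unchanged(self):
        ds = DistanceDataset(np.array([10.0, 20.0]))
        out, n = apply_cutoff(ds, 250.0)
        assert n == 0 and len(out) == 2

    def test_filtering_and_count(self):
        ds = DistanceDataset(np.array([240.0, 260.0]))
        out, n = apply_cutoff(ds, 250.0)
        np.testing.assert_array_equal(out.distances, [240.0])
        assert n == 1

    def test_idempotent(self):
        ds = DistanceDataset(np.array([100.0, 300.0]), span_bp=5000)
        once, _ = apply_cutoff(ds)
        twice, n2 = apply_cutoff(once)
        assert n2 == 0
        np.testing.assert_array_equal(once.distances, twice.distances)


class TestProjection:
    def test_z_only_difference_projects_to_zero(self):
        a = np.array([[0.0, 1.0, 2.0]])
        b = np.array([[9.0, 1.0, 2.0]])
        assert project_omit_z(a, b)[0] == 0.0

    def test_no_z_difference_equal(self):
        a = np.array([[5.0, 0.0, 0.0]])
        b = np.array([[5.0, 3.0, 4.0]])
        assert project_omit_z(a, b)[0] == pytest.approx(5.0)

    def test_projection_inequality(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(500, 3))
        b = rng.normal(size=(500, 3))
        d2 = project_omit_z(a, b)
        d3 = np.linalg.norm(a - b, axis=1)
        assert np.all(d2 <= d3 + 1e-12)
        assert d2.mean() < d3.mean()

    def test_random_projection_mode(self):
        ds = DistanceDataset(np.full(2000, 100.0))
        out = random_projection_2d(ds, seed=0)
        assert out.dimensionality == "2D"
        assert np.all(out.distances <= 100.0 + 1e-9)
        # E[sin theta] = pi/4 for uniform-sphere polar angle
        assert out.distances.mean() == pytest.approx(100 * np.pi / 4, rel=0.02)


class TestHistogram:
    def test_point_mass_density(self):
        ds = DistanceDataset(np.full(50, 25.0))
        h = histogram(ds, bin_width=10.0, range_nm=(0, 100))
        assert h.density[2] == pytest.approx(1.0 / 10.0)
        assert h.integral == pytest.approx(1.0, abs=1e-9)

    def test_integral_normalized(self):
        rng = np.random.default_rng(1)
        ds = DistanceDataset(rng.uniform(0, 200, 1000))
        h = histogram(ds, bin_width=10.0, range_nm=(0, 200))
        assert h.integral == pytest.approx(1.0, abs=1e-9)

    def test_refining_preserves_integral(self):
        rng = np.random.default_rng(2)
        ds = DistanceDataset(rng.uniform(0, 200, 1000))
        coarse = histogram(ds, bin_width=20.0, range_nm=(0, 200))
        fine = histogram(ds, bin_width=5.0, range_nm=(0, 200))
        assert coarse.integral == pytest.approx(fine.integral, abs=1e-9)

    def test_binning_mismatch_rejected(self):
        h1 = Histogram(np.arange(5.0), np.ones(4) / 4)
        h2 = Histogram(np.arange(6.0), np.ones(5) / 5)
        with pytest.raises(ValueError, match="binning"):
            rmse_hist(h1, h2)


class TestMixtureFit:
    def _sampled_hists(self, seed=0, n=10_000):
        rng = np.random.default_rng(seed)
        edges = np.arange(0.0, 260.0, 10.0)
        comps = []
        for med, sig in [(50, 0.3), (110, 0.25), (180, 0.15)]:
            d = DistanceDataset(rng.lognormal(np.log(med), sig, n))
            comps.append(histogram(d, edges=edges))
        return edges, comps

    def test_identity_component(self):
        edges, comps = self._sampled_hists()
        fit = fit_mixture(comps[0], [comps[0]])
        assert fit.weights[0] == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_known_half_half_combination(self):
        edges, comps = self._sampled_hists()
        target = Histogram(edges, 0.5 * comps[0].density + 0.5 * comps[1].density)
        fit = fit_mixture(target, comps[:2])
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-6)

    def test_matches_grid_search(self):
        """QP solution equals an exhaustive 0.01-resolution grid minimum."""
        edges, comps = self._sampled_hists(seed=3)
        target = Histogram(
            edges,
            0.2 * comps[0].density + 0.5 * comps[1].density + 0.3 * comps[2].density,
        )
        fit = fit_mixture(target, comps)
        A = np.stack([c.density for c in comps], axis=1)
        best, best_sse = None, np.inf
        for w0, w1 in itertools.product(np.arange(0, 1.01, 0.01), repeat=2):
            w2 = 1.0 - w0 - w1
            if w2 < -1e-12:
                continue
            w = np.array([w0, w1, max(w2, 0.0)])
            sse = np.sum((A @ w - target.density) ** 2)
            if sse < best_sse:
                best, best_sse = w, sse
        np.testing.assert_allclose(fit.weights, best, atol=0.011)

    def test_degenerate_component_rejected(self):
        edges = np.arange(0.0, 50.0, 10.0)
        good = Histogram(edges, np.ones(4) / 40.0)
        zero = Histogram(edges, np.zeros(4))
        with pytest.raises(ValueError, match="zero"):
            fit_mixture(good, [good, zero])


class TestRmse:
    def test_identical_zero(self):
        h = Histogram(np.arange(4.0), np.array([0.2, 0.5, 0.3]))
        assert rmse_hist(h, h) == 0.0

    def test_hand_computed(self):
        e = np.arange(4.0)
        a = Histogram(e, np.array([0.2, 0.5, 0.3]))
        b = Histogram(e, np.array([0.3, 0.4, 0.3]))
        assert rmse_hist(a, b) == pytest.approx(np.sqrt((0.01 + 0.01 + 0) / 3))
        assert rmse_hist(a, b) == rmse_hist(b, a)


class TestSummaryStats:
    def test_basic(self):
        s = summary_stats(DistanceDataset(np.array([1.0, 2.0, 3.0])))
        assert s["median"] == 2.0 and s["mean"] == 2.0 and s["n"] == 3

    def test_constant_sd_zero(self):
        s = summary_stats(DistanceDataset(np.full(10, 7.0)))
        assert s["sd"] == 0.0

    def test_lognormal_moments(self):
        mu, sig, n = np.log(100), 0.4, 20_000
        rng = np.random.default_rng(6)
        d = rng.lognormal(mu, sig, n)
        s = summary_stats(DistanceDataset(d))
        mean_exact = np.exp(mu + sig**2 / 2)
        sd_exact = mean_exact * np.sqrt(np.exp(sig**2) - 1)
        assert abs(s["mean"] - mean_exact) < 3 * sd_exact / np.sqrt(n)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summary_stats(DistanceDataset(np.zeros(0)))


class TestRankSum:
    def test_identical_samples(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100, 10, 200)
        _, p = rank_sum_compare(DistanceDataset(np.abs(x)), DistanceDataset(np.abs(x)))
        assert p > 0.9

    def test_disjoint_support(self):
        a = DistanceDataset(np.linspace(1, 50, 100))
        b = DistanceDataset(np.linspace(100, 150, 100))
        _, p = rank_sum_compare(a, b)
        assert p < 1e-10

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(4, 0.3, 150)
        b = rng.lognormal(4.2, 0.3, 150)
        s1, p1 = rank_sum_compare(DistanceDataset(a), DistanceDataset(b))
        s2, p2 = rank_sum_compare(DistanceDataset(np.sqrt(a)), DistanceDataset(np.sqrt(b)))
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)


class TestTableIO:
    def test_roundtrip(self, tmp_path):
        ds = DistanceDataset(np.array([10.0, 20.0, 30.0]), "2D")
        path = tmp_path / "d.tsv"
        write_distance_table(ds, path, pair_label="AB")
        back = read_distance_table(path)
        np.testing.assert_allclose(back.distances, ds.distances)
        assert back.dimensionality == "2D"
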