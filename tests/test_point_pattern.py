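import math

import numpy as np
import pytest
from scipy import stats

from deadwood.point_pattern import (
    classify_pattern,
    csr_envelope,
    default_r_grid,
    pcf_estimate,
    simulate_csr,
    summarize_runs,
    PCFEnvelope,
    PCFEstimate,
)
from deadwood.stand_io import PlotWindow, StandError


def brute_force_pcf(pts, window, r_grid, h, correction):
    """Naive O(n^2) double-loop estimator, scalar arithmetic throughout."""

    def circle_fraction(x, y, r):
        d_edges = [x - window.x_min, window.x_max - x, y - window.y_min,
                   window.y_max - y]
        ac = [math.acos(min(max(d / r, -1.0), 1.0)) for d in d_edges]
        exterior = 2.0 * sum(ac)
        for a1, a2 in ((ac[0], ac[2]), (ac[2], ac[1]), (ac[1], ac[3]),
                       (ac[3], ac[0])):
            exterior -= max(0.0, a1 + a2 - math.pi / 2.0)
        return 1.0 - exterior / (2.0 * math.pi)

    n = len(pts)
    area = window.area
    lam = n / area
    out = []
    for r in r_grid:
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                u = (r - d) / h
                if abs(u) >= 1.0:
                    continue
                kern = 0.75 * (1.0 - u * u) / h
                if correction == "isotropic":
                    e = 1.0 / circle_fraction(pts[i][0], pts[i][1], d)
                else:
                    e = area / (
                        (window.width - abs(pts[i][0] - pts[j][0]))
                        * (window.height - abs(pts[i][1] - pts[j][1]))
                    )
                total += kern * e
        out.append(total / (2.0 * math.pi * r * lam * lam * area))
    return np.array(out)


class TestPCFEstimate:
    @pytest.mark.parametrize("correction", ["isotropic", "translation"])
    def test_matches_brute_force_oracle(self, window, correction):
        pts = simulate_csr(50, window, np.random.default_rng(3))
        r_grid = np.arange(1.0, 30.1, 1.0)
        est = pcf_estimate(pts, window, r_grid, bandwidth=2.0, correction=correction)
        oracle = brute_force_pcf(pts, window, r_grid, 2.0, correction)
        assert np.max(np.abs(est.g_hat - oracle)) < 1e-10

    def test_csr_pattern_hovers_at_one(self, window):
        pts = simulate_csr(500, window, np.random.default_rng(11))
        est = pcf_estimate(pts, window, np.arange(2.0, 30.1, 0.5))
        assert abs(est.g_hat.mean() - 1.0) < 0.1

    def test_two_points_peak_at_their_distance(self, window):
        pts = [(40.0, 40.0), (45.0, 40.0)]
        r_grid = np.arange(1.0, 30.1, 0.5)
        est = pcf_estimate(pts, window, r_grid, bandwidth=2.0)
        # the 1/r factor skews the kernel bump slightly below the pair distance
        assert abs(r_grid[np.argmax(est.g_hat)] - 5.0) <= 0.5

    def test_corrections_agree_away_from_edges(self, window):
        pts = simulate_csr(400, window, np.random.default_rng(7))
        r_grid = np.arange(2.0, 10.1, 0.5)
        iso = pcf_estimate(pts, window, r_grid, correction="isotropic").g_hat
        tra = pcf_estimate(pts, window, r_grid, correction="translation").g_hat
        assert np.max(np.abs(iso - tra)) < 0.1

    def test_input_validation(self, window):
        with pytest.raises(StandError, match="at least 2"):
            pcf_estimate([(1, 1)], window, [5.0])
        with pytest.raises(StandError, match="half the short"):
            pcf_estimate([(1, 1), (2, 2)], window, [50.0])
        with pytest.raises(StandError, match="increasing"):
            pcf_estimate([(1, 1), (2, 2)], window, [5.0, 5.0])


class TestSimulateCSR:
    def test_zero_points(self, window):
        assert simulate_csr(0, window, np.random.default_rng(0)).shape == (0, 2)

    def test_uniform_moments(self, window):
        pts = simulate_csr(10_000, window, np.random.default_rng(1))
        se_x = 100 / math.sqrt(12) / math.sqrt(10_000)
        assert abs(pts[:, 0].mean() - 50.0) < 4 * se_x
        assert abs(pts[:, 1].mean() - 40.0) < 4 * (80 / math.sqrt(12) / 100)

    def test_quadrat_test_type_one_error_calibrated(self):
        """A 4x4 quadrat chi^2 test should reject CSR in ~5% of seeds."""
        window = PlotWindow(0, 0, 80, 80)
        rejections = 0
        for seed in range(200):
            pts = simulate_csr(160, window, np.random.default_rng(seed))
            counts, _, _ = np.histogram2d(
                pts[:, 0], pts[:, 1], bins=4, range=[[0, 80], [0, 80]]
            )
            p = stats.chisquare(counts.ravel()).pvalue
            rejections += p < 0.05
        assert rejections <= 20  # ~5% expected; 10% is a generous 200-seed bound


class TestEnvelope:
    def test_lower_never_exceeds_upper(self, window):
        pts = simulate_csr(100, window, np.random.default_rng(2))
        _, env = csr_envelope(pts, window, np.arange(2, 30.1, 1.0), n_sim=99,
                              rng=np.random.default_rng(5))
        assert np.all(env.lower <= env.upper)

    def test_pointwise_coverage_near_95_percent(self, window):
        """Fresh CSR estimates fall inside a fixed CSR envelope ~95% of the time."""
        r_grid = np.arange(2.0, 30.1, 0.5)
        _, env = csr_envelope(
            simulate_csr(300, window, np.random.default_rng(1)),
            window, r_grid, n_sim=199, rng=np.random.default_rng(2),
        )
        inside = []
        for s in range(60):
            g = pcf_estimate(
                simulate_csr(300, window, np.random.default_rng(1000 + s)),
                window, r_grid,
            ).g_hat
            inside.append(((g >= env.lower) & (g <= env.upper)).mean())
        assert 0.92 < np.mean(inside) < 0.98

    def test_csr_pattern_labelled_mostly_random(self, window):
        pts = simulate_csr(300, window, np.random.default_rng(5))
        _, env = csr_envelope(pts, window, np.arange(2, 30.1, 0.5), n_sim=199,
                              rng=np.random.default_rng(42))
        assert np.mean(env.labels == "random") > 0.8

    def test_thomas_cluster_process_labelled_clustered_at_small_r(self, window):
        rng = np.random.default_rng(21)
        parents = rng.random((rng.poisson(0.002 * window.area), 2)) * [100, 80]
        pts = []
        for p in parents:
            off = p + rng.normal(0, 1.0, (rng.poisson(10), 2))
            keep = (off[:, 0] > 0) & (off[:, 0] < 100) & (off[:, 1] > 0) & (off[:, 1] < 80)
            pts.append(off[keep])
        pts = np.vstack(pts)
        r_grid = np.arange(1.0, 30.1, 0.25)
        _, env = csr_envelope(pts, window, r_grid, n_sim=99,
                              rng=np.random.default_rng(9))
        assert np.all(env.labels[r_grid <= 3.0] == "clustered")

    def test_too_few_simulations_warns(self, window):
        pts = simulate_csr(50, window, np.random.default_rng(3))
        with pytest.warns(UserWarning, match="coarse"):
            csr_envelope(pts, window, [5.0, 6.0], n_sim=19,
                         rng=np.random.default_rng(0))


class TestClassifyPattern:
    def _pair(self, g_hat, lower, upper, r=None):
        r = np.asarray(r if r is not None else np.arange(1.0, 1.0 + len(g_hat)))
        est = PCFEstimate(r_grid=r, g_hat=np.asarray(g_hat, float), bandwidth=1.0,
                          correction="isotropic", intensity=0.1)
        env = PCFEnvelope(r_grid=r, lower=np.asarray(lower, float),
                          upper=np.asarray(upper, float), n_sim=999,
                          labels=np.array([]))
        return est, env

    def test_midpoint_curve_is_all_random(self):
        est, env = self._pair([1, 1, 1], [0.5] * 3, [1.5] * 3)
        labels, runs = classify_pattern(est, env)
        assert all(labels == "random") and len(runs) == 1

    def test_excursion_interval_reported(self):
        r = np.arange(1.0, 6.0)  # 1..5
        g = [2.0, 2.0, 2.0, 1.0, 1.0]
        est, env = self._pair(g, [0.5] * 5, [1.5] * 5, r)
        labels, runs = classify_pattern(est, env)
        assert runs[0] == {"label": "clustered", "r_from": 1.0, "r_to": 3.0}
        assert "clustered 1-3 m" in summarize_runs(runs)

    def test_labels_match_independent_comparison_oracle(self, window):
        rng = np.random.default_rng(17)
        g = rng.uniform(0, 2, 40)
        lo = rng.uniform(0.4, 0.8, 40)
        hi = lo + rng.uniform(0.1, 0.8, 40)
        est, env = self._pair(g, lo, hi, np.arange(1.0, 41.0))
        labels, _ = classify_pattern(est, env)
        for k in range(40):
            if g[k] > hi[k]:
                assert labels[k] == "clustered"
            elif g[k] < lo[k]:
                assert labels[k] == "regular"
            else:
                assert labels[k] == "random"

    def test_grid_mismatch_raises(self):
        est, env = self._pair([1.0, 1.0], [0.5, 0.5], [1.5, 1.5])
        env.r_grid = env.r_grid + 0.5
        with pytest.raises(StandError, match="grid"):
            classify_pattern(est, env)


def test_default_r_grid_respects_half_short_side(window):
    grid = default_r_grid(window, r_step=0.25, bandwidth=1.2)
    assert grid[0] == pytest.approx(1.2)
    assert grid[-1] <= 40.0
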