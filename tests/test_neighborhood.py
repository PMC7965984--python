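import math

import numpy as np
import pytest

from deadwood.neighborhood import (
    StructureUnit,
    build_units,
    dominance,
    group_means,
    mingling,
    uniform_angle,
)
from deadwood.point_pattern import simulate_csr
from deadwood.stand_io import PlotWindow, StandError
from conftest import make_map


def unit_from_azimuths(azimuths_deg, ref_species="a", neighbor_species=None,
                       ref_dbh=10.0, neighbor_dbh=None, distances=None):
    n = len(azimuths_deg)
    return StructureUnit(
        ref_id="ref",
        neighbor_ids=[f"n{i}" for i in range(n)],
        distances=np.asarray(distances if distances is not None else [1.0] * n),
        azimuths=np.deg2rad(azimuths_deg),
        ref_species=ref_species,
        ref_dbh=ref_dbh,
        neighbor_species=neighbor_species or ["a"] * n,
        neighbor_dbh=neighbor_dbh or [10.0] * n,
    )


class TestBuildUnits:
    def test_five_stems_reference_gets_other_four(self):
        m = make_map([(50, 40), (48, 40), (52, 40), (50, 38), (50, 42)])
        units = build_units(m, buffer_width=5.0)
        by_ref = {u.ref_id: u for u in units}
        assert sorted(by_ref["s00000"].neighbor_ids) == [
            "s00001", "s00002", "s00003", "s00004"]

    def test_buffer_stem_emits_no_unit_but_serves_as_neighbor(self):
        coords = [(3, 40), (10, 40), (11, 41), (12, 39), (13, 40)]
        m = make_map(coords)
        units = build_units(m, buffer_width=5.0)
        refs = {u.ref_id for u in units}
        assert "s00000" not in refs  # 3 m from edge -> buffer
        assert any("s00000" in u.neighbor_ids for u in units)

    def test_neighbors_match_brute_force_sort(self):
        rng = np.random.default_rng(15)
        pts = rng.random((200, 2)) * [100, 80]
        m = make_map(pts)
        units = build_units(m, buffer_width=5.0)
        stems = sorted(m.stems, key=lambda s: s.id)
        for u in units[::7]:
            ref = m.by_id(u.ref_id)
            ranked = sorted(
                ((math.hypot(s.x - ref.x, s.y - ref.y), s.id)
                 for s in stems if s.id != ref.id),
            )
            assert u.neighbor_ids == [sid for _, sid in ranked[:4]]

    def test_too_small_pool_raises(self):
        m = make_map([(1, 1), (2, 2), (3, 3)])
        with pytest.raises(StandError, match="at least 5"):
            build_units(m)


class TestUniformAngle:
    def test_perfect_cross_is_fully_uniform(self):
        assert uniform_angle(unit_from_azimuths([0, 90, 180, 270])) == 0.0

    def test_tight_fan_scores_three_quarters(self):
        # gaps 10, 10, 10, 330 degrees -> three below 72
        assert uniform_angle(unit_from_azimuths([0, 10, 20, 30])) == 0.75

    def test_gap_equal_to_standard_angle_not_counted(self):
        # gaps 72, 72, 72, 144: none strictly below the standard angle
        assert uniform_angle(unit_from_azimuths([0, 72, 144, 216]), 72.0) == 0.0
        # gaps 71, 71, 71, 147: three strictly below
        assert uniform_angle(unit_from_azimuths([0, 71, 142, 213]), 72.0) == 0.75

    def test_coincident_neighbor_raises(self):
        u = unit_from_azimuths([0, 90, 180, 270], distances=[0.0, 1, 1, 1])
        with pytest.raises(StandError, match="coincide"):
            uniform_angle(u)


class TestMinglingDominance:
    def test_mingling_fractions(self):
        assert mingling(unit_from_azimuths([0, 90, 180, 270])) == 0.0
        u = unit_from_azimuths([0, 90, 180, 270],
                               neighbor_species=["a", "a", "b", "b"])
        assert mingling(u) == 0.5

    def test_dominance_strict_inequality_on_ties(self):
        u = unit_from_azimuths([0, 90, 180, 270], ref_dbh=10.0,
                               neighbor_dbh=[12.0, 8.0, 10.0, 15.0])
        assert dominance(u) == 0.5

    def test_dominant_reference_scores_zero(self):
        u = unit_from_azimuths([0, 90, 180, 270], ref_dbh=30.0,
                               neighbor_dbh=[12.0, 8.0, 10.0, 15.0])
        assert dominance(u) == 0.0

    def test_missing_dbh_raises(self):
        u = unit_from_azimuths([0, 90, 180, 270], ref_dbh=None)
        with pytest.raises(StandError, match="DBH"):
            dominance(u)

    def test_iid_continuous_dbh_gives_mean_half(self):
        rng = np.random.default_rng(23)
        pts = simulate_csr(1500, PlotWindow(0, 0, 100, 80), rng)
        m = make_map(pts, dbh=list(rng.lognormal(2.5, 0.4, 1500)))
        units = build_units(m, buffer_width=5.0)
        u_vals = [dominance(u) for u in units]
        # exchangeability: each neighbor is larger with probability 1/2
        assert abs(np.mean(u_vals) - 0.5) < 0.02


class TestGroupMeans:
    def test_single_species_stand_has_zero_mingling(self):
        rng = np.random.default_rng(3)
        m = make_map(simulate_csr(400, PlotWindow(0, 0, 100, 80), rng))
        summary = group_means(m)
        assert (summary.means["mean_M"] == 0.0).all()

    def test_suppressed_deadwood_has_full_dominance(self):
        rng = np.random.default_rng(4)
        pts = simulate_csr(300, PlotWindow(0, 0, 100, 80), rng)
        status = ["snag" if i % 10 == 0 else "live_planted" for i in range(300)]
        dbh = [2.0 if s == "snag" else 40.0 for s in status]
        m = make_map(pts, status=status, dbh=dbh)
        # live-only neighbor pool: every snag is ringed by giant live trees
        summary = group_means(m, neighbor_pool=("live_planted", "live_lcp"))
        means = summary.means.set_index("group")
        assert means.loc["snag", "mean_U"] == 1.0
        assert 0.0 <= means.loc["live_planted", "mean_U"] < 0.2

    def test_csr_two_species_stand_matches_expectations(self):
        """Random pattern: mean W in the published random interval; mean M of
        the focal species near the heterospecific share."""
        rng = np.random.default_rng(31)
        vals = []
        m_vals = []
        for seed in range(3):
            pts = simulate_csr(2000, PlotWindow(0, 0, 100, 80),
                               np.random.default_rng(500 + seed))
            labels = np.where(np.random.default_rng(600 + seed).random(2000) < 0.7,
                              "chinese_fir", "schima")
            m = make_map(pts, species=list(labels),
                         dbh=list(rng.lognormal(2.5, 0.3, 2000)))
            summary = group_means(m)
            vals.append(summary.per_tree["W"].to_numpy())
            focal = summary.per_tree.merge(
                m.to_frame()[["id", "species"]], on="id")
            m_vals.append(
                focal.loc[focal["species"] == "chinese_fir", "M"].to_numpy())
        grand_w = np.concatenate(vals).mean()
        assert 0.475 < grand_w < 0.517
        grand_m = np.concatenate(m_vals).mean()
        assert abs(grand_m - 0.3) < 0.03

    def test_indices_invariant_under_translation(self):
        rng = np.random.default_rng(9)
        pts = rng.random((150, 2)) * [60, 60] + [20, 10]
        dbh = list(rng.lognormal(2.4, 0.3, 150))
        m1 = make_map(pts, dbh=dbh)
        m2 = make_map(pts + [5.0, -3.0], dbh=dbh)
        s1 = group_means(m1, buffer_width=0.0).per_tree
        s2 = group_means(m2, buffer_width=0.0).per_tree
        for col in ("W", "M", "U"):
            np.testing.assert_allclose(s1[col], s2[col])

    def test_indices_invariant_under_rotation(self):
        rng = np.random.default_rng(10)
        pts = rng.random((150, 2)) * [60, 60]
        dbh = list(rng.lognormal(2.4, 0.3, 150))
        win = PlotWindow(0, 0, 60, 60)
        rotated = np.column_stack([pts[:, 1], 60 - pts[:, 0]])  # 90 degrees
        s1 = group_means(make_map(pts, window=win, dbh=dbh),
                         buffer_width=0.0).per_tree
        s2 = group_means(make_map(rotated, window=win, dbh=dbh),
                         buffer_width=0.0).per_tree
        for col in ("W", "M", "U"):
            np.testing.assert_allclose(s1[col], s2[col])

    def test_per_tree_values_live_on_the_quarter_grid(self):
        rng = np.random.default_rng(13)
        m = make_map(simulate_csr(300, PlotWindow(0, 0, 100, 80), rng),
                     dbh=list(rng.lognormal(2.5, 0.3, 300)))
        per_tree = group_means(m).per_tree
        allowed = {0.0, 0.25, 0.5, 0.75, 1.0}
        for col in ("W", "M", "U"):
            assert set(per_tree[col].unique()) <= allowed
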