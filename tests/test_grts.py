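import numpy as np
import pytest
from scipy.spatial import cKDTree

from potholeveg.grts import (
    FramePoint,
    GRTSError,
    SelectionDraw,
    SiteFrame,
    StratumConfig,
    grts_draw,
    hierarchical_address,
    read_site_frame,
    replace_site,
    reverse_hierarchical_order,
    write_draw,
)
from potholeveg.synthetic import generate_site_frame

BBOX = (0.0, 0.0, 16.0, 16.0)


class TestHierarchicalAddress:
    def test_identity_permutation_repeated_quadrant(self):
        # point always in the SW quadrant of every subdivision
        assert hierarchical_address((0.1, 0.1), (0, 0, 8, 8), 3, seed=None) == "000"
        # NE quadrant at every level (center-offset upward): 3 repeated
        assert hierarchical_address((7.9, 7.9), (0, 0, 8, 8), 3, seed=None) == "333"

    def test_points_in_different_quadrants_differ_in_first_digit(self):
        a = hierarchical_address((1, 1), BBOX, 4, seed=7)
        b = hierarchical_address((15, 15), BBOX, 4, seed=7)
        assert a[0] != b[0]

    def test_grid_addresses_unique_at_matching_depth(self):
        pts = [(x + 0.5, y + 0.5) for x in range(16) for y in range(16)]
        addrs = [hierarchical_address(p, BBOX, 4, seed=3) for p in pts]
        assert len(set(addrs)) == 256

    def test_point_outside_bbox_rejected(self):
        with pytest.raises(GRTSError):
            hierarchical_address((20, 1), BBOX, 3, seed=0)


class TestReverseHierarchicalOrder:
    def test_prefixes_spread_over_level_cells(self):
        # positions sorted by address put position i in coarse cell i // 4;
        # any prefix of length k must cover min(k, 4) of those cells
        order = reverse_hierarchical_order(16)
        for k in (2, 3, 4, 8):
            coarse = {i // 4 for i in order[:k]}
            assert len(coarse) == min(k, 4)

    def test_is_a_permutation(self):
        for n in (1, 5, 16, 50):
            order = reverse_hierarchical_order(n)
            assert sorted(order) == list(range(n))


def _draw_ids(draw: SelectionDraw) -> list[str]:
    return [s.site_id for s in draw.sites]


class TestDraw:
    def test_exhaustive_draw_selects_everything_as_primary(self):
        frame = generate_site_frame(30, {"a": 1.0}, seed=1)
        draw = grts_draw(frame, StratumConfig({"a": (30, 0)}, seed=2))
        assert len(draw.primaries()) == 30
        assert not draw.alternates()

    def test_250_site_stratified_draw(self):
        frame = generate_site_frame(400, {"a": 0.25, "b": 0.25,
                                          "c": 0.25, "d": 0.25}, seed=3)
        cfg = StratumConfig(
            {"a": (50, 13), "b": (50, 13), "c": (50, 12), "d": (50, 12)}, seed=5
        )
        draw = grts_draw(frame, cfg)
        assert len(draw.sites) == 250
        assert len(draw.primaries()) == 200
        assert len(draw.alternates()) == 50
        assert len(set(_draw_ids(draw))) == 250

    def test_deterministic_under_seed(self):
        frame = generate_site_frame(200, {"a": 0.5, "b": 0.5}, seed=2)
        cfg = StratumConfig({"a": (20, 5), "b": (20, 5)}, seed=4)
        assert _draw_ids(grts_draw(frame, cfg)) == _draw_ids(grts_draw(frame, cfg))

    def test_different_seeds_differ(self):
        frame = generate_site_frame(200, {"a": 1.0}, seed=2)
        d1 = grts_draw(frame, StratumConfig({"a": (20, 5)}, seed=1))
        d2 = grts_draw(frame, StratumConfig({"a": (20, 5)}, seed=2))
        assert _draw_ids(d1) != _draw_ids(d2)

    def test_infeasible_config_names_stratum(self):
        frame = generate_site_frame(20, {"a": 1.0}, seed=2)
        with pytest.raises(GRTSError, match="'a'"):
            grts_draw(frame, StratumConfig({"a": (20, 5)}, seed=1))


class TestReplacement:
    def _study_draw(self):
        frame = generate_site_frame(400, {"a": 0.25, "b": 0.25,
                                          "c": 0.25, "d": 0.25}, seed=3)
        cfg = StratumConfig(
            {"a": (50, 13), "b": (50, 13), "c": (50, 12), "d": (50, 12)}, seed=5
        )
        return grts_draw(frame, cfg)

    def test_single_replacement_conserves_primary_count(self):
        draw = self._study_draw()
        victim = draw.primaries()[0].site_id
        replace_site(draw, victim, "inaccessible")
        assert len(draw.primaries()) == 200
        assert len(draw.replacement_log) == 1
        assert draw.get(victim).replaced_by is not None

    def test_24_replacements_leave_26_alternates(self):
        draw = self._study_draw()
        for stratum in ("a", "b", "c", "d"):
            victims = [p for p in draw.primaries() if p.stratum == stratum][:6]
            for v in victims:
                replace_site(draw, v.site_id, "misclassified")
        assert len(draw.replacement_log) == 24
        assert len(draw.primaries()) == 200
        assert len(draw.alternates()) == 26

    def test_replacement_stays_in_stratum(self):
        draw = self._study_draw()
        victim = [p for p in draw.primaries() if p.stratum == "b"][0]
        replace_site(draw, victim.site_id)
        old, new, _ = draw.replacement_log[-1]
        assert draw.get(new).stratum == "b"

    def test_exhausted_alternates_error(self):
        frame = generate_site_frame(30, {"a": 1.0}, seed=1)
        draw = grts_draw(frame, StratumConfig({"a": (5, 1)}, seed=2))
        replace_site(draw, draw.primaries()[0].site_id)
        with pytest.raises(GRTSError, match="no alternates"):
            replace_site(draw, draw.primaries()[0].site_id)

    def test_non_primary_rejected(self):
        draw = self._study_draw()
        alt = draw.alternates()[0]
        with pytest.raises(GRTSError):
            replace_site(draw, alt.site_id)


def _voronoi_occupancy_variance(frame_xy, sample_xy):
    """Variance of frame-point counts over the sample's Voronoi cells."""
    _, idx = cKDTree(sample_xy).query(frame_xy)
    return np.bincount(idx, minlength=len(sample_xy)).var()


class TestSpatialBalance:
    def test_grts_beats_srs_on_voronoi_occupancy(self):
        """Mean Voronoi-cell-count variance over seeded replicates is lower
        for the spatially balanced draws than for simple random samples."""
        n_frame, n_samp, reps = 1000, 50, 100
        grts_var, srs_var = [], []
        for rep in range(reps):
            frame = generate_site_frame(n_frame, {"all": 1.0}, seed=rep)
            xy = np.array([(p.x, p.y) for p in frame.points])
            draw = grts_draw(frame, StratumConfig({"all": (n_samp, 0)}, seed=rep))
            sel = {s.site_id for s in draw.primaries()}
            sxy = np.array([(p.x, p.y) for p in frame.points if p.site_id in sel])
            grts_var.append(_voronoi_occupancy_variance(xy, sxy))
            rng = np.random.default_rng(10_000 + rep)
            srs = xy[rng.choice(n_frame, n_samp, replace=False)]
            srs_var.append(_voronoi_occupancy_variance(xy, srs))
        assert np.mean(grts_var) < np.mean(srs_var)

    def test_primary_prefix_is_balanced(self):
        """The first half of the ordered primaries spreads over quadrants."""
        frame = generate_site_frame(1000, {"all": 1.0}, seed=42,
                                    bbox=(0, 0, 100, 100))
        draw = grts_draw(frame, StratumConfig({"all": (40, 0)}, seed=42))
        ranked = sorted(draw.primaries(), key=lambda s: s.order_rank)[:20]
        pts = {p.site_id: p for p in frame.points}
        quads = [
            2 * (pts[s.site_id].y > 50) + (pts[s.site_id].x > 50) for s in ranked
        ]
        counts = np.bincount(quads, minlength=4)
        assert counts.min() >= 2  # no quadrant starved in the prefix


class TestFrameIO:
    def test_round_trip(self, tmp_path):
        frame = generate_site_frame(25, {"x": 0.4, "y": 0.6}, seed=9)
        from potholeveg.grts import write_frame

        p = tmp_path / "frame.csv"
        write_frame(frame, p)
        back = read_site_frame(p)
        assert [q.site_id for q in back.points] == [q.site_id for q in frame.points]

    def test_draw_output_schema(self, tmp_path):
        frame = generate_site_frame(30, {"a": 1.0}, seed=1)
        draw = grts_draw(frame, StratumConfig({"a": (10, 2)}, seed=2))
        p = tmp_path / "draw.csv"
        write_draw(draw, p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["site_id", "stratum", "order_rank", "role",
                                    "replaced_by"]
        assert len(df) == 12

    def test_duplicate_ids_rejected(self):
        pts = [FramePoint("a", 0, 0, "s"), FramePoint("a", 1, 1, "s")]
        with pytest.raises(GRTSError):
            SiteFrame(points=pts)
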