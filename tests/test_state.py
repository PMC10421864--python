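import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lucflux as lf
from lucflux.parameters import Category

F, S, P, U, W = 1, 2, 3, 4, 5


class TestDetectChange:
    def test_identical_maps_no_records(self):
        a = np.array([F, S, P])
        assert lf.detect_change(a, a, 214369.0) == []

    def test_single_conversion_area_in_ha(self):
        prev, cur = np.array([F, F]), np.array([P, F])
        recs = lf.detect_change(prev, cur, 214369.0, year=2005)
        assert len(recs) == 1
        r = recs[0]
        assert (r.cell, r.from_category, r.to_category) == (0, Category.FOREST,
                                                            Category.PLANTATION)
        assert r.ca_ha == pytest.approx(21.4369)

    def test_multiple_changes_enumerated(self):
        prev, cur = np.array([F, S, W]), np.array([U, S, F])
        recs = lf.detect_change(prev, cur, 1e4)
        assert [(r.cell, int(r.from_category), int(r.to_category)) for r in recs] == [
            (0, F, U), (2, W, F)]
        assert sum(r.ca_ha for r in recs) == pytest.approx(2 * 1.0)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            lf.detect_change(np.zeros(3), np.zeros(4), 1e4)


class TestFireCounting:
    def _fires(self, conf):
        return [lf.FireEvent(cell=0, year=2001, days=(100, 101, 102, 200),
                             confidence=conf)]

    def test_run_merging(self):
        counts = lf.count_fire_events(self._fires("high"), 2001, 3)
        assert counts[0] == 2  # {100,101,102} merge, {200} separate
        assert counts[1] == 0

    def test_confidence_regimes(self):
        low = self._fires("low")
        assert lf.count_fire_events(low, 2001, 1, regime="NCM")[0] == 0
        assert lf.count_fire_events(low, 2001, 1, regime="LCM")[0] == 2

    def test_ncm_subset_of_lcm_on_random_schedules(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fires = [
                lf.FireEvent(cell=int(rng.integers(0, 5)), year=2001,
                             days=tuple(sorted(set(rng.integers(1, 366, 3).tolist()))),
                             confidence=str(rng.choice(["low", "nominal", "high"])))
                for _ in range(rng.integers(1, 6))
            ]
            ncm = lf.count_fire_events(fires, 2001, 5, regime="NCM")
            lcm = lf.count_fire_events(fires, 2001, 5, regime="LCM")
            assert (ncm <= lcm).all()

    def test_history_cumulative_ordinals(self):
        fires = [
            lf.FireEvent(cell=0, year=2001, days=(10,), confidence="high"),
            lf.FireEvent(cell=0, year=2002, days=(10, 50), confidence="high"),
            lf.FireEvent(cell=0, year=2003, days=(10,), confidence="high"),
        ]
        fh = lf.fire_history(fires, [2001, 2002, 2003], 2)
        np.testing.assert_array_equal(fh.counts[0], [1, 2, 1])
        np.testing.assert_array_equal(fh.start_ordinal[0], [0, 1, 3])
        np.testing.assert_array_equal(fh.cumulative[0], [1, 3, 4])
        assert (fh.cumulative[0] == np.cumsum(fh.counts[0])).all()


class TestDrainage:
    def test_always_forest_peat_never_drained(self):
        maps = np.full((2, 5), F)
        peat = np.array([True, False])
        assert not lf.update_drainage(peat, maps).any()

    def test_drained_from_first_nonforest_year(self):
        maps = np.array([[F, F, P, F, F]])
        drained = lf.update_drainage(np.array([True]), maps)
        np.testing.assert_array_equal(drained[0], [False, False, True, True, True])

    def test_static_reading_drains_whole_period(self):
        maps = np.array([[F, F, P, F, F]])
        drained = lf.update_drainage(np.array([True]), maps, static=True)
        assert drained[0].all()

    def test_water_is_not_drainage(self):
        maps = np.array([[F, W, W, W, W]])
        assert not lf.update_drainage(np.array([True]), maps).any()

    def test_non_peat_never_drained(self):
        maps = np.array([[P, P, P]])
        assert not lf.update_drainage(np.array([False]), maps).any()


class TestBackcast:
    def test_linear_backcast(self):
        out = lf.backcast_agb(np.array([150.0]), 2010, 2000, np.array([F]),
                              {Category.FOREST: 3.0})
        assert out[0] == pytest.approx(120.0)

    def test_floored_at_zero(self):
        out = lf.backcast_agb(np.array([10.0]), 2010, 2000, np.array([F]),
                              {Category.FOREST: 3.0})
        assert out[0] == 0.0

    def test_zero_growth_unchanged(self):
        out = lf.backcast_agb(np.array([75.0]), 2010, 2000, np.array([W]),
                              {Category.WATER: 0.0})
        assert out[0] == pytest.approx(75.0)

    def test_missing_growth_rate_is_config_error(self):
        with pytest.raises(KeyError):
            lf.backcast_agb(np.array([75.0]), 2010, 2000, np.array([F]), {})


class TestAdvanceAgb:
    def _params(self, central, **over):
        return central

    def test_fire_depletion(self, central):
        p = central
        agb, pre = lf.advance_agb(np.array([100.0]), np.array([F]), np.array([F]),
                                  np.array([1]), p)
        g = p.growth[Category.FOREST]
        be = p.BE[Category.FOREST]
        assert pre[0] == pytest.approx(100.0 + g)
        assert agb[0] == pytest.approx((100.0 + g) * (1 - be))

    def test_growth_only(self, central):
        agb, _ = lf.advance_agb(np.array([100.0]), np.array([F]), np.array([F]),
                                np.array([0]), central)
        assert agb[0] == pytest.approx(100.0 + central.growth[Category.FOREST])

    def test_conversion_assigns_agb_post(self, central):
        agb, _ = lf.advance_agb(np.array([500.0]), np.array([F]),
                                np.array([P]), np.array([0]), central)
        assert agb[0] == central.AGB_post[Category.PLANTATION]

    def test_nan_rejected(self, central):
        with pytest.raises(ValueError):
            lf.advance_agb(np.array([np.nan]), np.array([F]), np.array([F]),
                           np.array([0]), central)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        agb0=st.floats(0, 500),
        events=st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5),
                                  st.integers(0, 3)), min_size=1, max_size=8),
    )
    def test_non_negative_under_random_event_sequences(self, central, agb0, events):
        """AGB stays >= 0 under arbitrary growth/fire/conversion sequences."""
        agb = np.array([agb0])
        for prev_cat, cur_cat, n_fires in events:
            agb, _ = lf.advance_agb(agb, np.array([prev_cat]),
                                    np.array([cur_cat]), np.array([n_fires]),
                                    central)
            assert agb[0] >= 0.0
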