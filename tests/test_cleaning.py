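"""Settlement-map cleaning: filtering, multipolygon resolution, decision log."""

import pandas as pd
import pytest
from shapely.geometry import box

from settlecarbon import cleaning, synth
from settlecarbon.cleaning import (Action, clean_settlements, filter_settlements,
                                   resolve_multipolygons)
from settlecarbon.geodata import area_ha

REGION = box(0, 0, 100_000, 100_000)


def _registry(ids, cat="PA"):
    return pd.DataFrame({
        "settlement_id": ids, "name": ids, "category": cat,
        "state": "Pará", "municipality": [f"mun_{i}" for i in ids],
        "creation_year": 2003, "families": 50,
        "reported_area_ha": 2500.0, "in_arc": False,
    })


def _layer(rows):
    return pd.DataFrame(rows)


class TestFilter:
    def test_inside_listed_allowed_is_kept(self):
        layer = _layer([{"settlement_id": "A", "category": "PA",
                         "municipality": "mun_A", "geometry": box(0, 0, 5000, 5000)}])
        kept, dec = filter_settlements(layer, _registry(["A"]), REGION)
        assert len(kept) == 1 and not dec

    def test_straddling_boundary_is_dropped(self):
        layer = _layer([{"settlement_id": "A", "category": "PA",
                         "municipality": "mun_A",
                         "geometry": box(99_000, 0, 101_000, 5000)}])
        kept, dec = filter_settlements(layer, _registry(["A"]), REGION)
        assert kept.empty
        assert dec[0].action == Action.DROPPED_OUTSIDE_REGION

    def test_non_settlement_category_is_dropped(self):
        layer = _layer([{"settlement_id": "U", "category": "conservation unit",
                         "municipality": "mun_U", "geometry": box(0, 0, 100, 100)}])
        kept, dec = filter_settlements(layer, _registry(["U"]), REGION)
        assert kept.empty
        assert dec[0].action == Action.DROPPED_NON_SETTLEMENT

    def test_unlisted_settlement_is_dropped(self):
        layer = _layer([{"settlement_id": "X", "category": "PA",
                         "municipality": "mun_X", "geometry": box(0, 0, 100, 100)}])
        kept, dec = filter_settlements(layer, _registry(["A"]), REGION)
        assert kept.empty
        assert dec[0].action == Action.DROPPED_NOT_IN_REGISTRY

    def test_log_partitions_input(self):
        layer = _layer([
            {"settlement_id": "A", "category": "PA", "municipality": "m",
             "geometry": box(0, 0, 100, 100)},
            {"settlement_id": "X", "category": "PA", "municipality": "m",
             "geometry": box(200, 0, 300, 100)},
            {"settlement_id": "U", "category": "UC", "municipality": "m",
             "geometry": box(400, 0, 500, 100)},
        ])
        kept, dec = filter_settlements(layer, _registry(["A"]), REGION)
        assert len(kept) + len(dec) == len(layer)


class TestResolve:
    def test_single_polygon_identity(self):
        g = box(0, 0, 1000, 1000)
        out, dec, _ = resolve_multipolygons([("f0", g, "m")], 100.0, "m")
        assert out.equals(g)

    def test_congruent_duplicates_keep_one(self):
        g = box(0, 0, 1000, 1000)
        out, dec, _ = resolve_multipolygons(
            [("f0", g, "m"), ("f1", box(0, 0, 1000, 1000), "m")], 100.0, "m")
        assert area_ha(out) == pytest.approx(100.0)
        assert any(d.action == Action.POLYGON_DEDUPLICATED for d in dec)

    def test_sum_matches_reported_merges(self):
        a, b = box(0, 0, 3000, 3000), box(4000, 0, 6000, 3000)  # 900 + 600 ha
        out, dec, _ = resolve_multipolygons(
            [("f0", a, "m"), ("f1", b, "m")], 1500.0, "m")
        assert area_ha(out) == pytest.approx(1500.0)
        assert any(d.action == Action.POLYGONS_MERGED for d in dec)

    def test_closest_single_kept_when_sum_far(self):
        a, b = box(0, 0, 3000, 3000), box(4000, 0, 6000, 3000)  # 900 + 600 ha
        out, dec, _ = resolve_multipolygons(
            [("f0", a, "m"), ("f1", b, "m")], 920.0, "m")
        assert area_ha(out) == pytest.approx(900.0)
        assert any(d.action == Action.POLYGON_SELECTED_CLOSEST_AREA for d in dec)

    def test_wrong_municipality_dropped_first(self):
        a = box(0, 0, 3000, 3000)
        sat = box(50_000, 0, 50_100, 100)
        out, dec, _ = resolve_multipolygons(
            [("f0", a, "m"), ("f1", sat, "elsewhere")], 900.0, "m")
        assert area_ha(out) == pytest.approx(900.0)
        assert dec[0].action == Action.POLYGON_DROPPED_WRONG_MUNICIPALITY

    def test_no_survivor_flags_settlement(self):
        out, dec, _ = resolve_multipolygons(
            [("f0", box(0, 0, 10, 10), "elsewhere")], 900.0, "m")
        assert out is None

    def test_order_independent(self):
        polys = [("f0", box(0, 0, 3000, 3000), "m"),
                 ("f1", box(4000, 0, 6000, 3000), "m"),
                 ("f2", box(7000, 0, 7500, 500), "m")]
        out1, _, _ = resolve_multipolygons(polys, 920.0, "m")
        out2, _, _ = resolve_multipolygons(polys[::-1], 920.0, "m")
        assert out1.equals(out2)


class TestEndToEnd:
    def test_one_polygon_per_kept_settlement(self, dataset, cleaned):
        assert cleaned["settlement_id"].is_unique
        assert len(cleaned) == len(dataset.registry)

    def test_idempotent_on_own_output(self, dataset, cleaned):
        layer = cleaned[["settlement_id", "category", "municipality", "geometry"]].copy()
        again, dec = clean_settlements(layer, dataset.registry, dataset.region_boundary)
        assert len(again) == len(cleaned)
        for sid in again["settlement_id"]:
            g0 = cleaned.loc[cleaned["settlement_id"] == sid, "geometry"].iloc[0]
            g1 = again.loc[again["settlement_id"] == sid, "geometry"].iloc[0]
            assert area_ha(g0.symmetric_difference(g1)) < 1e-6

    @pytest.mark.parametrize("mode,action", [
        ("duplicate_polygons", "polygon_deduplicated"),
        ("wrong_municipality", "polygon_dropped_wrong_municipality"),
        ("split_settlement", "polygons_merged"),
    ])
    def test_perturbation_round_trip(self, dataset, cleaned, mode, action):
        """Injected map pathologies are fixed and logged with the expected action,
        and the cleaned geometry matches the unperturbed result."""
        corrupted, expected = synth.perturb(dataset, mode, seed=5)
        out, dec = clean_settlements(
            corrupted.settlements, corrupted.registry, corrupted.region_boundary)
        log = cleaning.decisions_frame(dec)
        assert out["settlement_id"].is_unique and len(out) == len(cleaned)
        for sid, exp_action in expected.items():
            assert exp_action == action
            assert ((log["settlement_id"] == sid) & (log["action"] == action)).any()
            g0 = cleaned.loc[cleaned["settlement_id"] == sid, "geometry"].iloc[0]
            g1 = out.loc[out["settlement_id"] == sid, "geometry"].iloc[0]
            assert area_ha(g0.symmetric_difference(g1)) < 1e-6
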