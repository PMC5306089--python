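"""Overlay union, final-class precedence and the partition invariant."""

import pandas as pd
import pytest
from shapely.geometry import box

from settlecarbon import reconcile as rc
from settlecarbon import synth
from settlecarbon.geodata import area_ha
from settlecarbon.reconcile import (CoverageGapError, FinalClass,
                                    assign_final_class, class_areas,
                                    clip_to_settlements, reconcile, union_layers)

HY, UR = synth.HYDRO_CLASS, synth.URBAN_CLASS


class TestDecisionTable:
    @pytest.mark.parametrize("prodes,year,pmdbbs,carbon,expected,exp_year,exp_flag", [
        # annual data wins over the savanna clearing class
        ("deforestation", 2004, True, 1, FinalClass.DEF_PRODES, 2004, False),
        # the savanna monitor's 2 ha unit sees what the forest monitor misses
        ("nonforest", None, True, 3, FinalClass.CLEAR_PMDBBS, None, False),
        ("forest", None, True, 1, FinalClass.CLEAR_PMDBBS, None, False),
        ("cloud", None, True, 1, FinalClass.CLEAR_PMDBBS, None, False),
        # plain classes pass through
        ("forest", None, False, 1, FinalClass.FOREST, None, False),
        ("cloud", None, False, 1, FinalClass.CLOUD, None, False),
        ("nonforest", None, False, 3, FinalClass.NONFOREST, None, False),
        # carbon-map hydrography and urban take precedence over everything
        ("forest", None, False, HY, FinalClass.WATER, None, False),
        ("deforestation", 2007, True, UR, FinalClass.EXCLUDED_URBAN, None, False),
        # off-register monitor hydrography: excluded, unless clearing underneath
        ("hydro", None, False, 1, FinalClass.EXCLUDED_HYDRO, None, False),
        ("hydro", None, True, 1, FinalClass.DEF_PRODES, None, True),
    ])
    def test_precedence(self, prodes, year, pmdbbs, carbon, expected, exp_year, exp_flag):
        fc, y, flag = assign_final_class(prodes, year, pmdbbs, carbon, HY, UR)
        assert (fc, y, flag) == (expected, exp_year, exp_flag)

    def test_coverage_gap_is_error(self):
        with pytest.raises(CoverageGapError):
            assign_final_class(None, None, False, None, HY, UR)


class TestClip:
    SETTLEMENTS = pd.DataFrame({
        "settlement_id": ["A"], "geometry": [box(0, 0, 10_000, 10_000)],
    })

    def test_disjoint_layer_empty_output(self):
        layer = pd.DataFrame({"prodes_class": ["forest"],
                              "geometry": [box(20_000, 0, 30_000, 10_000)]})
        assert clip_to_settlements(layer, self.SETTLEMENTS).empty

    def test_covering_layer_clipped_to_settlement(self):
        layer = pd.DataFrame({"prodes_class": ["forest"],
                              "geometry": [box(-5000, -5000, 50_000, 50_000)]})
        out = clip_to_settlements(layer, self.SETTLEMENTS)
        assert len(out) == 1
        assert area_ha(out["geometry"].iloc[0]) == pytest.approx(10_000.0)

    def test_partial_overlap_area(self):
        layer = pd.DataFrame({"prodes_class": ["forest"],
                              "geometry": [box(6000, 2000, 14_000, 7000)]})
        out = clip_to_settlements(layer, self.SETTLEMENTS)
        # 4000 m × 5000 m remains inside
        assert area_ha(out["geometry"].iloc[0]) == pytest.approx(2000.0, rel=1e-9)


class TestUnion:
    def test_single_layer_identity_coverage(self):
        s = box(0, 0, 1000, 1000)
        prodes = pd.DataFrame({"prodes_class": ["forest"], "prodes_year": [None],
                               "geometry": [s]})
        frags = union_layers(s, "A", prodes, None, None)
        assert len(frags) == 1
        assert frags["area_ha"].iloc[0] == pytest.approx(100.0)
        assert frags["prodes_class"].iloc[0] == "forest"

    def test_half_overlapping_squares_three_fragments(self):
        a, b = box(0, 0, 1000, 1000), box(500, 0, 1500, 1000)
        s = a.union(b)
        prodes = pd.DataFrame({"prodes_class": ["forest"], "prodes_year": [None],
                               "geometry": [a]})
        carbon = pd.DataFrame({"carbon_class": [1], "geometry": [b]})
        frags = union_layers(s, "A", prodes, None, carbon)
        assert len(frags) == 3
        key = {}
        for _, f in frags.iterrows():
            key[(f["prodes_class"], f["carbon_class"])] = f["area_ha"]
        assert key[("forest", None)] == pytest.approx(50.0)
        assert key[("forest", 1)] == pytest.approx(50.0)
        assert key[(None, 1)] == pytest.approx(50.0)

    def test_layer_order_invariance(self, dataset, cleaned):
        """Permuting source-layer row order leaves the per-class areas unchanged."""
        frags1 = reconcile(cleaned.iloc[:4], dataset.prodes, dataset.pmdbbs,
                           dataset.carbon, hydro_class_id=HY, urban_class_id=UR)
        frags2 = reconcile(cleaned.iloc[:4], dataset.prodes.iloc[::-1],
                           dataset.pmdbbs.iloc[::-1], dataset.carbon.iloc[::-1],
                           hydro_class_id=HY, urban_class_id=UR)
        a1, a2 = class_areas(frags1), class_areas(frags2)
        pd.testing.assert_frame_equal(a1, a2, check_exact=False, atol=1e-6)

    def test_sliver_dissolved_into_longest_neighbour(self):
        s = box(0, 0, 1000, 1000)
        # 0.0005 m-wide strip = 5e-5 ha, below the 1e-4 ha sliver threshold
        prodes = pd.DataFrame({
            "prodes_class": ["forest", "deforestation"],
            "prodes_year": [None, 2004],
            "geometry": [box(0, 0, 999.9995, 1000), box(999.9995, 0, 1000, 1000)],
        })
        frags = union_layers(s, "A", prodes, None, None, sliver_ha=1e-4)
        # the sliver is absorbed into the forest fragment; coverage preserved
        assert len(frags) == 1
        assert frags["area_ha"].sum() == pytest.approx(100.0, abs=1e-4)


class TestPartition:
    def test_classes_partition_each_settlement(self, cleaned, fragments):
        """Σ area over all final classes (incl. excluded) = settlement area."""
        totals = class_areas(fragments).sum(axis=1)
        ref = cleaned.set_index("settlement_id")["area_ha"]
        for sid, tot in totals.items():
            assert tot == pytest.approx(ref[sid], abs=1e-4)

    def test_monotone_precedence(self, dataset, cleaned):
        """Adding an annual-deforestation polygon can never increase the
        forest or savanna-clearing area."""
        sub = cleaned.iloc[:3]
        base = class_areas(reconcile(sub, dataset.prodes, dataset.pmdbbs,
                                     dataset.carbon, hydro_class_id=HY,
                                     urban_class_id=UR))
        x0, y0, x1, y1 = sub["geometry"].iloc[0].bounds
        extra = pd.DataFrame([{"prodes_class": "deforestation", "prodes_year": 2010,
                               "geometry": box(x0, y0, (x0 + x1) / 2, (y0 + y1) / 2)}])
        prodes2 = pd.concat([dataset.prodes, extra], ignore_index=True)
        more = class_areas(reconcile(sub, prodes2, dataset.pmdbbs, dataset.carbon,
                                     hydro_class_id=HY, urban_class_id=UR))
        assert (more["FOREST"] <= base["FOREST"] + 1e-6).all()
        assert (more["CLEAR_PMDBBS"] <= base["CLEAR_PMDBBS"] + 1e-6).all()
        assert (more["DEF_PRODES"] >= base["DEF_PRODES"] - 1e-6).all()

    def test_matches_generator_truth(self, dataset, fragments):
        got = class_areas(fragments)
        want = dataset.truth.class_areas.set_index("settlement_id")
        for col in got.columns:
            pd.testing.assert_series_equal(
                got[col], want[col], check_names=False, atol=1e-6, rtol=1e-9)
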