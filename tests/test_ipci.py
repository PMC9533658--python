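"""Scoring-table fidelity, worked-example arithmetic, and index invariants.

The oracle below hand-encodes the published metric value ranges as literal
threshold chains, independently of the packaged YAML configuration, and the
tests scan dense value grids to show the two encodings agree everywhere.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scoring_oracle import oracle_category, oracle_score

from potholeveg.ipci import (
    METRIC_IDS,
    SCORE_SET,
    MetricVector,
    assess,
    categorize,
    compute_metrics,
    default_category_table,
    default_scoring_table,
    fqi,
    round_half_up,
    score_metric,
    total_score,
)
from potholeveg.survey import (
    HydroClass,
    Observation,
    WetlandSite,
    WetlandSurvey,
    Zone,
)
from potholeveg.traits import (
    GrowthForm,
    Lifespan,
    Nativity,
    SpeciesTrait,
    TraitTable,
)

CLASSES = ("temporarily_ponded", "seasonally_ponded")
COUNT_METRICS = [m for m in METRIC_IDS if m not in
                 ("pct_annual_biennial_introduced", "avg_c", "fqi")]


class TestScoringTableFidelity:
    @pytest.mark.parametrize("cls", CLASSES)
    @pytest.mark.parametrize("metric", COUNT_METRICS)
    def test_count_metrics_match_oracle_exhaustively(self, metric, cls):
        for v in range(0, 101):
            assert score_metric(metric, v, cls) == oracle_score(metric, v, cls)

    @pytest.mark.parametrize("cls", CLASSES)
    def test_percentage_metric_matches_oracle_on_decimal_grid(self, cls):
        for v in np.round(np.arange(0.0, 100.05, 0.1), 1):
            got = score_metric("pct_annual_biennial_introduced", float(v), cls)
            assert got == oracle_score("pct_annual_biennial_introduced", v, cls)

    @pytest.mark.parametrize("cls", CLASSES)
    @pytest.mark.parametrize("metric,vmax", [("avg_c", 10.0), ("fqi", 60.0)])
    def test_real_metrics_match_oracle_on_centesimal_grid(self, metric, vmax, cls):
        for v in np.round(np.arange(0.0, vmax + 0.005, 0.01), 2):
            assert score_metric(metric, float(v), cls) == oracle_score(
                metric, v, cls
            )

    @pytest.mark.parametrize(
        "metric,value,cls,expected",
        [
            ("pct_annual_biennial_introduced", 41.1, "temporarily_ponded", 0),
            ("pct_annual_biennial_introduced", 41.0, "temporarily_ponded", 4),
            ("avg_c", 3.53, "seasonally_ponded", 11),
            ("avg_c", 3.52, "seasonally_ponded", 7),
            ("fqi", 23.00, "seasonally_ponded", 11),
            ("fqi", 22.99, "seasonally_ponded", 7),
            ("richness_native_perennial", 0, "temporarily_ponded", 0),
            ("richness_native_perennial", 0, "seasonally_ponded", 0),
        ],
    )
    def test_printed_boundaries(self, metric, value, cls, expected):
        assert score_metric(metric, value, cls) == expected

    def test_rounding_closes_printed_gaps(self):
        # 35.05 rounds half-up to 35.1 -> score 4; 35.04 -> 35.0 -> score 7
        assert score_metric(
            "pct_annual_biennial_introduced", 35.05, "temporarily_ponded") == 4
        assert score_metric(
            "pct_annual_biennial_introduced", 35.04, "temporarily_ponded") == 7
        # 22.995 -> 23.00 attains the seasonal FQI top class
        assert score_metric("fqi", 22.995, "seasonally_ponded") == 11


class TestCategories:
    @pytest.mark.parametrize("cls", CLASSES)
    def test_partition_of_totals_matches_oracle(self, cls):
        for total in range(100):
            assert categorize(total, cls) == oracle_category(total, cls)

    def test_temporary_class_has_three_categories(self):
        cats = {categorize(t, "temporarily_ponded") for t in range(100)}
        assert cats == {"Poor", "Fair", "Good"}

    def test_seasonal_class_has_five_categories(self):
        cats = {categorize(t, "seasonally_ponded") for t in range(100)}
        assert cats == {"Very poor", "Poor", "Fair", "Good", "Very good"}

    def test_out_of_range_total_rejected(self):
        with pytest.raises(ValueError):
            categorize(100, "seasonally_ponded")


class TestTotals:
    def test_extremes(self):
        assert total_score([11] * 9) == 99
        assert total_score([0] * 9) == 0
        assert total_score([11, 0, 0, 0, 0, 0, 0, 11, 0]) == 22

    def test_wrong_count_and_illegal_scores_rejected(self):
        with pytest.raises(ValueError):
            total_score([11] * 8)
        with pytest.raises(ValueError):
            total_score([11] * 8 + [5])


class TestFQI:
    def test_square_root_identity(self):
        assert fqi(4.0, 16) == pytest.approx(16.0)
        assert fqi(7.3, 0) == 0.0

    def test_top_class_attainable(self):
        assert fqi(5.75, 16) == pytest.approx(23.00)
        assert score_metric("fqi", fqi(5.75, 16), "seasonally_ponded") == 11

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fqi(-1.0, 4)


class TestComputeMetrics:
    def test_worked_example(self, four_species_survey, four_species_traits):
        mv = compute_metrics(four_species_survey, four_species_traits)
        assert mv.richness_native_perennial == 2
        assert mv.genera_native_perennial == 2
        assert mv.native_grass_grasslike == 1
        assert mv.pct_annual_biennial_introduced == 50.0
        assert mv.wetmeadow_native_perennial == 1
        assert mv.count_c_ge_5 == 2
        assert mv.wetmeadow_count_c_ge_4 == 1
        assert mv.avg_c == 4.67  # (8 + 5 + 1) / 3
        assert mv.fqi == 8.08  # (14/3) * sqrt(3)

    def test_worked_example_assessment(self, four_species_survey,
                                       four_species_traits):
        r = assess(four_species_survey, four_species_traits)
        assert r.scores == (0, 0, 0, 0, 0, 0, 0, 11, 0)
        assert r.total == 11
        assert r.category == "Very poor"

    def test_empty_seasonal_survey_is_all_zero_very_poor(self,
                                                         four_species_traits):
        site = WetlandSite("e", HydroClass.SEASONALLY_PONDED, "native", 2020)
        r = assess(WetlandSurvey(site, []), four_species_traits)
        assert r.metrics.as_dict() == {m: 0 for m in METRIC_IDS}
        assert r.total == 0 and r.category == "Very poor"

    def test_empty_temporary_survey_floor_category_is_poor(self,
                                                           four_species_traits):
        site = WetlandSite("e", HydroClass.TEMPORARILY_PONDED, "native", 2020)
        r = assess(WetlandSurvey(site, []), four_species_traits)
        assert r.total == 0 and r.category == "Poor"

    def test_single_top_species(self):
        tt = TraitTable()
        tt.add(SpeciesTrait("Carex lasiocarpa", "Carex", Nativity.NATIVE,
                            Lifespan.PERENNIAL, GrowthForm.GRASS_LIKE, 10))
        site = WetlandSite("s", HydroClass.SEASONALLY_PONDED, "native", 2020)
        sv = WetlandSurvey(site, [Observation("Carex lasiocarpa",
                                              Zone.WET_MEADOW, 9)])
        mv = compute_metrics(sv, tt)
        assert mv.as_dict() == {
            "richness_native_perennial": 1, "genera_native_perennial": 1,
            "native_grass_grasslike": 1, "pct_annual_biennial_introduced": 0.0,
            "wetmeadow_native_perennial": 1, "count_c_ge_5": 1,
            "wetmeadow_count_c_ge_4": 1, "avg_c": 10.0, "fqi": 10.0,
        }

    def test_unknown_species_enter_denominator_only(self, four_species_survey,
                                                    four_species_traits):
        extra = four_species_survey.observations + [
            Observation("Mystery plantum", Zone.LOW_PRAIRIE, 2)
        ]
        sv = WetlandSurvey(four_species_survey.site, extra)
        with pytest.warns(UserWarning):
            from potholeveg.traits import warn_unknown
            warn_unknown({"Mystery plantum"}, four_species_traits)
        mv = compute_metrics(sv, four_species_traits)
        assert mv.richness_native_perennial == 2
        assert mv.pct_annual_biennial_introduced == 40.0  # 2 of 5

    def test_native_without_c_counts_in_richness_not_c_metrics(self):
        tt = TraitTable()
        tt.add(SpeciesTrait("Aa aa", "Aa", Nativity.NATIVE, Lifespan.PERENNIAL,
                            GrowthForm.FORB, 6))
        tt.add(SpeciesTrait("Bb bb", "Bb", Nativity.NATIVE, Lifespan.PERENNIAL,
                            GrowthForm.FORB, None))
        site = WetlandSite("s", HydroClass.SEASONALLY_PONDED, "native", 2020)
        sv = WetlandSurvey(site, [Observation("Aa aa", Zone.WET_MEADOW, 9),
                                  Observation("Bb bb", Zone.WET_MEADOW, 9)])
        mv = compute_metrics(sv, tt)
        assert mv.richness_native_perennial == 2
        assert mv.avg_c == 6.0  # mean over the single scored native
        assert mv.fqi == round_half_up(6.0 * np.sqrt(2), 2)  # natives = 2


def _survey_from_flags(flags):
    """Build a survey/traits pair from a list of (nativity, lifespan) flags."""
    tt = TraitTable()
    obs = []
    site = WetlandSite("s", HydroClass.SEASONALLY_PONDED, "native", 2020)
    for i, (native, perennial) in enumerate(flags):
        name = f"Genus{i} species{i}"
        tt.add(SpeciesTrait(
            name, f"Genus{i}",
            Nativity.NATIVE if native else Nativity.INTRODUCED,
            Lifespan.PERENNIAL if perennial else Lifespan.ANNUAL,
            GrowthForm.FORB,
            5 if native else None,
        ))
        obs.append(Observation(name, Zone.WET_MEADOW, 9))
    return WetlandSurvey(site, obs), tt


class TestMonotonicity:
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_adding_native_perennial_never_hurts_richness(self, flags):
        sv, tt = _survey_from_flags(flags)
        before = compute_metrics(sv, tt)
        sv2, tt2 = _survey_from_flags(flags + [(True, True)])
        after = compute_metrics(sv2, tt2)
        assert after.richness_native_perennial >= before.richness_native_perennial
        assert after.genera_native_perennial >= before.genera_native_perennial
        assert (after.pct_annual_biennial_introduced
                <= before.pct_annual_biennial_introduced)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_score_set_closure(self, flags):
        sv, tt = _survey_from_flags(flags)
        r = assess(sv, tt)
        assert set(r.scores) <= SCORE_SET
        assert 0 <= r.total <= 99
        assert r.metrics.wetmeadow_native_perennial <= (
            r.metrics.richness_native_perennial)
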