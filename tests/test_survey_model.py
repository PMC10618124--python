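"""Survey schema: flag derivation, expansion, complete cases, file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from settlescan import io as sio
from settlescan.errors import DomainError, ParseError, SchemaError
from settlescan.schema import (
    ANALYSIS_VARIABLES,
    MaterialVocabulary,
    classify_jmp_basic,
    derive_flags,
    derive_inadequate_materials,
    derive_overcrowded,
    expand_to_individuals,
    filter_complete_cases,
    validate_households,
)

from conftest import household_record, make_households, roster_for

VOCAB = MaterialVocabulary.packaged()


class TestDerivations:
    @pytest.mark.parametrize("wall,roof,floor,expected", [
        ("finished_brick", "metal_sheet", "cement", False),
        ("wood_planks", "metal_sheet", "cement", True),       # rudimentary planks
        ("finished_brick", "metal_sheet", "unfinished_surface", True),  # one surface suffices
        ("wood_planks", "thatch", "earth", True),
    ])
    def test_inadequate_materials(self, wall, roof, floor, expected):
        assert derive_inadequate_materials(wall, roof, floor) is expected

    def test_unknown_material_code_named_in_error(self):
        with pytest.raises(SchemaError, match="bamboo_xyz"):
            derive_inadequate_materials("bamboo_xyz", "metal_sheet", "cement")

    def test_missing_surface_gives_na_unless_nondurable_seen(self):
        assert derive_inadequate_materials(pd.NA, "metal_sheet", "cement") is pd.NA
        assert derive_inadequate_materials(pd.NA, "thatch", "cement") is True

    @pytest.mark.parametrize("members,rooms,expected", [
        (3, 1, False),   # exactly 3 per room is not "more than"
        (4, 1, True),    # more than three individuals per room
        (7, 2, True),    # 3.5 > 3
        (6, 2, False),
        (1, 1, False),
    ])
    def test_overcrowded(self, members, rooms, expected):
        assert derive_overcrowded(members, rooms) is expected

    def test_overcrowded_rejects_nonpositive_rooms(self):
        with pytest.raises(DomainError):
            derive_overcrowded(4, 0)

    @pytest.mark.parametrize("code,service,expected", [
        ("piped_on_premises", "water", True),
        ("open_defecation", "sanitation", False),
        ("handwashing_water_soap", "hygiene", True),   # water and soap present
        ("handwashing_water_only", "hygiene", False),
        ("unprotected_well", "water", False),
        ("pit_latrine_slab", "sanitation", True),
    ])
    def test_jmp_ladder_classification(self, code, service, expected):
        assert classify_jmp_basic(code, service) is expected

    def test_unmapped_facility_code_raises(self):
        with pytest.raises(SchemaError, match="water"):
            classify_jmp_basic("magic_fountain", "water")

    @settings(max_examples=50, deadline=None)
    @given(
        wall=st.sampled_from(sorted(VOCAB.codes)),
        roof=st.sampled_from(sorted(VOCAB.codes)),
        floor=st.sampled_from(sorted(VOCAB.codes)),
        members=st.integers(1, 15),
        rooms=st.integers(1, 6),
    )
    def test_flags_are_pure_functions_of_raw_fields(self, wall, roof, floor, members, rooms):
        hh = make_households([household_record(
            wall_material=wall, roof_material=roof, floor_material=floor,
            n_members=members, n_rooms=rooms)])
        f1, f2 = derive_flags(hh), derive_flags(hh)
        pd.testing.assert_frame_equal(f1, f2)
        assert f1.loc[0, "inadequate_materials"] == (
            not {wall, roof, floor} <= set(VOCAB.durable))
        assert f1.loc[0, "overcrowded"] == (members / rooms > 3)


class TestExpansion:
    def test_row_count_equals_roster_and_covariates_inherited(self):
        hh = make_households([
            household_record(0, n_members=3, indoor_cooking=True),
            household_record(1, n_members=5, indoor_cooking=False),
        ])
        ind = roster_for(hh)
        rows = expand_to_individuals(hh, ind)
        assert len(rows) == 8
        by_hh = rows.groupby("household_id")["indoor_cooking"].all()
        assert by_hh["s1-H000"] and not rows.loc[
            rows["household_id"] == "s1-H001", "indoor_cooking"].any()
        assert list(rows.columns[5:]) == ANALYSIS_VARIABLES

    def test_empty_input_gives_empty_table(self):
        rows = expand_to_individuals(make_households([]).reindex(columns=["household_id"]),
                                     pd.DataFrame(columns=["person_id", "household_id"]))
        assert rows.empty

    def test_extra_flags_carried_when_requested(self):
        hh = make_households([household_record(0, n_members=4, n_rooms=1)])
        rows = expand_to_individuals(hh, roster_for(hh),
                                     extra_flags=("basic_water", "overcrowded"))
        assert rows["overcrowded"].all()
        assert rows["basic_water"].all()


class TestCompleteCases:
    def test_no_missingness_drops_nothing(self, analysis_rows):
        full = analysis_rows.dropna()
        kept, dropped = filter_complete_cases(full)
        assert dropped == 0 and len(kept) == len(full)

    def test_one_missing_hygiene_drops_one_row(self):
        hh = make_households([household_record(i, n_members=1) for i in range(3)])
        rows = expand_to_individuals(hh, roster_for(hh))
        rows.loc[1, "basic_hygiene"] = pd.NA
        kept, dropped = filter_complete_cases(rows)
        assert dropped == 1 and len(kept) + dropped == len(rows)

    def test_synthetic_missingness_near_valid_rate(self, survey, analysis_rows):
        # households invalid w.p. 0.1; kept share ≈ 0.9 within binomial error
        kept, dropped = filter_complete_cases(analysis_rows)
        share = len(kept) / len(analysis_rows)
        n_hh = len(survey.households)
        se = np.sqrt(0.9 * 0.1 / n_hh)
        assert abs(share - 0.9) < 4 * se

    def test_missing_required_column_is_a_schema_error(self, analysis_rows):
        with pytest.raises(SchemaError, match="basic_hygiene"):
            filter_complete_cases(analysis_rows.drop(columns=["basic_hygiene"]))


class TestIO:
    def test_csv_round_trip_is_identity(self, tmp_path, survey):
        hh = survey.households
        sio.write_households_csv(hh, tmp_path / "hh.csv")
        back = sio.read_households_csv(tmp_path / "hh.csv")
        pd.testing.assert_frame_equal(back, hh, check_dtype=False)
        ind = survey.individuals
        sio.write_individuals_csv(ind, tmp_path / "ind.csv")
        back = sio.read_individuals_csv(tmp_path / "ind.csv")
        pd.testing.assert_frame_equal(back, ind, check_dtype=False)

    def test_csv_extra_columns_preserved(self, tmp_path):
        hh = make_households([household_record(0)])
        hh["enumerator"] = "team-3"
        sio.write_households_csv(hh, tmp_path / "hh.csv")
        back = sio.read_households_csv(tmp_path / "hh.csv")
        assert list(back["enumerator"]) == ["team-3"]

    def test_geojson_round_trip_preserves_coordinates(self, tmp_path, survey):
        hh = survey.households
        sio.write_households_geojson(hh, tmp_path / "hh.geojson")
        back = sio.read_households_geojson(tmp_path / "hh.geojson")
        assert len(back) == len(hh)
        np.testing.assert_allclose(back["lon"], hh["lon"], atol=1e-6)
        np.testing.assert_allclose(back["lat"], hh["lat"], atol=1e-6)
        pd.testing.assert_series_equal(back["indoor_cooking"], hh["indoor_cooking"],
                                       check_dtype=False)

    def test_geojson_missing_columns_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text('{"type":"FeatureCollection","features":[{"type":"Feature",'
                        '"geometry":{"type":"Point","coordinates":[0,0]},'
                        '"properties":{"household_id":"h1"}}]}')
        with pytest.raises(ParseError, match="lack properties"):
            sio.read_households_geojson(path)

    def test_malformed_geometry_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text('{"type":"FeatureCollection","features":[{"type":"Feature",'
                        '"geometry":{"type":"Point"},"properties":{}}]}')
        with pytest.raises(ParseError, match="malformed geometry"):
            sio.read_households_geojson(path)

    def test_sites_geojson_round_trip(self, tmp_path, survey):
        sio.write_sites_geojson(survey.sites, tmp_path / "sites.geojson")
        back = sio.read_sites_geojson(tmp_path / "sites.geojson")
        assert [s.site_id for s in back] == [s.site_id for s in survey.sites]
        for a, b in zip(back, survey.sites):
            assert a.boundary.equals_exact(b.boundary, tolerance=1e-9)


def test_validate_households_accepts_simulated_survey(survey):
    validate_households(survey.households, survey.individuals, survey.sites)


def test_validate_households_rejects_member_count_mismatch(survey):
    bad = survey.households.copy()
    bad.loc[0, "n_members"] = bad.loc[0, "n_members"] + 1
    with pytest.raises(SchemaError, match="n_members"):
        validate_households(bad, survey.individuals, survey.sites)
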