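"""Survey reading, filtering, matrices and effort accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import elevdiv as ed
from elevdiv.datasets import (
    load_camera_table,
    load_trap_success_table,
    trap_success_survey,
)
from elevdiv.exceptions import (
    ConsistencyError,
    EmptyDatasetError,
    SchemaError,
    UnsupportedInputError,
    ValidationError,
)


class TestReadSurvey:
    def test_toy_roundtrip(self, toy_ds, tmp_path):
        assert toy_ds.n_records == 8
        paths = ed.write_survey(toy_ds, tmp_path)
        back = ed.read_survey(paths["records"], paths["efforts"], paths["meta"])
        pd.testing.assert_frame_equal(back.records, toy_ds.records)
        pd.testing.assert_frame_equal(back.efforts, toy_ds.efforts)

    def test_missing_species_column_is_schema_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("mountain,location,elevation,trap_class\nA,500,500,ground\n")
        with pytest.raises(SchemaError, match="species"):
            ed.read_survey(p)

    def test_negative_elevation_is_validation_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "species,mountain,location,elevation,trap_class\nX,A,500,-10,ground\n"
        )
        with pytest.raises(ValidationError, match="elevation"):
            ed.read_survey(p)

    def test_unknown_species_gets_unknown_status_with_warning(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "species,mountain,location,elevation,trap_class\nX,A,500,500,ground\n"
        )
        m = tmp_path / "m.csv"
        m.write_text("species,endemic\nY,endemic\n")
        with pytest.warns(UserWarning, match="unknown"):
            ds = ed.read_survey(p, meta_path=m)
        assert (
            ds.meta.set_index("species").loc["X", "endemic"] == "unknown"
        )


class TestFilterRecords:
    def test_trap_class_filters(self, toy_ds):
        flt = ed.filter_records(toy_ds, include_recaptures=True)
        assert set(flt.records["trap_class"]) == {"ground"}
        assert set(flt.efforts["trap_class"]) == {"ground"}

    def test_all_flags_true_is_identity(self, toy_ds):
        flt = ed.filter_records(toy_ds, True, True, True)
        pd.testing.assert_frame_equal(flt.records, toy_ds.records)
        pd.testing.assert_frame_equal(flt.efforts, toy_ds.efforts)

    def test_idempotent(self, toy_ds):
        once = ed.filter_records(toy_ds)
        twice = ed.filter_records(once)
        pd.testing.assert_frame_equal(once.records, twice.records)
        pd.testing.assert_frame_equal(once.efforts, twice.efforts)

    def test_provenance_grows(self, toy_ds):
        flt = ed.filter_records(toy_ds)
        assert len(flt.provenance) == len(toy_ds.provenance) + 1

    def test_published_totals_with_and_without_side_traps(self):
        # tall-mountain totals: 213 captures / 2,044 nights including
        # arboreal+pitfall, 209 / 2,022 after excluding them
        ds = trap_success_survey()
        full = ed.trap_success(ds, group_by="mountain").set_index("mountain")
        assert full.loc["Kinabalu", "n_captures"] == 213
        assert full.loc["Kinabalu", "trap_nights"] == 2044
        flt = ed.trap_success(ed.filter_records(ds), group_by="mountain").set_index(
            "mountain"
        )
        assert flt.loc["Kinabalu", "n_captures"] == 209
        assert flt.loc["Kinabalu", "trap_nights"] == 2022


class TestAbundanceMatrix:
    def test_counts_and_shared_species(self):
        rec = pd.DataFrame(
            {
                "species": ["X", "X", "Y", "X"],
                "mountain": ["A", "A", "A", "B"],
                "location": ["500", "500", "500", "900"],
                "elevation": [500, 510, 505, 900],
                "trap_class": "ground",
            }
        )
        ds = ed.SurveyDataset(
            records=ed.survey._normalise_records(rec),
            efforts=pd.DataFrame(columns=["mountain", "location", "trap_class", "trap_nights"]),
            meta=pd.DataFrame({"species": ["X", "Y"], "endemic": ["unknown", "unknown"]}),
        )
        am = ed.build_abundance_matrix(ds)
        assert am.counts.loc[("A", "500"), "X"] == 2
        assert list(am.counts.columns).count("X") == 1  # once despite 2 mountains
        assert am.counts.loc[("B", "900"), "X"] == 1

    def test_empty_dataset_raises(self, toy_ds):
        empty = ed.SurveyDataset(
            records=toy_ds.records.iloc[0:0],
            efforts=toy_ds.efforts,
            meta=toy_ds.meta,
        )
        with pytest.raises(EmptyDatasetError):
            ed.build_abundance_matrix(empty)

    def test_row_sums_match_generator_truth(self, preset_sim):
        _, ds, truth = preset_sim
        flt = ed.filter_records(ds)
        am = ed.build_abundance_matrix(flt)
        got = am.counts.sum(axis=1)
        want = truth.capture_totals.set_index(["mountain", "location"])[
            "n_ground_captures"
        ]
        for site in got.index:
            assert got.loc[site] == want.loc[site]
        # count conservation over the whole matrix
        assert am.counts.to_numpy().sum() == flt.n_records


class TestTrapSuccess:
    def test_reproduces_every_printed_percentage(self):
        tab = load_trap_success_table()
        ds = trap_success_survey()
        incl = ed.trap_success(ds, "location").set_index(["mountain", "location"])
        excl = ed.trap_success(ed.filter_records(ds), "location").set_index(
            ["mountain", "location"]
        )
        for _, row in tab.iterrows():
            key = (row["mountain"], str(row["location"]))
            assert incl.loc[key, "percent"] == pytest.approx(row["pct_all"])
            assert excl.loc[key, "percent"] == pytest.approx(row["pct_ground"])

    def test_internal_consistency_of_reported_rows(self):
        out = ed.trap_success(trap_success_survey(), "location")
        for _, r in out.iterrows():
            again = 100.0 * r["n_captures"] / r["trap_nights"]
            assert ed.survey.round_half_up(again, 1) == r["percent"]

    def test_zero_captures_is_zero_percent(self):
        ds = trap_success_survey()
        ds.efforts.loc[len(ds.efforts)] = ["Kinabalu", "9999", "ground", 100]
        out = ed.trap_success(ds, "location").set_index(["mountain", "location"])
        assert out.loc[("Kinabalu", "9999"), "percent"] == 0.0

    def test_captures_without_effort_is_consistency_error(self, toy_ds):
        broken = ed.SurveyDataset(
            records=toy_ds.records,
            efforts=toy_ds.efforts.iloc[0:0],
            meta=toy_ds.meta,
        )
        with pytest.raises(ConsistencyError):
            ed.trap_success(broken, "location")


class TestAccumulationCurve:
    def test_no_captures_is_flat_zero(self, toy_ds):
        ds = ed.SurveyDataset(
            records=toy_ds.records.iloc[0:0],
            efforts=toy_ds.efforts,
            meta=toy_ds.meta,
        )
        curve = ed.accumulation_curve(ds, ("North", "500"))
        assert (curve["cumulative_richness"] == 0).all()

    def test_missing_capture_day_is_unsupported(self, toy_ds):
        ds = ed.SurveyDataset(
            records=toy_ds.records.assign(capture_day=pd.NA),
            efforts=toy_ds.efforts,
            meta=toy_ds.meta,
        )
        with pytest.raises(UnsupportedInputError):
            ed.accumulation_curve(ds, ("North", "500"))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        days=st.lists(st.integers(1, 12), min_size=1, max_size=60),
        n_sp=st.integers(1, 8),
    )
    def test_monotone_and_ends_at_site_richness(self, days, n_sp, toy_ds):
        rng = np.random.default_rng(len(days) * 131 + n_sp)
        rec = pd.DataFrame(
            {
                "species": [f"sp{rng.integers(n_sp)}" for _ in days],
                "mountain": "M",
                "location": "500",
                "elevation": 500,
                "trap_class": "ground",
                "capture_day": days,
            }
        )
        ds = ed.SurveyDataset(
            records=ed.survey._normalise_records(rec),
            efforts=pd.DataFrame(
                [{"mountain": "M", "location": "500", "trap_class": "ground",
                  "trap_nights": 40 * max(days)}]
            ),
            meta=pd.DataFrame(
                {"species": rec["species"].unique(), "endemic": "unknown"}
            ),
        )
        curve = ed.accumulation_curve(ds, ("M", "500"))
        assert (np.diff(curve["cumulative_trap_nights"]) >= 0).all()
        assert (np.diff(curve["cumulative_richness"]) >= 0).all()
        # brute-force replay of the event log
        expect = len(set(rec["species"]))
        assert curve["cumulative_richness"].iloc[-1] == expect


class TestCameraRates:
    def test_reproduces_printed_rates(self):
        tab = load_camera_table()
        usable = tab[~tab["denominator_ambiguous"]]
        out = ed.camera_relative_abundance(usable)
        assert (out["rate_per_100_nights"] == out["printed_rate"]).all()

    def test_known_values(self):
        tab = pd.DataFrame(
            {
                "camera_id": [1, 1, 1],
                "species": ["a", "b", "c"],
                "n_series": [1, 2, 0],
                "camera_nights": [42, 42, 42],
            }
        )
        out = ed.camera_relative_abundance(tab)
        assert list(out["rate_per_100_nights"]) == [2.38, 4.76, 0.0]

    def test_nonpositive_nights_rejected(self):
        tab = pd.DataFrame(
            {"camera_id": [1], "species": ["a"], "n_series": [1], "camera_nights": [0]}
        )
        with pytest.raises(ValidationError):
            ed.camera_relative_abundance(tab)
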