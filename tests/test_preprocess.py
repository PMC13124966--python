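"""Cleaning rules: synonym normalization, the dedup tie-breaks, deleted
cases, plausibility filters, unique-PS selection and exact accounting."""

import numpy as np
import pandas as pd
import pytest

from faersig.preprocess import (PlausibilityRules, apply_plausibility_filters,
                                build_analysis_universe, clean_pipeline,
                                deduplicate, drop_deleted, load_synonyms,
                                normalize_drug_names, select_unique_ps)
from faersig.synthetic import SyntheticConfig, generate_bundle


class TestNormalize:
    synonyms = load_synonyms()

    @pytest.mark.parametrize("raw,expected", [
        ("ALIMTA", "pemetrexed"),
        ("alimta ", "pemetrexed"),
        ("Pemetrexed Disodium", "pemetrexed"),
        ("oxygen", "oxygen"),          # passthrough, lower-cased
        ("Oxygen", "oxygen"),
    ])
    def test_mapping(self, raw, expected):
        df = pd.DataFrame({"primaryid": ["1"], "drug_seq": ["1"],
                           "name_raw": [raw], "name_norm": [""],
                           "role": ["PS"], "start_dt": [""]})
        out = normalize_drug_names(df, self.synonyms)
        assert out["name_norm"].iloc[0] == expected

    def test_empty_table_warns_and_passes_through(self, caplog):
        df = pd.DataFrame({"primaryid": ["1"], "drug_seq": ["1"],
                           "name_raw": ["Foo"], "name_norm": [""],
                           "role": ["PS"], "start_dt": [""]})
        with caplog.at_level("WARNING"):
            out = normalize_drug_names(df, {})
        assert out["name_norm"].iloc[0] == "foo"
        assert "empty synonym table" in caplog.text


class TestDeduplicate:
    def test_most_recent_fda_dt_wins(self, bundle_builder):
        b = bundle_builder(reports=[
            {"primaryid": "1001", "caseid": "100", "fda_dt": "20230101"},
            {"primaryid": "1002", "caseid": "100", "fda_dt": "20230301"}])
        out, rep = deduplicate(b)
        assert list(out.reports["primaryid"]) == ["1002"]
        assert rep.removed["duplicates"] == 1

    def test_fda_tie_broken_by_higher_primaryid(self, bundle_builder):
        b = bundle_builder(reports=[
            {"primaryid": "5", "caseid": "100", "fda_dt": "20230101"},
            {"primaryid": "9", "caseid": "100", "fda_dt": "20230101"}])
        out, _ = deduplicate(b)
        assert list(out.reports["primaryid"]) == ["9"]

    def test_singleton_unchanged(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": "1", "caseid": "c"}])
        out, rep = deduplicate(b)
        assert out.equals(b) and rep.removed["duplicates"] == 0

    def test_child_rows_of_dropped_report_removed(self, bundle_builder):
        b = bundle_builder(
            reports=[{"primaryid": "1", "caseid": "c", "fda_dt": "20200101"},
                     {"primaryid": "2", "caseid": "c", "fda_dt": "20210101"}],
            reactions=[{"primaryid": "1", "pt": "rash"},
                       {"primaryid": "2", "pt": "rash"}])
        out, _ = deduplicate(b)
        assert set(out.reactions["primaryid"]) == {"2"}

    def test_missing_caseid_is_singleton(self, bundle_builder):
        b = bundle_builder(reports=[
            {"primaryid": "1", "caseid": ""},
            {"primaryid": "2", "caseid": ""}])
        out, _ = deduplicate(b)
        assert out.n_reports == 2

    def test_idempotent_on_generated_bundle(self):
        bundle, _ = generate_bundle(SyntheticConfig(n_reports=800, seed=5,
                                                    duplicate_rate=0.2))
        once, rep1 = deduplicate(bundle)
        twice, rep2 = deduplicate(once)
        assert once.equals(twice)
        assert rep1.removed["duplicates"] == 160
        assert rep2.removed["duplicates"] == 0


class TestDropDeleted:
    def test_removal_counted(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": str(i), "caseid": f"c{i}"}
                                    for i in range(3)])
        out, rep = drop_deleted(b, {"c1"})
        assert out.n_reports == 2 and rep.removed["deleted-cases"] == 1

    def test_empty_set_and_absent_id_are_noops(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": "1", "caseid": "c1"}])
        for ids in (set(), {"zzz"}):
            out, rep = drop_deleted(b, ids)
            assert out.equals(b) and rep.removed["deleted-cases"] == 0


class TestPlausibility:
    def test_extreme_age_removed(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": "1", "age_years": 650.0},
                                    {"primaryid": "2", "age_years": 64.0}],
                           reactions=[{"primaryid": "1", "pt": "rash"},
                                      {"primaryid": "2", "pt": "rash"}])
        out, rep = apply_plausibility_filters(b)
        assert rep.removed["extreme-values"] == 1
        assert list(out.reports["primaryid"]) == ["2"]

    def test_event_before_start_removed(self, bundle_builder):
        b = bundle_builder(
            reports=[{"primaryid": "1", "event_dt": "20230101"},
                     {"primaryid": "2", "event_dt": "20230301"}],
            drugs=[{"primaryid": "1", "start_dt": "20230201"},
                   {"primaryid": "2", "start_dt": "20230201"}],
            reactions=[{"primaryid": "1", "pt": "rash"},
                       {"primaryid": "2", "pt": "rash"}])
        out, rep = apply_plausibility_filters(b)
        assert rep.removed["inconsistent-timeline"] == 1
        assert list(out.reports["primaryid"]) == ["2"]

    def test_partial_dates_not_judged(self, bundle_builder):
        # event at month precision preceding the start: unknowable, kept
        b = bundle_builder(
            reports=[{"primaryid": "1", "event_dt": "202301"}],
            drugs=[{"primaryid": "1", "start_dt": "20230615"}],
            reactions=[{"primaryid": "1", "pt": "rash"}])
        out, rep = apply_plausibility_filters(b)
        assert out.n_reports == 1
        assert rep.removed["inconsistent-timeline"] == 0

    def test_missing_event_date_retained(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": "1", "event_dt": ""}],
                           reactions=[{"primaryid": "1", "pt": "rash"}])
        out, _ = apply_plausibility_filters(b)
        assert out.n_reports == 1

    def test_out_of_window_removed(self, bundle_builder):
        # partial-precision receipt date is not judged; the valid 2025
        # receipt falls outside the study window
        b = bundle_builder(reports=[{"primaryid": "1", "fda_dt": "202512"},
                                    {"primaryid": "2", "fda_dt": "20250301"}],
                           reactions=[{"primaryid": "1", "pt": "rash"},
                                      {"primaryid": "2", "pt": "rash"}])
        rules = PlausibilityRules(study_window=("20040101", "20241231"))
        out, rep = apply_plausibility_filters(b, rules)
        assert rep.removed["out-of-window"] == 1
        assert "2" not in set(out.reports["primaryid"])

    def test_non_ae_reports_removed(self, bundle_builder):
        b = bundle_builder(reports=[{"primaryid": "1"}, {"primaryid": "2"},
                                    {"primaryid": "3"}],
                           reactions=[{"primaryid": "2", "pt": "Off label use"},
                                      {"primaryid": "3", "pt": "rash"}])
        out, rep = apply_plausibility_filters(b)
        assert rep.removed["non-AE"] == 2  # no-reaction report and admin-only
        assert list(out.reports["primaryid"]) == ["3"]


class TestUniquePS:
    def _bundle(self, bundle_builder, roles):
        drugs = [{"primaryid": "1", "drug_seq": str(i + 1), "name_norm": name,
                  "role": role} for i, (name, role) in enumerate(roles)]
        return bundle_builder(reports=[{"primaryid": "1"}], drugs=drugs,
                              reactions=[{"primaryid": "1", "pt": "rash"}])

    def test_ps_with_ss_codrug_retained(self, bundle_builder):
        b = self._bundle(bundle_builder,
                         [("pemetrexed", "PS"), ("cisplatin", "SS")])
        out, _ = select_unique_ps(b, "pemetrexed")
        assert out.n_reports == 1
        assert set(out.drugs["name_norm"]) == {"pemetrexed", "cisplatin"}

    def test_two_ps_excluded(self, bundle_builder):
        b = self._bundle(bundle_builder,
                         [("pemetrexed", "PS"), ("cisplatin", "PS")])
        out, rep = select_unique_ps(b, "pemetrexed")
        assert out.n_reports == 0 and rep.removed["multi-PS"] == 1

    def test_ss_only_excluded(self, bundle_builder):
        b = self._bundle(bundle_builder, [("pemetrexed", "SS"),
                                          ("cisplatin", "PS")])
        out, rep = select_unique_ps(b, "pemetrexed")
        assert out.n_reports == 0 and rep.removed["target-not-PS"] == 1

    def test_absent_drug_warns_empty(self, bundle_builder, caplog):
        b = self._bundle(bundle_builder, [("aspirin", "PS")])
        with caplog.at_level("WARNING"):
            out, _ = select_unique_ps(b, "pemetrexed")
        assert out.n_reports == 0
        assert "absent" in caplog.text

    def test_universe_keeps_background(self, bundle_builder):
        b = bundle_builder(
            reports=[{"primaryid": "1"}, {"primaryid": "2"}, {"primaryid": "3"}],
            drugs=[{"primaryid": "1", "name_norm": "pemetrexed", "role": "PS"},
                   {"primaryid": "2", "name_norm": "pemetrexed", "role": "SS"},
                   {"primaryid": "3", "name_norm": "aspirin", "role": "PS"}],
            reactions=[{"primaryid": str(i), "pt": "rash"} for i in (1, 2, 3)])
        out, rep = build_analysis_universe(b, "pemetrexed")
        assert set(out.reports["primaryid"]) == {"1", "3"}
        assert rep.removed["target-not-unique-PS"] == 1


def test_pipeline_partitions_input_exactly():
    bundle, _ = generate_bundle(SyntheticConfig(n_reports=2000, seed=8,
                                                duplicate_rate=0.1))
    cleaned, reports = clean_pipeline(bundle, target_drug="pemetrexed")
    n = bundle.n_reports
    for rep in reports:
        rep.validate()
        assert rep.input_count == n
        n = rep.retained
    assert cleaned.n_reports == n
    # every retained report has the target as its unique PS drug
    ps = cleaned.drugs[cleaned.drugs["role"] == "PS"]
    per = ps.groupby("primaryid")["name_norm"].agg(list)
    assert set(per.index) == set(cleaned.reports["primaryid"])
    assert all(v == ["pemetrexed"] for v in per)
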