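"""Completeness, matching, concordance and LQAS classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehrdqa import (
    Concordance,
    MetricResult,
    completeness,
    concordance_score,
    date_error_profile,
    facility_summary,
    lqas_sample_size,
    matching,
)
from ehrdqa.variables import CONCORDANCE_VARIABLES

from conftest import make_record


class TestCompleteness:
    def test_counts_nonmissing_per_source(self):
        records = [
            make_record("P1"),
            make_record("P2", ehr={"vl1_value": ""}),
            make_record("P3", ehr={"vl1_value": "unknown"},
                        paper={"vl1_value": ""}),
        ]
        res = completeness(records, "vl1_value", "ehr")
        assert (res.numerator, res.denominator) == (1, 3)
        paper = completeness(records, "vl1_value", "paper")
        assert paper.numerator == 2

    def test_all_filled_is_high_quality(self):
        res = completeness([make_record()], "gender", "paper")
        assert res.fraction == 1.0 and res.high_quality

    def test_none_filled_is_low_quality(self):
        recs = [make_record(paper={"who_stage": ""}) for _ in range(4)]
        res = completeness(recs, "who_stage", "paper")
        assert res.fraction == 0.0 and not res.high_quality

    def test_unknown_variable_is_an_error(self):
        with pytest.raises(KeyError, match="nope"):
            completeness([make_record()], "nope", "paper")

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            completeness([], "gender", "paper")


class TestMatching:
    def test_denominator_is_complete_in_both(self):
        records = [
            make_record("P1"),                                # match
            make_record("P2", ehr={"gender": "M"}),           # mismatch
            make_record("P3", ehr={"gender": ""}),            # one-sided
        ]
        res = matching(records, "gender")
        assert (res.numerator, res.denominator) == (1, 2)

    def test_identical_sources_match_fully(self):
        res = matching([make_record() for _ in range(3)], "date_enrollment")
        assert res.fraction == 1.0

    def test_zero_denominator_reports_not_applicable(self):
        recs = [make_record(paper={"regimen3_drugs": ""},
                            ehr={"regimen3_drugs": ""})]
        res = matching(recs, "regimen3_drugs")
        assert res.denominator == 0
        assert res.fraction is None and res.high_quality is None

    def test_threshold_flips_exactly_at_85_percent(self):
        # 17/20 = 85% exactly -> high quality; 16/20 -> not
        at = MetricResult("x", 17, 20)
        below = MetricResult("x", 16, 20)
        assert at.high_quality is True
        assert below.high_quality is False


class TestBruteForceOracle:
    """Metrics equal an independent cell-by-cell recount."""

    def _fixture(self):
        recs = []
        for i in range(12):
            paper, ehr = {}, {}
            if i % 3 == 0:
                ehr["who_stage"] = ""
            if i % 4 == 0:
                ehr["date_enrollment"] = "2009-04-02"
            if i % 5 == 0:
                paper["who_stage"] = "Stage IV"
            recs.append(make_record(f"P{i}", paper=paper, ehr=ehr))
        return recs

    def test_completeness_and_matching_recount(self):
        from ehrdqa.normalization import is_missing, values_match
        from ehrdqa.variables import get_spec

        recs = self._fixture()
        for var in ("who_stage", "date_enrollment", "gender"):
            spec = get_spec(var)
            for source in ("paper", "ehr"):
                manual = sum(
                    0 if is_missing(r.value(var, source), spec, r.missingness)
                    else 1 for r in recs)
                assert completeness(recs, var, source).numerator == manual
            both = [r for r in recs
                    if not is_missing(r.paper(var), spec, r.missingness)
                    and not is_missing(r.ehr(var), spec, r.missingness)]
            m = matching(recs, var)
            assert m.denominator == len(both)
            assert m.numerator == sum(
                1 for r in both
                if values_match(r.paper(var), r.ehr(var), spec, r.missingness))


class TestConcordance:
    def test_perfect_record_scores_15(self):
        assert concordance_score(make_record()).score == 15

    def test_all_missing_both_sides_scores_15(self):
        # blank the full VL series too: the aligned most-recent pair
        # would otherwise fall back to the later entries
        blank = {v.name: "" for v in CONCORDANCE_VARIABLES}
        blank |= {n: "" for n in ("vl2_date", "vl2_value",
                                  "vl3_date", "vl3_value")}
        rec = make_record(paper=blank, ehr=blank)
        res = concordance_score(rec)
        assert res.score == 15
        assert all(c is Concordance.BOTH_MISSING
                   for v, c in res.per_variable.items()
                   if v in blank)

    def test_category_enumeration(self):
        # 10 matching, 3 missing in both, 2 present but different -> 13
        both_missing = ["who_stage", "regimen2_start_date", "regimen2_drugs"]
        differing = {"gender": "M", "date_of_birth": "1975-06-16"}
        paper = {v: "" for v in both_missing}
        ehr = {v: "" for v in both_missing} | differing
        res = concordance_score(make_record(paper=paper, ehr=ehr))
        cats = list(res.per_variable.values())
        assert cats.count(Concordance.BOTH_MISSING) == 3
        assert cats.count(Concordance.DISCORDANT) == 2
        assert cats.count(Concordance.MATCH) == 10
        assert res.score == 13

    def test_missing_in_one_source_is_discordant(self):
        res = concordance_score(make_record(ehr={"gender": ""}))
        assert res.per_variable["gender"] is Concordance.DISCORDANT

    def test_score_is_15_minus_discordant_count(self):
        rec = make_record(ehr={"gender": "M", "who_stage": ""})
        res = concordance_score(rec)
        n_disc = sum(1 for c in res.per_variable.values()
                     if c is Concordance.DISCORDANT)
        assert res.score == 15 - n_disc

    def test_aligned_vl_rescues_lagged_ehr(self):
        """With the EHR one result behind, positional comparison fails
        but the date-aligned most-recent pair agrees."""
        ehr = {"vl1_date": "2018-03-01", "vl1_value": "150",
               "vl2_date": "2017-09-01", "vl2_value": "900",
               "vl3_date": "", "vl3_value": ""}
        rec = make_record(ehr=ehr)
        aligned = concordance_score(rec, use_aligned_vl=True)
        positional = concordance_score(rec, use_aligned_vl=False)
        # aligned: newest pair is paper-only -> discordant on both VL vars
        assert aligned.per_variable["vl1_value"] is Concordance.DISCORDANT
        # positional: paper vl1 (20 @ 2018-09-01) vs EHR vl1 (150 @ 2018-03-01)
        assert positional.per_variable["vl1_value"] is Concordance.DISCORDANT
        assert positional.per_variable["vl1_date"] is Concordance.DISCORDANT


class TestDateErrorProfile:
    def test_no_mismatches_gives_empty_profile(self):
        assert date_error_profile([make_record()], "date_enrollment") == {}

    def test_single_small_mismatch(self):
        rec = make_record(ehr={"date_enrollment": "2009-04-11"})  # 10 days
        prof = date_error_profile([rec], "date_enrollment")
        assert prof["within_1_month"] == 1.0

    def test_bucketing_and_cumulative(self):
        offsets = {"P1": "2009-04-11", "P2": "2009-05-11", "P3": "2009-10-18"}
        recs = [make_record(pid, ehr={"date_enrollment": d})
                for pid, d in offsets.items()]  # 10, 40, 200 days
        prof = date_error_profile(recs, "date_enrollment")
        assert prof["within_1_month"] == pytest.approx(1 / 3)
        assert prof["1_to_3_months"] == pytest.approx(1 / 3)
        assert prof["beyond_3_months"] == pytest.approx(1 / 3)
        assert prof["cum_within_3_months"] == pytest.approx(2 / 3)
        total = (prof["within_1_month"] + prof["1_to_3_months"]
                 + prof["beyond_3_months"])
        assert total == pytest.approx(1.0)

    def test_non_date_variable_rejected(self):
        with pytest.raises(ValueError):
            date_error_profile([make_record()], "gender")


class TestFacilitySummary:
    def test_single_facility_equals_dataset_level(self):
        recs = [make_record(f"P{i}") for i in range(3)]
        df = facility_summary(recs, ["HF001"])
        assert len(df) == 1
        assert df.loc["HF001", "n_records"] == 3
        assert df.loc["HF001", "mean_concordance"] == 15.0

    def test_identical_facilities_get_equal_rows(self):
        recs = [make_record("P1", "HF001"), make_record("P2", "HF002")]
        df = facility_summary(recs, ["HF001", "HF002"])
        assert df.loc["HF001", "mean_concordance"] == \
            df.loc["HF002", "mean_concordance"]

    def test_dataset_mean_is_record_weighted_combination(self):
        recs = ([make_record(f"A{i}", "HF001") for i in range(2)]
                + [make_record(f"B{i}", "HF002",
                               ehr={"gender": "M"}) for i in range(3)])
        df = facility_summary(recs, ["HF001", "HF002"])
        weighted = (df["mean_concordance"] * df["n_records"]).sum() \
            / df["n_records"].sum()
        overall = sum(concordance_score(r).score for r in recs) / len(recs)
        assert weighted == pytest.approx(overall)

    def test_orphan_facility_is_an_error(self):
        with pytest.raises(ValueError, match="HF001"):
            facility_summary([make_record()], ["HF999"])


class TestLQASSampleSize:
    @pytest.mark.parametrize("volume,expected", [
        (10_000, 76),   # clamp at the maximum
        (30, 30),       # cannot sample more charts than patients
        (100, 48),      # at the low-volume knot
        (1000, 76),
    ])
    def test_known_points(self, volume, expected):
        assert lqas_sample_size(volume) == expected

    def test_interpolation_stays_in_band(self):
        assert 48 <= lqas_sample_size(60) <= 60
        assert 48 <= lqas_sample_size(550) <= 76

    @given(st.integers(1, 20_000), st.integers(1, 20_000))
    def test_monotone_nondecreasing(self, v1, v2):
        lo, hi = sorted([v1, v2])
        assert lqas_sample_size(lo) <= lqas_sample_size(hi)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            lqas_sample_size(0)
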