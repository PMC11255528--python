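"""Correlation and contingency statistics for facility-level factors."""

import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ehrdqa import (
    ContingencyTable2x2,
    FacilityProfile,
    alert_effect_table,
    chi_square_2x2,
    concordance_covariate_correlation,
    phi_coefficient,
)

from conftest import make_record

# counts observed when cross-classifying drug pickups by alert status
PICKUP_TABLE = ContingencyTable2x2(a=280, b=494, c=183, d=798)


def facility(fid, tier, avail=4, tech=2):
    return FacilityProfile(
        facility_id=fid, arm="intervention" if tier else "control",
        alert_tier=tier, ehr_availability=avail, tech_experience=tech,
        years_ehr_use=5.0)


class TestChiSquare:
    def test_yates_statistic_on_pickup_counts(self):
        chi2, df, p = chi_square_2x2(PICKUP_TABLE, continuity=True)
        assert chi2 == pytest.approx(67.5, abs=0.05)
        assert df == 1 and p < 0.001

    def test_uncorrected_exceeds_corrected(self):
        chi_u, _, _ = chi_square_2x2(PICKUP_TABLE, continuity=False)
        chi_c, _, _ = chi_square_2x2(PICKUP_TABLE, continuity=True)
        assert chi_u == pytest.approx(68.39, abs=0.01)
        assert chi_u >= chi_c >= 0

    def test_identical_row_proportions_give_zero(self):
        t = ContingencyTable2x2(20, 40, 10, 20)
        chi2, _, p = chi_square_2x2(t, continuity=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_balanced_table_gives_zero(self):
        chi2, _, _ = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10),
                                    continuity=False)
        assert chi2 == 0.0

    def test_zero_marginal_is_an_error(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))

    tables = st.tuples(*(st.integers(1, 500),) * 4)

    @given(tables)
    def test_oracle_sum_over_expected_counts(self, cells):
        """The closed form equals the brute-force sum of (O-E)^2/E, and
        the continuity-corrected form matches scipy's independent
        implementation."""
        a, b, c, d = cells
        t = ContingencyTable2x2(a, b, c, d)
        obs = t.as_array()
        n = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        oracle = float(((obs - expected) ** 2 / expected).sum())
        chi_u, _, p_u = chi_square_2x2(t, continuity=False)
        assert chi_u == pytest.approx(oracle, rel=1e-10)
        sp_chi, sp_p, sp_df, _ = stats.chi2_contingency(obs, correction=True)
        chi_c, df, p_c = chi_square_2x2(t, continuity=True)
        assert chi_c == pytest.approx(float(sp_chi), rel=1e-10)
        assert p_c == pytest.approx(float(sp_p), rel=1e-8)

    @given(tables)
    def test_continuity_never_increases_statistic(self, cells):
        t = ContingencyTable2x2(*cells)
        chi_u, _, _ = chi_square_2x2(t, continuity=False)
        chi_c, _, _ = chi_square_2x2(t, continuity=True)
        assert 0.0 <= chi_c <= chi_u + 1e-12


class TestPhi:
    def test_effect_size_on_pickup_counts(self):
        phi, lo, hi = phi_coefficient(PICKUP_TABLE, seed=0)
        assert phi == pytest.approx(0.20, abs=0.005)
        assert lo == pytest.approx(0.15, abs=0.02)
        assert hi == pytest.approx(0.24, abs=0.02)
        assert lo <= phi <= hi

    def test_perfect_association(self):
        phi, _, _ = phi_coefficient(ContingencyTable2x2(50, 0, 0, 50),
                                    ci_method="fisher")
        assert phi == pytest.approx(1.0)

    def test_no_association(self):
        phi, _, _ = phi_coefficient(ContingencyTable2x2(25, 25, 25, 25),
                                    ci_method="fisher")
        assert phi == 0.0

    @given(st.tuples(*(st.integers(1, 300),) * 4))
    def test_equals_sqrt_chi2_over_n_and_transpose_invariant(self, cells):
        t = ContingencyTable2x2(*cells)
        phi, _, _ = phi_coefficient(t, ci_method="fisher")
        chi_u, _, _ = chi_square_2x2(t, continuity=False)
        assert phi == pytest.approx(np.sqrt(chi_u / t.n), rel=1e-12)
        transposed = ContingencyTable2x2(t.a, t.c, t.b, t.d)
        phi_t, _, _ = phi_coefficient(transposed, ci_method="fisher")
        assert phi_t == pytest.approx(phi, rel=1e-12)

    def test_bootstrap_ci_is_deterministic_given_seed(self):
        r1 = phi_coefficient(PICKUP_TABLE, seed=42)
        r2 = phi_coefficient(PICKUP_TABLE, seed=42)
        assert r1 == r2


class TestCorrelation:
    def test_perfect_linear_pair(self):
        res = concordance_covariate_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)

    def test_self_and_negated_correlation(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert concordance_covariate_correlation(x, x).r == pytest.approx(1.0)
        neg = [-v for v in x]
        assert concordance_covariate_correlation(x, neg).r == pytest.approx(-1.0)

    def test_constant_covariate_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            concordance_covariate_correlation([1, 2, 3], [5, 5, 5])

    def test_bonferroni_adjustment_and_df(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = concordance_covariate_correlation(x, y, m_comparisons=3)
        assert res.df == 48
        assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_raw))
        assert res.ci_low <= res.r <= res.ci_high
        # t statistic consistent with r and df
        expected_t = res.r * np.sqrt(res.df / (1 - res.r ** 2))
        assert res.t_stat == pytest.approx(expected_t)

    def test_fisher_ci_covers_on_known_example(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = 0.16 * x + rng.normal(size=2000) * np.sqrt(1 - 0.16 ** 2)
        res = concordance_covariate_correlation(x, y)
        assert res.ci_low < 0.16 < res.ci_high


class TestFacilityProfileInvariants:
    def test_alert_tier_arm_consistency(self):
        with pytest.raises(ValueError):
            FacilityProfile("HF1", "control", 2, 3, 2, 4.0)
        with pytest.raises(ValueError):
            FacilityProfile("HF1", "intervention", 0, 3, 2, 4.0)

    def test_vl_alert_is_tier_two_and_up(self):
        assert facility("HF1", 2).has_vl_alert
        assert facility("HF1", 3).has_vl_alert
        assert not facility("HF1", 1).has_vl_alert
        assert not facility("HF1", 0).has_vl_alert


class TestAlertEffectTable:
    CUTOFF = datetime.date(2018, 7, 1)

    def _records(self):
        # HF-A has the missing-VL alert; HF-B does not.
        recs = [
            # post-cutoff, EHR pickup dates: 3 entries, 2 match
            make_record("A1", "HFA", ehr={"pickup3_date": "2018-08-22"}),
            # pre-cutoff record must be excluded
            make_record("A2", "HFA", paper={"date_last_visit": "2018-05-01"},
                        ehr={"date_last_visit": "2018-05-01"}),
            # post-cutoff control: 3 entries, 1 matches
            make_record("B1", "HFB", ehr={"pickup1_date": "2018-10-21",
                                          "pickup2_date": "2018-09-19"}),
        ]
        facs = [facility("HFA", tier=2), facility("HFB", tier=0)]
        return recs, facs

    def test_hand_counted_pickup_table(self):
        recs, facs = self._records()
        res = alert_effect_table(recs, facs, family="pickup_match",
                                 cutoff_date=self.CUTOFF)
        t = res.table
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert res.n_records == 2  # the pre-cutoff record is excluded

    def test_vl_family_uses_date_alignment(self):
        recs = [
            make_record("A1", "HFA"),  # identical series: 3 aligned matches
            make_record("B1", "HFB", ehr={"vl1_value": "999"}),  # 1 mismatch
        ]
        facs = [facility("HFA", tier=2), facility("HFB", tier=0)]
        res = alert_effect_table(recs, facs, family="vl_match",
                                 cutoff_date=self.CUTOFF)
        t = res.table
        assert (t.a, t.b) == (3, 0)
        assert (t.c, t.d) == (2, 1)

    def test_all_records_pre_cutoff_is_an_error(self):
        recs, facs = self._records()
        with pytest.raises(ValueError, match="alert"):
            alert_effect_table(recs, facs, family="pickup_match",
                               cutoff_date=datetime.date(2019, 1, 1))

    def test_facility_percentages_ranked(self):
        recs, facs = self._records()
        res = alert_effect_table(recs, facs, family="pickup_match",
                                 cutoff_date=self.CUTOFF)
        pct = res.facility_percentages["match_pct"]
        assert list(pct) == sorted(pct, reverse=True)
        assert res.alert_match_pct == pytest.approx(100 * 2 / 3)
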