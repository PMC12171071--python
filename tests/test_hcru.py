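"""Visit derivation, CPI adjustment, annualization, windows, conservation."""

import numpy as np
import pandas as pd
import pytest
from util import coverage_frame, med_claims, rx_claims, visit_oracle

from viticlaims.hcru import (DAYS_PER_YEAR, UnitCostTable, adjust_cost,
                             annualized_hcru, derive_visits, subset_claims,
                             window_comparison)


class TestDeriveVisits:
    def test_inpatient_chain_within_seven_days(self):
        med = med_claims([dict(person_id=1, service_date=d, setting="inpatient")
                          for d in ("2015-01-01", "2015-01-06", "2015-01-20")])
        v = derive_visits(med)
        inp = v[v["visit_type"] == "inpatient"]
        assert len(inp) == 2
        assert inp.iloc[0]["length_days"] == 6
        assert inp.iloc[0]["n_claims_merged"] == 2

    def test_chaining_is_transitive(self):
        med = med_claims([dict(person_id=1, service_date=d, setting="inpatient")
                          for d in ("2015-01-01", "2015-01-07", "2015-01-13")])
        v = derive_visits(med)
        assert len(v) == 1
        assert v.iloc[0]["length_days"] == 13

    def test_same_day_ed_claims_merge(self):
        med = med_claims([dict(person_id=1, service_date="2015-02-01",
                               setting="ed")] * 3)
        v = derive_visits(med)
        assert len(v) == 1
        assert v.iloc[0]["n_claims_merged"] == 3

    def test_no_claims_no_visits(self):
        assert len(derive_visits(med_claims([dict(person_id=1,
                                                  service_date="2015-01-01")])
                                 .iloc[0:0])) == 0

    def test_input_order_invariance(self):
        rows = [dict(person_id=int(p), service_date=d, setting=s)
                for p, d, s in [(1, "2015-01-05", "inpatient"),
                                (1, "2015-01-01", "inpatient"),
                                (2, "2015-01-01", "ed"),
                                (1, "2015-03-01", "outpatient"),
                                (1, "2015-03-01", "outpatient")]]
        a = derive_visits(med_claims(rows))
        b = derive_visits(med_claims(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_matches_transitive_closure_oracle_on_random_sets(self):
        rng = np.random.default_rng(11)
        settings = np.array(["inpatient", "ed", "outpatient", "other"])
        for _ in range(200):
            n = rng.integers(1, 25)
            rows = [dict(person_id=int(rng.integers(1, 4)),
                         service_date=pd.Timestamp("2015-01-01")
                         + pd.Timedelta(days=int(rng.integers(0, 60))),
                         setting=str(rng.choice(settings)))
                    for _ in range(n)]
            got = derive_visits(med_claims(rows))
            got_t = sorted((int(r["person_id"]), r["visit_type"],
                            (r["start_date"] - pd.Timestamp("2015-01-01")).days,
                            (r["end_date"] - pd.Timestamp("2015-01-01")).days,
                            int(r["n_claims_merged"]))
                           for _, r in got.iterrows())
            oracle = visit_oracle([(r["person_id"],
                                    (r["service_date"] - pd.Timestamp("2015-01-01")).days,
                                    r["setting"]) for r in rows])
            assert got_t == sorted(oracle)


class TestCostAdjustment:
    def test_identity_when_base_is_target(self):
        t = UnitCostTable(cpi_series={2021: 137.9}, target_year=2021)
        assert adjust_cost(1369.0, 2021, t) == pytest.approx(1369.0)

    def test_cpi_ratio_applied(self):
        t = UnitCostTable(cpi_series={2012: 100.0, 2021: 110.0}, target_year=2021)
        assert adjust_cost(161.38, 2012, t) == pytest.approx(177.518)

    def test_missing_cpi_year_raises(self):
        t = UnitCostTable(cpi_series={2021: 137.9}, target_year=2021)
        with pytest.raises(KeyError):
            adjust_cost(100.0, 2012, t)


def _cohort(person_id=1, start="2015-01-01", end="2016-12-31"):
    return pd.DataFrame({"person_id": [person_id],
                         "index_date": [pd.Timestamp(start)],
                         "follow_up_end": [pd.Timestamp(end)]})


class TestAnnualization:
    def test_formula(self):
        days = [f"2015-{m:02d}-10" for m in range(1, 9)]
        med = med_claims([dict(person_id=1, service_date=d) for d in days])
        per = annualized_hcru(med, rx_claims([dict(person_id=1,
                                                   dispense_date="2015-06-01")]),
                              _cohort())
        fu = (pd.Timestamp("2016-12-31") - pd.Timestamp("2015-01-01")).days + 1
        assert per["ann_n_outpatient"].iloc[0] == pytest.approx(8 * DAYS_PER_YEAR / fu)

    def test_scale_invariance(self):
        """Doubling both window length and claim count leaves the
        annualized rate unchanged."""
        med1 = med_claims([dict(person_id=1, service_date=f"2015-0{m}-10")
                           for m in range(1, 5)])
        med2 = med_claims([dict(person_id=1, service_date=f"201{y}-0{m}-10")
                           for y in (5, 6) for m in range(1, 5)])
        rx = rx_claims([dict(person_id=1, dispense_date="2015-02-01")])
        a = annualized_hcru(med1, rx, _cohort(end="2015-12-31"))
        b = annualized_hcru(med2, rx, _cohort(end="2016-12-30"))
        # windows of 365 and 730 days
        assert a["ann_n_outpatient"].iloc[0] == pytest.approx(
            b["ann_n_outpatient"].iloc[0], rel=0.005)

    def test_group_mean_is_mean_of_person_rates(self):
        med = med_claims(
            [dict(person_id=1, service_date=f"2015-{m:02d}-10") for m in range(1, 13)]
            + [dict(person_id=2, service_date="2015-03-10")])
        rx = rx_claims([dict(person_id=1, dispense_date="2015-02-01")])
        cohort = pd.DataFrame({
            "person_id": [1, 2],
            "index_date": pd.to_datetime(["2015-01-01", "2015-01-01"]),
            "follow_up_end": pd.to_datetime(["2015-12-31", "2016-12-30"])})
        per = annualized_hcru(med, rx, cohort)
        from viticlaims.hcru import summarize_hcru
        s = summarize_hcru(per, pd.Series({1: "g", 2: "g"}))
        manual = per["ann_n_outpatient"].mean()  # not ratio of sums
        assert s["mean_ann_n_outpatient"].iloc[0] == pytest.approx(manual)

    def test_cost_conservation_exact(self, small_dataset):
        ds = small_dataset
        cohort = pd.DataFrame({
            "person_id": ds.persons["person_id"].head(300),
            "index_date": pd.Timestamp("2012-01-01"),
            "follow_up_end": pd.Timestamp("2018-12-31")})
        per = annualized_hcru(ds.medical_claims, ds.pharmacy_claims, cohort)
        np.testing.assert_allclose(
            per["total_healthcare_cost"],
            per["total_services_cost"] + per["medication_cost"], rtol=1e-12)
        np.testing.assert_allclose(
            per["total_services_cost"],
            per["visit_imputed_cost"] + per["medical_service_cost"], rtol=1e-12)
        np.testing.assert_allclose(
            per["visit_imputed_cost"],
            per[["cost_inpatient", "cost_ed", "cost_outpatient",
                 "cost_other"]].sum(axis=1), rtol=1e-12)


class TestSubsets:
    def test_mental_health_ranges(self):
        med = med_claims([
            dict(person_id=1, service_date="2015-01-01", dx_code="296.2"),
            dict(person_id=2, service_date="2015-01-01", dx_code="F32.1",
                 dx_system="icd10"),
            dict(person_id=3, service_date="2015-01-01", dx_code="320.0"),
            dict(person_id=4, service_date="2015-01-01", dx_code="289.9"),
        ])
        got = subset_claims(med, "mental_health")
        assert set(got["person_id"]) == {1, 2}

    def test_vitiligo_related(self):
        med = med_claims([
            dict(person_id=1, service_date="2015-01-01", dx_code="709.1"),
            dict(person_id=2, service_date="2015-01-01", dx_code="L80",
                 dx_system="icd10"),
            dict(person_id=3, service_date="2015-01-01", dx_code="696.1"),
        ])
        assert set(subset_claims(med, "vitiligo_related")["person_id"]) == {1, 2}


class TestWindowComparison:
    COV = coverage_frame([(1, "2010-01-01", "2019-12-31"),
                          (2, "2015-01-01", "2015-12-31")])

    def _anchors(self, pid=1, date="2015-06-01"):
        return pd.DataFrame({"person_id": [pid],
                             "anchor_date": [pd.Timestamp(date)]})

    def test_insufficient_pre_coverage_excluded(self):
        med = med_claims([dict(person_id=2, service_date="2015-07-01")])
        rx = rx_claims([dict(person_id=2, dispense_date="2015-07-01")])
        with pytest.warns(UserWarning):
            out = window_comparison(med, rx, self._anchors(pid=2), self.COV,
                                    "2010-01-01", "2019-12-31")
        assert out.empty

    def test_paired_difference(self):
        pre_days = ["2015-01-10", "2015-02-10", "2015-03-10"]
        post_days = ["2015-07-10", "2015-08-10", "2015-09-10", "2015-10-10",
                     "2015-11-10"]
        med = med_claims([dict(person_id=1, service_date=d)
                          for d in pre_days + post_days])
        rx = rx_claims([dict(person_id=1, dispense_date="2015-01-01")])
        out = window_comparison(med, rx, self._anchors(), self.COV,
                                "2010-01-01", "2019-12-31")
        assert len(out) == 1
        assert out["post_n_outpatient"].iloc[0] - out["pre_n_outpatient"].iloc[0] == 2

    def test_anchor_day_claims_excluded_from_both_windows(self):
        med = med_claims([dict(person_id=1, service_date="2015-06-01")])
        rx = rx_claims([dict(person_id=1, dispense_date="2014-01-01")])
        out = window_comparison(med, rx, self._anchors(), self.COV,
                                "2010-01-01", "2019-12-31")
        assert out["pre_n_outpatient"].iloc[0] == 0
        assert out["post_n_outpatient"].iloc[0] == 0
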