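"""Visits, annualized healthcare resource utilization, and CPI-adjusted costs.

Visits are derived from medical claims by the claim-merging heuristics:
inpatient claims of a person are chained into one admission while
consecutive claim dates are <=7 days apart (transitively, so claims at days
1, 7, 13 form one stay); ED claims on the same date are one ED visit;
outpatient (and "other") claims merge per calendar day. Visit costs are
imputed from unit costs — an inpatient day, an ED visit, an outpatient
visit — each CPI-adjusted from its base year to the target year.

Costing splits into medication cost (pharmacy claim amounts; in-hospital
medication is never in pharmacy claims), medical service cost (physician
fee amounts), and visit-imputed hospital costs. total_services_cost =
visit-imputed costs + physician fees; total_healthcare_cost adds
medication. Utilization is annualized per person with a 365.25-day year;
pre/post windows around an anchor are [anchor-365, anchor) and
(anchor, anchor+365].
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .codes import mental_health_mask, vitiligo_dx_mask

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
VISIT_TYPES = ("inpatient", "ed", "outpatient", "other")
INPATIENT_CHAIN_DAYS = 7

#: Editable Québec all-items annual CPI (2002 = 100). Approximate Statistics
#: Canada series; replace with an exact extract for production costing.
DEFAULT_CPI_QUEBEC: dict[int, float] = {
    2010: 114.7, 2011: 118.2, 2012: 120.7, 2013: 121.6, 2014: 123.2,
    2015: 124.6, 2016: 125.5, 2017: 126.8, 2018: 129.0, 2019: 131.7,
    2020: 132.8, 2021: 137.9,
}


@dataclasses.dataclass(frozen=True)
class UnitCostTable:
    """Unit costs with their base years, and the CPI series used to restate
    them in target-year dollars."""

    inpatient_daily: float = 1369.0
    inpatient_base_year: int = 2016
    ed_visit: float = 161.38
    ed_base_year: int = 2012
    outpatient_visit: float = 29.82
    outpatient_base_year: int = 2012
    #: no published unit cost for "other" visits; outpatient cost applied
    other_visit: float = 29.82
    other_base_year: int = 2012
    target_year: int = 2021
    cpi_series: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CPI_QUEBEC))

    def adjusted(self, visit_type: str) -> float:
        amount, base = {
            "inpatient": (self.inpatient_daily, self.inpatient_base_year),
            "ed": (self.ed_visit, self.ed_base_year),
            "outpatient": (self.outpatient_visit, self.outpatient_base_year),
            "other": (self.other_visit, self.other_base_year),
        }[visit_type]
        return adjust_cost(amount, base, self)


def adjust_cost(amount: float, base_year: int, table: UnitCostTable) -> float:
    """Restate ``amount`` from ``base_year`` to the table's target year via
    the CPI ratio."""
    cpi = table.cpi_series
    for y in (base_year, table.target_year):
        if y not in cpi:
            raise KeyError(f"CPI series lacks year {y}")
    return amount * cpi[table.target_year] / cpi[base_year]


def derive_visits(medical_claims: pd.DataFrame) -> pd.DataFrame:
    """Merge claims into visits (person_id, visit_type, start_date,
    end_date, n_claims_merged, length_days).

    The result is invariant to claim input order. Claims with an
    unrecognized setting are counted under "other" (logged).
    """
    cols = ["person_id", "visit_type", "start_date", "end_date",
            "n_claims_merged", "length_days"]
    if medical_claims.empty:
        return pd.DataFrame(columns=cols)
    d = medical_claims[["person_id", "service_date", "setting"]].copy()
    setting = d["setting"].astype(str)
    unknown = ~setting.isin(VISIT_TYPES)
    if unknown.any():
        logger.info("%d claims with unknown setting counted as 'other'",
                    int(unknown.sum()))
        setting = setting.where(~unknown, "other")
    d["setting"] = setting

    parts = []

    # inpatient: transitive <=7-day chaining per person
    inp = d[d["setting"] == "inpatient"].sort_values(["person_id", "service_date"])
    if len(inp):
        pid = inp["person_id"].to_numpy()
        day = inp["service_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        new = np.ones(len(inp), dtype=bool)
        new[1:] = (pid[1:] != pid[:-1]) | (day[1:] - day[:-1] > INPATIENT_CHAIN_DAYS)
        vid = np.cumsum(new) - 1
        g = pd.DataFrame({"vid": vid, "person_id": pid, "day": day}).groupby("vid")
        agg = g.agg(person_id=("person_id", "first"), s=("day", "min"),
                    e=("day", "max"), n=("day", "size"))
        parts.append(pd.DataFrame({
            "person_id": agg["person_id"], "visit_type": "inpatient",
            "start": agg["s"], "end": agg["e"], "n_claims_merged": agg["n"]}))

    # ed / outpatient / other: one visit per distinct claim date
    for vt in ("ed", "outpatient", "other"):
        sub = d[d["setting"] == vt]
        if not len(sub):
            continue
        day = sub["service_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
        g = (pd.DataFrame({"person_id": sub["person_id"].to_numpy(), "day": day})
             .groupby(["person_id", "day"]).size().rename("n_claims_merged")
             .reset_index())
        parts.append(pd.DataFrame({
            "person_id": g["person_id"], "visit_type": vt,
            "start": g["day"], "end": g["day"],
            "n_claims_merged": g["n_claims_merged"]}))

    v = pd.concat(parts, ignore_index=True)
    epoch = np.datetime64("1970-01-01")
    v["start_date"] = pd.to_datetime(epoch + v["start"].to_numpy().astype("timedelta64[D]"))
    v["end_date"] = pd.to_datetime(epoch + v["end"].to_numpy().astype("timedelta64[D]"))
    v["length_days"] = (v["end"] - v["start"] + 1).astype(int)
    v = v.sort_values(["person_id", "start_date", "visit_type"],
                      kind="stable").reset_index(drop=True)
    return v[cols]


def subset_claims(medical_claims: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Restrict claims to a cause subset: all_cause, mental_health (ICD-9
    290-319 / ICD-10 F chapter) or vitiligo_related (709.x / L80.x)."""
    if subset == "all_cause":
        return medical_claims
    if subset == "mental_health":
        m = mental_health_mask(medical_claims["dx_code"], medical_claims["dx_system"])
        return medical_claims[m]
    if subset == "vitiligo_related":
        return medical_claims[vitiligo_dx_mask(medical_claims["dx_code"])]
    raise ValueError(f"unknown subset {subset!r}")


def _window_mask(dates: pd.Series, start, end) -> pd.Series:
    return (dates >= start) & (dates <= end)


def person_period_hcru(medical_claims: pd.DataFrame, pharmacy_claims: pd.DataFrame,
                       periods: pd.DataFrame,
                       unit_costs: Optional[UnitCostTable] = None) -> pd.DataFrame:
    """Counts and costs per person over per-person periods.

    ``periods``: person_id, start, end (inclusive). Returns one row per
    period with visit counts by type, inpatient days, visit-imputed costs,
    physician fee cost, medication cost and the cost totals (exact sums of
    their components).
    """
    unit_costs = unit_costs or UnitCostTable()
    u = {vt: unit_costs.adjusted(vt) for vt in VISIT_TYPES}

    med = medical_claims.merge(periods, on="person_id")
    med = med[_window_mask(med["service_date"], med["start"], med["end"])]
    visits = derive_visits(med)

    out = periods.copy()
    out["period_days"] = (out["end"] - out["start"]).dt.days + 1
    for vt in VISIT_TYPES:
        sub = visits[visits["visit_type"] == vt]
        cnt = sub.groupby("person_id").size()
        out[f"n_{vt}"] = out["person_id"].map(cnt).fillna(0).astype(int)
    ip_days = visits[visits["visit_type"] == "inpatient"].groupby(
        "person_id")["length_days"].sum()
    out["inpatient_days"] = out["person_id"].map(ip_days).fillna(0).astype(int)

    out["cost_inpatient"] = out["inpatient_days"] * u["inpatient"]
    out["cost_ed"] = out["n_ed"] * u["ed"]
    out["cost_outpatient"] = out["n_outpatient"] * u["outpatient"]
    out["cost_other"] = out["n_other"] * u["other"]

    fees = med.groupby("person_id")["fee"].sum()
    out["medical_service_cost"] = out["person_id"].map(fees).fillna(0.0)

    rx = pharmacy_claims.merge(periods, on="person_id")
    rx = rx[_window_mask(rx["dispense_date"], rx["start"], rx["end"])]
    medcost = rx.groupby("person_id")["cost"].sum()
    out["medication_cost"] = out["person_id"].map(medcost).fillna(0.0)

    out["visit_imputed_cost"] = (out["cost_inpatient"] + out["cost_ed"]
                                 + out["cost_outpatient"] + out["cost_other"])
    out["total_services_cost"] = out["visit_imputed_cost"] + out["medical_service_cost"]
    out["total_healthcare_cost"] = out["total_services_cost"] + out["medication_cost"]
    return out


_COUNT_COLS = [f"n_{vt}" for vt in VISIT_TYPES] + ["inpatient_days"]
_COST_COLS = ["cost_inpatient", "cost_ed", "cost_outpatient", "cost_other",
              "visit_imputed_cost", "medical_service_cost", "medication_cost",
              "total_services_cost", "total_healthcare_cost"]


def annualized_hcru(medical_claims: pd.DataFrame, pharmacy_claims: pd.DataFrame,
                    cohort: pd.DataFrame,
                    unit_costs: Optional[UnitCostTable] = None,
                    subset: str = "all_cause") -> pd.DataFrame:
    """Per-person annualized utilization over [index, follow-up end].

    Counts and costs are scaled by 365.25 / follow-up days; persons with
    zero follow-up are excluded with a reason column in the log. Adds
    ``any_<type>`` flags (>=1 visit of the type during follow-up).
    """
    med = subset_claims(medical_claims, subset)
    periods = cohort.rename(columns={"index_date": "start",
                                     "follow_up_end": "end"})[
        ["person_id", "start", "end"]].copy()
    fu_days = (periods["end"] - periods["start"]).dt.days + 1
    bad = fu_days <= 0
    if bad.any():
        logger.warning("%d persons excluded from annualization (zero follow-up)",
                       int(bad.sum()))
    periods = periods[~bad]
    per = person_period_hcru(med, pharmacy_claims, periods, unit_costs)
    factor = DAYS_PER_YEAR / per["period_days"]
    for c in _COUNT_COLS + _COST_COLS:
        per[f"ann_{c}"] = per[c] * factor
    for vt in VISIT_TYPES:
        per[f"any_{vt}"] = per[f"n_{vt}"] >= 1
    return per


def summarize_hcru(per_person: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group mean/SD of annualized measures (mean over persons, not
    ratio-of-sums) and the share of persons with >=1 visit per type."""
    df = per_person.copy()
    df["group"] = df["person_id"].map(groups)
    rows = []
    for g, sub in df.groupby("group", observed=True):
        row = {"group": g, "n": len(sub)}
        for c in _COUNT_COLS + _COST_COLS:
            row[f"mean_ann_{c}"] = sub[f"ann_{c}"].mean()
            row[f"sd_ann_{c}"] = sub[f"ann_{c}"].std(ddof=1)
        for vt in VISIT_TYPES:
            row[f"pct_any_{vt}"] = 100.0 * sub[f"any_{vt}"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def window_comparison(medical_claims: pd.DataFrame, pharmacy_claims: pd.DataFrame,
                      anchors: pd.DataFrame, coverage: pd.DataFrame,
                      study_start, study_end, window_days: int = 365,
                      unit_costs: Optional[UnitCostTable] = None,
                      subset: str = "all_cause") -> pd.DataFrame:
    """Paired pre/post windows around per-person anchor dates.

    ``anchors``: person_id, anchor_date. Only persons with a full window of
    observable data on both sides qualify: the windows must lie inside the
    study period and inside one coverage interval of the person. Returns a
    wide frame with ``pre_``/``post_`` columns for every count and cost
    measure, ready for paired tests.
    """
    med = subset_claims(medical_claims, subset)
    a = anchors.copy()
    a["pre_start"] = a["anchor_date"] - pd.Timedelta(days=window_days)
    a["post_end"] = a["anchor_date"] + pd.Timedelta(days=window_days)
    in_study = (a["pre_start"] >= pd.Timestamp(study_start)) & \
               (a["post_end"] <= pd.Timestamp(study_end))
    a = a[in_study]
    if a.empty:
        import warnings as _w
        _w.warn("no persons with a full pre/post window; empty comparison")
        return pd.DataFrame()

    cov = a.merge(coverage, on="person_id")
    ok = (cov["cov_start"] <= cov["pre_start"]) & (cov["cov_end"] >= cov["post_end"])
    eligible = set(cov.loc[ok, "person_id"])
    a = a[a["person_id"].isin(eligible)]
    if a.empty:
        import warnings as _w
        _w.warn("no persons with a full pre/post window; empty comparison")
        return pd.DataFrame()

    pre = a.rename(columns={"pre_start": "start"})[["person_id", "start"]].copy()
    pre["end"] = a["anchor_date"].to_numpy() - pd.Timedelta(days=1)
    post = a[["person_id"]].copy()
    post["start"] = a["anchor_date"].to_numpy() + pd.Timedelta(days=1)
    post["end"] = a["post_end"].to_numpy()

    pre_h = person_period_hcru(med, pharmacy_claims, pre, unit_costs)
    post_h = person_period_hcru(med, pharmacy_claims, post, unit_costs)
    keep = ["person_id"] + _COUNT_COLS + _COST_COLS
    merged = pre_h[keep].add_prefix("pre_").rename(
        columns={"pre_person_id": "person_id"}).merge(
        post_h[keep].add_prefix("post_").rename(
            columns={"post_person_id": "person_id"}), on="person_id")
    return merged
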