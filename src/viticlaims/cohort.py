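"""Case ascertainment, eligibility and exact matched-control construction.

The case algorithm: a person is a treated-vitiligo case if they carry >=1
ICD-10 L80.x claim, or >=1 ICD-9 709.x (other skin disorders) claim together
with >=1 vitiligo-related treatment record (tacrolimus, pimecrolimus, or
phototherapy), inside the ascertainment window. The index date is the date
of the first qualifying 709.x/L80.x claim. Controls are service-active
persons with no 709.x/L80.x claim in the window, indexed at their first
pharmacy dispensation; matching is exact on (coarse age band, sex) at up to
``ratio`` controls per case, without replacement.

Everyone must be drug-plan covered for >=3 months after their index date;
follow-up runs to the end of the covering interval or the study end,
whichever comes first.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .codes import (PHOTOTHERAPY_FLAG, QUALIFYING_TREATMENTS, coarse_band_series,
                    startswith_mask, vitiligo_dx_mask)

DEFAULT_CASE_WINDOW = (pd.Timestamp("2010-01-01"), pd.Timestamp("2019-09-30"))
DEFAULT_ACTIVITY_WINDOW = (pd.Timestamp("2018-01-01"), pd.Timestamp("2019-12-31"))


def qualifying_diagnosis_claims(medical_claims: pd.DataFrame,
                                window: tuple = DEFAULT_CASE_WINDOW) -> pd.DataFrame:
    """All 709.x / L80.x claims inside the window (person_id, service_date,
    is_l80)."""
    d = medical_claims
    in_win = (d["service_date"] >= window[0]) & (d["service_date"] <= window[1])
    mask = vitiligo_dx_mask(d["dx_code"]) & in_win.to_numpy()
    out = d.loc[mask, ["person_id", "service_date", "dx_code"]].copy()
    out["is_l80"] = startswith_mask(out["dx_code"], ("L80",))
    return out.drop(columns="dx_code")


def qualifying_treatment_persons(medical_claims: pd.DataFrame,
                                 pharmacy_claims: pd.DataFrame,
                                 window: tuple = DEFAULT_CASE_WINDOW) -> pd.Series:
    """person_id -> date of first vitiligo-related treatment record."""
    rx = pharmacy_claims
    rx_in = (rx["dispense_date"] >= window[0]) & (rx["dispense_date"] <= window[1])
    rx_mask = rx["treatment_class"].isin([c for c in QUALIFYING_TREATMENTS]) & rx_in
    rx_first = rx.loc[rx_mask].groupby("person_id")["dispense_date"].min()

    med = medical_claims
    md_in = (med["service_date"] >= window[0]) & (med["service_date"] <= window[1])
    md_mask = (med["procedure_flag"] == PHOTOTHERAPY_FLAG) & md_in
    md_first = med.loc[md_mask].groupby("person_id")["service_date"].min()

    both = pd.concat([rx_first, md_first])
    return both.groupby(level=0).min()


def identify_cases(medical_claims: pd.DataFrame, pharmacy_claims: pd.DataFrame,
                   window: tuple = DEFAULT_CASE_WINDOW,
                   max_treatment_lag_days: Optional[int] = None) -> pd.DataFrame:
    """Apply the case algorithm; returns person_id + index_date.

    ``max_treatment_lag_days`` optionally requires the qualifying treatment
    to fall within that many days of a 709.x claim (default: co-occurrence
    anywhere in the window, which is the study's rule).
    """
    dx = qualifying_diagnosis_claims(medical_claims, window)
    if dx.empty:
        return pd.DataFrame(columns=["person_id", "index_date"])

    l80_persons = set(dx.loc[dx["is_l80"], "person_id"].unique())
    dx9 = dx.loc[~dx["is_l80"]]
    treat_first = qualifying_treatment_persons(medical_claims, pharmacy_claims, window)

    if max_treatment_lag_days is None:
        treated = set(treat_first.index)
        alg_persons = l80_persons | (set(dx9["person_id"].unique()) & treated)
    else:
        # require |treatment date - some 709.x claim date| <= lag
        rx = pharmacy_claims
        rx_mask = rx["treatment_class"].isin(list(QUALIFYING_TREATMENTS)) & \
            (rx["dispense_date"] >= window[0]) & (rx["dispense_date"] <= window[1])
        tdates = pd.concat([
            rx.loc[rx_mask, ["person_id", "dispense_date"]].rename(
                columns={"dispense_date": "t_date"}),
            medical_claims.loc[
                (medical_claims["procedure_flag"] == PHOTOTHERAPY_FLAG)
                & (medical_claims["service_date"] >= window[0])
                & (medical_claims["service_date"] <= window[1]),
                ["person_id", "service_date"]].rename(columns={"service_date": "t_date"}),
        ])
        pairs = dx9.merge(tdates, on="person_id")
        ok = (pairs["t_date"] - pairs["service_date"]).abs().dt.days <= max_treatment_lag_days
        alg_persons = l80_persons | set(pairs.loc[ok, "person_id"].unique())

    sel = dx.loc[dx["person_id"].isin(alg_persons)]
    idx = sel.groupby("person_id")["service_date"].min().rename("index_date")
    return idx.reset_index()


def select_control_pool(persons: pd.DataFrame, medical_claims: pd.DataFrame,
                        pharmacy_claims: pd.DataFrame,
                        activity_window: tuple = DEFAULT_ACTIVITY_WINDOW,
                        exclusion_window: tuple = DEFAULT_CASE_WINDOW) -> pd.DataFrame:
    """Control candidates: >=1 medical service in the activity window, zero
    709.x/L80.x claims in the exclusion window, and an assignable index date
    (first pharmacy dispensation in the study period)."""
    med = medical_claims
    active = med.loc[(med["service_date"] >= activity_window[0])
                     & (med["service_date"] <= activity_window[1]), "person_id"].unique()
    dx = qualifying_diagnosis_claims(med, exclusion_window)
    excluded = set(dx["person_id"].unique())
    first_rx = pharmacy_claims.groupby("person_id")["dispense_date"].min()
    pool = pd.DataFrame({"person_id": active})
    pool = pool[~pool["person_id"].isin(excluded)]
    pool = pool.merge(first_rx.rename("index_date").reset_index(), on="person_id")
    return pool.sort_values("person_id").reset_index(drop=True)


def compute_follow_up(coverage: pd.DataFrame, assignments: pd.DataFrame,
                      study_end: pd.Timestamp,
                      min_follow_up: pd.DateOffset = pd.DateOffset(months=3)
                      ) -> pd.DataFrame:
    """Attach follow_up_end and eligibility to (person_id, index_date) rows.

    follow_up_end = min(end of the coverage interval containing the index
    date, study_end). Ineligible rows carry a reason code:
    ``no_coverage_at_index`` or ``follow_up_lt_3_months``.
    """
    study_end = pd.Timestamp(study_end)
    if assignments.empty:
        out = assignments.copy()
        out["follow_up_end"] = pd.Series(dtype="datetime64[ns]")
        out["eligible"] = pd.Series(dtype=bool)
        out["exclusion_reason"] = pd.Series(dtype=object)
        return out
    m = assignments.merge(coverage, on="person_id", how="left")
    inside = (m["index_date"] >= m["cov_start"]) & (m["index_date"] <= m["cov_end"])
    cov = m[inside].drop_duplicates("person_id", keep="first")
    out = assignments.merge(cov[["person_id", "cov_end"]], on="person_id", how="left")
    out["follow_up_end"] = out["cov_end"].clip(upper=study_end)
    min_end = out["index_date"] + min_follow_up
    out["eligible"] = out["cov_end"].notna() & (out["follow_up_end"] >= min_end)
    out["exclusion_reason"] = ""
    out.loc[out["cov_end"].isna(), "exclusion_reason"] = "no_coverage_at_index"
    out.loc[out["cov_end"].notna() & ~out["eligible"],
            "exclusion_reason"] = "follow_up_lt_3_months"
    return out.drop(columns="cov_end")


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 3,
                   seed: int = 0) -> pd.DataFrame:
    """1:ratio exact matching on (coarse age band, sex), without replacement.

    ``cases`` and ``pool`` need person_id, index_date, sex, age_group
    columns. Within each stratum the pool is shuffled under the seed and
    handed out to cases in ascending person_id order; a case in a depleted
    stratum receives fewer than ``ratio`` controls ("up to" semantics).
    Returns control rows with matched_case_id.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    if pool.empty:
        warnings.warn("empty control pool: no controls matched")
        return pd.DataFrame(columns=["person_id", "index_date", "matched_case_id"])

    cs = cases.copy()
    cs["stratum"] = coarse_band_series(cs["age_group"]) + "|" + cs["sex"].astype(str)
    pl = pool.copy()
    pl["stratum"] = coarse_band_series(pl["age_group"]) + "|" + pl["sex"].astype(str)

    queues: dict[str, list] = {}
    for stratum, sub in pl.sort_values("person_id").groupby("stratum", sort=True):
        idx = rng.permutation(len(sub))
        queues[stratum] = list(sub.index.to_numpy()[idx])

    taken = []
    short = 0
    for _, case in cs.sort_values("person_id").iterrows():
        q = queues.get(case["stratum"], [])
        got = 0
        while got < ratio and q:
            taken.append((q.pop(), case["person_id"]))
            got += 1
        if got < ratio:
            short += 1
    if short:
        warnings.warn(f"{short} case(s) matched to fewer than {ratio} controls")

    if not taken:
        return pd.DataFrame(columns=["person_id", "index_date", "matched_case_id"])
    rows = pl.loc[[t[0] for t in taken],
                  ["person_id", "index_date", "sex", "age_group"]].copy()
    rows["matched_case_id"] = [t[1] for t in taken]
    return rows.sort_values(["matched_case_id", "person_id"]).reset_index(drop=True)


@dataclasses.dataclass
class CohortResult:
    """Final cohort plus the per-person exclusion ledger."""

    cohort: pd.DataFrame       # person_id, group, index_date, matched_case_id, follow_up_end
    exclusions: pd.DataFrame   # person_id, stage, reason


def build_cohort(persons: pd.DataFrame, medical_claims: pd.DataFrame,
                 pharmacy_claims: pd.DataFrame, coverage: pd.DataFrame,
                 study_end, ratio: int = 3, seed: int = 0,
                 case_window: tuple = DEFAULT_CASE_WINDOW,
                 activity_window: tuple = DEFAULT_ACTIVITY_WINDOW) -> CohortResult:
    """Full cohort construction: cases, eligibility, pool, matching.

    The coverage/3-month rule is applied identically to cases and controls;
    matched controls are drawn only from eligible pool members.
    """
    demo = persons[["person_id", "sex", "age_group"]]

    def _excl(fu: pd.DataFrame, stage: str) -> pd.DataFrame:
        bad = fu.loc[~fu["eligible"], ["person_id", "exclusion_reason"]].copy()
        bad["stage"] = stage
        return bad.rename(columns={"exclusion_reason": "reason"})

    cases = identify_cases(medical_claims, pharmacy_claims, window=case_window)
    cases_fu = compute_follow_up(coverage, cases, study_end)
    cases_ok = cases_fu[cases_fu["eligible"]].merge(demo, on="person_id")

    pool = select_control_pool(persons, medical_claims, pharmacy_claims,
                               activity_window=activity_window,
                               exclusion_window=case_window)
    pool_fu = compute_follow_up(coverage, pool, study_end)
    pool_ok = pool_fu[pool_fu["eligible"]].merge(demo, on="person_id")

    matched = match_controls(cases_ok, pool_ok, ratio=ratio, seed=seed)
    matched_fu = matched.merge(
        pool_fu[["person_id", "follow_up_end"]], on="person_id", how="left")

    case_rows = cases_ok[["person_id", "index_date", "follow_up_end"]].copy()
    case_rows["group"] = "vitiligo"
    case_rows["matched_case_id"] = pd.NA
    ctrl_rows = matched_fu[["person_id", "index_date", "follow_up_end",
                            "matched_case_id"]].copy()
    ctrl_rows["group"] = "control"
    cohort = pd.concat([case_rows, ctrl_rows], ignore_index=True)[
        ["person_id", "group", "index_date", "matched_case_id", "follow_up_end"]]
    cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    cohort["follow_up_end"] = pd.to_datetime(cohort["follow_up_end"])
    cohort = cohort.sort_values(["group", "person_id"],
                                ascending=[False, True]).reset_index(drop=True)
    excl = pd.concat([_excl(cases_fu, "case_eligibility"),
                      _excl(pool_fu, "pool_eligibility")],
                     ignore_index=True)[["person_id", "stage", "reason"]]
    return CohortResult(cohort=cohort, exclusions=excl)
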