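"""Incidence and point prevalence of algorithm-identified vitiligo.

Yearly incidence: persons with a qualifying diagnosis in a calendar year
and none in the previous calendar year (one-year washout; the first study
year therefore has no estimate). Point prevalence at an as-of date: persons
with a qualifying diagnosis within the previous five years who also had
>=1 medical or pharmaceutical service in the previous year (alive and in
contact with the system), over persons with drug-plan coverage at the
as-of date. Estimates can be stratified by sex and coarse age band and
extrapolated to a target population.

"Qualifying diagnosis" means a 709.x/L80.x claim of a person who satisfies
the full case algorithm (diagnosis plus vitiligo-related treatment); pass
the claims returned by ``case_diagnosis_dates``.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from .codes import coarse_band_series
from .cohort import identify_cases, qualifying_diagnosis_claims

_EPI_COLS = ["measure", "period", "stratum", "numerator", "denominator",
             "proportion", "extrapolated_count"]


def case_diagnosis_dates(medical_claims: pd.DataFrame,
                         pharmacy_claims: pd.DataFrame,
                         window=None) -> pd.DataFrame:
    """709.x/L80.x claim dates restricted to algorithm-identified cases."""
    from .cohort import DEFAULT_CASE_WINDOW
    window = window or DEFAULT_CASE_WINDOW
    cases = identify_cases(medical_claims, pharmacy_claims, window=window)
    dx = qualifying_diagnosis_claims(medical_claims, window)
    out = dx[dx["person_id"].isin(set(cases["person_id"]))]
    return out[["person_id", "service_date"]].rename(columns={"service_date": "dx_date"})


def _row(measure, period, stratum, num, den, target_population):
    prop = num / den if den else float("nan")
    extra = int(round(prop * target_population)) if target_population and den else None
    return {"measure": measure, "period": period, "stratum": stratum,
            "numerator": int(num), "denominator": int(den),
            "proportion": prop, "extrapolated_count": extra}


def _stratify(persons: Optional[pd.DataFrame], by: Optional[Sequence[str]]):
    """Yield (stratum label, person_id set) pairs; 'overall' first."""
    yield "overall", None
    if persons is None or not by:
        return
    p = persons.copy()
    if "coarse_band" in by and "coarse_band" not in p:
        p["coarse_band"] = coarse_band_series(p["age_group"])
    for col in by:
        for value, sub in p.groupby(col, observed=True):
            yield f"{col}={value}", set(sub["person_id"])


def yearly_incidence(case_dx: pd.DataFrame, coverage: pd.DataFrame, year: int,
                     study_start=None, persons: Optional[pd.DataFrame] = None,
                     by: Optional[Sequence[str]] = None,
                     target_population: Optional[int] = None) -> pd.DataFrame:
    """Incidence of algorithm-identified vitiligo in ``year``.

    Numerator: persons with a qualifying diagnosis in ``year`` and none in
    ``year - 1``. Denominator: persons with any coverage day in ``year``.
    Raises for the first study year (no lookback available).
    """
    if study_start is not None and year <= pd.Timestamp(study_start).year:
        raise ValueError(f"incidence undefined for the first study year ({year}): "
                         "no one-year lookback available")
    y0, y1 = pd.Timestamp(f"{year}-01-01"), pd.Timestamp(f"{year}-12-31")
    py0, py1 = pd.Timestamp(f"{year - 1}-01-01"), pd.Timestamp(f"{year - 1}-12-31")

    dx = case_dx
    in_year = set(dx.loc[(dx["dx_date"] >= y0) & (dx["dx_date"] <= y1), "person_id"])
    in_prev = set(dx.loc[(dx["dx_date"] >= py0) & (dx["dx_date"] <= py1), "person_id"])
    incident = in_year - in_prev

    cov = coverage
    observed = set(cov.loc[(cov["cov_start"] <= y1) & (cov["cov_end"] >= y0),
                           "person_id"])
    rows = []
    for label, members in _stratify(persons, by):
        num = incident if members is None else incident & members
        den = observed if members is None else observed & members
        rows.append(_row("incidence", year, label, len(num & observed), len(den),
                         target_population))
    return pd.DataFrame(rows, columns=_EPI_COLS)


def point_prevalence(case_dx: pd.DataFrame, services: pd.DataFrame,
                     coverage: pd.DataFrame, as_of,
                     lookback_years: int = 5, activity_window_years: int = 1,
                     study_start=None, persons: Optional[pd.DataFrame] = None,
                     by: Optional[Sequence[str]] = None,
                     target_population: Optional[int] = None) -> pd.DataFrame:
    """Point prevalence at ``as_of``.

    ``services`` is a frame of (person_id, service_date) covering all
    medical and pharmaceutical services (used for the one-year activity
    requirement). A lookback reaching before the study start is truncated
    with a warning.
    """
    as_of = pd.Timestamp(as_of)
    lb_start = as_of - pd.DateOffset(years=lookback_years)
    if study_start is not None and lb_start < pd.Timestamp(study_start):
        warnings.warn("lookback reaches before study start; truncated")
        lb_start = pd.Timestamp(study_start)
    act_start = as_of - pd.DateOffset(years=activity_window_years)

    dx = case_dx
    qualified = set(dx.loc[(dx["dx_date"] >= lb_start) & (dx["dx_date"] <= as_of),
                           "person_id"])
    sv = services
    active = set(sv.loc[(sv["service_date"] >= act_start)
                        & (sv["service_date"] <= as_of), "person_id"])
    cov = coverage
    covered = set(cov.loc[(cov["cov_start"] <= as_of) & (cov["cov_end"] >= as_of),
                          "person_id"])
    prevalent = qualified & active & covered

    rows = []
    for label, members in _stratify(persons, by):
        num = prevalent if members is None else prevalent & members
        den = covered if members is None else covered & members
        rows.append(_row("prevalence", as_of.date().isoformat(), label,
                         len(num), len(den), target_population))
    return pd.DataFrame(rows, columns=_EPI_COLS)


def all_services(medical_claims: pd.DataFrame,
                 pharmacy_claims: pd.DataFrame) -> pd.DataFrame:
    """Medical + pharmacy claim dates as one (person_id, service_date) frame."""
    return pd.concat([
        medical_claims[["person_id", "service_date"]],
        pharmacy_claims[["person_id", "dispense_date"]].rename(
            columns={"dispense_date": "service_date"}),
    ], ignore_index=True)


def incidence_series(case_dx: pd.DataFrame, coverage: pd.DataFrame,
                     years: Sequence[int], persons: Optional[pd.DataFrame] = None,
                     by: Optional[Sequence[str]] = None,
                     target_population: Optional[int] = None) -> pd.DataFrame:
    """Yearly incidence over a span of years (excluding the first study
    year by construction of ``years``)."""
    return pd.concat([yearly_incidence(case_dx, coverage, y, persons=persons,
                                       by=by, target_population=target_population)
                      for y in years], ignore_index=True)
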