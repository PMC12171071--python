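"""Comorbidity flagging, Charlson index, and the study's statistical tests.

Comorbidities are flagged from >=1 mapped diagnosis code in the year after
the person's index date. The shipped ICD map is a documented reconstruction:
the source tabulation lists condition names, not codes, so each condition
carries a conventional set of ICD-9/ICD-10 prefixes (editable; see
``load_comorbidity_map``). The Charlson index uses the Quan et al. (2005)
claims coding algorithm with the original integer weights.

Group comparisons follow the study conventions: equal-variance independent
t tests for continuous variables, Pearson chi-square for categorical ones
switching to the two-sided Fisher exact test when any expected cell count is
below 5 (sparse rows in the source tabulation show p = 1.00, which a
chi-square cannot produce), and paired t tests for pre/post contrasts.
Percentages are reported at one decimal, half-up.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .codes import coarse_band_series, startswith_mask

# ---------------------------------------------------------------------------
# Comorbidity map (category -> condition -> ICD prefixes). Version 1.
# Reconstructed from condition names; prefixes are matched with startswith.

DEFAULT_COMORBIDITY_MAP: dict[str, dict[str, dict[str, list[str]]]] = {
    "autoimmune": {
        "multiple_sclerosis": {"icd9": ["340"], "icd10": ["G35"]},
        "inflammatory_bowel_disease": {"icd9": ["555", "556"], "icd10": ["K50", "K51"]},
        "rheumatoid_arthritis": {"icd9": ["714"], "icd10": ["M05", "M06"]},
        "myasthenia_gravis": {"icd9": ["358.0"], "icd10": ["G70.0"]},
        "systemic_lupus_erythematosus": {"icd9": ["710.0"], "icd10": ["M32"]},
        "idiopathic_thrombocytopenic_purpura": {"icd9": ["287.31"], "icd10": ["D69.3"]},
    },
    "mental_health": {
        "anxiety": {"icd9": ["300.0"], "icd10": ["F40", "F41"]},
        "depression": {"icd9": ["296.2", "296.3", "300.4", "311"], "icd10": ["F32", "F33"]},
        "sleep_disturbances": {"icd9": ["307.4", "327", "780.5"], "icd10": ["F51", "G47"]},
        "adjustment_disorders": {"icd9": ["309"], "icd10": ["F43"]},
        "schizophrenia": {"icd9": ["295"], "icd10": ["F20"]},
        "personality_disorder": {"icd9": ["301"], "icd10": ["F60", "F61"]},
        "childhood_psychiatric_disorders": {"icd9": ["313"], "icd10": ["F93", "F94"]},
        "adhd": {"icd9": ["314"], "icd10": ["F90"]},
        "eating_disorders": {"icd9": ["307.1", "307.5"], "icd10": ["F50"]},
        "parkinsonism": {"icd9": ["332"], "icd10": ["G20", "G21"]},
        "substance_use_disorder": {"icd9": ["303", "304", "305"],
                                   "icd10": ["F10", "F11", "F12", "F13", "F14",
                                             "F15", "F16", "F18", "F19"]},
        "conduct_disorder": {"icd9": ["312"], "icd10": ["F91"]},
        "ocd": {"icd9": ["300.3"], "icd10": ["F42"]},
    },
    "metabolic": {
        "hypertension": {"icd9": ["401", "402", "403", "404", "405"],
                         "icd10": ["I10", "I11", "I12", "I13", "I15"]},
        "diabetes": {"icd9": ["250"], "icd10": ["E10", "E11", "E13", "E14"]},
        "dyslipidemia": {"icd9": ["272"], "icd10": ["E78"]},
        "obesity": {"icd9": ["278.0"], "icd10": ["E66"]},
    },
    "other": {
        "thyroid_disorders": {"icd9": ["240", "241", "242", "243", "244", "245", "246"],
                              "icd10": ["E00", "E01", "E02", "E03", "E04", "E05", "E06", "E07"]},
        "breast_cancer": {"icd9": ["174", "175"], "icd10": ["C50"]},
        "lymphoma": {"icd9": ["200", "201", "202"],
                     "icd10": ["C81", "C82", "C83", "C84", "C85"]},
        "thyroid_cancer": {"icd9": ["193"], "icd10": ["C73"]},
    },
    "skin": {
        "psoriasis": {"icd9": ["696.0", "696.1"], "icd10": ["L40"]},
        "acne": {"icd9": ["706.0", "706.1"], "icd10": ["L70"]},
        "urticaria": {"icd9": ["708"], "icd10": ["L50"]},
        "atopic_dermatitis": {"icd9": ["691.8"], "icd10": ["L20"]},
        "herpes_zoster": {"icd9": ["053"], "icd10": ["B02"]},
    },
}


def load_comorbidity_map(path: str | Path) -> dict:
    """Load a user-edited comorbidity map from YAML (same nesting as the
    shipped default)."""
    with open(path) as fh:
        cmap = yaml.safe_load(fh)
    for cat, conds in cmap.items():
        for cond, codes in conds.items():
            for system in ("icd9", "icd10"):
                if not codes.get(system):
                    raise ValueError(f"{cat}/{cond}: no {system} prefixes")
    return cmap


# ---------------------------------------------------------------------------
# Charlson index (Quan 2005 coding, original weights)


def _icd9_span(lo: int, hi: int) -> list[str]:
    return [str(c).zfill(3) for c in range(lo, hi + 1)]


def _icd10_span(letter: str, lo: int, hi: int) -> list[str]:
    return [f"{letter}{c:02d}" for c in range(lo, hi + 1)]


DEFAULT_CHARLSON: dict[str, dict] = {
    "myocardial_infarction": {"weight": 1, "icd9": ["410", "412"],
                              "icd10": ["I21", "I22", "I25.2"]},
    "congestive_heart_failure": {"weight": 1, "icd9": ["428", "398.91", "402.01",
                                                       "402.11", "402.91"],
                                 "icd10": ["I50", "I09.9", "I11.0", "I13.0", "I13.2"]},
    "peripheral_vascular_disease": {"weight": 1, "icd9": ["440", "441", "443.9", "785.4"],
                                    "icd10": ["I70", "I71", "I73.1", "I73.9"]},
    "cerebrovascular_disease": {"weight": 1, "icd9": _icd9_span(430, 438),
                                "icd10": _icd10_span("I", 60, 69) + ["G45", "G46"]},
    "dementia": {"weight": 1, "icd9": ["290", "294.1", "331.2"],
                 "icd10": ["F00", "F01", "F02", "F03", "G30"]},
    "chronic_pulmonary_disease": {"weight": 1,
                                  "icd9": _icd9_span(490, 496) + _icd9_span(500, 505),
                                  "icd10": _icd10_span("J", 40, 47) + _icd10_span("J", 60, 67)},
    "rheumatic_disease": {"weight": 1,
                          "icd9": ["710.0", "710.1", "710.4", "714.0", "714.1",
                                   "714.2", "725"],
                          "icd10": ["M05", "M06", "M32", "M33", "M34"]},
    "peptic_ulcer_disease": {"weight": 1, "icd9": _icd9_span(531, 534),
                             "icd10": ["K25", "K26", "K27", "K28"]},
    "mild_liver_disease": {"weight": 1, "icd9": ["571.2", "571.4", "571.5", "571.6"],
                           "icd10": ["B18", "K70.3", "K73", "K74"]},
    "diabetes": {"weight": 1,
                 "icd9": ["250.0", "250.1", "250.2", "250.3", "250.8", "250.9"],
                 "icd10": ["E10.0", "E10.1", "E10.9", "E11.0", "E11.1", "E11.9"]},
    "diabetes_with_complications": {"weight": 2,
                                    "icd9": ["250.4", "250.5", "250.6", "250.7"],
                                    "icd10": ["E10.2", "E10.3", "E10.4", "E10.5",
                                              "E11.2", "E11.3", "E11.4", "E11.5"]},
    "hemiplegia": {"weight": 2, "icd9": ["342", "343"], "icd10": ["G81", "G82"]},
    "renal_disease": {"weight": 2, "icd9": ["582", "583", "585", "586", "588"],
                      "icd10": ["N18", "N19", "N03", "N05"]},
    "malignancy": {"weight": 2,
                   "icd9": _icd9_span(140, 172) + _icd9_span(174, 195) + _icd9_span(200, 208),
                   "icd10": _icd10_span("C", 0, 26) + _icd10_span("C", 30, 34)
                            + _icd10_span("C", 37, 41) + ["C43"] + _icd10_span("C", 45, 58)
                            + _icd10_span("C", 60, 76) + _icd10_span("C", 81, 85)
                            + ["C88"] + _icd10_span("C", 90, 97)},
    "moderate_severe_liver_disease": {"weight": 3,
                                      "icd9": ["572.2", "572.3", "572.4", "572.8"],
                                      "icd10": ["K72", "K76.6", "K76.7", "I85"]},
    "metastatic_solid_tumour": {"weight": 6, "icd9": ["196", "197", "198", "199"],
                                "icd10": ["C77", "C78", "C79", "C80"]},
    "aids": {"weight": 6, "icd9": ["042"], "icd10": ["B20", "B21", "B22", "B24"]},
}

# A flagged severe form supersedes its mild counterpart when scoring.
_CHARLSON_HIERARCHY = (
    ("diabetes_with_complications", "diabetes"),
    ("moderate_severe_liver_disease", "mild_liver_disease"),
    ("metastatic_solid_tumour", "malignancy"),
)


def _window_claims(claims: pd.DataFrame, cohort: pd.DataFrame,
                   window_days: int) -> pd.DataFrame:
    """Claims restricted to each cohort member's (index, index+window] window."""
    merged = claims.merge(cohort[["person_id", "index_date"]], on="person_id")
    delta = (merged["service_date"] - merged["index_date"]).dt.days
    return merged[(delta > 0) & (delta <= window_days)]


def _condition_mask(claims: pd.DataFrame, codes: Mapping[str, Sequence[str]]) -> np.ndarray:
    icd9 = (claims["dx_system"] == "icd9").to_numpy()
    icd10 = (claims["dx_system"] == "icd10").to_numpy()
    m = np.zeros(len(claims), dtype=bool)
    if codes.get("icd9"):
        m |= icd9 & startswith_mask(claims["dx_code"], tuple(codes["icd9"]))
    if codes.get("icd10"):
        m |= icd10 & startswith_mask(claims["dx_code"], tuple(codes["icd10"]))
    return m


def flag_comorbidities(claims: pd.DataFrame, cohort: pd.DataFrame,
                       cmap: Optional[dict] = None,
                       window_days: int = 365) -> pd.DataFrame:
    """Per-person condition flags from claims in the year after index.

    Returns a boolean frame indexed by person_id with one column per
    condition; persons may hold several flags per category.
    """
    cmap = cmap if cmap is not None else DEFAULT_COMORBIDITY_MAP
    win = _window_claims(claims, cohort, window_days)
    out = pd.DataFrame(index=pd.Index(cohort["person_id"], name="person_id"))
    for cat, conds in cmap.items():
        for cond, codes in conds.items():
            hit = win.loc[_condition_mask(win, codes), "person_id"].unique()
            out[cond] = out.index.isin(hit)
    return out


def charlson_index(claims: pd.DataFrame, cohort: pd.DataFrame,
                   weights: Optional[dict] = None,
                   window_days: int = 365) -> pd.Series:
    """Charlson comorbidity score per person over the post-index window.

    Sum of weights over distinct flagged conditions; a severe form
    supersedes its mild counterpart (complicated diabetes over diabetes,
    severe over mild liver disease, metastatic disease over malignancy).
    """
    weights = weights if weights is not None else DEFAULT_CHARLSON
    win = _window_claims(claims, cohort, window_days)
    flags = pd.DataFrame(index=pd.Index(cohort["person_id"], name="person_id"))
    for cond, spec in weights.items():
        hit = win.loc[_condition_mask(win, spec), "person_id"].unique()
        flags[cond] = flags.index.isin(hit)
    for severe, mild in _CHARLSON_HIERARCHY:
        if severe in flags and mild in flags:
            flags[mild] &= ~flags[severe]
    w = pd.Series({c: s["weight"] for c, s in weights.items()})
    return (flags * w).sum(axis=1).astype(int).rename("charlson_index")


# ---------------------------------------------------------------------------
# Tests and tabulation


@dataclasses.dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: Optional[float]
    summary: dict
    note: str = ""


def percent(count: int, n: int) -> float:
    """Percentage at one decimal, half-up (tabulation convention)."""
    if n == 0:
        return float("nan")
    return math.floor(100.0 * count / n * 10 + 0.5) / 10


def format_count_percent(count: int, n: int) -> str:
    if count == 0:
        return "0"
    return f"{count} ({percent(count, n):.1f})"


def exact_test_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def two_group_test(group_a, group_b, kind: str, n_a: Optional[int] = None,
                   n_b: Optional[int] = None, equal_var: bool = True) -> TestResult:
    """Compare two groups.

    continuous: ``group_a``/``group_b`` are value vectors; equal-variance
    independent t test (unequal-variance mode available).
    categorical: ``group_a``/``group_b`` are positive counts with group
    sizes ``n_a``/``n_b``; Pearson chi-square, or Fisher exact when any
    expected cell count is < 5.
    """
    if kind == "continuous":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be non-empty")
        summary = {"n": (len(a), len(b)),
                   "mean": (float(a.mean()), float(b.mean())),
                   "sd": (float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                          float(b.std(ddof=1)) if len(b) > 1 else 0.0)}
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                return TestResult("independent_t", 0.0, 1.0, summary,
                                  "zero variance, identical means")
            return TestResult("independent_t", math.inf, None, summary,
                              "zero variance, unequal means")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        return TestResult("independent_t", float(t), float(p), summary)

    if kind == "categorical":
        if n_a is None or n_b is None:
            raise ValueError("categorical tests need group sizes n_a, n_b")
        if n_a == 0 or n_b == 0:
            raise ValueError("both groups must be non-empty")
        ca, cb = int(group_a), int(group_b)
        table = np.array([[ca, n_a - ca], [cb, n_b - cb]])
        summary = {"counts": (ca, cb), "n": (n_a, n_b),
                   "percent": (percent(ca, n_a), percent(cb, n_b))}
        if ca == 0 and cb == 0:
            return TestResult("chi_square", 0.0, None, summary, "no events in either group")
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            p = exact_test_2x2(table)
            return TestResult("fisher_exact", float("nan"), p, summary)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return TestResult("chi_square", float(chi2), float(p), summary)

    raise ValueError(f"unknown kind {kind!r}")


def paired_test(pre_values, post_values) -> TestResult:
    """Paired t test on post - pre differences."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired vectors must have equal length")
    if len(pre) < 2:
        raise ValueError("paired test needs n >= 2")
    diff = post - pre
    summary = {"n": len(diff), "mean_pre": float(pre.mean()),
               "mean_post": float(post.mean()), "mean_diff": float(diff.mean())}
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            return TestResult("paired_t", 0.0, 1.0, summary, "all differences zero")
        return TestResult("paired_t", math.inf, None, summary,
                          "zero-variance non-zero differences")
    t, p = stats.ttest_rel(post, pre)
    return TestResult("paired_t", float(t), float(p), summary)


def tabulate_comorbidities(flags: pd.DataFrame, groups: pd.Series,
                           cmap: Optional[dict] = None,
                           charlson: Optional[pd.Series] = None) -> pd.DataFrame:
    """Two-group comorbidity table: category and condition rows with
    ``n (%)`` per group and a p-value, mirroring the study's layout.

    ``groups`` maps person_id -> {"vitiligo", "control"}; category rows
    count persons with >=1 condition in the category.
    """
    cmap = cmap if cmap is not None else DEFAULT_COMORBIDITY_MAP
    groups = groups.reindex(flags.index)
    in_v = (groups == "vitiligo").to_numpy()
    in_c = (groups == "control").to_numpy()
    n_v, n_c = int(in_v.sum()), int(in_c.sum())
    rows = []

    def add_row(label, level, mask):
        cv = int(mask[in_v].sum())
        cc = int(mask[in_c].sum())
        if n_v and n_c and (cv or cc):
            res = two_group_test(cv, cc, "categorical", n_a=n_v, n_b=n_c)
            pval, test = res.p_value, res.test_name
        else:
            pval, test = None, ""
        rows.append({
            "row": label, "level": level,
            "vitiligo": format_count_percent(cv, n_v) if n_v else "",
            "control": format_count_percent(cc, n_c) if n_c else "",
            "vitiligo_n": cv, "control_n": cc,
            "vitiligo_pct": percent(cv, n_v) if n_v else float("nan"),
            "control_pct": percent(cc, n_c) if n_c else float("nan"),
            "p_value": pval, "test": test,
        })

    for cat, conds in cmap.items():
        names = [c for c in conds if c in flags.columns]
        if not names:
            continue
        add_row(cat, "category", flags[names].any(axis=1).to_numpy())
        for cond in names:
            add_row(cond, "condition", flags[cond].to_numpy())

    out = pd.DataFrame(rows)
    if charlson is not None and n_v and n_c:
        ch = charlson.reindex(flags.index)
        res = two_group_test(ch[in_v], ch[in_c], "continuous")
        out = pd.concat([out, pd.DataFrame([{
            "row": "charlson_index", "level": "continuous",
            "vitiligo": f"{res.summary['mean'][0]:.2f} ({res.summary['sd'][0]:.2f})",
            "control": f"{res.summary['mean'][1]:.2f} ({res.summary['sd'][1]:.2f})",
            "vitiligo_n": n_v, "control_n": n_c,
            "vitiligo_pct": float("nan"), "control_pct": float("nan"),
            "p_value": res.p_value, "test": res.test_name}])],
            ignore_index=True)
    return out


def age_midpoint_summary(persons: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) estimated age per cohort group, using band midpoints."""
    from .codes import band_midpoint
    df = cohort.merge(persons[["person_id", "age_group", "sex"]], on="person_id")
    df["age_est"] = df["age_group"].map(band_midpoint)
    df["coarse_band"] = coarse_band_series(df["age_group"])
    rows = []
    for g, sub in df.groupby("group", observed=True):
        rows.append({"group": g, "n": len(sub),
                     "mean_age": sub["age_est"].mean(),
                     "sd_age": sub["age_est"].std(ddof=1),
                     "pct_female": percent(int((sub["sex"] == "F").sum()), len(sub))})
    return pd.DataFrame(rows)
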