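"""Synthetic public-claims generator.

Emulates the structure of a provincial health-insurer extract (persons with
banded ages and drug-plan coverage intervals, physician medical-service
claims with ICD diagnosis codes, pharmacy dispensation claims) so that every
downstream stage — case ascertainment, matching, treatment episodes,
epidemiology, HCRU/costing — can be exercised and validated without access
to real data.

Disease model
-------------
Treated vitiligo is generated as a chronic condition: a case has an onset
(first qualifying diagnosis) date drawn uniformly over the ascertainment
window, one 709.x (or, configurably, L80.x) diagnosis claim in the onset
year and one in every later calendar year, and dispensation/procedure
records for its assigned treatment classes starting shortly after onset.
Under this model the configured ``treated_vitiligo_prevalence`` equals the
fraction of persons who are active, identifiable cases at the end of the
study, and the implied annual incidence is prevalence divided by the length
of the ascertainment window in years (prevalence = incidence x duration for
a condition that never resolves within the study). Either knob may be given;
if both are given they must agree.

A configurable fraction of non-cases are "decoys" which exercise the
specificity of the case algorithm: some carry 709.x codes with no qualifying
treatment, others carry a qualifying treatment (tacrolimus or phototherapy)
with no 709.x/L80.x code. Decoys are never labelled cases in the truth
table.

Coverage gaps (a mid-study break in drug-plan coverage) are assigned only to
non-case persons: chronically treated patients are modelled as continuously
covered, which also guarantees that a gap can never delete a case's
qualifying claims. All claims fall inside their person's coverage intervals.

Everything is generated with a single ``numpy`` Generator from the config
seed, so identical configs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .codes import FINE_AGE_BANDS, QUALIFYING_TREATMENTS, TREATMENT_CLASSES
from .comorbidity import DEFAULT_CHARLSON, DEFAULT_COMORBIDITY_MAP

# ---------------------------------------------------------------------------
# Defaults (the study conditions the generator emulates)

#: Marginal probability that a case is ever assigned each treatment class.
#: TCS / tacrolimus / phototherapy anchored to the reported treated fractions
#: (69.0% / 42.5% / 33.6%); the remaining classes set to small realistic
#: shares consistent with "few patients were prescribed dexamethasone (n=3)
#: and methotrexate (n=5)" in a 113-case cohort.
DEFAULT_TREATMENT_MIX: dict[str, float] = {
    "TCS": 0.690,
    "tacrolimus": 0.425,
    "pimecrolimus": 0.120,
    "phototherapy": 0.336,
    "prednisone": 0.200,
    "dexamethasone": 0.027,
    "methotrexate": 0.044,
    "cyclosporine": 0.020,
    "calcipotriene": 0.050,
}

#: Per-class dispensation behaviour: mean days supplied per fill, mean gap
#: between fills (days), mean number of fills beyond the first. Phototherapy
#: "fills" are billed sessions (supply 1, ~2 per week).
DEFAULT_DISPENSATION_MODEL: dict[str, tuple[float, float, float]] = {
    "TCS": (30, 45, 4),
    "tacrolimus": (30, 40, 4),
    "pimecrolimus": (30, 40, 3),
    "phototherapy": (1, 3.5, 17),
    "prednisone": (14, 30, 2),
    "dexamethasone": (7, 45, 1),
    "methotrexate": (28, 30, 5),
    "cyclosporine": (28, 30, 4),
    "calcipotriene": (30, 45, 3),
}

#: Annual probability of >=1 coded claim, per comorbid condition; anchored
#: to the non-vitiligo control column of the comorbidity table (a
#: service-active public-plan population).
DEFAULT_COMORBIDITY_RATES: dict[str, float] = {
    "multiple_sclerosis": 0.006,
    "inflammatory_bowel_disease": 0.006,
    "rheumatoid_arthritis": 0.003,
    "myasthenia_gravis": 0.001,
    "systemic_lupus_erythematosus": 0.001,
    "idiopathic_thrombocytopenic_purpura": 0.0005,
    "anxiety": 0.071,
    "depression": 0.041,
    "sleep_disturbances": 0.021,
    "adjustment_disorders": 0.018,
    "schizophrenia": 0.009,
    "personality_disorder": 0.012,
    "childhood_psychiatric_disorders": 0.006,
    "adhd": 0.003,
    "eating_disorders": 0.003,
    "parkinsonism": 0.006,
    "substance_use_disorder": 0.003,
    "conduct_disorder": 0.0005,
    "ocd": 0.0005,
    "hypertension": 0.147,
    "diabetes": 0.068,
    "dyslipidemia": 0.065,
    "obesity": 0.006,
    "thyroid_disorders": 0.024,
    "breast_cancer": 0.009,
    "lymphoma": 0.003,
    "thyroid_cancer": 0.0005,
    "psoriasis": 0.003,
    "acne": 0.006,
    "urticaria": 0.006,
    "atopic_dermatitis": 0.003,
    "herpes_zoster": 0.006,
    # Charlson-scored chronic conditions (not tabulated individually but
    # needed for a realistic comorbidity-severity distribution).
    "myocardial_infarction": 0.010,
    "congestive_heart_failure": 0.025,
    "chronic_pulmonary_disease": 0.060,
    "cerebrovascular_disease": 0.025,
    "renal_disease": 0.015,
    "malignancy": 0.030,
}

#: Per-person-year claim rates by care setting, plus background pharmacy
#: fills of non-vitiligo medication ("other" class). Outpatient anchored to
#: the control-group mean of 5.5 visits/year.
DEFAULT_BACKGROUND_RATES: dict[str, float] = {
    "outpatient": 5.0,
    "ed": 0.22,
    "inpatient": 0.08,
    "other": 0.30,
    "pharmacy": 3.0,
}

#: Public-drug-plan-like age mix, skewed toward 65+ (universal coverage at
#: that age). One weight per fine band, summing to 1.
DEFAULT_AGE_GROUP_WEIGHTS: tuple[float, ...] = (
    0.008, 0.030, 0.038, 0.040, 0.042, 0.055, 0.060, 0.060, 0.058, 0.055,
    0.055, 0.058, 0.060, 0.062, 0.080, 0.075, 0.065, 0.050, 0.049,
)

DEFAULT_REGIONS: dict[str, float] = {
    "montreal": 0.30, "monteregie": 0.17, "capitale-nationale": 0.12,
    "laurentides": 0.09, "lanaudiere": 0.07, "other": 0.25,
}

# Benign background diagnosis pool: deliberately disjoint from the vitiligo
# codes, the comorbidity map and the Charlson ranges.
_BACKGROUND_DX = ("460", "466.0", "486", "524.60", "558.9", "599.0",
                  "724.2", "729.5", "780.99", "786.50")

_VITILIGO_DX9 = ("709.00", "709.01", "709.09", "709.1", "709.9")


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic population and its claims."""

    model_config = ConfigDict(frozen=True)

    n_persons: int = Field(gt=0)
    seed: int = 0
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2019, 12, 31)
    #: end of the case-ascertainment window (diagnoses after it never found).
    case_window_end: date = date(2019, 9, 30)
    treated_vitiligo_prevalence: Optional[float] = 0.0009
    annual_incidence: Optional[float] = None
    #: fraction of cases identified via ICD-10 L80.x instead of ICD-9 709.x.
    icd10_case_fraction: float = 0.0
    decoy_dx_rate: float = 0.01
    decoy_treatment_rate: float = 0.005
    female_fraction: float = 0.5
    age_group_weights: tuple[float, ...] = DEFAULT_AGE_GROUP_WEIGHTS
    region_weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_REGIONS))
    treatment_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TREATMENT_MIX))
    dispensation_model: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_DISPENSATION_MODEL))
    comorbidity_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_RATES))
    background_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_RATES))
    coverage_gap_rate: float = 0.05
    #: extra per-person-year claim rate after onset, by setting — used to
    #: inject a known post-index utilization shift for recovery studies.
    post_index_rate_shift: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if not self.study_start < self.case_window_end <= self.study_end:
            raise ValueError("case_window_end must lie inside the study period")
        for name in ("icd10_case_fraction", "decoy_dx_rate", "decoy_treatment_rate",
                     "female_fraction", "coverage_gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for k, v in self.treatment_mix.items():
            if k not in TREATMENT_CLASSES:
                raise ValueError(f"unknown treatment class {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError("treatment_mix probabilities must be in [0, 1]")
        if not any(self.treatment_mix.get(c, 0) > 0 for c in QUALIFYING_TREATMENTS):
            raise ValueError("treatment_mix must give positive mass to a qualifying class")
        for k, v in self.comorbidity_rates.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"comorbidity rate for {k} must be in [0, 1)")
        if abs(sum(self.age_group_weights) - 1.0) > 1e-9 or len(self.age_group_weights) != len(FINE_AGE_BANDS):
            raise ValueError("age_group_weights must be one weight per fine band, summing to 1")
        p = self.case_probability()
        if not 0.0 <= p <= 1.0:
            raise ValueError("implied case probability outside [0, 1]")
        return self

    def window_years(self) -> float:
        return ((self.case_window_end - self.study_start).days + 1) / 365.25

    def case_probability(self) -> float:
        """Fraction of persons generated as cases.

        prevalence = incidence x window length (chronic-disease identity);
        whichever knob is given determines the other.
        """
        prev, inc = self.treated_vitiligo_prevalence, self.annual_incidence
        if prev is None and inc is None:
            return 0.0
        if prev is not None and inc is not None:
            if abs(prev - inc * self.window_years()) > 1e-9:
                raise ValueError(
                    "treated_vitiligo_prevalence and annual_incidence are inconsistent; "
                    "set one and leave the other None")
            return prev
        return prev if prev is not None else inc * self.window_years()


@dataclasses.dataclass
class ClaimsDataset:
    """A generated dataset plus its ground truth.

    ``truth`` holds one row per person (is_case, true index date, assigned
    treatment classes, decoy type); ``truth_comorbidities`` the injected
    comorbid conditions in long form.
    """

    persons: pd.DataFrame
    medical_claims: pd.DataFrame
    pharmacy_claims: pd.DataFrame
    coverage: pd.DataFrame
    truth: pd.DataFrame
    truth_comorbidities: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(outdir / "persons.csv", index=False)
        self.medical_claims.to_csv(outdir / "medical_claims.csv", index=False)
        self.pharmacy_claims.to_csv(outdir / "pharmacy_claims.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.truth_comorbidities.to_csv(outdir / "truth_comorbidities.csv", index=False)


def parse_coverage(persons: pd.DataFrame) -> pd.DataFrame:
    """Expand the persons table's ``coverage_intervals`` strings.

    The string format is ``start..end`` with ``;`` between intervals
    (ISO-8601 dates). Returns one row per interval: person_id, cov_start,
    cov_end.
    """
    rows = persons["coverage_intervals"].str.split(";")
    pid = persons["person_id"].to_numpy().repeat(rows.str.len().to_numpy())
    flat = np.concatenate(rows.to_numpy())
    start = pd.to_datetime([s[:10] for s in flat])
    end = pd.to_datetime([s[12:] for s in flat])
    return pd.DataFrame({"person_id": pid, "cov_start": start, "cov_end": end})


def load_dataset(indir: str | Path) -> ClaimsDataset:
    """Read a dataset directory written by :meth:`ClaimsDataset.write`."""
    indir = Path(indir)
    persons = pd.read_csv(indir / "persons.csv")
    med = pd.read_csv(indir / "medical_claims.csv",
                      parse_dates=["service_date"], keep_default_na=False,
                      dtype={"dx_code": str, "procedure_flag": str})
    rx = pd.read_csv(indir / "pharmacy_claims.csv", parse_dates=["dispense_date"])
    truth_p = indir / "truth.csv"
    truth = pd.read_csv(truth_p) if truth_p.exists() else pd.DataFrame()
    tc_p = indir / "truth_comorbidities.csv"
    tcom = pd.read_csv(tc_p) if tc_p.exists() else pd.DataFrame()
    return ClaimsDataset(persons, med, rx, parse_coverage(persons), truth, tcom)


# ---------------------------------------------------------------------------
# Generation internals. All dates are int day offsets from study_start until
# final table assembly.


def _grouped_cumsum(values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each group boundary (groups given by
    consecutive run lengths)."""
    if len(values) == 0:
        return values
    c = np.cumsum(values)
    first = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    # values at group-first positions are already absolute offsets (0)
    base = c[first] - values[first]
    return c - np.repeat(base, lengths)


def _year_boundaries(start: date, end: date) -> tuple[np.ndarray, np.ndarray]:
    years = np.arange(start.year, end.year + 1)
    starts = np.array([(date(y, 1, 1) - start).days for y in years])
    starts[0] = 0
    lengths = np.diff(np.append(starts, (end - start).days + 1))
    return years, starts


class _Tables:
    """Accumulators for claim rows (plain array columns)."""

    def __init__(self):
        self.med: list[dict] = []
        self.rx: list[dict] = []

    def add_medical(self, pidx, day, dx, system, setting, specialty, proc, fee):
        n = len(pidx)
        if n:
            self.med.append(dict(pidx=pidx, day=day, dx=dx, system=system,
                                 setting=setting, specialty=specialty,
                                 proc=proc, fee=fee))

    def add_pharmacy(self, pidx, day, cls, supply, cost):
        if len(pidx):
            self.rx.append(dict(pidx=pidx, day=day, cls=cls, supply=supply, cost=cost))


# Emitted code per condition: the first ICD-9 prefix of its map entry,
# except where a more specific code keeps the comorbidity map and the
# Charlson algorithm consistent (250.00 flags both).
_EMITTED_CODE_OVERRIDES = {"diabetes": "250.00"}


def _first_icd9(condition: str) -> str:
    if condition in _EMITTED_CODE_OVERRIDES:
        return _EMITTED_CODE_OVERRIDES[condition]
    for _cat, conds in DEFAULT_COMORBIDITY_MAP.items():
        if condition in conds:
            return conds[condition]["icd9"][0]
    if condition in DEFAULT_CHARLSON:
        return DEFAULT_CHARLSON[condition]["icd9"][0]
    raise KeyError(f"no ICD-9 code known for condition {condition!r}")


def generate_dataset(config: GeneratorConfig) -> ClaimsDataset:
    """Generate persons, medical claims, pharmacy claims and ground truth.

    Deterministic for a fixed config (single seeded Generator; stable
    sorts). Cases always carry >=1 qualifying diagnosis claim and >=1
    qualifying treatment record inside the ascertainment window; decoys
    carry exactly one side of the conjunction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    D = (config.study_end - config.study_start).days + 1
    W = (config.case_window_end - config.study_start).days
    years_full = D / 365.25
    years_vec, year_starts = _year_boundaries(config.study_start, config.study_end)
    year_lengths = np.diff(np.append(year_starts, D))

    # --- persons -----------------------------------------------------------
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age_idx = rng.choice(len(FINE_AGE_BANDS), size=n, p=np.asarray(config.age_group_weights))
    region_names = list(config.region_weights)
    rw = np.asarray(list(config.region_weights.values()), dtype=float)
    region_idx = rng.choice(len(region_names), size=n, p=rw / rw.sum())

    p_case = config.case_probability()
    is_case = rng.random(n) < p_case
    u = rng.random(n)
    decoy_dx = ~is_case & (u < config.decoy_dx_rate)
    decoy_rx = ~is_case & ~decoy_dx & (u < config.decoy_dx_rate + config.decoy_treatment_rate)

    onset = np.full(n, -1, dtype=np.int64)
    case_idx = np.nonzero(is_case)[0]
    m = len(case_idx)
    onset[case_idx] = rng.integers(0, W + 1, m)

    # Coverage gaps: non-cases only (see module docstring).
    gap_draw = rng.random(n)
    gap_len = rng.integers(30, 366, n)
    gap_start = rng.integers(0, np.maximum(1, D - gap_len))
    has_gap = ~is_case & (gap_draw < config.coverage_gap_rate)
    gap_start = np.where(has_gap, gap_start, -1)
    gap_end = np.where(has_gap, gap_start + gap_len, -1)  # exclusive

    def drop_in_gap(pidx: np.ndarray, day: np.ndarray) -> np.ndarray:
        keep = ~((gap_start[pidx] >= 0) & (day >= gap_start[pidx]) & (day < gap_end[pidx]))
        return keep & (day >= 0) & (day < D)

    T = _Tables()
    bg = config.background_rates

    # --- background medical claims ----------------------------------------
    n_bg_dx = len(_BACKGROUND_DX)
    for setting in ("outpatient", "ed", "other"):
        rate = bg.get(setting, 0.0)
        if rate <= 0:
            continue
        counts = rng.poisson(rate * years_full, n)
        pidx = np.repeat(np.arange(n), counts)
        day = rng.integers(0, D, len(pidx))
        keep = drop_in_gap(pidx, day)
        pidx, day = pidx[keep], day[keep]
        dx = rng.integers(0, n_bg_dx, len(pidx))
        spec = rng.choice(3, size=len(pidx), p=(0.70, 0.03, 0.27))  # gp/derm/other
        fee = np.round(rng.gamma(2.0, 35.0, len(pidx)), 2)
        T.add_medical(pidx, day, dx, None, setting, spec, None, fee)

    # inpatient stays: an admission emits 1 + Poisson(0.8) claims spread
    # over the stay, so the <=7-day chaining rule has something to merge.
    rate = bg.get("inpatient", 0.0)
    if rate > 0:
        ev_counts = rng.poisson(rate * years_full, n)
        ev_p = np.repeat(np.arange(n), ev_counts)
        ev_day = rng.integers(0, D, len(ev_p))
        stay = 1 + rng.poisson(4.0, len(ev_p))
        ncl = 1 + rng.poisson(0.8, len(ev_p))
        pidx = np.repeat(ev_p, ncl)
        base = np.repeat(ev_day, ncl)
        off = rng.integers(0, np.repeat(stay, ncl))
        day = base + off
        keep = drop_in_gap(pidx, day)
        pidx, day = pidx[keep], day[keep]
        dx = rng.integers(0, n_bg_dx, len(pidx))
        spec = rng.choice(3, size=len(pidx), p=(0.45, 0.02, 0.53))
        fee = np.round(rng.gamma(2.0, 120.0, len(pidx)), 2)
        T.add_medical(pidx, day, dx, None, "inpatient", spec, None, fee)

    # injected post-onset utilization shift (cases only)
    for setting, extra in config.post_index_rate_shift.items():
        if extra <= 0 or m == 0:
            continue
        exposure = (D - onset[case_idx]) / 365.25
        counts = rng.poisson(extra * exposure)
        pidx = np.repeat(case_idx, counts)
        span = np.repeat(D - onset[case_idx], counts)
        day = np.repeat(onset[case_idx], counts) + rng.integers(
            1, np.maximum(2, span))
        keep = (day >= 0) & (day < D)
        pidx, day = pidx[keep], day[keep]
        dx = rng.integers(0, n_bg_dx, len(pidx))
        spec = rng.choice(3, size=len(pidx), p=(0.70, 0.03, 0.27))
        fee = np.round(rng.gamma(2.0, 35.0, len(pidx)), 2)
        T.add_medical(pidx, day, dx, None, setting, spec, None, fee)

    # --- comorbidity claims ------------------------------------------------
    comorb_rows_p, comorb_rows_c = [], []
    cond_names = list(config.comorbidity_rates)
    for ci, cond in enumerate(cond_names):
        p_ann = config.comorbidity_rates[cond]
        lam = -np.log1p(-p_ann) * years_full  # P(>=1 claim per year) == p_ann
        counts = rng.poisson(lam, n)
        pidx = np.repeat(np.arange(n), counts)
        day = rng.integers(0, D, len(pidx))
        keep = drop_in_gap(pidx, day)
        pidx, day = pidx[keep], day[keep]
        spec = rng.choice(3, size=len(pidx), p=(0.75, 0.02, 0.23))
        fee = np.round(rng.gamma(2.0, 40.0, len(pidx)), 2)
        T.add_medical(pidx, day, np.full(len(pidx), -(ci + 1)), None,
                      "outpatient", spec, None, fee)
        comorb_rows_p.append(np.unique(pidx))
        comorb_rows_c.append(ci)

    # --- case diagnosis claims --------------------------------------------
    is_l80 = np.zeros(m, dtype=bool)
    if m:
        is_l80 = rng.random(m) < config.icd10_case_fraction
        onset_c = onset[case_idx]
        onset_year = np.searchsorted(year_starts, onset_c, side="right") - 1
        last_year = len(years_vec) - 1
        # one claim at onset...
        dx9 = rng.integers(0, len(_VITILIGO_DX9), m)
        T.add_medical(case_idx, onset_c, np.where(is_l80, -1000, 1000 + dx9),
                      None, "outpatient",
                      rng.choice(3, size=m, p=(0.35, 0.60, 0.05)), None,
                      np.round(rng.gamma(2.0, 45.0, m), 2))
        # ...and one per later calendar year (chronic follow-up)
        n_after = last_year - onset_year
        grp = np.repeat(np.arange(m), n_after)
        k = _grouped_cumsum(np.ones(len(grp), dtype=np.int64), n_after[n_after > 0]) if len(grp) else grp
        yr = onset_year[grp] + k
        day = year_starts[yr] + rng.integers(0, year_lengths[yr])
        pidx = case_idx[grp]
        dx9y = rng.integers(0, len(_VITILIGO_DX9), len(pidx))
        T.add_medical(pidx, day, np.where(is_l80[grp], -1000, 1000 + dx9y),
                      None, "outpatient",
                      rng.choice(3, size=len(pidx), p=(0.35, 0.60, 0.05)), None,
                      np.round(rng.gamma(2.0, 45.0, len(pidx)), 2))

    # decoy diagnosis-only persons: 1-3 709.x claims, no qualifying treatment
    d_idx = np.nonzero(decoy_dx)[0]
    if len(d_idx):
        ncl = rng.integers(1, 4, len(d_idx))
        pidx = np.repeat(d_idx, ncl)
        day = rng.integers(0, W + 1, len(pidx))
        keep = drop_in_gap(pidx, day)
        pidx, day = pidx[keep], day[keep]
        dx9d = rng.integers(0, len(_VITILIGO_DX9), len(pidx))
        T.add_medical(pidx, day, 1000 + dx9d, None, "outpatient",
                      rng.choice(3, size=len(pidx), p=(0.55, 0.40, 0.05)), None,
                      np.round(rng.gamma(2.0, 45.0, len(pidx)), 2))

    # --- treatments --------------------------------------------------------
    mix = np.array([config.treatment_mix.get(c, 0.0) for c in TREATMENT_CLASSES])
    qual_cols = np.array([c in QUALIFYING_TREATMENTS for c in TREATMENT_CLASSES])
    assigned = np.zeros((m, len(TREATMENT_CLASSES)), dtype=bool)
    if m:
        assigned = rng.random((m, len(TREATMENT_CLASSES))) < mix
        # every case must hold >=1 qualifying treatment (algorithm premise)
        missing = ~assigned[:, qual_cols].any(axis=1)
        if missing.any():
            qp = mix[qual_cols] / mix[qual_cols].sum()
            forced = rng.choice(np.nonzero(qual_cols)[0], size=missing.sum(), p=qp)
            assigned[np.nonzero(missing)[0], forced] = True

    def _emit_treatment(pids: np.ndarray, class_i: int, start_day: np.ndarray):
        """Refill chains for one treatment class (vectorized over persons)."""
        cls = TREATMENT_CLASSES[class_i]
        supply_mu, refill_mu, n_mu = config.dispensation_model[cls]
        nfill = 1 + rng.poisson(n_mu, len(pids))
        pidx = np.repeat(pids, nfill)
        iv = np.maximum(1, np.round(rng.exponential(refill_mu, len(pidx)))).astype(np.int64)
        # first fill of each chain sits at start_day
        first = np.concatenate(([0], np.cumsum(nfill)[:-1]))
        iv[first] = 0
        day = np.repeat(start_day, nfill) + _grouped_cumsum(iv, nfill)
        supply = np.maximum(1, rng.poisson(supply_mu, len(pidx))).astype(np.int64)
        keep = (day >= 0) & (day < D)
        # decoy-treatment persons can have gaps; their claims must respect them
        keep &= drop_in_gap(pidx, day)
        # chains are emitted in order, but guarantee the chain's first fill
        # survives for cases (gap-free by construction, so always true).
        pidx, day, supply = pidx[keep], day[keep], supply[keep]
        if cls == "phototherapy":
            spec = np.full(len(pidx), 1)  # dermatologist-administered
            fee = np.round(rng.gamma(2.0, 30.0, len(pidx)), 2)
            T.add_medical(pidx, day, np.full(len(pidx), -2000), None,
                          "outpatient", spec, 1, fee)
        else:
            cost = np.round(rng.gamma(2.0, 18.0, len(pidx)), 2)
            T.add_pharmacy(pidx, day, np.full(len(pidx), class_i), supply, cost)

    for ci in range(len(TREATMENT_CLASSES)):
        who = np.nonzero(assigned[:, ci])[0]
        if len(who) == 0:
            continue
        pids = case_idx[who]
        # first fill 0-120 days after onset, but never past the
        # ascertainment window end (a case must be identifiable)
        start = np.minimum(onset[pids] + rng.integers(0, 121, len(pids)), W)
        _emit_treatment(pids, ci, start)

    # decoy treatment-only persons: short tacrolimus run or phototherapy
    r_idx = np.nonzero(decoy_rx)[0]
    if len(r_idx):
        half = rng.random(len(r_idx)) < 0.5
        start = rng.integers(0, W + 1, len(r_idx))
        tac = r_idx[half]
        if len(tac):
            _emit_treatment(tac, TREATMENT_CLASSES.index("tacrolimus"), start[half])
        pho = r_idx[~half]
        if len(pho):
            _emit_treatment(pho, TREATMENT_CLASSES.index("phototherapy"), start[~half])

    # --- background pharmacy ----------------------------------------------
    rate = bg.get("pharmacy", 0.0)
    if rate > 0:
        counts = rng.poisson(rate * years_full, n)
        pidx = np.repeat(np.arange(n), counts)
        day = rng.integers(0, D, len(pidx))
        keep = drop_in_gap(pidx, day)
        pidx, day = pidx[keep], day[keep]
        supply = rng.choice(np.array([30, 60, 90]), size=len(pidx), p=(0.5, 0.3, 0.2))
        cost = np.round(rng.gamma(2.0, 15.0, len(pidx)), 2)
        T.add_pharmacy(pidx, day, np.full(len(pidx), -1), supply, cost)

    # --- assemble tables ----------------------------------------------------
    # dx encoding used while accumulating: j in [0, len(pool)): background
    # pool; 1000+j: vitiligo ICD-9 pool; -1000: L80; -2000: procedure (blank
    # dx); -(ci+1): comorbid condition ci. Decoded once via a lookup table.
    d0_64 = np.datetime64(config.study_start)

    def to_dates(day: np.ndarray):
        return (d0_64 + day.astype("timedelta64[D]")).astype("datetime64[ns]")

    dx_cats: list[str] = []
    _cat_index: dict[str, int] = {}

    def _cat_of(code_str: str) -> int:
        if code_str not in _cat_index:
            _cat_index[code_str] = len(dx_cats)
            dx_cats.append(code_str)
        return _cat_index[code_str]

    ENC_OFFSET = 2000
    lut = np.full(ENC_OFFSET + 1000 + len(_VITILIGO_DX9) + 1, -1, dtype=np.int32)
    for j, c in enumerate(_BACKGROUND_DX):
        lut[ENC_OFFSET + j] = _cat_of(c)
    for j, c in enumerate(_VITILIGO_DX9):
        lut[ENC_OFFSET + 1000 + j] = _cat_of(c)
    lut[ENC_OFFSET - 1000] = _cat_of("L80")
    lut[ENC_OFFSET - 2000] = _cat_of("")
    for ci, cond in enumerate(cond_names):
        lut[ENC_OFFSET - (ci + 1)] = _cat_of(_first_icd9(cond))

    SETTING_NAMES = ("outpatient", "ed", "inpatient", "other")
    set_id = {s: i for i, s in enumerate(SETTING_NAMES)}
    spec_names = ("general_practitioner", "dermatologist", "other")

    if T.med:
        pidx = np.concatenate([np.asarray(p["pidx"]) for p in T.med])
        day = np.concatenate([np.asarray(p["day"]) for p in T.med])
        dx = np.concatenate([np.asarray(p["dx"], dtype=np.int64) for p in T.med])
        setg = np.concatenate([np.full(len(p["pidx"]), set_id[p["setting"]], np.int8)
                               for p in T.med])
        specl = np.concatenate([np.asarray(p["specialty"], dtype=np.int8) for p in T.med])
        proc = np.concatenate([np.full(len(p["pidx"]), 1 if p["proc"] == 1 else 0, np.int8)
                               for p in T.med])
        fee = np.concatenate([np.asarray(p["fee"]) for p in T.med])
        # (person, day) order; ties keep emission order (stable, seeded)
        order = np.argsort((pidx << 13) | day, kind="stable")
        pidx, day, dx = pidx[order], day[order], dx[order]
        setg, specl, proc, fee = setg[order], specl[order], proc[order], fee[order]
        medical = pd.DataFrame({
            "person_id": pidx + 1,
            "service_date": to_dates(day),
            "dx_code": pd.Categorical.from_codes(lut[dx + ENC_OFFSET], categories=dx_cats),
            "dx_system": pd.Categorical.from_codes(
                (dx == -1000).astype(np.int8), categories=["icd9", "icd10"]),
            "setting": pd.Categorical.from_codes(setg, categories=list(SETTING_NAMES)),
            "specialty": pd.Categorical.from_codes(specl, categories=list(spec_names)),
            "procedure_flag": pd.Categorical.from_codes(proc, categories=["", "phototherapy"]),
            "fee": fee,
        })
    else:
        medical = pd.DataFrame(columns=["person_id", "service_date", "dx_code",
                                        "dx_system", "setting", "specialty",
                                        "procedure_flag", "fee"])

    class_names = ["other"] + list(TREATMENT_CLASSES)
    if T.rx:
        pidx = np.concatenate([np.asarray(p["pidx"]) for p in T.rx])
        day = np.concatenate([np.asarray(p["day"]) for p in T.rx])
        cls = np.concatenate([np.asarray(p["cls"], dtype=np.int16) for p in T.rx])
        supply = np.concatenate([np.asarray(p["supply"], dtype=np.int64) for p in T.rx])
        cost = np.concatenate([np.asarray(p["cost"]) for p in T.rx])
        order = np.argsort((pidx << 13) | day, kind="stable")
        pidx, day, cls = pidx[order], day[order], cls[order]
        supply, cost = supply[order], cost[order]
        pharmacy = pd.DataFrame({
            "person_id": pidx + 1,
            "dispense_date": to_dates(day),
            "treatment_class": pd.Categorical.from_codes(
                (cls + 1).astype(np.int16), categories=class_names),
            "days_supply": supply,
            "cost": cost,
        })
    else:
        pharmacy = pd.DataFrame(columns=["person_id", "dispense_date",
                                         "treatment_class", "days_supply", "cost"])

    # persons + coverage ----------------------------------------------------
    d0 = np.datetime64(config.study_start)
    full_end = np.datetime64(config.study_end)

    def dstr(days: np.ndarray) -> np.ndarray:
        return np.datetime_as_string((d0 + days.astype("timedelta64[D]")), unit="D")

    cov_strings = np.empty(n, dtype=object)
    full = f"{config.study_start.isoformat()}..{config.study_end.isoformat()}"
    cov_strings[:] = full
    gap_idx = np.nonzero(has_gap)[0]
    cov_rows = [pd.DataFrame({"person_id": np.arange(n)[~has_gap] + 1,
                              "cov_start": pd.Timestamp(config.study_start),
                              "cov_end": pd.Timestamp(config.study_end)})]
    if len(gap_idx):
        gs, ge = gap_start[gap_idx], gap_end[gap_idx]
        s1 = dstr(np.zeros(len(gap_idx), dtype=np.int64))
        e1 = dstr(gs - 1)
        s2 = dstr(ge)
        e2 = np.full(len(gap_idx), str(full_end))
        first_ok = gs > 0
        second_ok = ge <= (config.study_end - config.study_start).days
        both = first_ok & second_ok
        cov_strings[gap_idx[both]] = [f"{a}..{b};{c}..{d}" for a, b, c, d in
                                      zip(s1[both], e1[both], s2[both], e2[both])]
        only1 = first_ok & ~second_ok
        cov_strings[gap_idx[only1]] = [f"{a}..{b}" for a, b in zip(s1[only1], e1[only1])]
        only2 = ~first_ok & second_ok
        cov_strings[gap_idx[only2]] = [f"{c}..{d}" for c, d in zip(s2[only2], e2[only2])]
        for mask_, ss, ee in ((both, s1, e1), (only1, s1, e1), (only2, s2, e2)):
            if mask_.any():
                cov_rows.append(pd.DataFrame({
                    "person_id": gap_idx[mask_] + 1,
                    "cov_start": pd.to_datetime(ss[mask_]),
                    "cov_end": pd.to_datetime(ee[mask_])}))
        if both.any():
            cov_rows.append(pd.DataFrame({
                "person_id": gap_idx[both] + 1,
                "cov_start": pd.to_datetime(s2[both]),
                "cov_end": pd.to_datetime(e2[both])}))

    coverage = pd.concat(cov_rows, ignore_index=True).sort_values(
        ["person_id", "cov_start"], kind="stable").reset_index(drop=True)

    persons = pd.DataFrame({
        "person_id": np.arange(n) + 1,
        "sex": sex,
        "age_group": np.array(FINE_AGE_BANDS, dtype=object)[age_idx],
        "region": np.array(region_names, dtype=object)[region_idx],
        "coverage_intervals": cov_strings,
    })

    # truth ------------------------------------------------------------------
    tx_labels = np.full(n, "", dtype=object)
    if m:
        cls_arr = np.array(TREATMENT_CLASSES, dtype=object)
        tx_labels[case_idx] = [";".join(cls_arr[row]) for row in assigned]
    decoy_type = np.full(n, "", dtype=object)
    decoy_type[decoy_dx] = "dx_only"
    decoy_type[decoy_rx] = "treatment_only"
    index_date = np.full(n, "", dtype=object)
    if m:
        index_date[case_idx] = dstr(onset[case_idx])
    truth = pd.DataFrame({
        "person_id": np.arange(n) + 1,
        "is_case": is_case,
        "index_date": index_date,
        "treatment_classes": tx_labels,
        "decoy_type": decoy_type,
    })

    if comorb_rows_p:
        tcom = pd.concat([pd.DataFrame({"person_id": p + 1,
                                        "condition": cond_names[c]})
                          for p, c in zip(comorb_rows_p, comorb_rows_c)],
                         ignore_index=True)
        tcom = tcom.sort_values(["person_id", "condition"], kind="stable").reset_index(drop=True)
    else:
        tcom = pd.DataFrame(columns=["person_id", "condition"])

    return ClaimsDataset(persons, medical, pharmacy, coverage, truth, tcom)
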