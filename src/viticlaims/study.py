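"""End-to-end study orchestration and report bundle.

``run_study`` composes the pipeline on a dataset directory (or in-memory
dataset): cohort construction, comorbidity table, incidence/prevalence
series, treatment patterns, HCRU/cost summaries and pre/post comparisons,
mirroring the structure of a claims burden-of-illness study report. The
bundle is deterministic for a fixed config and is written as delimited text
files plus a JSON manifest (seed, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .codes import TREATMENT_CLASSES
from .cohort import CohortResult, build_cohort
from .comorbidity import (age_midpoint_summary, charlson_index,
                          flag_comorbidities, paired_test,
                          tabulate_comorbidities, two_group_test)
from .epidemiology import (all_services, case_diagnosis_dates, incidence_series,
                           point_prevalence)
from .hcru import (UnitCostTable, annualized_hcru, summarize_hcru,
                   window_comparison)
from .synthetic import ClaimsDataset, load_dataset
from .treatment import (adherence_table, build_episodes, concomitant_pairs,
                        persistence_and_discontinuation, seasonality_profile,
                        sequence_table, treatment_records)


class StudyConfig(BaseModel):
    """Study parameters (defaults follow the reference design: 90-day gap,
    1:3 matching, 365-day windows, 80% MPR threshold)."""

    data_dir: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    gap_days: int = 90
    match_ratio: int = 3
    window_days: int = 365
    mpr_threshold: float = 0.80
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2019, 12, 31)
    case_window_end: date = date(2019, 9, 30)
    activity_start: date = date(2018, 1, 1)
    prevalence_as_of: date = date(2019, 12, 31)
    target_population: Optional[int] = None
    unit_costs: dict = Field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclasses.dataclass
class StudyReport:
    """Tabular outputs of one study run."""

    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    demographics: pd.DataFrame
    table1: pd.DataFrame
    epi: pd.DataFrame
    treatment_distribution: pd.DataFrame
    episode_histogram: pd.DataFrame
    sequences: pd.DataFrame
    concomitance: pd.DataFrame
    adherence: pd.DataFrame
    persistence: pd.DataFrame
    seasonality: pd.DataFrame
    hcru_summary: pd.DataFrame
    hcru_tests: pd.DataFrame
    prepost_index: pd.DataFrame
    prepost_treatment: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self) if f.name != "manifest"}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(outdir / f"{name}.csv", index=isinstance(df.index, pd.MultiIndex)
                      or df.index.name is not None)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _paired_rows(comparison: pd.DataFrame, label: str) -> pd.DataFrame:
    rows = []
    if comparison.empty:
        return pd.DataFrame(columns=["window", "measure", "n", "mean_pre",
                                     "mean_post", "t", "p_value", "note"])
    measures = sorted({c[4:] for c in comparison.columns if c.startswith("pre_")})
    for m in measures:
        pre, post = comparison[f"pre_{m}"], comparison[f"post_{m}"]
        if len(pre) < 2:
            continue
        res = paired_test(pre, post)
        rows.append({"window": label, "measure": m, "n": res.summary["n"],
                     "mean_pre": res.summary["mean_pre"],
                     "mean_post": res.summary["mean_post"],
                     "t": res.statistic, "p_value": res.p_value, "note": res.note})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig,
              dataset: Optional[ClaimsDataset] = None) -> StudyReport:
    """Run the full study; deterministic for a fixed config + dataset."""
    if dataset is None:
        if config.data_dir is None:
            raise ValueError("either a dataset or config.data_dir is required")
        dataset = load_dataset(config.data_dir)

    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    case_window = (study_start, pd.Timestamp(config.case_window_end))
    activity_window = (pd.Timestamp(config.activity_start), study_end)
    unit_costs = UnitCostTable(**config.unit_costs) if config.unit_costs else UnitCostTable()

    med, rx = dataset.medical_claims, dataset.pharmacy_claims
    persons, coverage = dataset.persons, dataset.coverage

    res: CohortResult = build_cohort(persons, med, rx, coverage, study_end,
                                     ratio=config.match_ratio, seed=config.seed,
                                     case_window=case_window,
                                     activity_window=activity_window)
    cohort = res.cohort
    cases = cohort[cohort["group"] == "vitiligo"]
    if cases.empty:
        warnings.warn("no vitiligo cases identified; case-only tables are empty")

    groups = cohort.set_index("person_id")["group"]
    follow_up = cohort.set_index("person_id")["follow_up_end"]

    # comorbidities ---------------------------------------------------------
    flags = flag_comorbidities(med, cohort, window_days=config.window_days)
    charlson = charlson_index(med, cohort, window_days=config.window_days)
    table1 = tabulate_comorbidities(flags, groups, charlson=charlson)
    demographics = age_midpoint_summary(persons, cohort)

    # epidemiology ----------------------------------------------------------
    case_dx = case_diagnosis_dates(med, rx, window=case_window)
    years = list(range(config.study_start.year + 1, config.study_end.year + 1))
    epi_inc = incidence_series(case_dx, coverage, years, persons=persons,
                               by=("sex", "coarse_band"),
                               target_population=config.target_population)
    epi_prev = point_prevalence(case_dx, all_services(med, rx), coverage,
                                config.prevalence_as_of, study_start=study_start,
                                persons=persons, by=("sex", "coarse_band"),
                                target_population=config.target_population)
    epi = pd.concat([epi_inc, epi_prev], ignore_index=True)

    # treatment patterns (cases, post-index records) ------------------------
    case_ids = set(cases["person_id"])
    recs = treatment_records(rx, med)
    recs = recs[recs["person_id"].isin(case_ids)
                & recs["treatment_class"].isin(TREATMENT_CLASSES)]
    idx_map = cases.set_index("person_id")["index_date"]
    recs = recs[recs["start_date"] >= recs["person_id"].map(idx_map)]
    episodes = build_episodes(recs, gap_days=config.gap_days)

    n_cases = len(cases)
    dist_rows = []
    for cls in TREATMENT_CLASSES:
        treated = episodes.loc[episodes["treatment_class"] == cls, "person_id"].nunique()
        dist_rows.append({"treatment_class": cls, "n_patients": treated,
                          "pct_patients": 100.0 * treated / n_cases if n_cases else float("nan")})
    treatment_distribution = pd.DataFrame(dist_rows)

    ep_counts = episodes.groupby("person_id").size() if len(episodes) else pd.Series(dtype=int)
    ep_counts = ep_counts.reindex(cases["person_id"], fill_value=0)
    hist = {"0": int((ep_counts == 0).sum()), "1": int((ep_counts == 1).sum()),
            "2": int((ep_counts == 2).sum()), "3": int((ep_counts == 3).sum()),
            ">=4": int((ep_counts >= 4).sum())}
    episode_histogram = pd.DataFrame(
        [{"episodes": k, "n_patients": v,
          "pct_patients": 100.0 * v / n_cases if n_cases else float("nan")}
         for k, v in hist.items()])

    seqs = sequence_table(episodes, cases["person_id"])
    seq_freq = (seqs.groupby("sequence").size().rename("n_patients")
                .sort_values(ascending=False).reset_index())
    seq_freq["pct_patients"] = 100.0 * seq_freq["n_patients"] / n_cases if n_cases else float("nan")

    conc_parts = []
    for pid, sub in episodes.groupby("person_id"):
        p = concomitant_pairs(sub)
        if len(p):
            p.insert(0, "person_id", pid)
            conc_parts.append(p)
    concomitance = (pd.concat(conc_parts, ignore_index=True) if conc_parts
                    else pd.DataFrame(columns=["person_id", "class_a", "class_b",
                                               "overlap_days"]))

    adherence = adherence_table(recs, episodes, follow_up)
    persistence = persistence_and_discontinuation(episodes)
    seasonality = seasonality_profile(recs)

    # HCRU and costs --------------------------------------------------------
    per_person = annualized_hcru(med, rx, cohort, unit_costs=unit_costs)
    hcru_summary = summarize_hcru(per_person, groups)
    test_rows = []
    gv = per_person[per_person["person_id"].map(groups) == "vitiligo"]
    gc = per_person[per_person["person_id"].map(groups) == "control"]
    if len(gv) > 1 and len(gc) > 1:
        for c in per_person.columns:
            if c.startswith("ann_"):
                r = two_group_test(gv[c], gc[c], "continuous")
                test_rows.append({"measure": c, "t": r.statistic,
                                  "p_value": r.p_value,
                                  "mean_vitiligo": r.summary["mean"][0],
                                  "mean_control": r.summary["mean"][1]})
    hcru_tests = pd.DataFrame(test_rows)

    anchors_idx = cases.rename(columns={"index_date": "anchor_date"})[
        ["person_id", "anchor_date"]]
    cmp_idx = window_comparison(med, rx, anchors_idx, coverage, study_start,
                                study_end, window_days=config.window_days,
                                unit_costs=unit_costs)
    prepost_index = _paired_rows(cmp_idx, "index")

    first_tx = (recs.groupby("person_id")["start_date"].min()
                .rename("anchor_date").reset_index())
    cmp_tx = window_comparison(med, rx, first_tx, coverage, study_start,
                               study_end, window_days=config.window_days,
                               unit_costs=unit_costs)
    prepost_treatment = _paired_rows(cmp_tx, "treatment")

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "n_persons": int(len(persons)),
        "n_cases": int(n_cases),
        "n_controls": int((cohort["group"] == "control").sum()),
        "n_excluded": int(len(res.exclusions)),
        "distinct_sequences": int(seq_freq["sequence"].nunique()),
    }

    return StudyReport(
        cohort=cohort, exclusions=res.exclusions, demographics=demographics,
        table1=table1, epi=epi, treatment_distribution=treatment_distribution,
        episode_histogram=episode_histogram, sequences=seq_freq,
        concomitance=concomitance, adherence=adherence, persistence=persistence,
        seasonality=seasonality, hcru_summary=hcru_summary,
        hcru_tests=hcru_tests, prepost_index=prepost_index,
        prepost_treatment=prepost_treatment, manifest=manifest,
    )
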