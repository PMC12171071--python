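"""Treatment episodes, sequences, concomitance, adherence and persistence.

A treatment episode is a maximal period of use of one treatment class
without discontinuation: successive dispensations belong to the same
episode while the gap between the supply exhausted so far (the running
maximum of start + days supplied) and the next dispensation is shorter than
the gap threshold (90 days; 180 in sensitivity analyses). Episodes lasting
>=30 days form the patient's treatment sequence; overlapping episodes of
different classes define concomitant use. Adherence is the medication
possession ratio (days supplied / follow-up, adherent at >=80%) and
persistence the length of the first episode.

Supply is never stockpiled: overlapping refills do not push the exhaustion
date beyond the latest (start + supply). The gap can alternatively be
measured start-to-start (``gap_mode="start"``).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import PHOTOTHERAPY_FLAG, TREATMENT_CLASSES

logger = logging.getLogger(__name__)

DEFAULT_GAP_DAYS = 90
SEQUENCE_MIN_DAYS = 30
MPR_ADHERENT_THRESHOLD = 0.80
DEFAULT_HORIZONS = (90, 180, 365)
NO_SEQUENCE = "no sequence"
SEQ_SEP = "→"  # arrow in sequence labels, e.g. "TCS→phototherapy"


def treatment_records(pharmacy_claims: pd.DataFrame,
                      medical_claims: pd.DataFrame,
                      start: Optional[pd.Timestamp] = None) -> pd.DataFrame:
    """Unified treatment records: pharmacy dispensations of the nine classes
    plus phototherapy sessions billed as medical procedures (supply 1 day).

    ``start`` optionally drops records before a date (e.g. the index date
    is applied per person by the caller). Records of unknown classes are
    kept under "other" and logged.
    """
    rx = pharmacy_claims
    known = rx["treatment_class"].astype(str).isin(TREATMENT_CLASSES)
    n_other = int((~known).sum())
    if n_other:
        logger.info("%d pharmacy records outside the nine classes kept as 'other'",
                    n_other)
    rec = pd.DataFrame({
        "person_id": rx["person_id"],
        "treatment_class": rx["treatment_class"].astype(str).where(known, "other"),
        "start_date": rx["dispense_date"],
        "supply_days": rx["days_supply"].astype(int),
    })
    med = medical_claims
    pho = med.loc[med["procedure_flag"] == PHOTOTHERAPY_FLAG]
    if len(pho):
        rec = pd.concat([rec, pd.DataFrame({
            "person_id": pho["person_id"],
            "treatment_class": PHOTOTHERAPY_FLAG,
            "start_date": pho["service_date"],
            "supply_days": 1,
        })], ignore_index=True)
    if start is not None:
        rec = rec[rec["start_date"] >= pd.Timestamp(start)]
    return rec.sort_values(["person_id", "treatment_class", "start_date",
                            "supply_days"], kind="stable").reset_index(drop=True)


def build_episodes(records: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS,
                   gap_mode: str = "exhaustion") -> pd.DataFrame:
    """Merge dispensation records into treatment episodes.

    Per (person, class), records sorted by start date open a new episode
    whenever the dispensation gap is >= ``gap_days``; the gap is measured
    from the running supply-exhaustion date (``gap_mode="exhaustion"``,
    default) or from the previous record's start (``gap_mode="start"``).
    Episode end is the last supplied day; duration counts both endpoints.
    """
    if gap_days <= 0:
        raise ValueError("gap_days must be positive")
    if gap_mode not in ("exhaustion", "start"):
        raise ValueError("gap_mode must be 'exhaustion' or 'start'")
    cols = ["person_id", "treatment_class", "episode_start", "episode_end",
            "duration_days", "episode_number", "n_records"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    r = records.sort_values(["person_id", "treatment_class", "start_date",
                             "supply_days"], kind="stable")
    pid = r["person_id"].to_numpy()
    cls = r["treatment_class"].astype(str).to_numpy()
    start = r["start_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    supply = r["supply_days"].to_numpy(dtype=np.int64)
    exhaust = start + supply  # first day without supply

    same = np.zeros(len(r), dtype=bool)
    same[1:] = (pid[1:] == pid[:-1]) & (cls[1:] == cls[:-1])

    if gap_mode == "start":
        ref = start
    else:
        # segmented running max of exhaustion per (person, class) run:
        # offset each segment into its own dominance range, accumulate, undo
        grp = np.cumsum(~same) - 1
        seg_offset = grp.astype(np.int64) << 42
        ref = np.maximum.accumulate(exhaust + seg_offset) - seg_offset

    gap = np.zeros(len(r), dtype=np.int64)
    gap[1:] = start[1:] - ref[:-1]
    new_episode = ~same | (gap >= gap_days)

    ep_id = np.cumsum(new_episode) - 1
    df = pd.DataFrame({"ep": ep_id, "person_id": pid, "treatment_class": cls,
                       "start": start, "exhaust": exhaust})
    agg = df.groupby("ep", sort=True).agg(
        person_id=("person_id", "first"),
        treatment_class=("treatment_class", "first"),
        s=("start", "min"),
        e=("exhaust", "max"),
        n_records=("start", "size"),
    )
    epoch = np.datetime64("1970-01-01")
    out = pd.DataFrame({
        "person_id": agg["person_id"].to_numpy(),
        "treatment_class": agg["treatment_class"].to_numpy(),
        "episode_start": pd.to_datetime(epoch + agg["s"].to_numpy().astype("timedelta64[D]")),
        "episode_end": pd.to_datetime(epoch + (agg["e"].to_numpy() - 1).astype("timedelta64[D]")),
        "duration_days": (agg["e"] - agg["s"]).to_numpy(),
        "n_records": agg["n_records"].to_numpy(),
    })
    out["episode_number"] = out.groupby(
        ["person_id", "treatment_class"]).cumcount() + 1
    return out[cols].reset_index(drop=True)


@dataclasses.dataclass
class TreatmentSequence:
    person_id: object
    classes: list[str]
    label: str


def derive_sequence(episodes: pd.DataFrame,
                    min_days: int = SEQUENCE_MIN_DAYS) -> TreatmentSequence:
    """Treatment sequence of one person: classes of episodes lasting
    >= ``min_days``, ordered by episode start (ties broken by class name),
    each class counted once at its first qualifying episode."""
    if episodes.empty:
        return TreatmentSequence(None, [], NO_SEQUENCE)
    pids = episodes["person_id"].unique()
    if len(pids) != 1:
        raise ValueError("derive_sequence expects episodes of a single person")
    elig = episodes[episodes["duration_days"] >= min_days]
    elig = elig.sort_values(["episode_start", "treatment_class"], kind="stable")
    seen: list[str] = []
    for c in elig["treatment_class"]:
        if c not in seen:
            seen.append(c)
    label = SEQ_SEP.join(seen) if seen else NO_SEQUENCE
    return TreatmentSequence(pids[0], seen, label)


def sequence_table(episodes: pd.DataFrame, person_ids: Iterable,
                   min_days: int = SEQUENCE_MIN_DAYS) -> pd.DataFrame:
    """Per-person sequence labels for a cohort (persons without qualifying
    episodes get "no sequence")."""
    labels = {}
    for pid, sub in episodes.groupby("person_id"):
        labels[pid] = derive_sequence(sub, min_days=min_days).label
    out = pd.DataFrame({"person_id": list(person_ids)})
    out["sequence"] = out["person_id"].map(labels).fillna(NO_SEQUENCE)
    return out


def concomitant_pairs(episodes: pd.DataFrame) -> pd.DataFrame:
    """Unordered class pairs of one person whose episodes overlap >=1 day.

    Overlap is summed (in calendar days, endpoints inclusive) over all
    overlapping episode pairs of the two classes.
    """
    if episodes.empty:
        return pd.DataFrame(columns=["class_a", "class_b", "overlap_days"])
    eps = episodes.reset_index(drop=True)
    pairs: dict[tuple[str, str], int] = {}
    recs = eps[["treatment_class", "episode_start", "episode_end"]].to_numpy()
    for i in range(len(recs)):
        ci, si, ei = recs[i]
        for j in range(i + 1, len(recs)):
            cj, sj, ej = recs[j]
            if ci == cj:
                continue
            ov = (min(ei, ej) - max(si, sj)).days + 1
            if ov >= 1:
                key = tuple(sorted((ci, cj)))
                pairs[key] = pairs.get(key, 0) + ov
    rows = [{"class_a": a, "class_b": b, "overlap_days": d}
            for (a, b), d in sorted(pairs.items())]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "overlap_days"])


@dataclasses.dataclass
class AdherenceResult:
    person_id: object
    treatment_class: str
    horizon_days: int
    mpr: float
    adherent: bool
    discontinued_by_horizon: Optional[bool] = None
    persistence_days: Optional[int] = None


def compute_mpr(records: pd.DataFrame, follow_up_days: int,
                horizon_days: int) -> AdherenceResult:
    """Medication possession ratio for one (person, class) record set.

    mpr = total days supplied by records starting within the horizon
    (counted from the first record) divided by min(horizon, follow-up).
    Reported uncapped; adherent iff mpr >= 0.80.
    """
    if follow_up_days <= 0:
        raise ValueError("follow-up must be positive to compute an MPR")
    if records.empty:
        raise ValueError("no records")
    pids = records["person_id"].unique()
    clss = records["treatment_class"].unique()
    if len(pids) != 1 or len(clss) != 1:
        raise ValueError("compute_mpr expects records of one person and class")
    t0 = records["start_date"].min()
    within = (records["start_date"] - t0).dt.days < horizon_days
    supplied = int(records.loc[within, "supply_days"].sum())
    denom = min(horizon_days, follow_up_days)
    mpr = supplied / denom
    return AdherenceResult(pids[0], clss[0], horizon_days, mpr,
                           mpr >= MPR_ADHERENT_THRESHOLD)


def persistence_and_discontinuation(
        episodes: pd.DataFrame,
        horizons: Sequence[int] = DEFAULT_HORIZONS) -> pd.DataFrame:
    """First-episode persistence and discontinuation status per horizon.

    Persistence is the length in days of episode #1 of each (person,
    class); the treatment is discontinued by a horizon when that episode
    ended before first-start + horizon (the episode construction's gap rule
    already confirms the discontinuation). Returns one row per (person,
    class, horizon).
    """
    cols = ["person_id", "treatment_class", "horizon_days",
            "persistence_days", "discontinued_by_horizon"]
    first = episodes[episodes["episode_number"] == 1]
    if first.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for _, ep in first.iterrows():
        for h in horizons:
            ended_before = ep["episode_end"] < ep["episode_start"] + pd.Timedelta(days=h)
            rows.append({
                "person_id": ep["person_id"],
                "treatment_class": ep["treatment_class"],
                "horizon_days": h,
                "persistence_days": int(ep["duration_days"]),
                "discontinued_by_horizon": bool(ended_before),
            })
    return pd.DataFrame(rows, columns=cols)


def adherence_table(records: pd.DataFrame, episodes: pd.DataFrame,
                    follow_up: pd.Series,
                    horizons: Sequence[int] = DEFAULT_HORIZONS) -> pd.DataFrame:
    """MPR at each horizon for (person, class) pairs still on treatment and
    still followed at that point: the first episode has not ended before
    the horizon and follow-up from treatment start reaches the horizon.

    ``follow_up`` maps person_id -> follow_up_end (Timestamp).
    """
    pd_disc = persistence_and_discontinuation(episodes, horizons=horizons)
    if pd_disc.empty:
        return pd.DataFrame(columns=["person_id", "treatment_class", "horizon_days",
                                     "mpr", "adherent"])
    rows = []
    for (pid, cls), sub in records.groupby(["person_id", "treatment_class"],
                                           observed=True):
        fu_end = follow_up.get(pid)
        if fu_end is None or pd.isna(fu_end):
            continue
        t0 = sub["start_date"].min()
        fu_days = (fu_end - t0).days + 1
        disc = pd_disc[(pd_disc["person_id"] == pid)
                       & (pd_disc["treatment_class"] == cls)]
        for h in horizons:
            drow = disc[disc["horizon_days"] == h]
            if len(drow) and bool(drow["discontinued_by_horizon"].iloc[0]):
                continue  # discontinued patients excluded at this follow-up point
            if fu_days < h:
                continue  # not covered/observed through the horizon
            res = compute_mpr(sub, fu_days, h)
            rows.append({"person_id": pid, "treatment_class": cls,
                         "horizon_days": h, "mpr": res.mpr,
                         "adherent": res.adherent})
    return pd.DataFrame(rows, columns=["person_id", "treatment_class",
                                       "horizon_days", "mpr", "adherent"])


def seasonality_profile(records: pd.DataFrame) -> pd.DataFrame:
    """Dispensation counts by calendar month (1..12), per class and overall.

    Bin counts sum to the total number of records.
    """
    months = range(1, 13)
    if records.empty:
        base = pd.DataFrame(0, index=["all"], columns=list(months))
        base.index.name = "treatment_class"
        return base
    r = records.copy()
    r["month"] = r["start_date"].dt.month
    table = (r.groupby(["treatment_class", "month"], observed=True).size()
             .unstack(fill_value=0).reindex(columns=list(months), fill_value=0))
    table.loc["all"] = table.sum(axis=0)
    table.index.name = "treatment_class"
    return table.astype(int)
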