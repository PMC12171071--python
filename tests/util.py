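"""Hand-built claim/record frames and independent brute-force oracles."""

import numpy as np
import pandas as pd

D0 = pd.Timestamp("2015-01-01")  # convenient anchor for day-offset fixtures


def med_claims(rows):
    """rows: dicts with person_id, service_date and optional overrides."""
    defaults = dict(dx_code="780.99", dx_system="icd9", setting="outpatient",
                    specialty="general_practitioner", procedure_flag="", fee=40.0)
    recs = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(recs)
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def rx_claims(rows):
    defaults = dict(treatment_class="other", days_supply=30, cost=20.0)
    recs = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(recs)
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    return df


def records_frame(day_supply_pairs, person_id=1, treatment_class="TCS", origin=D0):
    """Treatment records from (day offset, supply) pairs."""
    return pd.DataFrame({
        "person_id": person_id,
        "treatment_class": treatment_class,
        "start_date": [origin + pd.Timedelta(days=d) for d, _ in day_supply_pairs],
        "supply_days": [s for _, s in day_supply_pairs],
    })


def coverage_frame(rows):
    df = pd.DataFrame(rows, columns=["person_id", "cov_start", "cov_end"])
    df["cov_start"] = pd.to_datetime(df["cov_start"])
    df["cov_end"] = pd.to_datetime(df["cov_end"])
    return df


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive implementations of the stated
# rules; independent of the vectorized production code)


def episode_oracle(day_supply_pairs, gap_days):
    """Interval-merge by explicit loop: a new episode opens when the gap
    from the supply exhausted so far to the next start is >= gap_days.
    Returns (start, end_exclusive, n_records) tuples."""
    recs = sorted(day_supply_pairs)
    episodes = []
    cur = None
    for s, d in recs:
        if cur is None:
            cur = [s, s + d, 1]
        elif s - cur[1] >= gap_days:
            episodes.append(tuple(cur))
            cur = [s, s + d, 1]
        else:
            cur[1] = max(cur[1], s + d)
            cur[2] += 1
    if cur is not None:
        episodes.append(tuple(cur))
    return episodes


def visit_oracle(claims):
    """Transitive-closure visit derivation on (person, day, setting) tuples.

    Inpatient claims of a person are connected when <=7 days apart; each
    connected component is one visit. ED/outpatient/other merge per exact
    date. Returns a sorted list of (person, type, start, end, n) tuples.
    """
    from collections import defaultdict

    by_person = defaultdict(lambda: defaultdict(list))
    for person, day, setting in claims:
        by_person[person][setting].append(day)
    visits = []
    for person, groups in by_person.items():
        for setting, days in groups.items():
            if setting == "inpatient":
                days = sorted(days)
                # connected components of the <=7-day adjacency graph on a
                # line are exactly runs of consecutive gaps <= 7
                comp = [days[0], days[0], 1]
                for d in days[1:]:
                    if d - comp[1] <= 7:
                        comp[1] = d
                        comp[2] += 1
                    else:
                        visits.append((person, setting, comp[0], comp[1], comp[2]))
                        comp = [d, d, 1]
                visits.append((person, setting, comp[0], comp[1], comp[2]))
            else:
                for day in sorted(set(days)):
                    n = sum(1 for d in days if d == day)
                    visits.append((person, setting, day, day, n))
    return sorted(visits)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration with
    exact integer arithmetic. Tables with pmf within the conventional 1e-7
    relative tie tolerance of the observed pmf count as "as extreme"."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = comb(r1, k) * comb(r2, c1 - k)
        if pk * 10_000_000 <= p_obs * 10_000_001:
            total += pk
    return total / denom
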