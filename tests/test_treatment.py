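"""Episode construction, sequences, concomitance, MPR, persistence."""

import numpy as np
import pandas as pd
import pytest
from util import D0, episode_oracle, records_frame

from viticlaims.treatment import (build_episodes, compute_mpr, concomitant_pairs,
                                  derive_sequence, persistence_and_discontinuation,
                                  seasonality_profile, sequence_table)


def _episodes_as_tuples(eps):
    return [((r["episode_start"] - D0).days, (r["episode_end"] - D0).days + 1,
             r["n_records"]) for _, r in eps.iterrows()]


class TestBuildEpisodes:
    def test_gap_below_threshold_merges(self):
        eps = build_episodes(records_frame([(0, 30), (100, 30)]), gap_days=90)
        assert len(eps) == 1
        assert eps["duration_days"].iloc[0] == 130  # day 0 through day 129

    def test_single_record(self):
        eps = build_episodes(records_frame([(0, 30)]))
        assert len(eps) == 1
        assert eps["duration_days"].iloc[0] == 30

    def test_gap_at_threshold_splits(self):
        eps = build_episodes(records_frame([(0, 30), (125, 30)]), gap_days=90)
        assert len(eps) == 2
        assert list(eps["episode_number"]) == [1, 2]

    def test_long_fill_bridges_short_one(self):
        # 200-day fill at day 0 still supplies through day 199: the day-150
        # record belongs to the same episode even though the short day-10
        # fill exhausted long before
        eps = build_episodes(records_frame([(0, 200), (10, 5), (150, 5)]),
                             gap_days=90)
        assert len(eps) == 1
        assert eps["duration_days"].iloc[0] == 200

    def test_start_mode_measures_start_to_start(self):
        # start-to-start gap 92 splits in start mode; supply runs to day 5
        # so the exhaustion gap is only 87 and the default mode merges
        recs = records_frame([(0, 5), (92, 5)])
        assert len(build_episodes(recs, gap_days=90, gap_mode="exhaustion")) == 1
        assert len(build_episodes(recs, gap_days=90, gap_mode="start")) == 2

    def test_classes_and_persons_never_mix(self):
        recs = pd.concat([
            records_frame([(0, 30)], person_id=1, treatment_class="TCS"),
            records_frame([(10, 30)], person_id=1, treatment_class="tacrolimus"),
            records_frame([(20, 30)], person_id=2, treatment_class="TCS"),
        ])
        eps = build_episodes(recs)
        assert len(eps) == 3

    @pytest.mark.parametrize("gap_days", [90, 180])
    def test_matches_bruteforce_oracle_on_random_sets(self, gap_days):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 12)
            pairs = [(int(rng.integers(0, 800)), int(rng.integers(1, 120)))
                     for _ in range(n)]
            eps = build_episodes(records_frame(pairs), gap_days=gap_days)
            got = [((r["episode_start"] - D0).days,
                    (r["episode_end"] - D0).days + 1, r["n_records"])
                   for _, r in eps.iterrows()]
            assert got == episode_oracle(pairs, gap_days)

    def test_episode_count_monotone_in_gap(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(1, 15)
            pairs = [(int(rng.integers(0, 1000)), int(rng.integers(1, 90)))
                     for _ in range(n)]
            recs = records_frame(pairs)
            assert len(build_episodes(recs, 180)) <= len(build_episodes(recs, 90))

    def test_episodes_cover_all_supply_and_never_overlap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pairs = [(int(rng.integers(0, 500)), int(rng.integers(1, 100)))
                     for _ in range(rng.integers(1, 10))]
            eps = build_episodes(records_frame(pairs), gap_days=90)
            ivals = sorted((int((r["episode_start"] - D0).days),
                            int((r["episode_end"] - D0).days))
                           for _, r in eps.iterrows())
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 < s2  # same-class episodes disjoint
            for s, d in pairs:
                assert any(a <= s and s + d - 1 <= b for a, b in ivals)

    def test_unknown_class_kept_as_other(self):
        from viticlaims.treatment import treatment_records
        rx = pd.DataFrame({"person_id": [1], "dispense_date": [D0],
                           "treatment_class": ["ruxolitinib"], "days_supply": [30],
                           "cost": [100.0]})
        med = pd.DataFrame(columns=["person_id", "service_date", "procedure_flag"])
        recs = treatment_records(rx, med)
        assert list(recs["treatment_class"]) == ["other"]

    def test_invalid_gap_rejected(self):
        with pytest.raises(ValueError):
            build_episodes(records_frame([(0, 30)]), gap_days=0)


class TestSequences:
    def test_short_episodes_excluded(self):
        recs = pd.concat([
            records_frame([(0, 45)], treatment_class="TCS"),
            records_frame([(20, 10)], treatment_class="tacrolimus"),
            records_frame([(60, 60)], treatment_class="phototherapy"),
        ])
        seq = derive_sequence(build_episodes(recs))
        assert seq.label == "TCS→phototherapy"

    def test_no_qualifying_episode_is_no_sequence(self):
        recs = records_frame([(0, 10)])
        assert derive_sequence(build_episodes(recs)).label == "no sequence"

    def test_same_day_tie_breaks_lexicographically(self):
        recs = pd.concat([
            records_frame([(0, 40)], treatment_class="tacrolimus"),
            records_frame([(0, 40)], treatment_class="TCS"),
        ])
        seq = derive_sequence(build_episodes(recs))
        assert seq.label == "TCS→tacrolimus"

    def test_class_counted_once_at_first_qualifying_episode(self):
        recs = pd.concat([
            records_frame([(0, 40)], treatment_class="TCS"),
            records_frame([(200, 40)], treatment_class="phototherapy"),
            records_frame([(400, 40)], treatment_class="TCS"),  # restart
        ])
        assert derive_sequence(build_episodes(recs)).label == "TCS→phototherapy"

    def test_sequence_table_covers_all_persons(self):
        recs = records_frame([(0, 45)], person_id=1)
        seqs = sequence_table(build_episodes(recs), person_ids=[1, 2])
        assert dict(zip(seqs["person_id"], seqs["sequence"])) == {
            1: "TCS", 2: "no sequence"}


class TestConcomitance:
    def test_overlap_length_inclusive(self):
        eps = build_episodes(pd.concat([
            records_frame([(0, 61)], treatment_class="TCS"),
            records_frame([(30, 61)], treatment_class="phototherapy"),
        ]))
        pairs = concomitant_pairs(eps)
        assert len(pairs) == 1
        assert pairs.iloc[0]["class_a"] == "TCS"
        assert pairs.iloc[0]["overlap_days"] == 31  # days 30..60

    def test_disjoint_episodes_no_pairs(self):
        eps = build_episodes(pd.concat([
            records_frame([(0, 30)], treatment_class="TCS"),
            records_frame([(200, 30)], treatment_class="phototherapy"),
        ]))
        assert len(concomitant_pairs(eps)) == 0

    def test_three_mutually_overlapping_classes_give_three_pairs(self):
        eps = build_episodes(pd.concat([
            records_frame([(0, 60)], treatment_class="TCS"),
            records_frame([(10, 60)], treatment_class="phototherapy"),
            records_frame([(20, 60)], treatment_class="tacrolimus"),
        ]))
        pairs = concomitant_pairs(eps)
        assert len(pairs) == 3


class TestAdherence:
    def test_mpr_formula(self):
        recs = records_frame([(0, 90), (90, 90), (180, 90)])  # 270 days
        res = compute_mpr(recs, follow_up_days=365, horizon_days=365)
        assert res.mpr == pytest.approx(270 / 365)
        assert not res.adherent

    def test_full_possession_is_adherent(self):
        recs = records_frame([(0, 365)])
        res = compute_mpr(recs, 365, 365)
        assert res.mpr == pytest.approx(1.0)
        assert res.adherent

    def test_mpr_uncapped_above_one(self):
        recs = records_frame([(0, 200), (100, 200)])  # 400 days supplied
        res = compute_mpr(recs, 365, 365)
        assert res.mpr == pytest.approx(400 / 365)
        assert res.adherent

    def test_zero_follow_up_rejected(self):
        with pytest.raises(ValueError):
            compute_mpr(records_frame([(0, 30)]), 0, 90)


class TestPersistence:
    def test_first_episode_defines_persistence(self):
        eps = build_episodes(records_frame([(0, 45), (300, 45)]))
        out = persistence_and_discontinuation(eps, horizons=(90,))
        assert out["persistence_days"].iloc[0] == 45
        assert bool(out["discontinued_by_horizon"].iloc[0])

    def test_ongoing_episode_not_discontinued(self):
        eps = build_episodes(records_frame([(0, 400)]))
        out = persistence_and_discontinuation(eps, horizons=(365,))
        assert not bool(out["discontinued_by_horizon"].iloc[0])

    def test_refill_within_gap_extends_episode(self):
        # exhausted day 88 but refilled day 100 (gap 12 < 90): still on
        # treatment at the 90-day point
        eps = build_episodes(records_frame([(0, 30), (30, 30), (60, 28),
                                            (100, 30)]))
        out = persistence_and_discontinuation(eps, horizons=(90,))
        assert len(eps) == 1
        assert not bool(out["discontinued_by_horizon"].iloc[0])


class TestSeasonality:
    def test_single_month_mass(self):
        recs = records_frame([(151 + i, 1) for i in range(5)])  # June 2015
        prof = seasonality_profile(recs)
        assert prof.loc["all", 6] == 5
        assert prof.loc["all"].sum() == 5

    def test_empty_input_all_zero(self):
        prof = seasonality_profile(records_frame([]).iloc[0:0])
        assert (prof.loc["all"] == 0).all()

    def test_uniform_months_within_multinomial_interval(self):
        """Records spread uniformly over days of several full years: each
        month bin stays inside the exact binomial 99% interval around its
        expected share (month length / year length)."""
        from scipy import stats
        rng = np.random.default_rng(17)
        days = rng.integers(0, 365 * 4, 12000)
        recs = records_frame([(int(d), 1) for d in days])
        prof = seasonality_profile(recs)
        month_days = [31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        n = 12000
        for m in range(1, 13):
            p = month_days[m - 1] / 365.25
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= prof.loc["all", m] <= hi
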