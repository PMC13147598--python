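import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_cohort, link_cohort

from flowstream._schema import ENCOUNTER_COLUMNS, EVENT_COLUMNS
from flowstream.config import DefectConfig
from flowstream.linkage_cleaning import (
    SchemaError,
    clean_events,
    deidentify,
    episodes_to_frames,
    frames_to_episodes,
    link_episodes,
)
from flowstream.synthetic_emr import generate_cohort, inject_defects


def _enc_row(mrn, start, end, enc_id="E1", enc_type="IP", team="cardiology", **kw):
    row = {
        "mrn": mrn, "encounter_id": enc_id, "encounter_type": enc_type,
        "start_ts": start, "end_ts": end, "admitting_team": team,
        "ward": "ward 5a", "age": 60, "gender": "female", "postcode": "5000",
        "usual_accommodation": "private residence", "admission_type": "Medical",
        "day_procedure": 0, "problem_list": "documented",
    }
    row.update(kw)
    return row


def _enc_frame(rows):
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def _ev_frame(rows=()):
    return pd.DataFrame(list(rows), columns=EVENT_COLUMNS)


class TestCleanEvents:
    def test_missing_column_named(self):
        enc = _enc_frame([_enc_row("M1", "2024-01-01", "2024-01-02")]).drop(columns=["ward"])
        with pytest.raises(SchemaError, match="ward"):
            clean_events(enc, _ev_frame())

    def test_negative_duration_excluded_and_logged(self):
        enc = _enc_frame([
            _enc_row("M1", "2024-01-02T10:00:00", "2024-01-01T10:00:00"),
            _enc_row("M2", "2024-01-01T10:00:00", "2024-01-02T10:00:00", enc_id="E2"),
        ])
        cleaned, _, log = clean_events(enc, _ev_frame())
        assert len(cleaned) == 1 and cleaned.iloc[0]["mrn"] == "M2"
        assert log.count("implausible_excluded") == 1

    def test_unparseable_timestamp_excluded(self):
        enc = _enc_frame([_enc_row("M1", "not a date", "2024-01-02")])
        cleaned, _, log = clean_events(enc, _ev_frame())
        assert cleaned.empty
        assert log.count("implausible_excluded") == 1

    def test_exact_duplicate_collapsed(self):
        row = _enc_row("M1", "2024-01-01T10:00:00", "2024-01-02T10:00:00")
        cleaned, _, log = clean_events(_enc_frame([row, row]), _ev_frame())
        assert len(cleaned) == 1
        assert log.count("duplicate_removed") == 1

    def test_name_canonicalisation(self):
        enc = _enc_frame([_enc_row("M1", "2024-01-01T10:00:00", "2024-01-02T10:00:00",
                                   team="  General   MEDICINE ")])
        cleaned, _, _ = clean_events(enc, _ev_frame())
        assert cleaned.iloc[0]["admitting_team"] == "general medicine"

    def test_absent_values_stay_absent(self):
        enc = _enc_frame([_enc_row("M1", "2024-01-01T10:00:00", "2024-01-02T10:00:00",
                                   problem_list="")])
        cleaned, _, _ = clean_events(enc, _ev_frame())
        assert cleaned.iloc[0]["problem_list"] == ""

    def test_cleaning_counts_match_injected_truth(self, defect_config):
        enc, ev, _ = build_cohort(400, seed=21)
        enc2, ev2, defect_log = inject_defects(enc, ev, defect_config, seed=21)
        _, _, log = clean_events(enc2, ev2)
        kinds = defect_log["kind"].value_counts()
        assert log.count("duplicate_removed") == kinds.get("duplicate", 0) > 0
        assert log.count("implausible_excluded") == kinds.get("negative_duration", 0) > 0


class TestLinkEpisodes:
    def test_small_gap_merges(self):
        enc = _enc_frame([
            _enc_row("M1", "2024-01-01T08:00:00", "2024-01-01T12:00:00", enc_id="A"),
            _enc_row("M1", "2024-01-01T14:00:00", "2024-01-02T10:00:00", enc_id="B"),
        ])
        enc, ev, _ = clean_events(enc, _ev_frame())
        episodes, _ = link_episodes(enc, ev, gap_threshold_hours=6)
        assert len(episodes) == 1
        assert len(episodes[0].encounters) == 2

    def test_large_gap_splits(self):
        enc = _enc_frame([
            _enc_row("M1", "2024-01-01T08:00:00", "2024-01-01T12:00:00", enc_id="A"),
            _enc_row("M1", "2024-01-03T12:00:00", "2024-01-04T10:00:00", enc_id="B"),
        ])
        enc, ev, _ = clean_events(enc, _ev_frame())
        episodes, _ = link_episodes(enc, ev, gap_threshold_hours=6)
        assert len(episodes) == 2

    def test_transitive_chain_merges(self):
        # A-B gap 3 h, B-C gap 3 h, A-C gap 6.5 h: one episode at threshold 6 h
        enc = _enc_frame([
            _enc_row("M1", "2024-01-01T00:00:00", "2024-01-01T04:00:00", enc_id="A"),
            _enc_row("M1", "2024-01-01T07:00:00", "2024-01-01T07:30:00", enc_id="B"),
            _enc_row("M1", "2024-01-01T10:30:00", "2024-01-01T20:00:00", enc_id="C"),
        ])
        enc, ev, _ = clean_events(enc, _ev_frame())
        episodes, _ = link_episodes(enc, ev, gap_threshold_hours=6)
        assert len(episodes) == 1
        assert {e.encounter_id for e in episodes[0].encounters} == {"A", "B", "C"}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            link_episodes(_enc_frame([]), _ev_frame(), gap_threshold_hours=0)

    def test_orphan_event_excluded(self):
        enc = _enc_frame([_enc_row("M1", "2024-01-01T08:00:00", "2024-01-02T08:00:00")])
        ev = _ev_frame([{
            "mrn": "GHOST", "event_type": "order", "order_subtype": "blood_test",
            "ts": "2024-01-01T10:00:00", "target_service": "", "location": "",
            "structured": 1,
        }])
        enc, ev, _ = clean_events(enc, ev)
        episodes, orphans = link_episodes(enc, ev)
        assert len(episodes) == 1 and not episodes[0].events
        assert len(orphans) == 1 and orphans.iloc[0]["mrn"] == "GHOST"

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 80), st.integers(1, 20)),
                    min_size=1, max_size=8),
           st.integers(1, 12))
    def test_cluster_count_matches_transitive_closure_oracle(self, intervals, gap_h):
        # brute-force oracle: transitive closure of "gap <= threshold" over all pairs
        base = pd.Timestamp("2024-01-01")
        rows = []
        spans = []
        for i, (start_h, dur_h) in enumerate(intervals):
            lo = base + pd.Timedelta(hours=start_h)
            hi = lo + pd.Timedelta(hours=dur_h)
            spans.append((lo, hi))
            rows.append(_enc_row("M1", lo.isoformat(), hi.isoformat(), enc_id=f"E{i}"))
        n = len(spans)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        # union i,j when the intervals overlap or one starts within the
        # threshold after the other ends; chaining is the transitive closure
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gap_ij = (spans[j][0] - spans[i][1]) / pd.Timedelta(hours=1)
                overlap = spans[j][0] <= spans[i][1] and spans[j][1] >= spans[i][0]
                if overlap or 0 <= gap_ij <= gap_h:
                    parent[find(i)] = find(j)
        expected_clusters = len({find(i) for i in range(n)})

        enc, ev, _ = clean_events(_enc_frame(rows), _ev_frame())
        episodes, _ = link_episodes(enc, ev, gap_threshold_hours=gap_h)
        assert len(episodes) == expected_clusters

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        t = pd.Timestamp("2024-01-01")
        for i in range(int(rng.integers(1, 7))):
            t = t + pd.Timedelta(hours=float(rng.uniform(0.5, 30)))
            end = t + pd.Timedelta(hours=float(rng.uniform(1, 48)))
            rows.append(_enc_row("M1", t.isoformat(), end.isoformat(), enc_id=f"E{i}"))
            t = end
        enc, ev, _ = clean_events(_enc_frame(rows), _ev_frame())
        counts = [len(link_episodes(enc, ev, gap_threshold_hours=h)[0])
                  for h in (1, 3, 6, 12, 24)]
        assert counts == sorted(counts, reverse=True)

    def test_permutation_invariance(self, small_cohort):
        enc, ev, _ = small_cohort
        enc_clean, ev_clean, _ = clean_events(enc, ev)
        eps_a, _ = link_episodes(enc_clean, ev_clean)
        shuffled_enc = enc_clean.sample(frac=1, random_state=42).reset_index(drop=True)
        shuffled_ev = ev_clean.sample(frac=1, random_state=42).reset_index(drop=True)
        eps_b, _ = link_episodes(shuffled_enc, shuffled_ev)
        assert len(eps_a) == len(eps_b)
        for a, b in zip(eps_a, eps_b):
            assert a.mrn == b.mrn
            assert a.admission_ts == b.admission_ts
            assert a.discharge_ts == b.discharge_ts
            assert [e.ts for e in a.events] == [e.ts for e in b.events]
            assert [e.event_type for e in a.events] == [e.event_type for e in b.events]

    def test_conservation(self, small_cohort):
        enc, ev, _ = small_cohort
        enc_clean, ev_clean, _ = clean_events(enc, ev)
        episodes, orphans = link_episodes(enc_clean, ev_clean)
        n_encounters = sum(len(ep.encounters) for ep in episodes)
        assert n_encounters == len(enc_clean)
        n_events = sum(len(ep.events) for ep in episodes)
        assert n_events == len(ev_clean) - len(orphans)

    def test_segmentation_matches_generator_intent(self, small_cohort):
        enc, ev, truth = small_cohort
        episodes, _, _, _ = link_cohort(enc, ev, deident=False)
        per_mrn = pd.Series([ep.mrn for ep in episodes]).value_counts()
        intended = dict(zip(truth.patients["mrn"], truth.patients["n_episodes"]))
        assert {m: int(c) for m, c in per_mrn.items()} == intended


class TestDeidentify:
    def test_distinct_mrns_distinct_ids(self):
        enc = _enc_frame([
            _enc_row(f"M{i}", "2024-01-01T08:00:00", "2024-01-02T08:00:00", enc_id=f"E{i}")
            for i in range(3)
        ])
        enc, ev, _ = clean_events(enc, _ev_frame())
        episodes, _ = link_episodes(enc, ev)
        deident, identity = deidentify(episodes)
        ids = {ep.study_id for ep in deident}
        assert len(ids) == 3
        assert len(identity.pairs) == 3

    def test_same_mrn_same_id_across_episodes(self):
        enc = _enc_frame([
            _enc_row("M1", "2024-01-01T08:00:00", "2024-01-02T08:00:00", enc_id="A"),
            _enc_row("M1", "2024-02-01T08:00:00", "2024-02-02T08:00:00", enc_id="B"),
        ])
        enc, ev, _ = clean_events(enc, _ev_frame())
        episodes, _ = link_episodes(enc, ev)
        deident, _ = deidentify(episodes)
        assert deident[0].study_id == deident[1].study_id

    def test_output_contains_no_mrn(self, linked_small_cohort):
        episodes, identity, _ = linked_small_cohort
        assert all(ep.mrn is None for ep in episodes)
        ep_frame, ev_frame = episodes_to_frames(episodes)
        assert "mrn" not in ep_frame.columns and "mrn" not in ev_frame.columns

    def test_round_trip_recovers_assignment(self):
        enc, ev, truth = build_cohort(100, seed=31)
        episodes, _, _, _ = link_cohort(enc, ev, deident=False)
        original = {(ep.admission_ts, ep.discharge_ts): ep.mrn for ep in episodes}
        deident, identity = deidentify(episodes)
        ep_frame, _ = episodes_to_frames(deident)
        recovered = identity.reidentify(ep_frame)
        for row in recovered.itertuples():
            key = (pd.Timestamp(row.admission_ts), pd.Timestamp(row.discharge_ts))
            assert original[key] == row.mrn


class TestFrameRoundTrip:
    def test_episode_frames_round_trip(self, linked_small_cohort, tmp_path):
        episodes, _, _ = linked_small_cohort
        ep_frame, ev_frame = episodes_to_frames(episodes)
        ep_frame.to_csv(tmp_path / "episodes.csv", index=False)
        ev_frame.to_csv(tmp_path / "events.csv", index=False)
        back = frames_to_episodes(pd.read_csv(tmp_path / "episodes.csv"),
                                  pd.read_csv(tmp_path / "events.csv"))
        assert len(back) == len(episodes)
        for a, b in zip(episodes, back):
            assert a.study_id == b.study_id
            assert a.admission_ts == b.admission_ts
            assert a.discharge_ts == b.discharge_ts
            assert a.admitting_team == b.admitting_team
            assert a.day_procedure == b.day_procedure
            assert len(a.events) == len(b.events)
            assert [e.ts for e in a.events] == [e.ts for e in b.events]
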