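"""Cleaning, deterministic episode linkage and de-identification.

The cleaning stage collapses exact duplicate rows, excludes rows with
unparseable timestamps or negative durations, and canonicalises team and
location names. Nothing is imputed: a structured value that is absent stays
absent.

Linkage is deterministic and time-based: per patient, encounters sorted by
start time are merged transitively whenever the gap to the running episode
end is at most ``gap_threshold_hours``; events are attached to the episode
whose chained span contains them, and events that match no episode (or no
patient) are warning-logged orphans, never fabricated into episodes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import pandas as pd

from flowstream._schema import (
    ENCOUNTER_COLUMNS,
    EVENT_COLUMNS,
    canonical_name,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass
class Encounter:
    """One cleaned raw encounter (identifier-free; the episode carries linkage)."""

    encounter_id: str
    encounter_type: str
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp
    admitting_team: str
    ward: str
    age: float
    gender: str
    postcode: str
    usual_accommodation: str
    admission_type: str
    day_procedure: bool
    problem_list: str


@dataclass
class CareEvent:
    """One cleaned timestamped care event."""

    ts: pd.Timestamp
    event_type: str
    order_subtype: str = ""
    target_service: str = ""
    location: str = ""
    structured: bool = True


@dataclass
class AdmissionEpisode:
    """A consolidated admission journey: linked encounters plus an ordered
    event stream. Demographics are the earliest encounter's snapshot."""

    mrn: str | None
    study_id: str | None
    episode_id: str | None
    encounters: list[Encounter]
    admission_ts: pd.Timestamp
    discharge_ts: pd.Timestamp
    admission_source: str
    admission_type: str
    admitting_team: str
    day_procedure: bool
    age: float
    gender: str
    postcode: str
    usual_accommodation: str
    events: list[CareEvent] = field(default_factory=list)

    @property
    def los_days(self) -> float:
        return (self.discharge_ts - self.admission_ts) / pd.Timedelta(days=1)


@dataclass
class CleaningLog:
    """Row-level record of cleaning actions.

    ``reason`` is one of ``duplicate_removed``, ``implausible_excluded``,
    ``format_standardised`` (the latter logged per affected column, with the
    column name as row reference).
    """

    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["reason", "table", "row_ref", "detail"]))

    def count(self, reason: str) -> int:
        if self.entries.empty:
            return 0
        return int((self.entries["reason"] == reason).sum())

    def append(self, rows: list[dict]) -> None:
        if rows:
            self.entries = pd.concat(
                [self.entries, pd.DataFrame(rows, columns=self.entries.columns)],
                ignore_index=True,
            )


@dataclass
class IdentityMap:
    """Bijective mrn <-> study_id mapping, stored apart from analytical output."""

    pairs: pd.DataFrame  # columns: mrn, study_id

    def study_id_for(self, mrn: str) -> str:
        return self._forward()[mrn]

    def mrn_for(self, study_id: str) -> str:
        return {v: k for k, v in self._forward().items()}[study_id]

    def _forward(self) -> dict:
        return dict(zip(self.pairs["mrn"], self.pairs["study_id"]))

    def reidentify(self, frame: pd.DataFrame, column: str = "study_id") -> pd.DataFrame:
        """Return ``frame`` with an ``mrn`` column recovered from the map."""
        reverse = {v: k for k, v in self._forward().items()}
        out = frame.copy()
        out["mrn"] = out[column].map(reverse)
        return out


# ---------------------------------------------------------------------------
# cleaning


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing mandatory column '{col}'")


def clean_events(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, CleaningLog]:
    """Apply the cleaning rules to the raw tables.

    Returns cleaned copies plus a :class:`CleaningLog`. Duplicate rows are
    collapsed to their first occurrence; rows with unparseable timestamps or
    end-before-start durations are excluded and logged.
    """
    _require_columns(encounters, ENCOUNTER_COLUMNS, "encounters")
    _require_columns(events, EVENT_COLUMNS, "events")
    log = CleaningLog()

    enc = encounters.copy().reset_index(drop=True)
    ev = events.copy().reset_index(drop=True)

    # format standardisation: timestamps parsed, names canonicalised
    for df, table, ts_cols, name_cols in (
        (enc, "encounters", ("start_ts", "end_ts"), ("admitting_team", "ward")),
        (ev, "events", ("ts",), ("target_service", "location")),
    ):
        for col in ts_cols:
            parsed = pd.to_datetime(df[col], errors="coerce", format="mixed")
            df[col] = parsed
            log.append([{"reason": "format_standardised", "table": table,
                         "row_ref": col, "detail": "timestamps parsed to ISO 8601"}])
        for col in name_cols:
            before = df[col].copy()
            df[col] = df[col].map(canonical_name)
            if not before.astype(str).equals(df[col].astype(str)):
                log.append([{"reason": "format_standardised", "table": table,
                             "row_ref": col, "detail": "names canonicalised"}])
    for col in ("mrn", "gender", "postcode", "usual_accommodation",
                "admission_type", "encounter_type", "problem_list"):
        if col in enc.columns:
            enc[col] = enc[col].fillna("").astype(str)
    ev["mrn"] = ev["mrn"].fillna("").astype(str)
    for col in ("event_type", "order_subtype"):
        ev[col] = ev[col].fillna("").astype(str)
    enc["day_procedure"] = pd.to_numeric(enc["day_procedure"], errors="coerce").fillna(0).astype(int)
    ev["structured"] = pd.to_numeric(ev["structured"], errors="coerce").fillna(1).astype(int)
    enc["age"] = pd.to_numeric(enc["age"], errors="coerce")

    # exact duplicate collapse (first occurrence survives)
    for df_name, table in (("enc", "encounters"), ("ev", "events")):
        df = enc if df_name == "enc" else ev
        dup_mask = df.duplicated(keep="first")
        if dup_mask.any():
            rows = []
            for idx in df.index[dup_mask]:
                ref = df.loc[idx, "encounter_id"] if table == "encounters" else f"row{idx}"
                rows.append({"reason": "duplicate_removed", "table": table,
                             "row_ref": ref, "detail": ""})
            log.append(rows)
            df = df.loc[~dup_mask].reset_index(drop=True)
        if df_name == "enc":
            enc = df
        else:
            ev = df

    # clinically implausible rows: unparseable timestamps, negative durations
    bad_enc = enc["start_ts"].isna() | enc["end_ts"].isna() | (enc["end_ts"] < enc["start_ts"])
    if bad_enc.any():
        log.append([
            {"reason": "implausible_excluded", "table": "encounters",
             "row_ref": enc.loc[idx, "encounter_id"],
             "detail": "negative duration or unparseable timestamp"}
            for idx in enc.index[bad_enc]
        ])
        enc = enc.loc[~bad_enc].reset_index(drop=True)
    bad_ev = ev["ts"].isna()
    if bad_ev.any():
        log.append([
            {"reason": "implausible_excluded", "table": "events",
             "row_ref": f"row{idx}", "detail": "unparseable timestamp"}
            for idx in ev.index[bad_ev]
        ])
        ev = ev.loc[~bad_ev].reset_index(drop=True)

    return enc, ev, log


# ---------------------------------------------------------------------------
# linkage


def link_episodes(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    gap_threshold_hours: float = 6.0,
) -> tuple[list[AdmissionEpisode], pd.DataFrame]:
    """Link cleaned encounters into admission episodes and attach events.

    Consecutive encounters of one patient are chained into a single episode
    whenever the gap from the running episode end to the next start is at
    most ``gap_threshold_hours`` (overlaps merge). Returns the episode list
    (sorted by mrn then admission time) and a frame of orphan events.
    """
    if gap_threshold_hours <= 0:
        raise ValueError("gap_threshold_hours must be > 0")
    gap = pd.Timedelta(hours=gap_threshold_hours)

    episodes: list[AdmissionEpisode] = []
    orphan_rows: list[dict] = []

    ev_sorted = events.sort_values(
        ["mrn", "ts", "event_type", "order_subtype", "target_service", "location"],
        kind="stable",
    )
    events_by_mrn = {mrn: grp for mrn, grp in ev_sorted.groupby("mrn", sort=True)}
    known_mrns = set(encounters["mrn"])
    for mrn, grp in events_by_mrn.items():
        if mrn not in known_mrns:
            logger.warning("events for mrn %s have no encounter; excluded as orphans", mrn)
            for idx in grp.index:
                orphan_rows.append({"mrn": mrn, "row_ref": f"row{idx}",
                                    "reason": "mrn_not_in_encounters"})

    for mrn, grp in encounters.sort_values(
        ["mrn", "start_ts", "end_ts", "encounter_id"], kind="stable"
    ).groupby("mrn", sort=True):
        clusters: list[list] = []
        current: list = []
        current_end: pd.Timestamp | None = None
        for row in grp.itertuples(index=False):
            if current and row.start_ts - current_end <= gap:
                current.append(row)
                current_end = max(current_end, row.end_ts)
            else:
                if current:
                    clusters.append(current)
                current = [row]
                current_end = row.end_ts
        if current:
            clusters.append(current)

        spans = [(min(r.start_ts for r in c), max(r.end_ts for r in c)) for c in clusters]
        cluster_events: list[list[CareEvent]] = [[] for _ in clusters]
        if mrn in events_by_mrn:
            for row in events_by_mrn[mrn].itertuples(index=True):
                placed = False
                for ci, (lo, hi) in enumerate(spans):
                    if lo <= row.ts <= hi:  # event at the episode end belongs to it
                        cluster_events[ci].append(CareEvent(
                            ts=row.ts, event_type=row.event_type,
                            order_subtype=row.order_subtype or "",
                            target_service=row.target_service or "",
                            location=row.location or "",
                            structured=bool(row.structured),
                        ))
                        placed = True
                        break
                if not placed:
                    logger.warning("event at %s for mrn %s falls outside every episode", row.ts, mrn)
                    orphan_rows.append({"mrn": mrn, "row_ref": f"row{row.Index}",
                                        "reason": "outside_episode_span"})

        for k, (cluster, evs) in enumerate(zip(clusters, cluster_events)):
            episodes.append(_build_episode(mrn, f"{mrn}-EP{k}", cluster, evs))

    orphans = pd.DataFrame(orphan_rows, columns=["mrn", "row_ref", "reason"])
    return episodes, orphans


def _build_episode(mrn: str, episode_id: str, cluster: list,
                   events: list[CareEvent]) -> AdmissionEpisode:
    first = cluster[0]
    inpatient = [r for r in cluster if r.encounter_type == "IP"]
    primary = min(inpatient, key=lambda r: r.start_ts) if inpatient else first
    encounters = [
        Encounter(
            encounter_id=r.encounter_id, encounter_type=r.encounter_type,
            start_ts=r.start_ts, end_ts=r.end_ts,
            admitting_team=r.admitting_team, ward=r.ward,
            age=r.age, gender=r.gender, postcode=r.postcode,
            usual_accommodation=r.usual_accommodation,
            admission_type=r.admission_type,
            day_procedure=bool(r.day_procedure), problem_list=r.problem_list,
        )
        for r in cluster
    ]
    return AdmissionEpisode(
        mrn=mrn, study_id=None, episode_id=episode_id, encounters=encounters,
        admission_ts=primary.start_ts,
        discharge_ts=max(r.end_ts for r in cluster),
        admission_source=first.encounter_type,
        admission_type=primary.admission_type,
        admitting_team=primary.admitting_team,
        day_procedure=bool(primary.day_procedure),
        age=first.age, gender=first.gender, postcode=first.postcode,
        usual_accommodation=first.usual_accommodation,
        events=events,
    )


# ---------------------------------------------------------------------------
# de-identification


def deidentify(episodes: list[AdmissionEpisode]) -> tuple[list[AdmissionEpisode], IdentityMap]:
    """Replace mrns with opaque study identifiers.

    The same mrn always maps to the same study_id; the map is returned
    separately and must be stored apart from the analytical dataset.
    """
    mrns = sorted({ep.mrn for ep in episodes if ep.mrn is not None})
    mapping = {mrn: f"S{idx:06d}" for idx, mrn in enumerate(mrns)}
    if len(set(mapping.values())) != len(mapping):
        raise RuntimeError("study_id collision during de-identification")
    seq: dict[str, int] = {}
    out = []
    for ep in sorted(episodes, key=lambda e: (e.mrn, e.admission_ts)):
        sid = mapping[ep.mrn]
        k = seq.get(sid, 0)
        seq[sid] = k + 1
        out.append(dataclasses.replace(ep, mrn=None, study_id=sid,
                                       episode_id=f"{sid}-EP{k}"))
    pairs = pd.DataFrame(
        {"mrn": list(mapping), "study_id": [mapping[m] for m in mapping]}
    )
    return out, IdentityMap(pairs=pairs)


# ---------------------------------------------------------------------------
# frame round-trip (episodes.csv / episode_events.csv)

EPISODE_COLUMNS = [
    "episode_id", "study_id", "admission_ts", "discharge_ts", "admission_source",
    "admission_type", "admitting_team", "day_procedure", "age", "gender",
    "postcode", "usual_accommodation", "n_encounters",
]
EPISODE_EVENT_COLUMNS = [
    "episode_id", "ts", "event_type", "order_subtype", "target_service",
    "location", "structured",
]


def episodes_to_frames(episodes: list[AdmissionEpisode]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten episodes into (episodes.csv, episode_events.csv) frames.

    Uses study_id when present, else mrn — call :func:`deidentify` first for
    analytical output.
    """
    ep_rows, ev_rows = [], []
    for ep in episodes:
        key = ep.study_id if ep.study_id is not None else ep.mrn
        ep_rows.append({
            "episode_id": ep.episode_id, "study_id": key, "admission_ts": ep.admission_ts,
            "discharge_ts": ep.discharge_ts, "admission_source": ep.admission_source,
            "admission_type": ep.admission_type, "admitting_team": ep.admitting_team,
            "day_procedure": int(ep.day_procedure), "age": ep.age, "gender": ep.gender,
            "postcode": ep.postcode, "usual_accommodation": ep.usual_accommodation,
            "n_encounters": len(ep.encounters),
        })
        for e in ep.events:
            ev_rows.append({
                "episode_id": ep.episode_id, "ts": e.ts, "event_type": e.event_type,
                "order_subtype": e.order_subtype, "target_service": e.target_service,
                "location": e.location, "structured": int(e.structured),
            })
    return (
        pd.DataFrame(ep_rows, columns=EPISODE_COLUMNS),
        pd.DataFrame(ev_rows, columns=EPISODE_EVENT_COLUMNS),
    )


def frames_to_episodes(episode_frame: pd.DataFrame,
                       event_frame: pd.DataFrame) -> list[AdmissionEpisode]:
    """Rebuild episode objects from the flat CSV frames (encounter detail is
    not round-tripped; only episode-level fields and events are)."""
    ep_frame = episode_frame.copy()
    for col in ("admission_ts", "discharge_ts"):
        ep_frame[col] = pd.to_datetime(ep_frame[col])
    evf = event_frame.copy()
    evf["ts"] = pd.to_datetime(evf["ts"])
    for col in ("order_subtype", "target_service", "location"):
        evf[col] = evf[col].fillna("").astype(str)
    events_by_id: dict = {
        eid: grp for eid, grp in evf.groupby("episode_id", sort=False)
    }
    episodes = []
    for row in ep_frame.itertuples(index=False):
        evs = []
        grp = events_by_id.get(row.episode_id)
        if grp is not None:
            evs = [
                CareEvent(ts=r.ts, event_type=r.event_type,
                          order_subtype=r.order_subtype,
                          target_service=r.target_service, location=r.location,
                          structured=bool(r.structured))
                for r in grp.itertuples(index=False)
            ]
            evs.sort(key=lambda e: (e.ts, e.event_type, e.order_subtype))
        episodes.append(AdmissionEpisode(
            mrn=None, study_id=row.study_id, episode_id=row.episode_id, encounters=[],
            admission_ts=row.admission_ts, discharge_ts=row.discharge_ts,
            admission_source=row.admission_source, admission_type=row.admission_type,
            admitting_team=row.admitting_team, day_procedure=bool(row.day_procedure),
            age=row.age, gender=row.gender, postcode=str(row.postcode),
            usual_accommodation=row.usual_accommodation, events=evs,
        ))
    return episodes
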