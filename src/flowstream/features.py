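"""Resource-utilisation features over an evaluation window.

Windows end at 24 h, 72 h, or discharge (``end_ts = min(admission + offset,
discharge)``). Only events strictly before ``end_ts`` are counted, so every
counter is monotone non-decreasing across the nested windows. ICU hours are
the cumulative length of paired entry/exit intervals clipped to the window;
an entry still open at the window end is clipped there, an exit without an
entry is noted and ignored. "Within 24 h" counters are anchored at admission
regardless of the evaluation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from flowstream._schema import canonical_name
from flowstream.linkage_cleaning import AdmissionEpisode

WINDOW_LABELS = ("24h", "72h", "discharge")
_OFFSETS = {"24h": 24.0, "72h": 72.0, "discharge": math.inf}

DEFAULT_CRITICAL_LOCATIONS = ("ED Resus", "Theatre", "ICU", "Spinal")
DEFAULT_POLYPHARMACY_THRESHOLD = 5

_HOUR = pd.Timedelta(hours=1)


def episode_key(episode: AdmissionEpisode) -> str | None:
    """The per-episode identifier used to key features and assignments."""
    for key in (episode.episode_id, episode.study_id, episode.mrn):
        if key is not None:
            return key
    return None


@dataclass(frozen=True)
class EvaluationWindow:
    """A labelled evaluation horizon: 24h, 72h, or discharge."""

    label: str

    def __post_init__(self):
        if self.label not in WINDOW_LABELS:
            raise ValueError(f"unknown window label: {self.label!r}")

    @property
    def offset_hours(self) -> float:
        return _OFFSETS[self.label]

    def end_ts(self, episode: AdmissionEpisode) -> pd.Timestamp:
        if math.isinf(self.offset_hours):
            return episode.discharge_ts
        return min(episode.admission_ts + self.offset_hours * _HOUR, episode.discharge_ts)

    def discharged_within(self, episode: AdmissionEpisode) -> bool:
        if math.isinf(self.offset_hours):
            return True
        return episode.discharge_ts <= episode.admission_ts + self.offset_hours * _HOUR


@dataclass
class ResourceFeatures:
    """Per-episode resource counters and flags for one evaluation window."""

    study_id: str | None
    episode_id: str | None
    window: str
    los_days_observed: float
    discharged_within_window: bool
    day_procedure_flag: bool
    n_consults_external: int
    n_consults_total: int
    n_consults_first24h: int
    n_bloods: int
    n_ct_mr: int
    n_ir: int
    group_hold_flag: bool
    icu_hours_cumulative: float
    critical_location_flag: bool
    emergency_theatre_flag: bool
    n_transfers_first24h: int
    n_transfers_total: int
    n_allied_health: int
    n_medications: int
    polypharmacy_flag: bool
    one_to_one_nursing_flag: bool
    n_unpaired_icu_exits: int = 0

    MONOTONE_COUNTERS = (
        "n_consults_external", "n_consults_total", "n_consults_first24h",
        "n_bloods", "n_ct_mr", "n_ir", "n_transfers_first24h",
        "n_transfers_total", "n_allied_health", "n_medications",
        "icu_hours_cumulative", "los_days_observed",
    )


def count_consults(
    episode: AdmissionEpisode,
    end_ts: pd.Timestamp,
    exclude_self: bool = True,
) -> tuple[int, int]:
    """Count consult orders before ``end_ts`` as (n_external, n_total).

    A consult addressed to the episode's admitting team (after name
    canonicalisation) is a self-consult: counted in the total, excluded from
    the external count when ``exclude_self``. Consults with an empty target
    service count in the total only. Allied health and pharmacy consults are
    separate order subtypes and never counted here.
    """
    team = canonical_name(episode.admitting_team)
    n_external = n_total = 0
    for e in episode.events:
        if e.event_type != "order" or e.order_subtype != "consult":
            continue
        if not (e.ts < end_ts):
            continue
        n_total += 1
        target = canonical_name(e.target_service)
        if not target:
            continue  # unaddressed consult: total only
        if exclude_self and target == team:
            continue
        n_external += 1
    return n_external, n_total


def _icu_hours(episode: AdmissionEpisode, end_ts: pd.Timestamp) -> tuple[float, int]:
    """Cumulative ICU hours from paired entry/exit events, clipped to
    [admission, end_ts]. Open stays clip at end_ts; stray exits are counted
    and ignored."""
    open_entries: list[pd.Timestamp] = []
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    unpaired_exits = 0
    for e in episode.events:  # episode events are time-sorted
        if e.event_type == "icu_entry":
            open_entries.append(e.ts)
        elif e.event_type == "icu_exit":
            if open_entries:
                intervals.append((open_entries.pop(0), e.ts))
            else:
                unpaired_exits += 1
    for entry in open_entries:
        intervals.append((entry, end_ts))
    total = 0.0
    for lo, hi in intervals:
        lo = max(lo, episode.admission_ts)
        hi = min(hi, end_ts)
        if hi > lo:
            total += (hi - lo) / _HOUR
    return total, unpaired_exits


def derive_features(
    episode: AdmissionEpisode,
    window: EvaluationWindow | str,
    rules=None,
) -> ResourceFeatures:
    """Derive the feature vector for one episode over one window.

    ``rules`` may be any object exposing ``fs4_critical_locations``,
    ``polypharmacy_threshold`` and ``exclude_self_consults`` (e.g. a
    :class:`flowstream.classifier.RuleConfig`); defaults apply otherwise.
    The function is pure: repeated calls agree exactly.
    """
    if isinstance(window, str):
        window = EvaluationWindow(window)
    critical = getattr(rules, "fs4_critical_locations", DEFAULT_CRITICAL_LOCATIONS)
    poly_threshold = getattr(rules, "polypharmacy_threshold", DEFAULT_POLYPHARMACY_THRESHOLD)
    exclude_self = getattr(rules, "exclude_self_consults", True)
    critical_set = {canonical_name(c) for c in critical}

    end_ts = window.end_ts(episode)
    discharged = window.discharged_within(episode)
    cut24 = min(episode.admission_ts + 24 * _HOUR, end_ts)

    n_bloods = n_ct_mr = n_ir = n_allied = n_meds = 0
    n_tr_total = n_tr_24 = n_cons_24 = 0
    group_hold = theatre = one_to_one = critical_flag = False
    team = canonical_name(episode.admitting_team)

    for e in episode.events:
        if not (e.ts < end_ts):
            continue
        if e.event_type == "order":
            st = e.order_subtype
            if st == "blood_test":
                n_bloods += 1
            elif st in ("ct", "mr"):
                n_ct_mr += 1
            elif st == "ir":
                n_ir += 1
            elif st in ("allied_health_consult", "pharmacy_consult"):
                n_allied += 1
            elif st == "medication":
                n_meds += 1
            elif st == "group_hold":
                group_hold = True
            elif st == "one_to_one_nursing":
                one_to_one = True
            elif st == "consult":
                target = canonical_name(e.target_service)
                if e.ts < cut24 and target and not (exclude_self and target == team):
                    n_cons_24 += 1
        elif e.event_type == "location_transfer":
            n_tr_total += 1
            if e.ts < cut24:
                n_tr_24 += 1
            if canonical_name(e.location) in critical_set:
                critical_flag = True
        elif e.event_type == "icu_entry":
            if "icu" in critical_set:
                critical_flag = True
        elif e.event_type == "theatre_emergency":
            theatre = True
            if "theatre" in critical_set:
                critical_flag = True

    n_external, n_total = count_consults(episode, end_ts, exclude_self=exclude_self)
    icu_hours, unpaired_exits = _icu_hours(episode, end_ts)
    if discharged:
        los = (episode.discharge_ts - episode.admission_ts) / pd.Timedelta(days=1)
    else:
        los = (end_ts - episode.admission_ts) / pd.Timedelta(days=1)

    return ResourceFeatures(
        study_id=episode.study_id if episode.study_id is not None else episode.mrn,
        episode_id=episode_key(episode),
        window=window.label,
        los_days_observed=los,
        discharged_within_window=discharged,
        day_procedure_flag=bool(episode.day_procedure),
        n_consults_external=n_external,
        n_consults_total=n_total,
        n_consults_first24h=n_cons_24,
        n_bloods=n_bloods,
        n_ct_mr=n_ct_mr,
        n_ir=n_ir,
        group_hold_flag=group_hold,
        icu_hours_cumulative=icu_hours,
        critical_location_flag=critical_flag,
        emergency_theatre_flag=theatre,
        n_transfers_first24h=n_tr_24,
        n_transfers_total=n_tr_total,
        n_allied_health=n_allied,
        n_medications=n_meds,
        polypharmacy_flag=n_meds >= poly_threshold,
        one_to_one_nursing_flag=one_to_one,
        n_unpaired_icu_exits=unpaired_exits,
    )
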