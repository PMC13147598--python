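"""Shared test utilities: episode builders and independent rule oracles.

The oracles here deliberately re-implement the stream rule set from the raw
thresholds with their own counting code; they must never call into the
package's feature or classifier internals beyond plain data access.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from flowstream.features import ResourceFeatures
from flowstream.linkage_cleaning import AdmissionEpisode, CareEvent

ADM = pd.Timestamp("2024-03-01 08:00")
HOUR = pd.Timedelta(hours=1)


def ev_order(hours, subtype, target="", location=""):
    return CareEvent(ts=ADM + hours * HOUR, event_type="order",
                     order_subtype=subtype, target_service=target, location=location)


def ev(hours, event_type, location=""):
    return CareEvent(ts=ADM + hours * HOUR, event_type=event_type, location=location)


def make_episode(los_days=2.0, events=(), day_procedure=False,
                 team="cardiology", source="ED", admission_type="Medical",
                 study_id="S1", **kw):
    evs = sorted(events, key=lambda e: (e.ts, e.event_type, e.order_subtype))
    return AdmissionEpisode(
        mrn=None, study_id=study_id, episode_id=study_id + "-EP0", encounters=[],
        admission_ts=ADM, discharge_ts=ADM + los_days * 24 * HOUR,
        admission_source=source, admission_type=admission_type,
        admitting_team=team, day_procedure=day_procedure,
        age=kw.get("age", 60), gender=kw.get("gender", "female"),
        postcode=kw.get("postcode", "5000"),
        usual_accommodation=kw.get("usual_accommodation", "private residence"),
        events=evs,
    )


def random_features(rng: np.random.Generator) -> ResourceFeatures:
    n_total = int(rng.integers(0, 6))
    n_external = int(rng.integers(0, n_total + 1))
    meds = int(rng.integers(0, 12))
    return ResourceFeatures(
        study_id=None, episode_id=None, window="discharge",
        los_days_observed=float(rng.uniform(0, 12)),
        discharged_within_window=bool(rng.random() < 0.6),
        day_procedure_flag=bool(rng.random() < 0.4),
        n_consults_external=n_external,
        n_consults_total=n_total,
        n_consults_first24h=int(rng.integers(0, 5)),
        n_bloods=int(rng.integers(0, 10)),
        n_ct_mr=int(rng.integers(0, 3)),
        n_ir=int(rng.integers(0, 2)),
        group_hold_flag=bool(rng.random() < 0.1),
        icu_hours_cumulative=float(rng.uniform(0, 60)) if rng.random() < 0.3 else 0.0,
        critical_location_flag=bool(rng.random() < 0.15),
        emergency_theatre_flag=bool(rng.random() < 0.1),
        n_transfers_first24h=int(rng.integers(0, 6)),
        n_transfers_total=int(rng.integers(0, 8)),
        n_allied_health=int(rng.integers(0, 6)),
        n_medications=meds,
        polypharmacy_flag=meds >= 5,
        one_to_one_nursing_flag=bool(rng.random() < 0.05),
    )


# ---------------------------------------------------------------------------
# independent oracles


def oracle_stream_from_features(f: ResourceFeatures) -> str:
    """Brute-force re-test of every default threshold, straight from the
    feature fields."""
    fs1 = (f.discharged_within_window
           and f.los_days_observed * 24.0 < 24.0
           and f.day_procedure_flag)
    fs4 = (f.icu_hours_cumulative >= 24.0
           or f.critical_location_flag
           or f.emergency_theatre_flag
           or (f.n_ct_mr >= 1 and f.n_bloods >= 5)
           or f.group_hold_flag
           or f.n_consults_first24h >= 3
           or f.n_transfers_first24h >= 4)
    fs2 = (f.n_consults_external <= 1
           and f.n_consults_total <= 2
           and f.los_days_observed < 5.0)
    if fs1:
        return "FS1"
    if fs4:
        return "FS4"
    if fs2:
        return "FS2"
    return "FS3"


def _canon(name) -> str:
    return " ".join(str(name or "").split()).casefold()


def oracle_classify_episode(episode: AdmissionEpisode, label: str) -> str:
    """Re-derive the stream for one episode at one window directly from the
    raw event rows, with independent counting and ICU pairing code."""
    offsets = {"24h": 24.0, "72h": 72.0, "discharge": None}
    off = offsets[label]
    adm, dis = episode.admission_ts, episode.discharge_ts
    if off is None:
        end, discharged = dis, True
    else:
        cutoff = adm + off * HOUR
        end = min(cutoff, dis)
        discharged = dis <= cutoff
    cut24 = min(adm + 24 * HOUR, end)
    team = _canon(episode.admitting_team)
    critical = {"ed resus", "theatre", "icu", "spinal"}

    bloods = ctmr = 0
    ext = total = cons24 = tr24 = 0
    group_hold = theatre = crit = False
    entries, exits = [], []
    for e in episode.events:
        if e.event_type == "icu_entry":
            entries.append(e.ts)
            continue
        if e.event_type == "icu_exit":
            exits.append(e.ts)
            continue
        if not (e.ts < end):
            continue
        if e.event_type == "order":
            if e.order_subtype == "blood_test":
                bloods += 1
            elif e.order_subtype in ("ct", "mr"):
                ctmr += 1
            elif e.order_subtype == "group_hold":
                group_hold = True
            elif e.order_subtype == "consult":
                total += 1
                tgt = _canon(e.target_service)
                if tgt and tgt != team:
                    ext += 1
                    if e.ts < cut24:
                        cons24 += 1
        elif e.event_type == "location_transfer":
            if e.ts < cut24:
                tr24 += 1
            if _canon(e.location) in critical:
                crit = True
        elif e.event_type == "theatre_emergency":
            theatre = True
            crit = True
    for ts in entries:
        if ts < end and "icu" in critical:
            crit = True

    # independent ICU-hour tally: pair entries/exits in time order
    entries.sort()
    exits.sort()
    icu_hours = 0.0
    used = [False] * len(exits)
    open_intervals = []
    for entry in entries:
        matched = None
        for j, ex in enumerate(exits):
            if not used[j] and ex >= entry:
                matched = j
                break
        if matched is None:
            open_intervals.append((entry, end))
        else:
            used[matched] = True
            open_intervals.append((entry, exits[matched]))
    for lo, hi in open_intervals:
        lo, hi = max(lo, adm), min(hi, end)
        if hi > lo:
            icu_hours += (hi - lo) / HOUR

    los = (dis - adm) / pd.Timedelta(days=1) if discharged else (end - adm) / pd.Timedelta(days=1)

    if discharged and los * 24 < 24 and episode.day_procedure:
        return "FS1"
    if (icu_hours >= 24 or crit or theatre or (ctmr >= 1 and bloods >= 5)
            or group_hold or cons24 >= 3 or tr24 >= 4):
        return "FS4"
    if ext <= 1 and total <= 2 and los < 5:
        return "FS2"
    return "FS3"
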