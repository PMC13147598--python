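"""Seeded synthetic EMR cohort generator.

Produces an encounter table and an event/order table shaped like a raw
hospital EMR extract, together with a ground-truth log of each patient's
intended flow-stream archetype and every injected documentation defect.

Archetype samplers are constructed so that, with defects off and default
parameters, the downstream classifier recovers the intended stream at the
discharge window:

* FS1 episodes are day procedures with total duration under 24 h.
* FS2 episodes stay under 5 days with at most one external consult and never
  trip a high-acuity criterion.
* FS3 episodes exceed 5 days and receive two external consults within the
  first 24 h (so the one-consult rule is already broken at the first
  evaluation window), while staying clear of every high-acuity criterion.
* FS4 episodes always carry at least one qualifying high-acuity pattern
  (ICU stay >= 24 h in 96 % of cases, otherwise a forced fallback pattern).

A configurable fraction of FS2/FS3 patients receive a late acuity surge: an
ICU stay beginning after the 24 h mark, so they reclassify to FS4 at 72 h or
discharge but not before.

Determinism: every random draw comes from a per-patient (or per-defect-kind)
``numpy`` Generator seeded as ``default_rng([seed, index])``, so identical
(config, seed) pairs give byte-identical tables and enlarging the cohort does
not perturb earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flowstream._schema import ENCOUNTER_COLUMNS, EVENT_COLUMNS, STREAMS
from flowstream.config import ArchetypeParams, CohortConfig, ConfigError, DefectConfig

_MIN = pd.Timedelta(minutes=1)

TEAMS = (
    "general medicine", "cardiology", "orthopaedics", "neurology",
    "gastroenterology", "vascular surgery", "respiratory medicine",
    "geriatric medicine", "general surgery", "urology",
)
WARDS = (
    "ward 5a", "ward 5b", "ward 7a", "ward 7b",
    "medical assessment unit", "rehabilitation unit",
)
_LEAD_ENCOUNTER = {
    # admission source -> (lead encounter type, team, ward)
    "ED": ("ED", "emergency medicine", "emergency department"),
    "OPD": ("OPD", "outpatient clinic", "outpatient clinic"),
    "ITF": ("ITF", "transfer centre", "transfer lounge"),
}
_SOURCES = ("ED", "OPD", "IP", "ITF")
_ADMISSION_TYPES = ("Medical", "Surgical", "Other")


@dataclass
class TruthLog:
    """Ground truth for a generated cohort.

    ``patients`` has one row per patient (mrn, intended_stream, escalated,
    n_episodes); ``defects`` has one row per injected defect
    (kind, table, mrn, row_ref, detail).
    """

    patients: pd.DataFrame = field(default_factory=lambda: _empty_patients())
    defects: pd.DataFrame = field(default_factory=lambda: _empty_defects())

    def defect_counts(self) -> dict[str, int]:
        if self.defects.empty:
            return {}
        return self.defects["kind"].value_counts().to_dict()


def _empty_patients() -> pd.DataFrame:
    return pd.DataFrame(columns=["mrn", "intended_stream", "escalated", "n_episodes"])


def _empty_defects() -> pd.DataFrame:
    return pd.DataFrame(columns=["kind", "table", "mrn", "row_ref", "detail"])


@dataclass
class EpisodePlan:
    """One sampled admission journey before table assembly."""

    admission_ts: pd.Timestamp
    los_days: float
    day_procedure: bool
    admission_source: str
    admission_type: str
    admitting_team: str
    ward: str
    events: list[dict]          # EVENT_COLUMNS minus mrn

    @property
    def discharge_ts(self) -> pd.Timestamp:
        return self.admission_ts + pd.Timedelta(minutes=int(round(self.los_days * 24 * 60)))


# ---------------------------------------------------------------------------
# archetype episode sampling


def _trunc_lognormal(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float) -> float:
    """Log-normal draw truncated to [lo, hi] by resampling (clip as fallback)."""
    mu = np.log(median)
    for _ in range(64):
        x = float(rng.lognormal(mu, sigma))
        if lo <= x <= hi:
            return x
    return float(min(max(rng.lognormal(mu, sigma), lo), hi))


class _Slots:
    """Allocates distinct minute offsets within an episode so the generated
    event table never contains accidental exact-duplicate rows (only the
    defect injector creates duplicates)."""

    def __init__(self, los_minutes: int):
        self.limit = max(los_minutes - 1, 1)
        self.used: set[int] = set()

    def take(self, hours: float) -> int:
        m = int(hours * 60)
        m = min(max(m, 1), self.limit)
        for _ in range(self.limit + 1):
            if m not in self.used:
                self.used.add(m)
                return m
            m = m + 1 if m < self.limit else 1
        self.used.add(m)  # saturated episode; collision tolerated
        return m


def _order(ts: pd.Timestamp, subtype: str, target: str = "", location: str = "") -> dict:
    return {
        "event_type": "order", "order_subtype": subtype, "ts": ts,
        "target_service": target, "location": location, "structured": 1,
    }


def _event(ts: pd.Timestamp, event_type: str, location: str = "") -> dict:
    return {
        "event_type": event_type, "order_subtype": "", "ts": ts,
        "target_service": "", "location": location, "structured": 1,
    }


def sample_archetype_episode(
    archetype: str,
    params: ArchetypeParams,
    rng: np.random.Generator,
    admission_ts: pd.Timestamp | str = "2024-01-01 08:00",
) -> EpisodePlan:
    """Sample one admission journey for the given stream archetype.

    Returns an :class:`EpisodePlan` whose event list is time-sorted and lies
    strictly inside ``[admission_ts, discharge_ts)``.
    """
    if archetype not in STREAMS:
        raise ValueError(f"unknown archetype: {archetype!r}")
    adm = pd.Timestamp(admission_ts).floor("min")

    los_days = _trunc_lognormal(rng, params.los_median_days, params.los_sigma,
                                params.los_min_days, params.los_max_days)
    day_procedure = bool(rng.random() < params.day_procedure_probability)
    team = str(rng.choice(TEAMS))
    ward = str(rng.choice(WARDS))
    source = str(rng.choice(_SOURCES, p=_norm(params.source_weights)))
    adm_type = str(rng.choice(_ADMISSION_TYPES, p=_norm(params.admission_type_weights)))

    builder = {"FS1": _fill_fs1, "FS2": _fill_fs2, "FS3": _fill_fs3, "FS4": _fill_fs4}[archetype]
    events, los_days = builder(params, rng, adm, los_days, team)

    events.sort(key=lambda e: (e["ts"], e["event_type"], e["order_subtype"]))
    return EpisodePlan(
        admission_ts=adm, los_days=los_days, day_procedure=day_procedure,
        admission_source=source, admission_type=adm_type,
        admitting_team=team, ward=ward, events=events,
    )


def _norm(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return w / w.sum()


def _external_team(rng: np.random.Generator, admitting_team: str) -> str:
    choices = [t for t in TEAMS if t != admitting_team]
    return str(rng.choice(choices))


def _common_orders(params: ArchetypeParams, rng, adm, slots, los_h, events,
                   blood_cap: int | None, n_ct: int) -> None:
    """Bloods, imaging, medications, allied health, risk assessments."""
    n_bloods = int(rng.poisson(params.blood_mean))
    if blood_cap is not None and n_ct > 0:
        n_bloods = min(n_bloods, blood_cap)
    for _ in range(n_bloods):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.02, 0.95) * los_h), "blood_test"))
    for _ in range(n_ct):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.05, 0.8) * los_h), "ct"))
    if rng.random() < params.ir_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.1, 0.8) * los_h), "ir"))
    if rng.random() < params.polypharmacy_fraction:
        n_meds = int(rng.integers(5, 12))
    else:
        n_meds = int(min(rng.poisson(1.2), 4))
    for _ in range(n_meds):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.01, 0.9) * los_h), "medication"))
    n_allied = int(rng.poisson(params.allied_health_mean))
    for i in range(n_allied):
        subtype = "pharmacy_consult" if i == 0 and rng.random() < 0.25 else "allied_health_consult"
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.1, 0.95) * los_h), subtype))
    if rng.random() < params.risk_assessment_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.01, 0.3) * los_h), "risk_assessment"))


def _ward_transfers(rng, adm, slots, events, hours: list[float]) -> None:
    for h in hours:
        events.append(_event(adm + _MIN * slots.take(h), "location_transfer", str(rng.choice(WARDS))))


def _fill_fs1(params, rng, adm, los_days, team):
    los_h = los_days * 24
    slots = _Slots(int(los_h * 60))
    events: list[dict] = []
    n_ct = 1 if rng.random() < params.imaging_probability else 0
    _common_orders(params, rng, adm, slots, los_h, events, blood_cap=4, n_ct=n_ct)
    if rng.random() < params.consult_mean:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.1, 0.8) * los_h),
                             "consult", target=_external_team(rng, team)))
    # rare short ICU stay wholly inside the sub-24 h admission
    if rng.random() < params.icu_probability:
        entry_h = rng.uniform(0.05, 0.3) * los_h
        dur_h = min(rng.uniform(params.icu_hours_lo, params.icu_hours_hi), 0.5 * los_h)
        events.append(_event(adm + _MIN * slots.take(entry_h), "icu_entry", "icu"))
        events.append(_event(adm + _MIN * slots.take(entry_h + dur_h), "icu_exit"))
    n_tr = int(min(rng.poisson(params.transfer_mean), 2))
    _ward_transfers(rng, adm, slots, events,
                    [rng.uniform(0.1, 0.9) * los_h for _ in range(n_tr)])
    return events, los_days


def _fill_fs2(params, rng, adm, los_days, team):
    los_h = los_days * 24
    slots = _Slots(int(los_h * 60))
    events: list[dict] = []
    n_ct = 1 if rng.random() < params.imaging_probability else 0
    _common_orders(params, rng, adm, slots, los_h, events, blood_cap=4, n_ct=n_ct)
    if min(rng.poisson(params.consult_mean), 1):  # at most one external consult
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.05, 0.9) * los_h),
                             "consult", target=_external_team(rng, team)))
    n_tr = int(min(rng.poisson(params.transfer_mean), 3))
    _ward_transfers(rng, adm, slots, events,
                    [rng.uniform(0.05, 0.9) * los_h for _ in range(n_tr)])
    return events, los_days


def _fill_fs3(params, rng, adm, los_days, team):
    los_h = los_days * 24
    slots = _Slots(int(los_h * 60))
    events: list[dict] = []
    n_ct = 1 if rng.random() < params.imaging_probability else 0
    _common_orders(params, rng, adm, slots, los_h, events, blood_cap=4, n_ct=n_ct)
    # two external consults inside the first 24 h mark the multidisciplinary
    # profile at the first evaluation window; later consults add on top
    for _ in range(2):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(1.0, 23.0)),
                             "consult", target=_external_team(rng, team)))
    for _ in range(int(rng.poisson(params.consult_mean))):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(25.0, los_h * 0.95)),
                             "consult", target=_external_team(rng, team)))
    early = [rng.uniform(1.0, 23.0) for _ in range(int(min(rng.poisson(1.0), 3)))]
    late = [rng.uniform(25.0, los_h * 0.95) for _ in range(int(rng.poisson(params.transfer_mean)))]
    _ward_transfers(rng, adm, slots, events, early + late)
    if rng.random() < params.icu_probability:  # off by default for separability
        entry_h = rng.uniform(25.0, los_h * 0.5)
        dur_h = min(rng.uniform(params.icu_hours_lo, params.icu_hours_hi), 20.0)
        events.append(_event(adm + _MIN * slots.take(entry_h), "icu_entry", "icu"))
        events.append(_event(adm + _MIN * slots.take(entry_h + dur_h), "icu_exit"))
    return events, los_days


def _fill_fs4(params, rng, adm, los_days, team):
    los_h = los_days * 24
    events: list[dict] = []
    qualifying = False

    icu = rng.random() < params.icu_probability
    if icu:
        entry_h = rng.uniform(0.5, 18.0)
        dur_h = rng.uniform(max(params.icu_hours_lo, 26.0), params.icu_hours_hi)
        if entry_h + dur_h + 4.0 > los_h:      # stretch the stay around the ICU block
            los_h = entry_h + dur_h + rng.uniform(4.0, 24.0)
            los_days = los_h / 24.0
        qualifying = True

    slots = _Slots(int(los_h * 60))
    if icu:
        events.append(_event(adm + _MIN * slots.take(entry_h), "icu_entry", "icu"))
        events.append(_event(adm + _MIN * slots.take(entry_h + dur_h), "icu_exit"))

    n_ct = 1 if rng.random() < params.imaging_probability else 0
    n_bloods_min = 0
    if rng.random() < params.group_hold_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.5, 24.0)), "group_hold"))
        qualifying = True
    if not qualifying:
        pattern = str(rng.choice(
            ["group_hold", "imaging_bloods", "consults_24h", "transfers_24h", "theatre_emergency"]
        ))
        if pattern == "group_hold":
            events.append(_order(adm + _MIN * slots.take(rng.uniform(0.5, 24.0)), "group_hold"))
        elif pattern == "imaging_bloods":
            n_ct, n_bloods_min = max(n_ct, 1), 5
        elif pattern == "consults_24h":
            for _ in range(3 + int(rng.poisson(1.0))):
                events.append(_order(adm + _MIN * slots.take(rng.uniform(0.5, 23.5)),
                                     "consult", target=_external_team(rng, team)))
        elif pattern == "transfers_24h":
            _ward_transfers(rng, adm, slots, events,
                            [rng.uniform(0.5, 23.5) for _ in range(4 + int(rng.poisson(1.0)))])
        else:
            events.append(_event(adm + _MIN * slots.take(rng.uniform(0.5, 23.5)),
                                 "theatre_emergency", "theatre"))

    n_bloods = max(int(rng.poisson(params.blood_mean)), n_bloods_min)
    for _ in range(n_bloods):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.02, 0.95) * los_h), "blood_test"))
    for _ in range(n_ct):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.02, 0.8) * los_h), "ct"))
    if rng.random() < params.ir_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.1, 0.8) * los_h), "ir"))
    for _ in range(int(rng.poisson(params.consult_mean))):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.05, 0.95) * los_h),
                             "consult", target=_external_team(rng, team)))
    _ward_transfers(rng, adm, slots, events,
                    [rng.uniform(0.05, 0.95) * los_h for _ in range(int(rng.poisson(params.transfer_mean)))])
    if rng.random() < params.polypharmacy_fraction:
        n_meds = int(rng.integers(5, 15))
    else:
        n_meds = int(min(rng.poisson(2.0), 4))
    for _ in range(n_meds):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.01, 0.9) * los_h), "medication"))
    for _ in range(int(rng.poisson(params.allied_health_mean))):
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.1, 0.95) * los_h),
                             "allied_health_consult"))
    if rng.random() < params.mtp_probability:
        events.append(_event(adm + _MIN * slots.take(rng.uniform(0.2, 20.0)), "mtp_activation"))
    if rng.random() < params.one_to_one_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.5, los_h * 0.5)), "one_to_one_nursing"))
    if rng.random() < params.risk_assessment_probability:
        events.append(_order(adm + _MIN * slots.take(rng.uniform(0.6, 12.0)), "risk_assessment"))
    return events, los_days


def _apply_escalation(plan: EpisodePlan, rng: np.random.Generator) -> None:
    """Append a late acuity surge: an ICU stay starting after the 24 h mark,
    so reclassification to FS4 happens at 72 h or discharge, never at 24 h."""
    entry_h = rng.uniform(25.0, 44.0)
    dur_h = rng.uniform(26.0, 70.0)
    exit_h = entry_h + dur_h
    # deterioration prolongs the whole stay: ward recovery follows the ICU block
    new_los_h = max(plan.los_days * 24.0, exit_h + rng.uniform(48.0, 240.0))
    plan.los_days = new_los_h / 24.0
    slots = _Slots(int(new_los_h * 60))
    for e in plan.events:
        slots.used.add(int((e["ts"] - plan.admission_ts) / _MIN))
    plan.events.append(_event(plan.admission_ts + _MIN * slots.take(entry_h), "icu_entry", "icu"))
    plan.events.append(_event(plan.admission_ts + _MIN * slots.take(exit_h), "icu_exit"))
    plan.events.sort(key=lambda e: (e["ts"], e["event_type"], e["order_subtype"]))


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(
    config: CohortConfig,
    defects: DefectConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLog]:
    """Generate the synthetic (encounters, events, truth) triple.

    When ``defects`` is given, documentation defects are injected after
    generation and recorded in the truth log.
    """
    config.validate()
    if defects is not None:
        defects.validate()

    enc_rows: list[dict] = []
    ev_rows: list[dict] = []
    patient_rows: list[dict] = []
    cal_start = pd.Timestamp(config.calendar_start)
    weights = _norm(config.mixing_weights)

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        mrn = f"MRN{i:07d}"
        archetype = str(rng.choice(list(STREAMS), p=weights))
        params = config.archetypes[archetype]
        escalated = bool(
            archetype in ("FS2", "FS3") and rng.random() < config.escalation_fraction
        )
        n_episodes = 2 if rng.random() < config.multi_episode_probability else 1

        age = int(np.clip(rng.normal(params.age_median, params.age_sd), 18, 99))
        gender = "female" if rng.random() < params.female_fraction else "male"
        postcode = str(5000 + int(rng.integers(0, 120)))
        accommodation = "residential aged care" if rng.random() < 0.10 else "private residence"

        adm = (cal_start + pd.Timedelta(hours=float(rng.uniform(0, config.calendar_days * 24)))).floor("min")
        for ep_idx in range(n_episodes):
            plan = sample_archetype_episode(archetype, params, rng, adm)
            if escalated and ep_idx == 0:
                _apply_escalation(plan, rng)
            if ep_idx == n_episodes - 1 and n_episodes > 1 and rng.random() < 0.2:
                accommodation = "residential aged care"  # genuine change before last episode
            demo = {
                "age": age, "gender": gender, "postcode": postcode,
                "usual_accommodation": accommodation,
                "problem_list": "documented problem list",
            }
            _emit_episode(enc_rows, ev_rows, mrn, ep_idx, plan, rng, config, demo)
            gap_h = max(
                _trunc_lognormal(rng, config.multi_episode_gap_median_hours,
                                 config.multi_episode_gap_sigma,
                                 config.multi_episode_gap_min_hours, 24 * 365.0),
                config.multi_episode_gap_min_hours,
            )
            adm = (plan.discharge_ts + pd.Timedelta(hours=gap_h)).floor("min")

        patient_rows.append({
            "mrn": mrn, "intended_stream": archetype,
            "escalated": int(escalated), "n_episodes": n_episodes,
        })

    encounters = pd.DataFrame(enc_rows, columns=ENCOUNTER_COLUMNS)
    events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    if not events.empty:
        events = events.sort_values(
            ["mrn", "ts", "event_type", "order_subtype", "target_service", "location"],
            kind="stable",
        ).reset_index(drop=True)
    truth = TruthLog(patients=pd.DataFrame(patient_rows, columns=_empty_patients().columns))

    if defects is not None:
        encounters, events, defect_log = inject_defects(encounters, events, defects, config.seed)
        truth.defects = defect_log
    return encounters, events, truth


def _emit_episode(enc_rows, ev_rows, mrn, ep_idx, plan: EpisodePlan, rng, config, demo) -> None:
    k = 0
    if plan.admission_source in _LEAD_ENCOUNTER:
        lead_type, lead_team, lead_ward = _LEAD_ENCOUNTER[plan.admission_source]
        lead_start = (plan.admission_ts
                      - pd.Timedelta(hours=float(rng.uniform(1.0, config.ed_lead_hours_max)))).floor("min")
        lead_end = (plan.admission_ts
                    - pd.Timedelta(minutes=int(rng.integers(5, 31))))
        enc_rows.append({
            "mrn": mrn, "encounter_id": f"{mrn}-{ep_idx}-{k}",
            "encounter_type": lead_type, "start_ts": lead_start, "end_ts": lead_end,
            "admitting_team": lead_team, "ward": lead_ward,
            "admission_type": plan.admission_type, "day_procedure": 0, **demo,
        })
        k += 1
    enc_rows.append({
        "mrn": mrn, "encounter_id": f"{mrn}-{ep_idx}-{k}",
        "encounter_type": "IP", "start_ts": plan.admission_ts, "end_ts": plan.discharge_ts,
        "admitting_team": plan.admitting_team, "ward": plan.ward,
        "admission_type": plan.admission_type,
        "day_procedure": int(plan.day_procedure), **demo,
    })
    for e in plan.events:
        ev_rows.append({"mrn": mrn, **e})


# ---------------------------------------------------------------------------
# defect injection


def inject_defects(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    defects: DefectConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inject documentation defects and return the corrupted tables plus a
    defect log (one row per injected defect).

    Kinds: ``duplicate`` (exact row copies appended), ``negative_duration``
    (encounter end moved before start), ``self_consult`` (consult order
    targeting the admitting team), ``missing_field`` (structured field
    blanked), ``demographic_overwrite`` (earlier encounters of a patient
    overwritten with the latest demographic snapshot), ``mtp_underreport``
    (MTP activation events dropped).
    """
    defects.validate()
    enc = encounters.copy().reset_index(drop=True)
    ev = events.copy().reset_index(drop=True)
    log: list[dict] = []

    def _rng(kind_idx: int) -> np.random.Generator:
        return np.random.default_rng([seed, defects.seed_offset, kind_idx])

    # negative durations first so duplicates are drawn from intact rows only
    if defects.negative_duration_rate > 0 and len(enc):
        rng = _rng(0)
        mask = rng.random(len(enc)) < defects.negative_duration_rate
        for idx in np.flatnonzero(mask):
            delta = pd.Timedelta(hours=float(rng.uniform(1.0, 12.0)))
            enc.loc[idx, "end_ts"] = enc.loc[idx, "start_ts"] - delta
            log.append({"kind": "negative_duration", "table": "encounters",
                        "mrn": enc.loc[idx, "mrn"],
                        "row_ref": enc.loc[idx, "encounter_id"], "detail": ""})

    if defects.duplicate_rate > 0:
        rng = _rng(1)
        if len(enc):
            ok = enc["end_ts"] >= enc["start_ts"]
            mask = (rng.random(len(enc)) < defects.duplicate_rate) & ok.to_numpy()
            dup = enc.loc[mask]
            for _, row in dup.iterrows():
                log.append({"kind": "duplicate", "table": "encounters", "mrn": row["mrn"],
                            "row_ref": row["encounter_id"], "detail": ""})
            enc = pd.concat([enc, dup], ignore_index=True)
        if len(ev):
            # MTP rows are excluded: the under-report defect drops them later
            # and must not be able to orphan one half of a duplicate pair
            eligible = (ev["event_type"] != "mtp_activation").to_numpy()
            mask = (rng.random(len(ev)) < defects.duplicate_rate) & eligible
            dup = ev.loc[mask]
            for idx, row in dup.iterrows():
                log.append({"kind": "duplicate", "table": "events", "mrn": row["mrn"],
                            "row_ref": f"row{idx}",
                            "detail": f"{row['event_type']}@{row['ts']}"})
            ev = pd.concat([ev, dup], ignore_index=True)

    if defects.self_consult_rate > 0 and len(enc):
        rng = _rng(2)
        new_rows = []
        ip = enc[enc["encounter_type"] == "IP"].sort_values("encounter_id")
        for _, row in ip.iterrows():
            if rng.random() < defects.self_consult_rate:
                ts = row["start_ts"] + pd.Timedelta(minutes=int(rng.integers(10, 90)))
                new_rows.append({
                    "mrn": row["mrn"], "event_type": "order", "order_subtype": "consult",
                    "ts": ts, "target_service": row["admitting_team"], "location": "",
                    "structured": 1,
                })
                log.append({"kind": "self_consult", "table": "events", "mrn": row["mrn"],
                            "row_ref": row["encounter_id"],
                            "detail": str(row["admitting_team"])})
        if new_rows:
            ev = pd.concat([ev, pd.DataFrame(new_rows, columns=EVENT_COLUMNS)], ignore_index=True)

    field_rates = dict(defects.missing_structured_field_rate)
    for j, (field_name, rate) in enumerate(sorted(field_rates.items())):
        if rate <= 0 or field_name not in enc.columns or not len(enc):
            continue
        rng = _rng(10 + j)
        # drawn per encounter id so duplicate row pairs stay exact copies
        ids = sorted(enc["encounter_id"].unique())
        chosen = {eid for eid in ids if rng.random() < rate}
        populated = enc[field_name].astype(str).str.len() > 0
        mask = enc["encounter_id"].isin(chosen).to_numpy() & populated.to_numpy()
        for idx in np.flatnonzero(mask):
            enc.loc[idx, field_name] = ""
            log.append({"kind": "missing_field", "table": "encounters",
                        "mrn": enc.loc[idx, "mrn"],
                        "row_ref": enc.loc[idx, "encounter_id"], "detail": field_name})

    if defects.demographic_overwrite_rate > 0 and len(enc):
        rng = _rng(3)
        for mrn, grp in enc.groupby("mrn", sort=True):
            if len(grp) < 2 or rng.random() >= defects.demographic_overwrite_rate:
                continue
            grp = grp.sort_values(["start_ts", "encounter_id"])
            latest = grp.iloc[-1]
            for idx in grp.index[:-1]:
                changed = []
                for col in ("postcode", "usual_accommodation"):
                    if enc.loc[idx, col] != latest[col]:
                        enc.loc[idx, col] = latest[col]
                        changed.append(col)
                if changed:
                    log.append({"kind": "demographic_overwrite", "table": "encounters",
                                "mrn": mrn, "row_ref": enc.loc[idx, "encounter_id"],
                                "detail": ",".join(changed)})

    if defects.high_acuity_underreport_fraction > 0 and len(ev):
        rng = _rng(4)
        mtp_idx = ev.index[ev["event_type"] == "mtp_activation"]
        drop = [int(idx) for idx in mtp_idx
                if rng.random() < defects.high_acuity_underreport_fraction]
        for idx in drop:
            log.append({"kind": "mtp_underreport", "table": "events",
                        "mrn": ev.loc[idx, "mrn"], "row_ref": f"row{idx}",
                        "detail": str(ev.loc[idx, "ts"])})
        ev = ev.drop(index=drop).reset_index(drop=True)

    return enc, ev, pd.DataFrame(log, columns=_empty_defects().columns)
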