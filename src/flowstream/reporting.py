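"""Stratified cohort summaries, source-by-stream tables and the data-quality
report.

All outputs are pure functions of the run artefacts: re-running a report on
saved inputs reproduces it exactly. Findings are descriptive only — no
inferential statistics are computed. Percentages are rendered to one decimal
place by the CSV writers in the CLI; values here are kept at full precision.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from flowstream._schema import ADMISSION_SOURCES, STREAMS, canonical_name
from flowstream.classifier import StreamAssignment
from flowstream.features import ResourceFeatures, episode_key
from flowstream.linkage_cleaning import AdmissionEpisode, CleaningLog

_QUARTILE_METHODS = {"linear": "linear", "nearest": "nearest"}


def _quartiles(values: Iterable[float], method: str) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=_QUARTILE_METHODS[method])
    return float(med), float(q1), float(q3)


def _as_stream_map(assignments) -> dict:
    if isinstance(assignments, Mapping):
        return dict(assignments)
    out = {}
    for a in assignments:
        if isinstance(a, StreamAssignment):
            out[a.episode_id if a.episode_id is not None else a.study_id] = a.stream
        else:
            raise TypeError("assignments must be StreamAssignments or a mapping")
    return out


def summarize_streams(
    episodes: list[AdmissionEpisode],
    discharge_assignments,
    features: Mapping[str, ResourceFeatures],
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Per-stream and overall summary: n, age, % female, LOS, admission-type
    mix, ICU %, polypharmacy %, allied health and consult counts.

    Medians/IQRs use the configured quartile definition (``linear``
    interpolation by default, ``nearest`` rank available). Mental Health
    admissions are excluded from the admission-type block only. Empty streams
    get an n=0 row with absent statistics, not zeros.
    """
    if quartile_method not in _QUARTILE_METHODS:
        raise ValueError(f"unknown quartile method: {quartile_method!r}")
    streams = _as_stream_map(discharge_assignments)
    for ep in episodes:
        if episode_key(ep) not in streams:
            raise ValueError(f"episode {episode_key(ep)} has no discharge assignment")

    rows = []
    groups = {name: [] for name in STREAMS}
    for ep in episodes:
        key = episode_key(ep)
        groups[streams[key]].append((ep, features[key]))

    def _summary(name: str, members: list) -> dict:
        row: dict = {"stream": name, "n": len(members)}
        if not members:
            return row
        eps = [ep for ep, _ in members]
        fts = [ft for _, ft in members]
        med, q1, q3 = _quartiles((ep.age for ep in eps), quartile_method)
        row.update(age_median=med, age_q1=q1, age_q3=q3)
        row["pct_female"] = 100.0 * sum(ep.gender == "female" for ep in eps) / len(eps)
        med, q1, q3 = _quartiles((ft.los_days_observed for ft in fts), quartile_method)
        row.update(los_median=med, los_q1=q1, los_q3=q3)
        non_mh = [ep for ep in eps if ep.admission_type != "Mental Health"]
        for adm_type in ("Medical", "Surgical", "Other"):
            n_type = sum(ep.admission_type == adm_type for ep in non_mh)
            row[f"n_{adm_type.lower()}"] = n_type
            row[f"pct_{adm_type.lower()}"] = (
                100.0 * n_type / len(non_mh) if non_mh else float("nan"))
        row["pct_icu"] = 100.0 * sum(ft.icu_hours_cumulative > 0 for ft in fts) / len(fts)
        row["pct_polypharmacy"] = 100.0 * sum(ft.polypharmacy_flag for ft in fts) / len(fts)
        med, q1, q3 = _quartiles((ft.n_allied_health for ft in fts), quartile_method)
        row.update(allied_median=med, allied_q1=q1, allied_q3=q3)
        med, q1, q3 = _quartiles((ft.n_consults_total for ft in fts), quartile_method)
        row.update(consults_median=med, consults_q1=q1, consults_q3=q3)
        return row

    for name in STREAMS:
        rows.append(_summary(name, groups[name]))
    rows.append(_summary("overall", [pair for name in STREAMS for pair in groups[name]]))
    return pd.DataFrame(rows)


def source_by_stream(
    episodes: list[AdmissionEpisode],
    discharge_assignments,
) -> pd.DataFrame:
    """Admission source (rows) by final stream (columns) count table."""
    streams = _as_stream_map(discharge_assignments)
    table = pd.DataFrame(0, index=list(ADMISSION_SOURCES), columns=list(STREAMS))
    for ep in episodes:
        if ep.admission_source not in ADMISSION_SOURCES:
            raise ValueError(f"unknown admission source: {ep.admission_source!r}")
        table.loc[ep.admission_source, streams[episode_key(ep)]] += 1
    table.index.name = "admission_source"
    table.columns.name = "stream"
    return table


def quality_report(
    raw_encounters: pd.DataFrame,
    raw_events: pd.DataFrame,
    cleaning_log: CleaningLog,
    episodes: list[AdmissionEpisode] | None = None,
    reference_counts: Mapping[str, float] | None = None,
    structured_fields: tuple[str, ...] = ("problem_list",),
) -> dict:
    """Data-quality metrics for one pipeline run.

    Returns a dict with per-field completeness, self-consult count/rate,
    duplicate and implausible row counts, the high-acuity (MTP) recorded ÷
    reference ratio (absent unless a positive external reference count is
    supplied), and — when episodes still carrying mrns are provided — the
    count of episodes whose demographic snapshot differs from the patient's
    latest recorded values.
    """
    report: dict = {}

    n_enc = len(raw_encounters)
    completeness = {}
    for fld in structured_fields:
        if fld not in raw_encounters.columns or n_enc == 0:
            completeness[fld] = float("nan")
        else:
            populated = raw_encounters[fld].fillna("").astype(str).str.strip().str.len() > 0
            completeness[fld] = float(populated.sum()) / n_enc
    report["field_completeness"] = completeness
    report["problem_list_population_rate"] = completeness.get("problem_list", float("nan"))

    # self-consults: consult orders addressed to the admitting team of the
    # patient's own encounter covering the order time
    consults = raw_events[
        (raw_events["event_type"] == "order") & (raw_events["order_subtype"] == "consult")
    ]
    n_self = 0
    if len(consults):
        enc = raw_encounters.copy()
        enc["_start"] = pd.to_datetime(enc["start_ts"], errors="coerce", format="mixed")
        enc["_end"] = pd.to_datetime(enc["end_ts"], errors="coerce", format="mixed")
        enc["_team"] = enc["admitting_team"].map(canonical_name)
        by_mrn = {mrn: grp for mrn, grp in enc.groupby("mrn", sort=False)}
        for row in consults.itertuples(index=False):
            grp = by_mrn.get(row.mrn)
            if grp is None:
                continue
            ts = pd.to_datetime(row.ts, errors="coerce")
            target = canonical_name(row.target_service)
            if target and ts is not pd.NaT:
                covering = grp[(grp["_start"] <= ts) & (ts <= grp["_end"]) & (grp["_team"] == target)]
                if len(covering):
                    n_self += 1
    report["self_consult_count"] = n_self
    report["self_consult_rate"] = n_self / len(consults) if len(consults) else float("nan")

    report["duplicate_rows_removed"] = cleaning_log.count("duplicate_removed")
    report["implausible_rows_excluded"] = cleaning_log.count("implausible_excluded")

    n_mtp = int((raw_events["event_type"] == "mtp_activation").sum())
    report["mtp_recorded_count"] = n_mtp
    ref = (reference_counts or {}).get("mtp_activation")
    report["mtp_reference_count"] = ref
    report["mtp_recorded_ratio"] = (n_mtp / ref) if ref else None

    if episodes is not None:
        inconsistent = _demographic_inconsistencies(raw_encounters, episodes)
        report["demographic_inconsistency_count"] = inconsistent
    return report


def _demographic_inconsistencies(raw_encounters: pd.DataFrame,
                                 episodes: list[AdmissionEpisode]) -> int | None:
    """Episodes whose snapshot (postcode, usual_accommodation) differs from
    the patient's latest recorded values. Requires episodes that still carry
    mrns (i.e. computed before de-identification)."""
    if any(ep.mrn is None for ep in episodes):
        return None
    enc = raw_encounters.copy()
    enc["_start"] = pd.to_datetime(enc["start_ts"], errors="coerce", format="mixed")
    latest = (
        enc.sort_values(["mrn", "_start"], kind="stable")
        .groupby("mrn", sort=False)
        .tail(1)
        .set_index("mrn")[["postcode", "usual_accommodation"]]
    )
    count = 0
    for ep in episodes:
        if ep.mrn not in latest.index:
            continue
        snap = latest.loc[ep.mrn]
        if (str(ep.postcode) != str(snap["postcode"])
                or str(ep.usual_accommodation) != str(snap["usual_accommodation"])):
            count += 1
    return count


def quality_report_frame(report: dict) -> pd.DataFrame:
    """Flatten a quality report dict into a (metric, value) frame for CSV."""
    rows = []
    for key, value in report.items():
        if isinstance(value, dict):
            for sub, v in value.items():
                rows.append({"metric": f"{key}.{sub}", "value": v})
        else:
            rows.append({"metric": key, "value": value})
    return pd.DataFrame(rows, columns=["metric", "value"])
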