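"""Column dictionaries and canonicalisation helpers shared across the pipeline."""

from __future__ import annotations

import pandas as pd

# Closed vocabularies -------------------------------------------------------

ENCOUNTER_TYPES = ("ED", "IP", "OPD", "ITF")
ADMISSION_SOURCES = ("ED", "OPD", "IP", "ITF")
ADMISSION_TYPES = ("Medical", "Surgical", "Other", "Mental Health")
STREAMS = ("FS1", "FS2", "FS3", "FS4")

EVENT_TYPES = (
    "order",
    "location_transfer",
    "icu_entry",
    "icu_exit",
    "theatre_emergency",
    "mtp_activation",
)
ORDER_SUBTYPES = (
    "blood_test",
    "ct",
    "mr",
    "ir",
    "consult",
    "group_hold",
    "medication",
    "allied_health_consult",
    "pharmacy_consult",
    "one_to_one_nursing",
    "risk_assessment",
)

# Column dictionaries -------------------------------------------------------
# encounters.csv: one row per raw EMR encounter.
ENCOUNTER_COLUMNS = [
    "mrn",                 # patient identifier (removed at de-identification)
    "encounter_id",        # unique per encounter row
    "encounter_type",      # ED | IP | OPD | ITF
    "start_ts",            # ISO 8601, minute resolution
    "end_ts",
    "admitting_team",      # service name (free text, canonicalised by cleaning)
    "ward",                # location name
    "age",                 # years at encounter start
    "gender",
    "postcode",
    "usual_accommodation",
    "admission_type",      # Medical | Surgical | Other | Mental Health
    "day_procedure",       # 0/1 scheduled day-procedure indicator
    "problem_list",        # structured problem-list field; empty = not populated
]

# events.csv: one row per timestamped order / transfer / ICU / acuity event.
EVENT_COLUMNS = [
    "mrn",
    "event_type",          # see EVENT_TYPES
    "order_subtype",       # see ORDER_SUBTYPES; present iff event_type == "order"
    "ts",                  # ISO 8601, minute resolution
    "target_service",      # consults only: service the consult is addressed to
    "location",            # location_transfer only: destination
    "structured",          # 0/1 whether captured in a structured field
]

TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


def canonical_name(value: object) -> str:
    """Canonical form for team/location names: trimmed, inner-whitespace
    collapsed, case-folded. Empty / missing values map to ''."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    text = str(value)
    if text.lower() == "nan":
        return ""
    return " ".join(text.split()).casefold()


def write_table(df: pd.DataFrame, path, timestamp_columns=()) -> None:
    """Write a CSV deterministically: fixed column order, ISO 8601 timestamps,
    no index. Identical frames produce byte-identical files."""
    out = df.copy()
    for col in timestamp_columns:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime(TS_FORMAT)
    out.to_csv(path, index=False)
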