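"""Configuration objects for the synthetic cohort generator.

Defaults are anchored to the reference stream profiles: length-of-stay medians
0.2 / 2.0 / 8.4 / 11.2 days, cohort mixing 45.0 / 32.7 / 18.6 / 3.7 %, ICU
admission in 3.1 % of FS1 and 96 % of FS4, polypharmacy in 0.6 % of FS1 and
93 % of FS3. Distributional shapes are stand-ins: the reference profiles give only
medians, IQRs and percentages, so log-normal LOS and Poisson counts are used
with dispersion chosen to bracket the printed IQRs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from flowstream._schema import STREAMS


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class ArchetypeParams:
    """Resource-intensity parameters for one stream archetype."""

    los_median_days: float
    los_sigma: float
    los_min_days: float
    los_max_days: float
    consult_mean: float              # external consult orders per episode
    blood_mean: float                # blood-test orders per episode
    imaging_probability: float       # P(>=1 CT/MR order)
    ir_probability: float = 0.0
    icu_probability: float = 0.0
    icu_hours_lo: float = 2.0
    icu_hours_hi: float = 12.0
    transfer_mean: float = 0.0
    polypharmacy_fraction: float = 0.0   # P(>=5 medication orders)
    allied_health_mean: float = 0.0
    day_procedure_probability: float = 0.0
    group_hold_probability: float = 0.0
    mtp_probability: float = 0.0
    one_to_one_probability: float = 0.0
    risk_assessment_probability: float = 0.3
    source_weights: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05)
    #    over admission sources (ED, OPD, IP, ITF)
    admission_type_weights: tuple[float, float, float] = (0.60, 0.35, 0.05)
    #    over (Medical, Surgical, Other)
    age_median: float = 63.0
    age_sd: float = 18.0
    female_fraction: float = 0.42


def _default_archetypes() -> dict[str, ArchetypeParams]:
    return {
        # Short-stay / ambulatory day care: LOS under a day, minimal workup.
        "FS1": ArchetypeParams(
            los_median_days=0.2, los_sigma=0.30, los_min_days=0.05, los_max_days=0.95,
            consult_mean=0.05, blood_mean=0.7, imaging_probability=0.15,
            icu_probability=0.031, icu_hours_lo=1.0, icu_hours_hi=4.0,
            transfer_mean=0.1, polypharmacy_fraction=0.006, allied_health_mean=0.05,
            day_procedure_probability=1.0, risk_assessment_probability=0.1,
            source_weights=(0.15, 0.70, 0.10, 0.05),
            admission_type_weights=(0.724, 0.187, 0.089),
            age_median=61.0, female_fraction=0.40,
        ),
        # Single-specialty admission, short stay, at most one external consult.
        "FS2": ArchetypeParams(
            los_median_days=2.0, los_sigma=0.55, los_min_days=0.30, los_max_days=4.90,
            consult_mean=0.6, blood_mean=2.0, imaging_probability=0.40,
            transfer_mean=0.8, polypharmacy_fraction=0.20, allied_health_mean=0.4,
            risk_assessment_probability=0.3,
            source_weights=(0.70, 0.10, 0.12, 0.08),
            admission_type_weights=(0.492, 0.498, 0.010),
            age_median=62.0, female_fraction=0.44,
        ),
        # Intermediate-complexity multidisciplinary admission: >1 consult, LOS >= 5 d.
        "FS3": ArchetypeParams(
            los_median_days=8.4, los_sigma=0.45, los_min_days=5.05, los_max_days=45.0,
            consult_mean=1.2, blood_mean=6.0, imaging_probability=0.50,
            ir_probability=0.05,
            transfer_mean=2.0, polypharmacy_fraction=0.93, allied_health_mean=3.0,
            risk_assessment_probability=0.7,
            source_weights=(0.70, 0.05, 0.15, 0.10),
            admission_type_weights=(0.600, 0.397, 0.003),
            age_median=70.0, female_fraction=0.44,
        ),
        # Hypercomplex, high-acuity admission with intensive resource mobilisation.
        "FS4": ArchetypeParams(
            los_median_days=11.2, los_sigma=0.80, los_min_days=1.50, los_max_days=90.0,
            consult_mean=2.0, blood_mean=8.0, imaging_probability=0.90,
            ir_probability=0.15,
            icu_probability=0.96, icu_hours_lo=26.0, icu_hours_hi=120.0,
            transfer_mean=3.0, polypharmacy_fraction=0.90, allied_health_mean=3.0,
            group_hold_probability=0.30, mtp_probability=0.15,
            one_to_one_probability=0.25, risk_assessment_probability=0.8,
            source_weights=(0.60, 0.02, 0.18, 0.20),
            admission_type_weights=(0.438, 0.561, 0.001),
            age_median=62.0, female_fraction=0.38,
        ),
    }


@dataclass
class CohortConfig:
    """Configuration for :func:`flowstream.synthetic_emr.generate_cohort`."""

    n_patients: int = 1000
    mixing_weights: tuple[float, float, float, float] = (0.450, 0.327, 0.186, 0.037)
    escalation_fraction: float = 0.04
    archetypes: dict[str, ArchetypeParams] = field(default_factory=_default_archetypes)
    seed: int = 0
    calendar_start: str = "2024-01-01"
    calendar_days: int = 365
    multi_episode_probability: float = 0.08
    multi_episode_gap_median_hours: float = 240.0
    multi_episode_gap_sigma: float = 0.6
    multi_episode_gap_min_hours: float = 48.0
    ed_lead_hours_max: float = 6.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if len(self.mixing_weights) != 4:
            raise ConfigError("mixing_weights must have four entries (FS1..FS4)")
        if any(w < 0 for w in self.mixing_weights):
            raise ConfigError("mixing_weights must be non-negative")
        if abs(sum(self.mixing_weights) - 1.0) > 1e-9:
            raise ConfigError("mixing_weights must sum to 1 within 1e-9")
        if not 0.0 <= self.escalation_fraction <= 1.0:
            raise ConfigError("escalation_fraction must be in [0, 1]")
        if set(self.archetypes) != set(STREAMS):
            raise ConfigError("archetypes must define exactly FS1, FS2, FS3, FS4")
        for name, params in self.archetypes.items():
            for fld in ("los_median_days", "los_sigma", "los_min_days", "los_max_days"):
                if getattr(params, fld) <= 0:
                    raise ConfigError(f"archetypes[{name}].{fld} must be > 0")
            if params.los_min_days >= params.los_max_days:
                raise ConfigError(f"archetypes[{name}].los_min_days must be < los_max_days")
            for fld in (
                "imaging_probability", "ir_probability", "icu_probability",
                "polypharmacy_fraction", "day_procedure_probability",
                "group_hold_probability", "mtp_probability",
                "one_to_one_probability", "risk_assessment_probability",
                "female_fraction",
            ):
                if not 0.0 <= getattr(params, fld) <= 1.0:
                    raise ConfigError(f"archetypes[{name}].{fld} must be in [0, 1]")
            for fld in ("consult_mean", "blood_mean", "transfer_mean", "allied_health_mean"):
                if getattr(params, fld) < 0:
                    raise ConfigError(f"archetypes[{name}].{fld} must be >= 0")
            if params.icu_hours_lo <= 0 or params.icu_hours_hi < params.icu_hours_lo:
                raise ConfigError(f"archetypes[{name}].icu_hours range invalid")
        if not 0.0 <= self.multi_episode_probability <= 1.0:
            raise ConfigError("multi_episode_probability must be in [0, 1]")
        if self.multi_episode_gap_min_hours <= 0:
            raise ConfigError("multi_episode_gap_min_hours must be > 0")
        if self.calendar_days <= 0:
            raise ConfigError("calendar_days must be > 0")


@dataclass
class DefectConfig:
    """Rates for the injected documentation-defect catalogue.

    ``missing_structured_field_rate`` maps field name to blanking rate; the
    default leaves the structured problem list unpopulated in 27 % of
    encounters. ``high_acuity_underreport_fraction`` drops MTP activation
    events so that roughly 144 of every 355 true activations survive.
    """

    duplicate_rate: float = 0.0
    negative_duration_rate: float = 0.0
    self_consult_rate: float = 0.0
    missing_structured_field_rate: Mapping[str, float] = field(
        default_factory=lambda: {"problem_list": 0.27}
    )
    demographic_overwrite_rate: float = 0.0
    high_acuity_underreport_fraction: float = 1.0 - 144.0 / 355.0
    seed_offset: int = 1_000_003

    def validate(self) -> None:
        for fld in (
            "duplicate_rate", "negative_duration_rate", "self_consult_rate",
            "demographic_overwrite_rate", "high_acuity_underreport_fraction",
        ):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1]")
        for name, rate in self.missing_structured_field_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing_structured_field_rate[{name}] must be in [0, 1]")

    @classmethod
    def none(cls) -> "DefectConfig":
        """A configuration that injects nothing."""
        return cls(missing_structured_field_rate={}, high_acuity_underreport_fraction=0.0)


def _build(cls, data: Mapping) -> object:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    return cls(**data)


def load_cohort_config(path: str | Path) -> tuple[CohortConfig, DefectConfig]:
    """Load a (cohort, defects) configuration from a TOML or JSON file.

    The file may contain top-level cohort fields, an ``[archetypes.FSx]``
    table of overrides, and a ``[defects]`` table.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        import tomllib

        data = tomllib.loads(path.read_text())
    data = dict(data)
    defect_data = data.pop("defects", {})
    arch_over = data.pop("archetypes", {})
    for key in ("mixing_weights", "source_weights", "admission_type_weights"):
        if key in data:
            data[key] = tuple(data[key])
    cohort = _build(CohortConfig, data)
    for name, over in arch_over.items():
        if name not in cohort.archetypes:
            raise ConfigError(f"archetypes.{name}: unknown archetype")
        for key, value in over.items():
            if not hasattr(cohort.archetypes[name], key):
                raise ConfigError(f"archetypes.{name}.{key}: unknown field")
            if key in ("source_weights", "admission_type_weights"):
                value = tuple(value)
            setattr(cohort.archetypes[name], key, value)
    defects = _build(DefectConfig, defect_data)
    cohort.validate()
    defects.validate()
    return cohort, defects
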