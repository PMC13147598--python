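import pandas as pd
import pytest

from flowstream.classifier import RuleConfig, classify_trajectories
from flowstream.config import CohortConfig, DefectConfig
from flowstream.linkage_cleaning import clean_events, deidentify, link_episodes
from flowstream.synthetic_emr import generate_cohort


def build_cohort(n_patients, seed=7, defects=None, **overrides):
    cfg = CohortConfig(n_patients=n_patients, seed=seed, **overrides)
    return generate_cohort(cfg, defects)


def link_cohort(encounters, events, gap_hours=6.0, deident=True):
    enc, ev, log = clean_events(encounters, events)
    episodes, orphans = link_episodes(enc, ev, gap_threshold_hours=gap_hours)
    identity = None
    if deident:
        episodes, identity = deidentify(episodes)
    return episodes, identity, log, orphans


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient defect-free cohort shared across read-only tests."""
    return build_cohort(300, seed=7)


@pytest.fixture(scope="session")
def linked_small_cohort(small_cohort):
    encounters, events, truth = small_cohort
    episodes, identity, log, orphans = link_cohort(encounters, events)
    return episodes, identity, truth


@pytest.fixture(scope="session")
def classified_small_cohort(linked_small_cohort):
    episodes, identity, truth = linked_small_cohort
    trajectories = classify_trajectories(episodes, RuleConfig())
    return episodes, identity, truth, trajectories


@pytest.fixture()
def rules():
    return RuleConfig()


def intended_stream_map(truth, identity):
    """study_id -> (intended stream, escalated flag)."""
    by_mrn = {
        row.mrn: (row.intended_stream, bool(row.escalated))
        for row in truth.patients.itertuples()
    }
    return {
        row.study_id: by_mrn[row.mrn] for row in identity.pairs.itertuples()
    }


@pytest.fixture(scope="session")
def defect_config():
    return DefectConfig(
        duplicate_rate=0.05,
        negative_duration_rate=0.02,
        self_consult_rate=0.05,
        missing_structured_field_rate={"problem_list": 0.27},
        demographic_overwrite_rate=0.3,
        high_acuity_underreport_fraction=1.0 - 144.0 / 355.0,
    )
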