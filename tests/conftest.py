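import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import vagidyn as v

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


GROUP_TAXA = list(v.synthetic_cohort.GROUP_TAXA)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with default effects, shared across read-only tests."""
    cfg = v.CohortConfig(n_placebo=6, n_treatment=10, seed=42)
    return v.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (18 placebo / 34 treatment) under default effects."""
    return v.generate_cohort(v.CohortConfig(seed=7))


@pytest.fixture()
def tiny_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "taxon_id\tS1\tS2\n"
        "ASV_a\t60\t10\n"
        "ASV_b\t40\t90\n"
    )
    return path


@pytest.fixture()
def tiny_taxonomy_tsv(tmp_path):
    path = tmp_path / "taxonomy.tsv"
    path.write_text(
        "asv_id\tgenus\tsubgenus_group\n"
        "ASV_a\tLactobacillus\tL_crispatus_group\n"
        "ASV_b\tGardnerella\t\n"
    )
    return path


def make_design(rows):
    """rows: (sample_id, participant_id, arm, timepoint)"""
    return v.StudyDesign(
        pd.DataFrame(
            rows, columns=["sample_id", "participant_id", "arm", "timepoint"]
        ).set_index("sample_id")
    )


def composition(**kw):
    """Relative abundance Series over the synthetic group-level taxa."""
    comp = pd.Series(0.0, index=GROUP_TAXA)
    for k, val in kw.items():
        comp[k] = val
    leftover = 1.0 - comp.sum()
    assert leftover >= -1e-12
    comp["unclassified"] += leftover
    return comp
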