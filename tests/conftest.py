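"""Shared fixtures: the 20-fish histology cohort and small simulated inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from testispec import CohortRecord, ExpressionMatrix, RunConfig
from testispec.simulate import SimulationConfig

# Printed histology overview of the 20-male cohort: (fish, most advanced
# stage, dominant stage, compartment size, observations).  The first 14 fish
# are immature (spermatogonia A only), the last 6 show advanced stages.
HISTOLOGY_ROWS = [
    ("188", "SPA", "SPA", "small", ()),
    ("233", "SPA", "SPA", "small", ()),
    ("240", "SPA", "SPA", "small", ()),
    ("176", "SPA", "SPA", "small", ()),
    ("193", "SPA", "SPA", "small", ()),
    ("203", "SPA", "SPA", "medium", ("tubules", "high cell division")),
    ("236", "SPA", "SPA", "small", ()),
    ("160", "SPA", "SPA", "medium", ("tubules", "high cell division")),
    ("198", "SPA", "SPA", "small", ("oocytes",)),
    ("255", "SPA", "SPA", "small", ("oocytes",)),
    ("250", "SPA", "SPA", "small", ()),
    ("221", "SPA", "SPA", "small", ("oocytes",)),
    ("226", "SPA", "SPA", "small", ()),
    ("180", "SPA", "SPA", "small", ()),
    ("184", "SPT", "SPB", "medium", ()),
    ("190", "SPT", "SPC", "large", ()),
    ("213", "SPC", "SPC", "large", ()),
    ("245", "SZ", "SPC", "large", ()),
    ("211", "SZ", "SPC", "large", ()),
    ("202", "SZ", "SPC", "large", ()),
]

# GSI (%): the values for fish 203, 160 and 250 are the published ones; the
# rest are synthetic, drawn once inside the groups' ranges (immature
# 0.01-0.08, pubertal 0.23-0.60) and frozen here.
GSI_PERCENT = {
    "188": 0.012, "233": 0.018, "240": 0.022, "176": 0.028, "193": 0.034,
    "203": 0.023, "236": 0.046, "160": 0.031, "198": 0.055, "255": 0.060,
    "250": 0.043, "221": 0.068, "226": 0.072, "180": 0.078,
    "184": 0.23, "190": 0.29, "213": 0.35, "245": 0.42, "211": 0.51,
    "202": 0.58,
}


@pytest.fixture(scope="session")
def cohort_records() -> list[CohortRecord]:
    return [
        CohortRecord(fish_id=fid, gsi=GSI_PERCENT[fid],
                     most_advanced_stage=most, dominant_stage=dom,
                     compartment_size=size, observations=obs)
        for fid, most, dom, size, obs in HISTOLOGY_ROWS
    ]


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = np.exp2(rng.normal(7, 1.5, size=(100, 20)))
    genes = [f"G{i:03d}" for i in range(100)]
    samples = [f"S{i:02d}" for i in range(20)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def two_groups(small_matrix) -> pd.Series:
    """14 immature + 6 pubertal labels for the 20 columns of small_matrix."""
    labels = ["immature"] * 14 + ["pubertal"] * 6
    return pd.Series(labels, index=small_matrix.sample_ids)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_genes=400)
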