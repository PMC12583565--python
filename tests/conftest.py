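"""Shared fixtures: the study-like synthetic suite and derived objects.

Expensive objects (fixture cohort, DMP table, trained model) are
session-scoped; tests treat them as read-only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from episig.dmp import moderated_t_test, select_probes
from episig.model import partition_training, train_classifier
from episig.simulate import fixture_objects
from episig.types import BetaMatrix, SampleSheet

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_suite():
    """(manifest, beta, sheet, truth) for the bundled study-like cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected planted-mean clipping
        return fixture_objects(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dmp(fixture_suite):
    _, beta, sheet, _ = fixture_suite
    return moderated_t_test(beta, sheet)


@pytest.fixture(scope="session")
def fixture_probes(fixture_dmp):
    return select_probes(fixture_dmp)


@pytest.fixture(scope="session")
def fixture_model(fixture_suite, fixture_probes):
    _, beta, sheet, _ = fixture_suite
    train_ids, test_ids = partition_training(sheet, 0.75, FIXTURE_SEED)
    return train_classifier(beta, fixture_probes, train_ids, sheet,
                            seed=FIXTURE_SEED, test_ids=test_ids)


@pytest.fixture()
def tiny_beta():
    """3 probes x 4 samples, hand-enterable values."""
    data = pd.DataFrame(
        {
            "s1": [0.10, 0.50, 0.90],
            "s2": [0.20, 0.55, 0.85],
            "s3": [0.15, 0.45, 0.80],
            "s4": [0.25, 0.60, 0.95],
        },
        index=["cgA", "cgB", "cgC"],
    )
    return BetaMatrix(data)


def make_sheet(case_ids, control_ids, **extra_roles):
    """Build a SampleSheet from id lists (extra_roles: role -> ids)."""
    rows = [(s, "case", "cases") for s in case_ids]
    rows += [(s, "control", "controls") for s in control_ids]
    for role, ids in extra_roles.items():
        rows += [(s, role, role) for s in ids]
    df = pd.DataFrame(rows, columns=["sample_id", "role", "cohort_label"])
    return SampleSheet(df.set_index("sample_id"))


def group_scores(score_table: pd.DataFrame, prefix: str) -> np.ndarray:
    s = score_table.set_index("sample_id")["mvp_score"]
    return s[[i for i in s.index if i.startswith(prefix)]].to_numpy()
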