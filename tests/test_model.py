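"""SVM episignature classifier: partitions, calibration, LOOCV, screening."""

import numpy as np
import pandas as pd
import pytest

from conftest import FIXTURE_SEED, group_scores, make_sheet
from episig.model import (EpisignatureModel, loo_cross_validate, mvp_score,
                          partition_training, screen_samples,
                          train_classifier)
from episig.types import ValidationError


def test_partition_arithmetic_40_controls():
    sheet = make_sheet([], [f"c{i}" for i in range(40)])
    train, test = partition_training(sheet, 0.75, seed=7)
    assert len(train) == 30 and len(test) == 10
    assert not set(train) & set(test)


def test_partition_stratifies_within_cohorts():
    rows = [(f"a{i}", "other_disorder", "dA") for i in range(8)]
    rows += [(f"b{i}", "other_disorder", "dB") for i in range(8)]
    from episig.types import SampleSheet
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "role", "cohort_label"]).set_index("sample_id"))
    train, test = partition_training(sheet, 0.75, seed=1)
    for prefix in ("a", "b"):
        assert sum(s.startswith(prefix) for s in train) == 6
        assert sum(s.startswith(prefix) for s in test) == 2


def test_partition_deterministic_and_cases_always_train():
    sheet = make_sheet([f"k{i}" for i in range(5)], [f"c{i}" for i in range(12)])
    a = partition_training(sheet, 0.75, seed=3)
    b = partition_training(sheet, 0.75, seed=3)
    assert a == b
    assert all(f"k{i}" in a[0] for i in range(5))


def test_tiny_cohort_goes_wholly_to_train():
    sheet = make_sheet(["k0", "k1"], ["c0", "c1", "c2"],
                       other_disorder=["solo"])
    with pytest.warns(UserWarning, match="<2 samples"):
        train, test = partition_training(sheet, 0.75, seed=0)
    assert "solo" in train and "solo" not in test


def test_training_separates_planted_fixture(fixture_suite, fixture_model):
    _, beta, sheet, _ = fixture_suite
    scores = mvp_score(fixture_model, beta)
    train_cases = scores[(scores["partition"] == "train")
                         & scores["sample_id"].str.startswith("case_")]
    assert (train_cases["mvp_score"] > 0.9).all()
    train_controls = scores[(scores["partition"] == "train")
                            & scores["sample_id"].str.startswith("control_")]
    assert (train_controls["mvp_score"] < 0.1).all()


def test_retraining_is_deterministic(fixture_suite, fixture_probes):
    _, beta, sheet, _ = fixture_suite
    train_ids, test_ids = partition_training(sheet, 0.75, FIXTURE_SEED)
    a = train_classifier(beta, fixture_probes, train_ids, sheet,
                         seed=FIXTURE_SEED, test_ids=test_ids)
    b = train_classifier(beta, fixture_probes, train_ids, sheet,
                         seed=FIXTURE_SEED, test_ids=test_ids)
    np.testing.assert_allclose(a.weights, b.weights, atol=1e-8)
    assert a.intercept == pytest.approx(b.intercept, abs=1e-8)


def test_single_class_training_rejected(fixture_suite, fixture_probes):
    _, beta, sheet, _ = fixture_suite
    controls = sheet.ids_with_role("control")
    with pytest.raises(ValidationError, match="both classes"):
        train_classifier(beta, fixture_probes, controls, sheet)


def test_model_json_round_trip_preserves_scores(tmp_path, fixture_suite,
                                                fixture_model):
    _, beta, _, _ = fixture_suite
    path = tmp_path / "model.json"
    fixture_model.save(path)
    back = EpisignatureModel.load(path)
    a = mvp_score(fixture_model, beta)["mvp_score"].to_numpy()
    b = mvp_score(back, beta)["mvp_score"].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_corrupt_model_json_rejected(tmp_path):
    path = tmp_path / "model.json"
    path.write_text("{not json")
    with pytest.raises(ValidationError, match="corrupt"):
        EpisignatureModel.load(path)
    path.write_text('{"schema_version": 99}')
    with pytest.raises(ValidationError, match="schema_version"):
        EpisignatureModel.load(path)


def test_missing_probe_is_an_error_not_imputed(fixture_suite, fixture_model):
    _, beta, _, _ = fixture_suite
    first_probe = fixture_model.probe_set.probe_ids[0]
    reduced = beta.data.drop(index=first_probe)
    from episig.types import BetaMatrix
    with pytest.raises(ValidationError, match=first_probe):
        mvp_score(fixture_model, BetaMatrix(reduced))


def test_scores_bounded_even_for_extreme_inputs(fixture_model):
    """Calibration output stays in [0, 1] for arbitrary valid betas."""
    from episig.types import BetaMatrix
    rng = np.random.default_rng(0)
    probes = fixture_model.probe_set.probe_ids
    data = pd.DataFrame(
        np.column_stack([np.zeros(len(probes)), np.ones(len(probes)),
                         rng.uniform(0, 1, len(probes))]),
        index=probes, columns=["all0", "all1", "rand"])
    scores = mvp_score(fixture_model, BetaMatrix(data))["mvp_score"]
    assert ((scores >= 0) & (scores <= 1)).all()


def test_held_out_specificity_and_test_sample_scores(fixture_suite,
                                                     fixture_model):
    """Held-out background samples score low; signature carriers high."""
    _, beta, sheet, _ = fixture_suite
    scores = mvp_score(fixture_model, beta)
    held_out = scores[scores["partition"] == "test"]["mvp_score"]
    assert (held_out < 0.5).all()
    assert (group_scores(scores, "validation") > 0.5).all()
    assert (group_scores(scores, "unresolved") > 0.5).all()
    assert (group_scores(scores, "vus") < 0.1).all()


def test_mosaic_score_monotone_in_dilution(fixture_suite, fixture_probes,
                                           fixture_model):
    """Median MVP is non-decreasing in the mosaic fraction."""
    import dataclasses
    import warnings

    from episig.simulate import FIXTURE_CONFIG, simulate_cohort, \
        simulate_manifest

    cfg = dataclasses.replace(FIXTURE_CONFIG, seed=FIXTURE_SEED,
                              mosaic_fractions=[0.0, 0.25, 0.5, 0.75, 1.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = simulate_manifest(cfg)
        beta, sheet, truth = simulate_cohort(cfg, manifest)
    mosaic_ids = [f"mosaic_{j+1:02d}" for j in range(5)]
    scores = mvp_score(fixture_model, beta, mosaic_ids)["mvp_score"].to_numpy()
    assert (np.diff(scores) >= -1e-9).all()
    assert scores[0] < 0.5 < scores[-1]


def test_screening_orders_flags_and_handles_empty(fixture_suite,
                                                  fixture_model):
    _, beta, sheet, _ = fixture_suite
    screen_ids = (sheet.ids_with_cohort("unresolved")
                  + sheet.ids_with_cohort("vus"))
    table = screen_samples(fixture_model, beta, screen_ids)
    assert (table["mvp_score"].diff().dropna() <= 1e-12).all()  # descending
    called = set(table[table["called"]]["sample_id"])
    assert called == set(sheet.ids_with_cohort("unresolved"))

    empty = screen_samples(fixture_model, beta, [])
    assert len(empty) == 0

    training_cases = screen_samples(fixture_model, beta,
                                    sheet.ids_with_role("case"))
    assert training_cases["called"].all()


def test_loocv_rounds_and_errors(fixture_suite):
    _, beta, sheet, _ = fixture_suite
    report = loo_cross_validate(beta, sheet, seed=FIXTURE_SEED)
    assert len(report) == 14  # one round per case
    assert (report["mvp"] > 0.5).all()
    assert report["clusters_with_cases"].all()

    two_cases = sheet.subset(sheet.ids_with_role("case")[:2]
                             + sheet.ids_with_role("control"))
    with pytest.raises(ValidationError, match=">=3 cases"):
        loo_cross_validate(beta, two_cases)
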