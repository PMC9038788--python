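"""Shared fixtures.

The expensive session fixture (`study`) trains the full desk-scale study:
both cross-validated ensembles plus QC models on 40 phantoms, with 20
held-out phantoms for evaluation. It is built once per session and shared by
the end-to-end and acceptance tests; per-case slice-extraction predictions on
the held-out set (and their disk-excluding crops) are cached alongside.
"""

from __future__ import annotations

import numpy as np
import pytest

import bodycomp as bc

TRAIN_SEED = 101
TEST_SEED = 202
COHORT_SEED = 303


@pytest.fixture(scope="session")
def phantom_case():
    return bc.generate_phantom(bc.PhantomSpec(seed=7), case_id="fix7")


@pytest.fixture(scope="session")
def small_cohort():
    cases, _ = bc.generate_cohort(6, bc.PhantomSpec(), seed=5)
    return cases


@pytest.fixture(scope="session")
def tiny_bundle(small_cohort):
    """A structurally complete but minimally trained bundle (fast)."""
    return bc.build_bundle(
        small_cohort,
        extractor_config=bc.ExtractorConfig(folds=2, epochs=2, seed=1),
        segmenter_config=bc.CDFNetConfig(folds=2, epochs=2, seed=1),
    )


@pytest.fixture(scope="session")
def study():
    """The full desk-scale study: train on 40 phantoms, hold out 20."""
    train_cases, _ = bc.generate_cohort(40, bc.PhantomSpec(), seed=TRAIN_SEED)
    test_cases, _ = bc.generate_cohort(20, bc.PhantomSpec(), seed=TEST_SEED,
                                       id_prefix="test")
    bundle = bc.build_bundle(train_cases)
    return {"bundle": bundle, "train": train_cases, "test": test_cases}


@pytest.fixture(scope="session")
def heldout_predictions(study):
    """Slice-extraction results for the held-out phantoms and their crops."""
    bundle = study["bundle"]
    preds, crop_preds = {}, {}
    for i, case in enumerate(study["test"]):
        preds[case.case_id] = bc.predict_disk(bundle.extractor, case.volume)
        crop = bc.crop_excluding_disk(case.volume, case.annotation,
                                      margin_mm=10.0, rng_seed=900 + i)
        crop_preds[case.case_id] = bc.predict_disk(bundle.extractor, crop)
    return {"full": preds, "cropped": crop_preds}
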