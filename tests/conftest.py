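"""Shared fixtures: simulated records and an extracted cohort matrix."""

import numpy as np
import pytest

from beatselect.features import FeatureMatrix, extract_features
from beatselect.preprocess import filter_record
from beatselect.synthetic import SimSpec, simulate_patients, simulate_record


@pytest.fixture(scope="session")
def sim200():
    """One 200-beat simulated record (all four classes usually present)."""
    return simulate_record(SimSpec(seed=7, n_beats=200))


@pytest.fixture(scope="session")
def matrix200(sim200):
    """Imputed 200 x 249 feature matrix for the simulated record."""
    rec = filter_record(sim200.record)
    return extract_features(rec, sim200.beats_ref, sim200.beats_det,
                            sim200.fiducials)


@pytest.fixture(scope="session")
def cohort():
    """A 9-patient cohort (6 train / 3 test) with its pooled feature matrix.

    Built once per session: extraction dominates the cost and several
    interpatient tests share the result.
    """
    sims = simulate_patients(9, 250, seed=11)
    parts = [
        extract_features(filter_record(s.record), s.beats_ref, s.beats_det,
                         s.fiducials)
        for s in sims
    ]
    fm = FeatureMatrix.concat(parts)
    ids = [s.record.record_id for s in sims]
    return {"sims": sims, "matrix": fm, "train_ids": ids[:6], "test_ids": ids[6:]}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
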