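import warnings

import numpy as np
import pytest

import focikit as fk


@pytest.fixture(scope="session")
def default_optics():
    return fk.OpticsModel()


@pytest.fixture(scope="session")
def two_timepoint_kinetics():
    return fk.KineticsParams(timepoints_min=(45, 120))


@pytest.fixture(scope="session")
def small_course(two_timepoint_kinetics):
    """One 20-nucleus field imaged at 45 and 120 min, with ground truth."""
    layout = fk.SimLayout(800, 800, 20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        images, gt = fk.generate_time_course(
            layout, fk.OpticsModel(), fk.NoiseModel(), two_timepoint_kinetics,
            seed=11)
    return layout, images, gt


@pytest.fixture(scope="session")
def noiseless_course():
    """Well-separated, modest-count, noiseless field: the detector should be
    exact on it."""
    layout = fk.SimLayout(800, 800, 12, n_distractors=0)
    kin = fk.KineticsParams(timepoints_min=(45, 120), initial_count_mean=6.0,
                            initial_count_sd=1.5)
    noise = fk.NoiseModel(shot_noise=False, read_noise_sd=0.0)
    images, gt = fk.generate_time_course(layout, fk.OpticsModel(), noise, kin,
                                         seed=5)
    return layout, images, gt


def match_detected_to_planted(records, cells):
    """Map detected nucleus labels to planted cell ids by nearest centre."""
    from scipy.spatial import cKDTree
    tree = cKDTree(cells[["row", "col"]].to_numpy())
    out = {}
    for r in records.itertuples():
        _, i = tree.query([r.centroid_row, r.centroid_col])
        out[int(r.label)] = int(cells.iloc[i].cell_id)
    return out
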