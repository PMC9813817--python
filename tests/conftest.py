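"""Shared fixtures: small simulated studies and toy paired-epoch frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hragree.io_align import (pair_study, schedules_from_frame,
                              series_from_frame)
from hragree.synthetic_data import (DeviceErrorModel, SimulationConfig,
                                    generate_study, schedule_frame)


def make_paired(diffs, hr_ref=80.0, subjects=None, phase="relaxation"):
    """Toy paired-epochs frame from explicit differences."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    ref = np.full(n, hr_ref) if np.isscalar(hr_ref) else np.asarray(hr_ref)
    if subjects is None:
        subjects = ["S1"] * n
    phases = [phase] * n if isinstance(phase, str) else list(phase)
    return pd.DataFrame({
        "subject": subjects, "phase": phases, "epoch_index": np.arange(n),
        "hr_ref": ref, "hr_test": ref + diffs, "diff": diffs,
    })


def paired_from_study(config, ref_model, test_model, epoch_s=5.0):
    study = generate_study(config, ref_model, test_model)
    series = series_from_frame(study)
    schedules = schedules_from_frame(schedule_frame(config))
    return pair_study(series, schedules, ref_model.device_label,
                      test_model.device_label, epoch_s=epoch_s)


@pytest.fixture(scope="session")
def small_paired():
    """20-subject study with a biased, noisy wearable; reused read-only."""
    config = SimulationConfig(n_subjects=20, seed=11)
    ref = DeviceErrorModel(device_label="ecg", noise_sd=1.0)
    test = DeviceErrorModel(device_label="wearable", bias_intercept=-2.0,
                            bias_hr_slope=-0.3, knee_bpm=90.0, noise_sd=2.0)
    return paired_from_study(config, ref, test)


@pytest.fixture(scope="session")
def perfect_paired():
    """Identical devices observing the same latent signal."""
    config = SimulationConfig(n_subjects=8, seed=5)
    ref = DeviceErrorModel(device_label="ecg")
    test = DeviceErrorModel(device_label="wearable")
    return paired_from_study(config, ref, test)
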