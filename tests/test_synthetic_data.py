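"""Generator contracts: determinism, degenerate cases, moment recovery."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from hragree.synthetic_data import (BLOCK_TO_PHASE, DeviceErrorModel,
                                    SimulationConfig, apply_device,
                                    generate_latent, generate_study,
                                    schedule_frame)

ALL_PHASES = ["relaxation", "anticipation", "oral", "arithmetic"]


def flat_config(**kw):
    return SimulationConfig(sigma2_subject=0.0, sigma2_interaction=0.0,
                            sigma2_resid=0.0, **kw)


class TestGenerateLatent:
    def test_zero_variances_give_exact_phase_means(self):
        cfg = flat_config(n_subjects=3, seed=0)
        for traj in generate_latent(cfg):
            expected = cfg.phase_means[BLOCK_TO_PHASE[traj.block]]
            assert np.all(traj.true_hr == expected)

    def test_same_seed_is_bit_identical(self):
        a = generate_latent(SimulationConfig(n_subjects=4, seed=9))
        b = generate_latent(SimulationConfig(n_subjects=4, seed=9))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.true_hr, tb.true_hr)
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_adding_subjects_keeps_earlier_draws(self):
        small = generate_latent(SimulationConfig(n_subjects=3, seed=21))
        big = generate_latent(SimulationConfig(n_subjects=6, seed=21))
        subj = {t.subject for t in small}
        kept = [t for t in big if t.subject in subj]
        for ta, tb in zip(small, kept):
            np.testing.assert_array_equal(ta.true_hr, tb.true_hr)

    def test_subject_variance_matches_injected(self):
        # oracle: Var(session mean deviation from phase means) =
        # s2_subject + s2_interaction * sum_p share_p^2 (wander negligible)
        cfg = SimulationConfig(n_subjects=2000, seed=1)
        shares = {}
        total = sum(d for _, d in cfg.phase_schedule)
        for block, dur in cfg.phase_schedule:
            ph = BLOCK_TO_PHASE[block]
            shares[ph] = shares.get(ph, 0.0) + dur / total
        expected = cfg.sigma2_subject + cfg.sigma2_interaction * sum(
            s ** 2 for s in shares.values())
        means = {}
        for t in generate_latent(cfg):
            dev = t.true_hr - cfg.phase_means[t.phase]
            acc = means.setdefault(t.subject, [])
            acc.extend(dev)
        sample_var = np.var([np.mean(v) for v in means.values()], ddof=1)
        assert sample_var == pytest.approx(expected, rel=0.10)

    def test_phase_means_converge(self):
        cfg = SimulationConfig(n_subjects=2000, seed=2)
        df = pd.DataFrame(
            [(t.phase, float(np.mean(t.true_hr)))
             for t in generate_latent(cfg)], columns=["phase", "m"])
        for ph, grp in df.groupby("phase"):
            assert grp["m"].mean() == pytest.approx(
                cfg.phase_means[ph], rel=0.02)

    def test_negative_variance_rejected_naming_field(self):
        with pytest.raises(ValidationError, match="sigma2_interaction"):
            SimulationConfig(sigma2_interaction=-1.0)

    def test_phase_mean_ordering_enforced(self):
        with pytest.raises(ValidationError, match="relaxation < anticipation"):
            SimulationConfig(phase_means={"relaxation": 90.0,
                                          "anticipation": 80.0,
                                          "arithmetic": 86.0, "oral": 95.0})


class TestApplyDevice:
    def test_identity_model_reproduces_latent(self):
        latent = generate_latent(SimulationConfig(n_subjects=2, seed=3))
        series = apply_device(latent, DeviceErrorModel(device_label="d"), 0)
        for s in series:
            truth = np.concatenate(
                [t.true_hr for t in sorted(
                    (x for x in latent if x.subject == s.subject),
                    key=lambda x: x.times[0])])
            np.testing.assert_array_equal(s.bpm, truth)

    def test_constant_bias_shifts_everything(self):
        latent = generate_latent(SimulationConfig(n_subjects=2, seed=3))
        model = DeviceErrorModel(device_label="d", bias_intercept=3.0)
        base = apply_device(latent, DeviceErrorModel(device_label="d"), 0)
        out = apply_device(latent, model, 0)
        for a, b in zip(base, out):
            np.testing.assert_allclose(b.bpm - a.bpm, 3.0)

    def test_knee_bias_closed_form(self):
        # slope -0.3 above 90 applied to a flat 120-bpm signal -> bias -9
        cfg = flat_config(n_subjects=1, seed=0,
                          phase_means={"relaxation": 72.0,
                                       "anticipation": 80.0,
                                       "arithmetic": 86.0, "oral": 120.0})
        latent = generate_latent(cfg)
        model = DeviceErrorModel(device_label="d", bias_hr_slope=-0.3,
                                 knee_bpm=90.0)
        series = apply_device(latent, model, 0)[0]
        oral = [t for t in latent if t.phase == "oral"]
        times = np.concatenate([t.times for t in oral])
        in_oral = np.isin(series.times, times)
        assert np.mean(series.bpm[in_oral] - 120.0) == pytest.approx(-9.0)

    def test_lag_beyond_shortest_phase_rejected(self):
        latent = generate_latent(SimulationConfig(n_subjects=1, seed=0))
        with pytest.raises(ValueError, match="lag"):
            apply_device(latent,
                         DeviceErrorModel(device_label="d", lag_s=181.0), 0)

    def test_phase_artifact_constant_within_subject_phase(self):
        latent = generate_latent(flat_config(n_subjects=3, seed=4))
        model = DeviceErrorModel(device_label="d",
                                 phase_artifact={"oral": (-5.0, 4.0)})
        for s in apply_device(latent, model, 1):
            oral_times = np.concatenate(
                [t.times for t in latent
                 if t.subject == s.subject and t.phase == "oral"])
            vals = s.bpm[np.isin(s.times, oral_times)]
            assert np.ptp(vals) == 0.0  # one offset per subject-phase
            rest = s.bpm[~np.isin(s.times, oral_times)]
            assert np.all(rest == np.round(rest))  # untouched phases


class TestGenerateStudy:
    def test_schema_and_both_devices(self):
        cfg = SimulationConfig(n_subjects=3, seed=0)
        ref = DeviceErrorModel(device_label="ecg")
        test = DeviceErrorModel(device_label="wearable", noise_sd=1.0)
        df = generate_study(cfg, ref, test)
        assert list(df.columns) == ["subject", "device", "phase",
                                    "epoch_time_s", "bpm"]
        assert set(df["device"]) == {"ecg", "wearable"}
        assert set(df["phase"]) == {b for b, _ in cfg.phase_schedule}

    def test_equal_device_labels_rejected(self):
        cfg = SimulationConfig(n_subjects=2, seed=0)
        m = DeviceErrorModel(device_label="x")
        with pytest.raises(ValueError, match="distinct"):
            generate_study(cfg, m, m)

    def test_different_seeds_same_schema(self):
        ref = DeviceErrorModel(device_label="ecg")
        test = DeviceErrorModel(device_label="wearable")
        a = generate_study(SimulationConfig(n_subjects=2, seed=1), ref, test)
        b = generate_study(SimulationConfig(n_subjects=2, seed=2), ref, test)
        assert list(a.columns) == list(b.columns)
        assert not a["bpm"].equals(b["bpm"])

    def test_identical_models_drop_the_same_epochs(self):
        cfg = SimulationConfig(n_subjects=5, seed=8)
        ref = DeviceErrorModel(device_label="a", dropout_prob=0.2)
        test = DeviceErrorModel(device_label="b", dropout_prob=0.2)
        df = generate_study(cfg, ref, test)
        for subj, grp in df.groupby("subject"):
            t_a = set(grp.loc[grp["device"] == "a", "epoch_time_s"])
            t_b = set(grp.loc[grp["device"] == "b", "epoch_time_s"])
            assert t_a == t_b

    def test_schedule_frame_covers_all_subjects(self):
        cfg = SimulationConfig(n_subjects=4, seed=0)
        sched = schedule_frame(cfg)
        assert sched["subject"].nunique() == 4
        assert len(sched) == 4 * len(cfg.phase_schedule)
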