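"""Synthetic paired heart-rate studies with known ground truth.

Emulates a laboratory stress-protocol session (Trier Social Stress Test):
each subject passes through two relaxation blocks (start and end of session),
a short anticipation block, an oral-speech block and a mental-arithmetic
block, while two devices — a reference ECG and a wrist wearable — record
beats per minute from the same underlying cardiac signal.

The latent heart rate follows the variance-components structure the
downstream mixed models assume:

    HR_sp(t) = mu_p + a_s + g_sp + w_sp(t)

with subject effect a_s ~ N(0, sigma2_subject), subject-by-phase effect
g_sp ~ N(0, sigma2_interaction) (shared by the two relaxation blocks, which
belong to the same merged phase), and a stationary AR(1) wander w with
stationary SD sqrt(sigma2_resid).  Devices observe the latent signal through
an error model with an optional constant bias, a high-rate proportional bias
above a knee (wearable optical sensors under-read at elevated heart rate),
additive noise, a reporting lag, per-epoch dropout and integer quantisation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "SimulationConfig",
    "DeviceErrorModel",
    "LatentTrajectory",
    "generate_latent",
    "apply_device",
    "generate_study",
    "schedule_frame",
    "write_study",
    "paper_like_scenario",
]

#: protocol blocks in session order with durations in seconds
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("relaxation_pre", 300.0),
    ("anticipation", 180.0),
    ("oral", 300.0),
    ("arithmetic", 300.0),
    ("relaxation_post", 300.0),
)

#: map protocol block -> analysis phase (the two relaxations are one phase)
BLOCK_TO_PHASE = {
    "relaxation_pre": "relaxation",
    "relaxation_post": "relaxation",
    "anticipation": "anticipation",
    "oral": "oral",
    "arithmetic": "arithmetic",
}

DEFAULT_PHASE_MEANS = {
    "relaxation": 72.0,
    "anticipation": 80.0,
    "arithmetic": 86.0,
    "oral": 90.0,
}


class SimulationConfig(BaseModel):
    """Study design and latent heart-rate model for the generator.

    Default variance components follow the magnitudes reported for this kind
    of stress-protocol validation data: between-subject 116.57, subject-by-
    phase 14.47 and within-phase residual 29.72 bpm^2.  ``wander_ar1`` is the
    lag-1 autocorrelation of the within-phase wander on the sampling grid; it
    is kept moderate (0.5) so that epoch-level mixed-model estimates of the
    residual and interaction components stay close to the generating values
    (see docs/methods.md for the bias analysis behind this default).
    """

    model_config = ConfigDict(validate_assignment=True)

    n_subjects: int = Field(default=34, ge=1)
    phase_schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    phase_means: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PHASE_MEANS))
    sigma2_subject: float = Field(default=116.57, ge=0,
                                  description="between-subject variance, bpm^2")
    sigma2_interaction: float = Field(default=14.47, ge=0,
                                      description="subject-by-phase variance, bpm^2")
    sigma2_resid: float = Field(default=29.72, ge=0,
                                description="within-phase wander variance, bpm^2")
    wander_ar1: float = Field(default=0.5, ge=0.0, lt=1.0)
    sample_step_s: float = Field(default=5.0, gt=0)
    phase_interaction_scale: dict[str, float] = Field(
        default_factory=dict,
        description="per-phase multiplier on the subject-by-phase SD")
    seed: int = 0

    @field_validator("phase_schedule")
    @classmethod
    def _check_schedule(cls, v):
        if not v:
            raise ValueError("phase_schedule must not be empty")
        for name, dur in v:
            if dur <= 0:
                raise ValueError(f"phase_schedule: duration of {name!r} must be > 0")
            if name not in BLOCK_TO_PHASE:
                raise ValueError(f"phase_schedule: unknown block {name!r}")
        return tuple((str(n), float(d)) for n, d in v)

    @model_validator(mode="after")
    def _check_means(self):
        m = self.phase_means
        needed = {BLOCK_TO_PHASE[b] for b, _ in self.phase_schedule}
        missing = needed - m.keys()
        if missing:
            raise ValueError(f"phase_means missing phases: {sorted(missing)}")
        order = ["relaxation", "anticipation", "arithmetic", "oral"]
        if all(p in m for p in order):
            vals = [m[p] for p in order]
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(
                    "phase_means must satisfy relaxation < anticipation "
                    "< arithmetic < oral")
        return self


class DeviceErrorModel(BaseModel):
    """How one device distorts the latent heart rate.

    ``bias_hr_slope`` acts only above ``knee_bpm``: observed bias grows
    linearly with latent HR beyond the knee, the signature error pattern of
    wrist-worn optical sensors at elevated heart rates.

    ``phase_artifact`` models motion-artifact susceptibility: in the listed
    phases each subject's device acquires a constant offset drawn from
    N(mean, sd^2), independently per device.  This is how heterogeneous
    per-subject sensor failure during, say, an agitated anticipation period
    enters the data: it inflates the subject-by-device variance of that
    phase without touching the latent heart rate.
    """

    model_config = ConfigDict(validate_assignment=True)

    device_label: str
    bias_intercept: float = 0.0
    bias_hr_slope: float = 0.0
    knee_bpm: float = 90.0
    noise_sd: float = Field(default=0.0, ge=0)
    lag_s: float = Field(default=0.0, ge=0)
    dropout_prob: float = Field(default=0.0, ge=0, lt=1)
    quantize: bool = False
    phase_artifact: dict[str, tuple[float, float]] = Field(
        default_factory=dict,
        description="phase -> (mean bpm, sd bpm) of a per-subject offset")

    @field_validator("phase_artifact")
    @classmethod
    def _check_artifact(cls, v):
        for ph, (_, sd) in v.items():
            if sd < 0:
                raise ValueError(f"phase_artifact[{ph!r}]: sd must be >= 0")
        return {str(p): (float(m), float(s)) for p, (m, s) in v.items()}

    def _stream_key(self, with_label: bool) -> int:
        payload = self.model_dump()
        if not with_label:
            payload.pop("device_label")
        return zlib.crc32(json.dumps(payload, sort_keys=True).encode())


@dataclass
class LatentTrajectory:
    """One subject's true heart rate through one protocol block."""

    subject: str
    block: str            # protocol block name (e.g. relaxation_pre)
    phase: str            # merged analysis phase
    times: np.ndarray     # protocol-relative seconds
    true_hr: np.ndarray   # bpm, > 0


def generate_latent(config: SimulationConfig) -> list[LatentTrajectory]:
    """Draw latent per-subject trajectories; deterministic given config.seed.

    One RNG stream is spawned per subject, so increasing ``n_subjects`` never
    perturbs the draws of earlier subjects.
    """
    step = config.sample_step_s
    phases = sorted({BLOCK_TO_PHASE[b] for b, _ in config.phase_schedule})
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    out: list[LatentTrajectory] = []
    rho = config.wander_ar1
    sd_w = np.sqrt(config.sigma2_resid)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject = f"S{i + 1:03d}"
        a_s = rng.normal(0.0, np.sqrt(config.sigma2_subject))
        g = {}
        for ph in phases:  # one draw per merged phase, shared across blocks
            scale = config.phase_interaction_scale.get(ph, 1.0)
            g[ph] = rng.normal(0.0, np.sqrt(config.sigma2_interaction) * scale)
        t0 = 0.0
        for block, dur in config.phase_schedule:
            ph = BLOCK_TO_PHASE[block]
            n = int(round(dur / step))
            times = t0 + step * np.arange(n)
            w = _ar1(rng, n, rho, sd_w)
            hr = config.phase_means[ph] + a_s + g[ph] + w
            out.append(LatentTrajectory(subject=subject, block=block, phase=ph,
                                        times=times,
                                        true_hr=np.maximum(hr, 1.0)))
            t0 += dur
    return out


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def apply_device(latent: list[LatentTrajectory], error_model: DeviceErrorModel,
                 seed: int) -> "list":
    """Pass latent trajectories through a device error model.

    Returns one :class:`hragree.io_align.HRSeries` per subject.  The noise
    stream is keyed by the full error model (including the device label), so
    two devices draw independent noise; the dropout stream is keyed by the
    model's parameters only, so identical error models drop the same epochs
    on both devices (the missingness is then symmetric, as it should be when
    the devices are exact copies).
    """
    from .io_align import HRSeries

    if not latent:
        raise ValueError("latent trajectories must be non-empty")
    shortest = min(t.times.size * _step_of(t) for t in latent)
    if error_model.lag_s > shortest:
        raise ValueError(
            f"lag_s={error_model.lag_s} exceeds the shortest phase "
            f"block ({shortest:.0f} s)")

    by_subject: dict[str, list[LatentTrajectory]] = {}
    for traj in latent:
        by_subject.setdefault(traj.subject, []).append(traj)
    subjects = sorted(by_subject)

    noise_root = np.random.SeedSequence(
        seed, spawn_key=(error_model._stream_key(with_label=True),))
    drop_root = np.random.SeedSequence(
        seed, spawn_key=(error_model._stream_key(with_label=False),))
    noise_children = noise_root.spawn(len(subjects))
    drop_children = drop_root.spawn(len(subjects))

    out = []
    for subj, nc, dc in zip(subjects, noise_children, drop_children):
        trajs = sorted(by_subject[subj], key=lambda t: t.times[0])
        times = np.concatenate([t.times for t in trajs])
        hr = np.concatenate([t.true_hr for t in trajs])
        sample_phase = np.concatenate(
            [np.repeat(t.phase, t.times.size) for t in trajs])
        step = float(np.median(np.diff(times))) if times.size > 1 else 1.0
        n_lag = int(round(error_model.lag_s / step))
        if n_lag > 0:
            hr = np.concatenate([np.full(n_lag, hr[0]), hr[:-n_lag]])
        obs = (hr + error_model.bias_intercept
               + error_model.bias_hr_slope
               * np.maximum(0.0, hr - error_model.knee_bpm))
        rng_noise = np.random.default_rng(nc)
        for ph in sorted(error_model.phase_artifact):
            mean, sd = error_model.phase_artifact[ph]
            offset = rng_noise.normal(mean, sd)
            obs = np.where(sample_phase == ph, obs + offset, obs)
        if error_model.noise_sd > 0:
            obs = obs + rng_noise.normal(0.0, error_model.noise_sd,
                                         size=obs.size)
        keep = np.ones(obs.size, dtype=bool)
        if error_model.dropout_prob > 0:
            keep = np.random.default_rng(dc).random(obs.size) >= \
                error_model.dropout_prob
        if error_model.quantize:
            obs = np.rint(obs)
        out.append(HRSeries(subject=subj, device=error_model.device_label,
                            times=times[keep], bpm=obs[keep]))
    return out


def _step_of(t: LatentTrajectory) -> float:
    return float(np.median(np.diff(t.times))) if t.times.size > 1 else 1.0


def generate_study(config: SimulationConfig, ref_model: DeviceErrorModel,
                   test_model: DeviceErrorModel):
    """Generate the long-format paired study table for both devices.

    Returns a pandas DataFrame with columns
    (subject, device, phase, epoch_time_s, bpm); ``phase`` carries the
    protocol block name (the two relaxation blocks are distinct here and are
    merged only by the analysis).
    """
    import pandas as pd

    if ref_model.device_label == test_model.device_label:
        raise ValueError("reference and test devices must have distinct labels")
    latent = generate_latent(config)
    edges, blocks = _block_edges(config)
    frames = []
    for model in (ref_model, test_model):
        for series in apply_device(latent, model, seed=config.seed):
            idx = np.searchsorted(edges, series.times, side="right") - 1
            frames.append(pd.DataFrame({
                "subject": series.subject,
                "device": series.device,
                "phase": np.asarray(blocks)[idx],
                "epoch_time_s": series.times,
                "bpm": series.bpm,
            }))
    return pd.concat(frames, ignore_index=True)


def _block_edges(config: SimulationConfig):
    edges, blocks, t0 = [], [], 0.0
    for block, dur in config.phase_schedule:
        edges.append(t0)
        blocks.append(block)
        t0 += dur
    return np.array(edges), blocks


def schedule_frame(config: SimulationConfig):
    """Per-subject protocol schedule (subject, phase, start_s, end_s)."""
    import pandas as pd

    rows = []
    for i in range(config.n_subjects):
        subject, t0 = f"S{i + 1:03d}", 0.0
        for block, dur in config.phase_schedule:
            rows.append((subject, block, t0, t0 + dur))
            t0 += dur
    return pd.DataFrame(rows, columns=["subject", "phase", "start_s", "end_s"])


def write_study(study, config: SimulationConfig, ref_model: DeviceErrorModel,
                test_model: DeviceErrorModel, path) -> Path:
    """Write the study CSV plus a JSON sidecar echoing the full configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    study.to_csv(path, index=False)
    sidecar = path.with_suffix(".config.json")
    sidecar.write_text(json.dumps({
        "simulation": json.loads(config.model_dump_json()),
        "ref_model": json.loads(ref_model.model_dump_json()),
        "test_model": json.loads(test_model.model_dump_json()),
        "seed": config.seed,
    }, indent=2, sort_keys=True))
    return path


def paper_like_scenario(n_subjects: int = 34, seed: int = 0):
    """Config and device pair emulating the validation study's conditions.

    The reference device is a near-ideal ECG; the test device is a wearable
    that under-reads above 92 bpm (saturating optical sensing at elevated
    heart rate), reports integer bpm with a 10-s lag, drops occasional
    epochs, and suffers heterogeneous motion artifacts during anticipation
    (subjects fidget while awaiting the stressor, degrading the wrist sensor
    by a different amount for each of them).  Under this scenario relaxation
    shows the best and anticipation the worst value on every agreement
    metric, the qualitative per-phase pattern such validation studies report.
    """
    config = SimulationConfig(
        n_subjects=n_subjects, seed=seed,
        phase_means={"relaxation": 72.0, "anticipation": 80.0,
                     "arithmetic": 89.0, "oral": 90.0})
    ref = DeviceErrorModel(device_label="ecg", noise_sd=1.0)
    test = DeviceErrorModel(device_label="wearable",
                            bias_hr_slope=-1.0, knee_bpm=92.0, noise_sd=3.0,
                            lag_s=10.0, dropout_prob=0.02, quantize=True,
                            phase_artifact={"anticipation": (-8.0, 12.0)})
    return config, ref, test
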