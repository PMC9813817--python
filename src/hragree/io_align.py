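"""Reading device streams, phase labelling, relaxation merging and pairing.

The analysis consumes long-format CSV files with one heart-rate sample per
row (subject, device, phase, epoch_time_s, bpm) and a per-subject phase
schedule (subject, phase, start_s, end_s).  Timestamps are protocol-relative
seconds.  The two relaxation blocks that open and close the session are
merged into a single "relaxation" phase before any statistics are computed.

Pairing cuts the protocol time axis into half-open epochs [k*e, (k+1)*e),
averages each device within an epoch and keeps only epochs where both
devices report; the between-device difference is oriented test - reference
throughout (a wearable that under-reads therefore shows a negative bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel

logger = logging.getLogger("hragree")

__all__ = [
    "HRSeries",
    "PhaseSchedule",
    "CsvDialect",
    "DataError",
    "read_hr_csv",
    "series_from_frame",
    "read_schedule_csv",
    "schedules_from_frame",
    "label_and_merge",
    "pair_epochs",
    "pair_study",
    "validate_paired",
    "PAIRED_COLUMNS",
    "MERGED_PHASES",
    "PROTOCOL_ORDER",
]

#: plausible human heart-rate range; samples outside are dropped on read
BPM_RANGE = (20.0, 250.0)

PROTOCOL_ORDER = ["relaxation_pre", "anticipation", "oral", "arithmetic",
                  "relaxation_post"]
_MERGE = {"relaxation_pre": "relaxation", "relaxation_post": "relaxation"}
MERGED_PHASES = ["relaxation", "anticipation", "oral", "arithmetic"]

PAIRED_COLUMNS = ["subject", "phase", "epoch_index", "hr_ref", "hr_test", "diff"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class CsvDialect(BaseModel):
    """Column names of the long-format heart-rate CSV."""

    subject: str = "subject"
    device: str = "device"
    time: str = "epoch_time_s"
    bpm: str = "bpm"
    allowed_devices: tuple[str, ...] | None = None


@dataclass
class HRSeries:
    """One device's timestamped bpm stream for one subject."""

    subject: str
    device: str
    times: np.ndarray
    bpm: np.ndarray
    phases: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times.shape != self.bpm.shape:
            raise DataError("times and bpm must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(
                f"timestamps not strictly increasing for subject "
                f"{self.subject!r} device {self.device!r}")

    @property
    def labeled(self) -> bool:
        return self.phases is not None


@dataclass
class PhaseSchedule:
    """Ordered, non-overlapping protocol blocks for one subject."""

    subject: str
    entries: list[tuple[str, float, float]]  # (block, start_s, end_s)

    def __post_init__(self):
        prev_end = -np.inf
        prev_rank = -1
        for block, start, end in self.entries:
            if block not in PROTOCOL_ORDER:
                raise DataError(f"unknown protocol block {block!r}")
            if end <= start:
                raise DataError(f"block {block!r}: end must exceed start")
            if start < prev_end:
                raise DataError(f"block {block!r} overlaps the previous block")
            rank = PROTOCOL_ORDER.index(block)
            if rank <= prev_rank:
                raise DataError(
                    f"blocks out of protocol order at {block!r} "
                    f"(expected {' < '.join(PROTOCOL_ORDER)})")
            prev_end, prev_rank = end, rank

    def span(self) -> tuple[float, float]:
        return self.entries[0][1], self.entries[-1][2]


def read_hr_csv(path, dialect: CsvDialect | None = None) -> list[HRSeries]:
    """Read a long-format heart-rate CSV into per-(subject, device) series.

    Rows with bpm outside the plausible range are dropped and counted in the
    log; duplicate timestamps within a series are an error.
    """
    return series_from_frame(pd.read_csv(path), dialect=dialect,
                             origin=str(path))


def series_from_frame(df: pd.DataFrame, dialect: CsvDialect | None = None,
                      origin: str = "<frame>") -> list[HRSeries]:
    """Split a long-format table into per-(subject, device) series."""
    dialect = dialect or CsvDialect()
    needed = [dialect.subject, dialect.device, dialect.time, dialect.bpm]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"{origin}: missing columns {missing}")
    if dialect.allowed_devices is not None:
        unknown = set(df[dialect.device].astype(str)) - set(dialect.allowed_devices)
        if unknown:
            raise DataError(f"{origin}: unknown device label(s) {sorted(unknown)}")
    ok = df[dialect.bpm].between(*BPM_RANGE)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d sample(s) with bpm outside %s",
                       origin, n_bad, BPM_RANGE)
        df = df[ok]
    out = []
    for (subj, dev), grp in df.groupby([dialect.subject, dialect.device],
                                       sort=True):
        grp = grp.sort_values(dialect.time)
        t = grp[dialect.time].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise DataError(f"duplicate timestamps for subject {subj!r} "
                            f"device {dev!r}")
        out.append(HRSeries(subject=str(subj), device=str(dev), times=t,
                            bpm=grp[dialect.bpm].to_numpy(dtype=float)))
    return out


def read_schedule_csv(path) -> dict[str, PhaseSchedule]:
    """Read a per-subject schedule CSV (subject, phase, start_s, end_s)."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "phase", "start_s", "end_s")
               if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return schedules_from_frame(df)


def schedules_from_frame(df: pd.DataFrame) -> dict[str, PhaseSchedule]:
    out = {}
    for subj, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("start_s")
        out[str(subj)] = PhaseSchedule(
            subject=str(subj),
            entries=[(str(r.phase), float(r.start_s), float(r.end_s))
                     for r in grp.itertuples()])
    return out


def label_and_merge(series: HRSeries, schedule: PhaseSchedule) -> HRSeries:
    """Tag every sample with its merged analysis phase.

    The opening and closing relaxation blocks are relabelled "relaxation";
    samples falling between blocks (or outside the schedule) are discarded.
    """
    if schedule.subject != series.subject:
        raise DataError("schedule subject does not match series subject")
    labels = np.full(series.times.size, "", dtype=object)
    for block, start, end in schedule.entries:
        inside = (series.times >= start) & (series.times < end)
        labels[inside] = _MERGE.get(block, block)
    keep = labels != ""
    if not np.any(keep):
        raise DataError(
            f"no samples of subject {series.subject!r} device "
            f"{series.device!r} fall inside the schedule")
    return HRSeries(subject=series.subject, device=series.device,
                    times=series.times[keep], bpm=series.bpm[keep],
                    phases=labels[keep].astype(str))


def pair_epochs(ref_series: HRSeries, test_series: HRSeries,
                epoch_s: float = 5.0) -> pd.DataFrame:
    """Average both devices onto shared epochs and difference them.

    Epochs are 0-based half-open windows [k*epoch_s, (k+1)*epoch_s) on the
    protocol time axis.  A device contributes to an epoch only if it supplies
    at least half the samples expected from its native sampling interval;
    epochs lacking either device, or straddling a phase boundary, are
    dropped.  The difference column is test - reference.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if ref_series.subject != test_series.subject:
        raise DataError("paired series must belong to the same subject")
    for s in (ref_series, test_series):
        if not s.labeled:
            raise DataError("series must be phase-labeled before pairing")

    ref = _epoch_means(ref_series, epoch_s)
    test = _epoch_means(test_series, epoch_s)
    merged = ref.merge(test, on="epoch_index", suffixes=("_ref", "_test"))
    merged = merged[merged["phase_ref"] == merged["phase_test"]]
    if merged.empty:
        raise DataError(
            f"no overlapping epochs for subject {ref_series.subject!r}")
    out = pd.DataFrame({
        "subject": ref_series.subject,
        "phase": merged["phase_ref"].to_numpy(),
        "epoch_index": merged["epoch_index"].to_numpy(),
        "hr_ref": merged["bpm_ref"].to_numpy(),
        "hr_test": merged["bpm_test"].to_numpy(),
    })
    out["diff"] = out["hr_test"] - out["hr_ref"]
    return out


def _epoch_means(series: HRSeries, epoch_s: float) -> pd.DataFrame:
    t = series.times
    step = float(np.median(np.diff(t))) if t.size > 1 else epoch_s
    expected = max(int(round(epoch_s / step)), 1)
    min_count = max(int(np.ceil(0.5 * expected)), 1)
    idx = np.floor(t / epoch_s).astype(int)
    df = pd.DataFrame({"epoch_index": idx, "bpm": series.bpm,
                       "phase": series.phases})
    agg = df.groupby("epoch_index").agg(
        bpm=("bpm", "mean"), n=("bpm", "size"),
        phase=("phase", "first"), nphase=("phase", "nunique"))
    agg = agg[(agg["n"] >= min_count) & (agg["nphase"] == 1)]
    return agg.reset_index()[["epoch_index", "bpm", "phase"]]


def pair_study(series: list[HRSeries], schedules: dict[str, PhaseSchedule],
               ref_device: str, test_device: str,
               epoch_s: float = 5.0) -> pd.DataFrame:
    """Label, merge and pair every subject present with both devices."""
    by_subject: dict[str, dict[str, HRSeries]] = {}
    for s in series:
        by_subject.setdefault(s.subject, {})[s.device] = s
    frames = []
    for subj in sorted(by_subject):
        devs = by_subject[subj]
        if ref_device not in devs or test_device not in devs:
            logger.warning("subject %s lacks one of the devices; skipped", subj)
            continue
        if subj not in schedules:
            raise DataError(f"no schedule for subject {subj!r}")
        ref = label_and_merge(devs[ref_device], schedules[subj])
        test = label_and_merge(devs[test_device], schedules[subj])
        frames.append(pair_epochs(ref, test, epoch_s))
    if not frames:
        raise DataError("no subject had both devices")
    return pd.concat(frames, ignore_index=True)


def validate_paired(paired: pd.DataFrame) -> pd.DataFrame:
    """Check the paired-epochs contract used by every downstream metric."""
    missing = [c for c in PAIRED_COLUMNS if c not in paired.columns]
    if missing:
        raise DataError(f"paired epochs missing columns {missing}")
    if paired[["hr_ref", "hr_test"]].isna().any().any():
        raise DataError("paired epochs contain missing heart rates")
    bad = set(paired["phase"]) - set(MERGED_PHASES)
    if bad:
        raise DataError(f"unexpected phase labels {sorted(bad)}; "
                        "relaxation blocks must be merged before analysis")
    return paired
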