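"""Time-intensity curves: ROI means, flash-destruction detection, replenishment segmentation.

A time-intensity curve (TIC) is the mean linear-scale contrast intensity over
an ROI per frame.  High-MI flash-destruction pulses clear the microbubbles
from the imaging plane and show up as abrupt intensity drops; the windows
between them (after a recirculation dead-time) are the replenishment segments
handed to the exponential reperfusion fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FrameSequence, RegionMaskSet

#: minimum number of samples for a segment to be fittable
MIN_SEGMENT_SAMPLES = 8


@dataclass
class TimeIntensityCurve:
    """Mean linear-scale ROI intensity per frame."""

    times: np.ndarray  # s
    intensities: np.ndarray  # linear a.u.
    roi_label: str = "roi"
    n_pixels: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be 1D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "intensity": self.intensities,
                "roi": self.roi_label,
                "n_pixels": self.n_pixels,
            }
        )

    def write_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path) -> "TimeIntensityCurve":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            roi_label=str(df["roi"].iloc[0]) if len(df) else "roi",
            n_pixels=int(df["n_pixels"].iloc[0]) if len(df) else 1,
        )


@dataclass
class ReplenishmentSegment:
    """A post-flash window restricted to [start, end], re-zeroed to the fit origin.

    ``flash_time`` is the destruction pulse; ``start`` additionally skips the
    recirculation dead-time, and ``times`` are relative to ``start`` (t' = 0 at
    the first fittable instant).
    """

    flash_time: float
    start: float
    end: float
    times: np.ndarray  # s, re-zeroed: t' = t - start
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.start < self.flash_time:
            raise ValueError("segment start must be >= flash_time")
        if self.end <= self.start:
            raise ValueError("segment end must be after start")
        if self.times.size < MIN_SEGMENT_SAMPLES:
            raise ValueError(
                f"segment needs >= {MIN_SEGMENT_SAMPLES} samples, got {self.times.size}"
            )

    @property
    def n_samples(self) -> int:
        return self.times.size


def extract_tic(
    seq: FrameSequence,
    masks: RegionMaskSet,
    label: str,
    background_label: str | None = None,
) -> TimeIntensityCurve:
    """ROI-mean TIC from a linear-scale sequence.

    With ``background_label`` the background ROI's per-frame mean is subtracted
    and negatives are clamped to 0.
    """
    if not seq.is_linear:
        raise ValueError(
            "sequence is log-compressed; linearize() it before extracting TICs"
        )
    mask = masks.require(label)
    if mask.shape != seq.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {seq.frame_shape}"
        )
    values = seq.frames[:, mask].mean(axis=1)
    if background_label is not None:
        bg = masks.require(background_label)
        values = np.clip(values - seq.frames[:, bg].mean(axis=1), 0.0, None)
    return TimeIntensityCurve(
        times=seq.times,
        intensities=values,
        roi_label=label,
        n_pixels=int(mask.sum()),
    )


def detect_flash_events(
    tic: TimeIntensityCurve,
    drop_fraction: float = 0.5,
    window: int = 3,
    median_window: float = 10.0,
    refractory: float = 5.0,
) -> list[float]:
    """Detect flash-destruction pulses as abrupt fractional intensity drops.

    A frame is an event when its intensity falls by at least ``drop_fraction``
    of the trailing ``median_window``-second median (the median is taken just
    before the allowed ``window``-frame drop transition, so drops spanning a
    couple of frames are still caught).  Events closer than ``refractory``
    seconds are merged to the first.  The test is ratio-based, hence invariant
    to global intensity scaling.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    vals = tic.intensities
    n = vals.size
    if n < 3:
        return []
    dt = tic.frame_interval
    mw = max(1, int(round(median_window / dt)))
    events: list[float] = []
    for i in range(1, n):
        j_prev = max(0, i - window)  # transition must start within `window` frames
        ref_end = max(1, j_prev)
        ref_start = max(0, ref_end - mw)
        med = float(np.median(vals[ref_start:ref_end]))
        if med <= 0:
            continue
        threshold = (1.0 - drop_fraction) * med
        # a flash: now below the drop threshold, but still above it `window`
        # frames ago — rules out re-triggering on the post-flash dead-time
        if vals[i] <= threshold and vals[j_prev] > threshold:
            t = float(tic.times[i])
            if events and t - events[-1] < refractory:
                continue  # merged into the previous event
            events.append(t)
    return events


def segment_replenishment(
    tic: TimeIntensityCurve,
    flash_times,
    recirc_delay: float = 30.0,
    end_policy: str = "next_flash",
    segment_duration: float | None = None,
    start_offset: int = 0,
    guard_frames: int = 1,
) -> list[ReplenishmentSegment]:
    """Cut one replenishment segment per flash.

    Each segment starts at ``flash + recirc_delay`` (plus ``start_offset``
    frames) and ends just before the next flash (``guard_frames`` frames are
    excluded so the next pulse's drop is never fitted), at the sequence end, or
    after ``segment_duration`` seconds when ``end_policy='fixed'``.  Segments
    shorter than the sample floor are dropped with a warning.  Segments never
    overlap: each inter-flash interval is covered at most once.
    """
    flash_times = sorted(float(t) for t in flash_times)
    if recirc_delay < 0:
        raise ValueError("recirc_delay must be >= 0")
    if end_policy not in {"next_flash", "sequence_end", "fixed"}:
        raise ValueError(f"unknown end_policy {end_policy!r}")
    if end_policy == "fixed" and not segment_duration:
        raise ValueError("end_policy='fixed' requires segment_duration")

    dt = tic.frame_interval
    t_end_seq = float(tic.times[-1])
    segments: list[ReplenishmentSegment] = []
    for j, flash in enumerate(flash_times):
        origin = flash + recirc_delay  # fit origin: t' = 0 here
        first = origin + start_offset * dt
        if end_policy == "next_flash" and j + 1 < len(flash_times):
            end = flash_times[j + 1] - guard_frames * dt
        elif end_policy == "fixed":
            end = min(first + segment_duration, t_end_seq)
            if j + 1 < len(flash_times):
                end = min(end, flash_times[j + 1] - guard_frames * dt)
        else:
            end = t_end_seq
            if j + 1 < len(flash_times):
                end = min(end, flash_times[j + 1] - guard_frames * dt)
        sel = (tic.times >= first) & (tic.times <= end)
        if sel.sum() < MIN_SEGMENT_SAMPLES:
            warnings.warn(
                f"replenishment segment after flash at {flash:.1f}s has "
                f"{int(sel.sum())} samples (< {MIN_SEGMENT_SAMPLES}); dropped",
                stacklevel=2,
            )
            continue
        t_sel = tic.times[sel]
        segments.append(
            ReplenishmentSegment(
                flash_time=flash,
                start=origin,
                end=float(t_sel[-1]),
                times=t_sel - origin,
                intensities=tic.intensities[sel],
            )
        )
    return segments
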