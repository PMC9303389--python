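"""Segmentation of noisy extension traces and dwell-time extraction.

A trace is median-filtered, each sample assigned to the nearest of the
configured state levels (baseline / scrunched / elongating-stalled), and
runs shorter than a minimum duration are merged away as noise flickers.
Residence times of the stalled complex are then read off as the duration of
each stalled segment, from entry into the stalled level to the return to
baseline; a stall still in progress at the end of the trace is
right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .survival import DwellRecord, DwellSet
from .synthetic_traces import Trace


@dataclass
class Segmentation:
    """Trace partitioned into constant-level state segments.

    ``segments`` is a list of (start s, end s, level name); segments tile
    the trace without overlap and adjacent segments differ in level.
    """

    segments: list[tuple[float, float, str]]
    levels: dict[str, float]
    dt: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def segment_trace(
    trace: Trace,
    filter_window: float = 0.5,
    level_tolerance: float = 15.0,
    levels: dict[str, float] | None = None,
    min_duration: float | None = None,
) -> Segmentation:
    """Assign every sample to the nearest state level after median filtering.

    Parameters
    ----------
    filter_window : float
        Median-filter window in seconds; must span at least 2 samples.
    level_tolerance : float
        Half-separation (nm) required between any two levels: levels closer
        than twice this are unresolvable and refused.
    levels : dict, optional
        Level name -> extension (nm); defaults to the trace's own
        ``meta['levels']``.
    min_duration : float, optional
        Runs shorter than this (seconds) are merged into their neighbour;
        default 3 samples.
    """
    if trace.times.size == 0:
        raise ValueError("empty trace")
    if levels is None:
        levels = trace.meta.get("levels")
        if levels is None:
            raise ValueError("no levels given and trace carries no meta['levels']")
    names = list(levels)
    vals = np.array([levels[n] for n in names])
    gaps = np.abs(vals[:, None] - vals[None, :])[np.triu_indices(len(vals), k=1)]
    if gaps.size and gaps.min() < 2 * level_tolerance:
        raise ValueError(
            f"levels separated by {gaps.min():.1f} nm are unresolvable at "
            f"tolerance {level_tolerance} nm"
        )
    dt = trace.dt
    win = int(round(filter_window / dt))
    if win < 2:
        raise ValueError(
            f"filter_window must span >= 2 samples, got {win} at dt={dt:.4g}s"
        )
    filtered = median_filter(trace.extensions, size=win, mode="nearest")
    assign = np.argmin(np.abs(filtered[:, None] - vals[None, :]), axis=1)

    min_samples = (
        3 if min_duration is None else max(1, int(round(min_duration / dt)))
    )
    assign = _merge_short_runs(assign, min_samples)

    # compress runs into segments
    change = np.flatnonzero(np.diff(assign)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [assign.size]])
    t0 = trace.times[0]
    t_end = trace.times[-1] + dt
    segments = [
        (
            float(trace.times[s]),
            float(trace.times[e] if e < assign.size else t_end),
            names[assign[s]],
        )
        for s, e in zip(starts, ends)
    ]
    # re-anchor first segment to trace start
    if segments:
        segments[0] = (t0, segments[0][1], segments[0][2])
    return Segmentation(segments=segments, levels=dict(levels), dt=dt)


def _merge_short_runs(assign: np.ndarray, min_samples: int) -> np.ndarray:
    """Reassign runs shorter than min_samples to the preceding run's level."""
    if min_samples <= 1:
        return assign
    assign = assign.copy()
    changed = True
    while changed:
        changed = False
        change = np.flatnonzero(np.diff(assign)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [assign.size]])
        for s, e in zip(starts, ends):
            if e - s < min_samples:
                if s > 0:
                    assign[s:e] = assign[s - 1]
                elif e < assign.size:
                    assign[s:e] = assign[e]
                changed = True
                break
    return assign


def extract_dwells(
    seg: Segmentation,
    trace_end: float,
    stalled_level: str = "stalled",
    baseline_level: str = "baseline",
) -> DwellSet:
    """Residence times of the stalled complex from a segmentation.

    One record per stalled segment, from entry into the stalled level to the
    return to baseline.  A final stalled segment that runs to ``trace_end``
    (within one sample) is censored rather than dropped.
    """
    records: list[DwellRecord] = []
    n = len(seg.segments)
    for i, (start, end, level) in enumerate(seg.segments):
        if level != stalled_level:
            continue
        duration = end - start
        if duration <= 0:
            continue
        is_last = i == n - 1
        censored = is_last and end >= trace_end - seg.dt
        if not censored and i + 1 < n and seg.segments[i + 1][2] != baseline_level:
            # stall not ending at baseline: treat as censored at its end
            censored = True
        records.append(DwellRecord(duration=duration, censored=censored))
    return DwellSet(records=records, condition={"source": "segmentation"})
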