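"""Centroid-speed profiles and active/inactive population subgrouping.

Downstream behavioural quantification on stitched trails: short observation
gaps (<1 s) are bridged by linear interpolation since a worm barely moves on
that timescale, longer gaps are excluded; positions are smoothed with a 1-s
centred running average to suppress centroid jitter, speeds with a 1-min
running average because the analysis targets slow activity changes; and
population profiles pool per-minute speed bins over worms.  Individuals are
labelled active or inactive per observation window by whether they
accumulate more than 5 minutes of above-threshold movement.

"Active movement" needs a speed cutoff the upstream analysis never had to
state; the default here is 0.02 body lengths/s (1 px/s at a 50 px body),
exposed as ``active_speed_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blob_io import RecordingMeta, Trail

__all__ = [
    "CentroidSeries",
    "SpeedProfile",
    "ActivityClassification",
    "DEFAULT_WINDOWS_MIN",
    "interpolate_gaps",
    "smooth_and_speed",
    "bin_speeds",
    "classify_activity",
]

DEFAULT_WINDOWS_MIN = ((0.0, 30.0), (30.0, 90.0), (90.0, 180.0))


@dataclass
class CentroidSeries:
    """A trail resampled onto the uniform frame grid with a validity mask."""

    trail_id: object
    frames: np.ndarray   # int, consecutive
    times: np.ndarray    # seconds
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray    # bool; False marks excluded gap regions
    fps: float


@dataclass
class SpeedProfile:
    """Smoothed speed series plus per-minute bin means for one trail."""

    trail_id: object
    times: np.ndarray
    speeds: np.ndarray    # px/s, >= 0
    valid: np.ndarray
    binned: np.ndarray    # per-minute mean speed over the recording grid (NaN = no data)
    bin_s: float = 60.0

    @property
    def duration(self) -> float:
        v = np.flatnonzero(self.valid)
        return float(self.times[v[-1]] - self.times[v[0]]) if v.size else 0.0


@dataclass
class ActivityClassification:
    trail_id: object
    windows_min: tuple
    active_minutes: tuple
    labels: tuple         # "active" | "inactive" per window


def interpolate_gaps(trail: Trail, meta: RecordingMeta,
                     max_gap_s: float = 1.0) -> CentroidSeries:
    """Resample a trail onto the frame grid, filling only sub-second gaps.

    Missing sections shorter than ``max_gap_s`` are filled by linear
    interpolation between the flanking observations; longer sections are
    marked invalid and excluded from all downstream analysis.  Observed
    samples are never altered.
    """
    obs = {b.frame: b.centroid for b in trail.blobs}
    f0, f1 = trail.blobs[0].frame, trail.blobs[-1].frame
    frames = np.arange(f0, f1 + 1)
    x = np.full(frames.size, np.nan)
    y = np.full(frames.size, np.nan)
    valid = np.zeros(frames.size, dtype=bool)
    for f, (cx, cy) in obs.items():
        i = f - f0
        x[i], y[i] = cx, cy
        valid[i] = True
    # classify each missing run by its length in seconds
    i = 0
    while i < frames.size:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < frames.size and not valid[j]:
            j += 1
        gap_s = (j - i) / meta.fps  # number of missing frames
        if gap_s < max_gap_s:
            # linear fill between observed neighbours (both exist: trail
            # starts and ends with observations)
            xi, xj = x[i - 1], x[j]
            yi, yj = y[i - 1], y[j]
            for k in range(i, j):
                t = (k - (i - 1)) / (j - (i - 1))
                x[k] = xi + t * (xj - xi)
                y[k] = yi + t * (yj - yi)
                valid[k] = True
        i = j
    return CentroidSeries(
        trail_id=trail.trail_id,
        frames=frames,
        times=frames / meta.fps,
        x=x, y=y, valid=valid, fps=meta.fps,
    )


def _running_mean(a: np.ndarray, half: int) -> np.ndarray:
    """Centred running mean with window shrinkage at the ends (exact, via
    cumulative sums)."""
    n = a.size
    if n == 0 or half == 0:
        return a.copy()
    cs = np.concatenate([[0.0], np.cumsum(a)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _valid_runs(valid: np.ndarray):
    runs = []
    i = 0
    n = valid.size
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def smooth_and_speed(series: CentroidSeries, meta: RecordingMeta,
                     pos_window_s: float = 1.0,
                     speed_window_s: float = 60.0,
                     bin_s: float = 60.0) -> SpeedProfile:
    """Jitter-suppressed centroid speed for one trail.

    Within each contiguous valid run: positions get a centred running mean
    over ``pos_window_s``; speed is the central-difference displacement rate
    (px/s); speeds get a centred running mean over ``speed_window_s``.
    Windows shrink at run boundaries, so invalid regions never leak into
    valid ones.  Per-minute bin means are computed on the recording grid.
    """
    fps = series.fps
    pos_half = int(round(pos_window_s * fps)) // 2
    speed_half = int(round(speed_window_s * fps)) // 2
    speeds = np.zeros(series.frames.size)
    for i, j in _valid_runs(series.valid):
        xs = _running_mean(series.x[i:j], pos_half)
        ys = _running_mean(series.y[i:j], pos_half)
        m = j - i
        if m < 2:
            continue
        v = np.zeros(m)
        # central differences in the interior, one-sided at run edges
        v[1:-1] = np.hypot(xs[2:] - xs[:-2], ys[2:] - ys[:-2]) * fps / 2.0
        v[0] = np.hypot(xs[1] - xs[0], ys[1] - ys[0]) * fps
        v[-1] = np.hypot(xs[-1] - xs[-2], ys[-1] - ys[-2]) * fps
        speeds[i:j] = _running_mean(v, speed_half)
    n_bins = int(np.ceil(meta.duration / bin_s)) if meta.duration > 0 else 0
    binned = np.full(max(n_bins, 1), np.nan)
    which = np.minimum((series.times / bin_s).astype(int), max(n_bins - 1, 0))
    for b in range(max(n_bins, 1)):
        sel = series.valid & (which == b)
        if sel.any():
            binned[b] = speeds[sel].mean()
    return SpeedProfile(
        trail_id=series.trail_id,
        times=series.times,
        speeds=speeds,
        valid=series.valid.copy(),
        binned=binned,
        bin_s=bin_s,
    )


def bin_speeds(profiles: list, meta: RecordingMeta, bin_s: float = 60.0,
               min_duration_s: float = 60.0) -> dict:
    """Pooled per-bin population speed profile.

    Pools all valid samples of all worms per time bin (sample-weighted mean);
    trails shorter than ``min_duration_s`` are excluded as the standard
    noise filter.  Bins with no data are NaN.
    """
    n_bins = int(np.ceil(meta.duration / bin_s)) if meta.duration > 0 else 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    worms = np.zeros(n_bins, dtype=int)
    for p in profiles:
        if p.duration < min_duration_s:
            continue
        which = np.minimum((p.times / bin_s).astype(int), n_bins - 1)
        seen = np.zeros(n_bins, dtype=bool)
        for b, s, ok in zip(which, p.speeds, p.valid):
            if ok:
                sums[b] += s
                counts[b] += 1
                seen[b] = True
        worms += seen
    mean = np.full(n_bins, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return {
        "time_bin_min": (np.arange(n_bins) * bin_s / 60.0),
        "mean_speed_px_s": mean,
        "n_worms": worms,
        "n_samples": counts,
    }


def classify_activity(profile: SpeedProfile,
                      windows_min: tuple = DEFAULT_WINDOWS_MIN,
                      active_min_threshold: float = 5.0,
                      active_speed_threshold: float = 1.0) -> ActivityClassification:
    """Label a worm active/inactive per observation window.

    ``active_minutes`` is the observed time (minutes) inside the window with
    smoothed speed above ``active_speed_threshold``; the label is "active"
    iff that exceeds ``active_min_threshold`` (default 5 min).  Partially
    covered windows are scored on observed time only.
    """
    dt_min = (1.0 / _fps_of(profile)) / 60.0 if profile.times.size else 0.0
    active_minutes = []
    labels = []
    for lo, hi in windows_min:
        sel = (profile.valid
               & (profile.times >= lo * 60.0)
               & (profile.times < hi * 60.0)
               & (profile.speeds > active_speed_threshold))
        minutes = sel.sum() * dt_min
        active_minutes.append(minutes)
        labels.append("active" if minutes > active_min_threshold else "inactive")
    return ActivityClassification(
        trail_id=profile.trail_id,
        windows_min=tuple(windows_min),
        active_minutes=tuple(active_minutes),
        labels=tuple(labels),
    )


def _fps_of(profile: SpeedProfile) -> float:
    if profile.times.size < 2:
        return 1.0
    return 1.0 / float(profile.times[1] - profile.times[0])
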