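"""Per-animal speed and duration-weighted group summaries.

The per-animal statistic is the classic track speed: the sum of distances
between sequential centroids divided by the duration of the track. Group
summaries weight each animal by its track duration, which makes the group
mean equal to (total distance travelled by the group) / (total tracked
time) and, crucially, invariant to track fragmentation: splitting a track
into contiguous pieces redistributes weight but cannot move the mean.

Analysis is restricted to the final two minutes of a ten-minute recording
by default ([480, 600) s): the early part of a recording is when animals
adapt to the plate and when a motion-triggered tracker is still acquiring
slow animals, so only the settled window is scored.

The weighted spread uses reliability (frequency-style) weights:

    s2_w  = sum(w_i (v_i - m)^2) / (W - sum(w_i^2)/W),   W = sum(w_i)
    n_eff = W^2 / sum(w_i^2)
    sem   = sqrt(s2_w / n_eff)

which reduces to the ordinary unbiased variance and sem when all
durations are equal. The median is the plain unweighted sample median,
the statistic usually annotated on assay speed histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Track

__all__ = [
    "SpeedRecord",
    "GroupSummary",
    "window_track",
    "animal_speed",
    "group_summary",
]

DEFAULT_WINDOW_S = (480.0, 600.0)
DEFAULT_BIN_WIDTH_MM_S = 0.01


@dataclass(frozen=True)
class SpeedRecord:
    """One animal's speed (mm/s) with its track duration (the weight)."""

    animal_id: int
    region: int
    speed_mm_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.speed_mm_s < 0:
            raise ValueError("speed_mm_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class GroupSummary:
    """Duration-weighted summary of one treatment group."""

    label: str
    n: int
    mean_mm_s: float
    sd_mm_s: float
    sem_mm_s: float
    median_mm_s: float
    unweighted_mean_mm_s: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def window_track(
    track: Track,
    window_start_s: float = DEFAULT_WINDOW_S[0],
    window_end_s: float = DEFAULT_WINDOW_S[1],
) -> Track | None:
    """Restrict a track to samples with t in [window_start_s, window_end_s).

    Returns ``None`` if fewer than two samples fall inside the window.
    """
    if window_start_s >= window_end_s:
        raise ValueError("window_start_s must be < window_end_s")
    mask = (track.t_s >= window_start_s) & (track.t_s < window_end_s)
    if mask.sum() < 2:
        return None
    return Track(
        animal_id=track.animal_id,
        frames=track.frames[mask],
        t_s=track.t_s[mask],
        x_mm=track.x_mm[mask],
        y_mm=track.y_mm[mask],
        region=track.region,
        meta=dict(track.meta),
    )


def smooth_track(track: Track, window: int = 3) -> Track:
    """Optional centered moving-average smoother for centroids (off by
    default in the pipeline; raw centroid differences are the standard)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1 or len(track) < window:
        return track
    kernel = np.ones(window) / window
    pad = window // 2
    def smooth(a: np.ndarray) -> np.ndarray:
        padded = np.pad(a, pad, mode="edge")
        return np.convolve(padded, kernel, mode="valid")
    return Track(
        animal_id=track.animal_id,
        frames=track.frames,
        t_s=track.t_s,
        x_mm=smooth(track.x_mm),
        y_mm=smooth(track.y_mm),
        region=track.region,
        meta=dict(track.meta),
    )


def animal_speed(track: Track) -> SpeedRecord:
    """Speed of one animal: summed centroid-to-centroid distance divided by
    the track duration; the duration is kept as the statistical weight."""
    if len(track) < 2:
        raise ValueError("track must have at least 2 samples")
    duration = track.duration_s
    if duration <= 0:
        raise ValueError("track duration must be positive")
    return SpeedRecord(
        animal_id=track.animal_id,
        region=track.region,
        speed_mm_s=track.path_length_mm() / duration,
        duration_s=duration,
    )


def speeds_from_tracks(
    tracks: list[Track],
    window_start_s: float = DEFAULT_WINDOW_S[0],
    window_end_s: float = DEFAULT_WINDOW_S[1],
) -> list[SpeedRecord]:
    """Window every track and score the survivors."""
    records = []
    for tr in tracks:
        sub = window_track(tr, window_start_s, window_end_s)
        if sub is not None:
            records.append(animal_speed(sub))
    return records


def group_summary(
    records: list[SpeedRecord],
    label: str = "",
    bin_width_mm_s: float = DEFAULT_BIN_WIDTH_MM_S,
) -> GroupSummary:
    """Duration-weighted mean/SD/SEM, unweighted median, and a histogram.

    The histogram covers [0, max speed] in bins of ``bin_width_mm_s``.
    """
    if not records:
        raise ValueError("group_summary needs at least one record")
    v = np.array([r.speed_mm_s for r in records])
    w = np.array([r.duration_s for r in records])
    total_w = w.sum()
    mean = float(np.sum(w * v) / total_w)
    denom = total_w - np.sum(w**2) / total_w
    if denom > 0:
        var = float(np.sum(w * (v - mean) ** 2) / denom)
    else:  # single record: spread undefined, report 0
        var = 0.0
    n_eff = total_w**2 / np.sum(w**2)
    sd = float(np.sqrt(var))
    sem = float(np.sqrt(var / n_eff))

    vmax = float(v.max())
    n_bins = max(1, int(np.ceil(vmax / bin_width_mm_s))) if vmax > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width_mm_s
    counts, _ = np.histogram(v, bins=edges)

    return GroupSummary(
        label=label,
        n=len(records),
        mean_mm_s=mean,
        sd_mm_s=sd,
        sem_mm_s=sem,
        median_mm_s=float(np.median(v)),
        unweighted_mean_mm_s=float(v.mean()),
        hist_counts=counts,
        hist_edges=edges,
    )
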