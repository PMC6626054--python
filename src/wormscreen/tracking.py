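"""Detection, linking and track filtering for multi-worm dark-field video.

The tracker mirrors the behaviour of a Multi-Worm-Tracker-style toolchain:
worms appear as bright blobs on a dark background; each frame is
thresholded and labelled, blob centroids are linked frame-to-frame by
mutual nearest neighbours under a distance gate, and the resulting tracks
are cleaned with two filters before any statistics are computed:

* a minimum-duration gate (drop tracks shorter than ``min_track_duration_s``,
  default 10 s — the usual minimum-time artifact filter), and
* a minimum-displacement gate (drop tracks that never move at least
  ``min_total_displacement_mm`` from their starting point, default 1 mm,
  about one body length) which removes shadows, dust and other stationary
  image artifacts masquerading as animals.

Collisions (merged blobs) terminate the involved tracks; detections after
a split start fresh tracks. Speed statistics downstream are per-track and
duration-weighted, so fragmentation costs statistical weight but does not
bias the group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label, regionprops

from .plate import PlateLayout

__all__ = [
    "Detection",
    "Track",
    "TrackerConfig",
    "detect",
    "link",
    "filter_tracks",
    "assign_regions",
]

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass(frozen=True)
class Detection:
    """One candidate animal in one frame: intensity-weighted centroid in mm."""

    frame_index: int
    t_s: float
    x_mm: float
    y_mm: float
    area_px: int


@dataclass(eq=False)
class Track:
    """One animal's centroid time series.

    ``frames`` are strictly increasing, and by default consecutive (the
    linker does no gap bridging). ``region`` is the plate region index or
    ``UNASSIGNED``. ``meta`` carries provenance such as the simulator's
    ground-truth speed.
    """

    animal_id: int
    frames: np.ndarray  # (n,) int
    t_s: np.ndarray  # (n,) float, seconds
    x_mm: np.ndarray  # (n,) float
    y_mm: np.ndarray  # (n,) float
    region: int = UNASSIGNED
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        n = len(self.frames)
        if not (len(self.t_s) == len(self.x_mm) == len(self.y_mm) == n):
            raise ValueError("track arrays must have equal length")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in mm."""
        return np.column_stack([self.x_mm, self.y_mm])

    def max_displacement_mm(self) -> float:
        """Largest distance of any sample from the first position."""
        dx = self.x_mm - self.x_mm[0]
        dy = self.y_mm - self.y_mm[0]
        return float(np.sqrt(dx * dx + dy * dy).max())

    def path_length_mm(self) -> float:
        """Sum of distances between sequential centroids."""
        if len(self) < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x_mm), np.diff(self.y_mm)).sum())


@dataclass(frozen=True)
class TrackerConfig:
    """Thresholds and gates for detection, linking and filtering.

    ``intensity_threshold`` is on the raw grayscale frame; blobs outside
    ``[min_area_px, max_area_px]`` are discarded. ``max_link_mm`` is the
    per-frame linking gate. The two filter gates are documented in the
    module docstring.
    """

    intensity_threshold: float = 40.0
    min_area_px: int = 5
    max_area_px: int = 10_000
    max_link_mm: float = 0.5
    min_track_duration_s: float = 10.0
    min_total_displacement_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.min_area_px <= 0 or self.max_area_px < self.min_area_px:
            raise ValueError("invalid blob area gates")
        if self.max_link_mm <= 0:
            raise ValueError("max_link_mm must be positive")
        if self.min_track_duration_s <= 0 or self.min_total_displacement_mm <= 0:
            raise ValueError("filter gates must be positive")


def detect(
    frame: np.ndarray,
    config: TrackerConfig,
    mm_per_px: float,
    frame_index: int = 0,
    t_s: float = 0.0,
) -> list[Detection]:
    """Detect bright blobs in one grayscale frame.

    Thresholds at ``config.intensity_threshold``, labels 8-connected
    components, keeps those within the area gates and returns their
    intensity-weighted centroids converted to mm.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    mask = frame > config.intensity_threshold
    if not mask.any():
        return []
    labels = label(mask, connectivity=2)
    out: list[Detection] = []
    for prop in regionprops(labels, intensity_image=frame):
        if not (config.min_area_px <= prop.area <= config.max_area_px):
            continue
        cy, cx = prop.centroid_weighted  # row, col
        out.append(
            Detection(
                frame_index=frame_index,
                t_s=t_s,
                x_mm=float(cx) * mm_per_px,
                y_mm=float(cy) * mm_per_px,
                area_px=int(prop.area),
            )
        )
    return out


def _mutual_nearest_pairs(
    prev_xy: np.ndarray, cur_xy: np.ndarray, gate_mm: float
) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbour pairs within the gate.

    Pairs are accepted in order of increasing distance (ties by lower
    previous index), so each endpoint is used at most once and every
    accepted pair is mutually nearest among the survivors.
    """
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - cur_xy[None, :, :], axis=-1)
    candidates = np.argwhere(d <= gate_mm)
    order = np.lexsort((candidates[:, 0], d[candidates[:, 0], candidates[:, 1]]))
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in candidates[order]:
        if i in used_prev or j in used_cur:
            continue
        used_prev.add(int(i))
        used_cur.add(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def link(
    detections_by_frame: list[list[Detection]], config: TrackerConfig
) -> list[Track]:
    """Link per-frame detections into tracks.

    Consecutive frames are matched greedily by mutual nearest neighbour
    with the ``max_link_mm`` gate; unmatched detections start new tracks
    and unmatched tracks terminate (no gap bridging). Track ids are
    assigned in order of creation.
    """
    open_tracks: dict[int, list[Detection]] = {}
    closed: list[list[Detection]] = []
    next_id = 0
    prev_ids: list[int] = []
    prev_dets: list[Detection] = []
    for dets in detections_by_frame:
        cur = list(dets)
        if prev_dets and cur:
            prev_xy = np.array([[d.x_mm, d.y_mm] for d in prev_dets])
            cur_xy = np.array([[d.x_mm, d.y_mm] for d in cur])
            pairs = _mutual_nearest_pairs(prev_xy, cur_xy, config.max_link_mm)
        else:
            pairs = []
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}
        new_prev_ids: list[int] = []
        new_prev_dets: list[Detection] = []
        for i, j in sorted(pairs, key=lambda p: prev_ids[p[0]]):
            tid = prev_ids[i]
            open_tracks[tid].append(cur[j])
            new_prev_ids.append(tid)
            new_prev_dets.append(cur[j])
        for i, tid in enumerate(prev_ids):
            if i not in matched_prev:
                closed.append(open_tracks.pop(tid))
        for j, det in enumerate(cur):
            if j not in matched_cur:
                open_tracks[next_id] = [det]
                new_prev_ids.append(next_id)
                new_prev_dets.append(det)
                next_id += 1
        prev_ids, prev_dets = new_prev_ids, new_prev_dets
    closed.extend(open_tracks[tid] for tid in sorted(open_tracks))

    tracks = []
    for aid, dets in enumerate(sorted(closed, key=lambda ds: (ds[0].frame_index, ds[0].x_mm))):
        tracks.append(
            Track(
                animal_id=aid,
                frames=np.array([d.frame_index for d in dets]),
                t_s=np.array([d.t_s for d in dets]),
                x_mm=np.array([d.x_mm for d in dets]),
                y_mm=np.array([d.y_mm for d in dets]),
            )
        )
    return tracks


def filter_tracks(tracks: list[Track], config: TrackerConfig) -> list[Track]:
    """Apply the minimum-duration and minimum-displacement gates.

    Idempotent: surviving tracks satisfy both gates, so a second pass
    removes nothing.
    """
    kept: list[Track] = []
    n_short = n_still = 0
    for tr in tracks:
        if len(tr) < 2 or tr.duration_s < config.min_track_duration_s:
            n_short += 1
            continue
        if tr.max_displacement_mm() < config.min_total_displacement_mm:
            n_still += 1
            continue
        kept.append(tr)
    logger.info(
        "filter_tracks: %d in, %d kept, %d below %.3gs duration, %d non-movers",
        len(tracks), len(kept), n_short, config.min_track_duration_s, n_still,
    )
    return kept


def assign_regions(tracks: list[Track], layout: PlateLayout) -> list[Track]:
    """Assign each track the region of its first centroid.

    A track with any sample outside that region (which glycerol confinement
    should prevent) is logged and excluded, so every surviving track is
    counted in exactly one region's statistics.
    """
    out: list[Track] = []
    n_crossed = 0
    for tr in tracks:
        region = layout.region_of(tr.x_mm[0], tr.y_mm[0])
        all_regions = layout.region_of(tr.x_mm, tr.y_mm)
        if np.any(all_regions != region):
            n_crossed += 1
            logger.warning(
                "track %d crossed out of region %d; excluded from statistics",
                tr.animal_id, region,
            )
            continue
        out.append(replace(tr, region=int(region)))
    if n_crossed:
        logger.info("assign_regions: excluded %d region-crossing tracks", n_crossed)
    return out
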