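"""Trajectory tables, plate manifests, packaged fixtures and the
end-to-end pipeline.

The on-disk trajectory dialect is a flat CSV/TSV with columns
``plate_id, region, animal_id, frame, t_s, x_mm, y_mm`` sorted by
(animal_id, frame) — one row per animal per frame. External tracker
exports can be converted in by renaming columns to this mapping. A
sidecar JSON may carry simulation ground truth (per-animal speed, group
multiplier, seed).

``run_pipeline`` chains every stage —
detect -> link -> filter -> assign_regions -> window -> speed ->
summaries -> Z'/ratios/hits — with per-stage in/out counts logged, and is
deterministic given its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import screening, stats, tracking
from .plate import PlateLayout
from .screening import ScreenResult, ZPrimeResult
from .stats import DEFAULT_WINDOW_S, GroupSummary, SpeedRecord
from .tracking import Track, TrackerConfig

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "load_table1",
    "RegionAssignment",
    "PlateManifest",
    "ScreenReport",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["plate_id", "region", "animal_id", "frame", "t_s", "x_mm", "y_mm"]

ROLES = {"treated", "negative_control", "positive_control", "healthy_reference", "disease_reference"}


def write_trajectories(
    tracks: list[Track], path: str | Path, plate_id: str = "plate0"
) -> None:
    """Write tracks in the flat trajectory dialect (TSV if the suffix is
    .tsv, else CSV). A ``<path>.truth.json`` sidecar is written when the
    tracks carry simulation ground truth."""
    path = Path(path)
    rows = []
    truth = {}
    for tr in tracks:
        for f, t, x, y in zip(tr.frames, tr.t_s, tr.x_mm, tr.y_mm):
            rows.append((plate_id, tr.region, tr.animal_id, int(f), t, x, y))
        if "true_speed_mm_s" in tr.meta:
            truth[str(tr.animal_id)] = tr.meta
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    df = df.sort_values(["animal_id", "frame"], kind="stable")
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.9f")
    if truth:
        with open(f"{path}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def read_trajectories(path: str | Path) -> list[Track]:
    """Read a trajectory table back into tracks.

    Raises on missing columns, duplicated (animal, frame) rows (the
    offending row is named), non-monotone frames within an animal, and
    files mixing several plates.
    """
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns: {missing}")
    if df.empty:
        return []
    if df["plate_id"].nunique() > 1:
        raise ValueError(
            f"trajectory file {path} mixes plates: {sorted(df['plate_id'].unique())}"
        )
    dup = df.duplicated(subset=["animal_id", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (animal_id={row['animal_id']}, frame={row['frame']}) "
            f"row in {path}"
        )
    tracks = []
    for aid, g in df.groupby("animal_id", sort=True):
        g = g.sort_index()
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"non-monotone frames for animal_id={aid} in {path}")
        regions = g["region"].unique()
        tracks.append(
            Track(
                animal_id=int(aid),
                frames=frames,
                t_s=g["t_s"].to_numpy(float),
                x_mm=g["x_mm"].to_numpy(float),
                y_mm=g["y_mm"].to_numpy(float),
                region=int(regions[0]) if len(regions) == 1 else tracking.UNASSIGNED,
            )
        )
    truth_path = Path(f"{path}.truth.json")
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        for tr in tracks:
            if str(tr.animal_id) in truth:
                tr.meta.update(truth[str(tr.animal_id)])
    return tracks


def load_table1() -> pd.DataFrame:
    """The packaged compound-ratio table from the reference 38-compound
    screen: rank, compound, blind_number, ratio (treated / untreated
    disease-model control), role (treated or positive_control)."""
    with resources.files("wormscreen").joinpath("data/table1_ratios.csv").open() as fh:
        df = pd.read_csv(fh)
    labels = [
        c if c != "-" else f"blind-{b}"
        for c, b in zip(df["compound"], df["blind_number"])
    ]
    df["label"] = labels
    return df


@dataclass(frozen=True)
class RegionAssignment:
    compound: str
    dose_um: float = 0.0
    role: str = "treated"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")


@dataclass(frozen=True)
class PlateManifest:
    """What is where on one assay plate, plus camera calibration."""

    plate_id: str
    layout: PlateLayout
    region_assignments: dict[int, RegionAssignment]
    mm_per_px: float = 0.033
    fps: float = 10.0

    def __post_init__(self) -> None:
        for r in self.region_assignments:
            if not 0 <= r < self.layout.n_regions:
                raise ValueError(f"region {r} out of range for layout")
        roles = [a.role for a in self.region_assignments.values()]
        if roles.count("negative_control") > 1:
            raise ValueError("at most one negative_control region")

    @classmethod
    def from_dict(cls, d: dict) -> "PlateManifest":
        layout = PlateLayout(**d.get("layout", {}))
        assignments = {
            int(k): RegionAssignment(**v) for k, v in d["region_assignments"].items()
        }
        cal = d.get("calibration", {})
        return cls(
            plate_id=d["plate_id"],
            layout=layout,
            region_assignments=assignments,
            mm_per_px=float(cal.get("mm_per_px", 0.033)),
            fps=float(cal.get("fps", 10.0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PlateManifest":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class ScreenReport:
    plate_id: str
    summaries: dict[int, GroupSummary]
    records: dict[int, list[SpeedRecord]]
    zprime: ZPrimeResult | None = None
    ratios: dict[str, float] = field(default_factory=dict)
    hits: list[ScreenResult] = field(default_factory=list)
    stage_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_text(self) -> str:
        """Deterministic plain-text rendering of the report."""
        lines = [f"plate: {self.plate_id}"]
        for stage, (n_in, n_out) in self.stage_counts.items():
            lines.append(f"stage {stage}: in={n_in} out={n_out} dropped={n_in - n_out}")
        for region in sorted(self.summaries):
            s = self.summaries[region]
            lines.append(
                f"region {region} [{s.label}]: n={s.n} mean={s.mean_mm_s:.6f} "
                f"sd={s.sd_mm_s:.6f} sem={s.sem_mm_s:.6f} median={s.median_mm_s:.6f}"
            )
        if self.zprime is not None:
            lines.append(f"zprime: {self.zprime.zprime:.6f}")
        for name in self.ratios:
            lines.append(f"ratio {name}: {self.ratios[name]:.6f}")
        for h in self.hits:
            lines.append(
                f"hit-rank {h.rank}: {h.compound} ratio={h.ratio:.6f} hit={h.is_hit}"
            )
        return "\n".join(lines) + "\n"

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.summaries):
            s = self.summaries[region]
            rows.append(
                dict(region=region, label=s.label, n=s.n, mean_mm_s=s.mean_mm_s,
                     sd_mm_s=s.sd_mm_s, sem_mm_s=s.sem_mm_s, median_mm_s=s.median_mm_s)
            )
        return pd.DataFrame(rows)

    def screen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(compound=h.compound, ratio=h.ratio, rank=h.rank, is_hit=h.is_hit)
             for h in self.hits]
        )


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def tracks_from_frames(
    frames: np.ndarray, config: TrackerConfig, mm_per_px: float, fps: float
) -> list[Track]:
    """Detect and link a frame stack into raw tracks."""
    dets = [
        tracking.detect(frame, config, mm_per_px, frame_index=k, t_s=k / fps)
        for k, frame in enumerate(frames)
    ]
    n_det = sum(len(d) for d in dets)
    tracks = tracking.link(dets, config)
    logger.info("tracking: %d detections -> %d raw tracks", n_det, len(tracks))
    return tracks


def run_pipeline(
    manifest: PlateManifest,
    *,
    frames: np.ndarray | None = None,
    tracks: list[Track] | None = None,
    tracker_config: TrackerConfig | None = None,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    bin_width_mm_s: float = stats.DEFAULT_BIN_WIDTH_MM_S,
    round_digits: int = 2,
) -> ScreenReport:
    """Run the full analysis on a frame stack or pre-tracked trajectories.

    Produces per-region duration-weighted group summaries, the Z'-factor
    when healthy and disease reference regions exist, ratios to the
    negative control when one exists, and a ranked hit list when a
    positive control is present as well (both controls excluded from the
    hit list).
    """
    cfg = tracker_config or TrackerConfig()
    counts: dict[str, tuple[int, int]] = {}
    try:
        if tracks is None:
            if frames is None:
                raise PipelineError("input", "provide either frames or tracks")
            tracks = tracks_from_frames(frames, cfg, manifest.mm_per_px, manifest.fps)
        n_raw = len(tracks)
        filtered = tracking.filter_tracks(tracks, cfg)
        counts["filter"] = (n_raw, len(filtered))
        assigned = tracking.assign_regions(filtered, manifest.layout)
        counts["assign_regions"] = (len(filtered), len(assigned))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-tag with stage name
        raise PipelineError("tracking", str(e)) from e

    try:
        records: dict[int, list[SpeedRecord]] = {}
        for tr in assigned:
            sub = stats.window_track(tr, *window_s)
            if sub is None:
                continue
            records.setdefault(tr.region, []).append(stats.animal_speed(sub))
        counts["window+speed"] = (len(assigned), sum(len(v) for v in records.values()))
        summaries: dict[int, GroupSummary] = {}
        for region, assignment in sorted(manifest.region_assignments.items()):
            if region in records:
                summaries[region] = stats.group_summary(
                    records[region], label=assignment.compound,
                    bin_width_mm_s=bin_width_mm_s,
                )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("behavior_stats", str(e)) from e

    report = ScreenReport(
        plate_id=manifest.plate_id, summaries=summaries, records=records,
        stage_counts=counts,
    )

    try:
        by_role: dict[str, list[int]] = {}
        for region, assignment in manifest.region_assignments.items():
            if region in summaries:
                by_role.setdefault(assignment.role, []).append(region)
        if by_role.get("healthy_reference") and by_role.get("disease_reference"):
            report.zprime = screening.zprime(
                summaries[by_role["healthy_reference"][0]],
                summaries[by_role["disease_reference"][0]],
            )
        neg = by_role.get("negative_control", [])
        if neg:
            control = summaries[neg[0]]
            for region, assignment in sorted(manifest.region_assignments.items()):
                if region in summaries and assignment.role in ("treated", "positive_control"):
                    report.ratios[assignment.compound] = screening.ratio_to_control(
                        summaries[region], control
                    )
            pos = by_role.get("positive_control", [])
            if pos:
                pos_name = manifest.region_assignments[pos[0]].compound
                screen = [
                    (name, ratio) for name, ratio in report.ratios.items()
                    if name != pos_name
                ]
                if screen:
                    report.hits = screening.call_hits(
                        screen, report.ratios[pos_name], round_digits=round_digits
                    )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("screening", str(e)) from e

    return report
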