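"""Synthetic worm populations, trajectories and dark-field frame stacks.

Downstream stages (tracking, speed statistics, screening) are validated
against populations generated here with known ground truth. The model:

* Per-animal crawl speed is log-normal, parameterized by the *group
  median* ``median_speed_mm_s`` (group medians are what locomotion assays
  of this kind report) with log-scale dispersion ``speed_sigma_log``.
  A drug effect is a multiplicative factor ``effect_multiplier`` applied
  to every animal's speed, so the treated/control ratio of group means
  converges to the multiplier as n grows.
* Each animal performs a persistent random walk at its constant speed:
  the heading diffuses with standard deviation
  ``heading_sigma_rad_per_sqrt_s * sqrt(dt)`` per step and flips by pi at
  Poisson reversal events (rate ``reversal_rate_per_s``).
* Animals are confined to the glycerol-bounded interior of their region
  by specular reflection at the inner border. Reflection flips a step's
  wall-normal component, so every step's chord length is exactly
  ``speed * dt``: with zero centroid noise the pipeline speed estimate
  (summed centroid distances over duration) equals the ground-truth speed
  to floating-point precision, at any frame rate.

Centroid noise defaults to zero because positional jitter inflates the
summed-distance speed estimator (a positive bias); it is opt-in for
robustness experiments.

Presets
-------
``PRESETS`` holds the reference conditions of the screening assay:
``healthy_reference`` (wild-type), ``disease_control`` (the untreated
motor-neuron-degeneration model, group median 0.043 mm/s) and
``nifedipine_treated`` (median 0.061 mm/s). The healthy median is set so
the disease model sits at a 70% reduction in mean speed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plate import PlateLayout
from .tracking import Track

__all__ = [
    "PopulationSpec",
    "SimConfig",
    "PRESETS",
    "simulate_population",
    "render_frames",
]

#: Maximum number of pixels per rendered frame (guards against absurd
#: memory when pixel_size_mm is tiny relative to the plate).
MAX_FRAME_PIXELS = 64_000_000

DISEASE_MEDIAN_MM_S = 0.043  # untreated disease-model group median
DISEASE_SPEED_REDUCTION = 0.70  # fractional reduction vs wild type
NIFEDIPINE_MEDIAN_MM_S = 0.061  # nifedipine-treated group median


@dataclass(frozen=True)
class PopulationSpec:
    """One treatment group: how many animals, how fast, in which region."""

    n_animals: int
    median_speed_mm_s: float
    speed_sigma_log: float = 0.4
    effect_multiplier: float = 1.0
    heading_sigma_rad_per_sqrt_s: float = 0.6
    reversal_rate_per_s: float = 0.05
    region_index: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.median_speed_mm_s <= 0:
            raise ValueError("median_speed_mm_s must be positive")
        if self.effect_multiplier < 0:
            raise ValueError("effect_multiplier must be >= 0")
        if self.speed_sigma_log < 0 or self.heading_sigma_rad_per_sqrt_s < 0:
            raise ValueError("dispersions must be >= 0")
        if self.reversal_rate_per_s < 0:
            raise ValueError("reversal_rate_per_s must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Recording parameters shared by all groups on a plate."""

    fps: float = 10.0
    duration_s: float = 600.0
    seed: int = 0
    centroid_noise_mm: float = 0.0
    pixel_size_mm: float = 0.033
    worm_area_px: float = 40.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.centroid_noise_mm < 0:
            raise ValueError("centroid_noise_mm must be >= 0")
        if self.pixel_size_mm <= 0 or self.worm_area_px <= 0:
            raise ValueError("pixel_size_mm and worm_area_px must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


#: Reference group conditions for the screening assay. Speeds in mm/s.
PRESETS: dict[str, PopulationSpec] = {
    "healthy_reference": PopulationSpec(
        n_animals=200,
        median_speed_mm_s=DISEASE_MEDIAN_MM_S / (1.0 - DISEASE_SPEED_REDUCTION),
    ),
    "disease_control": PopulationSpec(
        n_animals=200, median_speed_mm_s=DISEASE_MEDIAN_MM_S
    ),
    "nifedipine_treated": PopulationSpec(
        n_animals=200, median_speed_mm_s=NIFEDIPINE_MEDIAN_MM_S
    ),
}


def _draw_speeds(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-animal ground-truth speeds: log-normal with the group median at
    ``median_speed_mm_s``, scaled by the effect multiplier."""
    z = rng.standard_normal(spec.n_animals)
    return spec.effect_multiplier * spec.median_speed_mm_s * np.exp(spec.speed_sigma_log * z)


def _reflect_step(x, y, dx, dy, bounds):
    """Advance positions by (dx, dy) with specular reflection at the walls.

    Flipping a step component preserves the chord length |(dx, dy)|, so
    reflected steps still advance exactly speed*dt. Steps are assumed
    smaller than the region interior (true for worm speeds and frame
    rates by orders of magnitude).
    """
    xmin, ymin, xmax, ymax = bounds
    nx = x + dx
    lo = nx < xmin
    hi = nx > xmax
    dx = np.where(lo | hi, -dx, dx)
    nx = x + dx
    ny = y + dy
    lo = ny < ymin
    hi = ny > ymax
    dy = np.where(lo | hi, -dy, dy)
    ny = y + dy
    return nx, ny, dx, dy


def simulate_population(
    spec: PopulationSpec, layout: PlateLayout, config: SimConfig
) -> list[Track]:
    """Simulate one treatment group and return its ground-truth tracks.

    Each returned :class:`~wormscreen.tracking.Track` is already assigned
    to ``spec.region_index`` and carries ``meta['true_speed_mm_s']``,
    ``meta['effect_multiplier']`` and ``meta['seed']``. Identical inputs
    give bit-identical output.
    """
    if not 0 <= spec.region_index < layout.n_regions:
        raise ValueError(
            f"region_index {spec.region_index} out of range [0, {layout.n_regions})"
        )
    rng = np.random.default_rng(config.seed)
    n = spec.n_animals
    n_frames = config.n_frames
    dt = 1.0 / config.fps
    bounds = layout.region_inner_bounds(spec.region_index)
    xmin, ymin, xmax, ymax = bounds

    speeds = _draw_speeds(spec, rng)
    # keep starting points a hair off the walls so the first reflected step
    # cannot overshoot the opposite wall
    pad = min(0.05 * (xmax - xmin), 0.05 * (ymax - ymin))
    x = rng.uniform(xmin + pad, xmax - pad, size=n)
    y = rng.uniform(ymin + pad, ymax - pad, size=n)
    heading = rng.uniform(0.0, 2.0 * np.pi, size=n)

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    xs[0], ys[0] = x, y
    sigma_step = spec.heading_sigma_rad_per_sqrt_s * np.sqrt(dt)
    p_reverse = 1.0 - np.exp(-spec.reversal_rate_per_s * dt)
    step = speeds * dt
    for k in range(1, n_frames):
        if sigma_step > 0:
            heading = heading + sigma_step * rng.standard_normal(n)
        if p_reverse > 0:
            flip = rng.random(n) < p_reverse
            heading = np.where(flip, heading + np.pi, heading)
        dx = step * np.cos(heading)
        dy = step * np.sin(heading)
        x, y, dx, dy = _reflect_step(x, y, dx, dy, bounds)
        heading = np.arctan2(dy, dx) if np.any(step > 0) else heading
        xs[k], ys[k] = x, y

    if config.centroid_noise_mm > 0:
        xs = xs + rng.normal(0.0, config.centroid_noise_mm, size=xs.shape)
        ys = ys + rng.normal(0.0, config.centroid_noise_mm, size=ys.shape)
        np.clip(xs, xmin, xmax, out=xs)
        np.clip(ys, ymin, ymax, out=ys)

    frames = np.arange(n_frames)
    t_s = frames * dt
    tracks: list[Track] = []
    for a in range(n):
        tracks.append(
            Track(
                animal_id=a,
                frames=frames.copy(),
                t_s=t_s.copy(),
                x_mm=xs[:, a].copy(),
                y_mm=ys[:, a].copy(),
                region=spec.region_index,
                meta={
                    "true_speed_mm_s": float(speeds[a]),
                    "effect_multiplier": spec.effect_multiplier,
                    "seed": config.seed,
                },
            )
        )
    return tracks


def simulate_plate(
    specs: list[PopulationSpec], layout: PlateLayout, config: SimConfig
) -> list[Track]:
    """Simulate several groups on one plate with independent substreams.

    Animal ids are globally unique (offset per group); each group's
    randomness derives from ``config.seed`` and its region index so
    groups are reproducible independently of plate composition.
    """
    tracks: list[Track] = []
    offset = 0
    for spec in specs:
        sub = replace(config, seed=int(np.random.SeedSequence(
            [config.seed, spec.region_index]).generate_state(1)[0] % (2**31)))
        group = simulate_population(spec, layout, sub)
        for tr in group:
            tr.animal_id += offset
        offset += spec.n_animals
        tracks.extend(group)
    return tracks


def render_frames(
    tracks: list[Track], layout: PlateLayout, config: SimConfig
) -> np.ndarray:
    """Render tracks as a dark-field frame stack (T, H, W) uint8.

    Each animal is a bright soft-edged disk of ~``worm_area_px`` pixels
    centred at its (sub-pixel) position; background is 0, peak intensity
    255. Pixel intensity falls linearly over the final pixel of the disk
    radius, so the intensity-weighted centroid of an isolated blob matches
    the true position to well under half a pixel. Overlapping animals
    merge into one connected component.
    """
    h = int(np.ceil(layout.height_mm / config.pixel_size_mm))
    w = int(np.ceil(layout.width_mm / config.pixel_size_mm))
    if h * w > MAX_FRAME_PIXELS:
        raise ValueError(
            f"frame of {h}x{w} px exceeds MAX_FRAME_PIXELS={MAX_FRAME_PIXELS}; "
            "increase pixel_size_mm or shrink the layout"
        )
    if not tracks:
        raise ValueError("no tracks to render")
    all_frames = sorted({int(f) for tr in tracks for f in tr.frames})
    frame_pos = {f: i for i, f in enumerate(all_frames)}
    stack = np.zeros((len(all_frames), h, w), dtype=np.float32)

    radius = np.sqrt(config.worm_area_px / np.pi)
    r_int = int(np.ceil(radius)) + 1
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]

    for tr in tracks:
        px = tr.x_mm / config.pixel_size_mm
        py = tr.y_mm / config.pixel_size_mm
        for f, cx, cy in zip(tr.frames, px, py):
            ix, iy = int(np.floor(cx)), int(np.floor(cy))
            fx, fy = cx - ix, cy - iy
            dist = np.sqrt((xx - fx) ** 2 + (yy - fy) ** 2)
            blob = np.clip(radius - dist + 0.5, 0.0, 1.0)
            x0, y0 = ix - r_int, iy - r_int
            sy0, sy1 = max(0, y0), min(h, y0 + blob.shape[0])
            sx0, sx1 = max(0, x0), min(w, x0 + blob.shape[1])
            if sy0 >= sy1 or sx0 >= sx1:
                continue
            sub = blob[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
            region = stack[frame_pos[int(f)], sy0:sy1, sx0:sx1]
            np.maximum(region, sub, out=region)

    return (stack * 255.0).astype(np.uint8)
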