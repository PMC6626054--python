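# Methods

## The assay being modelled

The screening assay quantifies crawling speed of many *C. elegans* at once on a
13 × 10 cm agar plate divided into a 4 × 2 grid of equal-area regions. Each region
is ringed by glycerol, an aversive high-osmolarity barrier, so a treatment group
stays in its region for the whole recording. A dark-field camera records the plate
for 10 minutes; a tracker reports one centroid per animal per frame. Only the
final 2 minutes are analysed: the early recording is when animals adapt to the
plate and when a motion-triggered tracker is still acquiring slow animals, so the
settled window gives the least biased speeds.

## Synthetic populations

The simulator provides ground truth for every downstream stage.

* **Speed law.** Per-animal crawl speed is constant over the recording and
  log-normal across animals: `v = m · exp(σ·Z)`, parameterized by the **group
  median** `m` (the statistic such assays report) with log-dispersion `σ = 0.4`
  (CV ≈ 0.42, a typical spread for per-animal crawl speeds within a synchronized
  population). A drug effect is a multiplicative factor applied to every animal,
  so the treated/untreated ratio of group means estimates the multiplier directly.
* **Trajectories.** Headings follow a persistent random walk — diffusion
  `0.6 rad/√s` plus Poisson reversals at `0.05 s⁻¹`, together giving a heading
  correlation time of ~3.6 s, i.e. runs of a few body lengths between effective
  reorientations. Positions advance by exactly `v·Δt` per frame.
* **Confinement.** At the region's inner border (2 mm inside the region edge,
  the glycerol margin) the heading reflects specularly. Reflection flips a step
  component, which preserves the step's chord length; combined with the exact
  `v·Δt` step this makes the pipeline's summed-distance speed estimator equal to
  the ground-truth speed to floating-point precision in the noiseless case, at
  any frame rate. This exactness is what lets the test suite separate estimator
  defects from sampling noise.
* **Centroid noise** defaults to 0 mm. Independent positional jitter adds a
  strictly positive bias to a summed-distance estimator (each step length is the
  norm of signal plus noise), so noise is opt-in for robustness experiments
  rather than part of the reference conditions.
* **Frame rate** is 10 fps (the recording hardware's rate is not a modelled
  quantity; all statistics are per unit time, and in the noiseless limit results
  are fps-invariant).

### Reference presets

| preset | group median (mm/s) | rationale |
|---|---|---|
| `disease_control` | 0.043 | untreated disease-model median |
| `nifedipine_treated` | 0.061 | strongest screened compound |
| `healthy_reference` | 0.043/0.30 ≈ 0.143 | places the disease model at a 70% reduction in mean speed |

Because all groups share σ, the ratio of group means equals the ratio of medians;
the healthy median is therefore fixed by the 70% reduction rather than chosen
independently.

## Tracking

Frames are thresholded (default grayscale 40), 8-connected components within
5–10 000 px are kept, and intensity-weighted centroids are converted to mm.
Linking is greedy mutual-nearest-neighbour between consecutive frames with a
0.5 mm gate, no gap bridging: an unmatched track terminates, an unmatched
detection starts a new track. Collisions (merged blobs) therefore terminate the
involved tracks and the post-split animals restart as new tracks; identities are
not re-stitched. This keeps every detection in at most one track and at most one
detection per frame per track; the cost — fragmentation — is absorbed by the
duration-weighted statistics, which are split-invariant.

Two filters clean the raw tracks, mirroring the usual artifact filters of
multi-worm tracker toolchains:

* drop tracks shorter than **10 s** (`-t 10`-style minimum time), and
* drop tracks whose maximum displacement from the first position is below
  **1 mm** (≈ one body length) — the non-mover rule that removes shadows, dust
  and agar marks, since a real tracked animal has moved from its initial
  position.

Each track is assigned the region of its first centroid; a track observed outside
that region (impossible under glycerol confinement, so a tracking artifact) is
excluded from statistics with a logged warning.

## Statistics

Per-animal speed is the summed centroid-to-centroid distance divided by the track
duration. Group summaries weight animals by track duration:

* weighted mean `m = Σwᵢvᵢ/Σwᵢ` (equal to group distance / group time; invariant
  to splitting any track into contiguous pieces, verified to 10⁻¹² relative
  error);
* weighted variance with reliability weights
  `s²_w = Σwᵢ(vᵢ−m)² / (Σwᵢ − Σwᵢ²/Σwᵢ)`, effective sample size
  `n_eff = (Σwᵢ)²/Σwᵢ²`, and `SEM = √(s²_w/n_eff)`. With equal durations these
  reduce exactly to the unweighted unbiased variance and SEM. The weighted
  summaries are the default; the unweighted mean is also reported for
  comparison.
* The median is unweighted, as annotated on assay speed histograms. Histogram
  bins default to 0.01 mm/s.
* No trajectory smoothing is applied before the speed computation; a centered
  moving-average smoother is available but off by default, since smoothing
  trades the (zero, in the noiseless model) jitter bias for a systematic
  underestimate on curved paths.

Two-group comparisons use Student's *t* on per-animal speeds (Welch optional).

## Screening decisions

* **Z′-factor** `1 − 3(SD₁+SD₂)/|μ₁−μ₂|` with duration-weighted means and SDs;
  the absolute difference makes it symmetric in group order; equal means raise an
  error. Note that with the default log-normal dispersion (CV 0.42 per animal)
  the simulated reference groups give a *negative* Z′: a per-animal assay window
  this wide is only usable because decisions are made on group means of hundreds
  of animals, not single wells. Z′ > 0.5 would require per-animal CVs below ~8%
  at a 70% separation.
* **Compound score**: ratio of treated to untreated-control duration-weighted
  mean speed, computed against the same-plate vehicle (DMSO) control region —
  the control region is named explicitly in the plate manifest, never guessed.
* **Hit rule**: ratio ≥ positive-control ratio after rounding both to the
  table's printed precision (2 decimals), so "as effective as" includes printed
  ties. On the packaged 38-compound table with the rapamycin control at 1.22
  this yields exactly 12 hits. Controls are excluded from the ranked hit list.
* **Dose series** are tabulated as mean ± SEM per dose with non-decreasing /
  non-increasing trend flags; simulated dose effects use a Hill model on the
  speed multiplier, `f(d) = 1 + (Emax−1)·dⁿ/(dⁿ+EC50ⁿ)`.

## Paired-seed design for recovery experiments

Validation experiments that compare two simulated groups (the 70%-reduction
recovery and effect-multiplier recovery in `scripts/acceptance.py`) use common
random numbers: both populations are generated from the same seed, so they share
their per-animal base draws and differ only by the group effect. This isolates
what the experiment measures — the pipeline's transmission of a known group
effect — from two groups' independent sampling noise (at n = 250 and CV 0.42 an
unpaired ratio carries ≈ 3.7% standard error, which would dominate the signal of
interest). Single-group quantities (median recovery) use independent seeds.
Filtering introduces a small residual bias in paired comparisons — the slower
group loses its slowest animals to the 1 mm displacement gate, raising its mean
slightly — visible as recovered ratios ~1% below the ground-truth multiplier.

## What the simulation does and does not capture

The generator reproduces the statistical structure the pipeline consumes: group
speed differences, per-animal heterogeneity, confinement, track duration weights,
and (optionally) centroid jitter and blob merging in rendered frames. It does not
model worm posture or undulation, speed fluctuations within an animal,
density-dependent interactions, tracker acquisition latency, or pharmacokinetics;
passing tests therefore certify the estimators and decision rules, not the
biology of any particular strain or compound. Real-animal figures from locomotion
studies are not reproducible from simulation and are out of scope.

## Problem sizes and numerics

Simulation-backed tests and the acceptance script use the assay-scale defaults
(600 s at 10 fps) with groups of 200–250 animals, the scale at which group-mean
standard errors are ~3%; rendering-based tests use small fields of view
(tens of mm at 0.05 mm/px, 30–60 s) with one animal per region where the
non-overlap invariant is required. Rendered blobs are soft-edged disks
(~40 px area) whose discretized intensity centroid matches the true position to
< 0.05 px, so round-trip speed errors stay well under the 5% gate. Frame sizes
are capped at 64 Mpx to guard against absurd pixel-size configurations. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds give
bit-identical trajectories.
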