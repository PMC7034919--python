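# Methods

This note documents the model, the synthetic worlds, the parameter
choices and the numerical decisions behind `oppnav`, in the spirit of a
model-description section. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Views and the familiarity read-out

The agent's visual input is a single-channel luminance panorama sampled
at 5°/pixel in azimuth (72 columns) and, by default, 5°/pixel vertically
over the above-horizon span 0–60° (12 rows). Below-horizon content is
never rendered: low-resolution panoramic homing information is carried
by the skyline and the contrast of terrestrial structures against the
sky, and cropping the ground keeps the view free of floor texture the
renderer does not model. The sky is uniform at luminance 1.0 and all
terrestrial content is darker, mimicking the strong sky/terrain contrast
of the blue/UV channel insects rely on. Column 0 of a view looks along
the agent's heading; columns advance clockwise in the visual field, so a
whole-pixel rotation of the agent is exactly a circular column shift —
a property the mapping module exploits and the tests assert bit-exactly.

Mismatch between two same-geometry views is the global root-mean-square
pixel difference, computed at the stored facing directions only (no
rotational alignment anywhere in the model: heading sensitivity is the
point). Familiarity against a bank is `1 − clip(min-mismatch / ν, 0, 1)`.

**Normalisation `ν`.** The mapping of RMS mismatch into [0, 1] is a free
choice. The default is the theoretical maximum RMS for unit-range
luminance (`ν = 1.0`): world-independent, deterministic, and it keeps
familiarity values comparable across worlds. An empirical mode
(`normalization_mode="empirical"`) instead uses the largest mismatch
observed among the calibration views; it stretches the familiarity scale
per world but couples it to the calibration sample. Only the relative
structure of familiarity matters to the opponent agent (the subtraction
removes common offsets), so this choice mostly rescales the gain axis of
the parameter sweeps.

**Average world familiarity.** The attractive-only drive needs a
centring constant. It is estimated by rendering 32 views at seeded
uniform-random in-bounds positions and headings and averaging the
familiarity over all C(32, 2) = 496 unordered pairs — every sample is
used and the estimate is deterministic given the seed.

## Memory banks

The attractive bank holds 25 nest-facing views sampled along an
Archimedean spiral around the nest (radius growing uniformly to a 2 m
span over 2 turns — spiral turn count and starting radius are not
biologically constrained; 2 turns gives even areal coverage and every
facing direction twice) plus nest-facing views every 0.5 m along a
straight 10 m foraging route (20 views; the spacing is a choice — dense
regular sampling along a habitual route). The repulsive bank holds the
25 anti-nest-facing views at the same spiral positions. Outbound-facing
route views can be appended to the repulsive bank with a flag, but no
experiment here requires them and the default excludes them.

Manipulations used by the robustness conditions: independent uniform
orientation noise on each stored facing (±90° in the noisy-learning
condition); a decoupled mode that acquires the repulsive views on a
second spiral at an independently drawn phase (position sets disjoint);
reduced view counts; reduced spans.

## The oscillatory walker

State is position, heading and an oscillator sign that flips every step
no matter what the agent sees. Per step: render the view, read the
drive (opponent subtraction or centred attractive-only), turn by
`clip(baseline − gain × drive, 0°, 180°)` in the oscillator's direction,
add heading noise, and advance one step of 0.2 m. Parameters, with
units and defaults:

| parameter   | unit                | default  | meaning |
|-------------|---------------------|----------|---------|
| baseline    | degrees             | 90       | turn amplitude at zero drive |
| gain        | degrees per unit familiarity | 1250 | drive-to-turn conversion |
| step_length | metres              | 0.2      | forward step |
| noise       | degrees             | Gaussian σ = 10 | heading noise after the turn |
| max_steps   | —                   | 120 (paths) / 320 (sweeps) | run length |

Numerical decisions:

- **Infinite gain** is a first-class value: turns are 0° for positive
  drive and 180° for negative; exactly zero drive falls back to the
  baseline (continuity with the finite-gain limit at drive = 0).
- **Noise placement**: the heading noise is added after the clipped
  turn, reading the update rule literally; it never changes the
  oscillator sign. A run can select Gaussian, uniform or no noise.
- **Initial conditions**: the initial heading is drawn uniformly unless
  given; the initial oscillator sign is randomised per run (alternation
  makes it asymptotically irrelevant, so it is not a parameter).
- **Bounds**: a step that leaves the square world truncates the run with
  status `out_of_world`; arrival distance is measured at truncation.
  Truncating (rather than reflecting or wrapping) keeps arrival-distance
  statistics honest.
- The default operating point (gain 1250, baseline 90) sits on the
  robust plateau identified by the opponent parameter sweep — the sweep
  is the calibration instrument, mirroring how the operating points of
  the original protocol were obtained.

## Synthetic worlds

The package replaces scanned-habitat meshes with procedural scenes
rendered by a column-wise occlusion painter over opaque vertical
cylinders plus a 360° distant skyline profile: for each azimuth column
the nearest object subtending it (else the skyline) paints the column up
to its angular top with its luminance; everything above is sky. Object
angular half-width uses `atan(radius / distance)` and top elevation
`atan((height − eye height) / distance)` with the eye 2 cm above ground.
Rendering is deterministic, dependency-free and exactly testable
(rotation equivariance, closed-form angular sizes, monotone occlusion).

Two archetypes emulate the two habitat types studied:

- **`open_distant`** (default, 64 × 64 m): a ring of large trees
  (radius 1.5–3.5 m, height 15–30 m) at 15–30 m from the nest carrying
  most of the visual mass, a few mid-field trees, and a smooth non-flat
  distant skyline (low-order harmonics, a few degrees of elevation).
  The far-dominated composition is deliberate: the image-difference
  function then falls smoothly over ~10 m of translation, which is what
  gives open natural habitats their large visual catchment areas. With
  near-field-dominated scenes the mismatch saturates within a couple of
  metres and single-view familiarity carries almost no spatial
  information — an instructive failure mode, but not the habitat being
  emulated. Objects keep clear of the nest/learning-walk area and of a
  walkable corridor east of the nest where the default foraging route
  runs (routes follow walkable ground; an object sitting on the route
  would put memorised views inside it).
- **`cluttered_local`** (20 × 20 m): 200 small objects (radius
  0.05–0.3 m, height 0.2–1.2 m) densely scattered around the nest and a
  perfectly flat, featureless horizon — guidance information comes only
  from nearby clutter, and views change rapidly with displacement.

What the generator does *not* emulate: ground texture and below-horizon
structure, object transparency/canopy structure, lighting and shadows,
and the metric irregularity of real vegetation. Tests passing on these
worlds show that the opponent-memory mechanism extracts directional
information from heading-locked panoramic matching whenever the scene
provides smooth parallax — they do not certify performance on real
habitat imagery.

## Familiarity landscapes and their statistics

The mapping module samples familiarity for both banks on a square
lattice (default 30 × 30 m every 0.5 m = 3600 positions) over a uniform
heading grid (default every 5° = 72 headings), using the render-once,
shift-per-heading fast path whenever the heading step is a multiple of
the azimuth resolution. Derived statistics:

- **Best-direction field**: per-position argmax heading (ties to the
  lowest heading) and directional specificity = max − median familiarity
  over headings, clipped to [0, 0.5] for reporting (clipping, not
  rescaling, read from the original figure convention).
- **Single-heading maps and transects**: the per-position value at one
  fixed heading; "north" maps to +y, and any fixed heading is accepted.
- **Angular-error statistics**: Spearman rank correlations of the
  single-heading values against (a) the angular distance between the
  fixed heading and the per-position nest bearing and (b) the Euclidean
  nest distance, for both read-out modes. Rank correlation is used
  because familiarity saturates nonlinearly; constant inputs are
  reported as correlation 0 with a degenerate flag.

## Experiment protocols and problem sizes

Parameter sweeps evaluate a (gain × baseline) grid — default six
log-spaced gains {0, 10, 50, 250, 1250, ∞} × six baselines
{0…180°} — by the median arrival distance of M = 10 agents released
every 36° around the nest (random initial headings, 320 steps = 64 m of
travel). The median, not the mean, scores a cell, so a few lost agents
do not mask a working parameter set. Per-run seeds derive from the
sweep seed via `SeedSequence`, making sweep matrices bit-reproducible.

Robustness conditions follow a boxplot protocol: 3 nest placements
(independent worlds) × 100 releases at 5 m, each run walking a 30 m
travel budget. Fixing the budget in metres (not steps) keeps conditions
with shorter steps comparable: the 10 cm-learning-walk condition walks
0.05 m steps — four times shorter, four times as many. The
`unfamiliar_release` condition releases agents around a fictive nest in
unvisited terrain, where both banks are uninformative and the drive
hovers near zero. The success criterion "arrival within 1 m" is
inclusive (≤); the boundary case has measure zero.

The default test and acceptance problem sizes are scaled-down versions
of the full protocols chosen to keep the whole suite at a few minutes on
one CPU: the landscape statistics use a 20 × 20 lattice (30 m extent at
1.5 m spacing — the full spatial range is retained because the distance
correlation needs it) with 36 headings; sweeps use the 6 × 6 grid above;
condition smoke tests use 1 nest × a handful of releases. The full
3600-position map and 300-run condition protocol run through the same
code paths via configuration.

## Known limitations

- Cylinders cannot occlude each other partially in elevation: the
  nearest object owns its whole column (a documented renderer
  simplification; with the sparse scenes used here, double occlusions
  are rare).
- A position inside an object's footprint sees that object everywhere
  (a degenerate all-dark view); world generation keeps memorised views
  out of objects, but a walking agent may briefly pass through one.
- Memory banks are constructed, not learned — no plasticity, no
  mushroom-body circuit; the opponent integration is a literal
  subtraction of two scalar familiarities.
- The attractive-only mode's centring constant is world-global; a
  per-region constant would change where (not whether) that mode's
  tuning problem appears.
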