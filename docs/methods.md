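# Methods

## The simulated system

`cmscreen.simulate` generates the data a nuclei-count proliferation
screen produces: wells of immature cardiomyocyte-like cells whose nuclei
are imaged every 12 h for up to a week after compound addition. Time 0 is
the first image after small molecules are added. The simulated arena is a
rectangular sub-region of a well (the imaged field); densities are always
cells per mm² of that arena, so plating densities carry over directly.

### Cell dynamics

At each 12-h step, every live **mononucleated** cell divides with
probability

```
p(d) = p_max                          d ≤ d_lo
     = linear ramp                    d_lo < d < d_hi
     = p_confluent                    d ≥ d_hi
```

where `d` is the current live-cell density of the well. The piecewise-
linear ramp with saturation is the minimal shape consistent with an
inverse density–proliferation relationship that plateaus at low density;
the knots default to `d_lo = 136` and `d_hi = 544` cells/mm², the
measured extent of the density-responsive range in hiCMs. A division
resolves as **binucleation** with probability `beta` (the cell gains a
second nucleus; hypertrophic outcome) and otherwise as **cytokinesis**
(a daughter cell appears near the parent; hyperplastic outcome). Either
way the well gains exactly one nucleus per division. Binucleated cells do
not re-enter mitosis — a deliberate simplification; there is no good
quantitative basis for a re-entry rate.

Compounds act through a `DrugEffect`: a multiplicative factor on the
division probability (clipped to [0, 1]) and a per-step death hazard
applied to every live cell at steps ending after `death_onset_h`. A
negative onset kills cells between compound addition and the first image,
producing day-0 deaths. Within a step, deaths are drawn before divisions,
and daughters born at a step's end are not at risk within it.

Ground-truth counts are total nuclei over live cells
(mononucleated + 2 × binucleated), recorded at every imaging time.

### Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| `p_max` | 0.05 / 12 h | hiCMs have a *slight* proliferative capacity; this yields a ~15–20% 72-h count increase at low density |
| `p_confluent` | 0.0 | mitotic events are rare at confluence |
| `d_lo`, `d_hi` | 136, 544 cells/mm² | measured density-responsive range |
| `beta` | 0.15 | standing binucleation proportion of the simulated populations |
| `initial_binucleated_fraction` | = `beta` | plated populations arrive pre-binucleated at the same proportion, making the standing proportion density-independent by construction |
| `interval_h`, `n_timepoints` | 12 h, 13 | every 12 h for six days |
| death-call `collapse_fraction`, `persistence` | 0.2, 2 points | a well below 20% of its initial count for a day is dead, not pausing |

Absolute proliferation rates are not published numerically for this
system, so `p_max`/`p_confluent` are this package's own realistic
defaults, not claims about any measured dataset.

The analysis window defaults to 0–72 h even though simulation continues
longer; fold changes over other windows are available via the `window`
argument / config.

### Imaging model

Nuclei render as 2-D Gaussian spots (σ = nucleus radius / 2, default
radius 5 µm, amplitude 300) on an additive Poisson background (mean 10),
at 2 µm/pixel by default, cut into an overlapping tile grid exactly as a
stage-scanned well is. Cell centers are placed with a hard-core exclusion
(16 µm) because cells have bodies; a binucleated cell's two nuclei sit
12 µm apart along a random axis. Boundary images are Voronoi tessellations
clipped to a 12-µm cell disk — an idealized junctional (β-catenin-like)
stain. Optionally, nuclei of dead cells persist as dim "debris" spots,
reproducing the fluorescent debris that makes counts of dead wells
unreliable and death calling necessary.

Not modelled: point-spread functions, uneven illumination, cell
migration, beating-motion blur, nucleus shape variation. Consequently,
passing segmentation tests here shows the pipeline logic is correct on
well-behaved data; it does not certify performance on real microscopy,
where focus drift and clumping dominate error.

### Seeding

All randomness flows from one `numpy.random.SeedSequence`. Per-well
streams use `SeedSequence(master, spawn_key=(screen, row, col))`, so
simulating more wells or screens never changes wells already simulated,
and identical (config, seed) is bit-identical everywhere, images
included.

## Quantification

Tiles are stitched purely by known grid position (no registration);
overlap strips are averaged. Segmentation is Gaussian smoothing (default
1 µm) → global threshold → connected components → declumping → area
filter, with detections in physical units. Numerical choices that matter:

* **Threshold floor.** Global Otsu fails catastrophically on images with
  no nuclei (dead wells): it splits the background noise. The Otsu
  threshold is therefore floored at median + 5 × 1.4826 × MAD of the
  smoothed image, a robust upper bound on background. A fixed threshold
  is available in config.
* **Declumping.** A component is split only when its area exceeds
  1.5 × the median component area (preventing shattering of single
  nuclei). Splitting is watershed seeded at local maxima of the smoothed
  *intensity*, not of the distance transform — intensity maxima stay
  separable down to about twice the effective spot σ, whereas the
  distance transform of two fused disks is unimodal well above that.
  `split_min_distance_um` (default 8 µm) is the closest nucleus-center
  separation the splitter is asked to resolve; the seed-exclusion radius
  is set just under half of it so that pairs at 0.8 × the split distance
  still yield two seeds after pixel discretization.
* **Edge handling.** Edge-touching detections are kept by default (a
  whole-well stitched field is almost entirely interior; discarding
  would bias counts low); configurable.
* **Binucleation scoring** assigns each detected centroid to the
  boundary-image label under it; centroids on background are reported
  unassigned. The proportion is cells with ≥ 2 nuclei over assigned
  cells.
* **Marker scoring** samples the marker channel in a disk of the
  detection's equivalent radius; the positivity threshold is a fixed
  config value, not adaptive.

## Analytics

Raw fold change is terminal/initial count over the window; normalized
fold change divides by the plate's control-well mean raw fold change —
the unique simple form with the three defining anchor values (control-like
→ 1, dead → 0, doubling vs control → 2). Normalization is per plate per
screen; replicate screens are independent experiments with their own
controls. Control wells therefore average exactly 1 on every plate, to
floating-point tolerance.

Aggregation excludes dead wells from compound means (debris-contaminated
counts) and records the exclusion; SEM uses n−1 degrees of freedom and is
undefined below two screens. Hit ranking filters strictly mean > 1 and
sorts ascending by SEM with deterministic tie-breaks (descending mean,
then compound id); compounds lacking a SEM sort last.

Death calling: collapse below `collapse_fraction × N(0)` sustained for
`persistence` points. A below-threshold run that reaches the end of the
series counts as death even if shorter than `persistence` — otherwise a
death at the final timepoint could never be called. Day bins are
`ceil(first-crossing hour / 24)` with crossings at or before the first
image as day 0, so a first crossing observed at 12 h or 24 h is day 1.

Dose–response output is a mean ± SEM table per concentration, ascending;
no EC50/4PL fitting is attempted, and no hypothesis-testing machinery is
included — ranking is by mean and SEM only.

## Problem sizes

Tests and built-in checks run on arenas of 0.59–1.56 mm² (one to four
320-px tiles at 2 µm/px), i.e. roughly 200–850 cells per well at
screening densities, with 50 wells per density for segmentation checks
and 200 wells per density for density-monotonicity estimates; the
5000-cell binucleation check uses a 17.8-mm² arena. These sizes keep the
Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

* Well-level (not local) density drives division; spatial clustering has
  no growth consequence.
* Binucleated cells never divide, and no endoreduplication/polyploidy
  beyond two nuclei is modelled.
* The boundary stain is ideal: real junctional stains produce broken
  boundaries and segmentation errors that this pipeline never sees.
* Death is a step-hazard process; gradual decline phenotypes ("spindly",
  elongated, enlarged, stress-fiber) are representable only as free-form
  annotation tags on summaries, not simulated or auto-detected.
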