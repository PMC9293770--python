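# Methods

This note records the models, estimators and numerical choices behind
`phagotrack`, in the order the pipeline applies them.

## Simulation model

Cargo motion is a continuous-time two-state Markov process.  In the
**directed** (motor-bound) state the bead advances at a constant per-run
speed along a fixed transport axis; the sojourn ends at rate `k_off`
(1/s).  In the **diffusive** state increments are Brownian with
diffusion constant `D_diff` (nm²/s); the sojourn ends at rate `k_on`.
Sojourn durations are drawn as continuous-time exponentials and recorded
as ground truth; state changes take effect at the next frame boundary,
an approximation that is benign because the 50 ms frame interval is
short relative to the sojourns of interest (≥ seconds).

Per-run speeds are drawn from a normal distribution truncated to
[50, 1500] nm/s — the range observed for bead-phagosomes — without
asserting any finer distributional shape.  Each new run keeps or
reverses the sign of the transport axis with probability `p_reverse`;
no microtubule-polarity bookkeeping is attempted, matching how the
experimental analysis treats bidirectional tracks.  Observed positions
are the true positions plus i.i.d. Gaussian localization noise of SD
`sigma_loc` per coordinate.

Defaults emulate the experimental recordings: 20 frames/s, 150 s per
bead, 27.6 nm/pixel, `sigma_loc` = 9.8 nm, `D_diff` = 1e4 nm²/s,
speeds 500 ± 200 nm/s (truncated), `k_off` = `k_on` = 0.4/s.  The
switching rates give mean sojourns of 2.5 s, chosen so that state
boundaries are resolvable by the 2.0 s analysis window with margin; at
sojourns equal to the window span, boundary smearing alone costs about
half a window of ambiguity per transition.  `mixed_benchmark_config()`
exposes the classification benchmark (identical but with a fixed
500 nm/s run speed), and `impaired_transport_config()` derives a
transport-defect condition (2× `k_off`, 0.5× `k_on`) from any control.

What the simulator does **not** emulate: speed fluctuations within a
run, cytoplasmic viscoelasticity (subdiffusive intervals with α < 1),
motor tug-of-war pauses inside the motor-bound state, drift, or optics
beyond an isotropic Gaussian spot.  Passing tests therefore demonstrate
that the analysis recovers the parameters of *this* generative model at
realistic noise levels — not that real cytoplasmic data obey it.

## Localization and tracking

Sub-pixel positions come from the intensity-weighted centroid of a
square ROI (halfwidth 12 px by default, sized to cover the rendered
spot) after subtracting the ROI minimum (or a low percentile) and
clamping negatives to zero.  Tracking feeds each frame's result in as
the next frame's guess, gated by `max_step` (default 500 nm per 50 ms
frame, ≈ 10 µm/s — far above biological speeds); a violated gate or a
failed localization terminates the track at the last good frame rather
than interpolating.  On synthetic stacks at default intensity/noise the
per-axis localization error is a few nm and whole-trajectory RMS error
is well under 15 nm; sub-nanometer precision is deliberately not part of
the contract, since it depends on optical settings the renderer does not
model.

## Sliding-window MSD classification

Each track is scanned with a 40-frame (2.0 s) window at stride 1.  Per
window the time-averaged MSD over all displacement pairs is computed at
lags 1..10 frames (one quarter of the window — the usual bias–variance
compromise), and fitted with

    MSD(t) = 4D·t^α + 2σ²

with σ fixed at 9.8 nm, α constrained to [0, 2.2] and D ≥ 0.  The fit
is linear in the amplitude 4D at fixed α, so the profile residual is
minimized over an α grid (step 0.005) with parabolic refinement; the
single-curve API (`fit_msd`) adds a bounded scalar polish and recovers
exact synthetic curves to better than four significant figures.  The
fit is on the linear MSD scale because the additive 2σ² offset breaks
log-log linearity.  The α ceiling of 2.2 leaves room for super-ballistic
noise excursions without unbounded estimates.

Each frame takes the α of the window centred on it (edge frames take
the nearest window).  The pooled α distribution is fitted by a
two-component Gaussian mixture (maximum likelihood, 10 restarts,
deterministic given the seed).  Because α estimates from 40-frame
windows carry sampling error of order 0.05 or more, a fitted component
narrower than that is not an interpretable motion mode — in practice the
unconstrained ML solution can dedicate a sliver-weight component to the
pile-up of purely ballistic windows at the α ceiling.  When that occurs
the mixture is refit with a shared (tied) variance, which restores the
two-mode decomposition; truly degenerate fits (component weight < 2% or
SD collapse) are rejected with a diagnostic.  On simulated mixed-motion
cohorts the decomposition lands near means 1.0 / 1.84 with a cutoff of
about 1.4 — consistent with the values reported for real bead-phagosome
data.

The cutoff is the point between the component means where the weighted
component densities are equal (the misclassification-minimizing
threshold under the fitted model); if both quadratic roots fall between
the means the smaller is used, and if none does (near-total overlap) the
midpoint of the means is the fallback.  Frames at or above the cutoff
are directed.  Maximal same-state intervals become segments; segments
shorter than 5 frames (configurable) are absorbed into the longer
neighbour to suppress single-window flicker.

`validate_separation` mirrors the experimental sanity check: it samples
up to 1500 segments per class, averages their MSDs, refits the model,
and reports the per-class average α (≈1 for the diffusive class, ≈2 for
the directed class on forced cohorts).

Frame-level accuracy against ground truth on the 63-bead benchmark is
≈ 90%.  The limit is physical: at the benchmark conditions the diffusive
per-frame step SD (√(2DΔt) ≈ 31.6 nm) exceeds the directed per-frame
advance (25 nm), so individual transitions carry no local signature and
are datable only to within a fraction of the 2 s window.

## Run parsing

Directed segments separated by diffusive gaps of ≤ 5 frames (0.25 s,
matching the minimum-run-duration granularity) are stitched into long
directed tracks, gap frames included.  Each stitched track is projected
onto its principal direction (first principal component of the centred
positions; speeds and change points are invariant to rigid rotations),
and the 1-D displacement is segmented into linear pieces by optimal
partitioning: an exact dynamic program with per-segment linear-fit
residual cost and penalty

    penalty = c · σ̂² · log n,   c = 12

per change point, with σ̂ estimated robustly from second differences
(MAD-based; second differences of a piecewise-linear signal plus noise
of SD s are N(0, 6s²) away from change points).  The penalty factor was
calibrated by simulation so that noisy constant-velocity tracks are
parsed as a single piece in ≥ 95% of cases while a 600→100 nm/s velocity
change is localized within ±3 frames; both properties are regression
tests.  The minimum piece length equals the minimum run duration
(6 frames = 0.25 s).

Pieces are classified against the run criteria — net displacement
> 200 nm **and** speed > 50 nm/s **and** duration ≥ 0.25 s for a *run*;
speed < 50 nm/s for a *pause*; the fast-but-short remainder is
*subthreshold*.  Net (not path-integrated) displacement along the
principal axis is used, since microtubule geometry is unknown; speed is
reported as a magnitude with the direction sign retained internally.

## Transport statistics

Percent directed/diffusive motion is time-weighted (classified frames)
per bead, averaged across beads with equal weight; a segment-count
variant would depend on the flicker-absorption parameter, which is why
time weighting is the default.  Run length and velocity are averaged
across runs; the dissociation rate across beads — matching how the
corresponding experimental n values are reported.

The dissociation rate of a bead is run terminations per unit
motor-bound time.  A run terminates when it ends in a pause, a diffusive
interval or another piece; runs cut off by the end of the recording are
censored — excluded from the numerator, their time kept in the
denominator.  Because the run criteria left-truncate the duration
distribution (a run is observable only if it lasts longer than
c = max(0.25 s, 200 nm / speed)), the default estimator is the
maximum-likelihood rate under the exponential-duration model with known
truncation: terminations / Σ(dᵢ − cᵢ), which is unbiased for the
simulator by memorylessness.  The literal terminations-per-total-time
ratio (biased low by roughly c/(c + 1/k_off)) is available via
`truncation_adjusted=False`.  Caveat: for very slow runs cᵢ approaches
dᵢ and per-bead rates become noisy; with broad speed distributions the
across-bead mean can run ~10–25% high.  Cohort comparisons are
unaffected in direction because both groups share the bias.

Group comparisons use Welch (unequal-variance) two-sample t-tests with
the conventional star thresholds (0.05 / 0.01 / 0.001 / 0.0001).  Two
identical groups compare as t = 0, p = 1 even in the degenerate
zero-variance case.

## Pipeline and reproducibility

`analyze_cohort` pools window α values across *all* beads and groups of
an analysis to fit one mixture and one cutoff — mirroring the use of a
single per-condition cutoff applied to both experimental groups — then
labels, stitches, parses and summarizes per bead, and runs the group
comparisons.  Beads shorter than one window are skipped and recorded in
the report's provenance, never silently dropped.  Reports carry the
package version, seed and a configuration hash; identical inputs,
configuration and seed give byte-identical reports.  All randomness in
simulation, mixture restarts and segment sampling flows from the
configured integer seeds.

## Problem sizes

The test suite and acceptance script use cohorts of 100 trajectories
(forced-state α-peak checks), 63 beads (classification benchmark),
50 beads per group (dissociation recovery), and 20 replicates of 16
beads per group at 100 s (end-to-end directionality) — sizes at which
the checked tolerances are several sampling SDs wide while the whole
suite runs in minutes on one core.

## Known limitations

- Two motion states only; no subdiffusive (viscoelastic) third mode, no
  hidden-Markov smoothing, no fBm/CTRW model selection.
- Boundary placement is limited to a fraction of the 2 s window where
  diffusive and directed per-frame displacements overlap (see above);
  frame-level accuracy ≈ 90% at the benchmark conditions is a property
  of the windowed-MSD method, not an implementation shortfall.
- Short diffusive interruptions (≲ 0.25 s) between runs are absorbed by
  segment merging and stitching, so consecutive runs can fuse; measured
  run durations then run slightly long and dissociation rates slightly
  low before truncation adjustment.
- The centroid tracker assumes one particle, no gap closing and no
  drift correction; rendered spots are Gaussian, not a DIC optical
  model.
- Mixture cutoffs are fitted per analysis (pooled across groups), not
  per cell; with strongly imbalanced groups the pooled cutoff shifts
  toward the larger group's α distribution.
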