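# phagotrack

Single-particle tracking and MSD-based motility analysis of phagocytosed
cargo.

## The problem

Inside a macrophage, a phagosome (for example an ingested ~800 nm bead)
alternates between **directed** transport — motor proteins hauling it
along microtubules at 50–1500 nm/s — and **diffusive** motion when the
motors are inactive or detached.  How much time cargo spends in each
mode, how long and fast its processive runs are, and how quickly it
drops out of the motor-bound state (the **dissociation rate**) are the
biophysical fingerprints of its trafficking machinery, and they change
when phagosome maturation is perturbed.

`phagotrack` implements the full analysis chain used to extract those
fingerprints from high-speed video tracking of single beads, plus a
stochastic simulator that generates ground-truth-labeled trajectories so
that every stage of the chain can be validated without any microscope.

## The method

1. **Localization / tracking** (`phagotrack.tracking`): sub-pixel bead
   positions by the background-subtracted intensity-weighted centroid of
   a region of interest, linked frame to frame (default 20 frames/s,
   27.6 nm/pixel).
2. **Motion-state classification** (`phagotrack.msd`): position tracks
   are scanned with a 2.0 s (40-frame) sliding window; each window's
   time-averaged mean-square displacement is fitted with

   ```
   MSD(t) = 4D · t^α + 2σ²,    σ = 9.8 nm (fixed)
   ```

   The scaling exponent α ≈ 1 for diffusion and α ≈ 2 for directed
   (ballistic) motion.  The pooled α distribution is fitted with a
   two-Gaussian mixture; the cutoff separating the modes is placed where
   the weighted component densities are equal, and frames are labeled
   directed (α ≥ cutoff) or diffusive.
3. **Run parsing** (`phagotrack.runs`): consecutive directed segments
   are stitched across short diffusive gaps, projected onto their
   principal direction, and parsed into constant-velocity pieces by
   penalized change-point detection.  Pieces with net displacement
   > 200 nm, speed > 50 nm/s and duration ≥ 0.25 s are **runs**; pieces
   slower than 50 nm/s are **pauses**.
4. **Transport statistics** (`phagotrack.summary`): per group, percent
   directed/diffusive motion (per bead), run length and velocity (per
   run), and the dissociation rate (run terminations per unit
   motor-bound time, per bead), each mean ± SEM, compared across groups
   with Welch two-sample t-tests.
5. **Simulator** (`phagotrack.simulate`): a continuous-time two-state
   Markov switching model (motor-bound ↔ diffusive) with per-run
   constant speeds from a truncated normal on [50, 1500] nm/s, Brownian
   diffusive intervals, and Gaussian localization noise — with every
   sojourn and speed recorded as ground truth.  It can also render
   trajectories into synthetic TIFF stacks to exercise the tracker.

## Worked example

Simulate a control cohort and a cohort with impaired transport (cargo
leaves the motor-bound state twice as fast, rebinds half as fast), then
run the whole pipeline:

```sh
phagotrack simulate --n 12 --seed 7 --out control
python - <<'EOF'
import phagotrack as pt
from phagotrack.simulate import impaired_transport_config
pt.save_config(impaired_transport_config(pt.SimulationConfig(seed=7)),
               "treated.yaml")
EOF
phagotrack simulate --config treated.yaml --n 12 --out treated
phagotrack pipeline --group control control --group treated treated \
    --out report.json
```

which prints

```
control: 12 beads, 310 runs; directed 52.0±2.1%
treated: 12 beads, 235 runs; directed 25.8±1.0%
report written to report.json
```

`report.json` holds the full summary.  For this run the fitted α-mixture
cutoff is 1.40; the treated group shows the impaired-transport
phenotype: percent directed motion 25.8 ± 1.0% versus 52.0 ± 2.1% in
control (Welch p = 3.6e-09, ****), mean run length 741 ± 37 nm versus
1364 ± 81 nm, and dissociation rate 1.01 ± 0.07 /s versus
0.48 ± 0.04 /s — less directed motion, shorter runs, faster motor
dissociation, while run velocities barely change (515 ± 11 versus
527 ± 10 nm/s).

The same stages are available as library calls (`simulate_cohort`,
`fit_windows`, `fit_alpha_distribution`, `label_segments`,
`stitch_directed`, `parse_constant_velocity`, `classify_runs`,
`summarize_group`, `compare_groups`) and as the single entry point
`analyze_cohort`.

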