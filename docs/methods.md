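# Methods

## Run-reverse-flick trajectory model

A swimmer is a point in the 2D imaging plane with a heading angle and a
binary motor state (forward / reverse). Per frame interval `dt = 1/frame_rate`:

1. a switch out of the current state occurs with probability
   `1 − exp(−k·dt)` (`k_fr` forward→reverse, `k_rf` reverse→forward), at most
   one switch per frame;
2. forward→reverse flips the heading by exactly 180° (recorded in the truth
   log as a `reverse` event at that frame interval);
3. reverse→forward applies a flick: a signed turn `±|N(flick_mean, flick_sd²)|`
   with equiprobable sign;
4. the heading then diffuses with variance `d_rot·dt`, and the position
   advances by `speed·dt` along the heading.

Reported positions add i.i.d. Gaussian localization noise `sigma_xy` per
coordinate. Per-cell sub-seeds come from `SeedSequence(seed, spawn_key=(i,))`,
so cohorts are reproducible independent of iteration order.

### Parameters, defaults, rationale

| parameter | default | unit | rationale |
|---|---|---|---|
| `v_fwd`, `v_rev` | 40 | µm/s | typical swarmer-cell swim speed; the source data report none |
| `k_fr`, `k_rf` | 0.15 | 1/s | with equal rates the total event rate is k; 0.15/s matches a smooth-swimming baseline cohort |
| `flick_mean` ± `flick_sd` | 90 ± 20 | deg | flicks re-orient by roughly a right angle; essentially all draws exceed the 45° detection threshold |
| `d_rot` | 30 | deg²/s | mild heading wobble standing in for the helical forward trajectory projected to 2D |
| `sigma_xy` | 0.1 | µm | see below |
| `frame_rate` | 16 | fps | the recording rate of the emulated experiments |
| `duration` | 30 | s | the recording length of the emulated experiments |

**Localization noise.** At 40 µm/s and 16 fps a step is 2.5 µm. Position
noise σ per coordinate propagates into the angular acceleration with standard
deviation `√20·σ/L` (Δθ is a third difference of positions), and consecutive
Δθ are anti-correlated (ρ = −0.75) — exactly the pattern the detector
triggers on. At σ = 0.2 µm the 45° cut is a 2.2σ threshold and noise alone
generates ≈ 0.13 false events/s, overwhelming biological rates; the detector
would be grossly inaccurate, contradicting the validated-accuracy premise of
the criterion on real recordings. The default is therefore σ = 0.1 µm — a
realistic centroid precision for phase-contrast tracking — which puts the cut
at ≈ 4.4σ and makes false triggers negligible (< 10⁻³ per cell per 30 s).
The parameter is config-exposed; users emulating noisier optics should note
the sharp false-positive transition near σ ≈ 0.15 µm at these speeds.

**One switch per frame.** Valid while `k_fr + k_rf ≪ frame_rate`; a warning
is emitted beyond 20% of the frame rate. At high rates the approximation
biases event counts low (switches in the same frame annihilate).

**Smeared reversals.** By default reversals are single-frame flips, matching
recordings where reversals complete in under two frames. A symmetric
two-frame reversal (90° + 90°) produces Δθ products of exactly zero and is
provably invisible to the criterion; a `smeared_reversals` mode generates
such events for robustness testing only.

### What the generator does not emulate

3D excursions and their projection artifacts, hydrodynamic surface
interactions, chemotactic modulation of switching rates, cell-cycle state,
tracker segmentation/linking errors, and frame drops. A green recovery test
therefore establishes that the detector recovers the programmed event
statistics under idealized imaging, not that it is robust to every real-world
tracking artifact.

## Reversal detection and summaries

Velocities `v_i = (r_{i+1} − r_i)/dt`; signed turn angles `θ_i` between
`v_i` and `v_{i+1}` via `atan2` of the 2D cross/dot products
(counter-clockwise positive, range (−180°, +180°], exact antiparallel mapped
to +180° — detection only uses magnitudes and sign *changes*, so results are
convention-independent, as the equivariance tests check). Events require
`Δθ_i·Δθ_{i+1} < 0` and both magnitudes strictly above 45°; ties are
non-events by the strict inequality.

Numerical/design choices:

- **Suppression window (2 frames).** Overlapping triggers within two frames
  of the previous event's large-turn frame are merged (first trigger kept),
  since a physical reversal occupies under two frames.
- **Speed gate (`min_step_speed`, 1 µm/s).** Headings of near-stationary
  steps are undefined rather than noisy; an undefined Δθ never triggers. The
  gate is dimensionful: under uniform spatial scaling of a trajectory the
  gate must scale along for exact equivariance.
- **Run speed.** Mean step speed excluding, per event, the two velocity
  steps that form the large turn; the frequency denominator is the full
  track duration, not time-in-run.
- **Truth-log comparisons.** A programmed switch in the first or last two
  frame intervals lacks the Δθ pair the criterion needs, and two switches in
  adjacent frames merge into one trigger (the middle product is ≥ 0).
  Exact-count recovery statements therefore refer to interior, isolated
  truth events with turn magnitude above threshold; at study scale (30 s,
  rates ≤ 0.45/s) these edge cases cost a few percent, which is why
  cohort-median recovery is the headline check.
- **Cohort histograms.** Left-closed right-open bins, last bin closed
  (numpy convention); default edges 0–1 /s in 0.05 steps for frequency and
  0–80 µm/s in 5 steps for speed (the emulated figures do not state their
  binning). Out-of-range cells are counted as under/overflow and kept in the
  normalization.
- **Cohort comparison.** Welch's unequal-variance t test, two-sided. Zero
  variance in both cohorts is flagged; equal means then give p = 1 by
  convention.

## Binding models and fitting

Models as in the README. Conventions: the association constant never
appears — all models are parameterized directly by `Kd`; ITC `dH` is per
mole of ligand bound (cal/mol), heats in µcal.

- **ITC geometry.** Cell volume `V0 = 1.4 mL` (the VP-ITC instrument class);
  not stated by the emulated experiments, config-exposed, and recovery is
  V0-consistent by construction. Dilution uses the standard per-injection
  factor `f_i = Π(1 − dV_j/V0)` with the mid-point displacement correction
  `ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`; no overfill variant,
  no first-injection discard by default (flag available).
- **Fitting.** Unweighted residuals (constant variance, matching the named
  instrument-software defaults). `Kd` is optimized as `log10 Kd`; bounds:
  Hill `n ∈ [0.3, 4]`, ITC `n_sites ∈ [0.3, 6]`, `Kd > 0` via wide log
  bounds. Multi-start: log-spaced `Kd` grid over `[min(x)/10, max(x)·10]`
  (for ITC, around the cell concentration), crossed with a small grid on the
  shape exponent; at each start the linear-in-parameters block
  (`Bmax/NS/B0`, `F0/F1`, `dH`) is initialized by an exact linear
  least-squares solve, then all parameters are polished by bounded
  Levenberg/TRF iterations (`xtol = ftol = 1e-14`); lowest residual sum of
  squares wins. Standard errors come from the Jacobian at the optimum
  (delta-method transform back from the log-Kd scale). Non-convergence is
  reported in the result, never raised; a flat response raises a degenerate-
  data error. The MST Hill coefficient floats (bounded) rather than being
  fixed at 1 — on noise-free n = 1 data the fit returns n = 1, so the choice
  is testable and conservative.
- **Stoichiometry default.** Synthetic ITC isotherms use `n_sites = 2`,
  consistent with two c-di-GMP molecules bound per protomer; the CleD-GFP
  experiment's own fitted stoichiometry is not published, so only the
  chimera's 2:1 value is treated as a recovery target.

## ARR motif scan

Unit pattern `[YF] X G P [DE] [RK] R`; `X` in the pattern matches anything
and `X` in the subject satisfies any class (recall-maximizing). Unit matches
are found with an overlapping regex; tandem placements are built
leftmost-first and greedily (pair each unconsumed unit with the nearest
following unit at gap ≤ `max_gap`, default 8, then continue after the second
unit), so placements never share a unit and a three-unit array yields one
tandem plus one partial hit. Flanking Arg (N-side) and Asp (C-side) within
`flank_window` (6) residues are annotations by default and requirements in
strict mode. `max_gap = 8` keeps `R + unit + gap + unit + D` within the
~32-residue span of a natural ARR. Positions are reported 1-based inclusive.

## Known limitations

- The literal 45° criterion counts supra-threshold flicks and reversals
  alike; the package does not attempt to distinguish them (nor did the
  emulated analysis).
- The Hill and one-site models share the usual identifiability caveats when
  the design does not bracket `Kd`; the multi-start reports the best local
  optimum found, not a global certificate.
- The ITC model is the single-set-of-identical-sites isotherm; sequential or
  two-site models and ΔG/ΔS decomposition are out of scope.
- The motif scanner reproduces the motif logic only — it is not a profile
  search and will not reproduce a database census.
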