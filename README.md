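# cletools

Quantitative tools for studying how the bacterial second messenger c-di-GMP
tunes the flagellar motor through CheY-like effector (Cle) proteins. The
package bundles the three desk-scale analyses such a study rests on:

1. **Swimming-reversal analysis.** *Caulobacter crescentus* swarmer cells swim
   in a three-step forward / reverse / flick pattern. Given 2D trajectories
   sampled at video rate (16 frames/s), the package detects directional
   changes with the angular-acceleration criterion: with velocity vectors
   `v_i = (r_{i+1} − r_i)/dt`, turn angles `θ_i` between consecutive
   velocities and angular accelerations `Δθ_i = θ_{i+1} − θ_i`, an event is
   called where `Δθ_i · Δθ_{i+1} < 0` with `|Δθ_i|, |Δθ_{i+1}| > 45°`. It
   then summarizes each cell (reversal frequency, mean run speed excluding
   reversal frames) and builds fraction-of-cells cohort distributions. A
   seeded run-reverse-flick simulator with ground-truth event logs stands in
   for raw video data.
2. **Binding-model fitting.** Forward models, synthetic-data generators and
   multi-start nonlinear least-squares fitting for the three equilibrium
   assays used to establish c-di-GMP affinities: saturation binding with a
   nonspecific term (`y = Bmax·x/(Kd + x) + NS·x + B0`), the Hill equation
   (`y = F0 + (F1 − F0)·xⁿ/(Kdⁿ + xⁿ)`), and the ITC single-set-of-sites
   (Wiseman) isotherm with displacement-dilution correction.
3. **ARR motif scanning.** Detection of the tandem arginine-rich-region
   (ARR) c-di-GMP binding motif `[YF]XGP[DE][RK]R` × 2 in protein FASTA
   files, with annotation of the conserved flanking Arg/Asp and candidate
   classification.

## Worked example

```python
import numpy as np
from cletools import motility, reversal, binding

# simulate a wild-type-like and a hyper-reversal cohort (200 cells each)
wt = motility.simulate_cohort(motility.MotilityParams(k_fr=0.15, k_rf=0.15), 200, seed=1)
hyper = motility.simulate_cohort(motility.MotilityParams(k_fr=0.45, k_rf=0.45), 200, seed=2)
sw = [reversal.analyze_trajectory(t)[0] for t in wt]
sh = [reversal.analyze_trajectory(t)[0] for t in hyper]
print(reversal.summarize_cohort(sw, "reversal_frequency").median)  # 0.133 /s
print(reversal.summarize_cohort(sh, "reversal_frequency").median)  # 0.400 /s
print(reversal.compare_cohorts(sw, sh, "reversal_frequency").p_value)  # 1.4e-91

# fit a noisy MST dilution series with the Hill model
x = binding.dilution_series(500.0)                     # 16-point 1:1 series, µM
curve = binding.simulate_curve("hill", binding.HillParams(0, 1, 14.8, 1.0),
                               x, noise_sd=0.02, seed=5, unit="uM")
fit = binding.fit_model(curve)
print(fit["Kd"], fit.stderr["Kd"], fit["n"])           # 14.02 ± 1.11 µM, n = 0.97
```

The detected cohort medians (0.133 and 0.400 events/s) recover the programmed
switching rates of 0.15 and 0.45 /s up to the finite 30 s recording (a cell's
event count is Poisson-like, so the per-cell frequency is quantized in steps
of 1/30 /s), and the Welch test cleanly separates the two phenotypes. The
noisy Hill fit recovers the true midpoint (14.8 µM) within its reported
standard error.

A command-line interface mirrors the library:

```bash
cletools simulate --n-cells 100 --seed 1 --out sim/
cletools analyze --in sim/trajectories.csv --out summaries.tsv --events events.tsv
cletools cohort --in summaries.tsv --variable reversal_frequency --out dist.tsv
cletools simulate-binding --model hill --params hill.yaml --noise-sd 0.02 --seed 1 --out curve.csv
cletools fit-binding --model hill --in curve.csv --out fit.json
cletools scan-arr --in proteome.fasta --out hits.tsv --classify candidates.tsv
```

## Acceptance script

`scripts/acceptance.py` regenerates, from scratch, the seven headline
binding-recovery numbers: for each published dissociation constant (UV
crosslink, two ITC experiments, three MST curves) and the ITC stoichiometry,
it synthesizes noise-free data from the package's own forward model at the
published assay geometry, re-fits from a seed-perturbed multi-start grid,
and writes the recovered constants as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/cletools/motility.py` — run-reverse-flick trajectory simulator
- `src/cletools/trajectory_io.py` — trajectory CSV dialect, filtering
- `src/cletools/reversal.py` — detector, per-cell and cohort statistics
- `src/cletools/binding.py` — binding models, simulation, fitting
- `src/cletools/motif.py` — ARR tandem-motif scanner
- `src/cletools/cli.py` — `cletools` command-line entry point
- `docs/methods.md` — models, assumptions, numerical choices, limitations
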