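# condensate-proximity

Quantitative analysis of **client proximity enhancement inside biomolecular
condensates** (liquid–liquid phase-separated droplets), for biophysicists and
cell biologists quantifying scaffold–client systems by fluorescence
microscopy.

When a client protein is recruited into a condensate, its apparent
concentration rises only a few fold (the partition coefficient), yet
proximity-dependent reporter signals — split-FP complementation, tetramerizing
photoswitchable probes — can rise far more. This package implements the
analysis chain that turns those observations into numbers:

* **Image statistics** — puncta segmentation (8-connected components above a
  threshold, area strictly > 0.01 µm²), the condensate-formation ratio,
  partition coefficients (mean inside/outside intensity), and channel signal
  ratios.
* **FRAP kinetics** — ratio normalization (ROB/TOT, 1 pre-bleach / 0 at
  bleach) and the first-order recovery fit *f(t) = A(1 − e^(−t/τ))* with
  mobile fraction *A* and half-life *t*₁/₂ = ln 2·τ.
* **Calibrations** — a monotone superlinear reporter curve *I(c)* (isotonic
  regression + shape-preserving interpolation) and linear dye calibrations
  with flagged extrapolation for absolute concentrations.
* **The two-state occupancy model** — the core. Clients are assumed to occupy
  a fraction *f*_occupy = *V*_occupy/*V*_total of the droplet volume, so

      c_actual   = c_occupy · f_occupy
      I_observed = I(c_occupy) · f_occupy

  Given a droplet's dye-measured global concentration *c*_actual, its
  reporter signal *I*_observed and the calibration *I(·)*, these are solved
  numerically (bracketed root finding; the objective is monotone for
  superlinear *I*) for *f*_occupy. The **overall proximity enhancement
  factor** is 1/*f*_occupy, and the **effective client–scaffold binding free
  energy** is ε = *k*_B*T*·ln *f*_occupy (≈ −1.65 kcal/mol for 16-fold
  enhancement at 300 K). For a power-law reporter *I* ∝ *c*ⁿ the closed form
  1/*f* = (*I*_obs/*I*_exp)^(1/(n−1)) serves as an independent oracle.
* **Synthetic data** — every input (droplet images with truth masks, FRAP
  traces, calibration tables, measurement tables generated exactly under the
  occupancy model) can be simulated with known ground truth, so the whole
  chain is testable without any raw data.

## Worked example

```python
from condensate_proximity import (
    DropletMeasurement, observed_over_expected, power_law_curve, solve_occupancy,
)

# one droplet: 4.87 uM client inside (from the dye channel), reporter reads
# 15,582 a.u. where the calibration expects 818 a.u. at 4.87 uM
curve = power_law_curve(818.0 / 4.87**2, 2.0)      # quadratic surrogate I(c)
m = DropletMeasurement(c_actual=4.87, i_observed=15582.0)

print(observed_over_expected(m, curve))             # 19.048899755501225
sol = solve_occupancy(m, curve, temperature_K=300.0)
print(sol.enhancement)                              # 19.048899755503143
print(sol.c_occupy)                                 # 92.7681418093003
print(sol.epsilon_kcal_mol)                         # -1.756892856084667
```

The droplet's reporter signal is 19× what its global client concentration
predicts: clients behave as if confined to ~1/19 of the droplet volume at an
effective ~93 µM, equivalent to ~1.76 kcal/mol of client–scaffold binding at
300 K.

The `examples/` directory holds one short script per capability (image
statistics, FRAP, calibrations, the occupancy model, and the end-to-end
pipeline); each prints its results with a note on what they mean. A thin CLI
(`proximity simulate|quantify|frap|solve|run`) wraps the same functions.

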