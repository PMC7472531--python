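# adcresponse

Modelling tumor growth and response to a pulse-dosed antibody-drug conjugate
(ADC) when the tumor contains subpopulations with different drug
sensitivity and only part of the tumor is reached by the drug.

The package is aimed at quantitative pharmacologists and mathematical
oncologists working with xenograft efficacy studies read out by
bioluminescence imaging (BLI), where flux (photons/s) is proportional to
viable cell number. Its motivating setting is glioblastoma patient-derived
xenografts implanted either in the flank (no blood-brain barrier, full drug
exposure) or intracranially (exposure limited by the barrier), with weekly
ADC boluses.

## The model

Two cell populations — high-sensitivity H and low-sensitivity L — grow
exponentially at net rate ρ (day⁻¹) and are killed in proportion to the
drug mass A (mg), the exposed fraction γ ∈ [0, 1], and kill rates
μ_H ≥ μ_L = z·μ_H (mg⁻¹day⁻¹, relative sensitivity z ∈ [0, 1]):

    dH/dt = ρH − γ μ_H A H
    dL/dt = ρL − γ z μ_H A L
    dA/dt = Σₙ A_dose(n) δ(t − tₙ) − λA

Boluses of A_dose = 0.1 mg (5 mg/kg at 20 g body weight) land every 7 days
and decay at λ = ln 2 / 7 day⁻¹ (7-day half-life). Because the kill terms
are linear in A, the system has a closed form in the cumulative exposure
E(t) = ∫₀ᵗ A ds = Σₙ (A_dose(n)/λ)(1 − e^{−λ(t−tₙ)}):

    H(t) = (1−q) C₀ e^{ρt − γ μ_H E(t)},   L(t) = q C₀ e^{ρt − γ z μ_H E(t)}

with q = L₀/C₀ the initially low-sensitive fraction and C = H + L the
observable total. On top of the forward model the package provides

- **staged calibration** (`run_pipeline`): per-subject bounded least squares
  in three steps — untreated fits give ρ per site; treated flank fits
  (γ = 1) give μ_H, z, q; treated intracranial fits, with the pooled flank
  μ_H passed in, give γ, z, q. Within one site only the product γ·μ_H is
  identifiable; the two-site design resolves the confound;
- **global sensitivity analysis** (`lhs_sample`, `prcc_over_time`): Latin
  hypercube parameter ensembles and time-resolved partial rank correlation
  coefficients against total burden and the low-sensitivity fraction L/C;
- **simulation experiments** (`run_heatmap`, `run_recovery_study`): the
  γ × z burden grid at fixed μ_H, and replicate-cohort recovery scoring of
  the calibration pipeline;
- **synthetic cohorts** (`simulate_cohort`): PDX-like BLI series with
  between-subject parameter variability and multiplicative lognormal noise,
  plus CSV round-trip I/O.

## Worked example

```python
import numpy as np
from adcresponse import (ModelParams, weekly_schedule, analytic_trajectory,
                         CohortDesign, simulate_cohort, run_pipeline)

sched = weekly_schedule(n_doses=12)          # 0.1 mg every 7 days from day 7
p = ModelParams(rho=0.3, mu_H=5.0, z=0.3, q=1e-3, gamma=1.0, C0=1e4)
print(analytic_trajectory(p, sched, np.arange(0., 85., 7.)).to_frame().round(3).head(6))
```

```
 day         H        L     A         C  frac_low
 0.0  9990.000   10.000 0.000 10000.000     0.001
 7.0 81580.037   81.662 0.100 81661.699     0.001
14.0 53349.696  312.677 0.150 53662.372     0.006
21.0  9872.902  819.790 0.175 10692.691     0.077
28.0   971.941 1778.582 0.188  2750.524     0.647
35.0    69.787 3510.167 0.194  3579.954     0.981
```

The treated tumor shrinks while the sensitive population H is killed, then
regrows from the resistant clone: by day 35 the low-sensitivity fraction has
risen from 0.001 to 0.98. Calibrating a noisy synthetic cohort (4 controls
and 5 treated per site, σ = 0.2 on log₁₀ flux):

```python
design = CohortDesign(noise_sigma_log=0.2, seed=1)
series, truth = simulate_cohort(design, schedule=sched)
calib = run_pipeline(series, sched)
print(f"{calib.rho_flank_mean:.4f} {calib.rho_ic_mean:.4f} {calib.mu_H_mean:.4f}")
```

prints `0.2790 0.4433 3.8786`: the pooled flank growth rate 0.279 day⁻¹
sits next to the generating per-subject truths (0.277, 0.263, 0.313,
0.268), and the pooled kill rate lands inside its generating range. Each
per-subject fit is a results object with estimates, bounds, the residual
norm and a multistart convergence diagnostic (`result.summary()`).

The same workflow is available from the shell:

```sh
adcresponse simulate --seed 1 --out runs/sim
adcresponse fit --cohort runs/sim/cohort.csv --out runs/fit
adcresponse sensitivity --seed 1 --out runs/sens
adcresponse heatmap --out runs/heat
adcresponse recover --seed 1 --out runs/recover
```

Every command takes a flat `key = value` config file (`--config`), writes
its numbers as CSV next to any figures, and records seed, config hash and
library versions in `run_info.txt`.

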