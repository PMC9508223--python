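# celltraffic

Whole-body cell-trafficking kinetics and the practical identifiability of
its parameters.

Physiologically-based pharmacokinetic (PBPK) compartment models are the
standard way to describe where a transferred cell population (for example
radiolabelled lymphocytes, or CAR T-cells) goes in the body: a central
blood pool feeds each organ's vascular space, cells extravasate into the
interstitium and return via the lymphatics. These models fit localisation
data beautifully — and that is exactly the problem. Many different
parameter sets produce near-identical curves, so a "good fit" says little
about whether the fitted rate constants are right. `celltraffic` is for
modellers and pharmacometricians who want to *measure* that gap: it
implements the trafficking model, generates synthetic data with realistic
multiplicative noise from known ground truth, and provides the whole
ladder of recovery instruments — analytic estimators, organ-wise and
basin-hopping least squares with the (deliberately misleading) local
covariance, per-parameter sensitivity and timescale diagnostics, and
multi-chain adaptive-covariance MCMC with Gelman–Rubin convergence.

## The model

For each organ *o* with vascular volume `V_o`, interstitial volume `Ṽ_o`
and blood flow `B_o`:

    V_o  dC_o/dt = B_o (C_h − C_o)
    Ṽ_o dC̃_o/dt = e_o B_o (C_o − μ_o C̃_o)

with `C_h` the blood-pool concentration, `e_o` the extravasation
probability and `e_o μ_o B_o C̃_o` the lymphatic return flux. The spleen,
stomach and small intestine drain venously into the liver (portal
system), lymph passes through the lymph-node interstitium, and the
pulmonary circuit carries the full cardiac output. The system is linear
and closed; total cell number is conserved exactly.

Two cheap identifiability indicators come with the model. Each organ has
equilibrium timescales

    τ_e = V_tot / (e_o B′_o)        τ_μ = Ṽ_o / (e_o μ_o B′_o)

(`B′_o` the effective organ flow): a parameter whose timescale falls
before the first or after the last data point cannot move the model
inside the observation window and will not be recovered from data. A 1%
local sensitivity matrix (parameters × data curves) tells a similar story
locally. The global instrument is MCMC: three adaptive-covariance chains
run in 5000-iteration cycles until the Gelman–Rubin `R̂ ≤ 1.1`, and the
last-cycle posterior densities separate identifiable (peaked) from
unidentifiable (diffuse or multimodal) parameters.

## Worked example

Generate noisy synthetic data from a documented ground truth, fit without
using the truth, and compare:

```python
import numpy as np
from celltraffic import (build_system, default_truth, make_dataset,
                         add_noise, NoiseConfig, timescale_table,
                         recovery_report)
from celltraffic.estimates import estimate_initial
from celltraffic.fitting import FitOptions, fit_organwise, fit_global, score

system = build_system()                      # 8-organ rat physiology
truth = default_truth(system, seed=0)        # documented, seeded truth
data = add_noise(make_dataset(system, truth), NoiseConfig(sigma=0.1, seed=42))

init = estimate_initial(data, system)        # analytic seeds
fit = fit_organwise(system, data, init=init, options=FitOptions(max_sweeps=10))
fit = fit_global(system, data, init=fit.params,
                 options=FitOptions(hops=2, seed=0))

print("fitted score :", round(fit.total_score, 4))
print("truth score  :", round(score(system, truth, data)[0], 4))
report = recovery_report(fit.params, truth, timescale_table(system, truth))
print(report.head(6).round(3))
print(report.attrs["summary"])
```

prints

```
fitted score : 0.0117
truth score  : 0.0129
    parameter  fitted  truth  ratio    timescale_flag
mu_LymphNodes   0.001  0.362  0.002     inside_window
 e_LymphNodes   0.002  0.026  0.067  above_last_datum
    mu_LungBS   0.143  0.014  9.991  above_last_datum
     e_LungBS   0.057  0.007  7.876  above_last_datum
     e_LungPC   0.930  0.550  1.691 below_first_datum
      mu_Skin   0.044  0.040  1.095  above_last_datum
{'within_5pct': 5, 'within_10pct': 11, 'within_50pct': 11, 'total': 16}
```

The fit is *better* than the truth scores on this noisy data
(0.0117 < 0.0129) — by the only metric a curve-fitter sees, it is a
perfect fit. Yet the worst-recovered parameters are off by factors of
10–500, and almost all of them are exactly the ones the timescale table
flags as lying outside the 0.5–24 h data window. On noise-free data the
same pipeline recovers every in-window parameter to within 5% and drives
the score below 1e-4; one standard deviation of multiplicative noise at
σ = 0.1 is enough to destroy practical identifiability while leaving the
fit visually immaculate.

## Command line

The numbered experiments (dense/sparse/noisy/censored/reduced-system/
fixed-e recovery studies and the MCMC fit) run from YAML configs:

```sh
celltraffic run --config experiment.yaml     # writes a reproducible bundle
celltraffic simulate --out data.csv
celltraffic fit --data data.csv --strategy organwise --out fit.json
celltraffic mcmc --data data.csv --chains 3 --rhat-target 1.1 --out chains/
```

Each bundle contains the dataset with provenance, fit result, recovery
report, sensitivity matrix, timescale tables and a `manifest.json` from
which the run is exactly reproducible.

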