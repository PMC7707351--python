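# dosemine

Voxel-based data-mining of the dose changes caused by residual patient-setup
errors in image-guided radiotherapy (IGRT), and of their association with
survival.

## The problem

Lung-cancer radiotherapy is delivered over ~20 daily fractions. Imaging at
the treatment machine corrects patient position only when the measured error
exceeds an action threshold (typically 5 mm), and only at imaged fractions,
so small **residual setup errors** remain. Under the shift-invariance
approximation, a residual displacement r translates the planned dose
against the patient — an anatomy point x receives D(x + r) — and the
accumulated course dose differs from the plan by a per-voxel **Δdose** map
(positive = more dose delivered than planned). Because residual errors are
random, Δdose is statistically independent of tumour and patient
characteristics, making it an unconfounded probe of dose–response: if
patients whose Δdose happens to be higher in some structure die earlier,
that structure is dose-sensitive.

`dosemine` implements the full analysis for that question, aimed at
radiotherapy outcomes researchers:

- IGRT protocol simulation (imaging schedule, action threshold, online
  correction) producing per-fraction residual errors, and the
  heart-shift summary |heart + r − target| − |heart − target|;
- shift-invariant dose accumulation and Δdose maps;
- voxel-wise image-based data-mining: spatial normalisation to a reference
  lattice, Gaussian blurring for registration uncertainty, the permutation-
  scaled t statistic t(v) = (mean Δdose_dead − mean Δdose_alive)/SD_perm(v),
  maxT family-wise inference, and extraction of the region at 80% of the
  maximum t;
- survival modelling of the mined region's dose: elastic-net Cox variable
  selection (equal ridge/lasso), multivariable Cox hazard ratios, a
  planned-dose **octile analysis** that locates the dose threshold where the
  Δdose effect switches on, and Kaplan–Meier/log-rank validation of that
  cut-point;
- a fully synthetic NSCLC-like cohort generator (55 Gy in 20 fractions)
  with a planted dose-sensitive heart-base region and known ground truth,
  so every stage is testable end-to-end.

See `docs/methods.md` for the model, its assumptions, and what the
synthetic cohort does and does not emulate.

## Worked example

```python
from dosemine import PipelineConfig, SimConfig, run_study
import numpy as np

config = PipelineConfig(
    sim=SimConfig(n_patients=300, master_seed=3002,
                  effect_beta_delta=float(np.log(1.25)),       # planted: HR 1.25/Gy
                  dose_threshold_window=(0.0, 1000.0)),        # active for everyone
    n_perm=500,
)
res = run_study(config)
t = res["tmap"]
print(f"max t = {t.max_t:.2f}, global p = {t.global_p:.3f}")
print(f"region voxels = {res['region'].mask.sum()}, "
      f"Dice vs planted = {res['dice_planted']:.2f}")
print(res["cox"].table.loc["mean_delta_region_gy"].round(3).to_dict())
```

prints

```
max t = 6.27, global p = 0.002
region voxels = 642, Dice vs planted = 0.63
{'coef': 0.325, 'hr': 1.384, 'ci_low': 1.29, 'ci_high': 1.485, 'p': 0.0}
```

Reading: the voxel-wise permutation test finds a family-wise-significant
region (p = 0.002, the smallest value 500 permutations can report) whose
80%-of-max-t contour overlaps the planted heart-base structure (Dice 0.63),
and the multivariable Cox model estimates a hazard ratio of 1.38 per Gy of
*measured* region Δdose against the planted 1.25/Gy of *true* region Δdose —
the per-Gy coefficient inflates because blurring and imperfect region
overlap shrink the measured Δdose scale relative to the true one.

The same pipeline runs from the shell:

```bash
dosemine run-all --seed 3002 --out results/demo
dosemine simulate --seed 1 --out cohort/          # write a cohort to disk
dosemine igrt --errors fractions.csv --out residuals.csv --threshold 5
```

`run-all` writes the t-map and region mask (NIfTI), the clinical and
region-summary tables (CSV) and a `results.json` stamped with the config
hash and master seed; reruns with the same config are bit-identical.

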