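# ctmpi — temporal-sampling bias in dynamic CT myocardial perfusion

Dynamic CT myocardial perfusion imaging (CTMPI) estimates myocardial blood
flow (MBF, mL/g/min) from the passage of an iodine contrast bolus: a tissue
attenuation curve (TAC) per myocardial segment and an arterial input
function (AIF) from the aorta. Clinical scanners, however, sample those
curves sparsely — an ECG-triggered *shuttle* scan revisits a slab only every
2–3 s — and the widely used maximum-upslope estimator

```
MBF = 60 · max dTAC/dt / (peak AIF enhancement · ρ)        [mL/g/min]
```

systematically under-reads the true slope when frames are that far apart.
This package simulates a pump-perfused ex-vivo heart experiment end to end
— contrast kinetics with known ground-truth flow, the acquisition timing of
three scan modes, and the estimators — so the bias attributable to temporal
sampling alone can be isolated and quantified. It is aimed at researchers
in perfusion quantification who need a controlled test bed for sampling
protocols and estimator settings.

## What is simulated

* **Kinetics** (`ctmpi.kinetics`) — a normalized gamma-variate AIF
  (injection of 15 mL at 3 mL/s, 5 s into a 60 s scan) and a
  single-compartment tissue model
  `dC_t/dt = k_in·c_a(t) − (k_in/v_d)·C_t`, with `k_in = E·F·ρ/60`,
  extraction fraction `E`, distribution volume `v_d` and true perfusion `F`.
  A fractional-flow-reserve (FFR) grade table reduces pump flow for tight
  stenoses and scales the circumflex (ischemic) territory.
* **Acquisition** (`ctmpi.sampling`) — shuttle mode (end-systolic trigger,
  slab revisited every 4th beat at 107–115 bpm → one frame per 2.1–2.2 s),
  non-shuttle mode (every beat), continuous mode (16 frames/s), with an
  optional gantry-rotation averaging window.
* **Estimators** (`ctmpi.estimators`) — maximum upslope, pump-derived true
  MBF (`input flow / heart weight`), Patlak graphical K1 and the
  extraction-fraction correction `F = K1/E`.
* **Image phantom** (`ctmpi.phantom`) — an optional 4D short-axis stack
  (AHA 16-segment annulus + AIF tube, NIfTI export) whose ROI extraction
  inverts the rendering exactly at zero noise.
* **Experiment** (`ctmpi.experiment`) — the full factorial (3 hearts ×
  3 scan modes × 5 analyzed FFR grades × 16 segments), median [IQR]
  summaries with percent underestimation, paired Wilcoxon mode contrasts
  and flow–MBF Pearson correlations.

Real data enter at the estimator stage: any `time_s,value_hu` CSV pair of
TAC and AIF is accepted (`ctmpi estimate`), and 4D NIfTI stacks can be ROI
reduced with `ctmpi.phantom.extract_segment_tacs`.

## Worked example

```python
from ctmpi import run_experiment, summarize, flow_mbf_correlation

rows = run_experiment(seed=1)                      # default factorial
print(summarize(rows[rows.method == "upslope"], ["mode"]))
print(flow_mbf_correlation(rows))
```

prints (seed 1):

```
       mode    n  median_mbf   q1_mbf   q3_mbf  mean_true_flow  underestimation_pct
    shuttle  165    0.621889 0.543706 0.724218        1.898736            67.247207
non_shuttle  165    1.023788 0.914272 1.241367        1.898736            46.080575
 continuous  165    1.275325 1.157861 1.528944        1.898736            32.832962
{'shuttle': 0.937, 'non_shuttle': 0.877, 'continuous': 0.870}
```

Each row pools the 165 analyzed (non-ischemic) segment records of one scan
mode. Reading it: the true pump-derived perfusion averages 1.90 mL/g/min,
yet the shuttle mode's median estimate is 0.62 mL/g/min (67% low), the
every-beat non-shuttle mode recovers 1.02 (46% low) and the 16 Hz
continuous mode 1.28 (33% low) — the estimate rises monotonically with
temporal sampling rate, and the residual continuous-mode deficit is the
incomplete contrast extraction (E = 0.6) that the maximum-upslope model
ignores. The Pearson r values show every mode still tracks the FFR-graded
input-flow reduction. The same pipeline is scriptable from the shell:

```
ctmpi run --seed 1 --out results/      # measurements.csv, one row per estimate
ctmpi summarize results/measurements.csv --by mode,method
ctmpi simulate --mode shuttle --out curves/   # dense + sampled curve CSVs
ctmpi phantom --out phantom/                  # 4D NIfTI + extracted curves
```

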