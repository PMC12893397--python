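# orgwave

Optical analysis of hybrid 2D/3D cardiomyocyte cultures: a central
beating organoid whose cells spread into a surrounding 2D monolayer,
imaged with a calcium indicator and in brightfield. The package is aimed
at cardiotoxicity screening workflows (doxorubicin is the built-in
positive control) where per-cell calcium handling and contractility must
be quantified, mapped in space around the organoid, and screened for
arrhythmia-prone morphology.

It provides, as importable modules behind one pipeline:

* **calcium transient morphometry** — baseline-drift removal, peak
  detection, and per-transient features: amplitude, time to peak,
  inter-peak time, full width at 20% of maximum (FW20%M) and its left
  (release) and right (reuptake) parts, maximum rate of rise dF/dt|max,
  and the area under the curve between the 20% crossings;
* **contractility** — frame-differencing speed and amplitude signals,
  dynamic-threshold beat segmentation into systole (onset→apex),
  diastole (apex→offset), beat duration and apex-to-apex period, plus
  period-normalized ratios (s/s) and a beating census;
* **spatial analysis** — concentric rings around the organoid (Center,
  then Close/Mid/Far at 185 µm spacing), per-region aggregation, and
  heat-map tables; synchrony against the organoid by normalized
  cross-correlation (synchronous cultures peak at lag 0);
* **abnormality screening** — a deterministic rule labeler for the four
  expert morphology criteria (bifid/multi-spiked peaks, plateau during
  uptake, early second upstroke, spontaneous diastolic release) and an
  RBF-kernel SVM over per-cell averaged features with stratified 10-fold
  cross-validation and a grid search over C ∈ {1e-3…1e3};
* **a synthetic scene generator** — control and doxorubicin presets with
  exact ground truth (kinetics calibrated in closed form to target
  functionals), which makes the entire chain testable without any
  microscopy data. Optionally rasterizes small TIFF stacks so the
  ROI-extraction path can be exercised too.

## Worked example

```python
from orgwave import CONTROL, generate_scene
from orgwave.pipeline import run_pipeline

scene = generate_scene(CONTROL, seed=2024)          # ~110 cells, 15 s @ 50 fps
bundle = run_pipeline(scene, outdir="results/demo")

print(bundle.calcium_cells["width20_ms"].mean())    # 615.8  (ms)
print(bundle.beating.iloc[0]["fraction_beating"])   # 0.769
print((bundle.synchrony["argmax_lag"] == 0).all())  # True
```

The mean FW20%M of 615.8 ms sits above the control kinetic target of
556.2 ms because scene cells carry regional slowing and abnormal-cell
prolongation on top of the group-mean kinetics; 76.9% of cells beat; and
every cell's calcium signal is synchronous with the organoid (maximum
cross-correlation at lag zero).

The numbered scripts under `analysis/` run the full story on one control
and one doxorubicin scene — simulation, per-cell features, regional
gradients with ANOVA/Tukey, the classifier benchmark, and the group
comparison. For example:

```
$ python analysis/05_group_comparison.py
width20_ms         control      615.8 ± 9.7   dox   1154 ± 19.5   t= -26.32  p=4.06e-68 ****
max_slope_aupms    control      0.081 ± 0.0012 dox  0.0547 ± 0.0009 t= 17.06  p=2.15e-41 ****
...
beating fraction control: 76.9%
beating fraction dox: 52.7%
```

showing the expected cardiotoxicity signature: prolonged transients with
a blunted upstroke and calcium overload (larger AUC), prolonged
systole/diastole, and fewer beating cells under doxorubicin.

```
$ python analysis/04_classifier_benchmark.py
n=1000 cells (62% abnormal): sensitivity 98.0%, specificity 99.7%,
accuracy 98.7%, ROC AUC 0.991, best C=1
```

A thin CLI wraps the same functions:

```bash
orgwave simulate --preset dox --seed 1 --out scene/ --stack
orgwave run-all  --preset control --seed 1 --out run/
```

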