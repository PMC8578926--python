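# elastnet

In silico estimation of left-ventricular end-systolic elastance (E_es)
from a single brachial blood-pressure waveform.

## The problem

E_es — the slope of the end-systolic pressure–volume relation — is the
canonical load-insensitive index of cardiac contractility, but measuring
it requires invasive pressure–volume catheterization. The arterial pulse
is cheap to record and its morphology is sensitive to contractility, so
an obvious question is how much of E_es can be read back from one
peripheral pressure waveform. `elastnet` studies that question entirely
in silico, for researchers in cardiovascular modelling and physiological
signal analysis:

1. a reduced-order hemodynamic simulator — a time-varying elastance left
   ventricle, P_LV = E(t)(V_LV − V_d) with E(t) cycling between E_ed and
   E_es, coupled to a tapered-tube arterial ladder network with
   three-element Windkessel terminals — produces pressure and flow
   waveforms at every arterial site;
2. a virtual population is sampled from published parameter
   distributions (9 cardiac/vascular parameters, truncated Gaussians),
   simulated, and filtered for physiological plausibility: every subject
   whose brachial or aortic SBP/DBP/MAP/PP leaves the normative
   mean ± 2.807 SD band is discarded;
3. two 1-D convolutional regressors map the 200-sample, min–max
   normalized brachial wave to E_es: CNN₁ uses the pressure wave alone,
   CNN₂ adds its central-difference time derivative as a second channel
   (four conv stages, kernel 5 / stride 2 / padding 2 + ReLU, one
   max-pool 3/2, affine head; Adam, MSE, batch size and epochs tuned on
   a validation split);
4. agreement is reported as Pearson r, RMSE, range-normalized RMSE,
   Bland–Altman bias with 1.96·SD limits of agreement, and error
   fractions, on clean test waves and under added white Gaussian noise
   at SNR 70–30 dB.

See `docs/methods.md` for the model equations, numerical scheme,
population definition and the design decisions (including what this
reduced simulator can and cannot say about the original question).

## Worked example

Simulate one virtual subject near the accepted-cohort mean and read off
its pressures:

```python
from elastnet import (VentricleParams, build_default_tree, simulate,
                      bp_summary, wave_speed)

ventricle = VentricleParams(E_es=2.4, E_ed=0.16, P_fill=16.5, t_es=328, HR=76)
tree = build_default_tree(height=169.2, distensibility=5.86, TPR=1.36)
result = simulate(ventricle, tree)

aortic = bp_summary(result.pressure["aortic_root"], "aortic root")
brachial = bp_summary(result.pressure["left_brachial"], "left brachial")
```

which prints (via the fields of the returned objects):

```
converged in 8 cycles
aortic root  : 118.5/86.5 mmHg (MAP 102.5)
left brachial: 140.1/82.3 mmHg (MAP 100.6)
pulse pressure amplification: 1.81
stroke volume 56.4 ml, ejection fraction 47.7%
aortic pulse wave speed: 4.65 m/s
```

— a normotensive subject with the expected distal amplification of the
pulse (peripheral SBP above central SBP, diastolic slightly below).

Training a regressor follows the statsmodels pattern — a model object
built from data whose `fit()` returns a results object:

```python
from elastnet import CNNArchitecture, ElastanceRegressor
from elastnet.pipeline import ensure_accepted_cohort, preprocess_cohort

cohort = ensure_accepted_cohort(2000, seed=1)          # ~8 min, one core
X, y, split, scalers, raw, periods = preprocess_cohort(cohort, "two_channel", 2)
model = ElastanceRegressor.from_dataset(X, y, split, CNNArchitecture.cnn2())
results = model.fit(seed=3)
print(results.summary())
report = results.evaluate(X[split.test], y[split.test])   # AgreementReport
```

`report.r`, `report.RMSE`, `report.bias`, `report.loa_low/high` etc.
carry the test-set agreement between predicted and reference E_es in
mmHg/ml. The same pipeline is scriptable from the shell:

```bash
elastnet run-all --n 16000 --min-accepted 2000 --seed 1 --out runs/demo
```

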