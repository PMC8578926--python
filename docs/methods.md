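# Methods

## The estimation problem

Left-ventricular end-systolic elastance E_es — the slope of the
end-systolic pressure–volume relation (ESPVR) — is the reference
load-insensitive index of cardiac contractility. Measuring it requires
invasive pressure–volume loops, so `elastnet` studies a non-invasive
alternative entirely in silico: a hemodynamic simulator generates a
virtual population of brachial pressure waveforms with known E_es, and
1-D convolutional regressors are trained to read E_es back from the
single waveform (one-channel model) or from the waveform plus its time
derivative (two-channel model). Agreement statistics and a
signal-to-noise sweep quantify how much contractility information a
single peripheral pulse carries.

## Cardiovascular model

### Ventricle

The left ventricle is a time-varying elastance: P_LV = E(t) (V_LV − V_d)
with E(t) = E_ed + (E_es − E_ed) e_n(t). The normalized curve e_n is a
piecewise raised cosine: half-cosine upstroke over [0, t_es], half-cosine
relaxation over (t_es, 1.5 t_es], zero for the rest of the cycle. It is
continuous, peaks at exactly 1 at t = t_es, and is fully specified by the
single timing parameter t_es, which is also the only systolic-timing
parameter the cohort samples. Parameter sets whose systole (1.5 t_es)
does not fit inside the cardiac cycle are rejected.

Filling comes from a constant pressure source P_fill through the venous
resistance R_ven; ejection passes through an ideal-diode aortic valve
with a small series resistance R_valve (default 0.006 mmHg·s/ml). Both
valves clamp flow, never pressure: transiently negative ventricular
pressures are legal and simply keep the valves shut.

### Arterial network

Each artery is a long tapered tube with constant distensibility D.
A segment of length l is discretized into lumped pi-elements with

    R = 128 mu l / (pi d^4)   (Poiseuille friction)
    L = 4 rho l / (pi d^2)    (blood inertia)
    C = D A l                 (wall storage)

evaluated at the local tapered diameter d. The element chain behaves as
a transmission line: it propagates pressure waves at the Moens–Korteweg
speed c = 1/sqrt(rho D) per unit area, reflects them at tapers,
bifurcations and terminals, and therefore reproduces the qualitative
morphology change from aortic root to periphery, including
pulse-pressure amplification > 1. Terminal branches drain through
three-element Windkessels (R_c in series with parallel R_p, C_t) into a
3 mmHg venous reservoir.

The packaged default network has 13 segments: the aorta (ascending,
arch x2, thoracic, abdominal) ending in a lumped iliac terminal, the
brachiocephalic → right-subclavian terminal, a left-carotid terminal,
and the left subclavian → axillary → brachial → forearm arm line. The
brachial waveform is recorded at the distal end of the left brachial
segment — an interior node, with the lumped radial/ulnar run-off beyond
it, because a cuff or tonometry site is not a Windkessel boundary and
measuring directly on the terminal load visibly distorts the wave.
Geometry, stiffness ratios (peripheral vessels 0.4–0.7× aortic
distensibility) and Windkessel constants live in an editable YAML config
(`elastnet/data/default_tree.yaml`).

Spatial resolution is ~1 element per 2 cm. Each element acts as an LC
low-pass section with cutoff ~c/(pi l_el); at 2 cm this passes the
~80–100 Hz content that late-systolic features (dicrotic-notch region)
occupy. A coarser ladder (4 cm) measurably blurs those features and
destroys part of the elastance information carried by the wave, which is
why the finer default was adopted.

### Numerics

The coupled ODE system (ventricular volume, node pressures, element
flows, Windkessel pressures) is integrated with fixed-step explicit RK4
at dt = 4e-4 s, in SI units internally, clinical units (mmHg, ml, s) at
every interface. Halving or quartering dt changes the converged
waveforms by < 0.5 mmHg (below the periodicity tolerance), while the
dominant error term — the spatial ladder — is controlled separately by
n_elements. Two stiff resistive modes bound stability: the aortic-root
node through R_valve while the valve is open, and terminal nodes through
R_c. Before integrating, the solver computes both eigenvalue estimates
and shrinks dt per subject so lambda·dt <= 2.5 stays inside the RK4
stability region; only low-distensibility/small-diameter subjects pay
this cost. Initial conditions are uniform node pressures at an Ohmic
mean-pressure estimate (clipped to 40–130 mmHg), zero flows, and a
ventricle filled to V_d + P_fill/E_ed. Cycles repeat until the maximum
cycle-to-cycle node-pressure change falls below 0.5 mmHg (typically 4–10
cycles, hard cap 20); the final cycle is resampled to 200 points per
cycle. Non-finite states raise; non-convergence is flagged and treated
as a cohort rejection, never an abort.

## Virtual population

Nine parameters are sampled as independent truncated Gaussians
(mean ± SD, redraw-until-inside):

| parameter | mean ± SD | bounds | units |
|---|---|---|---|
| E_es | 2.3 ± 1.0 | 0.3–6 | mmHg/ml |
| E_ed | 0.2 ± 0.11 | 0.02–0.6 | mmHg/ml |
| P_fill | 15 ± 5.4 | 3–30 | mmHg |
| t_es | 327 ± 39 | 200–500 | ms |
| HR | 63.7 ± 9.5 | 40–110 | bpm |
| aortic distensibility | 5.86 ± 3.23 | 0.5–16 | 1e-3/mmHg |
| TPR | 1.28 ± 0.31 | 0.5–2.5 | mmHg·s/ml |
| aortic diameter | 33.2 ± 4.1 | 20–48 | mm |
| height | 169.2 ± 8.9 | 140–200 | cm |

The aortic diameter is interpreted in millimetres (33.2 cm would be
anatomically impossible). Heights scale all segment lengths relative to
the 180 cm reference; the sampled aortic diameter scales all diameters
uniformly; distensibility moves the whole stiffness-ratio map and the
terminal compliances together; terminal R_p values are rescaled
uniformly so the parallel total matches the sampled TPR. V_d (15 ml),
R_ven (0.003) and R_valve (0.006) are fixed across the population. No
parameter covariances are modelled.

Each simulated subject is kept only if all eight pressure summaries
(SBP, DBP, MAP, PP at the aortic root and left brachial site) fall
within mean ± 2.807 SD (a 99.5% band, boundary inclusive) of a normative
reference table (brachial 123±15 / 76±10 / 92±10 / 47±12 mmHg; aortic
112±15 / 77±10 / 92±10 / 35±11; editable YAML). Under these defaults the
simulator accepts ~19% of draws, and the accepted population lands near
published normative hemodynamics (brachial ~118/72 mmHg, stroke volume
~55 ml, ejection fraction ~47%, pulse-pressure amplification ~1.4).

## Preprocessing and networks

Accepted brachial waves are linearly resampled to 200 uniform samples
per cycle, differentiated with periodic central differences
(f'[n] = (f[n+1] − f[n−1])/(2 tau), tau = period/200; the endpoints wrap
because the wave is one full cycle), and min–max normalized per time
point with statistics fitted on the 60% training partition only
(validation/test values may leave [0,1]; constant columns map to 0).
The derivative channel is computed from the raw mmHg wave before
normalization and normalized with its own scaler. Targets stay in
native mmHg/ml. The 60/20/20 split rounds the two 20% partitions to the
nearest integer (3748 subjects → 2248/750/750).

Both regressors are four 1-D convolution stages (kernel 5, stride 2,
padding 2, ReLU) followed by one max-pool (kernel 3, stride 2), flatten,
and an affine head to a single scalar; channel progressions 1→2→4→8→16
(one-channel, flatten 16·6 = 96) and 2→8→16→18→24 (two-channel, flatten
24·6 = 144). Spatial chain: 200→100→50→25→13→6. The layers, Adam
optimizer and MSE loss are implemented directly on NumPy arrays with
explicit forward/backward passes (verified against numerical gradients
to ~1e-8); weights initialize fan-in uniform from a dedicated seeded
generator, so training is bit-reproducible single-threaded. Training
runs Adam at lr 1e-3 for each batch size in {32, 64, 128} up to 400
epochs, records validation MSE each epoch while checkpointing the best
weights (equivalent to tuning the epoch count over 1..400 at one
training cost), and restores the globally best (batch size, epoch).

## Noise sweep

Measurement error is emulated by adding white Gaussian noise to the raw
test-partition brachial waves at SNR 70/60/50/40/30 dB, with SNR defined
against each subject's measured mean-square wave power. The derivative
channel is recomputed from the corrupted wave — so noise propagates
through the central differences, amplified by 1/tau — and both channels
are renormalized with the frozen training scalers before prediction.
Agreement is reported per SNR as ordinary least squares
(slope/intercept), Pearson r with Wald-t p, RMSE, range-normalized RMSE,
Bland–Altman bias with 1.96·SD limits of agreement (differences are
estimated − reference, SDs use n−1), and strict-inequality error
fractions.

## What the generator does and does not emulate

The simulator reproduces the mechanistic chain the estimation idea rests
on — contractility shapes the ejection waveform, the arterial tree
propagates, reflects and amplifies it, and a peripheral cuff site sees a
transformed copy — with physiologic pressure levels and population
spread. It deliberately omits (out of scope by design) the full
103-segment anatomy with cerebral/coronary beds, pressure-dependent
nonlinear wall compliance, frequency-dependent (Womersley) friction,
nonuniform aortic stiffening in elderly/hypertensive subjects, and any
parameter inter-dependencies.

These omissions matter for what passing tests can claim. In this
surrogate the brachial wave determines end-systolic *pressure* well, but
end-systolic *volume* only weakly: EDV = V_d + P_fill/E_ed is set by two
sampled parameters that barely imprint on the arterial pulse, and
E_es ≈ P_es/(ESV − V_d). Oracle probes make this sharp: a
random-forest readout of the wave alone reaches r ≈ 0.6, the same
readout given the true ESV reaches r ≈ 0.98, and the closed form
SBP/(ESV − V_d) correlates with the true E_es at r ≈ 0.99. The richer
original model evidently encodes more volume information in the wave
shape. Agreement statistics obtained here therefore bound the method's
behaviour *in this reduced world* and are expected to sit below the
original headline values; the qualitative conclusions (the derivative
channel helps; noise hurts the two-channel model more; the one-channel
model is noise-robust to ~40 dB) are the transferable part. None of this
says anything about real tonometer data, which no in silico test can.

## Numerical/design choices worth knowing

- Elastance curve: raised cosine with relaxation time t_es/2 — the
  simplest continuous curve honoring the one sampled timing parameter.
- Plausibility boundary inclusive (measure-zero choice, fixed for
  testability); rejection reasons are recorded per subject
  (first violated quantity, `non_converged`, `diverged`,
  `systole_exceeds_cycle`, `e_es_below_e_ed`).
- Scalers are fitted on the training partition only and frozen for
  validation/test and for every noise condition (leakage avoidance).
- Error fractions use strict <; the "within 0.5 mmHg/ml" summary uses <=.
- Max-pool ties resolve to the first maximum; conv biases enabled; no
  activation after the output affine (plain regression).
- Problem sizes: the packaged study targets >= 2000 accepted subjects
  (~11k–13k draws) and trains both models with the full recipe; one such
  run is roughly a quarter hour of single-core compute.

## Known limitations

- Constant-distensibility, reduced-topology surrogate: waveform-level
  equivalence with the original 1-D model is not claimed, and the
  information ceiling discussed above is the practical consequence.
- The literature reference table behind the plausibility filter is a
  plausible normative choice, not the (unpublished) original one, so the
  37.48% acceptance rate of the source study is not exactly
  reproducible.
- Independent Gaussian sampling generates some physiologically odd
  corners (handled by truncation + filtering) and no realistic
  covariance structure.
- Training is CPU-only and deliberately small; no augmentation,
  ensembling, or transfer to clinical data.
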