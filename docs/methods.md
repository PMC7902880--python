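# Methods

This note documents the models implemented in `cardiossae`, the choices made
where the design was genuinely open, the synthetic data the toolkit is
validated on, and what the tests do and do not demonstrate.

## 1. Sparsity-regularized stacked autoencoder (`cardiossae.sae`)

One layer encodes `h = σ(W_e x + b_e)` and decodes `y = σ(W_d h + b_d)` with
the logistic σ throughout.  The training objective is

    K(W,b) = 1/(2p) Σᵢ ‖xᵢ − yᵢ‖²  +  λ/2 (‖W_e‖² + ‖W_d‖²)  +  β Σⱼ KL(ρ ‖ ρ̄ⱼ)

with `p` the batch size, `ρ̄ⱼ` the batch-mean activation of hidden unit `j`
and `KL` the Bernoulli relative entropy.  The sparsity term drives most
hidden units toward suppression (mean activation near the target ρ), which
is what lets hidden layers be useful even when wider than the input.

Choices and rationale:

* **Logistic activation everywhere.**  Required for ρ̄ ∈ (0,1) to be
  commensurate with the Bernoulli target ρ.
* **Hidden delta.**  The backpropagated hidden error is
  `δ⁽²⁾ = (W_dᵀ δ⁽³⁾ + β/p (−ρ/ρ̄ + (1−ρ)/(1−ρ̄))) ⊙ h(1−h)`.
  Correctness is established by central finite differences (relative error
  ≤ 1e-6 over randomized layer configurations; see the test suite).
* **Optimizer.**  Deterministic full-batch L-BFGS (`scipy.optimize.minimize`),
  the practical quasi-Newton family at these sizes; determinism enables
  exact regression tests.  Per-iteration objectives are recorded and are
  non-increasing across accepted iterates.
* **Initialization.**  Uniform on ±√(6/(d_in+d_hidden)), seeded; zero biases.
* **Defaults.**  λ = 1e-4, β = 3, ρ = 0.05, max_iter = 400.  These are
  config values, not claims; they behave well across the synthetic studies.
* **ρ̄ clamping.**  ρ̄ is clipped into [1e-8, 1−1e-8] before logarithms.
* **Stacking.**  Greedy layer-wise unsupervised pretraining (each layer
  trains on the previous layer's codes), hidden sizes 120-60-30-15 for the
  250-sample beat input.  A SoftMax head is then attached: first a convex
  head-only fit on the frozen deep features, then joint fine-tuning of all
  encoder weights plus the head on cross-entropy with the same λ decay.
  Tie-breaks in `argmax` go to the lowest class index.
* **Beat window = 250 samples at 360 Hz** (100 before the R peak, 150
  after), min-max normalized to [0,1] per beat so inputs live in the
  logistic range; a constant window maps to all-0.5.  The input width was
  chosen larger than the first hidden layer (120) so the first layer is
  compressive.

## 2. Beat pipeline (`cardiossae.beatclass`)

R peaks: 5–15 Hz Butterworth band-pass (zero-phase), squared derivative,
150 ms moving-window integration, candidate peaks at a 200 ms refractory
distance.  The detection threshold is adaptive: candidate heights are
bimodal (QRS versus T-wave/noise), and half the geometric mean of the
median and maximum height sits in the gap between the modes.  Each
detection is refined to the nearby maximum of the 9-sample median-filtered
signal — the median kills the few-sample-wide pacing spike while leaving
the broader QRS apex, so the refined index is the R apex for all six
classes.  Flat records yield no peaks (not an error).

Evaluation builds a 6×6 confusion matrix with **rows = predicted class,
columns = true class**; overall accuracy is trace/total, per-class
sensitivity is diagonal/column-sum (0, with a warning, for classes absent
from the truth).  Because "average accuracy" can mean either, both overall
and macro-averaged accuracy are reported in metrics documents.

## 3. Serial leaky echo-state network (`cardiossae.esn`)

Reservoir update: `x(t) = (1−a)x(t−1) + a·tanh(W_in[1;u(t)] + W_res x(t−1))`,
`x(0)=0`.  `W_res` is sparse Gaussian (density 0.1) rescaled so its largest
absolute eigenvalue equals the configured spectral radius exactly; `W_in`
is uniform on ±input_scaling.  Defaults follow the sensitivity study this
design reproduces: spectral radius 0.001, input scaling 0.1, leak rate
0.95 ("close to 1"); the leak parameter is interpreted as the coefficient
`a` itself.  The radius default is unusually small for reservoir computing
— the network is then driven almost purely by the input — so the radius is
configurable and its directional effect (0.1 → 0.01) is tested separately.

**Serial (tandem) structure.**  Stage k receives the raw input concatenated
with stage k−1's state at the same step; only the final stage feeds the
readout.  Defaults: 3 stages of 300 units, washout 100 steps.

**Input representation** (not specified by the design source; our choice):
the ECG window is band-passed 0.5–30 Hz, resampled to 90 Hz, and scaled by
a fixed gain of 5.  The gain matters: a typical ECG has ~0.2 mV RMS, and
with input scaling 0.1 the tanh units would stay in their linear range,
where time-averaged states collapse to near-constants (the mean of an odd
function of a roughly symmetric signal).  At ~unit RMS the pooled states
expose the input's moment structure — QRS duty cycle, amplitude, added
oscillation power — which is exactly what distinguishes the window classes.

**Readout.**  Windows are summarized by mean-pooling post-washout final-
stage states.  Pooled features span several orders of magnitude in
variance, so they are standardized with training-set statistics before a
closed-form ridge regression onto ±1 labels (intercept unpenalized,
default λ = 0.1).  Without standardization the ridge penalty suppresses
small-variance but informative features (observed as chance-level accuracy
in the weak-drift buckets).  λ = 0 demands full column rank and otherwise
raises an error suggesting λ > 0.  Prediction is the sign of the readout
score with 0 mapping to non-SCD.

Windows are 60 s; the per-minute report gives the accuracy of each
minutes-before-onset bucket k ∈ {1..5} and their unweighted mean.

## 4. OCT A-line pipeline (`cardiossae.octplaque`)

Polar frames are row 0 = lumen side, columns = angles.  Unfolding takes,
per column, the 100 pixels below the lumen border (zero-padded past the
image bottom, pad count recorded).  The lumen border is an input; a simple
fallback (first row exceeding an Otsu-style global threshold) is *not* an
implementation of any published border detector and phantom ground truth
is normally used.

A-line classification: guidewire shadow (GS) is a pre-filter — profiles
whose maximum is below 0.08 are "close to the zero line" and bypass the
network; everything else goes to a sparse stacked autoencoder with a
4-class SoftMax head (F, F-C, F-L, GS), pretrained unsupervised on
unlabeled A-lines and fine-tuned on labelled ones (hidden sizes 60-30-15
for the 100-pixel input).

Regions: a circular majority filter of width 5 smooths per-column labels;
runs shorter than 8 columns merge into the larger neighbor (ties to the
following one); GS runs are excluded; runs joining across the 0/n_angle
seam are reported once with end_col > n_angle.

Cap thickness (fibro-lipid regions): per column, pixel pitch × the first
depth index at which the A-line falls below 50% of its cap plateau (the
A-line maximum); columns without a drop point report the full 100-pixel
window and are flagged.  A region is vulnerable (TCFA) when its minimum
cap is below the configurable thin-cap threshold, default 65 µm.  Both the
50% rule and the 65 µm default are this package's choices.

Segmentation metrics: Dice, Jaccard, boundary Hausdorff (pixels),
precision, recall.  Empty-mask conventions: both empty → overlap metrics 1
and Hausdorff 0; exactly one empty → overlap metrics 0 and Hausdorff equal
to the image diagonal.  "Area overlap" is reported as Dice, with Jaccard
alongside.

## 5. Synthetic generators (`cardiossae.synthgen`)

Every generator is a pure function of (parameters, seed).

* **Beats** are sums of Gaussian bumps (ECGSYN-style morphology), one per
  P/Q/R/S/T component, with a per-class table.  N and AP differ only in
  the P wave (small amplitude — the clinically hard distinction), the wide
  classes (PVC/RBBB/LBBB) share a QRS ≥ 1.5× normal width under a
  10%-of-R threshold scan but differ in notch and T polarity, and PACE
  carries a 1.4 mV, 3.5 ms pacing spike.  Jitter perturbs each component's
  amplitude, center and width fractionally.
* **Records** place beats at Gaussian RR intervals (0.75 s base, scaled by
  each class's prematurity factor), add baseline wander (amplitude
  3×noise_sd at 0.2–0.35 Hz) and white noise; noise_sd = 0 gives an exactly
  clean record.
* **Pre-SCD windows** at k minutes before onset drift with magnitude
  m = severity·(6−k)/5: QRS widened ×(1+0.8m), amplitudes ×(1−0.35m), plus
  a 4–7 Hz oscillation of 0.18·m mV, with per-beat stochastic jitter; the
  paired non-SCD windows are stationary normal rhythm.  These effect sizes
  were fixed once as a plausible qualitative emulation of pre-arrest
  morphology change; they claim no clinical calibration.
* **Phantoms** carry class-specific depth signatures below the border —
  F: bright plateau then slow exponential decay; F-C: bright cap, sharp
  drop into a low sharply-bordered pool; F-L: moderate flat cap then a
  rapid drop below half the cap level with a diffuse exponential tail (so
  the 50% rule recovers the programmed cap exactly on clean data); GS:
  zero.  Intensities live on [0,1]; default pitch 10 µm/pixel.

**What passing tests show — and don't.**  The generators reproduce the
qualitative structure the methods rely on (class-specific morphology, a
monotone drift dial, distinct A-line signatures), so green tests show the
algorithms extract exactly the structure they are supposed to.  They do not
show clinical performance: real recordings carry inter-patient variability,
electrode artifacts, speckle and class imbalance that these generators do
not model, and no usable clinical accession was available to calibrate
against.

## 6. Reproducibility

One master seed fans out to every stage as SHA-256("<master>:<stage>")
mod 2³¹.  A `RunManifest` snapshots config, derived seeds, input digests
and toolkit version; metrics documents embed the manifest digest, carry
floats at 6 significant digits with sorted keys, and are byte-identical
across reruns.  Model files round-trip bit-exactly.

## 7. Problem sizes of the bundled studies

The standard study conditions used by the test suite and the acceptance
script: beats — 600 train / 200 test per class, jitter 0.05, noise 0.02 mV;
SCD — 200 window pairs (60 s windows), first half train / second half
test, drift severity 1; OCT — a 20-phantom noiseless evaluation suite with
a 24-phantom training suite (large enough to cover the full range of cap
thicknesses in each tissue class).  These sizes give stable estimates while
keeping each study in the minutes range on one CPU.

## 8. Known limitations

* The beat classifier is beat-level only; no rhythm context, multi-lead
  fusion or noise-class rejection.
* The ESN studies use fixed-length windows; no online/streaming use.
* The OCT pipeline assumes a supplied lumen border and polar geometry; no
  Cartesian conversion, stent-strut or thrombus handling.
* All reported numbers are measured on synthetic data; see §5.
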