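# Methods

## Problem

ECG-based user recognition enrolls a subject with a fixed-size template — here
an ordered run of five heartbeat cycles — and later identifies probes of the
same size. In practice a probe often holds fewer usable cycles than the
template (short acquisition, state change, artifact rejection), creating a
data-size inconsistency. The package implements one resolution: fill the
missing probe slots with *subject-conditional synthetic cycles* from an
auxiliary-classifier adversarial network, and compare that against the naive
alternative of repeating the last real cycle.

## Synthetic study generator

Real multi-state biometric ECG corpora with per-beat ground truth are rarely
shareable, so the package carries its own labelled study generator.

**Beat model.** One heartbeat is a sum of five Gaussians, one per wave
(P, Q, R, S, T). Wave *w* has a phase angle θ_w (radians relative to the R
event, θ_R = 0), an amplitude a_w (mV) and a width b_w (radians). For a beat
with R at time t_R and RR interval T, wave *w* contributes
a_w · exp(−(t − t_R − θ_w T / 2π)² / 2σ²) with σ = b_w T / 2π, so faster
beats are proportionally compressed. A subject is a draw of the 15
parameters from documented uniform ranges (`DEFAULT_WAVE_RANGES`) centred on
textbook lead-I morphology; invariants enforce wave ordering, R dominance and
positive widths. This is the simplest model exposing exactly the P/QRS/T
structure the downstream stages consume; a coupled-oscillator dynamical model
would add realism (RR autocorrelation, respiratory modulation) but none of the
structure the pipeline tests need.

**States.** Four acquisition states modulate heart rate and wave timing:
lying 62 ± 2.5 bpm, before exercise 65 ± 3, standing 74 ± 3.5, after exercise
128 ± 5 (kept above 120 bpm). A compression factor in (0, 1] scales θ_P and
θ_T toward 0 — after exercise (0.70) the P and T waves sit visibly closer to
the QRS complex than at rest (1.0). RR intervals are Normal(60/HR,
60·HR_sd/HR²), truncated at 0.3 s. A beat is not started within 50 ms of the
record end, so every ground-truth R peak has its full deflection in the
signal.

**Noise** is additive and independent: sinusoidal baseline drift (default
0.15 mV at 0.25 Hz — below the 0.5 Hz high-pass corner), 60 Hz powerline
interference (0.05 mV) and white Gaussian "muscle" noise (0.02 mV against an
R amplitude of 0.8–1.4 mV). Transient motion artifacts are deliberately out
of scope.

**What passing tests do and do not show.** The generator's cycles are smooth,
unimodal per wave, and stationarity is perfect within a recording; real ECG
has ectopy, electrode motion, and slow morphology drift. Results on this
fixture demonstrate that the pipeline's machinery is correct and that the
qualitative synthetic-vs-repetition comparison holds under controlled
conditions; they do not predict absolute accuracy on clinical data.

## Preprocessing

Zero-phase (forward-backward) filtering throughout, so R-peak latency is
undistorted: third-order Butterworth high-pass at 0.5 Hz for baseline drift,
IIR notch at 60 Hz (Q = 30) for powerline pickup.

R peaks are detected with the classical Pan–Tompkins stages: 5–15 Hz
band-pass, five-point derivative, squaring, 150 ms moving-window integration,
dual adaptive signal/noise thresholds with a 200 ms refractory period and
half-threshold search-back when a gap longer than 1.66× the running mean RR
opens. Two boundary details matter at record edges: the moving-window
integral is normalised by the actual in-bounds window coverage (otherwise the
last beat's integral droops by up to half), and candidates may lie on the
record boundary. Detections are refined to the band-passed local maximum
within ±50 ms. Thresholds adapt to running signal levels, making detection
invariant to global amplitude scaling.

Cycles are cut on an R-centred asymmetric window (0.25 s before, 0.45 s
after — covering P through T at rest and after exercise), resampled to 256
samples (a power of two convenient for the pooling stages) and max-abs
normalised so real and generated cycles share the [−1, 1] scale. Peaks whose
window overruns the record are dropped, not padded: padding would inject
artificial morphology into training data. Sequences are non-overlapping
consecutive runs of five cycles within one (subject, state, session) group.

## Conditional adversarial generation

The generator consumes a noise vector of the *same length as the cycle to be
generated* (256) and a class id. The class enters through a learned
embedding of dimension 256 combined element-wise (multiplicatively by
default; additive available) with the noise. The body is nine 1D
convolutional layers (kernel 9, channel schedule (4,4,6,6,8,8,10,10,12),
leaky-rectifier activations) with max-pooling after layers 3 and 6, closed by
one fully connected layer with tanh saturation — output bounded in [−1, 1] by
construction. The discriminator is deliberately shallower (four conv layers,
enforced strictly fewer than nine) with a shared trunk and two heads: a
real/fake source score and an auxiliary class classifier.

**Losses** follow the standard auxiliary-classifier formulation: the
discriminator minimises binary source cross-entropy plus categorical class
cross-entropy on both real and generated cycles; the generator minimises the
fooling term plus the class loss on its own outputs. Adam (lr 2·10⁻⁴,
β₁ = 0.5) for both networks. Any non-finite loss aborts with an error naming
the epoch — deeper generators demonstrably diverge, which is why the 9-layer
skeleton is enforced as an invariant rather than a default.

**Warm-up.** Before the adversarial phase the generator alone is trained for
a few epochs (default 40, Adam lr 10⁻³) to regress its output onto real
cycles of the conditioned class (converging toward the class-conditional
mean). This is an initialization choice fixing a real failure mode we
measured: without it, small conditional GANs settle — in roughly half of
seeds on 2-class problems — into a *permuted-code* equilibrium in which the
generator's class k reproduces real class j and the auxiliary classifier
cooperates with the permutation, all losses happily low. The warm-up anchors
the embedding to the true identities; the adversarial phase then adds the
per-cycle variability the regression solution lacks.

**Checkpoint selection.** Adversarial training does not converge
monotonically: generation quality oscillates between epochs. Every
`eval_every` epochs (default 10) the generator's class-conditional samples —
drawn with fixed evaluation noise — are scored by cosine similarity against
the class-mean cycles, and the best-scoring generator weights are the ones a
finished checkpoint carries (`select_best`, on by default; the score trace is
kept in the training history). The discriminator stored is always the final
one, since its auxiliary classifier only sharpens with further training.

All randomness flows through one `numpy.random.Generator` seeded from the
config, so training is bit-reproducible. The network kit itself (convolution
via strided-view GEMM, manual backprop, float32) is a minimal numpy
implementation whose gradients are verified against central finite
differences in the test suite.

## Similarity scoring

Two measures compare generated and real cycles:

- **Cosine similarity** of each synthetic cycle against its class's mean real
  cycle (the most stable single reference).
- **Cross-correlation next-beat distance**: with c the current real cycle,
  n the next real cycle and s a synthetic cycle, compute the full normalised
  cross-correlations x_cs = xcorr(c, s)/(‖c‖‖s‖) and x_cn = xcorr(c, n)/(‖c‖‖n‖)
  and report ‖x_cs − x_cn‖₂ / √(2L−1). The value is 0 exactly when the
  synthetic cycle is a positive rescaling of the genuine next beat, and grows
  when it correlates with the current cycle the way another subject's cycle
  would. No lag alignment is applied before subtraction (the correlation
  waveforms are compared at matched lags). The √(2L−1) scaling makes the
  number a per-lag RMS difference; distances under ~0.05 on this fixture
  indicate next-beat-like behaviour, and the absolute scale is a convention
  of this implementation.

## Recognition ensemble

Six parallel 1D CNN members see each five-cycle sequence as one concatenated
1280-sample signal. Members deliberately differ: the canonical
hyperparameter grid crosses epochs {500, 750} × batch {256, 512} with dropout
{0.50, 0.70}, learning rate fixed at 0.001 (these bounds are *enforced* in
paper-faithful mode; scaled-down members for desk-size fixtures relax them
explicitly), and each member uses a different conv-channel/kernel variant so
the ensemble attends to different features. A member is conv → leaky-ReLU →
max-pool (twice) → dropout → dense hidden (64) → softmax. Max pooling is
fixed: average pooling would down-weight the sparse large deflections that
carry subject identity.

The three members with the best validation accuracy (ties to the lower
member id) are kept. Their penultimate-layer (hidden) vectors are
concatenated per input — 192 features — into a fused registration set;
"result data" could also mean raw signals or softmax scores, but raw signals
would make the members pointless and final scores lose information. A single
dense softmax classifier is retrained on the fused features (dense-only:
fused features have no spatial order for convolution to exploit). A probe is
embedded by the three members, concatenated, and classified; probes from
subjects unseen at enrollment are counted as errors with a logged warning.

## Scheme comparison experiment

Registration uses sessions 1–2 across all four states; comparison uses the
held-out session 3, honouring time-independent probes. Comparison templates
are state-homogeneous (a probe's five cycles come from one recording).
Synthetic cycles for scheme slots are generated once per subject with a fixed
generation seed so all schemes share the same synthetic material. The seven
canonical schemes (all-real; 4, 3 or 2 real cycles padded with synthetic
cycles; the same padded with repetition) are a closed table — unknown names
are rejected.

**Desk-scale defaults** (stated as the package's study conditions): 5
subjects × 4 states × 3 sessions × 20 s at 500 Hz; GAN trained on up to 100
registration cycles per subject for 60 adversarial epochs after a 120-epoch
warm-up; 6 members at 50 epochs (batch 32) with top-3 fusion; ~200 enrollment
sequences and ~100 probes. One full run takes about two minutes on one CPU. The
generation-quality study uses the larger fixed setting of 3 subjects ×
200 cycles × 300 epochs at cycle length 256 (~4–5 min). The paper-faithful
hyperparameter grid (500/750-epoch members) is available behind
`paper_faithful=True` but is not exercised by the default test suite.

## Numerical choices and degenerate inputs

- Zero-norm vectors are rejected by the similarity metrics (undefined
  cosine), zero-amplitude cycles are dropped at segmentation.
- Member selection and scheme tables break ties deterministically; every
  stochastic component draws from an explicitly seeded generator, and the
  experiment manifest records all three seeds (fixture, GAN, ensemble).
- `epochs=0` adversarial training is a strict no-op returning the
  initialisation (warm-up included in the skip).
- Filtering is idempotent in its stop band to within 1% RMS; applying the
  notch twice is safe.

## Known limitations

- The synthetic cohort's between-subject variability is parametric and
  optimistic; absolute accuracies near 100% at desk scale reflect that, and
  only the *ordering* of schemes is the meaningful result.
- The acquisition protocol's "data expansion" to tens of thousands of
  training items in the original study setting is undefined; the package uses
  honest counts from simulated recordings instead.
- Single-lead, normal-rhythm signals only; no ectopic-beat rejection, no
  open-set (unknown-subject) identification, no verification (1:1) mode.
- The numpy network kit is single-threaded and CPU-bound by design; it is not
  a general deep-learning framework.
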