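# Methods

## Scope and model

`tracefret` analyzes multichannel fluorescence intensity trajectories of
single surface-immobilized molecules carrying one, two or three dyes, as
recorded frame-wise on TIRF or confocal setups (with alternating laser
excitation for two- and three-color FRET).  The package covers the full
chain: a forward simulator that generates labeled trajectories, per-frame
classifiers that sort traces and decode hidden states, photobleaching-based
correction factors and accurate FRET efficiencies, and kinetic analysis via
transition density plots (TDPs) and dwell-time fits, with a Gaussian-emission
hidden Markov model (HMM) as the reference method.

### Kinetic model

A molecule occupies one of `K` (1–4) conformational states and hops between
them as a continuous-time Markov chain with rate matrix `k_ij` (1/s,
off-diagonal ≥ 0, rows summing to zero).  The mean dwell time of state `i`
is `−1/k_ii` and sojourn times are exponential.  Each state carries fixed
FRET efficiencies for every dye pair present (`E_DA`; `E_BY`, `E_BR`, `E_YR`
for three colors), or a relative brightness level for one-color (quencher)
data.

State indices are *canonical* throughout the package: states are ordered by
ascending expected value of the first kinetic channel (for FRET pairs this
means descending efficiency), so indices are comparable across traces,
classifiers and the HMM.

### Frame formation

The chain is sampled exactly by exponential waiting times and integrated
over each camera exposure, so the per-frame record is the *time-averaged*
state occupancy.  A transition inside a frame produces a mixed frame whose
signal lies between the two state levels.  This is deliberate: dynamics at
the acquisition time scale are the hard case any per-frame method must face,
and a simulator that only switched states at frame boundaries would hide it.

Two consequences are documented here because they shape every accuracy
number in the test suite:

* **Pure-frame scoring.** A frame that contains a sub-frame transition has
  no well-defined single-state label (the stored truth is the majority-
  occupancy state, which for a 51/49 split is a coin toss).  Frame-accuracy
  figures are therefore computed over frames with unambiguous truth
  (occupancy > 0.99).  Including mixed frames lowers all methods by roughly
  `P(transition per frame) × 0.3`.
* **Discretization bias of dwell statistics.** Dwell times read off any
  per-frame state path — including the ground-truth path itself — are
  biased against the continuous-time rates, because opposite-state visits
  shorter than about one frame merge adjacent dwells.  Measured on truth
  paths, the fitted τ is high by ~2% at dwell/frame ≈ 35 and ~16% at ratio
  9; below ratio ~3 most events are averaged out and the detected
  transition count collapses.  Recovery statements in the tests therefore
  compare decoded paths against the truth *path* (what a per-frame method
  can possibly know); truth-path-versus-rate agreement is asserted only at
  ratios ≥ 25.

### Photophysics and detection

Each dye bleaches in a single exponential step (rate per dye; blinking is
not modeled — artifact-class traces contain blinking-like dips instead).
Detection imperfections are parameterized per donor→acceptor pair:

* `alpha` — spectral crosstalk of donor emission into the acceptor channel,
* `delta` — direct excitation of the acceptor by the donor laser,
  normalized to the acceptor-excitation signal,
* `gamma` — acceptor/donor detection-efficiency and quantum-yield ratio.

Noise is additive Gaussian per channel with
`sigma = (summed dye brightness) / SNR`; SNR is drawn log-uniformly from the
configured range.  This emulates background-dominated EMCCD read noise with
excess noise folded into sigma; shot-noise scaling with signal level is not
modeled.  The forward mixing is constructed to invert *exactly* under the
correction formulas (verified to 1e-10 in the tests), so the corrections
module is validated independently of noise considerations.

For CW two-color data (no acceptor-excitation channel) direct excitation is
physically present but cannot be estimated or subtracted; the exact
round-trip for that modality holds with `delta = 0`, which is precisely the
limitation ALEX removes.

### Simulation envelope and junk categories

Defaults reproduce the training envelope: FRET efficiencies uniform in
[0.01, 0.99] (with a configurable minimum inter-state contrast, default 0.1,
enforced by an exact minimum-gap sampler), dwell times log-uniform over
1–100 frames, SNR log-uniform over 0.3–50, 2000 frames per trace at 50 ms.
Reject categories are generated as: *noisy* — an ordinary molecule rendered
at SNR below 1; *aggregate* — the summed channels of 2–3 independent
molecules (several bleach steps per dye, stoichiometry > 1); *artifact* —
uncorrelated level jumps, blinking-like dips and baseline drift.  The
quantitative recipes for these categories are this package's own choices;
only the category names and roles are field-standard.

## Classifiers

Each classifier couples an omni-scale temporal feature bank with a
multilayer-perceptron softmax head (scikit-learn `MLPClassifier`), trained
on pooled frames:

* per-trace robust normalization (2nd/98th percentile anchors of a smoothed
  copy, so noise extremes do not set the scale);
* moving mean and moving spread over odd windows {3, 7, 15, 31, 61} frames
  — receptive fields from a single frame to ~2× the longest expected dwell;
* forward and backward exponential-memory traces (decays 0.05, 0.2) giving
  each frame bidirectional context, e.g. on which side of a bleach step it
  lies;
* single-frame and two-frame spike contrasts, which carry the signature of
  dwells at the frame-time scale;
* scale-free acceptor-fraction (proximity-ratio) series for each FRET pair;
* trace-global context tiled across frames: level spread, long-lag
  autocorrelation, step counts (on each channel and on the summed
  intensity, where aggregate bleach ladders appear), ratio statistics
  restricted to the donor-active region, and a scale-invariant per-channel
  SNR estimate (mean signal over high-frequency noise) — absolute
  information that per-trace normalization would otherwise erase.

The trace classifier consumes all channels and predicts the full per-frame
category alphabet (photoactive-set labels expanded per modality, plus the
three junk labels).  State classifiers (2/3/4 states) consume only the
kinetic channels — the acceptor signal under direct acceptor excitation is
constant while the acceptor lives and carries no kinetic information.
Training oversamples frames within ±2 of a state transition (duplicated
twice): transition frames are rare but decide whether frame-time-scale
dwells are detected at all; without the oversampling the decoded dwell
times at dwell/frame ≈ 9 run ~7% long (missed short dwells merge their
neighbors), with it they sit within ~3%.

The number-of-states classifier is a trace-level model over summary
features of the dynamic segment (histograms of the smoothed observable, a
1-D k-means inertia profile for k = 1..5, autocorrelations and increment
statistics).

Confidence is the mean top-class probability over frames not called fully
bleached; traces below the threshold (default 0.9) are flagged for discard.
Classifier label output is smoothed by absorbing runs shorter than 3 frames
into their longer neighbor before segmentation.

### Training scale

The default suite and the acceptance script train at a reduced smoke scale:
2000 training / 400 validation traces of 300 frames drawn from the
separable part of the envelope (SNR 8–30, dwells 15–80 frames, contrast
≥ 0.25), with the MLP capped at 250k training frames and 30 epochs.  At
this scale the two-state classifier reaches ~99% held-out frame accuracy
and the trace classifier ~97–98% precision on usable smFRET categories at
the 0.9 threshold.  The full-envelope figures quoted in the field
(including the hardest four-state, one-channel case) require
hundreds of thousands of 2000-frame training traces and correspondingly
long training.

## Correction factors and accurate FRET

Frames in which exactly one dye of a pair is photoactive calibrate the
detection: donor-only segments give `alpha`, acceptor-only segments give
`delta` (ALEX only), and the acceptor bleach step inside an active region
gives `gamma = -Δ⟨F_sens⟩/Δ⟨I_DexDem⟩` with 2 guard frames excluded around
the step and the pre-window restricted to the modal state.  Minimum segment
length is 10 frames; background is the mean of the all-bleached segment
(zero if absent).  Factors are estimated in two passes over a dataset:
alpha/delta medians first, then gamma using trace-wise values where
available and medians otherwise — a trace whose acceptor bleached first has
no acceptor-only segment, and using 0 instead of the median delta there
would bias gamma high.  For the three-color blue pairs (BY, BR) the gamma
step analysis is valid once the third dye has bleached, reducing the blue
block to an effective two-color pair; otherwise dataset medians are used.

Accurate two-color efficiency: `F = I_DexAem − alpha·I_DexDem −
delta·I_AexAem`, `E = F/(F + gamma·I_DexDem)`.  For three colors the YR
pair is corrected from the yellow-excitation block exactly as two-color;
the blue block uses the corrected emissions and the *state-averaged*
corrected `E_YR` (clamped at 0.95) in `E_BY = I_Y/(T·(1−E_YR))`,
`E_BR = 1 − I_B/T − E_BY`.  Frame-wise division by `(1−E_YR)` amplifies
noise dramatically as `E_YR → 1` — the tests verify the corrected BY
variance grows monotonically with `E_YR` — and state-averaging suppresses
exactly that broadening.  State-level efficiencies are computed as ratios
of state-averaged intensities (not averages of per-frame ratios, which are
biased at low signal).  Corrected efficiencies are not clipped; histograms
span [−0.2, 1.2] in 0.02 bins so miscorrection stays visible.

Distances follow `R = R0·(1/E − 1)^(1/6)`; with the Förster radius 68 Å of
the Cy3B/Atto647N pair, the corrected state efficiencies 0.81 and 0.14
correspond to 53 Å and 92 Å.

## Kinetics

Maximal constant runs of a state path are dwells; the first and last run of
each segment touch the observation boundary (censored) and are excluded
from dwell statistics, while their transition endpoints still feed the TDP.
The TDP is the 2-D histogram of the mean observable before vs after each
transition (apparent FRET, or normalized intensity for one color);
rectangular gates select transition classes and are plain dictionaries so a
gating scheme replays from a config.  Dwell distributions are fit by least
squares of `1 − exp(−t/τ)` to the empirical CDF at the sorted dwell values;
the 95% CI comes from the Jacobian-based covariance of the fit, and R² is
reported to flag degenerate inputs.  One-frame dwells are retained by
default.

## HMM baseline

`hmmlearn`'s Gaussian-emission HMM fit by Baum-Welch with Viterbi decoding,
applied to the 1-D observable per trace (local) or with shared parameters
across traces (global).  Parameterization: convergence threshold 1e-9 on
the log-likelihood, iteration cap 1e8, two states by default.
Initialization (a choice this package had to make): quantile-split means,
residual variances, sticky uniform transitions (0.95 self-transition).  The
M-step is pure maximum likelihood (no covariance prior), which keeps the EM
log-likelihood non-decreasing — asserted per iteration in the tests — with
a hard variance floor of 1e-6 that engages only on degenerate input and is
flagged.  On simulated data the classifier and the local HMM agree within
~0.3 accuracy points at SNR 10 and the classifier leads by ~5 points at
SNR 1; the global HMM matches local fits on homogeneous data and misses
transitions in traces whose state means deviate from the ensemble — both
behaviors are regression-tested.

## End-to-end reference analysis

The pipeline (classify → segment → correct → decode states → TDP → dwell
fits) is exercised on a simulated analog of a two-state DNA-origami
tether: τ = 1.75 s and 2.65 s at 50 ms frames, state efficiencies
0.81/0.14, 1000 traces of 2000 frames, SNR 10, exponential bleaching with
200 s mean per dye (slow, as for photostabilized dyes; trace length and
bleaching matter because dwells complete only inside the active window —
windows shorter than ~40τ visibly depress fitted τ).  Both the classifier
path and the HMM path recover both dwell times within 5% and agree with
each other within 2%, and the dataset medians recover the simulated
alpha/delta/gamma within a few percent.

## Known limitations

* Junk-category recipes are stand-ins; real artifact/aggregate phenomenology
  is richer.
* Noise is additive Gaussian; Poisson shot-noise scaling and EMCCD excess
  noise statistics are not modeled, so SNR-dependent conclusions transfer
  to real data only qualitatively.
* Blinking is absent from usable categories; a blinking dye would be
  segmented as an early bleach.
* The three-color forward model treats per-state pair efficiencies as
  branching fractions (`E_BY + E_BR ≤ 0.95` enforced); it does not model
  rate competition between acceptors, so pair efficiencies whose sum
  exceeds 1 (possible in rate-competition formalisms) are out of scope.
* Dwell-time estimates inherit the per-frame discretization bias described
  above; no missed-event correction is applied, matching the plain
  mono-exponential CDF convention.
* Classifier accuracies are reported at the smoke training scale; they are
  lower bounds on what full-scale training achieves.
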