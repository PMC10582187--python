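# tracefret

Automated analysis of one-, two- and three-color single-molecule FRET
intensity trajectories: trace sorting and per-frame classification,
photobleaching-based correction factors, accurate FRET efficiencies and
dye-pair distances, and kinetic analysis through transition density plots
and dwell-time fits — benchmarked against a Gaussian-emission hidden Markov
model.

## The problem

Single-molecule FRET movies yield thousands of intensity traces per
condition, of which only a fraction are usable: one fluorophore per dye
slot, photoactive long enough, free of aggregates, artifacts and excessive
noise.  Sorting them by hand is slow and subjective, and every downstream
quantity — crosstalk (α), direct excitation (δ) and detection-efficiency
(γ) corrections, state assignment, dwell times — depends on which frames
the analyst selects.  `tracefret` automates the whole chain on a per-frame
basis:

1. a **trace classifier** labels every frame of every trace with its
   category (dynamic / static with all dyes active, each photobleached
   combination, or one of the junk classes noisy / artifact / aggregate);
2. the photobleached segments it finds calibrate the **correction factors**
   per trace (trace-wise values, dataset medians as fallback), giving
   accurate FRET efficiencies `E = F/(F + γ·I_DD)` with
   `F = I_DA − α·I_DD − δ·I_AA`, and distances `R = R0·(1/E − 1)^(1/6)`;
3. a **state classifier** decodes the hidden conformational state of each
   dynamic frame; transitions feed a transition density plot and
   mono-exponential dwell-time CDF fits with Jacobian-based 95% CIs;
4. a **Gaussian HMM** (Baum–Welch, Viterbi, tolerance 1e-9) provides the
   conventional reference analysis, locally per trace or globally.

Classifiers pair an omni-scale temporal feature bank (multi-width moving
statistics, bidirectional exponential memory, spike contrasts, trace-global
context) with an MLP softmax head, trained purely on the package's own
labeled simulator — a continuous-time Markov chain with intra-frame
time-averaging, single-step photobleaching, the full α/δ/γ detection model
and additive Gaussian noise.  Every analysis step is validated against this
simulator's ground truth (see `docs/methods.md`).

## Worked example

Simulate 300 two-state ALEX traces (E = 0.81/0.14, dwell times 1.75 s and
2.65 s at 50 ms frames, SNR 10, α = 0.05, δ = 0.08, γ = 1.15, slow
bleaching), recover the correction factors from the bleach-classified
frames, and fit the dwell times:

```python
import numpy as np
import tracefret as tf
from tracefret.classify import segments_from_labels

km = tf.KineticModel(
    n_states=2,
    rates=np.array([[-1 / 1.75, 1 / 1.75], [1 / 2.65, -1 / 2.65]]),
    fret={"DA": np.array([0.81, 0.14])},
)
det = tf.DetectionModel(alpha={"DA": 0.05}, delta={"DA": 0.08}, gamma={"DA": 1.15})
rng = np.random.default_rng(7)
alphabet = tf.CategoryAlphabet("2c_alex")

traces, segs = [], []
for i in range(300):
    pm = tf.PhotophysicsModel(
        bleach_rate={"D": 1 / 120.0, "A": 1 / 120.0},
        brightness={"D": rng.uniform(800, 1200), "A": rng.uniform(700, 1100)},
    )
    _, occ = tf.sample_state_path(km, 2000, 0.05, rng)
    tr = tf.render_trace(occ, km, pm, det, "2c_alex", rng, 0.05, snr=10.0)
    tr.trace_id = i
    traces.append(tr)
    segs.append(segments_from_labels(tr.labels, alphabet))

factors = tf.estimate_factors_dataset(traces, segs)
med = factors.medians["DA"]
print(f"alpha = {med.alpha:.4f}   delta = {med.delta:.4f}   gamma = {med.gamma:.4f}")
```

followed by transition extraction (`tf.extract_transitions` on each state
path, interior dwells only), `tf.fit_dwell_cdf` per state and
`tf.corrected_fret_2c` / `tf.fret_to_distance`, prints:

```
alpha = 0.0501   delta = 0.0801   gamma = 1.1381
state 1: tau = 1.78 s  (95% CI 1.78-1.78, n = 3081)
state 2: tau = 2.60 s  (95% CI 2.60-2.60, n = 3032)
state 1: corrected E = 0.81  ->  R = 54 A
state 2: corrected E = 0.14  ->  R = 92 A
```

All three detection factors come back within ~1% of the simulated truth,
the dwell times within ~2%, and the corrected state efficiencies map to the
expected inter-dye distances for a 68 Å Förster radius.

## Command line

```sh
tracefret simulate --modality 2c_alex --n-traces 2000 --n-frames 2000 \
    --frame-time 0.05 --seed 7 --out train.h5
tracefret train --task trace   --data train.h5 --out models/trace.joblib
tracefret train --task states2 --data train.h5 --out models/states2.joblib
tracefret run --data experiment.h5 --models models/ --threshold 0.9 --out report.json
```

Subcommands: `simulate`, `train`, `classify`, `correct`, `kinetics`,
`hmm`, `benchmark`, `run`.  Datasets are HDF5 containers (documented layout,
CSV export available) with JSON manifests carrying every ground-truth
parameter and seed.

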