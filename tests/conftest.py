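"""Shared fixtures: smoke-scale datasets and trained classifiers.

The classifier fixtures are trained once per session at the reduced smoke
scale (hundreds to a couple thousand 300-frame traces drawn from the
well-separated part of the simulation envelope: SNR 8-30, dwells 15-80
frames, FRET contrast >= 0.25) so the whole suite runs on one CPU in
minutes.
"""

import warnings

import numpy as np
import pytest

import tracefret as tf

warnings.filterwarnings("ignore", category=FutureWarning)

SMOKE = dict(
    n_frames=300,
    frame_time=0.05,
    dwell_range_frames=(15.0, 80.0),
    snr_range=(8.0, 30.0),
    min_contrast=0.25,
)


def smoke_config(modality="2c_alex", n_traces=500, seed=0, dynamic_only=False,
                 n_states=None, **overrides):
    kw = dict(SMOKE)
    kw.update(overrides)
    if dynamic_only:
        kw.setdefault("category_fractions", {
            "dynamic": 1.0, "static": 0.0, "noisy": 0.0,
            "aggregate": 0.0, "artifact": 0.0,
        })
        kw.setdefault("bleach_lifetime_frac", None)
    if n_states is not None:
        kw["n_states_choices"] = (n_states,)
    return tf.SimConfig(modality=modality, n_traces=n_traces, seed=seed, **kw)


@pytest.fixture(scope="session")
def states2_model():
    """Two-state state classifier trained at the 2000-trace smoke scale."""
    ds = tf.generate_dataset(smoke_config(n_traces=2000, seed=11, dynamic_only=True,
                                          n_states=2))
    spec = tf.build_model("2c_alex", "states2")
    return tf.train_model(spec, ds, tf.TrainConfig(seed=0, max_train_frames=250_000,
                                                   max_epochs=30))


@pytest.fixture(scope="session")
def states2_fast_model():
    """Two-state classifier trained on short dwells (5-30 frames) for
    kinetics at the frame-time scale."""
    ds = tf.generate_dataset(smoke_config(n_traces=1200, seed=41, dynamic_only=True,
                                          n_states=2, dwell_range_frames=(5.0, 30.0)))
    spec = tf.build_model("2c_alex", "states2")
    return tf.train_model(spec, ds, tf.TrainConfig(seed=0, max_train_frames=250_000,
                                                   max_epochs=30))


@pytest.fixture(scope="session")
def trace_model():
    """Trace/category classifier (full default mixture, with bleaching)."""
    ds = tf.generate_dataset(smoke_config(n_traces=1200, seed=12))
    spec = tf.build_model("2c_alex", "trace")
    return tf.train_model(spec, ds, tf.TrainConfig(seed=0, max_train_frames=200_000,
                                                   max_epochs=30))


@pytest.fixture(scope="session")
def origami_analog_dataset():
    """Simulated analog of the two-state origami pointer: tau 1.75/2.65 s,
    50 ms frames, high/low FRET 0.81/0.14, slow bleaching, SNR 10."""
    k12, k21 = 1.0 / 1.75, 1.0 / 2.65
    det = tf.DetectionModel(alpha={"DA": 0.05}, delta={"DA": 0.08}, gamma={"DA": 1.15})
    km = tf.KineticModel(2, np.array([[-k12, k12], [k21, -k21]]),
                         {"DA": np.array([0.81, 0.14])})
    rng = np.random.default_rng(42)
    traces = []
    for i in range(1000):
        pm = tf.PhotophysicsModel(
            bleach_rate={"D": 1.0 / 200.0, "A": 1.0 / 200.0},
            brightness={"D": rng.uniform(800, 1200), "A": rng.uniform(800, 1200)},
        )
        _, occ = tf.sample_state_path(km, 2000, 0.05, rng)
        tr = tf.render_trace(occ, km, pm, det, "2c_alex", rng, 0.05, snr=10.0)
        tr.trace_id = i
        traces.append(tr)
    return tf.TraceDataset(traces=traces, config=None, detection=det, manifest={})
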