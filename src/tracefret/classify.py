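"""Per-frame trace, state and number-of-states classifiers.

Architecture
------------
Each classifier couples an *omni-scale* temporal feature bank with a learned
per-frame softmax head.  The feature bank convolves every (per-trace min-max
normalized) channel with moving-average and moving-spread kernels over a
geometric spread of odd widths — covering receptive fields from a single
frame up to roughly twice the longest expected dwell — plus forward and
backward exponential-memory traces that give each frame bidirectional
context (what happened before a frame and what happens after it, e.g. on
which side of a photobleach step it lies).  A multilayer perceptron maps the
per-frame feature vector to class probabilities.  The classifier head is a
scikit-learn ``MLPClassifier``; all temporal structure lives in the feature
bank.

Tasks
-----
``trace``     per-frame category over the modality's full alphabet
              (all channels as input).
``states2/3/4``  per-frame hidden-state index on dynamic segments
              (kinetic channels only).
``n_states``  trace-level routing classifier predicting how many states a
              dynamic segment contains ({2, 3, 4}).

State indices are canonical: state 1 has the lowest expected first kinetic
channel (for FRET pairs, the highest efficiency), so indices are comparable
across traces, models and the HMM baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter
from sklearn.neural_network import MLPClassifier

from .alphabet import (
    CHANNELS,
    DYES,
    JUNK_LABELS,
    KINETIC_CHANNELS,
    CategoryAlphabet,
)
from .simulate import LabeledTrace, TraceDataset

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TraceModel",
    "FrameClassification",
    "StateClassification",
    "TraceSegments",
    "ConfusionReport",
    "build_model",
    "train_model",
    "classify_frames",
    "segment_trace",
    "segments_from_labels",
    "classify_states",
    "predict_n_states",
    "evaluate_confusion",
    "benchmark_vs_hmm",
    "match_accuracy",
    "smooth_labels",
]

TASKS = ("trace", "states2", "states3", "states4", "n_states")


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Architecture descriptor for one (modality, task) classifier."""

    modality: str
    task: str
    n_input_channels: int
    n_classes: int
    class_names: tuple
    #: odd moving-window widths of the omni-scale feature bank
    kernel_sizes: tuple[int, ...] = (3, 7, 15, 31, 61)
    #: decay constants of the bidirectional exponential-memory traces
    ema_decays: tuple[float, ...] = (0.05, 0.2)
    #: (donor, acceptor) input-channel index pairs whose scale-free ratio
    #: acc/(don+acc) is added as a derived feature series
    ratio_pairs: tuple[tuple[int, int], ...] = ()
    hidden_layers: tuple[int, ...] = (64, 32)


def build_model(modality: str, task: str) -> ModelSpec:
    """Resolve input width and class set for a (modality, task) pair.

    The trace task consumes every recorded channel; state tasks consume only
    the kinetic channels (the acceptor signal after direct acceptor
    excitation carries no kinetic information and is excluded).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if modality not in CHANNELS:
        raise ValueError(f"unknown modality {modality!r}")
    # donor/acceptor ratio features: channel index pairs within the input
    ratios = {
        "1c": (),
        "2c": ((0, 1),),
        "2c_alex": ((0, 1),),
        "3c_alex": ((0, 1), (0, 2), (3, 4)),
    }[modality]
    if task == "trace":
        alphabet = CategoryAlphabet(modality)
        return ModelSpec(
            modality=modality,
            task=task,
            n_input_channels=len(CHANNELS[modality]),
            n_classes=len(alphabet),
            class_names=alphabet.labels,
            ratio_pairs=ratios,
        )
    kin = KINETIC_CHANNELS[modality]
    if task == "n_states":
        return ModelSpec(
            modality=modality,
            task=task,
            n_input_channels=len(kin),
            n_classes=3,
            class_names=(2, 3, 4),
            ratio_pairs=ratios,
        )
    k = int(task[-1])
    return ModelSpec(
        modality=modality,
        task=task,
        n_input_channels=len(kin),
        n_classes=k,
        class_names=tuple(range(1, k + 1)),
        ratio_pairs=ratios,
    )


@dataclass
class TrainConfig:
    seed: int = 0
    max_train_frames: int = 400_000  # frames are subsampled above this
    max_epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 1e-3
    early_stopping: bool = True
    validation_fraction: float = 0.1


# --------------------------------------------------------------------------
# omni-scale feature bank
# --------------------------------------------------------------------------


def _minmax(x: np.ndarray) -> np.ndarray:
    """Robust per-trace normalization to ~[0, 1].

    The scale anchors are the 2nd/98th percentiles of a lightly smoothed
    copy, so noise extremes do not dictate the mapping; values are clipped
    to [-0.5, 1.5].
    """
    sm = uniform_filter1d(x, 5, mode="nearest")
    lo, hi = np.percentile(sm, [2.0, 98.0])
    if hi - lo <= 0:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), -0.5, 1.5)


def _ratio_series(channels: np.ndarray, i: int, j: int) -> np.ndarray:
    """Scale-free acceptor fraction acc/(don+acc) on raw counts."""
    don = channels[:, i].astype(float)
    acc = channels[:, j].astype(float)
    den = don + acc
    scale = np.abs(den).max()
    guard = den <= 0.05 * scale  # near-zero total: ratio undefined
    out = np.where(guard, 0.5, np.clip(acc, 0, None) / np.where(guard, 1.0, den))
    return np.clip(out, 0.0, 1.0)


def _global_series_features(x: np.ndarray) -> list[float]:
    """Trace-global context of one series, tiled across frames.

    Gives every frame access to whole-trace properties a per-frame window
    cannot see: overall level spread (dynamic vs static), long-lag memory,
    step counts (multiple bleach steps of an aggregate), and the
    high-frequency noise floor.
    """
    sm = uniform_filter1d(x, 15, mode="nearest")
    noise = float(np.std(np.diff(x)) / np.sqrt(2.0)) if len(x) > 1 else 0.0
    d = np.abs(np.diff(sm))
    step_thresh = 4.0 * max(noise / np.sqrt(15.0), 1e-3)
    p5, p95 = np.percentile(sm, [5.0, 95.0])
    mid = float(((sm > 0.2) & (sm < 0.8)).mean())  # plateau structure
    return [
        float(p95 - p5),
        float(sm.std()),
        _autocorr(sm, 20),
        _autocorr(sm, 50),
        float(np.log1p((d > step_thresh).sum())),
        min(noise, 2.0),
        mid,
    ]


def frame_features(channels: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Per-frame omni-scale features for one trace, shape (n_frames, n_feat)."""
    n_frames, n_ch = channels.shape
    series = [_minmax(channels[:, c].astype(float)) for c in range(n_ch)]
    series += [_ratio_series(channels, i, j) for i, j in spec.ratio_pairs]
    feats = []
    glob: list[float] = []
    for x in series:
        feats.append(x)
        # short-event contrast: deviation of a frame (and a 2-frame block)
        # from its immediate surroundings — sensitizes the head to dwells at
        # the frame-time scale that wider windows average away
        left = np.roll(x, 1)
        right = np.roll(x, -1)
        left[0], right[-1] = x[0], x[-1]
        feats.append(x - 0.5 * (left + right))
        two = 0.5 * (x + right)
        left2 = np.roll(x, 2)
        left2[:2] = x[0]
        right3 = np.roll(x, -2)
        right3[-2:] = x[-1]
        feats.append(two - 0.5 * (left2 + right3))
        for w in spec.kernel_sizes:
            m = uniform_filter1d(x, w, mode="nearest")
            m2 = uniform_filter1d(x * x, w, mode="nearest")
            feats.append(m)
            feats.append(np.sqrt(np.maximum(m2 - m * m, 0.0)))
        for a in spec.ema_decays:
            b, aa = [a], [1.0, -(1.0 - a)]
            fwd = lfilter(b, aa, x, zi=[x[0] * (1.0 - a)])[0]
            bwd = lfilter(b, aa, x[::-1], zi=[x[-1] * (1.0 - a)])[0][::-1]
            feats.append(fwd)
            feats.append(bwd)
        glob.extend(_global_series_features(x))
    # summed intensity of all channels: multi-step bleaching (aggregates)
    # shows up here regardless of which dye carries the step
    total = channels.astype(float).sum(axis=1)
    glob.extend(_global_series_features(_minmax(total)))
    # FRET dynamics isolated from bleaching: ratio statistics restricted to
    # the region where the pair's total signal is still high
    for i, j in spec.ratio_pairs[:1]:
        pair_total = channels[:, i].astype(float) + channels[:, j].astype(float)
        sm_tot = uniform_filter1d(pair_total, 9, mode="nearest")
        mask = sm_tot > 0.5 * np.percentile(sm_tot, 90)
        r = _ratio_series(channels, i, j)
        if mask.sum() >= 30:
            glob.extend(_global_series_features(r[mask]))
        else:
            glob.extend([0.0] * 7)
    # scale-invariant per-channel SNR estimate (counts cancel): mean signal
    # over high-frequency noise of the *raw* channel — absolute SNR context
    # that per-trace normalization would otherwise erase
    for c in range(n_ch):
        raw = channels[:, c].astype(float)
        noise = float(np.std(np.diff(raw)) / np.sqrt(2.0)) if len(raw) > 1 else 0.0
        snr_est = abs(float(raw.mean())) / max(noise, 1e-9)
        glob.append(float(np.log1p(min(snr_est, 100.0))))
    out = np.stack(feats, axis=1)
    return np.concatenate([out, np.tile(glob, (n_frames, 1))], axis=1)


def _trace_level_features(channels: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Summary features of a dynamic segment for the n-states classifier.

    Level multiplicity shows up in the histogram of the smoothed primary
    observable (acceptor ratio when a pair exists, else normalized
    intensity); autocorrelation and increment statistics add time-scale
    context.
    """
    if spec.ratio_pairs:
        i, j = spec.ratio_pairs[0]
        obs = _ratio_series(channels, i, j)
    else:
        obs = _minmax(channels[:, 0].astype(float))
    sm = uniform_filter1d(obs, 5, mode="nearest")
    hist, _ = np.histogram(sm, bins=24, range=(0.0, 1.0), density=True)
    x = _minmax(channels[:, 0].astype(float))
    sx = uniform_filter1d(x, 5, mode="nearest")
    hist2, _ = np.histogram(sx, bins=24, range=(0.0, 1.0), density=True)
    d = np.diff(sm)
    ac = [_autocorr(sm, lag) for lag in (1, 2, 5, 10, 20)]
    extra = [sm.std(), np.abs(d).mean(), d.std()]
    # level-multiplicity profile: how much 1-D clustering with k centers
    # reduces the spread of the smoothed observable
    var = max(float(sm.var()), 1e-12)
    inertia = [_kmeans_inertia_1d(sm, k) / var for k in (1, 2, 3, 4, 5)]
    return np.concatenate([hist, hist2, ac, extra, inertia])


def _kmeans_inertia_1d(x: np.ndarray, k: int, n_iter: int = 12) -> float:
    """Within-cluster sum of squares per point for 1-D k-means."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            sel = x[assign == j]
            if len(sel):
                centers[j] = sel.mean()
    d = np.min(np.abs(x[:, None] - centers[None, :]), axis=1)
    return float((d**2).mean())


def _autocorr(x: np.ndarray, lag: int) -> float:
    if len(x) <= lag + 1:
        return 0.0
    a, b = x[:-lag], x[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


# --------------------------------------------------------------------------
# trained model wrapper
# --------------------------------------------------------------------------


@dataclass
class TraceModel:
    """A trained classifier: feature bank + MLP head + bookkeeping."""

    spec: ModelSpec
    mlp: MLPClassifier
    history: dict = field(default_factory=dict)

    def _inputs(self, trace_channels: np.ndarray) -> np.ndarray:
        if self.spec.task == "trace":
            take = slice(None)
        else:
            take = list(KINETIC_CHANNELS[self.spec.modality])
        x = trace_channels[:, take]
        if x.shape[1] != self.spec.n_input_channels:
            raise ValueError(
                f"expected {self.spec.n_input_channels} input channels, got {x.shape[1]}"
            )
        return x

    def predict_proba_frames(self, trace_channels: np.ndarray) -> np.ndarray:
        """(n_frames, n_classes) probabilities; rows sum to 1."""
        x = self._inputs(trace_channels)
        if self.spec.task == "n_states":
            feats = _trace_level_features(x, self.spec)[None, :]
            p = self.mlp.predict_proba(feats)
            return np.repeat(p, x.shape[0], axis=0)
        feats = frame_features(x, self.spec)
        return self._proba_full(feats)

    def _proba_full(self, feats: np.ndarray) -> np.ndarray:
        """predict_proba padded to all classes (guards sklearn class subset)."""
        p_fit = self.mlp.predict_proba(feats)
        if p_fit.shape[1] == self.spec.n_classes:
            return p_fit
        p = np.zeros((feats.shape[0], self.spec.n_classes))
        p[:, np.asarray(self.mlp.classes_, dtype=int)] = p_fit
        return p


def _collect_training_frames(spec: ModelSpec, dataset: TraceDataset):
    """Stack per-frame feature matrices and integer targets for a task."""
    xs, ys = [], []
    alphabet = CategoryAlphabet(spec.modality)
    for trace in dataset:
        if trace.modality != spec.modality:
            raise ValueError("dataset modality does not match model spec")
        if spec.task == "trace":
            feats = frame_features(trace.channels, spec)
            xs.append(feats)
            ys.append(trace.labels)
        elif spec.task == "n_states":
            k = trace.kinetic_model.n_states if trace.kinetic_model else 0
            if k not in (2, 3, 4):
                continue
            x = trace.channels[:, list(KINETIC_CHANNELS[spec.modality])]
            mask = trace.states > 0
            if mask.sum() < 20:
                continue
            xs.append(_trace_level_features(x[mask], spec)[None, :])
            ys.append(np.array([k - 2]))
        else:
            k = int(spec.task[-1])
            if trace.kinetic_model is None or trace.kinetic_model.n_states != k:
                continue
            mask = trace.states > 0
            if not mask.any():
                continue
            x = trace.channels[:, list(KINETIC_CHANNELS[spec.modality])]
            feats = frame_features(x, spec)
            xs.append(feats[mask])
            ys.append(trace.states[mask] - 1)
            # transition frames are rare but decide whether dwells at the
            # frame-time scale are detected at all: oversample them
            edge = np.zeros(len(mask), dtype=bool)
            change = np.flatnonzero(np.diff(trace.states)) + 1
            for c in change:
                edge[max(c - 2, 0) : c + 2] = True
            edge &= mask
            if edge.any():
                xs.append(np.repeat(feats[edge], 2, axis=0))
                ys.append(np.repeat(trace.states[edge] - 1, 2))
    if not xs:
        raise ValueError(f"no training data for task {spec.task!r}")
    return np.concatenate(xs), np.concatenate(ys)


def train_model(
    spec: ModelSpec, dataset: TraceDataset, config: TrainConfig | None = None
) -> TraceModel:
    """Fit the classifier head on a labeled dataset.

    Frames are pooled across traces (per-trace normalization already
    happened in the feature bank) and subsampled to ``max_train_frames``.
    Raises if any of the model's classes is absent from the training data.
    """
    config = config or TrainConfig()
    X, y = _collect_training_frames(spec, dataset)
    present = np.unique(y)
    if len(present) < spec.n_classes and spec.task != "trace":
        missing = sorted(set(range(spec.n_classes)) - set(present.tolist()))
        names = [spec.class_names[m] for m in missing]
        raise ValueError(f"classes absent from training data: {names}")

    rng = np.random.default_rng(config.seed)
    if X.shape[0] > config.max_train_frames:
        idx = rng.choice(X.shape[0], config.max_train_frames, replace=False)
        X, y = X[idx], y[idx]

    mlp = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        batch_size=config.batch_size,
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=5,
        random_state=int(rng.integers(2**31 - 1)),
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    history = {
        "loss_curve": [float(v) for v in mlp.loss_curve_],
        "n_train_frames": int(X.shape[0]),
        "train_accuracy": float(mlp.score(X, y)),
    }
    return TraceModel(spec=spec, mlp=mlp, history=history)


# --------------------------------------------------------------------------
# inference products
# --------------------------------------------------------------------------


@dataclass
class FrameClassification:
    """Per-frame category probabilities for one trace."""

    prob: np.ndarray  # (n_frames, n_classes)
    labels: np.ndarray  # argmax codes
    class_names: tuple
    confidence: float  # mean top-class probability over non-bleached frames
    accepted: bool  # confidence >= threshold
    threshold: float


@dataclass
class StateClassification:
    """Per-frame state calls on a dynamic segment (canonical indices)."""

    states: np.ndarray  # 1-based
    p: np.ndarray  # per-frame probability of the called state
    confidence: float  # mean of p


@dataclass
class TraceSegments:
    """Intervals derived from (smoothed) per-frame labels."""

    analysis: tuple[int, int] | None  # [start, end) all-dyes-active run
    dynamic: bool
    bleach_frame: dict[str, int | None]
    background: tuple[int, int] | None  # [start, end) all-bleached run
    junk: bool
    smoothed_labels: np.ndarray


def smooth_labels(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Absorb label islands shorter than ``min_run`` into their neighbors.

    Short runs are merged into the longer adjacent run, repeatedly, so a
    single-frame flicker inside a long segment disappears while genuine
    segment boundaries stay put.
    """
    codes = codes.copy()
    if min_run <= 1:
        return codes
    while True:
        starts, lengths, values = _runs(codes)
        if len(values) <= 1:
            return codes
        short = np.where(lengths < min_run)[0]
        # never absorb everything: keep the longest run as anchor
        short = [i for i in short if lengths[i] < lengths.max()]
        if not short:
            return codes
        i = min(short, key=lambda j: lengths[j])
        left_len = lengths[i - 1] if i > 0 else -1
        right_len = lengths[i + 1] if i < len(values) - 1 else -1
        src = i - 1 if left_len >= right_len else i + 1
        codes[starts[i] : starts[i] + lengths[i]] = values[src]


def _runs(codes: np.ndarray):
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(codes)]])
    return starts, ends - starts, codes[starts]


def segments_from_labels(
    codes: np.ndarray, alphabet: CategoryAlphabet, min_run: int = 3
) -> TraceSegments:
    """Derive analysis/bleach/background segments from per-frame labels.

    Works identically on ground-truth labels and on classifier output; an
    unusable trace yields an empty result (``analysis=None``), never an
    exception.
    """
    codes = smooth_labels(np.asarray(codes), min_run=min_run)
    junk_codes = {alphabet.index(j) for j in JUNK_LABELS}
    junk_frames = np.isin(codes, list(junk_codes))
    if junk_frames.mean() > 0.5:
        return TraceSegments(None, False, {d: None for d in DYES[alphabet.modality]},
                             None, True, codes)

    dyes = DYES[alphabet.modality]
    active = np.zeros((len(codes), len(dyes)), dtype=bool)
    for code in np.unique(codes):
        act = alphabet.active_dyes(alphabet.labels[code])
        row = np.array([d in act for d in dyes])
        active[codes == code] = row

    all_active = active.all(axis=1)
    analysis = _longest_true_run(all_active)
    dynamic = False
    if analysis is not None:
        seg_codes = codes[analysis[0] : analysis[1]]
        dynamic = (seg_codes == alphabet.index(alphabet.dynamic_label)).mean() > 0.5

    bleach_frame: dict[str, int | None] = {}
    for k, d in enumerate(dyes):
        on = np.flatnonzero(active[:, k])
        if len(on) == 0:
            bleach_frame[d] = 0
        elif on[-1] == len(codes) - 1:
            bleach_frame[d] = None  # photoactive until the end
        else:
            bleach_frame[d] = int(on[-1] + 1)

    background = _longest_true_run(~active.any(axis=1))
    return TraceSegments(analysis, dynamic, bleach_frame, background, False, codes)


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    starts, lengths, values = _runs(mask.astype(np.int8))
    best = None
    for s, l, v in zip(starts, lengths, values):
        if v and (best is None or l > best[1] - best[0]):
            best = (int(s), int(s + l))
    return best


def classify_frames(
    model: TraceModel, trace: LabeledTrace | np.ndarray, threshold: float = 0.9
) -> FrameClassification:
    """Run the trace classifier on one trace and apply the confidence gate.

    Confidence is the mean probability of the called class over frames not
    called fully bleached; traces below ``threshold`` are flagged for
    discard (the gate is user-adjustable).
    """
    channels = trace.channels if isinstance(trace, LabeledTrace) else trace
    if channels.shape[0] < max(model.spec.kernel_sizes):
        raise ValueError("trace shorter than the widest feature kernel")
    prob = model.predict_proba_frames(channels)
    codes = np.argmax(prob, axis=1)
    top = prob[np.arange(len(codes)), codes]
    alphabet = CategoryAlphabet(model.spec.modality)
    bleached = codes == alphabet.index("bleached")
    conf = float(top[~bleached].mean()) if (~bleached).any() else 0.0
    return FrameClassification(
        prob=prob,
        labels=codes,
        class_names=model.spec.class_names,
        confidence=conf,
        accepted=conf >= threshold,
        threshold=threshold,
    )


def segment_trace(fc: FrameClassification, min_run: int = 3) -> TraceSegments:
    """Segment a classified trace (see :func:`segments_from_labels`)."""
    alphabet = CategoryAlphabet(_modality_from_classes(fc.class_names))
    return segments_from_labels(fc.labels, alphabet, min_run=min_run)


def _modality_from_classes(class_names) -> str:
    for m in CHANNELS:
        if tuple(CategoryAlphabet(m).labels) == tuple(class_names):
            return m
    raise ValueError("class names do not match any modality alphabet")


def classify_states(model: TraceModel, segment_channels: np.ndarray) -> StateClassification:
    """Per-frame state calls on the kinetic channels of a dynamic segment."""
    prob = model.predict_proba_frames(segment_channels)
    idx = np.argmax(prob, axis=1)
    p = prob[np.arange(len(idx)), idx]
    return StateClassification(states=idx + 1, p=p, confidence=float(p.mean()))


def predict_n_states(model: TraceModel, segment_channels: np.ndarray) -> np.ndarray:
    """Probability vector over {2, 3, 4} states for a dynamic segment."""
    if model.spec.task != "n_states":
        raise ValueError("model is not a number-of-states classifier")
    return model.predict_proba_frames(segment_channels)[0]


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class ConfusionReport:
    confusion: np.ndarray  # row-normalized (recall matrix)
    counts: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    accuracy: float
    class_names: tuple


def evaluate_confusion(model: TraceModel, dataset: TraceDataset) -> ConfusionReport:
    """Frame-wise confusion of a classifier against ground-truth labels."""
    from sklearn.metrics import confusion_matrix

    y_true, y_pred = [], []
    for trace in dataset:
        if model.spec.task == "trace":
            prob = model.predict_proba_frames(trace.channels)
            y_pred.append(np.argmax(prob, axis=1))
            y_true.append(trace.labels)
        else:
            k = int(model.spec.task[-1])
            if trace.kinetic_model is None or trace.kinetic_model.n_states != k:
                continue
            mask = trace.states > 0
            if trace.pure_frames is not None:
                # frames spanning a sub-frame transition have no
                # well-defined state label and are not scored
                mask &= trace.pure_frames
            if not mask.any():
                continue
            x = trace.channels[:, list(KINETIC_CHANNELS[model.spec.modality])]
            sc = classify_states(model, x)
            y_pred.append(sc.states[mask] - 1)
            y_true.append(trace.states[mask] - 1)
    y_true = np.concatenate(y_true)
    y_pred = np.concatenate(y_pred)
    labels = np.arange(model.spec.n_classes)
    counts = confusion_matrix(y_true, y_pred, labels=labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = counts / counts.sum(axis=1, keepdims=True)
        precision = np.diag(counts) / counts.sum(axis=0)
        recall = np.diag(counts) / counts.sum(axis=1)
    return ConfusionReport(
        confusion=np.nan_to_num(norm),
        counts=counts,
        precision=np.nan_to_num(precision),
        recall=np.nan_to_num(recall),
        accuracy=float((y_true == y_pred).mean()),
        class_names=model.spec.class_names,
    )


def match_accuracy(pred: np.ndarray, truth: np.ndarray, n_states: int) -> float:
    """Frame accuracy under the best label permutation (<= 4 states).

    Canonical ordering should already align labels, but methods that assign
    arbitrary labels (e.g. an HMM fit) are scored on the matching that is
    most favorable to them.
    """
    best = 0.0
    for perm in permutations(range(n_states)):
        mapped = np.array(perm)[pred - 1] + 1
        best = max(best, float((mapped == truth).mean()))
    return best


def benchmark_vs_hmm(
    state_model: TraceModel,
    snr_values=(1.0, 3.0, 10.0),
    contrast_values=(0.2, 0.4),
    dwell_frames_values=(10.0, 30.0),
    n_traces: int = 20,
    n_frames: int = 300,
    frame_time: float = 0.05,
    seed: int = 0,
):
    """Grid comparison of the state classifier against the local HMM.

    For each (SNR, FRET contrast, dwell) cell, freshly simulated two-state
    traces (no bleaching, ideal detection) are decoded by both methods and
    per-frame accuracy against the ground-truth path is averaged.  Returns a
    pandas DataFrame with one row per cell.
    """
    import pandas as pd

    from .corrections import apparent_fret
    from .hmm import fit_local_hmm
    from .simulate import (
        DetectionModel,
        KineticModel,
        PhotophysicsModel,
        render_trace,
        sample_state_path,
    )

    modality = state_model.spec.modality
    rng = np.random.default_rng(seed)
    rows = []
    for snr in snr_values:
        for contrast in contrast_values:
            for dwell in dwell_frames_values:
                acc_clf, acc_hmm = [], []
                for _ in range(n_traces):
                    e_mid = rng.uniform(0.3, 0.7)
                    fret = np.array([e_mid + contrast / 2, e_mid - contrast / 2])
                    k = 1.0 / (dwell * frame_time)
                    kmodel = KineticModel(
                        n_states=2,
                        rates=np.array([[-k, k], [k, -k]]),
                        fret={"DA": fret} if modality != "1c" else {"L": fret},
                    )
                    dyes = DYES[modality]
                    pmodel = PhotophysicsModel(
                        bleach_rate={d: 0.0 for d in dyes},
                        brightness={d: 1000.0 for d in dyes},
                    )
                    _, occ = sample_state_path(kmodel, n_frames, frame_time, rng)
                    trace = render_trace(
                        occ, kmodel, pmodel, DetectionModel.ideal(modality),
                        modality, rng, frame_time, snr=snr,
                    )
                    truth = trace.states
                    pure = (
                        trace.pure_frames
                        if trace.pure_frames is not None
                        else np.ones(len(truth), dtype=bool)
                    )
                    x = trace.channels[:, list(KINETIC_CHANNELS[modality])]
                    sc = classify_states(state_model, x)
                    acc_clf.append(
                        match_accuracy(sc.states[pure], truth[pure], 2)
                    )
                    obs = np.asarray(
                        trace.channels[:, 0]
                        if modality == "1c"
                        else apparent_fret(trace)["DA"]
                    )
                    ok = np.isfinite(obs)
                    fit = fit_local_hmm(obs[ok], n_states=2, max_iter=1000)
                    acc_hmm.append(
                        match_accuracy(
                            (fit.viterbi + 1)[pure[ok]], truth[ok][pure[ok]], 2
                        )
                    )
                rows.append(
                    {
                        "snr": snr,
                        "contrast": contrast,
                        "dwell_frames": dwell,
                        "classifier_accuracy": float(np.mean(acc_clf)),
                        "hmm_accuracy": float(np.mean(acc_hmm)),
                    }
                )
    return pd.DataFrame(rows)
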