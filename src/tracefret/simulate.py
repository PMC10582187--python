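"""Forward simulation of labeled single-molecule fluorescence trajectories.

Molecules hop between up to four conformational states following a
continuous-time Markov chain; each state has fixed FRET efficiencies for the
dye pairs present.  The chain is sampled exactly (exponential waiting times),
and each camera frame records the *time-averaged* state occupancy, so
transitions inside a frame produce genuinely mixed frames — the hard case a
per-frame classifier has to cope with at time scales comparable to the
acquisition time.

Dyes photobleach in single exponential steps; afterwards their contributions
(including FRET quenching of their donors) vanish.  Detection imperfections
(spectral crosstalk alpha, direct acceptor excitation delta, relative
detection efficiency gamma) are mixed into the noise-free expected channels
so that the correction formulas in :mod:`tracefret.corrections` invert the
forward model exactly.  Additive Gaussian read noise is parameterized by a
signal-to-noise ratio: SNR = (summed brightness of the dyes) / (per-channel
noise sigma).

Besides analyzable traces the generator produces the three junk categories a
trace classifier must learn to reject: high-noise traces, multi-molecule
aggregates (several bleach steps per dye), and artifact traces with
uncorrelated intensity jumps, drifts and blinking-like dips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .alphabet import (
    CHANNELS,
    DYES,
    MODALITIES,
    PAIRS,
    CategoryAlphabet,
    n_channels,
)

__all__ = [
    "KineticModel",
    "PhotophysicsModel",
    "DetectionModel",
    "SimConfig",
    "LabeledTrace",
    "TraceDataset",
    "sample_kinetic_model",
    "sample_state_path",
    "render_trace",
    "make_junk_trace",
    "generate_dataset",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class KineticModel:
    """Hidden-state kinetics: rate matrix plus per-state observables.

    ``rates[i, j]`` (i != j) is the transition rate i -> j in 1/s; diagonal
    entries are minus the row sum, so each row sums to zero and the mean
    dwell time of state i is ``-1 / rates[i, i]``.  ``fret`` maps each dye
    pair to the per-state FRET efficiency; for 1-color data the single key
    ``"L"`` holds the per-state relative brightness level instead.
    """

    n_states: int
    rates: np.ndarray
    fret: dict[str, np.ndarray]

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if not 1 <= self.n_states <= 4:
            raise ValueError("n_states must be in 1..4")
        if self.rates.shape != (self.n_states, self.n_states):
            raise ValueError("rate matrix shape mismatch")
        off = self.rates[~np.eye(self.n_states, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.rates.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate matrix rows must sum to 0")
        self.fret = {k: np.asarray(v, dtype=float) for k, v in self.fret.items()}
        for key, e in self.fret.items():
            if e.shape != (self.n_states,):
                raise ValueError(f"fret[{key!r}] must have one value per state")
            if np.any((e < 0) | (e > 1)):
                raise ValueError("efficiencies must lie in [0, 1]")

    @property
    def mean_dwell_s(self) -> np.ndarray:
        """Mean dwell time per state in seconds (inf for absorbing/1-state)."""
        diag = np.diag(self.rates)
        with np.errstate(divide="ignore"):
            return np.where(diag < 0, -1.0 / np.where(diag < 0, diag, -1), np.inf)

    def stationary_distribution(self) -> np.ndarray:
        if self.n_states == 1:
            return np.ones(1)
        # left null vector of the rate matrix
        w, v = np.linalg.eig(self.rates.T)
        idx = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class PhotophysicsModel:
    """Single-step exponential bleaching and brightness per dye."""

    bleach_rate: dict[str, float]  # 1/s, 0 disables bleaching
    brightness: dict[str, float]  # total detected counts/frame when unquenched

    def __post_init__(self):
        for dye, r in self.bleach_rate.items():
            if r < 0:
                raise ValueError(f"bleach_rate[{dye!r}] must be >= 0")
        for dye, b in self.brightness.items():
            if b <= 0:
                raise ValueError(f"brightness[{dye!r}] must be > 0")


@dataclass
class DetectionModel:
    """Detection imperfections per dye pair plus additive channel noise."""

    alpha: dict[str, float]  # donor crosstalk into acceptor channel
    delta: dict[str, float]  # direct acceptor excitation by donor laser
    gamma: dict[str, float]  # acceptor/donor detection-efficiency ratio
    noise_sigma: float | None = None  # counts/frame; None -> derive from SNR

    def __post_init__(self):
        for name, d in (("alpha", self.alpha), ("delta", self.delta)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] must be >= 0")
        for k, v in self.gamma.items():
            if v <= 0:
                raise ValueError(f"gamma[{k!r}] must be > 0")

    @classmethod
    def ideal(cls, modality: str) -> "DetectionModel":
        pairs = PAIRS[modality]
        return cls(
            alpha={p: 0.0 for p in pairs},
            delta={p: 0.0 for p in pairs},
            gamma={p: 1.0 for p in pairs},
            noise_sigma=None,
        )


@dataclass
class SimConfig:
    """Simulation envelope and dataset composition.

    Defaults follow the training envelope used throughout: FRET efficiencies
    in [0.01, 0.99], dwell times of 1-100 frames (log-uniform) and SNR of
    0.3-50 (log-uniform).  ``category_fractions`` controls the mixture of
    trace categories; fractions must sum to 1.
    """

    modality: str = "2c_alex"
    n_traces: int = 100
    n_frames: int = 2000
    frame_time: float = 0.05  # s
    seed: int = 0
    e_range: tuple[float, float] = (0.01, 0.99)
    dwell_range_frames: tuple[float, float] = (1.0, 100.0)
    snr_range: tuple[float, float] = (0.3, 50.0)
    category_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "dynamic": 0.35,
            "static": 0.25,
            "noisy": 0.15,
            "aggregate": 0.125,
            "artifact": 0.125,
        }
    )
    n_states_choices: tuple[int, ...] = (2, 3, 4)  # for dynamic traces
    min_contrast: float = 0.1  # minimum pairwise per-state FRET separation
    brightness_range: tuple[float, float] = (500.0, 1500.0)
    # expected bleach time as a fraction of the trace duration is drawn
    # uniformly from this window; None disables bleaching entirely
    bleach_lifetime_frac: tuple[float, float] | None = (0.3, 1.2)
    noisy_snr_range: tuple[float, float] = (0.3, 0.9)  # junk "noisy" traces
    detection: DetectionModel | None = None  # None -> sampled per dataset

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_frames < 2 or self.n_traces < 1:
            raise ValueError("n_frames/n_traces too small")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        total = sum(self.category_fractions.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError("category fractions must sum to 1")
        if any(v < 0 for v in self.category_fractions.values()):
            raise ValueError("category fractions must be >= 0")
        lo, hi = self.e_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("e_range must satisfy 0 <= lo <= hi <= 1")
        lo, hi = self.dwell_range_frames
        if not (0 < lo <= hi):
            raise ValueError("dwell range must be positive and ordered")


@dataclass
class LabeledTrace:
    """One simulated trajectory with full per-frame ground truth.

    ``labels`` holds integer codes into ``CategoryAlphabet(modality).labels``.
    ``states`` holds 1-based state indices on frames where the molecule is
    analyzable (all dyes photoactive, non-junk) and 0 elsewhere.
    """

    modality: str
    channels: np.ndarray  # (n_frames, n_channels) float counts
    labels: np.ndarray  # (n_frames,) int codes
    states: np.ndarray  # (n_frames,) int, 0 = undefined
    frame_time: float
    snr: float
    #: frames whose ground-truth state is unambiguous (no sub-frame
    #: transition inside the exposure); None when not simulated
    pure_frames: np.ndarray | None = None
    trace_id: int = 0
    kinetic_model: KineticModel | None = None
    photophysics: PhotophysicsModel | None = None
    detection: DetectionModel | None = None
    bleach_time_s: dict[str, float] = field(default_factory=dict)
    category: str = ""  # trace-level category the generator drew

    @property
    def n_frames(self) -> int:
        return self.channels.shape[0]

    @property
    def alphabet(self) -> CategoryAlphabet:
        return CategoryAlphabet(self.modality)


@dataclass
class TraceDataset:
    traces: list[LabeledTrace]
    config: SimConfig
    detection: DetectionModel
    manifest: dict

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    if lo == hi:
        return np.full(size, float(lo)) if size else float(lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _min_gap_uniform(rng, lo: float, hi: float, n: int, gap: float) -> np.ndarray:
    """n values uniform over the set with all pairwise distances >= gap.

    Spacing transform: uniform order statistics on the shrunken interval,
    shifted apart by the gap, then randomly permuted (states carry no order
    at this point).
    """
    if n == 1:
        return rng.uniform(lo, hi, size=1)
    span = max((hi - lo) - (n - 1) * gap, 0.0)
    u = np.sort(rng.uniform(0.0, span, size=n)) if span > 0 else np.zeros(n)
    vals = lo + u + gap * np.arange(n)
    return vals[rng.permutation(n)]


def _canonical_order(modality: str, fret: dict[str, np.ndarray]) -> np.ndarray:
    """State permutation sorting by ascending expected first kinetic channel."""
    if modality == "1c":
        key = fret["L"]
    elif modality in ("2c", "2c_alex"):
        key = 1.0 - fret["DA"]
    else:
        key = 1.0 - fret["BY"] - fret["BR"]
    return np.argsort(key, kind="stable")


def sample_kinetic_model(
    config: SimConfig,
    rng: np.random.Generator,
    n_states: int | None = None,
) -> KineticModel:
    """Draw a random kinetic model inside the configured envelope.

    Mean dwell times are log-uniform over ``dwell_range_frames``; per-state
    efficiencies are uniform over ``e_range``, redrawn until every pair of
    states differs by at least ``min_contrast`` in each FRET coordinate.
    States are relabeled so that the expected first kinetic channel is
    ascending in the state index, which makes indices comparable across
    traces and analyses.
    """
    if n_states is None:
        n_states = int(rng.choice(config.n_states_choices))
    lo, hi = config.dwell_range_frames
    dwell_s = _log_uniform(rng, lo, hi, size=n_states) * config.frame_time

    rates = np.zeros((n_states, n_states))
    for i in range(n_states):
        k_exit = 1.0 / dwell_s[i]
        others = [j for j in range(n_states) if j != i]
        if others:
            w = rng.dirichlet(np.ones(len(others))) if len(others) > 1 else [1.0]
            for j, wj in zip(others, w):
                rates[i, j] = k_exit * wj
            rates[i, i] = -k_exit

    pairs = PAIRS[config.modality] or ("L",)
    e_lo, e_hi = config.e_range
    span = e_hi - e_lo
    if n_states > 1 and (n_states - 1) * config.min_contrast > span + 1e-12:
        raise ValueError("contrast floor infeasible for e_range and n_states")
    for _ in range(1000):
        fret = {
            p: _min_gap_uniform(rng, e_lo, e_hi, n_states, config.min_contrast)
            for p in pairs
        }
        if config.modality == "3c_alex" and np.any(fret["BY"] + fret["BR"] > 0.95):
            continue  # keep the cascade physical
        break
    else:
        raise RuntimeError("could not draw states satisfying the cascade bound")

    order = _canonical_order(config.modality, fret)
    rates = rates[np.ix_(order, order)]
    fret = {p: e[order] for p, e in fret.items()}
    return KineticModel(n_states=n_states, rates=rates, fret=fret)


def sample_state_path(
    model: KineticModel,
    n_frames: int,
    frame_time: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, float, float]], np.ndarray]:
    """Exact CTMC sample plus per-frame time-averaged occupancy.

    Returns ``(events, occupancy)`` where ``events`` is a list of
    ``(state, t_start, t_end)`` sojourns covering ``[0, T]`` and
    ``occupancy[f, s]`` is the fraction of frame ``f`` spent in state ``s``
    (rows sum to 1); sub-frame transitions therefore yield mixed frames.
    """
    T = n_frames * frame_time
    occ = np.zeros((n_frames, model.n_states))
    events: list[tuple[int, float, float]] = []

    state = int(rng.choice(model.n_states, p=model.stationary_distribution()))
    t = 0.0
    while t < T:
        k_exit = -model.rates[state, state]
        dt = rng.exponential(1.0 / k_exit) if k_exit > 0 else T - t
        t_end = min(t + dt, T)
        events.append((state, t, t_end))
        _accumulate_occupancy(occ, t, t_end, state, frame_time)
        if t + dt >= T:
            break
        p = model.rates[state].copy()
        p[state] = 0.0
        p /= p.sum()
        state = int(rng.choice(model.n_states, p=p))
        t += dt
    return events, occ


def _accumulate_occupancy(occ, t0, t1, state, frame_time):
    n = occ.shape[0]
    f0 = min(int(t0 / frame_time), n - 1)
    f1 = min(int(t1 / frame_time), n - 1)
    if t1 >= n * frame_time:
        f1 = n - 1
    if f0 == f1:
        occ[f0, state] += (t1 - t0) / frame_time
        return
    occ[f0, state] += f0 + 1 - t0 / frame_time
    if f1 > f0 + 1:
        occ[f0 + 1 : f1, state] += 1.0
    occ[f1, state] += min(t1 / frame_time, n) - f1


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _active_fraction(bleach_t: float, n_frames: int, frame_time: float):
    """Per-frame fraction of the exposure during which the dye still emits."""
    edges = np.arange(n_frames) * frame_time
    return np.clip((bleach_t - edges) / frame_time, 0.0, 1.0)


def _expected_channels_2c(e_da, a_d, a_a, I_D, I_A, det):
    """Noise-free 2-color ALEX channels given frame-averaged efficiency."""
    al, de, ga = det.alpha["DA"], det.delta["DA"], det.gamma["DA"]
    e_eff = e_da * a_a  # acceptor bleach removes quenching
    I_dd = I_D * a_d * (1.0 - e_eff)
    F = ga * I_D * a_d * e_eff  # sensitized emission (gamma-weighted)
    I_aa = I_A * a_a
    I_da = F + al * I_dd + de * I_aa
    return I_dd, I_da, I_aa


def _expected_channels_3c(e_by, e_br, e_yr, a_b, a_y, a_r, I_B, I_Y, I_R, det):
    """Noise-free 3-color ALEX channels (blue + yellow + red blocks)."""
    e_by_eff = e_by * a_y
    e_br_eff = e_br * a_r
    e_yr_eff = e_yr * a_r
    # yellow-excitation block behaves like a 2-color pair
    I_yy = I_Y * a_y * (1.0 - e_yr_eff)
    I_rr = I_R * a_r
    F_yr = det.gamma["YR"] * I_Y * a_y * e_yr_eff
    I_yr = F_yr + det.alpha["YR"] * I_yy + det.delta["YR"] * I_rr
    # blue-excitation block: energy cascade B -> Y -> R
    S_b = I_B * a_b * (1.0 - e_by_eff - e_br_eff)
    S_y = I_B * a_b * e_by_eff * (1.0 - e_yr_eff)
    S_r = I_B * a_b * (e_br_eff + e_by_eff * e_yr_eff)
    I_bb = S_b
    I_by = det.gamma["BY"] * S_y + det.alpha["BY"] * S_b + det.delta["BY"] * I_yy
    I_br = det.gamma["BR"] * S_r + det.alpha["BR"] * S_b + det.delta["BR"] * I_rr
    return I_bb, I_by, I_br, I_yy, I_yr, I_rr


def render_trace(
    occupancy: np.ndarray,
    kmodel: KineticModel,
    pmodel: PhotophysicsModel,
    dmodel: DetectionModel,
    modality: str,
    rng: np.random.Generator,
    frame_time: float,
    snr: float | None = None,
    dynamic: bool | None = None,
    bleach_time_s: dict[str, float] | None = None,
) -> LabeledTrace:
    """Render noise-plus-bleaching channels and ground-truth labels.

    Bleach times are drawn exponentially per dye unless supplied.  The
    per-channel noise sigma is ``dmodel.noise_sigma`` if set, else the summed
    dye brightness divided by ``snr``.
    """
    n_frames = occupancy.shape[0]
    dyes = DYES[modality]
    alphabet = CategoryAlphabet(modality)
    if dynamic is None:
        dynamic = kmodel.n_states > 1

    if bleach_time_s is None:
        bleach_time_s = {}
        for dye in dyes:
            rate = pmodel.bleach_rate.get(dye, 0.0)
            bleach_time_s[dye] = rng.exponential(1.0 / rate) if rate > 0 else np.inf

    frac = {d: _active_fraction(bleach_time_s[d], n_frames, frame_time) for d in dyes}

    if modality == "1c":
        level = occupancy @ kmodel.fret["L"]
        sig = pmodel.brightness["D"] * frac["D"] * level
        channels = sig[:, None]
        total_bright = pmodel.brightness["D"]
    elif modality in ("2c", "2c_alex"):
        e_da = occupancy @ kmodel.fret["DA"]
        I_dd, I_da, I_aa = _expected_channels_2c(
            e_da, frac["D"], frac["A"], pmodel.brightness["D"], pmodel.brightness["A"], dmodel
        )
        cols = [I_dd, I_da] if modality == "2c" else [I_dd, I_da, I_aa]
        channels = np.stack(cols, axis=1)
        total_bright = pmodel.brightness["D"] + pmodel.brightness["A"]
    else:
        if np.any(kmodel.fret["BY"] + kmodel.fret["BR"] > 1.0):
            raise ValueError("E_BY + E_BR exceeds 1 for some state")
        e_by = occupancy @ kmodel.fret["BY"]
        e_br = occupancy @ kmodel.fret["BR"]
        e_yr = occupancy @ kmodel.fret["YR"]
        chans = _expected_channels_3c(
            e_by, e_br, e_yr, frac["B"], frac["Y"], frac["R"],
            pmodel.brightness["B"], pmodel.brightness["Y"], pmodel.brightness["R"], dmodel,
        )
        channels = np.stack(chans, axis=1)
        total_bright = sum(pmodel.brightness[d] for d in dyes)

    if dmodel.noise_sigma is not None:
        sigma = dmodel.noise_sigma
    elif snr is not None and snr > 0:
        sigma = total_bright / snr
    else:
        sigma = 0.0
    if sigma > 0:
        channels = channels + rng.normal(0.0, sigma, size=channels.shape)

    # ground-truth labels: a dye counts as active while it covers >50% of the
    # frame; dynamic/static only applies while every dye is active
    active = {d: frac[d] > 0.5 for d in dyes}
    bits = np.zeros(n_frames, dtype=np.int64)
    for k, d in enumerate(dyes):
        bits |= active[d].astype(np.int64) << k
    labels = np.empty(n_frames, dtype=np.int64)
    for pattern in np.unique(bits):
        act = frozenset(d for k, d in enumerate(dyes) if (pattern >> k) & 1)
        labels[bits == pattern] = alphabet.index(alphabet.label_for(act, dynamic))

    states = np.zeros(n_frames, dtype=np.int64)
    all_active = np.logical_and.reduce([active[d] for d in dyes])
    states[all_active] = np.argmax(occupancy[all_active], axis=1) + 1

    eff_snr = total_bright / sigma if sigma > 0 else np.inf
    return LabeledTrace(
        modality=modality,
        channels=channels,
        labels=labels,
        states=states,
        frame_time=frame_time,
        snr=float(eff_snr),
        pure_frames=occupancy.max(axis=1) > 0.99,
        kinetic_model=kmodel,
        photophysics=pmodel,
        detection=dmodel,
        bleach_time_s=dict(bleach_time_s),
        category="dynamic" if dynamic else "static",
    )


# --------------------------------------------------------------------------
# junk categories
# --------------------------------------------------------------------------


def _sample_photophysics(config: SimConfig, rng) -> PhotophysicsModel:
    dyes = DYES[config.modality]
    T = config.n_frames * config.frame_time
    brightness = {d: rng.uniform(*config.brightness_range) for d in dyes}
    if config.bleach_lifetime_frac is None:
        rates = {d: 0.0 for d in dyes}
    else:
        lo, hi = config.bleach_lifetime_frac
        rates = {d: 1.0 / (rng.uniform(lo, hi) * T) for d in dyes}
    return PhotophysicsModel(bleach_rate=rates, brightness=brightness)


def make_junk_trace(
    kind: str,
    config: SimConfig,
    rng: np.random.Generator,
    detection: DetectionModel | None = None,
) -> LabeledTrace:
    """Generate a trace of one of the reject categories.

    ``noisy``  : an ordinary molecule recorded below the usability SNR floor.
    ``aggregate``: 2-3 co-located molecules, several bleach steps per dye.
    ``artifact`` : uncorrelated level jumps, drifts and blinking-like dips.
    """
    if kind not in ("noisy", "aggregate", "artifact"):
        raise ValueError(f"unknown junk kind {kind!r}")
    alphabet = CategoryAlphabet(config.modality)
    det = detection if detection is not None else DetectionModel.ideal(config.modality)

    def _base(snr):
        kmodel = sample_kinetic_model(config, rng, n_states=int(rng.choice((1, 2))))
        pmodel = _sample_photophysics(config, rng)
        _, occ = sample_state_path(kmodel, config.n_frames, config.frame_time, rng)
        return render_trace(
            occ, kmodel, pmodel, det, config.modality, rng, config.frame_time, snr=snr
        )

    if kind == "noisy":
        snr = _log_uniform(rng, *config.noisy_snr_range)
        trace = _base(snr)
    elif kind == "aggregate":
        n_mol = int(rng.choice((2, 3)))
        parts = [_base(snr=None) for _ in range(n_mol)]  # noise added once below
        channels = np.sum([p.channels for p in parts], axis=0)
        snr = _log_uniform(rng, *config.snr_range)
        sigma = channels.max() / max(snr, 1e-9)
        channels = channels + rng.normal(0.0, sigma, size=channels.shape)
        trace = parts[0]
        trace.channels = channels
        trace.snr = float(snr)
    else:  # artifact
        trace = _base(snr=_log_uniform(rng, 5.0, 30.0))
        n_frames, n_ch = trace.channels.shape
        scale = np.abs(trace.channels).max()
        # uncorrelated jumps
        for _ in range(int(rng.integers(3, 8))):
            ch = int(rng.integers(n_ch))
            f0 = int(rng.integers(n_frames - 1))
            f1 = int(rng.integers(f0 + 1, n_frames + 1))
            trace.channels[f0:f1, ch] += rng.uniform(-0.8, 1.5) * scale
        # blinking-like dips
        for _ in range(int(rng.integers(1, 4))):
            f0 = int(rng.integers(n_frames - 5))
            width = int(rng.integers(2, 12))
            trace.channels[f0 : f0 + width] *= rng.uniform(0.0, 0.3)
        # slow non-exponential drift
        drift = np.linspace(0, rng.uniform(-0.5, 0.5) * scale, n_frames)
        trace.channels += drift[:, None]

    trace.labels = np.full(config.n_frames, alphabet.index(kind), dtype=np.int64)
    trace.states = np.zeros(config.n_frames, dtype=np.int64)
    trace.category = kind
    return trace


# --------------------------------------------------------------------------
# dataset factory
# --------------------------------------------------------------------------


def _sample_detection(modality: str, rng) -> DetectionModel:
    pairs = PAIRS[modality]
    return DetectionModel(
        alpha={p: rng.uniform(0.01, 0.10) for p in pairs},
        delta={p: rng.uniform(0.01, 0.10) for p in pairs},
        gamma={p: rng.uniform(0.8, 1.3) for p in pairs},
        noise_sigma=None,
    )


def generate_dataset(config: SimConfig) -> TraceDataset:
    """Generate a reproducible labeled dataset with the configured mixture.

    The detection model (alpha/delta/gamma) is a property of the instrument
    and therefore shared by all traces of the dataset; per-trace quantities
    (kinetics, brightness, bleach times, SNR) are drawn independently.  Two
    calls with the same config produce identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    detection = config.detection
    if detection is None:
        detection = (
            DetectionModel.ideal(config.modality)
            if config.modality == "1c"
            else _sample_detection(config.modality, rng)
        )

    cats = sorted(config.category_fractions)
    probs = np.array([config.category_fractions[c] for c in cats])
    draws = rng.choice(len(cats), size=config.n_traces, p=probs)

    traces: list[LabeledTrace] = []
    for i, ci in enumerate(draws):
        cat = cats[ci]
        if cat in ("dynamic", "static"):
            n_states = (
                int(rng.choice(config.n_states_choices)) if cat == "dynamic" else 1
            )
            kmodel = sample_kinetic_model(config, rng, n_states=n_states)
            pmodel = _sample_photophysics(config, rng)
            _, occ = sample_state_path(kmodel, config.n_frames, config.frame_time, rng)
            snr = _log_uniform(rng, *config.snr_range)
            trace = render_trace(
                occ, kmodel, pmodel, detection, config.modality, rng,
                config.frame_time, snr=snr, dynamic=(cat == "dynamic"),
            )
            trace.category = cat
        else:
            trace = make_junk_trace(cat, config, rng, detection=detection)
        trace.trace_id = i
        traces.append(trace)

    manifest = {
        "config": _config_dict(config),
        "detection": {
            "alpha": detection.alpha,
            "delta": detection.delta,
            "gamma": detection.gamma,
        },
        "n_traces": len(traces),
        "categories": {c: int((draws == i).sum()) for i, c in enumerate(cats)},
        "traces": [
            {
                "trace_id": t.trace_id,
                "category": t.category,
                "snr": t.snr,
                "n_states": t.kinetic_model.n_states if t.kinetic_model else 0,
                "bleach_time_s": {
                    k: (v if np.isfinite(v) else None)
                    for k, v in t.bleach_time_s.items()
                },
            }
            for t in traces
        ],
    }
    return TraceDataset(traces=traces, config=config, detection=detection, manifest=manifest)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if d.get("detection") is not None:
        d["detection"].pop("noise_sigma", None)
    return json.loads(json.dumps(d, default=lambda o: None))
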