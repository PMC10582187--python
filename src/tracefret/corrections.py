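"""FRET correction factors, accurate efficiencies and distances.

Photobleaching is the calibration source: frames in which exactly one dye of
a pair is still photoactive reveal the detection imperfections directly.

*  crosstalk ``alpha`` — on donor-only frames (acceptor bleached) all signal
   in the acceptor detection channel after donor excitation is donor leakage:
   ``alpha = <I_DexAem> / <I_DexDem>`` (background subtracted).
*  direct excitation ``delta`` — on acceptor-only frames the donor-excitation
   acceptor signal is direct excitation: ``delta = <I_DexAem> / <I_AexAem>``.
*  detection efficiency ``gamma`` — across an acceptor bleach step inside an
   otherwise active region the sensitized emission drops by ``gamma*I_D*E``
   while the donor signal rises by ``I_D*E``, so
   ``gamma = -d<F_sens> / d<I_DexDem>`` with
   ``F_sens = I_DexAem - alpha*I_DexDem - delta*I_AexAem``.

Accurate two-color efficiency: ``E = F / (F + gamma*I_DexDem)``.

For three-color ALEX the yellow/red pair is corrected exactly like a
two-color pair from the yellow-excitation block.  The blue block is a
cascade: after removing crosstalk and direct excitation and rescaling by the
pair gammas, the corrected emissions ``I_B, I_Y, I_R`` (sum ``T``) give

    E_BY = I_Y / (T * (1 - E_YR)),     E_BR = 1 - I_B / T - E_BY,

where ``E_YR`` is the *state-averaged* corrected YR efficiency of the
frame's state — frame-wise division by ``(1 - E_YR)`` would amplify noise
dramatically near E_YR -> 1, and the state average suppresses exactly that
broadening.  ``E_YR`` is clamped at 0.95 before the division.

Efficiencies convert to distances through the Forster relation
``R = R0 * (1/E - 1)^(1/6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import PAIRS, CategoryAlphabet
from .classify import TraceSegments
from .simulate import LabeledTrace

__all__ = [
    "PairFactors",
    "CorrectionFactors",
    "estimate_alpha",
    "estimate_delta",
    "estimate_gamma",
    "estimate_factors_trace",
    "estimate_factors_dataset",
    "apparent_fret",
    "corrected_fret_2c",
    "corrected_fret_3c",
    "statewise_fret_3c",
    "fret_to_distance",
    "build_histogram",
    "HIST_BINS",
]

MIN_SEGMENT_FRAMES = 10  # shortest usable calibration segment
GAMMA_GUARD_FRAMES = 2  # frames excluded on both sides of a bleach step
EYR_CLAMP = 0.95

#: shared histogram binning: 0.02-wide bins over [-0.2, 1.2] so that
#: miscorrection (E outside [0,1]) remains visible
HIST_BINS = np.arange(-0.2, 1.2 + 1e-9, 0.02)


@dataclass
class PairFactors:
    alpha: float | None = None
    delta: float | None = None
    gamma: float | None = None


@dataclass
class CorrectionFactors:
    """Trace-wise factors plus dataset medians, per dye pair."""

    table: pd.DataFrame  # trace_id, pair, alpha, delta, gamma
    medians: dict[str, PairFactors] = field(default_factory=dict)

    def resolve(self, trace_id: int, pair: str) -> tuple[PairFactors, str]:
        """Trace-wise factors where estimable, dataset median otherwise."""
        med = self.medians.get(pair, PairFactors())
        rows = self.table[
            (self.table.trace_id == trace_id) & (self.table.pair == pair)
        ]
        out = PairFactors()
        source = []
        for name in ("alpha", "delta", "gamma"):
            val = rows[name].iloc[0] if len(rows) else None
            if val is None or (isinstance(val, float) and np.isnan(val)):
                val = getattr(med, name)
                source.append("median")
            else:
                source.append("trace")
            setattr(out, name, val)
        return out, ",".join(source)

    def resolved_table(self) -> pd.DataFrame:
        """Per-trace factors with medians filled in and their provenance.

        One row per (trace, pair) with the values that downstream
        correction would actually use and a ``source`` column
        ('trace,trace,median' style, one entry per factor).
        """
        rows = []
        for (tid, pair), _ in self.table.groupby(["trace_id", "pair"]):
            pf, source = self.resolve(tid, pair)
            rows.append(
                {"trace_id": tid, "pair": pair, "alpha": pf.alpha,
                 "delta": pf.delta, "gamma": pf.gamma, "source": source}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# channel bookkeeping
# --------------------------------------------------------------------------

#: for each (modality, pair): channel indices (Dex_Dem, Dex_Aem, Aex_Aem or
#: None), the (donor, acceptor) dye names, and dyes that must already be
#: bleached for the pair's gamma step analysis to reduce to two colors
_PAIR_LAYOUT = {
    ("2c", "DA"): ((0, 1, None), ("D", "A"), frozenset()),
    ("2c_alex", "DA"): ((0, 1, 2), ("D", "A"), frozenset()),
    ("3c_alex", "YR"): ((3, 4, 5), ("Y", "R"), frozenset()),
    ("3c_alex", "BY"): ((0, 1, 3), ("B", "Y"), frozenset({"R"})),
    ("3c_alex", "BR"): ((0, 2, 5), ("B", "R"), frozenset({"Y"})),
}


def _layout(modality: str, pair: str):
    try:
        return _PAIR_LAYOUT[(modality, pair)]
    except KeyError:
        raise ValueError(f"pair {pair!r} not defined for modality {modality!r}")


def _background(channels: np.ndarray, segments: TraceSegments) -> np.ndarray:
    """Per-channel background: mean of the all-bleached segment, else 0."""
    if segments.background is None:
        return np.zeros(channels.shape[1])
    s, e = segments.background
    if e - s < MIN_SEGMENT_FRAMES:
        return np.zeros(channels.shape[1])
    return channels[s:e].mean(axis=0)


def _frames_with(
    segments: TraceSegments, modality: str, active: set[str], inactive: set[str]
) -> np.ndarray:
    """Non-junk frames on which ``active`` dyes emit and ``inactive`` do not."""
    alphabet = CategoryAlphabet(modality)
    codes = segments.smoothed_labels
    mask = np.zeros(len(codes), dtype=bool)
    for code in np.unique(codes):
        name = alphabet.labels[code]
        if alphabet.is_junk(name):
            continue
        act = set(alphabet.active_dyes(name))
        if active <= act and not (inactive & act):
            mask |= codes == code
    return mask


# --------------------------------------------------------------------------
# factor estimators
# --------------------------------------------------------------------------


def estimate_alpha(
    trace: LabeledTrace, segments: TraceSegments, pair: str | None = None
) -> float | None:
    """Crosstalk from a donor-only segment; ``None`` if no such segment."""
    pair = pair or PAIRS[trace.modality][0]
    (i_dd, i_da, _), (don, acc), _ = _layout(trace.modality, pair)
    mask = _frames_with(segments, trace.modality, {don}, {acc})
    if mask.sum() < MIN_SEGMENT_FRAMES:
        return None
    bg = _background(trace.channels, segments)
    num = trace.channels[mask, i_da].mean() - bg[i_da]
    den = trace.channels[mask, i_dd].mean() - bg[i_dd]
    if den <= 0:
        return None
    return float(num / den)


def estimate_delta(
    trace: LabeledTrace, segments: TraceSegments, pair: str | None = None
) -> float | None:
    """Direct excitation from an acceptor-only segment (needs ALEX)."""
    pair = pair or PAIRS[trace.modality][0]
    (i_dd, i_da, i_aa), (don, acc), _ = _layout(trace.modality, pair)
    if i_aa is None:
        raise ValueError(
            "direct excitation requires an acceptor-excitation channel (ALEX); "
            f"modality {trace.modality!r} has none for pair {pair!r}"
        )
    mask = _frames_with(segments, trace.modality, {acc}, {don})
    if mask.sum() < MIN_SEGMENT_FRAMES:
        return None
    bg = _background(trace.channels, segments)
    num = trace.channels[mask, i_da].mean() - bg[i_da]
    den = trace.channels[mask, i_aa].mean() - bg[i_aa]
    if den <= 0:
        return None
    return float(num / den)


def estimate_gamma(
    trace: LabeledTrace,
    segments: TraceSegments,
    alpha: float,
    delta: float,
    pair: str | None = None,
    min_frames: int = MIN_SEGMENT_FRAMES,
) -> float | None:
    """Detection-efficiency ratio across the acceptor bleach step.

    Requires an acceptor bleach event with at least ``min_frames`` usable
    frames on both sides; ``GAMMA_GUARD_FRAMES`` frames around the step are
    excluded to avoid mixed frames.  The pre window is restricted to the
    modal state (same state regime) when a state path is available.  Returns
    ``None`` when the event or the sign of the differences is unusable.
    """
    pair = pair or PAIRS[trace.modality][0]
    (i_dd, i_da, i_aa), (don, acc), must_be_dark = _layout(trace.modality, pair)
    f_bleach = segments.bleach_frame.get(acc)
    don_bleach = segments.bleach_frame.get(don)
    if f_bleach is None or f_bleach < min_frames + GAMMA_GUARD_FRAMES:
        return None
    # donor must survive the acceptor by a usable post window
    post_end = don_bleach if don_bleach is not None else trace.n_frames
    post = np.arange(f_bleach + GAMMA_GUARD_FRAMES, min(post_end, trace.n_frames))
    pre = np.arange(0, f_bleach - GAMMA_GUARD_FRAMES)
    # both windows must show the pair active/dark pattern (third-dye dark
    # for the blue 3c pairs, so the cascade reduces to two colors)
    pre_mask = _frames_with(
        segments, trace.modality, {don, acc}, set(must_be_dark)
    )
    post_mask = _frames_with(
        segments, trace.modality, {don}, {acc} | set(must_be_dark)
    )
    pre = pre[pre_mask[pre]]
    post = post[post_mask[post]]
    if len(pre) < min_frames or len(post) < min_frames:
        return None
    # same state regime before the bleach: restrict to the modal state
    if trace.states is not None and (trace.states[pre] > 0).any():
        st = trace.states[pre]
        vals, cnt = np.unique(st[st > 0], return_counts=True)
        pre = pre[st == vals[np.argmax(cnt)]]
        if len(pre) < min_frames:
            return None
    bg = _background(trace.channels, segments)
    dd = trace.channels[:, i_dd] - bg[i_dd]
    da = trace.channels[:, i_da] - bg[i_da]
    aa = trace.channels[:, i_aa] - bg[i_aa] if i_aa is not None else np.zeros_like(dd)
    f_sens = da - alpha * dd - delta * aa
    d_f = f_sens[pre].mean() - f_sens[post].mean()
    d_dd = dd[post].mean() - dd[pre].mean()
    if d_f <= 0 or d_dd <= 0:
        return None
    return float(d_f / d_dd)


def estimate_factors_trace(
    trace: LabeledTrace,
    segments: TraceSegments,
    fallback: dict[str, PairFactors] | None = None,
) -> dict[str, PairFactors]:
    """All estimable alpha/delta/gamma for every pair of the modality.

    The gamma step analysis needs alpha and delta already resolved; where a
    trace cannot provide one (e.g. the acceptor bleached first, so no
    acceptor-only segment exists for delta), values from ``fallback``
    (typically dataset medians) are used, else gamma stays ``None``.  For
    the three-color blue pairs (BY, BR) the step analysis is only valid once
    the third dye has bleached (the blue block then reduces to an effective
    two-color pair); the active-set masks enforce that and simply yield
    ``None`` when unavailable.
    """
    fallback = fallback or {}
    out: dict[str, PairFactors] = {}
    for pair in PAIRS[trace.modality]:
        fb = fallback.get(pair, PairFactors())
        alpha = estimate_alpha(trace, segments, pair)
        try:
            delta = estimate_delta(trace, segments, pair)
        except ValueError:
            delta = None
        gamma = None
        alpha_eff = alpha if alpha is not None else fb.alpha
        delta_eff = delta if delta is not None else fb.delta
        if trace.modality == "2c" and delta is None:
            delta_eff = 0.0  # no acceptor-excitation channel at all
        if alpha_eff is not None and delta_eff is not None:
            gamma = estimate_gamma(trace, segments, alpha_eff, delta_eff, pair)
        out[pair] = PairFactors(alpha=alpha, delta=delta, gamma=gamma)
    return out


def estimate_factors_dataset(
    traces, segments_list, pairs: tuple[str, ...] | None = None
) -> CorrectionFactors:
    """Trace-wise factor table plus per-pair dataset medians.

    Two passes: alpha and delta are estimated per trace and their medians
    computed; gamma (which needs both) then uses the trace-wise value where
    available and the dataset median otherwise, mirroring how the factors
    are applied downstream.
    """
    usable = [
        (t, s) for t, s in zip(traces, segments_list) if not s.junk
    ]
    first = [estimate_factors_trace(t, s) for t, s in usable]
    pre_medians: dict[str, PairFactors] = {}
    all_pairs = pairs or tuple(
        dict.fromkeys(p for res in first for p in res)
    )
    for pair in all_pairs:
        med = PairFactors()
        for name in ("alpha", "delta"):
            vals = [
                getattr(res[pair], name)
                for res in first
                if pair in res and getattr(res[pair], name) is not None
            ]
            if vals:
                setattr(med, name, float(np.median(vals)))
        pre_medians[pair] = med

    rows = []
    for (trace, segments), _ in zip(usable, first):
        for pair, pf in estimate_factors_trace(trace, segments, pre_medians).items():
            rows.append(
                {
                    "trace_id": trace.trace_id,
                    "pair": pair,
                    "alpha": pf.alpha,
                    "delta": pf.delta,
                    "gamma": pf.gamma,
                }
            )
    table = pd.DataFrame(rows, columns=["trace_id", "pair", "alpha", "delta", "gamma"])
    medians: dict[str, PairFactors] = {}
    for pair in all_pairs:
        sub = table[table.pair == pair]
        med = PairFactors()
        for name in ("alpha", "delta", "gamma"):
            vals = pd.to_numeric(sub[name], errors="coerce").dropna()
            if len(vals):
                setattr(med, name, float(vals.median()))
        medians[pair] = med
    return CorrectionFactors(table=table, medians=medians)


# --------------------------------------------------------------------------
# efficiencies
# --------------------------------------------------------------------------


def apparent_fret(trace: LabeledTrace) -> pd.DataFrame:
    """Proximity ratio per frame and pair: ``I_acc / (I_acc + I_don)``.

    Frames with non-positive denominator are NaN (undefined), all defined
    values lie in [0, 1].
    """
    out = {}
    for pair in PAIRS[trace.modality]:
        (i_dd, i_da, _), _, _ = _layout(trace.modality, pair)
        don = trace.channels[:, i_dd]
        acc = trace.channels[:, i_da]
        den = don + acc
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = np.where(den > 0, np.clip(acc, 0, None) / np.where(den > 0, den, 1), np.nan)
        out[pair] = np.clip(pr, 0.0, 1.0)
    return pd.DataFrame(out)


def corrected_fret_2c(trace: LabeledTrace, factors: PairFactors) -> np.ndarray:
    """Accurate two-color efficiency per frame (not clipped to [0, 1])."""
    missing = [n for n in ("alpha", "delta", "gamma") if getattr(factors, n) is None]
    if missing:
        raise ValueError(f"correction factors unresolved: {missing}")
    (i_dd, i_da, i_aa), _, _ = _layout(trace.modality, "DA")
    dd = trace.channels[:, i_dd]
    da = trace.channels[:, i_da]
    aa = trace.channels[:, i_aa] if i_aa is not None else np.zeros_like(dd)
    F = da - factors.alpha * dd - factors.delta * aa
    den = F + factors.gamma * dd
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, F / np.where(den != 0, den, 1), np.nan)


def corrected_fret_3c(
    trace: LabeledTrace,
    factors: dict[str, PairFactors],
    states: np.ndarray,
) -> pd.DataFrame:
    """Accurate three-color efficiencies with state-averaged YR correction.

    ``states`` is the per-frame 1-based state path (0 = undefined); frames
    whose state-averaged E_YR reaches the 0.95 clamp are flagged in the
    ``clamped`` column.
    """
    for pair in ("BY", "BR", "YR"):
        pf = factors.get(pair)
        if pf is None or None in (pf.alpha, pf.delta, pf.gamma):
            raise ValueError(f"correction factors unresolved for pair {pair!r}")
    ch = trace.channels
    i_bb, i_by, i_br, i_yy, i_yr, i_rr = range(6)

    # YR pair from the yellow-excitation block, exactly as two-color
    yr = factors["YR"]
    F_yr = ch[:, i_yr] - yr.alpha * ch[:, i_yy] - yr.delta * ch[:, i_rr]
    den = F_yr + yr.gamma * ch[:, i_yy]
    with np.errstate(invalid="ignore", divide="ignore"):
        e_yr = np.where(den != 0, F_yr / np.where(den != 0, den, 1), np.nan)

    # state-averaged E_YR per frame
    e_yr_bar = np.full(len(e_yr), np.nan)
    states = np.asarray(states)
    for s in np.unique(states[states > 0]):
        m = states == s
        e_yr_bar[m] = np.nanmean(e_yr[m])
    clamped = e_yr_bar >= EYR_CLAMP
    e_yr_bar = np.clip(e_yr_bar, None, EYR_CLAMP)

    by, br = factors["BY"], factors["BR"]
    I_b = ch[:, i_bb]
    I_y = (ch[:, i_by] - by.alpha * I_b - by.delta * ch[:, i_yy]) / by.gamma
    I_r = (ch[:, i_br] - br.alpha * I_b - br.delta * ch[:, i_rr]) / br.gamma
    T = I_b + I_y + I_r
    with np.errstate(invalid="ignore", divide="ignore"):
        e_by = I_y / (T * (1.0 - e_yr_bar))
        e_br = 1.0 - I_b / T - e_by
    return pd.DataFrame(
        {"BY": e_by, "BR": e_br, "YR": e_yr, "YR_state_mean": e_yr_bar, "clamped": clamped}
    )


def statewise_fret_3c(
    trace: LabeledTrace,
    factors: dict[str, PairFactors],
    states: np.ndarray,
) -> pd.DataFrame:
    """Per-state corrected three-color efficiencies from averaged intensities.

    State-level efficiencies are ratios of *state-averaged* corrected
    intensities rather than averages of per-frame ratios; this removes the
    ratio-estimator bias that grows as ``1 - E_YR`` shrinks and is the
    quantity shown in state-wise corrected histograms.
    """
    frame = corrected_fret_3c(trace, factors, states)
    ch = trace.channels
    by, br, yr = factors["BY"], factors["BR"], factors["YR"]
    I_b = ch[:, 0]
    I_y = (ch[:, 1] - by.alpha * I_b - by.delta * ch[:, 3]) / by.gamma
    I_r = (ch[:, 2] - br.alpha * I_b - br.delta * ch[:, 5]) / br.gamma
    rows = []
    states = np.asarray(states)
    for s in np.unique(states[states > 0]):
        m = states == s
        e_yr = float(np.clip(frame.loc[m, "YR_state_mean"].iloc[0], 0.0, EYR_CLAMP))
        b, y, r = I_b[m].mean(), I_y[m].mean(), I_r[m].mean()
        T = b + y + r
        e_by = y / (T * (1.0 - e_yr))
        rows.append(
            {"state": int(s), "n_frames": int(m.sum()), "E_BY": e_by,
             "E_BR": 1.0 - b / T - e_by, "E_YR": e_yr}
        )
    return pd.DataFrame(rows).set_index("state")


def fret_to_distance(e: float, r0: float) -> float:
    """Inter-dye distance from efficiency: ``R = R0 * (1/E - 1)^(1/6)``.

    ``r0`` (Forster radius) and the result share units (typically Angstrom).
    """
    if not 0.0 < e < 1.0:
        raise ValueError("E must lie strictly inside (0, 1)")
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    return float(r0 * (1.0 / e - 1.0) ** (1.0 / 6.0))


def build_histogram(
    values: np.ndarray,
    mode: str = "framewise",
    dwell_table: pd.DataFrame | None = None,
    bins: np.ndarray = HIST_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Efficiency histogram, frame-wise or dwell-weighted state-wise.

    ``framewise``: one entry per defined frame value.  ``statewise``: one
    entry per dwell at the dwell's mean value, weighted by the dwell length
    in frames (requires a transition table with ``from_value`` and
    ``dwell_frames`` columns).  Returns ``(counts, bin_edges)``.
    """
    if mode == "framewise":
        vals = np.asarray(values, dtype=float)
        vals = vals[np.isfinite(vals)]
        counts, edges = np.histogram(vals, bins=bins)
        return counts, edges
    if mode == "statewise":
        if dwell_table is None or not len(dwell_table):
            return np.zeros(len(bins) - 1, dtype=float), bins
        counts, edges = np.histogram(
            dwell_table["from_value"].to_numpy(dtype=float),
            bins=bins,
            weights=dwell_table["dwell_frames"].to_numpy(dtype=float),
        )
        return counts, edges
    raise ValueError(f"unknown histogram mode {mode!r}")
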