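"""Transition extraction, transition density plots and dwell-time fits.

A per-frame state path decomposes into maximal constant runs (dwells).  The
first and last run of every segment touch the observation boundary and are
right/left-censored, so they are excluded from dwell statistics (censored
dwells bias the time constant downward); their transition endpoints still
contribute to the TDP wherever both flanking dwells exist.

Dwell-time distributions of a Markovian system are exponential with mean
1/exit-rate; the time constant is obtained by least-squares fitting of
``1 - exp(-t/tau)`` to the empirical CDF evaluated at the sorted dwell
values, with a 95% confidence interval from the Jacobian-based covariance
of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TDP",
    "DwellFit",
    "extract_transitions",
    "build_tdp",
    "gate_tdp",
    "fit_dwell_cdf",
    "compare_cdfs",
]

#: transition table columns; ``interior`` marks dwells free of boundary
#: truncation (only those enter dwell statistics)
TRANSITION_COLUMNS = (
    "segment_id",
    "from_state",
    "to_state",
    "dwell_frames",
    "dwell_s",
    "from_value",
    "to_value",
    "interior",
)


@dataclass
class TDP:
    """2-D transition histogram over (observable before, observable after)."""

    hist: np.ndarray
    xedges: np.ndarray
    yedges: np.ndarray
    n_transitions: int


@dataclass
class DwellFit:
    tau: float  # seconds
    ci95: tuple[float, float]
    n_dwells: int
    r_squared: float

    @property
    def poor_fit(self) -> bool:
        return self.r_squared < 0.9


def extract_transitions(
    path: np.ndarray,
    frame_time: float,
    values: np.ndarray | None = None,
    segment_id: int = 0,
) -> pd.DataFrame:
    """Transition records from one per-frame state path.

    ``path`` holds 1-based state indices (frames with 0 are trimmed from the
    ends; a 0 inside the path raises).  ``values`` is an optional per-frame
    observable (normalized intensity or apparent FRET); each dwell records
    its mean observable, which becomes the TDP coordinate.  A constant path
    yields an empty table.  Each row describes the dwell *preceding* the
    transition; the final (censored) dwell appears with ``to_state`` equal
    to its own state and ``interior=False``.
    """
    path = np.asarray(path)
    defined = np.flatnonzero(path > 0)
    if len(defined) == 0:
        return _empty_table()
    lo, hi = defined[0], defined[-1] + 1
    path = path[lo:hi]
    if np.any(path <= 0):
        raise ValueError("state path contains undefined frames inside the segment")
    vals = None if values is None else np.asarray(values, dtype=float)[lo:hi]

    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(path)]])
    n_runs = len(starts)
    if n_runs == 1:
        return _empty_table()

    rows = []
    for r in range(n_runs):
        s, e = starts[r], ends[r]
        nxt = path[ends[r]] if r < n_runs - 1 else path[s]
        rows.append(
            {
                "segment_id": segment_id,
                "from_state": int(path[s]),
                "to_state": int(nxt),
                "dwell_frames": int(e - s),
                "dwell_s": float((e - s) * frame_time),
                "from_value": _finite_mean(vals[s:e]) if vals is not None else np.nan,
                "to_value": _finite_mean(vals[ends[r] : ends[r + 1]])
                if vals is not None and r < n_runs - 1
                else np.nan,
                "interior": 0 < r < n_runs - 1,
            }
        )
    return pd.DataFrame(rows, columns=list(TRANSITION_COLUMNS))


def _finite_mean(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    return float(a.mean()) if len(a) else np.nan


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(TRANSITION_COLUMNS))


def build_tdp(
    table: pd.DataFrame,
    bins: int = 100,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> TDP:
    """Histogram of (value before, value after) over real transitions.

    Only rows with a defined following dwell count (``from_state !=
    to_state``); the histogram total therefore equals the number of
    transitions.
    """
    if not len(table):
        raise ValueError("transition table is empty")
    trans = table[table.from_state != table.to_state]
    x = trans["from_value"].to_numpy(dtype=float)
    y = trans["to_value"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    hist, xe, ye = np.histogram2d(
        x[ok], y[ok], bins=bins, range=[value_range, value_range]
    )
    return TDP(hist=hist, xedges=xe, yedges=ye, n_transitions=int(ok.sum()))


def gate_tdp(
    table: pd.DataFrame,
    gates: list[dict],
) -> dict[str, np.ndarray]:
    """Partition interior dwells by rectangular TDP gates.

    Each gate is ``{"name", "x0", "x1", "y0", "y1"}`` in TDP coordinates
    (value before, value after).  Dwells matching several gates are assigned
    to the first match, with a warning.  Gates are plain dictionaries so a
    gating scheme serializes into a config for unattended reruns.
    """
    trans = table[(table.from_state != table.to_state) & table.interior]
    x = trans["from_value"].to_numpy(dtype=float)
    y = trans["to_value"].to_numpy(dtype=float)
    d = trans["dwell_s"].to_numpy(dtype=float)
    assigned = np.zeros(len(trans), dtype=bool)
    out: dict[str, np.ndarray] = {}
    overlap = False
    for gate in gates:
        m = (
            (x >= gate["x0"]) & (x <= gate["x1"])
            & (y >= gate["y0"]) & (y <= gate["y1"])
        )
        if (m & assigned).any():
            overlap = True
        m = m & ~assigned
        assigned |= m
        out[gate["name"]] = d[m]
    if overlap:
        warnings.warn("overlapping TDP gates: first-match assignment used")
    return out


def fit_dwell_cdf(dwells_s: np.ndarray, min_dwells: int = 10) -> DwellFit:
    """Mono-exponential fit ``1 - exp(-t/tau)`` to the empirical dwell CDF.

    The CDF is evaluated at the sorted dwell values; the 95% confidence
    interval comes from the Jacobian-based covariance estimate of the
    least-squares fit.  Degenerate inputs still return a finite tau but are
    flagged through a low R^2.
    """
    dwells = np.sort(np.asarray(dwells_s, dtype=float))
    n = len(dwells)
    if n < min_dwells:
        raise ValueError(f"need at least {min_dwells} dwells, got {n}")
    ecdf = np.arange(1, n + 1) / n

    def model(t, tau):
        return 1.0 - np.exp(-t / tau)

    p0 = max(dwells.mean(), 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(model, dwells, ecdf, p0=[p0], maxfev=10000)
    tau = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    resid = ecdf - model(dwells, tau)
    ss_tot = np.sum((ecdf - ecdf.mean()) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
    return DwellFit(
        tau=tau,
        ci95=(tau - 1.96 * se, tau + 1.96 * se),
        n_dwells=n,
        r_squared=r2,
    )


def compare_cdfs(
    dwells_a: np.ndarray,
    dwells_b: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pointwise difference of two empirical dwell CDFs on a common grid.

    Returns ``(grid, cdf_a - cdf_b, max |difference|)``; used to compare a
    classifier-derived dwell distribution with the HMM-derived one.
    """
    a = np.sort(np.asarray(dwells_a, dtype=float))
    b = np.sort(np.asarray(dwells_b, dtype=float))
    if grid is None:
        hi = max(a[-1] if len(a) else 1.0, b[-1] if len(b) else 1.0)
        grid = np.linspace(0.0, hi, 512)
    cdf_a = np.searchsorted(a, grid, side="right") / max(len(a), 1)
    cdf_b = np.searchsorted(b, grid, side="right") / max(len(b), 1)
    diff = cdf_a - cdf_b
    return grid, diff, float(np.abs(diff).max())
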