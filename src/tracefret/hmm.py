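"""Gaussian-emission hidden Markov baseline for kinetic analysis.

The reference method the classifier is benchmarked against: an HMM with
Gaussian emission distributions fit by Baum-Welch (EM) and decoded with
Viterbi, applied per trace ("local", the conventional workflow on
normalized intensity for 1-color or apparent FRET for 2-color data) or with
one parameter set shared across a dataset ("global").  Defaults follow the
conventional parameterization: convergence threshold 1e-9 on the
log-likelihood and a maximum of 1e8 iterations.

The implementation wraps :class:`hmmlearn.hmm.GaussianHMM`; initialization
(unspecified by convention) uses a quantile split of the observable for the
state means, residual-based variances with a 1e-6 floor against collapse,
and a sticky uniform transition matrix (0.95 self-transition).  Fitted
states are reordered to canonical form (ascending emission mean) so state
indices compare across traces and with the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from .kinetics import extract_transitions

__all__ = ["HmmModel", "HmmFit", "fit_local_hmm", "fit_global_hmm", "hmm_transitions"]

VARIANCE_FLOOR = 1e-6


@dataclass
class HmmModel:
    n_states: int
    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be > 0")


@dataclass
class HmmFit:
    model: HmmModel
    log_likelihoods: list[float]  # one entry per EM iteration, non-decreasing
    viterbi: np.ndarray  # 0-based canonical path (per-trace list for global)
    n_iter_used: int
    converged: bool
    variance_floored: bool = False
    paths: list[np.ndarray] = field(default_factory=list)  # global fits only


class _FlooredGaussianHMM(GaussianHMM):
    """GaussianHMM with a hard variance floor applied every M-step.

    Keeps the pure-ML update (monotone EM) except when a state's variance
    collapses, in which case the floor engages and the fit is flagged.
    """

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        floored = self._covars_ < VARIANCE_FLOOR
        if np.any(floored):
            self._covars_ = np.maximum(self._covars_, VARIANCE_FLOOR)
            self.floor_engaged_ = True


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trajectory."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _init_hmm(obs: np.ndarray, n_states: int, tol: float, max_iter: int) -> GaussianHMM:
    """Quantile-split initialization of a GaussianHMM."""
    q = np.quantile(obs, np.linspace(0, 1, n_states + 1))
    means = np.array(
        [[obs[(obs >= q[i]) & (obs <= q[i + 1])].mean()] for i in range(n_states)]
    )
    means = np.nan_to_num(means, nan=float(obs.mean()))
    # residual variance against the nearest initial mean
    nearest = np.argmin(np.abs(obs[:, None] - means[None, :, 0]), axis=1)
    var = np.array(
        [max(float(np.var(obs[nearest == i])), VARIANCE_FLOOR) for i in range(n_states)]
    )
    transmat = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.95)

    model = _FlooredGaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        tol=tol,
        n_iter=int(max_iter),
        min_covar=VARIANCE_FLOOR,
        covars_prior=0.0,  # pure ML M-step keeps EM monotone
        covars_weight=0.0,
        init_params="",
        params="stmc",
    )
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = transmat
    model.means_ = means
    model.covars_ = var[:, None]
    model.floor_engaged_ = False
    return model


def _canonicalize(model: GaussianHMM):
    """Permutation sorting states by ascending emission mean."""
    return np.argsort(model.means_[:, 0], kind="stable")


def _fit(
    sequences: list[np.ndarray], n_states: int, tol: float, max_iter: int
) -> HmmFit:
    obs = np.concatenate(sequences)
    if len(obs) <= n_states:
        raise ValueError("series length must exceed the number of states")
    model = _init_hmm(obs, n_states, tol, max_iter)
    monitor = _HistoryMonitor(model.tol, model.n_iter, model.verbose)
    model.monitor_ = monitor

    X = obs[:, None]
    lengths = [len(s) for s in sequences]
    model.fit(X, lengths=lengths)

    floored = bool(getattr(model, "floor_engaged_", False))
    order = _canonicalize(model)
    inv = np.empty_like(order)
    inv[order] = np.arange(n_states)

    hmm_model = HmmModel(
        n_states=n_states,
        means=model.means_[order, 0].copy(),
        variances=np.asarray(model.covars_).reshape(n_states, -1)[order, 0].copy(),
        transmat=model.transmat_[np.ix_(order, order)].copy(),
        startprob=model.startprob_[order].copy(),
    )
    paths = []
    pos = 0
    for n in lengths:
        _, raw = model.decode(X[pos : pos + n], algorithm="viterbi")
        paths.append(inv[raw])
        pos += n
    return HmmFit(
        model=hmm_model,
        log_likelihoods=monitor.full_history,
        viterbi=paths[0] if len(paths) == 1 else np.concatenate(paths),
        n_iter_used=len(monitor.full_history),
        converged=bool(monitor.converged),
        variance_floored=floored,
        paths=paths,
    )


def fit_local_hmm(
    series: np.ndarray,
    n_states: int = 2,
    tol: float = 1e-9,
    max_iter: int = 10**8,
) -> HmmFit:
    """Baum-Welch fit of a single observable series (one molecule).

    ``series`` is the 1-D observable (normalized intensity or apparent
    FRET).  The returned Viterbi path uses canonical 0-based state indices
    (ascending emission mean).  The log-likelihood trajectory is recorded
    per iteration and is non-decreasing up to the convergence tolerance.
    """
    series = np.asarray(series, dtype=float).ravel()
    series = series[np.isfinite(series)]
    return _fit([series], n_states, tol, max_iter)


def fit_global_hmm(
    series_list: list[np.ndarray],
    n_states: int = 2,
    tol: float = 1e-9,
    max_iter: int = 10**8,
) -> HmmFit:
    """One shared parameter set maximizing the summed likelihood.

    Per-trace Viterbi paths are returned in ``paths``.  A single input
    series reduces to the local fit.  Shared parameters help when molecules
    are homogeneous but miss transitions in outlier traces when state means
    vary across the dataset.
    """
    seqs = []
    for s in series_list:
        s = np.asarray(s, dtype=float).ravel()
        seqs.append(s[np.isfinite(s)])
    if not seqs:
        raise ValueError("need at least one series")
    return _fit(seqs, n_states, tol, max_iter)


def hmm_transitions(fit: HmmFit, frame_time: float, values=None):
    """Transition table from the Viterbi path(s) (same contract as kinetics).

    For global fits one table per trace is concatenated with distinct
    segment ids.  ``values`` supplies the per-frame observable whose dwell
    means become TDP coordinates; by default the fitted emission mean of the
    decoded state is used.
    """
    import pandas as pd

    paths = fit.paths if fit.paths else [fit.viterbi]
    tables = []
    for i, p in enumerate(paths):
        vals = None
        if values is not None:
            vals = values[i] if isinstance(values, list) else values
        elif fit.model is not None:
            vals = fit.model.means[p]
        tables.append(extract_transitions(p + 1, frame_time, values=vals, segment_id=i))
    return pd.concat(tables, ignore_index=True) if tables else tables
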