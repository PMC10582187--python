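"""Correction factors, accurate FRET, distances, histograms."""

import numpy as np
import pandas as pd
import pytest

import tracefret as tf
from tracefret.classify import segments_from_labels
from tracefret.corrections import HIST_BINS, build_histogram

from conftest import smoke_config


def _two_state_trace(det, bleach=None, snr=None, n_frames=600, seed=0,
                     e=(0.81, 0.14), brightness=(1000.0, 900.0)):
    km = tf.KineticModel(
        2, np.array([[-1 / 1.75, 1 / 1.75], [1 / 2.65, -1 / 2.65]]),
        {"DA": np.array(e)},
    )
    pm = tf.PhotophysicsModel(
        {"D": 0.0, "A": 0.0}, {"D": brightness[0], "A": brightness[1]}
    )
    rng = np.random.default_rng(seed)
    _, occ = tf.sample_state_path(km, n_frames, 0.05, rng)
    tr = tf.render_trace(occ, km, pm, det, "2c_alex", rng, 0.05, snr=snr,
                         bleach_time_s=bleach or {"D": np.inf, "A": np.inf})
    return tr, occ


DET = tf.DetectionModel(alpha={"DA": 0.05}, delta={"DA": 0.08}, gamma={"DA": 1.3})


class TestFactorEstimators:
    def test_alpha_noise_free(self):
        tr, _ = _two_state_trace(DET, bleach={"D": 25.0, "A": 12.0})
        segs = segments_from_labels(tr.labels, tr.alphabet)
        assert tf.estimate_alpha(tr, segs) == pytest.approx(0.05, abs=1e-10)

    def test_delta_noise_free(self):
        tr, _ = _two_state_trace(DET, bleach={"D": 12.0, "A": 25.0})
        segs = segments_from_labels(tr.labels, tr.alphabet)
        assert tf.estimate_delta(tr, segs) == pytest.approx(0.08, abs=1e-10)

    def test_gamma_noise_free(self):
        tr, _ = _two_state_trace(DET, bleach={"D": 25.0, "A": 12.0})
        segs = segments_from_labels(tr.labels, tr.alphabet)
        g = tf.estimate_gamma(tr, segs, 0.05, 0.08)
        assert g == pytest.approx(1.3, rel=1e-9)

    def test_missing_segments_give_none(self):
        # no bleaching at all: neither donor-only nor acceptor-only frames
        tr, _ = _two_state_trace(DET)
        segs = segments_from_labels(tr.labels, tr.alphabet)
        assert tf.estimate_alpha(tr, segs) is None
        assert tf.estimate_delta(tr, segs) is None
        assert tf.estimate_gamma(tr, segs, 0.05, 0.08) is None

    def test_cw_two_color_delta_unavailable(self):
        det = tf.DetectionModel(alpha={"DA": 0.05}, delta={"DA": 0.0},
                                gamma={"DA": 1.0})
        km = tf.KineticModel(1, np.zeros((1, 1)), {"DA": np.array([0.5])})
        pm = tf.PhotophysicsModel({"D": 0.0, "A": 0.0}, {"D": 1000.0, "A": 900.0})
        rng = np.random.default_rng(0)
        occ = np.ones((200, 1))
        tr = tf.render_trace(occ, km, pm, det, "2c", rng, 0.05, snr=None,
                             bleach_time_s={"D": 8.0, "A": 4.0})
        segs = segments_from_labels(tr.labels, tf.CategoryAlphabet("2c"))
        with pytest.raises(ValueError, match="ALEX"):
            tf.estimate_delta(tr, segs)

    def test_gamma_none_when_bleach_at_trace_end(self):
        tr, _ = _two_state_trace(DET, bleach={"D": np.inf, "A": 29.8})
        segs = segments_from_labels(tr.labels, tr.alphabet)
        assert tf.estimate_gamma(tr, segs, 0.05, 0.08) is None

    def test_median_recovery_at_snr10(self):
        """Dataset medians recover alpha/delta/gamma within 5% (500 traces)."""
        rng = np.random.default_rng(7)
        alphabet = tf.CategoryAlphabet("2c_alex")
        km = tf.KineticModel(
            2, np.array([[-1 / 1.75, 1 / 1.75], [1 / 2.65, -1 / 2.65]]),
            {"DA": np.array([0.81, 0.14])},
        )
        traces, segs = [], []
        for i in range(500):
            pm = tf.PhotophysicsModel(
                {"D": 1 / 20.0, "A": 1 / 20.0},
                {"D": rng.uniform(800, 1200), "A": rng.uniform(700, 1100)},
            )
            _, occ = tf.sample_state_path(km, 800, 0.05, rng)
            tr = tf.render_trace(occ, km, pm, DET, "2c_alex", rng, 0.05, snr=10.0)
            tr.trace_id = i
            traces.append(tr)
            segs.append(segments_from_labels(tr.labels, alphabet))
        med = tf.estimate_factors_dataset(traces, segs).medians["DA"]
        assert med.alpha == pytest.approx(0.05, rel=0.05)
        assert med.delta == pytest.approx(0.08, rel=0.05)
        assert med.gamma == pytest.approx(1.3, rel=0.05)


class TestFret:
    def test_apparent_fret_examples(self):
        tr, _ = _two_state_trace(tf.DetectionModel.ideal("2c_alex"))
        tr.channels = np.array([[20.0, 80.0, 50.0], [50.0, 0.0, 50.0],
                                [50.0, 50.0, 50.0], [0.0, 0.0, 50.0]])
        pr = tf.apparent_fret(tr)["DA"].to_numpy()
        assert pr[0] == pytest.approx(0.8)
        assert pr[1] == 0.0
        assert pr[2] == pytest.approx(0.5)
        assert np.isnan(pr[3])  # zero denominator -> undefined

    def test_identity_correction_equals_proximity_ratio(self):
        tr, _ = _two_state_trace(tf.DetectionModel.ideal("2c_alex"), snr=20.0)
        e = tf.corrected_fret_2c(tr, tf.PairFactors(0.0, 0.0, 1.0))
        pr = tf.apparent_fret(tr)["DA"].to_numpy()
        ok = np.isfinite(pr)
        # PR is clipped to [0,1]; compare on frames where E is inside
        inside = ok & (e > 0) & (e < 1)
        assert np.allclose(e[inside], pr[inside], atol=1e-12)

    def test_noise_free_round_trip_2c(self):
        tr, occ = _two_state_trace(DET)
        e = tf.corrected_fret_2c(tr, tf.PairFactors(0.05, 0.08, 1.3))
        truth = occ @ np.array([0.81, 0.14])
        assert np.abs(e - truth).max() < 1e-10

    def test_missing_factor_raises_with_names(self):
        tr, _ = _two_state_trace(DET)
        with pytest.raises(ValueError, match="gamma"):
            tf.corrected_fret_2c(tr, tf.PairFactors(0.05, 0.08, None))

    def test_noise_free_round_trip_3c(self):
        det = tf.DetectionModel(
            alpha={"BY": 0.04, "BR": 0.03, "YR": 0.05},
            delta={"BY": 0.06, "BR": 0.02, "YR": 0.08},
            gamma={"BY": 1.2, "BR": 0.9, "YR": 1.3},
        )
        km = tf.KineticModel(
            1, np.zeros((1, 1)),
            {"BY": np.array([0.3]), "BR": np.array([0.1]), "YR": np.array([0.6])},
        )
        pm = tf.PhotophysicsModel({d: 0.0 for d in "BYR"},
                                  {"B": 1000.0, "Y": 900.0, "R": 800.0})
        occ = np.ones((300, 1))
        tr = tf.render_trace(occ, km, pm, det, "3c_alex",
                             np.random.default_rng(0), 0.05, snr=None)
        factors = {p: tf.PairFactors(det.alpha[p], det.delta[p], det.gamma[p])
                   for p in ("BY", "BR", "YR")}
        out = tf.corrected_fret_3c(tr, factors, tr.states)
        assert np.abs(out["YR"] - 0.6).max() < 1e-10
        assert np.abs(out["BY"] - 0.3).max() < 1e-10
        assert np.abs(out["BR"] - 0.1).max() < 1e-10

    def test_3c_reduces_to_intensity_fraction_at_zero_eyr(self):
        det = tf.DetectionModel.ideal("3c_alex")
        km = tf.KineticModel(
            1, np.zeros((1, 1)),
            {"BY": np.array([0.4]), "BR": np.array([0.2]), "YR": np.array([0.0])},
        )
        pm = tf.PhotophysicsModel({d: 0.0 for d in "BYR"},
                                  {d: 1000.0 for d in "BYR"})
        occ = np.ones((100, 1))
        tr = tf.render_trace(occ, km, pm, det, "3c_alex",
                             np.random.default_rng(0), 0.05, snr=None)
        factors = {p: tf.PairFactors(0.0, 0.0, 1.0) for p in ("BY", "BR", "YR")}
        out = tf.corrected_fret_3c(tr, factors, tr.states)
        t = tr.channels[:, 0] + tr.channels[:, 1] + tr.channels[:, 2]
        assert np.allclose(out["BY"], tr.channels[:, 1] / t, atol=1e-10)

    def test_3c_state_averaging_keeps_static_br_static(self):
        """With state-independent E_BR, the corrected BR histogram collapses
        to one population although the apparent BR is bimodal."""
        det = tf.DetectionModel.ideal("3c_alex")
        km = tf.KineticModel(
            2, np.array([[-1.0, 1.0], [1.0, -1.0]]),
            {"BY": np.array([0.30, 0.60]), "BR": np.array([0.30, 0.30]),
             "YR": np.array([0.81, 0.08])},
        )
        pm = tf.PhotophysicsModel({d: 0.0 for d in "BYR"},
                                  {d: 1000.0 for d in "BYR"})
        rng = np.random.default_rng(1)
        _, occ = tf.sample_state_path(km, 4000, 0.05, rng)
        tr = tf.render_trace(occ, km, pm, det, "3c_alex", rng, 0.05, snr=30.0)
        factors = {p: tf.PairFactors(0.0, 0.0, 1.0) for p in ("BY", "BR", "YR")}
        pure = np.max(occ, axis=1) > 0.99
        app_br = tf.apparent_fret(tr)["BR"].to_numpy()[pure]
        state_means_app = [app_br[tr.states[pure] == s].mean() for s in (1, 2)]
        state_table = tf.statewise_fret_3c(tr, factors, tr.states)
        cor = state_table["E_BR"]
        assert abs(state_means_app[0] - state_means_app[1]) > 0.1  # bimodal
        assert abs(cor.loc[1] - cor.loc[2]) < 0.03  # static after correction
        assert cor.mean() == pytest.approx(0.30, abs=0.03)

    def test_corrected_by_broadens_as_eyr_grows(self):
        """Var(corrected BY) increases monotonically with E_YR at fixed noise."""
        det = tf.DetectionModel.ideal("3c_alex")
        variances = []
        for e_yr in (0.2, 0.6, 0.9):
            km = tf.KineticModel(
                1, np.zeros((1, 1)),
                {"BY": np.array([0.3]), "BR": np.array([0.2]),
                 "YR": np.array([e_yr])},
            )
            pm = tf.PhotophysicsModel({d: 0.0 for d in "BYR"},
                                      {d: 1000.0 for d in "BYR"})
            occ = np.ones((3000, 1))
            tr = tf.render_trace(occ, km, pm, det, "3c_alex",
                                 np.random.default_rng(2), 0.05, snr=10.0)
            factors = {p: tf.PairFactors(0.0, 0.0, 1.0) for p in ("BY", "BR", "YR")}
            out = tf.corrected_fret_3c(tr, factors, tr.states)
            variances.append(np.nanvar(out["BY"].to_numpy()))
        assert variances[0] < variances[1] < variances[2]


class TestDistance:
    def test_half_efficiency_gives_forster_radius(self):
        assert tf.fret_to_distance(0.5, 68.0) == pytest.approx(68.0)

    @pytest.mark.parametrize("e,expected", [(0.81, 53), (0.14, 92)])
    def test_origami_worked_examples(self, e, expected):
        assert round(tf.fret_to_distance(e, 68.0)) == expected

    def test_strictly_decreasing_and_r0_scaling(self):
        es = np.linspace(0.05, 0.95, 50)
        d = np.array([tf.fret_to_distance(e, 68.0) for e in es])
        assert np.all(np.diff(d) < 0)
        ratio = [tf.fret_to_distance(0.3, r0) / r0 for r0 in (10.0, 68.0, 100.0)]
        assert np.allclose(ratio, ratio[0])

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_out_of_range_efficiency(self, bad):
        with pytest.raises(ValueError):
            tf.fret_to_distance(bad, 68.0)


class TestHistograms:
    def test_counts_conserved_and_single_state_single_bin(self):
        vals = np.full(500, 0.63)
        counts, edges = build_histogram(vals, "framewise")
        assert counts.sum() == 500
        assert (counts > 0).sum() == 1
        assert edges[0] == pytest.approx(-0.2) and edges[-1] == pytest.approx(1.2)

    def test_equal_occupancy_states_have_equal_mass(self):
        km = tf.KineticModel(
            2, np.array([[-1.0, 1.0], [1.0, -1.0]]), {"DA": np.array([0.8, 0.2])}
        )
        rng = np.random.default_rng(3)
        _, occ = tf.sample_state_path(km, 30000, 0.05, rng)
        vals = occ @ np.array([0.8, 0.2])
        counts, _ = build_histogram(vals, "framewise")
        centers = 0.5 * (HIST_BINS[:-1] + HIST_BINS[1:])
        hi = counts[centers > 0.5].sum()
        lo = counts[centers <= 0.5].sum()
        n = hi + lo
        assert abs(hi - lo) < 3.29 * np.sqrt(n)  # binomial 99.9%

    def test_statewise_weighted_by_dwell_length(self):
        table = pd.DataFrame(
            {"from_value": [0.8, 0.2], "dwell_frames": [30, 10]}
        )
        counts, _ = build_histogram(None, "statewise", dwell_table=table)
        assert counts.sum() == 40
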