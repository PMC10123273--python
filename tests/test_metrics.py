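"""Metric extraction and beat classification against constructed waveforms."""

import math

import numpy as np
import pytest

from tests.conftest import make_trace
from txcardio.metrics import (EAD, NORMAL, REPOL_FAILURE, SPONTANEOUS,
                              ClassifierConfig, ap_metrics, cat_metrics,
                              classify_arrhythmia, classify_change,
                              compare_rankings, contraction_metrics,
                              rank_drugs, waveform_metrics)

DT = 1e-4  # dense sampling for constructed waveforms


def piecewise_ap(plateau_ms=100.0, repol_ms=300.0, v_peak=40.0, v_rest=-80.0,
                 n_beats=2, period=1.0):
    """Piecewise-linear AP train: instant upstroke, flat plateau, linear repol."""
    t = np.arange(0.0, n_beats * period + DT / 2, DT)
    v = np.full_like(t, v_rest)
    for b in range(n_beats):
        t0 = b * period
        up = 0.002  # 2 ms linear upstroke
        for i, ti in enumerate(t):
            rel = ti - t0
            if 0 <= rel < up:
                v[i] = v_rest + (v_peak - v_rest) * rel / up
            elif up <= rel < up + plateau_ms / 1000:
                v[i] = v_peak
            elif up + plateau_ms / 1000 <= rel < up + (plateau_ms + repol_ms) / 1000:
                frac = (rel - up - plateau_ms / 1000) / (repol_ms / 1000)
                v[i] = v_peak + (v_rest - v_peak) * frac
    stims = [b * period for b in range(n_beats)]
    return t, v, stims


def brute_force_apd(t, v, v_rest, fraction):
    """Dense threshold-crossing scan: independent APD oracle."""
    dv = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dv >= 0.9 * dv.max()))
    i_pk = i_up + int(np.argmax(v[i_up:]))
    level = v[i_pk] - fraction * (v[i_pk] - v_rest)
    below = np.nonzero(v[i_pk:] < level)[0]
    return (t[i_pk + below[0]] - t[i_up]) * 1000.0


class TestAPMetrics:
    def test_piecewise_linear_matches_brute_force(self):
        t, v, stims = piecewise_ap()
        trace = make_trace(t, v, stim_times=stims)
        m = ap_metrics(trace)
        sel = t < 1.0
        for frac, key in ((0.5, "APD50"), (0.9, "APD90")):
            oracle = brute_force_apd(t[sel], v[sel], -80.0, frac)
            assert m[key] == pytest.approx(oracle, abs=0.5)

    def test_square_ap_has_unit_triangulation(self):
        # near-instant repolarization: APD90 == APD50
        t, v, stims = piecewise_ap(plateau_ms=200.0, repol_ms=1.0)
        m = ap_metrics(make_trace(t, v, stim_times=stims))
        assert m["AP_triangulation"] == pytest.approx(1.0, abs=0.01)

    def test_slower_terminal_repolarization_raises_triangulation(self):
        t1, v1, stims = piecewise_ap(plateau_ms=150.0, repol_ms=150.0)
        base = ap_metrics(make_trace(t1, v1, stim_times=stims))
        t2, v2, _ = piecewise_ap(plateau_ms=50.0, repol_ms=350.0)
        tri = ap_metrics(make_trace(t2, v2, stim_times=stims))
        assert tri["AP_triangulation"] > base["AP_triangulation"]

    def test_window_without_complete_beat_raises(self):
        t = np.arange(0, 0.5, DT)
        trace = make_trace(t, np.full_like(t, -80.0), stim_times=[0.0])
        with pytest.raises(ValueError, match="no complete"):
            ap_metrics(trace)


class TestCaTMetrics:
    def make_cat(self, tau_s=0.25, amp=0.3, baseline=0.05, n_beats=2):
        t = np.arange(0.0, n_beats * 1.0 + DT / 2, DT)
        ca = np.full_like(t, baseline)
        for b in range(n_beats):
            rel = t - b * 1.0
            rise = (rel >= 0.01) & (rel < 0.03)
            ca[rise] = baseline + amp * (rel[rise] - 0.01) / 0.02
            decay = (rel >= 0.03) & (rel < 1.0)
            ca[decay] = baseline + amp * np.exp(-(rel[decay] - 0.03) / tau_s)
        return t, ca

    def test_exponential_decay_tau_recovered(self):
        t, ca = self.make_cat(tau_s=0.25)
        trace = make_trace(t, np.full_like(t, -80.0), Cai=ca,
                           stim_times=[0.0, 1.0])
        m = cat_metrics(trace)
        assert m["Decay_Tau"] == pytest.approx(250.0, abs=1.0)
        assert m["CaT_amplitude"] == pytest.approx(0.3, abs=0.01)
        assert m["CaT_triangulation"] >= 1.0

    def test_flat_cai_gives_zero_auc(self):
        t = np.arange(0.0, 2.0, DT)
        trace = make_trace(t, np.full_like(t, -80.0),
                           Cai=np.full_like(t, 0.05), stim_times=[0.0, 1.0])
        m = cat_metrics(trace)
        assert m["CaT_AUC"] == 0.0

    def test_auc_invariant_to_constant_baseline_offset(self):
        t, ca = self.make_cat()
        a = cat_metrics(make_trace(t, np.full_like(t, -80.0), Cai=ca,
                                   stim_times=[0.0, 1.0]))
        b = cat_metrics(make_trace(t, np.full_like(t, -80.0), Cai=ca + 0.5,
                                   stim_times=[0.0, 1.0]))
        assert b["CaT_AUC"] == pytest.approx(a["CaT_AUC"], rel=1e-9)


class TestContractionMetrics:
    def test_constant_sl_is_zero_percent_not_error(self):
        t = np.arange(0.0, 2.0, DT)
        trace = make_trace(t, np.full_like(t, -80.0),
                           SL=np.full_like(t, 2.0), stim_times=[0.0, 1.0])
        assert contraction_metrics(trace)["fractional_shortening"] == 0.0

    def test_ten_percent_dip(self):
        t = np.arange(0.0, 2.0, DT)
        sl = np.full_like(t, 2.0)
        for b in (0, 1):
            dip = (t >= b + 0.1) & (t < b + 0.3)
            sl[dip] = 1.8
        trace = make_trace(t, np.full_like(t, -80.0), SL=sl,
                           stim_times=[0.0, 1.0])
        fs = contraction_metrics(trace)["fractional_shortening"]
        assert fs == pytest.approx(10.0, abs=0.01)


class TestClassifier:
    def test_clean_paced_beats_are_normal(self):
        t, v, stims = piecewise_ap(n_beats=3)
        call = classify_arrhythmia(make_trace(t, v, stim_times=stims))
        assert call.label == NORMAL and not call.is_arrhythmic

    def test_ead_hump_during_repolarization(self):
        """A 10 mV hump around -30 mV on the repolarizing limb is an EAD."""
        t, v, stims = piecewise_ap(n_beats=2)
        # superimpose a hump where V crosses about -30 mV in beat 0
        on_limb = (v < -20) & (v > -45) & (t < 1.0) & (t > 0.05)
        idx = np.nonzero(on_limb)[0]
        mid = idx[len(idx) // 2]
        width = int(0.015 / DT)
        lo, hi = mid - width, mid + width
        bump = 10.0 * np.sin(np.linspace(0, np.pi, hi - lo)) ** 2
        v2 = v.copy()
        v2[lo:hi] += bump
        call = classify_arrhythmia(make_trace(t, v2, stim_times=stims))
        assert call.label == EAD
        assert call.beat_index == 0
        assert 0.0 < call.time < 1.0

    def test_clamped_plateau_is_repolarization_failure(self):
        t = np.arange(0.0, 2.0, DT)
        v = np.full_like(t, -20.0)
        up = t < 0.002
        v[up] = -75 + (95) * t[up] / 0.002
        call = classify_arrhythmia(make_trace(t, v, stim_times=[0.0, 1.0]))
        assert call.label == REPOL_FAILURE

    def test_prestimulus_upstroke_is_spontaneous(self):
        t, v, stims = piecewise_ap(plateau_ms=50, repol_ms=150, n_beats=2)
        # full extra AP starting 300 ms before the second stimulus
        t0 = 0.7
        extra = (t >= t0) & (t < t0 + 0.2)
        rel = t[extra] - t0
        ap = np.where(rel < 0.002, -80 + 120 * rel / 0.002,
                      np.maximum(40 - 120 * (rel - 0.002) / 0.198, -80.0))
        v2 = v.copy()
        v2[extra] = np.maximum(v2[extra], ap)
        call = classify_arrhythmia(make_trace(t, v2, stim_times=stims))
        assert call.label == SPONTANEOUS

    def test_window_without_stimulus_marks_raises(self):
        t = np.arange(0.0, 1.0, DT)
        trace = make_trace(t, np.full_like(t, -80.0), stim_times=[])
        with pytest.raises(ValueError, match="stimulus"):
            classify_arrhythmia(trace)

    def test_normal_trace_has_one_upstroke_per_stimulus(self, baseline_trace):
        """Classifier consistency on the real model's baseline run."""
        win = baseline_trace.window(3.0)
        call = classify_arrhythmia(win)
        assert call.label == NORMAL
        cfg = ClassifierConfig()
        dv = np.gradient(win.V, win.time)
        fast = dv >= cfg.upstroke_dvdt
        onsets = np.nonzero(fast & ~np.roll(fast, 1))[0]
        stims = win.stimulus_times
        complete = [s for s in stims if s + 1.0 <= win.time[-1] + 1e-6]
        matched = [o for o in win.time[onsets]
                   if any(0 <= o - s <= 0.03 for s in stims)]
        assert len(matched) >= len(complete)
        assert len(win.time[onsets]) == len(matched)


class TestChangeClassification:
    @pytest.mark.parametrize("ratio,expected", [
        (1.25, "increase"), (1.0, "no_change"), (0.79, "decrease"),
        (1.2, "no_change"), (0.8, "no_change"),  # strict boundaries
        (1.2000001, "increase"), (0.7999999, "decrease"),
    ])
    def test_twenty_percent_rule(self, ratio, expected):
        assert classify_change(ratio * 5.0, 5.0) == expected

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            classify_change(1.0, 0.0)


class TestRankings:
    def test_rank_is_descending_log_change_with_lexicographic_ties(self):
        ranked = rank_drugs({"X": 2.0, "A": 4.0, "B": 2.0}, k=3)
        assert [d for d, _ in ranked] == ["A", "B", "X"]
        assert ranked[0][1] == pytest.approx(2.0)  # log2(4)

    def test_identical_rankings_have_rho_one(self):
        order = ["D1", "D2", "D3", "D4"]
        assert compare_rankings(order, order, k=4) == pytest.approx(1.0)

    def test_reversed_rankings_have_rho_minus_one(self):
        order = ["D1", "D2", "D3", "D4", "D5"]
        assert compare_rankings(order, order[::-1], k=5) == pytest.approx(-1.0)

    def test_spearman_closed_form_three_items(self):
        # ranks (1,2),(2,1),(3,3): rho = 1 - 6*2/(3*8) = 0.5
        assert compare_rankings(["a", "b", "c"], ["b", "a", "c"],
                                k=3) == pytest.approx(0.5)

    def test_union_of_topk_uses_full_cohort_ranks(self):
        a = ["d1", "d2", "d3", "d4"]
        b = ["d3", "d4", "d1", "d2"]
        rho = compare_rankings(a, b, k=2)
        # union = {d1,d2,d3,d4}; ranks a=(1,2,3,4), b=(3,4,1,2)
        assert rho == pytest.approx(1 - 6 * (4 + 4 + 4 + 4) / (4 * 15))


class TestWaveformMetricsOnModel:
    def test_baseline_metrics_are_physiological(self, baseline_trace):
        m = waveform_metrics(baseline_trace, 3.0)
        assert m.APD90 >= m.APD50 > 0
        assert m.AP_triangulation >= 1.0
        assert m.CaT_triangulation >= 1.0
        assert m.Decay_Tau > 0
        assert m.CaT_AUC >= 0
        assert 5.0 <= m.fractional_shortening <= 10.0
        assert m.resting_V < -65.0
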