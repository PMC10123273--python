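"""Action potential, Ca2+ transient and contraction metrics, and beat classification.

Duration metrics (APD50/90, CaD50/90) are measured per beat from the upstroke
(time of maximal rate of rise) to the time the signal recovers by 50%/90% of
its beat amplitude, with linear interpolation between samples, then averaged
over the analysis window.  Triangulation is the 90/50 duration ratio: a more
triangular (slower terminal) repolarization gives a larger value and is an
established proarrhythmic indicator.

Beat classification distinguishes early afterdepolarizations (a depolarizing
deflection during repolarization), failure to repolarize before the next
stimulus, and spontaneous (pre-stimulus) upstrokes; all detector thresholds
are configurable on :class:`ClassifierConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .model import SimTrace


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else math.nan

__all__ = [
    "WaveformMetrics",
    "ArrhythmiaCall",
    "ClassifierConfig",
    "ap_metrics",
    "cat_metrics",
    "contraction_metrics",
    "waveform_metrics",
    "classify_arrhythmia",
    "classify_change",
    "rank_drugs",
    "compare_rankings",
]

NORMAL = "normal"
EAD = "EAD"
REPOL_FAILURE = "repolarization_failure"
SPONTANEOUS = "spontaneous_depolarization"
SIM_FAILURE = "simulation_failure"
ARRHYTHMIC_LABELS = (EAD, REPOL_FAILURE, SPONTANEOUS, SIM_FAILURE)


@dataclass
class WaveformMetrics:
    """Per-condition waveform summary (averages over analyzed beats)."""

    APD50: float            # ms
    APD90: float            # ms
    AP_triangulation: float  # APD90/APD50
    resting_V: float        # mV
    CaT_amplitude: float    # uM
    CaD50: float            # ms
    CaD90: float            # ms
    CaT_triangulation: float  # CaD90/CaD50
    Decay_Tau: float        # ms (nan if the exponential fit fails)
    CaT_AUC: float          # uM*s per beat
    fractional_shortening: float  # percent

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


@dataclass
class ArrhythmiaCall:
    label: str
    beat_index: Optional[int] = None
    time: Optional[float] = None  # s, time of the triggering feature

    @property
    def is_arrhythmic(self) -> bool:
        return self.label != NORMAL


@dataclass(frozen=True)
class ClassifierConfig:
    """Detector thresholds for beat classification (defaults documented)."""

    ead_prominence: float = 2.0      # mV rise from a local minimum
    ead_band: Tuple[float, float] = (-70.0, 0.0)  # mV, repolarization band
    repol_fail_level: float = -60.0  # mV; V must fall below this per beat
    spont_lead: float = 0.050        # s before a stimulus
    upstroke_dvdt: float = 5000.0    # mV/s, full-upstroke detector
    paced_response_window: float = 0.030  # s after a stimulus = paced upstroke


# ---------------------------------------------------------------------------
# beat segmentation helpers


def _windowed(trace: SimTrace, window: Optional[float]) -> SimTrace:
    if window is None or trace.truncated_to_window:
        return trace
    return trace.window(window)


def _beat_edges(trace: SimTrace) -> List[Tuple[float, float]]:
    """(start, end) of every complete beat in the trace, stimulus-aligned."""
    stims = trace.stimulus_times
    t_end = trace.time[-1]
    period = 1.0 / trace.pacing_rate
    edges = []
    for st in stims:
        e = min(st + period, t_end)
        if e - st >= period - 1e-6:
            edges.append((float(st), float(e)))
    return edges


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First downward crossing time of ``level``; linear interpolation."""
    below = y < level
    if not below.any():
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


def _duration(t: np.ndarray, y: np.ndarray, baseline: float,
              fraction: float) -> float:
    """Time from upstroke (max dy/dt) to recovery by ``fraction`` of amplitude."""
    # upstroke onset: first sample reaching 90% of the beat's max dy/dt
    # (deterministic on piecewise-linear ramps, where argmax ties)
    dy = np.diff(y) / np.diff(t)
    i_up = int(np.argmax(dy >= 0.9 * dy.max()))
    t_up = t[i_up]
    i_pk = i_up + int(np.argmax(y[i_up:]))
    peak = y[i_pk]
    level = peak - fraction * (peak - baseline)
    t_cross = _interp_crossing(t[i_pk:], y[i_pk:], level)
    return (t_cross - t_up) * 1000.0 if math.isfinite(t_cross) else math.nan


def _beat_slices(trace: SimTrace):
    for k, (t0, t1) in enumerate(_beat_edges(trace)):
        sel = (trace.time >= t0 - 1e-12) & (trace.time <= t1 + 1e-12)
        yield k, t0, t1, sel


# ---------------------------------------------------------------------------
# metric extraction


def ap_metrics(trace: SimTrace, window: Optional[float] = None) -> Dict[str, float]:
    """APD50, APD90, triangulation (APD90/APD50) and resting V, beat-averaged."""
    tr = _windowed(trace, window)
    apd50, apd90, rest = [], [], []
    for _, t0, t1, sel in _beat_slices(tr):
        t, v = tr.time[sel], tr.V[sel]
        rest.append(v[0])
        apd50.append(_duration(t, v, v[0], 0.5))
        apd90.append(_duration(t, v, v[0], 0.9))
    if not apd50:
        raise ValueError("no complete paced beat in the analysis window")
    a50 = _nanmean(apd50)
    a90 = _nanmean(apd90)
    return {"APD50": a50, "APD90": a90,
            "AP_triangulation": a90 / a50 if a50 > 0 else math.nan,
            "resting_V": float(np.mean(rest))}


def _fit_decay_tau(t: np.ndarray, ca: np.ndarray, diastolic: float) -> float:
    """Mono-exponential time constant (ms) of the CaT decay segment.

    The fitted segment runs from 10% of decay below the peak down to 5% of
    amplitude above the diastolic level; returns nan if the least-squares fit
    does not converge.
    """
    i_pk = int(np.argmax(ca))
    peak = ca[i_pk]
    amp = peak - diastolic
    if amp <= 0:
        return math.nan
    hi = peak - 0.10 * amp
    lo = diastolic + 0.05 * amp
    td, cd = t[i_pk:], ca[i_pk:]
    start = np.argmax(cd <= hi) if (cd <= hi).any() else None
    if start is None:
        return math.nan
    stop_arr = np.nonzero(cd <= lo)[0]
    stop = stop_arr[0] if stop_arr.size else len(cd)
    if stop - start < 4:
        return math.nan
    ts, cs = td[start:stop], cd[start:stop]
    t0 = ts[0]

    def mono(tt, a, tau, c):
        return a * np.exp(-(tt - t0) / tau) + c

    try:
        popt, _ = curve_fit(
            mono, ts, cs,
            p0=(cs[0] - diastolic, max((ts[-1] - ts[0]) / 2.0, 1e-3), diastolic),
            maxfev=5000)
    except RuntimeError:
        return math.nan
    tau = popt[1]
    return float(tau * 1000.0) if tau > 0 else math.nan


def cat_metrics(trace: SimTrace, window: Optional[float] = None) -> Dict[str, float]:
    """CaT amplitude, CaD50/90, triangulation, decay tau, per-beat AUC."""
    tr = _windowed(trace, window)
    amp, cad50, cad90, taus, aucs = [], [], [], [], []
    for _, t0, t1, sel in _beat_slices(tr):
        t, ca = tr.time[sel], tr.Cai[sel]
        diastolic = ca[0]
        amp.append(ca.max() - diastolic)
        cad50.append(_duration(t, ca, diastolic, 0.5))
        cad90.append(_duration(t, ca, diastolic, 0.9))
        taus.append(_fit_decay_tau(t, ca, diastolic))
        aucs.append(float(np.trapezoid(ca - diastolic, t)))
    if not amp:
        raise ValueError("no complete Ca2+ transient in the analysis window")
    c50 = _nanmean(cad50)
    c90 = _nanmean(cad90)
    return {"CaT_amplitude": float(np.mean(amp)),
            "CaD50": c50, "CaD90": c90,
            "CaT_triangulation": c90 / c50 if c50 > 0 else math.nan,
            "Decay_Tau": _nanmean(taus),
            "CaT_AUC": float(np.mean(aucs))}


def contraction_metrics(trace: SimTrace,
                        window: Optional[float] = None) -> Dict[str, float]:
    """Fractional sarcomere shortening, percent, averaged over beats.

    A constant sarcomere length gives 0% (a valid outcome, not an error).
    """
    tr = _windowed(trace, window)
    fs = []
    for _, t0, t1, sel in _beat_slices(tr):
        sl = tr.SL[sel]
        sl_dia = sl[0]
        fs.append((sl_dia - sl.min()) / sl_dia * 100.0)
    if not fs:
        raise ValueError("no complete beat in the analysis window")
    return {"fractional_shortening": float(np.mean(fs))}


def waveform_metrics(trace: SimTrace,
                     window: Optional[float] = None) -> WaveformMetrics:
    """All AP / CaT / contraction metrics for one trace."""
    out = {}
    out.update(ap_metrics(trace, window))
    out.update(cat_metrics(trace, window))
    out.update(contraction_metrics(trace, window))
    return WaveformMetrics(**out)


# ---------------------------------------------------------------------------
# arrhythmia classification


def _detect_ead(t: np.ndarray, v: np.ndarray,
                cfg: ClassifierConfig) -> Optional[float]:
    """Time of the first EAD-like deflection in one beat, else None.

    During repolarization (after the beat's peak, inside the configured
    voltage band, before V first reaches the band floor), a rise of at least
    ``ead_prominence`` mV above the running local minimum counts as an EAD.
    """
    lo, hi = cfg.ead_band
    i_pk = int(np.argmax(v))
    seg_t, seg_v = t[i_pk:], v[i_pk:]
    reached = np.nonzero(seg_v <= lo)[0]
    stop = reached[0] + 1 if reached.size else len(seg_v)
    seg_t, seg_v = seg_t[:stop], seg_v[:stop]
    run_min = np.minimum.accumulate(seg_v)
    rise = seg_v - run_min
    mask = (seg_v > lo) & (seg_v < hi) & (rise >= cfg.ead_prominence)
    if mask.any():
        return float(seg_t[int(np.argmax(mask))])
    return None


def _detect_upstrokes(t: np.ndarray, v: np.ndarray,
                      cfg: ClassifierConfig) -> np.ndarray:
    """Onset times of full upstrokes (dV/dt threshold crossings from below)."""
    dv = np.gradient(v, t)
    fast = dv >= cfg.upstroke_dvdt
    onsets = np.nonzero(fast & ~np.roll(fast, 1))[0]
    if fast.size and fast[0]:
        onsets = np.union1d(onsets, [0])
    return t[onsets]


def classify_arrhythmia(trace: SimTrace, window: Optional[float] = None,
                        config: Optional[ClassifierConfig] = None,
                        ) -> ArrhythmiaCall:
    """Label the analysis window as normal or one arrhythmic category.

    Precedence when several features coexist: EAD, then repolarization
    failure, then spontaneous depolarization.
    """
    cfg = config or ClassifierConfig()
    tr = _windowed(trace, window)
    if tr.stimulus_times.size == 0:
        raise ValueError("analysis window contains no stimulus marks")

    edges = _beat_edges(tr)
    repol_fail: Optional[Tuple[int, float]] = None
    spont: Optional[Tuple[int, float]] = None
    for k, (t0, t1) in enumerate(edges):
        sel = (tr.time >= t0 - 1e-12) & (tr.time <= t1 + 1e-12)
        t, v = tr.time[sel], tr.V[sel]
        t_ead = _detect_ead(t, v, cfg)
        if t_ead is not None:
            return ArrhythmiaCall(EAD, beat_index=k, time=t_ead)
        # failure to repolarize: after the beat's peak, V never returns below
        # the diastolic level before the next stimulus
        i_pk = int(np.argmax(v))
        if v[i_pk:].min() > cfg.repol_fail_level and repol_fail is None:
            repol_fail = (k, float(t[i_pk + int(np.argmin(v[i_pk:]))]))
        if spont is None:
            next_stim = t1
            for t_up in _detect_upstrokes(t, v, cfg):
                if (t_up - t0 > cfg.paced_response_window
                        and next_stim - t_up >= cfg.spont_lead):
                    spont = (k, float(t_up))
                    break
    if repol_fail is not None:
        return ArrhythmiaCall(REPOL_FAILURE, *repol_fail)
    if spont is not None:
        return ArrhythmiaCall(SPONTANEOUS, *spont)
    return ArrhythmiaCall(NORMAL)


# ---------------------------------------------------------------------------
# change classification and rankings


def classify_change(metric_drug: float, metric_ctrl: float,
                    threshold: float = 0.20) -> str:
    """'increase' (>20%), 'decrease' (<20%), or 'no_change'.

    Boundaries are strict: a ratio of exactly 1.2 or 0.8 is 'no_change'.
    """
    if not metric_ctrl > 0:
        raise ValueError("control metric must be positive")
    ratio = metric_drug / metric_ctrl
    if ratio > 1.0 + threshold:
        return "increase"
    if ratio < 1.0 - threshold:
        return "decrease"
    return "no_change"


def rank_drugs(metric_ratios: Mapping[str, float],
               k: Optional[int] = 10) -> List[Tuple[str, float]]:
    """Top-k drugs by log2 metric change vs control, descending.

    ``metric_ratios`` maps drug id to (drug metric / control metric).  Ties
    are broken by drug id lexicographically.
    """
    for d, r in metric_ratios.items():
        if not (np.isfinite(r) and r > 0):
            raise ValueError(f"non-positive or non-finite ratio for {d!r}")
    ranked = sorted(metric_ratios.items(),
                    key=lambda kv: (-math.log2(kv[1]), kv[0]))
    ranked = [(d, math.log2(r)) for d, r in ranked]
    return ranked if k is None else ranked[:int(k)]


def compare_rankings(full_ranking_a: Sequence[str],
                     full_ranking_b: Sequence[str],
                     k: int = 10) -> float:
    """Spearman rank correlation between two drug rankings.

    Computed over the union of drugs appearing in either top-k list, using
    each drug's full-cohort rank in both orderings.
    """
    rank_a = {d: i + 1 for i, d in enumerate(full_ranking_a)}
    rank_b = {d: i + 1 for i, d in enumerate(full_ranking_b)}
    union = sorted(set(list(full_ranking_a)[:k]) | set(list(full_ranking_b)[:k]))
    missing = [d for d in union if d not in rank_a or d not in rank_b]
    if missing:
        raise ValueError(f"drugs missing from one ranking: {missing}")
    if len(union) < 2:
        raise ValueError("need at least two drugs to correlate rankings")
    rho, _ = spearmanr([rank_a[d] for d in union], [rank_b[d] for d in union])
    return float(rho)
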