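"""Graded arrhythmogenic insults, susceptibility thresholds, Arrhythmic Index, ΔQ.

Three secondary insults are applied on top of a (possibly drug-scaled) model:
hypokalemia (lowered extracellular [K+]), an increase of L-type Ca2+ current,
and block of the rapid delayed rectifier I_Kr.  Each insult is graded over 10
levels from none to severe; the minimal level at which the paced model shows
arrhythmic dynamics (EAD, repolarization failure, spontaneous depolarization,
or outright integrator failure) is the susceptibility threshold.  Per-drug
threshold shifts relative to control are summarized in an Arrhythmic Index
(positive = increased susceptibility), and mechanisms are decomposed by
integrating each of the 8 analyzed ionic currents over one action potential
(ΔQ = Q_drug − Q_control; negative ΔQ opposes repolarization, proarrhythmic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import (NORMAL, SIM_FAILURE, ClassifierConfig,
                      classify_arrhythmia)
from .model import (CURRENT_NAMES, PacingProtocol, ParameterSet, SimTrace,
                    SimulationError, SolverSettings,
                    set_extracellular_potassium, simulate)

__all__ = [
    "InsultSpec",
    "ThresholdResult",
    "AIResult",
    "ChargeDelta",
    "INSULT_TYPES",
    "apply_insult",
    "find_threshold",
    "arrhythmic_index",
    "delta_Q",
    "mechanism_report",
    "SimulationCache",
    "hypokalemia_experimental_ladder",
]

HYPOKALEMIA = "hypokalemia"
ICAL_INCREASE = "ICaL_increase"
IKR_BLOCK = "IKr_block"
INSULT_TYPES = (HYPOKALEMIA, ICAL_INCREASE, IKR_BLOCK)

NO_THRESHOLD = None  # sentinel: no level produced arrhythmia


@dataclass(frozen=True)
class InsultSpec:
    """One graded insult: type plus an ordered mild-to-severe level ladder.

    Level values are Ko in mM for hypokalemia (decreasing), a multiplicative
    G_CaL factor >= 1 (increasing), or an I_Kr block fraction in [0, 1)
    (increasing).  Level index 0 means "no insult" in :func:`apply_insult`.
    """

    insult_type: str
    levels: Tuple[float, ...]

    def __post_init__(self):
        if self.insult_type not in INSULT_TYPES:
            raise ValueError(f"unknown insult type {self.insult_type!r}")
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 1:
            raise ValueError("an insult needs at least one level")
        diffs = np.diff(lv)
        if self.insult_type == HYPOKALEMIA:
            if not (lv > 0).all() or (diffs >= 0).any():
                raise ValueError("hypokalemia levels must be positive, strictly decreasing")
        elif self.insult_type == ICAL_INCREASE:
            if not (lv >= 1).all() or (diffs <= 0).any():
                raise ValueError("ICaL factors must be >= 1, strictly increasing")
        else:
            if not ((lv >= 0) & (lv < 1)).all() or (diffs <= 0).any():
                raise ValueError("IKr block fractions must be in [0, 1), strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def default_grid(cls, insult_type: str, n_levels: int = 10) -> "InsultSpec":
        """Default mild-to-severe ladders (10 levels, no-insult first).

        Hypokalemia: Ko linear 5.4 -> 2.0 mM (embeds the experimental ladder
        range); ICaL factor 1.0 -> 3.0; IKr block 0 -> 90%.
        """
        if insult_type == HYPOKALEMIA:
            levels = np.linspace(5.4, 2.0, n_levels)
        elif insult_type == ICAL_INCREASE:
            levels = np.linspace(1.0, 3.0, n_levels)
        elif insult_type == IKR_BLOCK:
            levels = np.linspace(0.0, 0.9, n_levels)
        else:
            raise ValueError(f"unknown insult type {insult_type!r}")
        return cls(insult_type, tuple(float(x) for x in levels))

    @classmethod
    def default_battery(cls) -> Tuple["InsultSpec", ...]:
        return tuple(cls.default_grid(t) for t in INSULT_TYPES)


def hypokalemia_experimental_ladder() -> InsultSpec:
    """The 4-step experimental [K+] ladder: 5.4, 4.1, 2.9, 2.5 mM."""
    return InsultSpec(HYPOKALEMIA, (5.4, 4.1, 2.9, 2.5))


def apply_insult(params: ParameterSet, spec: InsultSpec,
                 level_index: int) -> ParameterSet:
    """Parameters at one insult level; index 0 = no insult.

    Insults compose multiplicatively with transcriptomic scaling (they act on
    the already-scaled parameter values).
    """
    if level_index == 0:
        return params
    if not 1 <= level_index <= spec.n_levels:
        raise IndexError(f"level index {level_index} outside 1..{spec.n_levels}")
    value = spec.levels[level_index - 1]
    if spec.insult_type == HYPOKALEMIA:
        return set_extracellular_potassium(params, value)
    if spec.insult_type == ICAL_INCREASE:
        return params.scaled({"G_CaL": value})
    return params.scaled({"G_Kr": 1.0 - value})


# ---------------------------------------------------------------------------
# simulation cache (the level sweeps revisit identical parameter sets)


class SimulationCache:
    """In-memory memo of analysis-window traces keyed by (params, protocol)."""

    def __init__(self, window_margin: float = 0.0):
        self._store: Dict[Tuple, object] = {}
        self.window_margin = window_margin

    def _key(self, params: ParameterSet, protocol: PacingProtocol):
        return (params.digest(), protocol.pacing_rate, protocol.total_duration,
                protocol.stimulus_amplitude, protocol.stimulus_duration,
                protocol.analysis_window)

    def get_window(self, params: ParameterSet, protocol: PacingProtocol,
                   solver: Optional[SolverSettings] = None) -> SimTrace:
        """Simulate (or reuse) and return the terminal analysis window.

        Integrator failures are cached too, and re-raised on reuse.
        """
        key = self._key(params, protocol)
        if key not in self._store:
            try:
                trace = simulate(params, protocol, solver=solver,
                                 keep_states=False)
            except SimulationError as err:
                self._store[key] = err
            else:
                self._store[key] = trace.window(
                    protocol.analysis_window + self.window_margin)
        hit = self._store[key]
        if isinstance(hit, SimulationError):
            raise hit
        return hit


@dataclass
class ThresholdResult:
    """Minimal arrhythmic insult level for one model under one insult."""

    insult_type: str
    threshold_index: Optional[int]   # 1..n, or None if no level is arrhythmic
    label: Optional[str]             # arrhythmia label at threshold
    spec: InsultSpec
    per_level_labels: Optional[List[str]] = None

    @property
    def found(self) -> bool:
        return self.threshold_index is not None


def find_threshold(params: ParameterSet, spec: InsultSpec,
                   protocol: Optional[PacingProtocol] = None,
                   classifier: Optional[ClassifierConfig] = None,
                   cache: Optional[SimulationCache] = None,
                   scan_all_levels: bool = False) -> ThresholdResult:
    """Scan insult levels mild -> severe and return the first arrhythmic one.

    A simulation failure at a level counts as arrhythmic at that level (severe
    insults can push the equations past integrability; skipping such levels
    would bias thresholds toward "safe").  A failure at level 0 (no insult)
    raises: the model is invalid before any insult.
    """
    protocol = protocol or PacingProtocol()
    cache = cache or SimulationCache()
    try:
        cache.get_window(params, protocol)
    except SimulationError as err:
        raise SimulationError(
            f"model fails to simulate with no insult applied: {err}") from err

    threshold, label = None, None
    labels: List[str] = []
    for idx in range(1, spec.n_levels + 1):
        try:
            win = cache.get_window(apply_insult(params, spec, idx), protocol)
            call = classify_arrhythmia(win, config=classifier)
            this_label = call.label
        except SimulationError:
            this_label = SIM_FAILURE
        labels.append(this_label)
        if this_label != NORMAL and threshold is None:
            threshold, label = idx, this_label
            if not scan_all_levels:
                break
    return ThresholdResult(insult_type=spec.insult_type,
                           threshold_index=threshold, label=label, spec=spec,
                           per_level_labels=labels if scan_all_levels else None)


# ---------------------------------------------------------------------------
# Arrhythmic Index


@dataclass
class AIResult:
    """Per-drug, per-cell-line susceptibility summary.

    ``susceptibility[i] = (t_ctrl − t_drug) / L`` for insult i, where L is the
    number of levels and a never-arrhythmic sentinel maps to L+1; AI is the
    weighted average.  Positive AI = the drug makes the cell arrhythmic at a
    milder insult than control (increased susceptibility).
    """

    drug_id: str
    cell_line: str
    susceptibility: Dict[str, float]
    AI: float


def _effective_threshold(res: ThresholdResult) -> int:
    return res.threshold_index if res.found else res.spec.n_levels + 1


def arrhythmic_index(drug_thresholds: Sequence[ThresholdResult],
                     ctrl_thresholds: Sequence[ThresholdResult],
                     weights: Optional[Sequence[float]] = None,
                     drug_id: str = "", cell_line: str = "") -> AIResult:
    """Weighted average of normalized threshold shifts over the insults."""
    if len(drug_thresholds) != len(ctrl_thresholds):
        raise ValueError("drug and control threshold lists differ in length")
    w = np.ones(len(drug_thresholds)) if weights is None else np.asarray(weights, float)
    if w.size != len(drug_thresholds) or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    susc: Dict[str, float] = {}
    for d, c in zip(drug_thresholds, ctrl_thresholds):
        if d.spec != c.spec:
            raise ValueError(
                f"mismatched insult specs for {d.insult_type}: thresholds are "
                "only comparable on identical level ladders")
        susc[d.insult_type] = (
            (_effective_threshold(c) - _effective_threshold(d)) / d.spec.n_levels)
    ai = float(np.dot(w, list(susc.values())) / w.sum())
    return AIResult(drug_id=drug_id, cell_line=cell_line,
                    susceptibility=susc, AI=ai)


# ---------------------------------------------------------------------------
# integrated charge (ΔQ)


@dataclass
class ChargeDelta:
    """Per-current integrated-charge differences (drug − control), A·ms/F.

    ``dq`` covers the 7 single-direction currents; NCX, which reverses during
    the action potential, is split into outward (positive) and inward
    (negative) components integrated separately.
    """

    dq: Dict[str, float]
    dq_ncx_outward: float
    dq_ncx_inward: float
    insult_type: Optional[str] = None
    level_index: Optional[int] = None

    @property
    def dq_ncx_total(self) -> float:
        return self.dq_ncx_outward + self.dq_ncx_inward

    def totals(self) -> Dict[str, float]:
        out = dict(self.dq)
        out["I_NCX"] = self.dq_ncx_total
        return out

    def as_table(self) -> pd.DataFrame:
        rows = []
        for name, val in sorted(self.totals().items(),
                                key=lambda kv: -abs(kv[1])):
            rows.append((name, "total", val, _direction(val)))
        rows.append(("I_NCX", "outward", self.dq_ncx_outward,
                     _direction(self.dq_ncx_outward)))
        rows.append(("I_NCX", "inward", self.dq_ncx_inward,
                     _direction(self.dq_ncx_inward)))
        return pd.DataFrame(rows, columns=["current", "component",
                                           "delta_Q", "direction"])


def _direction(dq: float) -> str:
    if dq < 0:
        return "proarrhythmic"
    if dq > 0:
        return "protective"
    return "neutral"


def _cross_time(t: np.ndarray, y: np.ndarray, level: float,
                upward: bool) -> Optional[float]:
    hit = y > level if upward else y < level
    if not hit.any():
        return None
    i = int(np.argmax(hit))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    return float(t[i - 1] + (level - y0) / (y1 - y0) * (t[i] - t[i - 1]))


def _ap_integration_window(trace: SimTrace) -> Tuple[float, float]:
    """Last complete AP: upstroke to min(90% repolarization, next stimulus).

    Both endpoints are located by linear interpolation of voltage-level
    crossings (10% of amplitude up; 90% repolarized down) so the window, and
    hence the integrated charge, is insensitive to the output sampling grid.
    """
    period = 1.0 / trace.pacing_rate
    t_end = trace.time[-1]
    starts = [st for st in trace.stimulus_times if st + period <= t_end + 1e-6]
    if not starts:
        raise ValueError("trace contains no complete action potential")
    t0, t1 = float(starts[-1]), float(starts[-1] + period)
    sel = (trace.time >= t0) & (trace.time <= t1)
    t, v = trace.time[sel], trace.V[sel]
    v0 = v[0]
    i_pk = int(np.argmax(v))
    peak = v[i_pk]
    t_up = _cross_time(t, v, v0 + 0.1 * (peak - v0), upward=True)
    if t_up is None:
        t_up = t0
    level = peak - 0.9 * (peak - v0)
    t_rep = _cross_time(t[i_pk:], v[i_pk:], level, upward=False)
    if t_rep is None:
        t_rep = t1  # repolarization failed: integrate to the next stimulus
    return t_up, min(t_rep, t1)


def _integrate_currents(trace: SimTrace,
                        window: Tuple[float, float]) -> Dict[str, float]:
    """Trapezoidal charge per current over the window, in A·ms/F.

    The window endpoints rarely coincide with output samples; current values
    there are obtained by linear interpolation so the quadrature converges
    with the sampling interval.
    """
    t0, t1 = window
    inside = (trace.time > t0) & (trace.time < t1)
    t = np.concatenate(([t0], trace.time[inside], [t1]))
    out: Dict[str, float] = {}
    for name in CURRENT_NAMES:
        raw = trace.currents[name]
        i = np.concatenate(([np.interp(t0, trace.time, raw)],
                            raw[inside],
                            [np.interp(t1, trace.time, raw)]))
        if name == "I_NCX":
            out["I_NCX_outward"] = float(
                np.trapezoid(np.where(i > 0, i, 0.0), t)) * 1000.0
            out["I_NCX_inward"] = float(
                np.trapezoid(np.where(i < 0, i, 0.0), t)) * 1000.0
        else:
            out[name] = float(np.trapezoid(i, t)) * 1000.0
    return out


def delta_Q(drug_trace: SimTrace, ctrl_trace: SimTrace,
            insult_type: Optional[str] = None,
            level_index: Optional[int] = None) -> ChargeDelta:
    """ΔQ per analyzed current over the last complete AP of each trace."""
    if not math.isclose(drug_trace.pacing_rate, ctrl_trace.pacing_rate):
        raise ValueError("traces were paced at different rates")
    q_drug = _integrate_currents(drug_trace, _ap_integration_window(drug_trace))
    q_ctrl = _integrate_currents(ctrl_trace, _ap_integration_window(ctrl_trace))
    dq = {k: q_drug[k] - q_ctrl[k] for k in q_drug
          if not k.startswith("I_NCX")}
    return ChargeDelta(
        dq=dq,
        dq_ncx_outward=q_drug["I_NCX_outward"] - q_ctrl["I_NCX_outward"],
        dq_ncx_inward=q_drug["I_NCX_inward"] - q_ctrl["I_NCX_inward"],
        insult_type=insult_type, level_index=level_index)


def mechanism_report(drug_params: ParameterSet, ctrl_params: ParameterSet,
                     spec: InsultSpec, threshold_index: Optional[int],
                     protocol: Optional[PacingProtocol] = None,
                     cache: Optional[SimulationCache] = None) -> ChargeDelta:
    """ΔQ decomposition at the insult level immediately before threshold.

    Simulations are run at ``threshold_index − 1`` (level 0, no insult, if the
    threshold is the first level), the state in which the next increment of
    insult tips the drug-treated cell into arrhythmia.
    """
    if threshold_index is None:
        raise ValueError("mechanism report requires a known threshold level")
    protocol = protocol or PacingProtocol()
    cache = cache or SimulationCache()
    level = max(int(threshold_index) - 1, 0)
    drug_win = cache.get_window(apply_insult(drug_params, spec, level), protocol)
    ctrl_win = cache.get_window(apply_insult(ctrl_params, spec, level), protocol)
    return delta_Q(drug_win, ctrl_win, insult_type=spec.insult_type,
                   level_index=level)
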