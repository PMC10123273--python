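"""End-to-end pipeline stages tying expression scaling to simulations and risk.

These are the library-level work units behind the command-line entry points:
baseline characterization, per-drug waveform prediction with change
classification and top-k rankings, and the secondary-insult battery
(thresholds, Arrhythmic Index, ΔQ mechanism decomposition).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import VEHICLE, ExpressionMatrix, GeneParameterMap, build_drug_models
from .insults import (InsultSpec, SimulationCache, arrhythmic_index,
                      find_threshold, mechanism_report)
from .metrics import (ClassifierConfig, classify_change, rank_drugs,
                      waveform_metrics)
from .model import (PacingProtocol, ParameterSet, SimTrace, SolverSettings,
                    simulate)

__all__ = [
    "run_baseline",
    "run_integration",
    "run_insult_battery",
    "RANKING_METRICS",
]

logger = logging.getLogger(__name__)

#: metrics the per-drug rankings are built on: AP triangulation increase and
#: contractile failure (fold reduction of fractional shortening)
RANKING_METRICS = ("AP_triangulation", "contractile_failure")

_CHANGE_METRICS = ("APD50", "APD90", "AP_triangulation", "CaT_amplitude",
                   "CaD50", "CaD90", "CaT_triangulation", "Decay_Tau",
                   "CaT_AUC", "fractional_shortening")


def run_baseline(params: Optional[ParameterSet] = None,
                 protocol: Optional[PacingProtocol] = None,
                 solver: Optional[SolverSettings] = None,
                 ) -> Tuple[SimTrace, pd.DataFrame]:
    """Simulate the unscaled model and extract its waveform metrics."""
    params = params or ParameterSet.default()
    protocol = protocol or PacingProtocol()
    trace = simulate(params, protocol, solver=solver)
    m = waveform_metrics(trace, protocol.analysis_window)
    table = pd.DataFrame([m.as_dict()])
    return trace, table


def run_integration(expr: ExpressionMatrix,
                    gene_map: Optional[GeneParameterMap] = None,
                    baseline: Optional[ParameterSet] = None,
                    protocol: Optional[PacingProtocol] = None,
                    solver: Optional[SolverSettings] = None,
                    drugs: Optional[Sequence[str]] = None,
                    cell_lines: Optional[Sequence[str]] = None,
                    top_k: int = 10,
                    cache: Optional[SimulationCache] = None,
                    ) -> Dict[str, object]:
    """Scale, simulate and summarize every (cell line, drug) condition.

    Returns a dict with the scale-factor audit table, the per-metric
    change-classification table, and per-cell-line top-k rankings for AP
    triangulation and contractile failure.
    """
    protocol = protocol or PacingProtocol()
    cache = cache or SimulationCache()
    models, audit = build_drug_models(expr, gene_map, baseline,
                                      drugs=drugs, cell_lines=cell_lines)

    metrics_by_cond: Dict[Tuple[str, str], Dict[str, float]] = {}
    for (line, cond), params in sorted(models.items()):
        win = cache.get_window(params, protocol)
        metrics_by_cond[(line, cond)] = waveform_metrics(win).as_dict()
        logger.info("metrics computed for %s / %s", line, cond)

    rows = []
    lines = sorted({line for line, _ in models})
    for line in lines:
        ctrl = metrics_by_cond[(line, VEHICLE)]
        for (l2, cond), vals in sorted(metrics_by_cond.items()):
            if l2 != line or cond == VEHICLE:
                continue
            for metric in _CHANGE_METRICS:
                c, d = ctrl[metric], vals[metric]
                ratio = d / c if c > 0 else np.nan
                call = (classify_change(d, c) if c > 0 else "undefined")
                rows.append((line, cond, metric, c, d, ratio, call))
    changes = pd.DataFrame(rows, columns=[
        "cell_line", "drug", "metric", "control_value", "drug_value",
        "ratio", "classification"])

    rankings: Dict[str, Dict[str, List[Tuple[str, float]]]] = {}
    for line in lines:
        ctrl = metrics_by_cond[(line, VEHICLE)]
        drugs_here = sorted(cond for l2, cond in metrics_by_cond
                            if l2 == line and cond != VEHICLE)
        if not drugs_here:
            continue
        tri = {d: metrics_by_cond[(line, d)]["AP_triangulation"]
               / ctrl["AP_triangulation"] for d in drugs_here}
        # contractile failure: fold *reduction* of shortening, so invert the
        # ratio; a floor guards drugs that abolish contraction entirely
        fs_floor = 1e-6
        con = {d: ctrl["fractional_shortening"]
               / max(metrics_by_cond[(line, d)]["fractional_shortening"], fs_floor)
               for d in drugs_here}
        rankings[line] = {
            "AP_triangulation": rank_drugs(tri, k=top_k),
            "contractile_failure": rank_drugs(con, k=top_k),
        }

    return {"models": models, "factors": audit, "changes": changes,
            "rankings": rankings, "metrics": metrics_by_cond}


def run_insult_battery(models: Mapping[Tuple[str, str], ParameterSet],
                       specs: Optional[Sequence[InsultSpec]] = None,
                       protocol: Optional[PacingProtocol] = None,
                       classifier: Optional[ClassifierConfig] = None,
                       ai_weights: Optional[Sequence[float]] = None,
                       cache: Optional[SimulationCache] = None,
                       ) -> Dict[str, pd.DataFrame]:
    """Thresholds, Arrhythmic Index and ΔQ mechanisms for every condition.

    ``models`` maps (cell_line, condition) to parameters and must contain a
    vehicle entry per cell line (the threshold reference).
    """
    specs = tuple(specs) if specs is not None else InsultSpec.default_battery()
    protocol = protocol or PacingProtocol()
    cache = cache or SimulationCache()

    lines = sorted({line for line, _ in models})
    ctrl_thresholds = {}
    for line in lines:
        if (line, VEHICLE) not in models:
            raise ValueError(f"no vehicle control model for cell line {line!r}")
        ctrl_thresholds[line] = [
            find_threshold(models[(line, VEHICLE)], spec, protocol,
                           classifier=classifier, cache=cache)
            for spec in specs]
        logger.info("control thresholds for line %s: %s", line,
                    [t.threshold_index for t in ctrl_thresholds[line]])

    thr_rows, ai_rows, dq_rows = [], [], []
    for (line, cond), params in sorted(models.items()):
        results = (ctrl_thresholds[line] if cond == VEHICLE else
                   [find_threshold(params, spec, protocol,
                                   classifier=classifier, cache=cache)
                    for spec in specs])
        for res in results:
            thr_rows.append((line, cond, res.insult_type,
                             res.threshold_index if res.found else "none",
                             res.label or "normal"))
        ai = arrhythmic_index(results, ctrl_thresholds[line],
                              weights=ai_weights, drug_id=cond, cell_line=line)
        ai_rows.append((line, cond, *ai.susceptibility.values(), ai.AI))

        if cond == VEHICLE:
            continue
        for spec, res in zip(specs, results):
            if not res.found:
                continue
            cd = mechanism_report(params, models[(line, VEHICLE)], spec,
                                  res.threshold_index, protocol, cache)
            for row in cd.as_table().itertuples(index=False):
                dq_rows.append((line, cond, spec.insult_type, cd.level_index,
                                row.current, row.component, row.delta_Q,
                                row.direction))

    thresholds = pd.DataFrame(thr_rows, columns=[
        "cell_line", "drug", "insult", "threshold_index", "label"])
    ai_table = pd.DataFrame(ai_rows, columns=[
        "cell_line", "drug", *(s.insult_type for s in specs), "AI"])
    dq_table = pd.DataFrame(dq_rows, columns=[
        "cell_line", "drug", "insult", "level", "current", "component",
        "delta_Q", "direction"])
    return {"thresholds": thresholds, "ai": ai_table, "dq": dq_table}
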