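"""Delimited-text readers and writers for every pipeline artifact.

All tables are tab-separated; floats are written with 17 significant digits
so a written table read back reproduces the in-memory values exactly.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .expression import ExpressionMatrix, GeneParameterMap
from .model import CURRENT_NAMES, SimTrace

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_map",
    "write_gene_map",
    "read_table",
    "write_table",
    "write_trace",
    "read_trace",
]

_FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path: str, index_col: Optional[int] = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def read_expression(expr_path: str, annot_path: str) -> ExpressionMatrix:
    """Expression matrix (genes as rows) plus sample-annotation sheet."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    annotations = pd.read_csv(annot_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, annotations)


def write_expression(expr: ExpressionMatrix, expr_path: str,
                     annot_path: str) -> None:
    write_table(expr.values, expr_path, index=True)
    write_table(expr.annotations, annot_path, index=True)


def read_gene_map(path: str) -> GeneParameterMap:
    return GeneParameterMap.from_frame(pd.read_csv(path, sep="\t"))


def write_gene_map(gene_map: GeneParameterMap, path: str) -> None:
    write_table(gene_map.to_frame(), path)


def write_trace(trace: SimTrace, path: str) -> None:
    """Trace export: time, V, Cai, SL and the 8 analyzed currents."""
    cols = {"time_s": trace.time, "V_mV": trace.V, "Cai_uM": trace.Cai,
            "SL_um": trace.SL}
    for name in CURRENT_NAMES:
        cols[f"{name}_ApF"] = trace.currents[name]
    write_table(pd.DataFrame(cols), path)


def read_trace(path: str) -> pd.DataFrame:
    return read_table(path)
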