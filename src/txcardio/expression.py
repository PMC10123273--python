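"""Conversion of drug-vs-control gene expression into model parameter scale factors.

The premise: a drug-induced change in the mRNA abundance of the genes encoding
an ion-transport pathway is mapped onto the corresponding model parameter as a
multiplicative fold change of weighted abundance sums,

    scale_factor = sum_i(w_i * Ybar_i,drug) / sum_i(w_i * Ybar_i,control)

where ``Ybar`` is the replicate-mean normalized abundance of gene ``i`` and the
sums run over the genes mapped to one parameter.  Each scaled conductance (or
pump/myofilament magnitude) is then ``default * scale_factor``, with all other
model equations unmodified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import SCALABLE_PARAMETERS, ParameterSet

__all__ = [
    "ExpressionMatrix",
    "GeneParameterMap",
    "ScaleFactorSet",
    "compute_scale_factor",
    "scale_parameters",
    "integrate_contractile_genes",
    "build_drug_models",
    "VEHICLE",
    "CONTRACTILE_PARAMETERS",
]

logger = logging.getLogger(__name__)

VEHICLE = "vehicle"
CONTRACTILE_PARAMETERS = ("Trop_Conc", "Myosin_scale", "Actin_scale")

#: pseudocount added to replicate-mean abundances, applied only when the
#: control weighted sum vanishes (guards the ratio against division by zero
#: without biasing well-measured factors)
PSEUDOCOUNT = 0.5


class ExpressionMatrix:
    """Normalized abundances (genes x samples) with sample annotations.

    ``values``: DataFrame indexed by gene symbol, columns = sample ids,
    non-negative CPM-like values.  ``annotations``: DataFrame indexed by
    sample id with columns ``cell_line``, ``condition`` (``vehicle`` or a
    drug id) and ``replicate``.
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing_cols = {"cell_line", "condition", "replicate"} - set(annotations.columns)
        if missing_cols:
            raise ValueError(f"annotation sheet lacks columns: {sorted(missing_cols)}")
        unknown = set(values.columns) - set(annotations.index)
        if unknown:
            raise ValueError(f"samples without annotation: {sorted(unknown)}")
        self.values = values
        self.annotations = annotations.loc[list(values.columns)]
        self._check_vehicle_controls()

    def _check_vehicle_controls(self):
        ann = self.annotations
        for line, sub in ann.groupby("cell_line"):
            drugs = set(sub["condition"]) - {VEHICLE}
            if drugs and not (sub["condition"] == VEHICLE).any():
                raise ValueError(
                    f"cell line {line!r} has drug conditions {sorted(drugs)} "
                    f"but no matching vehicle control samples")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> List[str]:
        return sorted(self.annotations["cell_line"].unique())

    def drugs(self, cell_line: Optional[str] = None) -> List[str]:
        ann = self.annotations
        if cell_line is not None:
            ann = ann[ann["cell_line"] == cell_line]
        return sorted(set(ann["condition"]) - {VEHICLE})

    def samples(self, cell_line: str, condition: str) -> List[str]:
        ann = self.annotations
        sel = (ann["cell_line"] == cell_line) & (ann["condition"] == condition)
        return list(ann.index[sel])

    def replicate_means(self, cell_line: str, condition: str) -> pd.Series:
        cols = self.samples(cell_line, condition)
        if not cols:
            raise KeyError(
                f"no samples for cell line {cell_line!r}, condition {condition!r}")
        return self.values[cols].mean(axis=1)


@dataclass(frozen=True)
class GeneParameterMap:
    """Mapping of model parameters to weighted gene sets."""

    entries: Mapping[str, Tuple[Tuple[str, float], ...]]

    def __post_init__(self):
        for param, genes in self.entries.items():
            if not genes:
                raise ValueError(f"parameter {param!r} has an empty gene set")
            for gene, w in genes:
                if w <= 0:
                    raise ValueError(f"non-positive weight for {gene} ({param})")

    @classmethod
    def default(cls) -> "GeneParameterMap":
        """The packaged 15-parameter map (one row per parameter-gene pair)."""
        ref = resources.files("txcardio.data").joinpath("gene_map.tsv")
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t")
        gpm = cls.from_frame(df)
        assert set(gpm.entries) == set(SCALABLE_PARAMETERS)
        return gpm

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneParameterMap":
        entries: Dict[str, Tuple[Tuple[str, float], ...]] = {}
        for param, sub in df.groupby("parameter", sort=False):
            entries[param] = tuple(
                (str(r.gene), float(r.weight)) for r in sub.itertuples())
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, g, w) for p, genes in self.entries.items() for g, w in genes]
        return pd.DataFrame(rows, columns=["parameter", "gene", "weight"])

    def genes(self) -> List[str]:
        return sorted({g for genes in self.entries.values() for g, _ in genes})

    def __getitem__(self, param: str) -> Tuple[Tuple[str, float], ...]:
        return self.entries[param]

    def __iter__(self):
        return iter(self.entries)


@dataclass
class ScaleFactorSet:
    """Per-parameter multiplicative scale factors for one (cell line, drug)."""

    cell_line: str
    drug_id: str
    factors: Dict[str, float]
    n_genes_used: Dict[str, int] = field(default_factory=dict)
    missing_genes: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.factors.items() if not v > 0}
        if bad:
            raise ValueError(f"scale factors must be positive: {bad}")


def compute_scale_factor(expr: ExpressionMatrix, cell_line: str, drug_id: str,
                         gene_set: Sequence[Tuple[str, float]],
                         pseudocount: float = PSEUDOCOUNT,
                         ) -> Tuple[float, int, List[str]]:
    """Weighted-sum abundance ratio (drug / vehicle) over a gene set.

    Returns ``(factor, n_genes_used, missing_genes)``.  Genes absent from the
    matrix are dropped from numerator and denominator symmetrically and
    reported.  The pseudocount is applied to the replicate means (both
    conditions symmetrically) only if the control weighted sum is zero.
    """
    drug_mean = expr.replicate_means(cell_line, drug_id)
    ctrl_mean = expr.replicate_means(cell_line, VEHICLE)

    present = [(g, w) for g, w in gene_set if g in expr.genes]
    missing = [g for g, _ in gene_set if g not in expr.genes]
    if missing:
        logger.warning("genes absent from matrix, dropped symmetrically: %s",
                       missing)
    if not present:
        raise ValueError("no mapped genes present in the expression matrix")

    genes = [g for g, _ in present]
    w = np.array([wt for _, wt in present], dtype=float)
    num = float(np.dot(w, drug_mean.loc[genes].to_numpy()))
    den = float(np.dot(w, ctrl_mean.loc[genes].to_numpy()))
    if den == 0.0:
        num_pc = float(np.dot(w, drug_mean.loc[genes].to_numpy() + pseudocount))
        den_pc = float(np.dot(w, ctrl_mean.loc[genes].to_numpy() + pseudocount))
        if den_pc == 0.0:
            raise ValueError("control abundance sum is zero even after "
                             f"pseudocount {pseudocount}")
        logger.warning(
            "control sum zero for genes %s; pseudocount %.2f applied "
            "(factor %.4g instead of undefined)", genes, pseudocount,
            num_pc / den_pc)
        num, den = num_pc, den_pc
    return num / den, len(present), missing


def integrate_contractile_genes(expr: ExpressionMatrix, cell_line: str,
                                drug_id: str,
                                gene_map: Optional[GeneParameterMap] = None,
                                ) -> Dict[str, float]:
    """Scale factors for the three contractile parameters.

    Troponin-C (TNNC1) is integrated exactly like an ion channel; the myosin
    heavy chain pair (MYH6+MYH7) scales maximal crossbridge force and ACTC1
    scales thin-filament availability.
    """
    gene_map = gene_map or GeneParameterMap.default()
    out = {}
    for param in CONTRACTILE_PARAMETERS:
        try:
            factor, _, _ = compute_scale_factor(expr, cell_line, drug_id,
                                                gene_map[param])
        except ValueError as e:
            raise ValueError(f"parameter {param}: {e}") from e
        out[param] = factor
    return out


def compute_scale_factors(expr: ExpressionMatrix, cell_line: str, drug_id: str,
                          gene_map: Optional[GeneParameterMap] = None,
                          ) -> ScaleFactorSet:
    """All 15 parameter scale factors for one (cell line, drug)."""
    gene_map = gene_map or GeneParameterMap.default()
    factors, n_used, missing = {}, {}, {}
    for param in gene_map:
        try:
            f, n, miss = compute_scale_factor(expr, cell_line, drug_id,
                                              gene_map[param])
        except ValueError as e:
            raise ValueError(f"parameter {param}: {e}") from e
        factors[param] = f
        n_used[param] = n
        if miss:
            missing[param] = miss
    return ScaleFactorSet(cell_line=cell_line, drug_id=drug_id,
                          factors=factors, n_genes_used=n_used,
                          missing_genes=missing)


def scale_parameters(baseline: ParameterSet,
                     factors: "ScaleFactorSet | Mapping[str, float]",
                     ) -> ParameterSet:
    """Multiply the covered scalable parameters by their factors."""
    mapping = factors.factors if isinstance(factors, ScaleFactorSet) else factors
    return baseline.scaled(dict(mapping))


def build_drug_models(expr: ExpressionMatrix,
                      gene_map: Optional[GeneParameterMap] = None,
                      baseline: Optional[ParameterSet] = None,
                      drugs: Optional[Sequence[str]] = None,
                      cell_lines: Optional[Sequence[str]] = None,
                      ) -> Tuple[Dict[Tuple[str, str], ParameterSet], pd.DataFrame]:
    """One scaled :class:`ParameterSet` per (cell line, drug), plus audit log.

    Vehicle controls map to the unscaled baseline.  The audit table has one
    row per (cell_line, drug, parameter) with the factor and the number of
    mapped genes actually present.
    """
    gene_map = gene_map or GeneParameterMap.default()
    baseline = baseline or ParameterSet.default()
    models: Dict[Tuple[str, str], ParameterSet] = {}
    rows = []
    for line in (cell_lines or expr.cell_lines):
        models[(line, VEHICLE)] = baseline
        for drug in (drugs or expr.drugs(line)):
            sfs = compute_scale_factors(expr, line, drug, gene_map)
            models[(line, drug)] = scale_parameters(baseline, sfs)
            for param, f in sfs.factors.items():
                rows.append((line, drug, param, f, sfs.n_genes_used[param]))
    audit = pd.DataFrame(
        rows, columns=["cell_line", "drug", "parameter", "factor",
                       "n_genes_used"])
    return models, audit
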