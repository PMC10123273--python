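"""Synthetic expression matrices with planted, per-cell-line drug effects.

Emulates the study design the pipeline consumes: two cell lines from
different donors, a 26-drug panel plus vehicle controls, and replicate-level
normalized (CPM-like) abundances.  Drug effects are planted as per-gene fold
changes; replicate noise is multiplicative log-normal, the simplest
positive-valued replicate model consistent with normalized expression data
(no count-level/UMI simulation — the pipeline consumes normalized values).

Alongside the matrix, a planted-truth table lists the parameter scale factors
implied analytically by the planted folds, so recovery can be tested without
re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import VEHICLE, ExpressionMatrix, GeneParameterMap

__all__ = [
    "SynthConfig",
    "generate_expression",
    "preset_divergent_scenario",
    "default_drug_ids",
    "DIVERGENT_DRUG",
]

#: drug whose planted effects diverge between cell lines in the preset
DIVERGENT_DRUG = "TRA"


def default_drug_ids() -> Tuple[str, ...]:
    """The 26-drug panel ids from the packaged roster."""
    ref = resources.files("txcardio.data").joinpath("drugs.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return tuple(df["drug_id"])


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the seed fully determines the output."""

    seed: int
    n_cell_lines: int = 2
    drug_ids: Tuple[str, ...] = field(default_factory=default_drug_ids)
    n_replicates: int = 3
    noise_sigma: float = 0.1          # std of log-normal multiplicative noise
    background_genes: int = 200       # unmapped decoy genes
    baseline_abundance: Mapping[str, float] = field(default_factory=dict)
    planted_effects: Mapping[Tuple[str, str, str], float] = field(
        default_factory=dict)         # (cell_line, drug, gene) -> fold change
    baseline_range: Tuple[float, float] = (10.0, 1000.0)  # log-uniform draw

    def __post_init__(self):
        if self.n_cell_lines < 1 or self.n_replicates < 1:
            raise ValueError("need at least one cell line and one replicate")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for key, fold in self.planted_effects.items():
            if not fold > 0:
                raise ValueError(f"planted fold change must be > 0: {key}")

    @property
    def cell_lines(self) -> Tuple[str, ...]:
        return tuple(chr(ord("A") + i) for i in range(self.n_cell_lines))


def _gene_universe(config: SynthConfig,
                   gene_map: GeneParameterMap) -> List[str]:
    mapped = gene_map.genes()
    decoys = [f"BG{i:04d}" for i in range(config.background_genes)]
    return mapped + decoys


def _baselines(config: SynthConfig, genes: Sequence[str],
               rng: np.random.Generator) -> Dict[str, float]:
    """Per-gene baseline abundances: overrides, else one broad log-uniform draw.

    The broad range exercises sum-based factors with unequal gene
    contributions.
    """
    lo, hi = config.baseline_range
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    base = {g: float(v) for g, v in zip(genes, draws)}
    base.update({g: float(v) for g, v in config.baseline_abundance.items()})
    return base


def _implied_factors(config: SynthConfig, baselines: Mapping[str, float],
                     gene_map: GeneParameterMap) -> pd.DataFrame:
    """Analytic per-parameter scale factors implied by the planted folds."""
    rows = []
    for line in config.cell_lines:
        for drug in config.drug_ids:
            for param in gene_map:
                num = den = 0.0
                for gene, w in gene_map[param]:
                    b = baselines[gene]
                    fold = config.planted_effects.get((line, drug, gene), 1.0)
                    num += w * b * fold
                    den += w * b
                rows.append((line, drug, param, num / den))
    return pd.DataFrame(rows, columns=["cell_line", "drug", "parameter",
                                       "true_factor"])


def generate_expression(config: SynthConfig,
                        gene_map: Optional[GeneParameterMap] = None,
                        ) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Seeded synthetic matrix plus its planted-truth factor table.

    value(gene, sample) = baseline × plantedFold (drug samples of targeted
    genes only) × exp(N(0, σ²)); vehicle samples carry no planted effect.
    """
    gene_map = gene_map or GeneParameterMap.default()
    genes = _gene_universe(config, gene_map)
    gene_set = set(genes)
    for (line, drug, gene) in config.planted_effects:
        if gene not in gene_set:
            raise KeyError(f"planted effect on unknown gene {gene!r}")
        if line not in config.cell_lines:
            raise KeyError(f"planted effect on unknown cell line {line!r}")
        if drug not in config.drug_ids:
            raise KeyError(f"planted effect on unknown drug {drug!r}")

    rng = np.random.default_rng(config.seed)
    baselines = _baselines(config, genes, rng)

    conditions = [VEHICLE, *config.drug_ids]
    columns: Dict[str, np.ndarray] = {}
    ann_rows = []
    base_vec = np.array([baselines[g] for g in genes])
    for line in config.cell_lines:
        for cond in conditions:
            fold_vec = np.array([
                config.planted_effects.get((line, cond, g), 1.0)
                if cond != VEHICLE else 1.0
                for g in genes])
            for rep in range(1, config.n_replicates + 1):
                sid = f"{line}_{cond}_r{rep}"
                noise = (np.exp(rng.normal(0.0, config.noise_sigma, len(genes)))
                         if config.noise_sigma > 0 else 1.0)
                columns[sid] = base_vec * fold_vec * noise
                ann_rows.append((sid, line, cond, rep))

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    annotations = pd.DataFrame(
        ann_rows, columns=["sample_id", "cell_line", "condition", "replicate"]
    ).set_index("sample_id")
    truth = _implied_factors(config, baselines, gene_map)
    return ExpressionMatrix(values, annotations), truth


def preset_divergent_scenario(seed: int = 0) -> SynthConfig:
    """Scenario with one drug that is dangerous in line A, protective in B.

    The drug downregulates K+-current genes (KCNJ2 for I_K1, KCND3 for I_to)
    in cell line A and upregulates the same genes in cell line B; opposite
    conductance scaling produces opposite-signed shifts of the insult
    thresholds, hence opposite-signed Arrhythmic Indices.  Baselines of the
    targeted genes are pinned so the planted genes dominate their parameter
    sums; noise is off so the pattern is deterministic.

    The downregulation is deliberately moderate: the drug-scaled model must
    remain non-arrhythmic with no insult applied (drug treatment alone rarely
    produces arrhythmia; susceptibility emerges under the secondary insult),
    which bounds how far the repolarizing conductances can be reduced.
    """
    folds = {("A", DIVERGENT_DRUG, "KCNJ2"): 0.5,
             ("A", DIVERGENT_DRUG, "KCND3"): 0.5,
             ("B", DIVERGENT_DRUG, "KCNJ2"): 1.8,
             ("B", DIVERGENT_DRUG, "KCND3"): 1.8}
    baselines = {"KCNJ2": 500.0, "KCNJ12": 25.0,
                 "KCND3": 300.0, "KCND2": 30.0, "KCNA4": 10.0, "KCNA7": 5.0}
    return SynthConfig(seed=seed, n_cell_lines=2, noise_sigma=0.0,
                       planted_effects=folds, baseline_abundance=baselines)
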