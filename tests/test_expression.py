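"""Unit tests for expression-to-parameter scale factor computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txcardio.expression import (CONTRACTILE_PARAMETERS, VEHICLE,
                                 ExpressionMatrix, GeneParameterMap,
                                 build_drug_models, compute_scale_factor,
                                 compute_scale_factors,
                                 integrate_contractile_genes, scale_parameters)
from txcardio.model import SCALABLE_PARAMETERS, ParameterSet


def matrix_from(gene_values, cell_line="A", drug="DRUG", n_rep=1):
    """Small two-condition matrix: gene -> (ctrl_value, drug_value)."""
    genes = list(gene_values)
    cols, ann = {}, []
    for cond in (VEHICLE, drug):
        for r in range(1, n_rep + 1):
            sid = f"{cell_line}_{cond}_r{r}"
            cols[sid] = [gene_values[g][0 if cond == VEHICLE else 1]
                         for g in genes]
            ann.append((sid, cell_line, cond, r))
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    annotations = pd.DataFrame(
        ann, columns=["sample_id", "cell_line", "condition", "replicate"]
    ).set_index("sample_id")
    return ExpressionMatrix(values, annotations)


class TestExpressionMatrix:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            matrix_from({"KCNH2": (-1.0, 2.0)})

    def test_missing_vehicle_control_rejected(self):
        values = pd.DataFrame({"A_DRUG_r1": [1.0]},
                              index=pd.Index(["KCNH2"], name="gene"))
        ann = pd.DataFrame([("A_DRUG_r1", "A", "DRUG", 1)],
                           columns=["sample_id", "cell_line", "condition",
                                    "replicate"]).set_index("sample_id")
        with pytest.raises(ValueError, match="vehicle"):
            ExpressionMatrix(values, ann)

    def test_duplicate_genes_rejected(self):
        values = pd.DataFrame({"A_vehicle_r1": [1.0, 2.0]},
                              index=pd.Index(["KCNH2", "KCNH2"], name="gene"))
        ann = pd.DataFrame([("A_vehicle_r1", "A", VEHICLE, 1)],
                           columns=["sample_id", "cell_line", "condition",
                                    "replicate"]).set_index("sample_id")
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values, ann)


class TestGeneParameterMap:
    def test_default_covers_the_15_parameters(self):
        gpm = GeneParameterMap.default()
        assert set(gpm.entries) == set(SCALABLE_PARAMETERS)
        assert gpm["G_Kr"] == (("KCNH2", 1.0),)
        assert [g for g, _ in gpm["Myosin_scale"]] == ["MYH6", "MYH7"]
        assert len(gpm["G_CaL"]) == 11  # all voltage-gated Ca channel genes
        assert "CACNA2D1" in [g for g, _ in gpm["G_CaL"]]

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            GeneParameterMap({"G_Kr": ()})


class TestComputeScaleFactor:
    def test_identical_drug_and_control_gives_one(self):
        expr = matrix_from({"KCNH2": (7.0, 7.0), "KCNJ2": (3.0, 3.0)})
        f, n, miss = compute_scale_factor(expr, "A", "DRUG",
                                          [("KCNH2", 1.0), ("KCNJ2", 1.0)])
        assert f == 1.0 and n == 2 and miss == []

    def test_single_gene_factor_is_exact_ratio(self):
        expr = matrix_from({"KCNH2": (8.0, 2.0)})
        f, _, _ = compute_scale_factor(expr, "A", "DRUG", [("KCNH2", 1.0)])
        assert f == pytest.approx(0.25, rel=1e-15)

    def test_two_gene_sum_ratio_hand_computed(self):
        # ctrl (10, 2), drug (5, 7), unit weights -> (5+7)/(10+2) = 1.0
        expr = matrix_from({"KCNJ2": (10.0, 5.0), "KCNJ12": (2.0, 7.0)})
        f, _, _ = compute_scale_factor(expr, "A", "DRUG",
                                       [("KCNJ2", 1.0), ("KCNJ12", 1.0)])
        assert f == pytest.approx(1.0, rel=1e-15)

    def test_weights_enter_the_sums(self):
        expr = matrix_from({"G1": (1.0, 2.0), "G2": (1.0, 4.0)})
        f, _, _ = compute_scale_factor(expr, "A", "DRUG",
                                       [("G1", 3.0), ("G2", 1.0)])
        assert f == pytest.approx((3 * 2 + 4) / (3 + 1), rel=1e-15)

    def test_missing_genes_dropped_symmetrically(self):
        expr = matrix_from({"KCNH2": (8.0, 4.0)})
        f, n, miss = compute_scale_factor(
            expr, "A", "DRUG", [("KCNH2", 1.0), ("NOTAGENE", 1.0)])
        assert f == pytest.approx(0.5) and n == 1 and miss == ["NOTAGENE"]

    def test_all_genes_missing_is_an_error(self):
        expr = matrix_from({"KCNH2": (8.0, 4.0)})
        with pytest.raises(ValueError, match="no mapped genes"):
            compute_scale_factor(expr, "A", "DRUG", [("NOPE", 1.0)])

    def test_zero_control_uses_pseudocount_and_logs(self, caplog):
        expr = matrix_from({"KCNH2": (0.0, 4.0)})
        with caplog.at_level("WARNING"):
            f, _, _ = compute_scale_factor(expr, "A", "DRUG", [("KCNH2", 1.0)])
        assert f == pytest.approx(4.5 / 0.5)
        assert "pseudocount" in caplog.text

    def test_replicates_averaged_before_ratio(self):
        values = pd.DataFrame(
            {"A_vehicle_r1": [2.0], "A_vehicle_r2": [4.0],
             "A_X_r1": [9.0], "A_X_r2": [3.0]},
            index=pd.Index(["KCNH2"], name="gene"))
        ann = pd.DataFrame(
            [("A_vehicle_r1", "A", VEHICLE, 1), ("A_vehicle_r2", "A", VEHICLE, 2),
             ("A_X_r1", "A", "X", 1), ("A_X_r2", "A", "X", 2)],
            columns=["sample_id", "cell_line", "condition", "replicate"]
        ).set_index("sample_id")
        expr = ExpressionMatrix(values, ann)
        f, _, _ = compute_scale_factor(expr, "A", "X", [("KCNH2", 1.0)])
        assert f == pytest.approx(6.0 / 3.0, rel=1e-15)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3,
                     allow_nan=False, allow_infinity=False))
    def test_scale_equivariance(self, c):
        """Multiplying all abundances by a constant leaves factors unchanged."""
        expr = matrix_from({"KCNJ2": (10.0, 5.0), "KCNJ12": (2.0, 7.0)})
        scaled = ExpressionMatrix(expr.values * c, expr.annotations)
        gs = [("KCNJ2", 1.0), ("KCNJ12", 1.0)]
        f0, _, _ = compute_scale_factor(expr, "A", "DRUG", gs)
        f1, _, _ = compute_scale_factor(scaled, "A", "DRUG", gs)
        assert f1 == pytest.approx(f0, rel=1e-9)


class TestScaleParameters:
    def test_all_unit_factors_is_identity(self, baseline_params):
        factors = {p: 1.0 for p in SCALABLE_PARAMETERS}
        out = scale_parameters(baseline_params, factors)
        assert np.array_equal(out.to_vector(), baseline_params.to_vector())

    def test_partial_coverage_scales_only_those_fields(self, baseline_params):
        out = scale_parameters(baseline_params, {"G_Kr": 0.5})
        assert out.G_Kr == 0.5 * baseline_params.G_Kr
        diff = np.nonzero(out.to_vector() != baseline_params.to_vector())[0]
        assert len(diff) == 1

    def test_unknown_parameter_rejected(self, baseline_params):
        with pytest.raises(KeyError):
            scale_parameters(baseline_params, {"G_whatever": 1.0})


class TestContractileIntegration:
    def test_unchanged_genes_give_unit_factors(self):
        expr = matrix_from({"TNNC1": (5.0, 5.0), "MYH6": (2.0, 2.0),
                            "MYH7": (3.0, 3.0), "ACTC1": (4.0, 4.0)})
        out = integrate_contractile_genes(expr, "A", "DRUG")
        assert set(out) == set(CONTRACTILE_PARAMETERS)
        assert all(v == 1.0 for v in out.values())

    def test_actin_halving_isolated(self):
        expr = matrix_from({"TNNC1": (5.0, 5.0), "MYH6": (2.0, 2.0),
                            "MYH7": (3.0, 3.0), "ACTC1": (4.0, 2.0)})
        out = integrate_contractile_genes(expr, "A", "DRUG")
        assert out["Actin_scale"] == pytest.approx(0.5)
        assert out["Trop_Conc"] == 1.0 and out["Myosin_scale"] == 1.0

    def test_myosin_uses_summed_heavy_chains(self):
        expr = matrix_from({"TNNC1": (5.0, 5.0), "MYH6": (2.0, 6.0),
                            "MYH7": (6.0, 2.0), "ACTC1": (4.0, 4.0)})
        out = integrate_contractile_genes(expr, "A", "DRUG")
        assert out["Myosin_scale"] == pytest.approx(1.0)


class TestBuildDrugModels:
    def test_planted_kcnh2_fold_recovered_in_model(self, baseline_params):
        gpm = GeneParameterMap.default()
        gene_vals = {g: (10.0, 10.0) for g in gpm.genes()}
        gene_vals["KCNH2"] = (10.0, 5.0)
        expr = matrix_from(gene_vals, drug="X")
        models, audit = build_drug_models(expr, gpm, baseline_params)
        assert models[("A", "X")].G_Kr == pytest.approx(
            0.5 * baseline_params.G_Kr, rel=1e-12)
        assert models[("A", VEHICLE)] is baseline_params
        row = audit[(audit.drug == "X") & (audit.parameter == "G_Kr")]
        assert row.factor.iloc[0] == pytest.approx(0.5)

    def test_condition_counts(self, baseline_params):
        from txcardio.synthetic import SynthConfig, generate_expression
        cfg = SynthConfig(seed=3, noise_sigma=0.0)
        expr, _ = generate_expression(cfg)
        models, audit = build_drug_models(expr, baseline=baseline_params)
        # 26 drugs x 2 cell lines + 2 vehicle controls
        assert len(models) == 26 * 2 + 2
        assert len(audit) == 26 * 2 * 15
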