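"""Three-stage limitation pipeline, reporting tables and flux comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from emoma import (
    LimitationSpec,
    ModelError,
    StageError,
    carbon_partition,
    compare_fluxes,
    exchange_profile,
    make_fixture,
    simulate_limitation,
)


class TestSimulateLimitation:
    def test_toy_a_nitrogen_block(self, toy_a, nitrogen_block):
        res = simulate_limitation(toy_a, nitrogen_block)
        assert res.mu_max == pytest.approx(10.0, abs=1e-6)
        assert res.reference.v_ref.as_dict() == pytest.approx(
            {"EX_glc": 10, "EX_nh4": 10, "GROWTH": 10, "DM_tag": 0}, abs=1e-6)
        assert res.limited.as_dict() == pytest.approx(
            {"EX_glc": 5, "EX_nh4": 0, "GROWTH": 0, "DM_tag": 5}, abs=1e-6)
        assert res.distance == pytest.approx(np.sqrt(25 + 100 + 100 + 25),
                                             abs=1e-5)

    def test_toy_a_carbon_block_zeroes_everything(self, toy_a):
        res = simulate_limitation(toy_a, LimitationSpec("EX_glc"))
        assert np.allclose(res.limited.values, 0.0, atol=1e-6)

    def test_stage2_growth_matches_stage1(self, toy_y, nitrogen_block):
        res = simulate_limitation(toy_y, nitrogen_block)
        biomass = res.reference.v_ref[toy_y.objective_id]
        assert biomass == pytest.approx(res.mu_max, abs=1e-6)

    def test_limited_biomass_zero_when_nutrient_essential(self, toy_y,
                                                          nitrogen_block):
        res = simulate_limitation(toy_y, nitrogen_block)
        assert res.limited[toy_y.objective_id] == pytest.approx(0.0, abs=1e-6)

    def test_blocked_exchange_cannot_import(self, toy_y, nitrogen_block):
        res = simulate_limitation(toy_y, nitrogen_block)
        rxn = toy_y.reaction("EX_nh4")
        assert rxn.import_sign() * res.limited["EX_nh4"] <= 1e-9

    def test_glucose_uptake_drops_under_limitation(self, toy_y, toy_b,
                                                   nitrogen_block):
        for model in (toy_b, toy_y):
            res = simulate_limitation(model, nitrogen_block)
            assert res.limited["EX_glc"] <= res.reference.v_ref["EX_glc"] + 1e-6

    def test_limitation_specificity(self, toy_y):
        """Nitrogen and phosphate blockage yield different limited states."""
        n = simulate_limitation(toy_y, LimitationSpec("EX_nh4"))
        p = simulate_limitation(toy_y, LimitationSpec("EX_pi"))
        assert p.limited[toy_y.objective_id] == pytest.approx(0.0, abs=1e-6)
        assert not np.allclose(n.limited.values, p.limited.values, atol=1e-3)

    def test_non_exchange_block_rejected(self, toy_a):
        with pytest.raises(ModelError, match="kind"):
            simulate_limitation(toy_a, LimitationSpec("GROWTH"))

    def test_stage_failure_names_stage(self, toy_a):
        with pytest.raises(StageError, match="emoma"):
            simulate_limitation(
                toy_a, LimitationSpec("EX_nh4"),
                extra_overrides={"GROWTH": (1.0, 1000.0)})

    @given(cap=st.floats(min_value=0.5, max_value=50.0))
    @hyp_settings(max_examples=15, deadline=None, derandomize=True)
    def test_limited_state_closed_form_scales_with_uptake_cap(self, cap):
        """With both uptake caps at `cap`, the nitrogen-blocked optimum
        splits the carbon deviation evenly: EX_glc = DM_tag = cap/2."""
        model = make_fixture("TOY-A", uptake_cap=cap)
        res = simulate_limitation(model, LimitationSpec("EX_nh4"))
        assert res.limited["EX_glc"] == pytest.approx(cap / 2, abs=1e-5)
        assert res.limited["DM_tag"] == pytest.approx(cap / 2, abs=1e-5)


class TestExchangeProfile:
    def test_toy_a_rows(self, toy_a, nitrogen_block):
        res = simulate_limitation(toy_a, nitrogen_block)
        table = exchange_profile(res, toy_a)
        rows = {r.reaction_id: (r.reference_flux, r.limited_flux)
                for r in table.itertuples()}
        assert rows["EX_glc"] == pytest.approx((10.0, 5.0), abs=1e-6)
        assert rows["EX_nh4"] == pytest.approx((10.0, 0.0), abs=1e-6)
        assert rows["DM_tag"] == pytest.approx((0.0, 5.0), abs=1e-6)

    def test_threshold_dominates(self, toy_a, nitrogen_block):
        res = simulate_limitation(toy_a, nitrogen_block)
        assert exchange_profile(res, toy_a, report_threshold=1e6).empty

    def test_toy_b_citrate_appears(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        table = exchange_profile(res, toy_b)
        cit = table.set_index("reaction_id").loc["EX_cit"]
        assert cit.limited_flux == pytest.approx(10 / 3, abs=1e-6)

    def test_ordering_by_limited_magnitude(self, toy_y, nitrogen_block):
        res = simulate_limitation(toy_y, nitrogen_block)
        table = exchange_profile(res, toy_y)
        mags = table.limited_flux.abs().to_numpy()
        assert (mags[:-1] >= mags[1:] - 1e-12).all()


class TestCarbonPartition:
    def test_single_sink_carries_all_carbon(self, toy_a, nitrogen_block):
        res = simulate_limitation(toy_a, nitrogen_block)
        table = carbon_partition(res, toy_a)
        assert list(table.reaction_id) == ["DM_tag"]
        assert table.carbon_pct.iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_equal_split_between_tag_and_citrate(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        table = carbon_partition(res, toy_b).set_index("reaction_id")
        assert table.loc["DM_tag", "carbon_pct"] == pytest.approx(50.0, abs=1e-4)
        assert table.loc["EX_cit", "carbon_pct"] == pytest.approx(50.0, abs=1e-4)

    def test_carbon_closure_on_toy_y(self, toy_y, nitrogen_block):
        """All consumed carbon is recovered in secreted/accumulated products
        (growth is zero, so no biomass carbon term)."""
        res = simulate_limitation(toy_y, nitrogen_block)
        table = carbon_partition(res, toy_y)
        assert table.carbon_pct.sum() == pytest.approx(100.0, rel=1e-4)
        assert (table.carbon_pct >= 0).all()

    def test_missing_formula_is_loud(self, toy_a, nitrogen_block):
        toy_a.metabolite("C").formula = None
        # TAG sink metabolite also loses its formula via shared species C
        res = simulate_limitation(toy_a, nitrogen_block)
        with pytest.raises(ModelError, match="C"):
            carbon_partition(res, toy_a)


class TestCompareFluxes:
    def test_self_comparison_is_perfect(self, toy_y, nitrogen_block):
        res = simulate_limitation(toy_y, nitrogen_block)
        table = pd.DataFrame({
            "reaction_id": res.limited.reaction_ids,
            "flux": res.limited.values,
        })
        table = table[table.flux.abs() > 1e-9]
        out = compare_fluxes(res.limited, table, "EX_glc")
        assert out["pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_negated_measurement_gives_minus_one(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        ids = ["EX_glc", "DM_tag", "EX_cit"]
        measured = pd.DataFrame({
            "reaction_id": ids,
            "flux": [-res.limited[r] for r in ids],
        })
        out = compare_fluxes(res.limited, measured, "EX_glc")
        assert out["pearson_r"] == pytest.approx(-1.0, abs=1e-9)

    def test_pearson_matches_hand_calculation(self, toy_a, nitrogen_block):
        # r for (1,2,3,4) vs (1,2,3,5): sum dx*dy = 6.5,
        # sum dx^2 = 5, sum dy^2 = 8.75 -> r = 6.5 / sqrt(43.75)
        expected = 6.5 / np.sqrt(5.0 * 8.75)
        res = simulate_limitation(toy_a, nitrogen_block)
        from emoma.solvers import FluxVector

        pred = FluxVector(np.array([1.0, 2.0, 3.0, 4.0]),
                          ["r1", "r2", "r3", "norm"], "optimal")
        measured = pd.DataFrame({"reaction_id": ["r1", "r2", "r3", "norm"],
                                 "flux": [1.0, 2.0, 3.0, 5.0]})
        out = compare_fluxes(pred, measured, "norm")
        assert out["pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_mapping_with_sign_flip(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        mapping = pd.DataFrame({
            "predicted_id": ["EX_glc", "DM_tag", "EX_cit"],
            "measured_id": ["GLCpts", "TAGacc", "CITout"],
            "sign": [1.0, -1.0, 1.0],
        })
        measured = pd.DataFrame({
            "reaction_id": ["GLCpts", "TAGacc", "CITout"],
            "flux": [res.limited["EX_glc"], -res.limited["DM_tag"],
                     res.limited["EX_cit"]],
        })
        out = compare_fluxes(res.limited, measured, "EX_glc", mapping=mapping)
        assert out["pearson_r"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out["table"].residual, 0.0, atol=1e-9)

    def test_zero_normalisation_flux_rejected(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        measured = pd.DataFrame({"reaction_id": ["EX_glc"], "flux": [1.0]})
        with pytest.raises(ValueError, match="GROWTH"):
            compare_fluxes(res.limited, measured, "GROWTH")

    def test_empty_inputs_rejected(self, toy_b, nitrogen_block):
        res = simulate_limitation(toy_b, nitrogen_block)
        with pytest.raises(ValueError, match="empty"):
            compare_fluxes(res.limited, pd.DataFrame(columns=["a", "b"]), "EX_glc")
        measured = pd.DataFrame({"reaction_id": ["nope"], "flux": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            compare_fluxes(res.limited, measured, "EX_glc")
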