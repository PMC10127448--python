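import pytest

from degrank import (
    ModelError,
    add_pathway,
    fba,
    growth_essential_under_production,
    load_pathway,
    packaged_pathway,
    pfba,
    production_support,
)
from degrank.pathways import write_pathway

from conftest import BIG, build_model, random_toy

CYT = "cytoplasm"


def ma_host():
    """Synthetic host with the metabolite names the packaged MA file maps."""
    names = {
        "dhs_c": "3-dehydroshikimate", "h2o_c": "H2O", "h_c": "H+",
        "co2_c": "carbon dioxide", "o2_c": "oxygen", "fmn_c": "FMN",
        "dmapp_c": "dimethylallyl diphosphate", "ppi_c": "diphosphate",
    }
    return build_model(
        {
            "EX_glc": ({"glc_c": -1}, -10, BIG, None),
            "to_dhs": ({"glc_c": -1, "dhs_c": 1}, 0, BIG, None),
            "EX_o2": ({"o2_c": -1}, -BIG, BIG, None),
            "EX_h2o": ({"h2o_c": -1}, -BIG, BIG, None),
            "EX_h": ({"h_c": -1}, -BIG, BIG, None),
            "EX_co2": ({"co2_c": -1}, -BIG, BIG, None),
            "sink_fmn": ({"fmn_c": -1}, 0, 0, None),
            "sink_dmapp": ({"dmapp_c": -1}, 0, 0, None),
            "sink_ppi": ({"ppi_c": -1}, 0, 0, None),
            "BIOMASS": ({"dhs_c": -1}, 0, BIG, None),
        },
        "BIOMASS",
        compartment=CYT,
        met_names=names,
    )


def ga_host():
    """Synthetic host with the metabolite names the packaged GA file maps."""
    names = {
        "oaa_c": "oxaloacetate", "h2o_c": "H2O", "h_c": "H+",
        "ac_c": "acetate", "atp_c": "ATP", "amp_c": "AMP",
        "ppi_c": "diphosphate", "coa_c": "coenzyme A", "nadph_c": "NADPH",
        "nadp_c": "NADP(+)", "glx_c": "glyoxylate",
        "g3p_c": "glyceraldehyde 3-phosphate", "pg3_c": "3-phosphoglycerate",
    }
    return build_model(
        {
            "EX_glc": ({"glc_c": -1}, -10, BIG, None),
            "to_oaa": ({"glc_c": -1, "oaa_c": 1}, 0, BIG, None),
            "to_g3p": ({"glc_c": -1, "g3p_c": 1}, 0, BIG, None),
            "pg3_drain": ({"pg3_c": -1}, 0, BIG, None),
            "EX_h2o": ({"h2o_c": -1}, -BIG, BIG, None),
            "EX_h": ({"h_c": -1}, -BIG, BIG, None),
            "EX_ac": ({"ac_c": -1}, 0, BIG, None),
            "atp_regen": ({"amp_c": -1, "atp_c": 1}, -BIG, BIG, None),
            "nadph_regen": ({"nadp_c": -1, "nadph_c": 1}, -BIG, BIG, None),
            "coa_cycle": ({"coa_c": -1, "coa_c_buf": 1}, -BIG, BIG, None),
            "sink_ppi": ({"ppi_c": -1}, 0, BIG, None),
            "glx_spill": ({"glx_c": -1}, 0, BIG, None),
            "BIOMASS": ({"oaa_c": -1}, 0, BIG, None),
        },
        "BIOMASS",
        compartment=CYT,
        met_names=names,
    )


class TestPackagedDefinitions:
    def test_muconic_acid_topology(self):
        ma = packaged_pathway("muconic_acid")
        assert ma.pathway_reaction_ids == ["AROZ", "AROY", "HQD2"]
        assert ma.auxiliary_reaction_ids == ["PAD1_PRFMN"]
        assert ma.product_exchange_id == "EX_ccmuconate"

    def test_glycolic_acid_topology(self):
        ga = packaged_pathway("glycolic_acid")
        assert ga.pathway_reaction_ids == ["OXA", "FAT2", "PANE2", "GLYR1"]
        assert ga.auxiliary_reaction_ids == ["GAPN"]
        assert ga.product_exchange_id == "EX_glycolate"

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        ma = packaged_pathway("muconic_acid")
        path = tmp_path / "dup.yaml"
        write_pathway(ma, path)
        text = path.read_text().replace("id: AROY", "id: AROZ", 1)
        path.write_text(text)
        with pytest.raises(ModelError, match="duplicate"):
            load_pathway(path)

    def test_unknown_species_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "name: bad\nhost_mapping: {}\nnew_metabolites: []\n"
            "reactions:\n- {id: R1, stoich: {mystery: -1, prod: 1}}\n"
            "- {id: EX_p, stoich: {prod: -1}}\n"
            "product_exchange: EX_p\nproduct_metabolite: prod\n"
        )
        with pytest.raises(ModelError, match="mystery"):
            load_pathway(path)

    def test_round_trip(self, tmp_path):
        ma = packaged_pathway("muconic_acid")
        path = tmp_path / "rt.yaml"
        write_pathway(ma, path)
        again = load_pathway(path)
        assert again.pathway_reaction_ids == ma.pathway_reaction_ids
        assert again.host_mapping == ma.host_mapping


class TestGrafting:
    def test_ma_graft_carries_product_flux(self):
        grafted = add_pathway(ma_host(), packaged_pathway("muconic_acid"))
        opt = fba(grafted, "EX_ccmuconate")
        assert opt.status == "optimal"
        assert opt.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_ga_graft_carries_product_flux(self):
        grafted = add_pathway(ga_host(), packaged_pathway("glycolic_acid"))
        opt = fba(grafted, "EX_glycolate")
        assert opt.status == "optimal"
        assert opt.objective_value > 1e-6

    def test_biomass_optimum_unchanged(self):
        host = ma_host()
        before = fba(host).objective_value
        after = fba(add_pathway(host, packaged_pathway("muconic_acid"))).objective_value
        assert after == pytest.approx(before, abs=1e-7)

    def test_double_graft_collides(self):
        host = ma_host()
        ma = packaged_pathway("muconic_acid")
        with pytest.raises(ModelError, match="collide"):
            add_pathway(add_pathway(host, ma), ma)

    def test_unmapped_precursor_named_in_error(self):
        host = ma_host()
        host.metabolites["dhs_c"] = host.metabolites["dhs_c"].__class__(
            "dhs_c", name="renamed", compartment=CYT
        )
        with pytest.raises(ModelError, match="3-dehydroshikimate"):
            add_pathway(host, packaged_pathway("muconic_acid"))


class TestProductionSupport:
    def _branch_model(self, with_bypass: bool):
        rxns = {
            "EX_S": ({"S": -1}, -10, BIG, None),
            "up": ({"S": -1, "A": 1}, 0, BIG, None),
            "p1": ({"A": -1, "P": 1}, 0, BIG, None),
            "p2": ({"P": -1, "Q": 1}, 0, BIG, None),
            "EX_Q": ({"Q": -1}, 0, BIG, None),
            "grow": ({"A": -1, "X": 1}, 0, BIG, None),
            "BIOMASS": ({"X": -1}, 0, BIG, None),
        }
        if with_bypass:
            rxns["p1_alt"] = ({"A": -1, "P": 1}, 0, BIG, None)
        return build_model(rxns, "BIOMASS")

    def test_sole_route_in_support(self):
        support = production_support(self._branch_model(False), "EX_Q")
        assert {"EX_S", "up", "p1", "p2", "EX_Q"} <= support
        assert "grow" not in support and "BIOMASS" not in support

    def test_bypassed_enzyme_not_in_support(self):
        support = production_support(self._branch_model(True), "EX_Q")
        assert "p1" not in support and "p1_alt" not in support
        assert {"up", "p2", "EX_Q"} <= support

    def test_zero_product_optimum_raises(self):
        model = self._branch_model(False).with_bounds({"p1": (0.0, 0.0)})
        with pytest.raises(RuntimeError, match="cannot carry flux"):
            production_support(model, "EX_Q")


class TestGrowthEssentialUnderProduction:
    def test_only_biomass_route_is_essential(self, chain3):
        ref = pfba(chain3)
        assert growth_essential_under_production(chain3, ["r_2"], ref) is True

    def test_parallel_route_not_essential(self, parallel_routes):
        ref = pfba(parallel_routes)
        assert growth_essential_under_production(
            parallel_routes, ["short"], ref
        ) is False

    def test_agrees_with_plain_fba_feasibility(self):
        # infeasibility of the constrained problem is reference-independent,
        # so lMOMA and a plain FBA feasibility check must agree
        for seed in range(6):
            model = random_toy(seed)
            wt = fba(model)
            ref = pfba(model)
            for rid in sorted(model.reactions):
                if rid == "BIOMASS":
                    continue
                verdict = growth_essential_under_production(model, [rid], ref)
                ko = model.with_bounds({
                    rid: (0.0, 0.0),
                    "BIOMASS": (0.9 * wt.objective_value,
                                model.reactions["BIOMASS"].upper_bound),
                })
                assert verdict == (fba(ko).status != "optimal")

    def test_reduces_to_ordinary_essentiality_at_small_fraction(self, parallel_routes, chain3):
        # as the growth requirement shrinks toward zero the verdict converges
        # to the ordinary essentiality call: any positive floor is unreachable
        # for a truly essential reaction, trivially reachable otherwise
        for model, rid, expected in (
            (chain3, "r_2", True),
            (parallel_routes, "short", False),
        ):
            ref = pfba(model)
            assert growth_essential_under_production(
                model, [rid], ref, growth_fraction=0.01
            ) is expected
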