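"""Model specification: rule census, parameters, variants, validation."""

import pytest

from autoswitch import ModelVariant, build_model, count_rules_by_class, validate_model
from autoswitch.bngl import parse_model, parse_pattern, parse_rule, write_model
from autoswitch.model import ModelSpecError, ParameterSet, SENSITIVITY_PARAMETERS


class TestRuleCensus:
    def test_seven_molecule_types(self, nominal_model):
        assert set(nominal_model.molecule_types) == {
            "rapa", "AMPK", "MTOR", "RPTOR", "ULK1", "EIF4EBP1", "AMBRA1"
        }

    def test_29_rules_27_unidirectional_2_bidirectional(self, nominal_model):
        rules = nominal_model.rules
        assert len(rules) == 29
        assert sum(r.bidirectional for r in rules) == 2
        assert {r.id for r in rules if r.bidirectional} == {"1", "2"}

    def test_class_partition(self, nominal_model):
        counts = count_rules_by_class(nominal_model)
        assert counts == {
            "reversible_binding": 2,
            "unidirectional_binding": 7,
            "phosphorylation": 10,
            "dephosphorylation": 10,
        }
        assert sum(counts.values()) == len(nominal_model.rules)

    def test_statistical_factors_only_on_doubled_rules(self, nominal_model):
        doubled = {r.id: r.stat_factor for r in nominal_model.rules
                   if r.stat_factor != 1.0}
        assert doubled == {"8B": 2.0, "15C": 2.0}

    def test_both_S792_dephosphorylation_rules_present(self, nominal_model):
        """S792 relaxes through two independent rules (u1 and u0); removing
        either would break the 27-rule unidirectional census."""
        refs = {r.id: r.rate_ref for r in nominal_model.rules}
        assert refs["15A"] == "u1"
        assert refs["19"] == "u0"


class TestParameters:
    def test_dependent_parameter_relations(self):
        p = ParameterSet()
        assert p.d3max == pytest.approx(100 * p.d3)
        assert p.u1 == pytest.approx(0.1 * p.u0)
        assert p.u2 == pytest.approx(0.01 * p.u0)
        assert p.p9 == 0.0

    def test_sensitivity_set_is_22_rate_constants_excluding_p9(self):
        assert len(SENSITIVITY_PARAMETERS) == 22
        assert "p9" not in SENSITIVITY_PARAMETERS

    def test_negative_parameter_rejected(self):
        with pytest.raises(ModelSpecError):
            ParameterSet(a1=-1.0)

    def test_model_file_round_trip_is_bitwise(self, nominal_model):
        """Serializing and re-parsing reproduces parameters bit-for-bit and
        the full rule set."""
        text = write_model(nominal_model)
        reparsed = parse_model(text)
        assert reparsed.params == nominal_model.params
        assert len(reparsed.rules) == 29
        assert write_model(reparsed).splitlines()[1:] == text.splitlines()[1:]


class TestVariants:
    def test_feedback_disabled_zeroes_p6(self):
        m = build_model(ModelVariant(feedback_enabled=False))
        assert m.params["p6"] == 0.0
        # the rule itself remains in the set; only its flux is removed
        assert m.rule("10").rate_ref == "p6"

    def test_p9_and_input_overrides(self):
        m = build_model(ModelVariant(p9=1e-7, ampk_star=90_000.0,
                                     rapamycin_star=500.0,
                                     overrides={"d5": 20.0}))
        assert m.params["p9"] == 1e-7
        assert m.params["ampk_star"] == 90_000.0
        assert m.params["rapamycin_star"] == 500.0
        assert m.params["d5"] == 20.0

    def test_unknown_override_rejected(self):
        with pytest.raises(ModelSpecError):
            build_model(ModelVariant(overrides={"qq": 1.0}))

    def test_negative_input_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelVariant(ampk_star=-1.0)

    def test_ampk_seed_carries_activating_phosphorylation(self, nominal_model):
        """Every AMPK copy is AMPK*: the kinase-domain site is fixed at P."""
        ampk = nominal_model.molecule_types["AMPK"].default_molecule()
        assert ampk.sites["T172"] == "P"


class TestValidation:
    def test_nominal_model_validates_clean(self, nominal_model):
        assert validate_model(nominal_model).ok

    def test_undeclared_site_reported(self, nominal_model):
        rule = parse_rule("bad", "ULK1(S999~P) -> ULK1(S999~0) u0",
                          nominal_model.molecule_types)
        m = build_model()
        m.rules.append(rule)
        report = validate_model(m)
        assert len(report.findings) >= 1
        assert any("S999" in f for f in report.findings)

    def test_unbound_rate_parameter_reported(self):
        m = build_model()
        m.rules[-1].rate_ref = "qq"
        report = validate_model(m)
        assert [f for f in report.findings if "qq" in f]


class TestSiteAliases:
    @pytest.mark.parametrize("alias", ["S855_Ser859", "S855-9"])
    def test_printed_site_name_variants_normalize(self, alias):
        pat = parse_pattern(f"RPTOR({alias}~PP)")
        assert "S855_S859" in pat.molecules[0].sites

    def test_printed_rule_text_matches_canonical_rule(self, nominal_model):
        """The rule for fast RPTOR release as printed (with its mixed site
        spellings) parses to the same patterns as the shipped rule set."""
        printed = ("RPTOR(ulk1!1,S792~P,S855_Ser859~PP).ULK1(straptor!1) -> "
                   "RPTOR(ulk1,S792~P,S855-9~PP) + ULK1(straptor) d3max")
        rule = parse_rule("3C", printed, nominal_model.molecule_types)
        ship = nominal_model.rule("3C")
        from autoswitch.graphs import unparse_pattern
        assert [unparse_pattern(p) for p in rule.reactants] == \
               [unparse_pattern(p) for p in ship.reactants]
        assert rule.rate_ref == "d3max"
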