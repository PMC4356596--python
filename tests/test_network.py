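"""Network expansion: toy-model oracles, closure, conservation, determinism,
and the plain-text network format."""

import numpy as np
import pytest

from autoswitch.bngl import parse_species
from autoswitch.fixtures import generate_fixtures
from autoswitch.network import (
    NetworkError,
    expand_network,
    read_network,
    verify_closure,
    write_network,
)

FIXTURES = generate_fixtures()


@pytest.mark.parametrize("fx", FIXTURES, ids=[f.name for f in FIXTURES])
class TestToyModelOracles:
    def test_species_set_matches_hand_enumeration(self, fx):
        net = expand_network(fx.model)
        got = {sp.label for sp in net.species}
        expected = {
            parse_species(lab, fx.model.molecule_types).label
            for lab in fx.expected_species_labels
        }
        assert got == expected
        assert net.n_species == fx.expected_species

    def test_reaction_count_matches_hand_enumeration(self, fx):
        net = expand_network(fx.model)
        assert net.n_reactions == fx.expected_reactions

    def test_closure(self, fx):
        net = expand_network(fx.model)
        assert verify_closure(net, fx.model)

    def test_mass_balance_per_reaction(self, fx):
        net = expand_network(fx.model)
        for rx in net.reactions:
            lhs = {}
            rhs = {}
            for i in rx.reactants:
                for t, c in net.species[i].molecule_counts().items():
                    lhs[t] = lhs.get(t, 0) + c
            for i in rx.products:
                for t, c in net.species[i].molecule_counts().items():
                    rhs[t] = rhs.get(t, 0) + c
            assert lhs == rhs


def test_competitive_binding_excludes_double_occupancy():
    fx = next(f for f in FIXTURES if f.name == "competitive_binding")
    net = expand_network(fx.model)
    for sp in net.species:
        types = sp.molecule_counts()
        assert not (types.get("L", 0) and types.get("R", 0))


class TestNominalExpansion:
    def test_closure_of_full_network(self, nominal_model, nominal_network):
        assert verify_closure(nominal_network, nominal_model)

    def test_conservation_structure(self, nominal_network):
        """Each molecule type's instance-count vector is stoichiometrically
        invariant under every reaction."""
        types, mat = nominal_network.molecule_count_matrix()
        for rx in nominal_network.reactions:
            for row in mat:
                assert sum(row[i] for i in rx.reactants) == \
                       sum(row[i] for i in rx.products)

    def test_embedding_multiplicity_is_one_throughout(self, nominal_network):
        """Regression guard for the statistical-factor convention: the
        doubled transitions carry explicit factors (2*p4, 2*u0), so no
        reaction may pick up extra embedding multiplicity."""
        assert {rx.multiplicity for rx in nominal_network.reactions} == {1}

    def test_duplicate_reactions_across_rules_kept_distinct(self, nominal_network):
        """S792 dephosphorylation appears once per generating rule (u1 and
        u0) for every RPTOR-containing species."""
        by_rule = {}
        for rx in nominal_network.reactions:
            by_rule.setdefault(rx.rule_id, []).append(rx)
        pairs_15a = {(r.reactants, r.products) for r in by_rule["15A"]}
        pairs_19 = {(r.reactants, r.products) for r in by_rule["19"]}
        assert pairs_15a == pairs_19
        assert len(pairs_15a) == 74

    def test_determinism_byte_identical_files(self, nominal_model,
                                              nominal_network):
        again = expand_network(nominal_model)
        assert write_network(again) == write_network(nominal_network)

    def test_species_cap_guards_divergence(self, nominal_model):
        with pytest.raises(NetworkError):
            expand_network(nominal_model, max_species=50)


class TestNetworkFormat:
    def test_round_trip_identity(self, nominal_network):
        text = write_network(nominal_network)
        net2 = read_network(text)
        assert write_network(net2) == text
        assert net2.n_species == nominal_network.n_species
        assert net2.n_reactions == nominal_network.n_reactions
        assert [sp.label for sp in net2.species] == \
               [sp.label for sp in nominal_network.species]

    def test_hand_edited_rate_reference_survives(self):
        fx = FIXTURES[0]
        net = expand_network(fx.model)
        text = write_network(net).replace(" kon ", " kon_fast ")
        net2 = read_network(text)
        assert "kon_fast" in {rx.rate_ref for rx in net2.reactions}

    def test_malformed_text_reports_line(self):
        fx = FIXTURES[0]
        lines = write_network(expand_network(fx.model)).splitlines()
        lines[2] = "begin species"  # leave earlier begin dangling
        lines.insert(3, "  broken line without fields")
        with pytest.raises(NetworkError, match=r"line \d+"):
            read_network("\n".join(lines))

    def test_seed_amounts_preserved(self, nominal_network):
        net2 = read_network(write_network(nominal_network))
        assert dict(net2.seeds) == dict(nominal_network.seeds)
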