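import numpy as np
import pytest

from emuflux.core import Metabolite, Reaction, ValidationError
from emuflux.fixtures import chain_network, tca_toy
from emuflux.network_io import (
    C13ReactionNetwork,
    ReactionNetwork,
    build_stoichiometric_matrix,
    carbon_transitions_ok,
    group_transitions,
    parse_atom_transition_lines,
    parse_atom_transitions,
    read_feed_csv,
    read_labeling_csv,
    read_sbml,
    write_atom_transitions,
    write_feed_csv,
    write_labeling_csv,
    write_sbml,
)


class TestStoichiometricMatrix:
    def test_linear_chain_balance_rows(self):
        net = chain_network()
        S = build_stoichiometric_matrix(net)
        assert S.shape == (2, 3)  # A and B balanced; boundary s, p excluded
        # steady state of the unit chain
        assert np.allclose(S @ np.array([1.0, 1.0, 1.0]), 0)

    def test_coefficient_two(self):
        net = ReactionNetwork(
            metabolites=[Metabolite("A"), Metabolite("B", is_excreted=True),
                         Metabolite("s", is_source=True)],
            reactions=[Reaction("in", [("s", 1)], [("A", 1)]),
                       Reaction("dim", [("A", 2)], [("B", 1)])],
        )
        S = build_stoichiometric_matrix(net)
        assert S[0, 1] == -2

    def test_empty_network(self):
        S = build_stoichiometric_matrix(ReactionNetwork())
        assert S.shape == (0, 0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            ReactionNetwork(metabolites=[Metabolite("A"), Metabolite("A")])


class TestSBMLRoundTrip:
    def test_round_trip_identity(self, tmp_path, tca_network):
        path = tmp_path / "model.xml"
        write_sbml(tca_network, path)
        again = read_sbml(path)
        assert again.metabolite_ids == tca_network.metabolite_ids
        assert again.reaction_ids == tca_network.reaction_ids
        for a, b in zip(again.metabolites, tca_network.metabolites):
            assert (a.carbon_count, a.is_source, a.is_excreted) == (
                b.carbon_count, b.is_source, b.is_excreted)
        for a, b in zip(again.reactions, tca_network.reactions):
            assert (a.reversible, a.lower_bound, a.upper_bound) == (
                b.reversible, b.lower_bound, b.upper_bound)
            assert a.reactants == b.reactants and a.products == b.products
        # write -> read -> write is byte-stable
        path2 = tmp_path / "model2.xml"
        write_sbml(again, path2)
        assert path.read_text() == path2.read_text()

    def test_objective_round_trip(self, tmp_path):
        net = chain_network()
        path = tmp_path / "chain.xml"
        write_sbml(net, path)
        assert read_sbml(path).objective == {"out": 1.0}

    def test_counts_match_file(self, tmp_path, tca_network):
        path = tmp_path / "m.xml"
        write_sbml(tca_network, path)
        text = path.read_text()
        assert text.count("<species ") == len(tca_network.metabolites)
        assert text.count("<reaction ") == len(tca_network.reactions)

    def test_truncated_file_is_parse_error(self, tmp_path, tca_network):
        path = tmp_path / "m.xml"
        write_sbml(tca_network, path)
        truncated = tmp_path / "bad.xml"
        truncated.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ValidationError):
            read_sbml(truncated)


class TestAtomTransitionDialect:
    def test_transfer_line(self):
        (t,) = parse_atom_transition_lines(["R1\tA(ab) --> B(ab)"])
        assert t.reaction_id == "R1"
        assert t.reactant_patterns == (("A", "ab"),)

    def test_condensation_line(self):
        (t,) = parse_atom_transition_lines(["CS\taccoa(ab) + oac(cdef) --> cit(fedbac)"])
        assert len(t.reactant_patterns) == 2
        assert t.product_patterns == (("cit", "fedbac"),)

    def test_carbon_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            parse_atom_transition_lines(["BAD\tA(ab) --> B(abc)"])

    def test_symmetric_duplicates_get_half_weight(self):
        ts = parse_atom_transition_lines(
            ["r5\tsuc(abcd) --> fum(abcd)", "r5\tsuc(abcd) --> fum(dcba)"]
        )
        assert [t.weight for t in ts] == [0.5, 0.5]

    def test_file_round_trip(self, tmp_path, tca_network):
        path = tmp_path / "transitions.txt"
        flat = [t for lst in tca_network.transitions.values() for t in lst]
        write_atom_transitions(flat, path)
        assert parse_atom_transitions(path) == flat

    def test_comments_and_blanks_ignored(self):
        ts = parse_atom_transition_lines(["# comment", "", "R1\tA(a) --> B(a)"])
        assert len(ts) == 1


class TestLabelingCSV:
    def test_read_write_round_trip(self, tmp_path):
        from emuflux.core import MDV

        rows = [("glu_1_2_3_4_5", MDV([0.25, 0.25, 0.25, 0.25, 0, 0],
                                      errors=[0.01] * 6))]
        path = tmp_path / "label.csv"
        write_labeling_csv(rows, path)
        (name, mdv), = read_labeling_csv(path)
        assert name == "glu_1_2_3_4_5"
        assert np.allclose(mdv.fractions, rows[0][1].fractions)
        assert np.allclose(mdv.errors, 0.01)

    def test_sum_deviation_warns_and_renormalizes(self, tmp_path, caplog):
        path = tmp_path / "label.csv"
        path.write_text("frag,0.5,0.4,0.01,0.01\n")  # sums to 0.9
        with caplog.at_level("WARNING"):
            (_, mdv), = read_labeling_csv(path)
        assert "renormalizing" in caplog.text
        assert mdv.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonnumeric_is_parse_error(self, tmp_path):
        path = tmp_path / "label.csv"
        path.write_text("frag,0.5,abc,0.01,0.01\n")
        with pytest.raises(ValidationError):
            read_labeling_csv(path)

    def test_sd_floor_applied(self, tmp_path):
        path = tmp_path / "label.csv"
        path.write_text("frag,0.5,0.5,0.0,0.0\n")
        (_, mdv), = read_labeling_csv(path)
        assert np.all(mdv.errors >= 0.003)

    def test_feed_round_trip(self, tmp_path):
        feed = {"accoa": [("00", 0.5), ("01", 0.25), ("11", 0.25)]}
        path = tmp_path / "feed.csv"
        write_feed_csv(feed, path)
        assert read_feed_csv(path) == feed


class TestCarbonTransitionsOK:
    def test_tca_fixture_is_consistent(self, tca_network):
        assert carbon_transitions_ok(tca_network) == []

    def test_transition_product_not_in_reaction(self, tca_network):
        bad = parse_atom_transition_lines(["r3\takg(abcde) --> suc(abcd) + co2(e)"])
        net = tca_toy()
        net.transitions["r3"] = bad
        reports = carbon_transitions_ok(net)
        assert any("r3" in r and "suc" in r for r in reports)

    def test_missing_transition_reported(self):
        net = tca_toy()
        del net.transitions["r3"]
        reports = carbon_transitions_ok(net)
        assert any("r3" in r for r in reports)
        assert any("glu" in r for r in reports)  # glu no longer produced

    def test_feed_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            net = tca_toy()
            C13ReactionNetwork(
                metabolites=net.metabolites,
                reactions=net.reactions,
                transitions=net.transitions,
                feed={"accoa": [("00", 0.5), ("01", 0.3)]},
            )
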