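import numpy as np
import pytest

from conftest import random_balanced_tca_fluxes, tca_truth_fluxes

from emuflux.core import EMU, Flux, Metabolite, Reaction, ValidationError
from emuflux.emu_engine import (
    brute_force_isotopomer_simulate,
    emu_transitions_for,
    feed_emu_mdv,
    required_emus,
    simulate_labeling,
)
from emuflux.network_io import C13ReactionNetwork, group_transitions, parse_atom_transition_lines


def _mini_network(lines, mets, feed, reactions=None):
    """Tiny helper: carbon-transfer networks for hand-checkable cases."""
    transitions = group_transitions(parse_atom_transition_lines(lines))
    if reactions is None:
        reactions = []
        for rid, tlist in transitions.items():
            t = tlist[0]
            reactions.append(
                Reaction(rid,
                         reactants=[(m, 1) for m, _ in t.reactant_patterns],
                         products=[(m, 1) for m, _ in t.product_patterns],
                         lower_bound=1.0, upper_bound=1.0)
            )
    return C13ReactionNetwork(
        metabolites=mets, reactions=reactions, transitions=transitions, feed=feed
    )


class TestRequiredEMUs:
    def test_backward_traversal_with_condensation(self):
        net = _mini_network(
            ["R1\tA(ab) --> B(ab)", "R2\tB(ab) + C(c) --> D(abc)"],
            [Metabolite("A", carbon_count=2, is_source=True),
             Metabolite("B", carbon_count=2),
             Metabolite("C", carbon_count=1, is_source=True),
             Metabolite("D", carbon_count=3, is_excreted=True)],
            feed={"A": [("00", 1.0)], "C": [("0", 1.0)]},
        )
        emus = required_emus(net, ["D_1_2_3"])
        assert {e.name for e in emus} == {"D_1_2_3", "B_1_2", "C_1", "A_1_2"}

    def test_feed_target_is_its_own_closure(self, tca_network):
        emus = required_emus(tca_network, ["accoa_1_2"])
        assert {e.name for e in emus} == {"accoa_1_2"}

    def test_single_transfer(self):
        net = _mini_network(
            ["R1\tA(a) --> B(a)"],
            [Metabolite("A", carbon_count=1, is_source=True),
             Metabolite("B", carbon_count=1, is_excreted=True)],
            feed={"A": [("0", 1.0)]},
        )
        assert {e.name for e in required_emus(net, ["B_1"])} == {"B_1", "A_1"}

    def test_unknown_target_metabolite(self, tca_network):
        with pytest.raises(ValidationError):
            required_emus(tca_network, [EMU("nope", (1,))])


class TestEMUTransitions:
    def test_citrate_synthase_condensation(self, tca_network):
        """Carbons 3-5 of citrate condense from accoa_1_2 and oac_2."""
        trans = emu_transitions_for(tca_network, ["cit_3_4_5"])
        forward = [t for t in trans if t.reaction_id == "r1"]
        assert len(forward) == 1
        (t,) = forward
        assert t.is_condensation
        assert sorted(s.name for s in t.source_emus) == ["accoa_1_2", "oac_2"]

    def test_reversible_reaction_has_both_directions(self, tca_network):
        trans = emu_transitions_for(tca_network, ["oac_1_2_3_4", "fum_1_2_3_4"])
        r6 = {(t.direction, t.target_emu.metabolite_id) for t in trans
              if t.reaction_id == "r6"}
        assert ("forward", "oac") in r6 and ("backward", "fum") in r6

    def test_transfer_target(self):
        net = _mini_network(
            ["R1\tA(ab) --> B(ab)"],
            [Metabolite("A", carbon_count=2, is_source=True),
             Metabolite("B", carbon_count=2, is_excreted=True)],
            feed={"A": [("00", 1.0)]},
        )
        (t,) = emu_transitions_for(net, ["B_2"])
        assert [s.name for s in t.source_emus] == ["A_2"]


class TestSimulateLabeling:
    def test_transfer_of_positional_label(self):
        net = _mini_network(
            ["R1\tA(a) --> B(a)"],
            [Metabolite("A", carbon_count=1, is_source=True),
             Metabolite("B", carbon_count=1, is_excreted=True)],
            feed={"A": [("1", 1.0)]},
        )
        sim = simulate_labeling(net, {"R1": Flux(net=1.0)}, ["B_1"])
        assert np.allclose(sim[EMU("B", (1,))].fractions, [0, 1])

    def test_unlabeled_feed_gives_unlabeled_everything(self, tca_network, tca_fluxes, glu_emu):
        net = tca_network
        net.feed = {"accoa": [("00", 1.0)], "asp": [("0000", 1.0)]}
        sim = simulate_labeling(net, tca_fluxes, [glu_emu])
        expected = np.zeros(6)
        expected[0] = 1.0
        assert np.allclose(sim[glu_emu].fractions, expected, atol=1e-12)

    def test_mdv_normalized_and_nonnegative(self, tca_network, tca_fluxes, glu_emu):
        sim = simulate_labeling(tca_network, tca_fluxes, [glu_emu])
        mdv = sim[glu_emu].fractions
        assert mdv.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(mdv >= -1e-12)

    def test_flux_scaling_invariance(self, tca_network, glu_emu):
        base = simulate_labeling(tca_network, tca_truth_fluxes(37.0, 20.0), [glu_emu])
        scaled = simulate_labeling(
            tca_network, tca_truth_fluxes(37.0, 20.0, scale=3.7), [glu_emu]
        )
        assert base[glu_emu].isclose(scaled[glu_emu], atol=1e-12)

    def test_unbalanced_fluxes_rejected(self, tca_network, tca_fluxes, glu_emu):
        bad = dict(tca_fluxes)
        bad["r3"] = Flux(net=80.0)
        with pytest.raises(ValidationError):
            simulate_labeling(tca_network, bad, [glu_emu])

    def test_result_independent_of_target_set(self, tca_network, tca_fluxes, glu_emu):
        alone = simulate_labeling(tca_network, tca_fluxes, [glu_emu])
        together = simulate_labeling(
            tca_network, tca_fluxes, [glu_emu, "oac_1_2_3_4", "co2_1"]
        )
        assert alone[glu_emu].isclose(together[glu_emu], atol=1e-12)


class TestCascadeVsCoupled:
    def test_schemes_agree_on_tca(self, tca_network, glu_emu):
        rng = np.random.default_rng(7)
        for _ in range(5):
            fluxes = random_balanced_tca_fluxes(rng)
            a = simulate_labeling(tca_network, fluxes, [glu_emu], scheme="cascade")
            b = simulate_labeling(tca_network, fluxes, [glu_emu], scheme="coupled")
            assert np.max(np.abs(a[glu_emu].fractions - b[glu_emu].fractions)) < 1e-10


class TestBruteForceOracle:
    def test_single_pool_fully_labeled(self):
        net = _mini_network(
            ["R1\tA(a) --> B(a)"],
            [Metabolite("A", carbon_count=1, is_source=True),
             Metabolite("B", carbon_count=1, is_excreted=True)],
            feed={"A": [("1", 1.0)]},
        )
        state = brute_force_isotopomer_simulate(net, {"R1": Flux(net=1.0)})
        assert np.allclose(state.distributions["B"], [0, 1])

    def test_unlabeled_feed_all_mass_at_zero(self, tca_network, tca_fluxes):
        net = tca_network
        net.feed = {"accoa": [("00", 1.0)], "asp": [("0000", 1.0)]}
        state = brute_force_isotopomer_simulate(net, tca_fluxes)
        for met, vec in state.distributions.items():
            if not net.metabolite(met).is_source:
                assert vec[0] == pytest.approx(1.0, abs=1e-12), met

    def test_emu_solution_matches_oracle(self, tca_network, glu_emu):
        rng = np.random.default_rng(3)
        for _ in range(5):
            fluxes = random_balanced_tca_fluxes(rng)
            sim = simulate_labeling(tca_network, fluxes, [glu_emu])
            oracle = brute_force_isotopomer_simulate(tca_network, fluxes)
            dev = np.max(np.abs(sim[glu_emu].fractions - oracle.mdv("glu").fractions))
            assert dev < 1e-8

    def test_emu_marginals_match_oracle(self, tca_network, tca_fluxes):
        """EMU sub-molecule MDVs equal oracle marginals, not just full molecules."""
        for name in ("oac_2", "cit_3_4_5", "akg_1_2_3"):
            emu = tca_network.fragment_emu(name)
            sim = simulate_labeling(tca_network, tca_fluxes, [emu])
            oracle = brute_force_isotopomer_simulate(tca_network, tca_fluxes)
            marg = oracle.mdv(emu.metabolite_id, emu.carbon_indices)
            assert np.allclose(sim[emu].fractions, marg.fractions, atol=1e-8)

    def test_state_guard(self):
        mets = [Metabolite("big", carbon_count=17, is_excreted=True),
                Metabolite("s", carbon_count=17, is_source=True)]
        net = _mini_network(
            ["R1\t" + "s(" + "abcdefghijklmnopq" + ") --> big(" + "abcdefghijklmnopq" + ")"],
            mets, feed={"s": [("0" * 17, 1.0)]},
        )
        with pytest.raises(ValidationError, match="refused"):
            brute_force_isotopomer_simulate(net, {"R1": Flux(net=1.0)})


class TestFeedEMUs:
    def test_feed_emu_marginalizes_mixture(self, tca_network):
        # accoa: 50% unlabeled, 25% [2-13C], 25% [1,2-13C]
        full = feed_emu_mdv(tca_network, EMU("accoa", (1, 2)))
        assert np.allclose(full, [0.5, 0.25, 0.25])
        c1 = feed_emu_mdv(tca_network, EMU("accoa", (1,)))
        assert np.allclose(c1, [0.75, 0.25])
        c2 = feed_emu_mdv(tca_network, EMU("accoa", (2,)))
        assert np.allclose(c2, [0.5, 0.5])
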