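import itertools

import numpy as np
import pytest
import scipy.stats

from conftest import TCA_FREE, tca_truth_fluxes

from emuflux.core import Flux, Metabolite, Reaction
from emuflux.fixtures import (
    chain_network,
    parallel_paths_network,
    soil_community_fixture,
    synth_measurements,
    tca_reference_flux_map,
    tca_toy,
    two_scale_toy,
)
from emuflux.flux_models import (
    FluxAnalysisError,
    InfeasibleProblemError,
    UnboundedProblemError,
    c13_fit,
    c13_fva,
    community_cue,
    elva,
    fba,
    fva,
    sample_flux_polytope,
    two_scale_fit,
)
from emuflux.network_io import ReactionNetwork


def enumerate_vertices(network: ReactionNetwork, tol: float = 1e-9):
    """All basic feasible points of {S v = 0, lb <= v <= ub} by fixing
    (n - rank S) coordinates at their bounds — the LP vertex oracle."""
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    n = len(network.reactions)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(choice) if S.size else np.zeros(0)
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None) if free else (np.zeros(0),)
            v = np.zeros(n)
            v[list(fixed)] = choice
            v[free] = sol
            if S.size and np.max(np.abs(S @ v)) > tol:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(v)
    return vertices


class TestFBA:
    def test_single_chain_optimum(self):
        dist = fba(chain_network(uptake=10.0))
        assert dist.objective_value == pytest.approx(10.0)
        assert dist.fluxes["upt"].net == pytest.approx(10.0)

    def test_parallel_paths_capacity_limited(self):
        dist = fba(parallel_paths_network(uptake=10.0, branch_capacity=6.0))
        assert dist.objective_value == pytest.approx(10.0)

    def test_contradictory_bounds_infeasible(self):
        net = chain_network()
        net.reaction("conv").lower_bound = 5.0
        net.reaction("conv").upper_bound = 1.0
        with pytest.raises(InfeasibleProblemError):
            fba(net)

    def test_unbounded_status(self):
        net = chain_network()
        net.reaction("upt").upper_bound = np.inf
        net.reaction("conv").upper_bound = np.inf
        net.reaction("out").upper_bound = np.inf
        with pytest.raises(UnboundedProblemError):
            fba(net)

    def test_optimum_dominates_every_vertex(self):
        for net in (chain_network(), parallel_paths_network(branch_capacity=6.0)):
            best = fba(net)
            c = np.array([net.objective.get(r, 0.0) for r in net.reaction_ids])
            for v in enumerate_vertices(net):
                assert best.objective_value >= c @ v - 1e-8

    def test_solution_balanced_and_bounded(self):
        net = parallel_paths_network()
        dist = fba(net)
        v = dist.net_vector(net.reaction_ids)
        assert np.max(np.abs(net.stoichiometric_matrix() @ v)) < 1e-8
        lb, ub = net.bounds_arrays()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


class TestFVA:
    def test_parallel_branches_fully_flexible_at_optimum(self):
        ranges = fva(parallel_paths_network(), fraction=1.0)
        assert ranges["b1"].lo == pytest.approx(0.0, abs=1e-8)
        assert ranges["b1"].hi == pytest.approx(10.0)
        assert ranges["b2"].hi == pytest.approx(10.0)

    def test_single_chain_fully_determined(self):
        ranges = fva(chain_network(), fraction=1.0)
        for rid, r in ranges.items():
            assert r.width == pytest.approx(0.0, abs=1e-8), rid

    def test_fraction_zero_recovers_stoichiometric_bounds(self):
        ranges = fva(chain_network(), fraction=0.0)
        for rid in ("upt", "conv", "out"):
            assert ranges[rid].lo == pytest.approx(0.0, abs=1e-8)
            assert ranges[rid].hi == pytest.approx(10.0)

    def test_ranges_contain_fba_solution(self):
        net = parallel_paths_network(branch_capacity=6.0)
        best = fba(net)
        ranges = fva(net, fraction=0.9)
        for rid, r in ranges.items():
            assert r.lo - 1e-8 <= best.fluxes[rid].net <= r.hi + 1e-8


class TestPolytopeSampling:
    def test_samples_feasible_and_balanced(self):
        net = parallel_paths_network()
        S = net.stoichiometric_matrix()
        lb, ub = net.bounds_arrays()
        for v in sample_flux_polytope(net, 10, rng=0):
            assert np.max(np.abs(S @ v)) < 1e-8
            assert np.all(v >= lb - 1e-8) and np.all(v <= ub + 1e-8)


class TestC13Fit:
    def test_noiseless_self_consistency(self):
        net = tca_toy(free=TCA_FREE)
        truth = tca_truth_fluxes(40.0, 20.0)
        net.measured_fragments = synth_measurements(net, truth, noise_sd=0.0)
        fit = c13_fit(net, n_restarts=4, seed=0)
        assert fit.ssr < 1e-6
        assert fit.converged
        assert fit.n_free_fluxes == 2
        assert np.allclose(fit.residuals, 0.0, atol=1e-3)

    def test_recovers_true_net_fluxes(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            truth_r4 = rng.uniform(15.0, 85.0)
            net = tca_toy(free=TCA_FREE)
            net.measured_fragments = synth_measurements(
                net, tca_truth_fluxes(truth_r4, rng.uniform(0, 50)), noise_sd=0.0
            )
            fit = c13_fit(net, n_restarts=4, seed=1)
            for rid in ("r3", "r4", "r7"):
                expected = truth_r4 if rid == "r4" else 100.0 - truth_r4
                assert fit.fluxes[rid].net == pytest.approx(expected, abs=1e-4)

    def test_all_fluxes_pinned_degenerates_to_simulation(self, tca_fluxes):
        net = tca_toy()  # everything pinned: the forward-simulation scenario
        net.measured_fragments = synth_measurements(net, tca_fluxes, noise_sd=0.02, seed=5)
        fit = c13_fit(net, exchange_bounds={"r6": (50.0, 50.0)}, seed=0,
                      error_model="independent")
        assert fit.n_free_fluxes == 0 and fit.restarts_used == 0
        # residuals are exactly (obs - simulated) / sd
        from emuflux.emu_engine import simulate_labeling

        emus = [net.fragment_emu(n) for n, _ in net.measured_fragments]
        sim = simulate_labeling(net, tca_fluxes, emus)
        expected = np.concatenate(
            [(m.fractions - sim[e].fractions) / m.errors
             for (_, m), e in zip(net.measured_fragments, emus)]
        )
        assert np.allclose(fit.residuals, expected, atol=1e-12)

    def test_ssr_is_sum_of_squared_residuals(self):
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(
            net, tca_truth_fluxes(40.0, 20.0), noise_sd=0.01, seed=2
        )
        fit = c13_fit(net, n_restarts=3, seed=0)
        assert fit.ssr == pytest.approx(float(fit.residuals @ fit.residuals), rel=1e-12)

    def test_noisy_ssr_has_chi_square_scale(self):
        """With sd-0.01 noise the whitened minimized SSR behaves like a
        chi-square with dof = n_whitened_residuals - n_free_parameters."""
        ssrs = []
        fit = None
        for seed in range(20):
            net = tca_toy(free=TCA_FREE)
            net.measured_fragments = synth_measurements(
                net, tca_truth_fluxes(40.0, 20.0), noise_sd=0.01, seed=seed
            )
            fit = c13_fit(net, n_restarts=3, seed=seed)
            ssrs.append(fit.ssr)
        dof = fit.n_measurements - fit.n_free_fluxes  # 19 - 2
        lo, hi = scipy.stats.chi2.ppf([0.001, 0.999], df=dof)
        within = sum(lo <= s <= hi for s in ssrs)
        assert within >= 17

    def test_fit_respects_balance_and_bounds(self):
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(
            net, tca_truth_fluxes(30.0, 10.0), noise_sd=0.01, seed=3
        )
        fit = c13_fit(net, n_restarts=3, seed=0)
        v = fit.fluxes.net_vector(net.reaction_ids)
        assert np.max(np.abs(net.stoichiometric_matrix() @ v)) < 1e-6
        lb, ub = net.bounds_arrays()
        assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)

    def test_missing_measurements_rejected(self):
        net = tca_toy(free=TCA_FREE)
        with pytest.raises(Exception):
            c13_fit(net)

    def test_wrong_length_measurement_rejected(self):
        from emuflux.core import MDV, ValidationError

        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = [("glu_1_2_3_4_5", MDV([0.5, 0.3, 0.2]))]
        with pytest.raises(ValidationError):
            c13_fit(net)


class TestC13FVA:
    def test_pinned_fluxes_have_zero_width(self, tca_fluxes):
        net = tca_toy()
        net.measured_fragments = synth_measurements(net, tca_fluxes, noise_sd=0.01, seed=1)
        fit = c13_fit(net, exchange_bounds={"r6": (50.0, 50.0)}, seed=0)
        ranges = c13_fva(fit)
        for rid, r in ranges.items():
            assert r.width < 1e-6, rid

    def test_noiseless_truth_inside_every_interval(self):
        truth = tca_truth_fluxes(40.0, 20.0)
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(net, truth, noise_sd=0.0)
        fit = c13_fit(net, n_restarts=4, seed=0)
        ranges = c13_fva(fit, confidence=0.95)
        for rid, r in ranges.items():
            assert r.lo - 1e-6 <= truth[rid].net <= r.hi + 1e-6, rid

    def test_best_fit_inside_every_interval(self):
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(
            net, tca_truth_fluxes(55.0, 5.0), noise_sd=0.01, seed=9
        )
        fit = c13_fit(net, n_restarts=3, seed=0)
        ranges = c13_fva(fit, confidence=0.95)
        for rid, r in ranges.items():
            assert r.contains(fit.fluxes[rid].net) or (
                abs(fit.fluxes[rid].net - r.best) < 1e-9
            )


class TestTwoScale:
    def test_reduction_to_c13_fit(self):
        ts = two_scale_toy(drain=0.0)
        meas = synth_measurements(ts.core, tca_reference_flux_map())
        ts.core.measured_fragments = meas
        fit2s, gs = two_scale_fit(ts, n_restarts=3, seed=0)
        fit = c13_fit(ts.core, n_restarts=3, seed=0)
        for rid in ts.core.reaction_ids:
            assert fit2s.fluxes[rid].net == pytest.approx(fit.fluxes[rid].net, abs=1e-3)
        assert gs.fluxes["akg_to_biomass"].net == pytest.approx(0.0, abs=1e-9)

    def test_positive_drain_shifts_core_flux_by_exactly_the_drain(self):
        for drain in (5.0, 10.0):
            ts = two_scale_toy(drain=drain)
            ts.core.measured_fragments = synth_measurements(ts.core, tca_reference_flux_map())
            fit, gs = two_scale_fit(ts, n_restarts=3, seed=0)
            # akg balance: r2 = r3 + r4 + drain, with r2, r4 pinned
            assert fit.fluxes["r3"].net == pytest.approx(50.0 - drain, abs=1e-6)
            assert gs.fluxes["akg_to_biomass"].net == pytest.approx(drain, abs=1e-9)

    def test_genome_scale_solution_balanced(self):
        ts = two_scale_toy(drain=7.0)
        ts.core.measured_fragments = synth_measurements(ts.core, tca_reference_flux_map())
        _, gs = two_scale_fit(ts, n_restarts=3, seed=0)
        v = gs.net_vector(ts.genome_scale.reaction_ids)
        assert np.max(np.abs(ts.genome_scale.stoichiometric_matrix() @ v)) < 1e-6


class TestELVA:
    def test_feed_emu_range_is_a_point(self):
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(net, tca_truth_fluxes(40.0, 20.0))
        fit = c13_fit(net, n_restarts=3, seed=0)
        ranges = elva(fit, ["accoa_1_2"])
        emu = net.fragment_emu("accoa_1_2")
        assert [r.width for r in ranges[emu]] == [0.0, 0.0, 0.0]
        assert [r.best for r in ranges[emu]] == pytest.approx([0.5, 0.25, 0.25])

    def test_fully_pinned_network_gives_zero_width(self, tca_fluxes):
        net = tca_toy()
        net.measured_fragments = synth_measurements(net, tca_fluxes, noise_sd=0.01, seed=4)
        fit = c13_fit(net, exchange_bounds={"r6": (50.0, 50.0)}, seed=0)
        ranges = elva(fit, ["fum_1_2_3_4"])
        emu = net.fragment_emu("fum_1_2_3_4")
        assert all(r.width < 1e-6 for r in ranges[emu])

    def test_ranges_cover_grid_search_extremes(self):
        """ELVA bounds must enclose the labeling attainable at any flux vector
        inside the confidence region (grid over the 1-dim free direction)."""
        net = tca_toy(free=TCA_FREE)
        net.measured_fragments = synth_measurements(
            net, tca_truth_fluxes(40.0, 20.0), noise_sd=0.01, seed=6
        )
        fit = c13_fit(net, n_restarts=3, seed=0)
        threshold = fit.ssr + scipy.stats.chi2.ppf(0.95, df=1)
        emu = net.fragment_emu("suc_1_2_3_4")
        ranges = elva(fit, [emu], confidence=0.95)

        from emuflux.emu_engine import simulate_labeling

        grid_vals = []
        for r4 in np.linspace(20.0, 60.0, 41):
            fluxes = tca_truth_fluxes(r4, 20.0)
            prob = fit._problem
            emus = prob.targets
            sim = simulate_labeling(net, fluxes, emus, check_balance=False)
            pred = np.concatenate([sim[t].fractions for t in emus])
            r = prob.whiten(prob.observed - pred)
            ssr = float(r @ r)
            if ssr <= threshold:
                target = simulate_labeling(net, fluxes, [emu], check_balance=False)
                grid_vals.append(target[emu].fractions)
        grid_vals = np.array(grid_vals)
        assert len(grid_vals) > 3
        for m in range(emu.size + 1):
            assert ranges[emu][m].lo <= grid_vals[:, m].min() + 1e-3
            assert ranges[emu][m].hi >= grid_vals[:, m].max() - 1e-3
        assert all(0.0 <= r.lo <= r.hi <= 1.0 for r in ranges[emu])


class TestCommunityCUE:
    def _simple_net(self):
        return ReactionNetwork(
            metabolites=[Metabolite("s", carbon_count=3, is_source=True),
                         Metabolite("x", carbon_count=3)],
            reactions=[Reaction("in", [("s", 1)], [("x", 1)]),
                       Reaction("bio", [("x", 1)], []),
                       Reaction("resp", [("x", 1)], [])],
        )

    @pytest.mark.parametrize("bio,resp,expected", [(0, 6, 0.0), (6, 0, 1.0), (3, 3, 0.5)])
    def test_limiting_cases(self, bio, resp, expected):
        net = self._simple_net()
        fluxes = {"in": Flux(net=bio + resp), "bio": Flux(net=bio), "resp": Flux(net=resp)}
        assert community_cue(net, fluxes, ["bio"], ["resp"]) == pytest.approx(expected)

    def test_zero_denominator_is_error(self):
        net = self._simple_net()
        fluxes = {"in": Flux(net=0), "bio": Flux(net=0), "resp": Flux(net=0)}
        with pytest.raises(FluxAnalysisError):
            community_cue(net, fluxes, ["bio"], ["resp"])

    def test_planted_cue_recovered_from_fixture(self):
        comm = soil_community_fixture(cue=0.3)
        for source, d in comm.items():
            net = next(iter(d["variants"].values()))
            cue = community_cue(net, d["fluxes"], d["biomass_reactions"], d["co2_reactions"])
            assert cue == pytest.approx(0.3, abs=1e-6), source
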