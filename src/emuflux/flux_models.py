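"""Flux analysis models: FBA, FVA, 13C MFA, 13C FVA, two-scale MFA, ELVA.

All optimization goes through open solver contracts: linear programs are
solved with scipy's HiGHS backend, and the nonlinear 13C least-squares
problems with SLSQP over a reduced flux parametrization. The reduction
eliminates the stoichiometric equality constraints analytically: with
pinned reactions (lower bound == upper bound) written as extra equality
rows, any balanced flux vector is ``v = v0 + N z`` where ``N`` spans the
null space of the stacked system. The optimizer then works in ``z`` plus
the exchange fluxes of reversible reactions, with the remaining bounds as
linear inequalities.

Confidence intervals (13C FVA, ELVA) follow the profile-likelihood
construction: a flux value is compatible with the data when the best
achievable variance-weighted SSR at that value stays within a chi-square
quantile (1 degree of freedom) of the global minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .core import Flux, MDV, RangedNumber, ValidationError
from .emu_engine import simulate_labeling
from .network_io import C13ReactionNetwork, ReactionNetwork, TwoScaleNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FluxDistribution",
    "FitResult",
    "RangedFluxDistribution",
    "FluxAnalysisError",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "fba",
    "fva",
    "c13_fit",
    "c13_fva",
    "two_scale_fit",
    "elva",
    "community_cue",
    "sample_flux_polytope",
]

#: default upper bound for exchange fluxes during fitting (ratio scale)
EXCHANGE_UB = 100.0

#: default measurement standard deviation when a fragment carries none
DEFAULT_SD = 0.01

_PIN_TOL = 1e-9


class FluxAnalysisError(RuntimeError):
    pass


class InfeasibleProblemError(FluxAnalysisError):
    pass


class UnboundedProblemError(FluxAnalysisError):
    pass


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class FluxDistribution:
    """Point estimate: reaction id -> :class:`Flux`, plus the LP objective."""

    fluxes: dict[str, Flux]
    objective_value: float | None = None

    def net(self, rid: str) -> float:
        return self.fluxes[rid].net

    def net_vector(self, reaction_ids) -> np.ndarray:
        return np.array([self.fluxes[r].net for r in reaction_ids])

    def items(self):
        return self.fluxes.items()

    def __getitem__(self, rid: str) -> Flux:
        return self.fluxes[rid]


@dataclass
class RangedFluxDistribution:
    """Per-reaction [lo, best, hi] flux ranges."""

    ranges: dict[str, RangedNumber]

    def __getitem__(self, rid: str) -> RangedNumber:
        return self.ranges[rid]

    def items(self):
        return self.ranges.items()


@dataclass
class FitResult:
    """Outcome of a 13C MFA fit."""

    fluxes: FluxDistribution
    ssr: float
    residuals: np.ndarray
    n_measurements: int
    n_free_fluxes: int
    converged: bool
    restarts_used: int = 0
    degenerate: bool = False
    # internal state enabling interval searches on the same problem
    _problem: "_C13FitProblem | None" = field(default=None, repr=False, compare=False)
    _x: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def dof(self) -> int:
        return self.n_measurements - self.n_free_fluxes


# ---------------------------------------------------------------------------
# linear programming: FBA / FVA
# ---------------------------------------------------------------------------


def _linprog(c, S, lb, ub, A_ub=None, b_ub=None):
    if np.any(np.asarray(lb) > np.asarray(ub)):
        raise InfeasibleProblemError("LP infeasible: lower bound exceeds upper bound")
    res = scipy.optimize.linprog(
        c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleProblemError("LP infeasible")
    if res.status == 3:
        raise UnboundedProblemError("LP unbounded")
    if not res.success:  # pragma: no cover
        raise FluxAnalysisError(f"LP failed: {res.message}")
    return res


def _objective_vector(network: ReactionNetwork, objective) -> np.ndarray:
    if objective is None:
        objective = network.objective
    if isinstance(objective, str):
        objective = {objective: 1.0}
    if not objective:
        raise ValidationError("no objective specified")
    c = np.zeros(len(network.reactions))
    idx = {r: i for i, r in enumerate(network.reaction_ids)}
    for rid, coeff in objective.items():
        c[idx[rid]] = coeff
    return c


def fba(network: ReactionNetwork, objective=None) -> FluxDistribution:
    """Maximize the objective over the steady-state flux polytope.

    Solves ``max c.v  s.t.  S v = 0, lb <= v <= ub`` and returns the optimal
    flux distribution with its objective value.
    """
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    c = _objective_vector(network, objective)
    res = _linprog(-c, S, lb, ub)
    fluxes = {rid: Flux(net=v) for rid, v in zip(network.reaction_ids, res.x)}
    return FluxDistribution(fluxes=fluxes, objective_value=float(-res.fun))


def fva(network: ReactionNetwork, objective=None, fraction: float = 1.0) -> RangedFluxDistribution:
    """Per-reaction flux ranges at a fraction of the optimal objective.

    For each reaction, minimizes and maximizes its flux subject to the
    steady-state constraints and ``c.v >= fraction * optimum``. Every range
    contains the FBA solution.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must lie in [0, 1]")
    best = fba(network, objective)
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    c = _objective_vector(network, objective)
    A_ub = -c[None, :]
    b_ub = np.array([-fraction * best.objective_value])
    ranges = {}
    for j, rid in enumerate(network.reaction_ids):
        e = np.zeros(len(network.reactions))
        e[j] = 1.0
        lo = float(_linprog(e, S, lb, ub, A_ub, b_ub).fun)
        hi = float(-_linprog(-e, S, lb, ub, A_ub, b_ub).fun)
        mid = min(max(best.fluxes[rid].net, lo), hi)
        ranges[rid] = RangedNumber(lo, mid, hi)
    return RangedFluxDistribution(ranges=ranges)


def sample_flux_polytope(
    network: ReactionNetwork, n_samples: int, rng=None, n_vertices: int = 12
) -> list[np.ndarray]:
    """Random interior points of {v : S v = 0, lb <= v <= ub}.

    Vertices found by LPs with random objectives are mixed with Dirichlet
    weights; points are interior whenever the polytope has positive volume.
    """
    rng = np.random.default_rng(rng)
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    vertices = []
    for _ in range(n_vertices):
        c = rng.standard_normal(len(network.reactions))
        vertices.append(_linprog(c, S, lb, ub).x)
    vertices = np.array(vertices)
    out = []
    for _ in range(n_samples):
        w = rng.dirichlet(np.ones(len(vertices)))
        out.append(w @ vertices)
    return out


# ---------------------------------------------------------------------------
# 13C MFA fitting machinery
# ---------------------------------------------------------------------------


class _C13FitProblem:
    """Reduced-parametrization 13C fit shared by c13_fit / c13_fva / elva.

    ``constraint_network`` supplies stoichiometry and bounds (the genome-scale
    network in the two-scale case); ``labeling_network`` carries the atom
    transitions, feed and measurements. ``mapping`` sends each labeling-network
    reaction to the constraint-network reactions whose net fluxes sum to it.
    """

    def __init__(
        self,
        constraint_network: ReactionNetwork,
        labeling_network: C13ReactionNetwork,
        measurements=None,
        mapping: dict[str, list[str]] | None = None,
        exchange_bounds: dict[str, tuple[float, float]] | None = None,
        exchange_ub: float = EXCHANGE_UB,
        error_model: str = "normalized",
    ):
        self.cnet = constraint_network
        self.lnet = labeling_network
        self.mapping = mapping or {}
        self.measurements = (
            measurements if measurements is not None else labeling_network.measured_fragments
        )
        if not self.measurements:
            raise ValidationError("13C fit requires at least one measured fragment")
        if not labeling_network.feed:
            raise ValidationError("13C fit requires a feed labeling specification")

        self.rids = self.cnet.reaction_ids
        self.ridx = {r: i for i, r in enumerate(self.rids)}
        S = self.cnet.stoichiometric_matrix()
        lb, ub = self.cnet.bounds_arrays()
        self.lb, self.ub = lb, ub
        pinned = np.where(ub - lb <= _PIN_TOL)[0]
        rows = [S] if S.size else []
        rhs = [np.zeros(S.shape[0])] if S.size else []
        if len(pinned):
            pin_rows = np.zeros((len(pinned), len(self.rids)))
            pin_rows[np.arange(len(pinned)), pinned] = 1.0
            rows.append(pin_rows)
            rhs.append(lb[pinned])
        stacked = np.vstack(rows) if rows else np.zeros((0, len(self.rids)))
        rhs = np.concatenate(rhs) if rhs else np.zeros(0)
        v0, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
        if stacked.size and np.max(np.abs(stacked @ v0 - rhs)) > 1e-6:
            raise InfeasibleProblemError("pinned fluxes are inconsistent with S v = 0")
        self.v0 = v0
        self.N = scipy.linalg.null_space(stacked) if stacked.size else np.eye(len(self.rids))
        self.k = self.N.shape[1]
        self.free_rows = np.where(ub - lb > _PIN_TOL)[0]

        # exchange fluxes for reversible labeling-network reactions
        exchange_bounds = exchange_bounds or {}
        self.exch_ids: list[str] = []
        exch_lo, exch_hi = [], []
        self.fixed_exchange: dict[str, float] = {}
        for rxn in self.lnet.reactions:
            if not rxn.reversible:
                continue
            lo, hi = exchange_bounds.get(rxn.id, (0.0, exchange_ub))
            if hi - lo <= _PIN_TOL:
                self.fixed_exchange[rxn.id] = lo
            else:
                self.exch_ids.append(rxn.id)
                exch_lo.append(lo)
                exch_hi.append(hi)
        self.exch_lo = np.array(exch_lo)
        self.exch_hi = np.array(exch_hi)
        self.n_params = self.k + len(self.exch_ids)

        self.targets = tuple(
            self.lnet.fragment_emu(name) for name, _ in self.measurements
        )
        self.observed = []
        self.sds = []
        for (_, mdv), emu in zip(self.measurements, self.targets):
            if len(mdv) != emu.size + 1:
                raise ValidationError(
                    f"measured MDV length {len(mdv)} does not match fragment {emu.name}"
                )
            self.observed.append(mdv.fractions)
            sd = mdv.errors if mdv.errors is not None else np.full(len(mdv), DEFAULT_SD)
            self.sds.append(sd)
        self.observed = np.concatenate(self.observed)
        self.sds = np.concatenate(self.sds)

        if error_model not in ("normalized", "independent"):
            raise ValidationError(f"unknown error model {error_model!r}")
        self.error_model = error_model
        if error_model == "normalized":
            # Measured MDVs are normalized to unit sum, which projects the raw
            # per-component noise onto the simplex: for a fragment with
            # observed vector s and component sd's d, the induced covariance
            # is Sigma = (I - s 1^T) diag(d^2) (I - 1 s^T), singular exactly
            # along the normalization direction. Residuals are whitened by
            # Sigma's pseudo-inverse square root (GLS); with independent
            # errors this reduces to the usual diagonal weighting.
            self._whiteners: list[tuple[int, int, np.ndarray]] = []
            offset = 0
            for t in self.targets:
                n1 = t.size + 1
                s = self.observed[offset : offset + n1]
                d = self.sds[offset : offset + n1]
                A = np.eye(n1) - np.outer(s, np.ones(n1))
                sigma = (A * d**2) @ A.T
                lam, V = np.linalg.eigh(sigma)
                keep = lam > 1e-12 * lam.max()
                self._whiteners.append(
                    (offset, n1, (V[:, keep] / np.sqrt(lam[keep])).T)
                )
                offset += n1

    # -- parametrization ----------------------------------------------------
    def v_of(self, x: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ x[: self.k]

    def core_fluxes(self, x: np.ndarray) -> dict[str, Flux]:
        v = self.v_of(x)
        exch = dict(zip(self.exch_ids, x[self.k :]))
        fluxes = {}
        for rxn in self.lnet.reactions:
            mapped = self.mapping.get(rxn.id, [rxn.id])
            net = float(sum(v[self.ridx[m]] for m in mapped))
            e = exch.get(rxn.id, self.fixed_exchange.get(rxn.id, 0.0))
            fluxes[rxn.id] = Flux(net=net, exchange=e)
        return fluxes

    def polytope_violations(self, x: np.ndarray) -> np.ndarray:
        """Nonnegative iff the free-reaction bounds hold."""
        v = self.v_of(x)
        f = self.free_rows
        return np.concatenate([v[f] - self.lb[f], self.ub[f] - v[f]])

    def predict(self, x: np.ndarray) -> np.ndarray:
        sim = simulate_labeling(
            self.lnet, self.core_fluxes(x), self.targets, check_balance=False
        )
        return np.concatenate([sim[t].fractions for t in self.targets])

    def whiten(self, diff: np.ndarray) -> np.ndarray:
        """Map raw (observed - predicted) differences to unit-variance residuals."""
        if self.error_model == "independent":
            return diff / self.sds
        return np.concatenate(
            [W @ diff[o : o + n] for o, n, W in self._whiteners]
        )

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.whiten(self.observed - self.predict(x))

    def ssr(self, x: np.ndarray) -> float:
        try:
            r = self.residuals(x)
        except (ValidationError, np.linalg.LinAlgError):
            return 1e12  # infeasible labeling system; repel the optimizer
        return float(r @ r)

    # -- starting points ----------------------------------------------------
    def sample_starts(self, n: int, rng) -> list[np.ndarray]:
        starts = []
        if self.k:
            points = sample_flux_polytope(self.cnet, n, rng=rng)
            for v in points:
                z = self.N.T @ (v - self.v0)
                starts.append(z)
        else:
            starts = [np.zeros(0)] * n
        out = []
        for z in starts:
            if self.exch_ids:
                e = rng.uniform(self.exch_lo, np.minimum(self.exch_hi, 10.0))
                out.append(np.concatenate([z, e]))
            else:
                out.append(np.asarray(z, dtype=float))
        return out

    def bounds(self):
        return [(None, None)] * self.k + list(zip(self.exch_lo, self.exch_hi))

    def constraints(self):
        if len(self.free_rows) == 0 or self.k == 0:
            return []
        return [{"type": "ineq", "fun": self.polytope_violations}]

    def minimize(self, x0: np.ndarray, extra_constraints=(), objective=None, maxiter=300):
        fun = self.ssr if objective is None else objective
        cons = self.constraints() + list(extra_constraints)
        return scipy.optimize.minimize(
            fun,
            x0,
            method="SLSQP",
            bounds=self.bounds(),
            constraints=cons,
            options={"maxiter": maxiter, "ftol": 1e-12},
        )


def _fit(problem: _C13FitProblem, n_restarts: int, seed) -> FitResult:
    rng = np.random.default_rng(seed)
    if problem.n_params == 0:
        # fully determined: pure forward simulation
        x = np.zeros(0)
        r = problem.residuals(x)
        return FitResult(
            fluxes=FluxDistribution(fluxes=problem.core_fluxes(x)),
            ssr=float(r @ r),
            residuals=r,
            n_measurements=len(r),
            n_free_fluxes=0,
            converged=True,
            restarts_used=0,
            _problem=problem,
            _x=x,
        )
    starts = problem.sample_starts(n_restarts, rng)
    best = None
    solutions = []
    for x0 in starts:
        res = problem.minimize(x0)
        if not np.isfinite(res.fun):
            continue
        solutions.append(res)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FluxAnalysisError("all restarts failed")
    degenerate = any(
        res is not best
        and abs(res.fun - best.fun) < 1e-6
        and np.max(np.abs(problem.v_of(res.x) - problem.v_of(best.x))) > 1e-3
        for res in solutions
    )
    if degenerate:
        logger.warning("degenerate fit: multiple equal-SSR optima with differing fluxes")
    r = problem.residuals(best.x)
    return FitResult(
        fluxes=FluxDistribution(fluxes=problem.core_fluxes(best.x)),
        ssr=float(r @ r),
        residuals=r,
        n_measurements=len(r),
        n_free_fluxes=problem.n_params,
        converged=bool(best.success),
        restarts_used=len(starts),
        degenerate=degenerate,
        _problem=problem,
        _x=best.x,
    )


def c13_fit(
    network: C13ReactionNetwork,
    measurements=None,
    exchange_bounds=None,
    exchange_ub: float = EXCHANGE_UB,
    n_restarts: int = 10,
    seed=0,
    error_model: str = "normalized",
) -> FitResult:
    """Fit fluxes to measured labeling by variance-weighted least squares.

    Minimizes the variance-weighted squared mismatch between measured and
    simulated fragment MDVs over balanced, bounded net fluxes and bounded
    exchange fluxes, with ``n_restarts`` multistart attempts from random
    points of the flux polytope (best SSR wins). Reactions with
    ``lower_bound == upper_bound`` are treated as measured and pinned; with
    every flux pinned the fit degenerates to a forward simulation and the
    residuals report the pure simulation mismatch.

    ``error_model="independent"`` weights each residual by its reported sd,
    ``sum_i ((obs_i - pred_i(v)) / sd_i)^2``. The default ``"normalized"``
    additionally accounts for the unit-sum constraint of a reported MDV:
    normalization projects the raw noise onto the simplex and correlates the
    components, so residuals are whitened with the induced covariance
    (generalized least squares). With truly independent errors both models
    coincide; on normalized data the independent model is anticonservative.
    """
    problem = _C13FitProblem(
        network,
        network,
        measurements=measurements,
        exchange_bounds=exchange_bounds,
        exchange_ub=exchange_ub,
        error_model=error_model,
    )
    return _fit(problem, n_restarts, seed)


def _chi2_delta(confidence: float) -> float:
    return float(scipy.stats.chi2.ppf(confidence, df=1))


def c13_fva(
    network_or_fit,
    fit: FitResult | None = None,
    confidence: float = 0.95,
    reactions=None,
) -> RangedFluxDistribution:
    """Profile-likelihood confidence intervals for fitted net fluxes.

    For each reaction, the reported range is the min/max net flux attainable
    while keeping the fit SSR within ``chi2(confidence, df=1)`` of its
    minimum — the flux values compatible with the experimental data.
    """
    if isinstance(network_or_fit, FitResult):
        fit = network_or_fit
    elif fit is None:
        raise ValidationError("c13_fva needs the FitResult of a prior c13_fit")
    problem, xbest = fit._problem, fit._x
    if problem is None or xbest is None:
        raise ValidationError("FitResult does not carry its fit problem")
    threshold = fit.ssr + _chi2_delta(confidence)
    chi2_con = [{"type": "ineq", "fun": lambda x: threshold - problem.ssr(x)}]

    if reactions is None:
        reactions = problem.lnet.reaction_ids
    ranges = {}
    core_best = problem.core_fluxes(xbest)
    for rid in reactions:
        best_val = core_best[rid].net
        mapped = problem.mapping.get(rid, [rid])
        cols = [problem.ridx[m] for m in mapped]
        coef = problem.N[cols, :].sum(axis=0) if problem.k else np.zeros(0)
        if problem.n_params == 0 or (problem.k and np.max(np.abs(coef)) < 1e-12):
            ranges[rid] = RangedNumber(best_val, best_val, best_val)
            continue

        def net_of(x, _cols=cols):
            v = problem.v_of(x)
            return float(sum(v[c] for c in _cols))

        lo_res = problem.minimize(xbest.copy(), extra_constraints=chi2_con, objective=net_of)
        hi_res = problem.minimize(
            xbest.copy(), extra_constraints=chi2_con, objective=lambda x: -net_of(x)
        )
        lo = min(net_of(lo_res.x), best_val)
        hi = max(-hi_res.fun if np.isfinite(hi_res.fun) else best_val, best_val)
        ranges[rid] = RangedNumber(lo, min(max(best_val, lo), hi), hi)
    return RangedFluxDistribution(ranges=ranges)


def two_scale_fit(
    ts: TwoScaleNetwork,
    measurements=None,
    exchange_bounds=None,
    exchange_ub: float = EXCHANGE_UB,
    n_restarts: int = 10,
    seed=0,
    error_model: str = "normalized",
) -> tuple[FitResult, FluxDistribution]:
    """Two-scale 13C MFA: fit core labeling under genome-scale stoichiometry.

    The labeling SSR is computed on the carbon-mapped core exactly as in
    :func:`c13_fit`, but the flux variables live in the genome-scale network
    and must satisfy its full mass balance — so drains to biomass and other
    genome-scale routes constrain the core boundary exchange. Returns the
    core fit plus the consistent genome-scale flux distribution. With
    core == genome-scale the result reduces to :func:`c13_fit`.
    """
    problem = _C13FitProblem(
        ts.genome_scale,
        ts.core,
        measurements=measurements,
        mapping=ts.mapping,
        exchange_bounds=exchange_bounds,
        exchange_ub=exchange_ub,
        error_model=error_model,
    )
    fit = _fit(problem, n_restarts, seed)
    v = problem.v_of(fit._x)
    gs = FluxDistribution(
        fluxes={rid: Flux(net=float(val)) for rid, val in zip(problem.rids, v)}
    )
    return fit, gs


def elva(
    fit: FitResult,
    external_emus,
    confidence: float = 0.95,
) -> dict:
    """External labeling variability analysis.

    For each queried EMU, reports per-mass-fraction [lo, best, hi] ranges of
    the predicted MDV attainable over flux vectors within the fit's
    chi-square confidence region. Metabolites pinned by stoichiometry get
    zero-width ranges; metabolites unconstrained by the measurements can
    span wide ranges.
    """
    problem, xbest = fit._problem, fit._x
    if problem is None or xbest is None:
        raise ValidationError("FitResult does not carry its fit problem")
    threshold = fit.ssr + _chi2_delta(confidence)
    chi2_con = [{"type": "ineq", "fun": lambda x: threshold - problem.ssr(x)}]
    lnet = problem.lnet
    emus = [
        e if hasattr(e, "carbon_indices") else lnet.fragment_emu(str(e))
        for e in external_emus
    ]

    out: dict = {}
    for emu in emus:
        if lnet.metabolite(emu.metabolite_id).is_source:
            from .emu_engine import feed_emu_mdv

            vec = feed_emu_mdv(lnet, emu)
            out[emu] = [RangedNumber(v, v, v) for v in vec]
            continue

        def mdv_component(x, m, _emu=emu):
            sim = simulate_labeling(lnet, problem.core_fluxes(x), [_emu], check_balance=False)
            return float(sim[_emu].fractions[m])

        best_vec = [mdv_component(xbest, m) for m in range(emu.size + 1)]
        ranges = []
        for m, best_val in enumerate(best_vec):
            if problem.n_params == 0:
                ranges.append(RangedNumber(best_val, best_val, best_val))
                continue
            lo_res = problem.minimize(
                xbest.copy(), extra_constraints=chi2_con, objective=lambda x: mdv_component(x, m)
            )
            hi_res = problem.minimize(
                xbest.copy(), extra_constraints=chi2_con, objective=lambda x: -mdv_component(x, m)
            )
            lo = max(0.0, min(mdv_component(lo_res.x, m), best_val))
            hi = min(1.0, max(-hi_res.fun, best_val))
            ranges.append(RangedNumber(lo, min(max(best_val, lo), hi), hi))
        out[emu] = ranges
    return out


def community_cue(network, fluxes, biomass_reactions, co2_reactions) -> float:
    """Carbon utilization efficiency of a (community) flux distribution.

    CUE = carbon flux into biomass / (carbon flux into biomass + carbon flux
    lost as CO2). Each reaction's carbon flux is its net rate times the
    carbons consumed from its reactants.
    """
    if hasattr(fluxes, "fluxes"):
        fluxes = fluxes.fluxes

    def carbon_flux(rid):
        rxn = network.reaction(rid)
        carbons = sum(
            coeff * network.metabolite(m).carbon_count for m, coeff in rxn.reactants
        )
        flux = fluxes[rid]
        net = flux.net if isinstance(flux, Flux) else float(flux)
        return net * carbons

    to_biomass = sum(carbon_flux(r) for r in biomass_reactions)
    to_co2 = sum(carbon_flux(r) for r in co2_reactions)
    total = to_biomass + to_co2
    if total <= 1e-12:
        raise FluxAnalysisError("carbon utilization efficiency undefined: zero carbon flux")
    return to_biomass / total
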