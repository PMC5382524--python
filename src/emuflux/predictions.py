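"""Knockout flux prediction: MoMA and ROOM.

Both methods predict the metabolic state after a gene/reaction knockout by
staying close to a reference (e.g. wild-type) flux distribution rather than
re-optimizing growth:

* MoMA (minimization of metabolic adjustment) minimizes the Euclidean
  distance ``sum_r (v_r - v_r_ref)^2`` — a convex quadratic program.
* ROOM (regulatory on/off minimization) minimizes the *number* of reactions
  whose flux changes significantly, i.e. leaves the tolerance window
  ``ref +/- (delta * |ref| + epsilon)`` — a mixed-integer linear program
  solved here with scipy's HiGHS branch-and-bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .core import ValidationError, Flux
from .flux_models import FluxDistribution, FluxAnalysisError
from .network_io import ReactionNetwork

__all__ = ["KnockoutSpec", "moma", "room", "LethalKnockoutError", "RoomResult"]

#: ROOM significance thresholds from the original publication
ROOM_DELTA = 0.03
ROOM_EPSILON = 0.001


class LethalKnockoutError(FluxAnalysisError):
    """The network admits no steady-state flux after the knockout."""


@dataclass(frozen=True)
class KnockoutSpec:
    """Reaction ids forced to zero flux."""

    reaction_ids: tuple[str, ...]

    def __init__(self, reaction_ids):
        if isinstance(reaction_ids, str):
            reaction_ids = (reaction_ids,)
        object.__setattr__(self, "reaction_ids", tuple(reaction_ids))

    def validate(self, network: ReactionNetwork) -> None:
        known = set(network.reaction_ids)
        missing = [r for r in self.reaction_ids if r not in known]
        if missing:
            raise ValidationError(f"knockout references unknown reactions {missing}")


def _ko_bounds(network: ReactionNetwork, ko: KnockoutSpec):
    lb, ub = network.bounds_arrays()
    lb, ub = lb.copy(), ub.copy()
    idx = {r: i for i, r in enumerate(network.reaction_ids)}
    for rid in ko.reaction_ids:
        lb[idx[rid]] = 0.0
        ub[idx[rid]] = 0.0
    return lb, ub


def _reference_vector(network: ReactionNetwork, reference) -> np.ndarray:
    if isinstance(reference, FluxDistribution):
        return reference.net_vector(network.reaction_ids)
    return np.array([float(reference[r]) for r in network.reaction_ids])


def moma(network: ReactionNetwork, reference, ko: KnockoutSpec) -> FluxDistribution:
    """Minimize squared flux distance to the reference after a knockout.

    Solves ``min sum (v - v_ref)^2  s.t.  S v = 0, bounds, v_ko = 0``.
    The QP is strictly convex, so the minimizer is unique; with an empty
    knockout (or one already at zero reference flux) it returns the
    reference itself.
    """
    ko = ko if isinstance(ko, KnockoutSpec) else KnockoutSpec(ko)
    ko.validate(network)
    ref = _reference_vector(network, reference)
    S = network.stoichiometric_matrix()
    lb, ub = _ko_bounds(network, ko)
    if np.any(lb > ub):
        raise LethalKnockoutError("knockout bounds are contradictory")

    n = len(ref)

    def objective(v):
        d = v - ref
        return float(d @ d)

    def grad(v):
        return 2.0 * (v - ref)

    x0 = np.clip(ref, lb, ub)
    constraints = []
    if S.size:
        constraints.append(scipy.optimize.LinearConstraint(S, 0.0, 0.0))
    res = scipy.optimize.minimize(
        objective,
        x0,
        jac=grad,
        hess=lambda v: 2.0 * np.eye(n),
        method="trust-constr",
        bounds=scipy.optimize.Bounds(lb, ub),
        constraints=constraints,
        options={"gtol": 1e-12, "xtol": 1e-12, "maxiter": 2000},
    )
    v = res.x
    if S.size and np.max(np.abs(S @ v)) > 1e-6:
        raise LethalKnockoutError("knockout leaves no steady-state flux distribution")
    fluxes = {rid: Flux(net=float(val)) for rid, val in zip(network.reaction_ids, v)}
    dist = FluxDistribution(fluxes=fluxes, objective_value=float(res.fun))
    return dist


@dataclass
class RoomResult:
    """ROOM solution: the flux distribution and its changed-reaction count."""

    fluxes: FluxDistribution
    n_changed: int
    changed_reactions: list[str] = field(default_factory=list)
    optimal: bool = True


def room(
    network: ReactionNetwork,
    reference,
    ko: KnockoutSpec,
    delta: float = ROOM_DELTA,
    epsilon: float = ROOM_EPSILON,
    time_limit: float = 60.0,
) -> RoomResult:
    """Minimize the number of significantly changed fluxes after a knockout.

    A reaction counts as changed when its flux leaves the window
    ``[ref - delta*|ref| - epsilon, ref + delta*|ref| + epsilon]``. Binary
    indicators y_r relax the window with big-M terms from the flux bounds;
    HiGHS solves the resulting MILP. Returns the minimizer together with the
    changed-flux count.
    """
    ko = ko if isinstance(ko, KnockoutSpec) else KnockoutSpec(ko)
    ko.validate(network)
    ref = _reference_vector(network, reference)
    S = network.stoichiometric_matrix()
    lb, ub = _ko_bounds(network, ko)

    n = len(ref)
    w_hi = ref + delta * np.abs(ref) + epsilon
    w_lo = ref - delta * np.abs(ref) - epsilon

    # variables: v (n continuous) then y (n binary)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    constraints = []
    if S.size:
        A = np.hstack([S, np.zeros((S.shape[0], n))])
        constraints.append(scipy.optimize.LinearConstraint(A, 0.0, 0.0))
    # v_r - y_r (ub_r - w_hi_r) <= w_hi_r
    big_up = np.maximum(ub - w_hi, 0.0)
    A_up = np.hstack([np.eye(n), -np.diag(big_up)])
    constraints.append(scipy.optimize.LinearConstraint(A_up, -np.inf, w_hi))
    # v_r + y_r (w_lo_r - lb_r) >= w_lo_r
    big_dn = np.maximum(w_lo - lb, 0.0)
    A_dn = np.hstack([np.eye(n), np.diag(big_dn)])
    constraints.append(scipy.optimize.LinearConstraint(A_dn, w_lo, np.inf))

    bounds = scipy.optimize.Bounds(
        np.concatenate([lb, np.zeros(n)]), np.concatenate([ub, np.ones(n)])
    )
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    res = scipy.optimize.milp(
        c,
        constraints=constraints,
        bounds=bounds,
        integrality=integrality,
        options={"time_limit": time_limit},
    )
    if res.status == 2 or res.x is None:
        raise LethalKnockoutError("knockout leaves no steady-state flux distribution")
    v = res.x[:n]
    y = res.x[n:]
    changed = [rid for rid, yi in zip(network.reaction_ids, y) if yi > 0.5]
    fluxes = {rid: Flux(net=float(val)) for rid, val in zip(network.reaction_ids, v)}
    return RoomResult(
        fluxes=FluxDistribution(fluxes=fluxes, objective_value=float(res.fun)),
        n_changed=int(round(res.fun)),
        changed_reactions=changed,
        optimal=(res.status == 0),
    )
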