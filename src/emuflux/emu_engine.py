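"""EMU decomposition and forward simulation of isotope labeling.

The forward problem of 13C MFA — given a flux distribution, what labeling
patterns result — is solved here with the elementary metabolite unit (EMU)
method: the atom-transition network is decomposed into the minimal set of
carbon subsets (EMUs) that influence the requested measurements, and their
mass distribution vectors are obtained by solving one linear system per EMU
size, in ascending size order. Condensation reactions couple sizes only
downward (a size-s EMU is formed from strictly smaller pieces), which is
what makes the cascade linear.

Two cross-checking alternatives to the cascade are provided:

* :func:`simulate_labeling` with ``scheme="coupled"`` solves all EMU
  balances simultaneously by fixed-point iteration, without size
  decoupling; it must agree with the cascade to numerical precision.
* :func:`brute_force_isotopomer_simulate` solves the full positional
  isotopomer balance (2^n states per n-carbon metabolite). It is exact,
  exponential in molecule size, and serves as the independent oracle for
  small networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import EMU, MDV, EMUTransition, Flux, ValidationError
from .network_io import C13ReactionNetwork

__all__ = [
    "required_emus",
    "emu_transitions_for",
    "simulate_labeling",
    "brute_force_isotopomer_simulate",
    "IsotopomerState",
    "feed_emu_mdv",
    "SingularEMUSystemError",
]

#: guard for the brute-force oracle: total isotopomer states must stay small
ORACLE_STATE_LIMIT = 2**16


class SingularEMUSystemError(ValidationError):
    """An EMU has no producing flux at the given flux distribution."""


# ---------------------------------------------------------------------------
# flux map plumbing
# ---------------------------------------------------------------------------


def as_flux_map(fluxes) -> dict[str, Flux]:
    """Accept {rxn: Flux}, {rxn: float} or a FluxDistribution-like object."""
    if hasattr(fluxes, "fluxes"):
        fluxes = fluxes.fluxes
    out = {}
    for rid, val in fluxes.items():
        out[rid] = val if isinstance(val, Flux) else Flux(net=float(val))
    return out


def check_flux_balance(network: C13ReactionNetwork, fluxes: dict[str, Flux], tol: float = 1e-6):
    S = network.stoichiometric_matrix()
    v = np.array([fluxes[r].net if r in fluxes else 0.0 for r in network.reaction_ids])
    resid = S @ v
    scale = max(1.0, float(np.max(np.abs(v))) if v.size else 1.0)
    if resid.size and np.max(np.abs(resid)) > tol * scale:
        worst = int(np.argmax(np.abs(resid)))
        met = network.internal_metabolites[worst].id
        raise ValidationError(
            f"fluxes violate steady state: |S v| = {np.max(np.abs(resid)):.3g} at {met}"
        )


# ---------------------------------------------------------------------------
# transition tracing
# ---------------------------------------------------------------------------


def _effective_transitions(network: C13ReactionNetwork):
    """Yield (rxn_id, direction, weight, lhs_patterns, rhs_patterns).

    Reversible reactions contribute both directions; the backward direction
    is the atom transition read right-to-left, weighted by the backward flux.
    """
    for rid, trans_list in network.transitions.items():
        rxn = network.reaction(rid)
        for t in trans_list:
            yield rid, "forward", t.weight, t.reactant_patterns, t.product_patterns
            if rxn.reversible:
                yield rid, "backward", t.weight, t.product_patterns, t.reactant_patterns


def _trace_sources(lhs, rhs, target: EMU) -> list[tuple[EMU, ...]]:
    """Source EMU tuples producing ``target``, one per product-side instance."""
    results = []
    for pmet, ppat in rhs:
        if pmet != target.metabolite_id:
            continue
        needed = {ppat[i - 1] for i in target.carbon_indices}
        sources = []
        for smet, spat in lhs:
            pos = tuple(i + 1 for i, ch in enumerate(spat) if ch in needed)
            if pos:
                sources.append(EMU(smet, pos))
        sources.sort()
        results.append(tuple(sources))
    return results


@dataclass
class _ProductionTerm:
    reaction_id: str
    direction: str
    weight: float
    sources: tuple[EMU, ...]


@dataclass
class EMUDecomposition:
    """Backward closure of the targets: per unknown EMU, its production terms."""

    targets: tuple[EMU, ...]
    terms: dict[EMU, list[_ProductionTerm]] = field(default_factory=dict)
    feed_emus: set[EMU] = field(default_factory=set)

    @property
    def unknown_emus(self) -> list[EMU]:
        return sorted(self.terms)

    def all_emus(self) -> set[EMU]:
        return set(self.terms) | self.feed_emus

    def sizes(self) -> list[int]:
        return sorted({e.size for e in self.terms})


def _decompose(network: C13ReactionNetwork, targets: tuple[EMU, ...]) -> EMUDecomposition:
    met_ids = set(network.metabolite_ids)
    for t in targets:
        if t.metabolite_id not in met_ids:
            raise ValidationError(f"target metabolite {t.metabolite_id} not in network")
        if t.carbon_indices[-1] > network.metabolite(t.metabolite_id).carbon_count:
            raise ValidationError(f"EMU {t.name} exceeds metabolite carbon count")

    effective = list(_effective_transitions(network))
    decomp = EMUDecomposition(targets=targets)
    stack = list(targets)
    seen: set[EMU] = set()
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        if network.metabolite(emu.metabolite_id).is_source:
            decomp.feed_emus.add(emu)
            continue
        terms = decomp.terms.setdefault(emu, [])
        for rid, direction, weight, lhs, rhs in effective:
            for sources in _trace_sources(lhs, rhs, emu):
                terms.append(_ProductionTerm(rid, direction, weight, sources))
                stack.extend(sources)
        if not terms:
            raise ValidationError(
                f"EMU {emu.name} has no producing transition; network is not carbon-closed"
            )
    return decomp


def _decomposition_cached(network: C13ReactionNetwork, targets: tuple[EMU, ...]) -> EMUDecomposition:
    cache = getattr(network, "_emu_cache", None)
    if cache is None:
        cache = {}
        setattr(network, "_emu_cache", cache)
    key = targets
    if key not in cache:
        cache[key] = _decompose(network, targets)
    return cache[key]


def _as_emu(network: C13ReactionNetwork, target) -> EMU:
    if isinstance(target, EMU):
        return target
    return EMU.from_name(str(target), known_metabolites=network.metabolite_ids)


def required_emus(network: C13ReactionNetwork, targets) -> set[EMU]:
    """Minimal EMU closure reachable backward from the targets (feed included)."""
    targets = tuple(_as_emu(network, t) for t in targets)
    return _decomposition_cached(network, targets).all_emus()


def emu_transitions_for(network: C13ReactionNetwork, emu_set) -> list[EMUTransition]:
    """EMU-level transitions whose targets lie in ``emu_set``."""
    emu_set = {(_as_emu(network, e)) for e in emu_set}
    out: list[EMUTransition] = []
    for rid, direction, weight, lhs, rhs in _effective_transitions(network):
        for emu in sorted(emu_set):
            if network.metabolite(emu.metabolite_id).is_source:
                continue
            for sources in _trace_sources(lhs, rhs, emu):
                out.append(EMUTransition(rid, sources, emu, direction=direction, weight=weight))
    return out


# ---------------------------------------------------------------------------
# feed labeling
# ---------------------------------------------------------------------------


def feed_emu_mdv(network: C13ReactionNetwork, emu: EMU) -> np.ndarray:
    """MDV of a feed-metabolite EMU from the positional-isotopomer mixture."""
    mixture = network.feed.get(emu.metabolite_id)
    if mixture is None:
        raise ValidationError(f"no feed labeling specified for {emu.metabolite_id}")
    mdv = np.zeros(emu.size + 1)
    for mask, frac in mixture:
        m = sum(1 for i in emu.carbon_indices if mask[i - 1] == "1")
        mdv[m] += frac
    return mdv


# ---------------------------------------------------------------------------
# cascade and coupled solvers
# ---------------------------------------------------------------------------


def _term_flux(term: _ProductionTerm, fluxes: dict[str, Flux]) -> float:
    flux = fluxes.get(term.reaction_id)
    if flux is None:
        raise ValidationError(f"no flux given for reaction {term.reaction_id}")
    rate = flux.forward if term.direction == "forward" else flux.backward
    return rate * term.weight


def simulate_labeling(
    network: C13ReactionNetwork,
    fluxes,
    targets,
    scheme: str = "cascade",
    check_balance: bool = True,
) -> dict[EMU, MDV]:
    """Compute steady-state MDVs of the target EMUs for a flux distribution.

    ``scheme="cascade"`` (default) solves one linear system per EMU size;
    ``scheme="coupled"`` iterates the full coupled balance without size
    decoupling. Both return identical results; the coupled path exists as an
    internal consistency check.

    Labeling depends only on flux ratios, so scaling all fluxes by a positive
    constant leaves the result unchanged.
    """
    fluxes = as_flux_map(fluxes)
    targets = tuple(_as_emu(network, t) for t in targets)
    if check_balance:
        check_flux_balance(network, fluxes)
    decomp = _decomposition_cached(network, targets)
    if scheme == "cascade":
        solution = _solve_cascade(network, decomp, fluxes)
    elif scheme == "coupled":
        solution = _solve_coupled(network, decomp, fluxes)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = {}
    for t in targets:
        vec = solution[t]
        if np.min(vec) < -1e-9:
            raise ValidationError(f"negative mass fraction in solved MDV for {t.name}")
        out[t] = MDV(np.clip(vec, 0.0, None), normalize=True)
    return out


def _known_value(emu: EMU, network, solution) -> np.ndarray | None:
    if network.metabolite(emu.metabolite_id).is_source:
        return feed_emu_mdv(network, emu)
    return solution.get(emu)


def _solve_cascade(network, decomp: EMUDecomposition, fluxes) -> dict[EMU, np.ndarray]:
    solution: dict[EMU, np.ndarray] = {}
    for fe in decomp.feed_emus:
        solution[fe] = feed_emu_mdv(network, fe)
    for size in decomp.sizes():
        unknowns = [e for e in decomp.unknown_emus if e.size == size]
        index = {e: i for i, e in enumerate(unknowns)}
        n = len(unknowns)
        A = np.zeros((n, n))
        b = np.zeros((n, size + 1))
        for e in unknowns:
            i = index[e]
            total = 0.0
            for term in decomp.terms[e]:
                f = _term_flux(term, fluxes)
                total += f
                if f == 0.0:
                    continue
                src = term.sources
                if (
                    len(src) == 1
                    and src[0].size == size
                    and not network.metabolite(src[0].metabolite_id).is_source
                ):
                    A[i, index[src[0]]] += f
                else:
                    vec = None
                    for s in src:
                        sval = _known_value(s, network, solution)
                        assert sval is not None, f"cascade ordering broken at {s.name}"
                        vec = sval if vec is None else np.convolve(vec, sval)
                    b[i] -= f * vec
            if total <= 1e-12:
                raise SingularEMUSystemError(
                    f"EMU {e.name} has zero production flux; system is singular"
                )
            A[i, i] -= total
        X = np.linalg.solve(A, b)
        for e, row in zip(unknowns, X):
            solution[e] = row
    return solution


def _solve_coupled(
    network,
    decomp: EMUDecomposition,
    fluxes,
    tol: float = 1e-14,
    max_iter: int = 100000,
) -> dict[EMU, np.ndarray]:
    """Jacobi fixed-point on the full EMU balance, all sizes at once."""
    solution: dict[EMU, np.ndarray] = {}
    for fe in decomp.feed_emus:
        solution[fe] = feed_emu_mdv(network, fe)
    unknowns = decomp.unknown_emus
    for e in unknowns:  # start unlabeled
        vec = np.zeros(e.size + 1)
        vec[0] = 1.0
        solution[e] = vec
    totals = {}
    for e in unknowns:
        totals[e] = sum(_term_flux(t, fluxes) for t in decomp.terms[e])
        if totals[e] <= 1e-12:
            raise SingularEMUSystemError(f"EMU {e.name} has zero production flux")
    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for e in unknowns:
            acc = np.zeros(e.size + 1)
            for term in decomp.terms[e]:
                f = _term_flux(term, fluxes)
                if f == 0.0:
                    continue
                vec = None
                for s in term.sources:
                    sval = solution[s]
                    vec = sval if vec is None else np.convolve(vec, sval)
                acc += f * vec
            acc /= totals[e]
            delta = max(delta, float(np.max(np.abs(acc - solution[e]))))
            new[e] = acc
        solution.update(new)
        if delta < tol:
            break
    else:  # pragma: no cover
        raise ValidationError("coupled EMU solve did not converge")
    return solution


# ---------------------------------------------------------------------------
# brute-force isotopomer oracle
# ---------------------------------------------------------------------------


@dataclass
class IsotopomerState:
    """Full positional-isotopomer distributions, one 2^n vector per metabolite."""

    distributions: dict[str, np.ndarray]
    carbon_counts: dict[str, int]

    def mdv(self, met_id: str, carbon_indices=None) -> MDV:
        """Marginalize a metabolite's isotopomers to an MDV.

        ``carbon_indices`` (1-based) restricts to an EMU of the metabolite;
        by default the full molecule is used.
        """
        vec = self.distributions[met_id]
        n = self.carbon_counts[met_id]
        if carbon_indices is None:
            carbon_indices = range(1, n + 1)
        bits = [i - 1 for i in carbon_indices]
        mdv = np.zeros(len(bits) + 1)
        for idx, p in enumerate(vec):
            m = sum((idx >> b) & 1 for b in bits)
            mdv[m] += p
        return MDV(mdv, normalize=True)


def _feed_distribution(network, met_id: str) -> np.ndarray:
    met = network.metabolite(met_id)
    vec = np.zeros(2 ** met.carbon_count)
    for mask, frac in network.feed[met_id]:
        idx = sum(1 << i for i, ch in enumerate(mask) if ch == "1")
        vec[idx] += frac
    return vec


def brute_force_isotopomer_simulate(
    network: C13ReactionNetwork,
    fluxes,
    tol: float = 1e-14,
    max_iter: int = 200000,
) -> IsotopomerState:
    """Solve the full isotopomer steady-state balance by fixed-point iteration.

    Every carbon-bearing, non-feed metabolite produced by some transition is
    tracked as a 2^n vector over positional isotopomers. Feasible only for
    small networks (guard: total states <= 2^16); intended as the exact
    oracle against which the EMU solver is verified.
    """
    fluxes = as_flux_map(fluxes)
    check_flux_balance(network, fluxes)

    tracked = []
    for met in network.metabolites:
        if met.carbon_count == 0 or met.is_source:
            continue
        tracked.append(met.id)
    total_states = sum(2 ** network.metabolite(m).carbon_count for m in tracked)
    if total_states > ORACLE_STATE_LIMIT:
        raise ValidationError(
            f"brute-force oracle refused: {total_states} isotopomer states exceed "
            f"{ORACLE_STATE_LIMIT}"
        )

    # precompute production machinery per tracked metabolite
    terms: dict[str, list] = {m: [] for m in tracked}
    for rid, direction, weight, lhs, rhs in _effective_transitions(network):
        for pmet, ppat in rhs:
            if pmet not in terms:
                continue
            sources = [(smet, spat) for smet, spat in lhs]
            # map: product carbon p gets letter ppat[p]; find (source index, pos)
            mapping = []
            for p, letter in enumerate(ppat):
                for si, (smet, spat) in enumerate(sources):
                    q = spat.find(letter)
                    if q >= 0:
                        mapping.append((si, q))
                        break
                else:
                    raise ValidationError(f"{rid}: letter {letter!r} not found on source side")
            src_sizes = [len(spat) for _, spat in sources]
            # joint index -> target isotopomer index
            n_joint = int(np.prod([2**s for s in src_sizes]))
            joint_bits = np.arange(n_joint)
            # decompose joint index into per-source indices (source 0 fastest)
            src_indices = []
            shift = 0
            for s in src_sizes:
                src_indices.append((joint_bits >> shift) & (2**s - 1))
                shift += s
            targ = np.zeros(n_joint, dtype=np.int64)
            for p, (si, q) in enumerate(mapping):
                targ |= (((src_indices[si] >> q) & 1) << p).astype(np.int64)
            terms[pmet].append((rid, direction, weight, [m for m, _ in sources], src_sizes, targ))

    dist: dict[str, np.ndarray] = {}
    for met in network.metabolites:
        if met.carbon_count == 0:
            continue
        if met.is_source:
            dist[met.id] = _feed_distribution(network, met.id)
    for m in tracked:
        n = network.metabolite(m).carbon_count
        vec = np.zeros(2**n)
        vec[0] = 1.0
        dist[m] = vec
        if not terms[m]:
            raise ValidationError(f"{m}: no producing transition in oracle")

    totals = {}
    for m in tracked:
        tot = 0.0
        for rid, direction, weight, _, _, _ in terms[m]:
            flux = fluxes[rid]
            tot += (flux.forward if direction == "forward" else flux.backward) * weight
        if tot <= 1e-12:
            raise SingularEMUSystemError(f"{m}: zero production flux in oracle")
        totals[m] = tot

    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for m in tracked:
            n = network.metabolite(m).carbon_count
            acc = np.zeros(2**n)
            for rid, direction, weight, src_mets, src_sizes, targ in terms[m]:
                flux = fluxes[rid]
                f = (flux.forward if direction == "forward" else flux.backward) * weight
                if f == 0.0:
                    continue
                joint = dist[src_mets[0]]
                for sm in src_mets[1:]:
                    joint = np.multiply.outer(dist[sm], joint).ravel()
                    # note: outer(b, a).ravel() keeps source 0 varying fastest
                acc += f * np.bincount(targ, weights=joint, minlength=2**n)
            acc /= totals[m]
            delta = max(delta, float(np.max(np.abs(acc - dist[m]))))
            new[m] = acc
        dist.update(new)
        if delta < tol:
            break
    else:  # pragma: no cover
        raise ValidationError("isotopomer fixed point did not converge")

    carbon_counts = {m: network.metabolite(m).carbon_count for m in dist}
    return IsotopomerState(distributions=dist, carbon_counts=carbon_counts)
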