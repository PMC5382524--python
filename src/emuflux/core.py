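"""Foundational domain types for flux and isotope-labeling models.

The vocabulary here is the standard one of constraint-based modeling and
13C metabolic flux analysis (MFA):

* a :class:`Metabolite` / :class:`Reaction` pair describes stoichiometry;
* a :class:`Flux` splits a reaction rate into net and exchange components
  (equivalently forward/backward rates);
* an :class:`AtomTransition` records the fate of every carbon atom in a
  reaction, e.g. ``accoa(ab) + oac(cdef) --> cit(fedbac)``;
* an :class:`EMU` (elementary metabolite unit) is a distinct subset of a
  metabolite's carbons, the minimal state variable for labeling simulation;
* an :class:`MDV` (mass distribution vector) gives the fraction of molecules
  of a fragment/EMU carrying 0, 1, ..., n labeled carbons.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "Flux",
    "RangedNumber",
    "AtomTransition",
    "EMU",
    "EMUTransition",
    "MDV",
    "flux_from_net_exchange",
    "ranged",
    "convolve_mdv",
    "parse_formula",
    "formula_to_string",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


# ---------------------------------------------------------------------------
# metabolites and reactions
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in a reaction network.

    Parameters
    ----------
    id : str
        Unique identifier, compartment suffix preserved (e.g. ``"accoa_c"``).
    carbon_count : int
        Number of backbone carbons tracked in labeling simulations.
    is_source : bool
        Feed metabolite: excluded from mass balance, labeling set by the feed.
    is_excreted : bool
        Boundary product: excluded from mass balance.
    """

    id: str
    name: str = ""
    carbon_count: int = 0
    compartment: str = ""
    is_source: bool = False
    is_excreted: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")
        if self.carbon_count < 0:
            raise ValidationError(f"{self.id}: carbon_count must be >= 0")

    @property
    def is_boundary(self) -> bool:
        return self.is_source or self.is_excreted


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDW/h.

    ``reactants`` and ``products`` are lists of ``(metabolite_id, coeff)``
    with positive coefficients on both sides; the sign convention lives in
    the stoichiometric matrix, not here.
    """

    id: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        for side in (self.reactants, self.products):
            for met, coeff in side:
                if coeff <= 0:
                    raise ValidationError(
                        f"{self.id}: stoichiometric coefficient for {met} must be > 0"
                    )
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"{self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ValidationError(f"{self.id}: irreversible reaction with negative lower bound")

    def participants(self) -> set[str]:
        return {m for m, _ in self.reactants} | {m for m, _ in self.products}


# ---------------------------------------------------------------------------
# fluxes and ranged numbers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Flux:
    """Reaction rate split into net and exchange components.

    The standard 13C-MFA decomposition is used::

        forward  = exchange + max(net, 0)
        backward = exchange + max(-net, 0)

    so that ``forward - backward == net`` and ``min(forward, backward) ==
    exchange``. The exchange flux governs label scrambling without net
    conversion.
    """

    net: float = 0.0
    exchange: float = 0.0

    def __post_init__(self) -> None:
        if self.exchange < 0:
            raise ValidationError(f"exchange flux must be >= 0, got {self.exchange}")

    @property
    def forward(self) -> float:
        return self.exchange + max(self.net, 0.0)

    @property
    def backward(self) -> float:
        return self.exchange + max(-self.net, 0.0)

    @classmethod
    def from_forward_backward(cls, forward: float, backward: float) -> "Flux":
        if forward < 0 or backward < 0:
            raise ValidationError("forward and backward fluxes must be >= 0")
        return cls(net=forward - backward, exchange=min(forward, backward))


def flux_from_net_exchange(net: float, exchange: float = 0.0) -> Flux:
    """Build a :class:`Flux` from net and (nonnegative) exchange components."""
    return Flux(net=float(net), exchange=float(exchange))


@dataclass(frozen=True)
class RangedNumber:
    """A best-fit value with lower/upper confidence limits, ``lo <= best <= hi``."""

    lo: float
    best: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.best <= self.hi):
            raise ValidationError(
                f"ranged number ordering violated: lo={self.lo}, best={self.best}, hi={self.hi}"
            )

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


def ranged(lo: float, best: float, hi: float) -> RangedNumber:
    return RangedNumber(float(lo), float(best), float(hi))


# ---------------------------------------------------------------------------
# atom transitions and EMUs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomTransition:
    """Carbon fate map for one reaction.

    Each pattern is a string of single-letter carbon labels, one letter per
    backbone carbon, e.g. ``[("accoa", "ab"), ("oac", "cdef")]`` on the
    reactant side and ``[("cit", "fedbac")]`` on the product side. The letter
    multiset must balance between the two sides (carbon conservation).

    ``weight`` < 1 is used for symmetric molecules: a molecule with a 2-fold
    rotation axis (succinate, fumarate) is represented by two half-weight
    transitions, one per indistinguishable orientation.
    """

    reaction_id: str
    reactant_patterns: tuple[tuple[str, str], ...]
    product_patterns: tuple[tuple[str, str], ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValidationError(f"{self.reaction_id}: transition weight must be in (0, 1]")
        lhs = Counter("".join(p for _, p in self.reactant_patterns))
        rhs = Counter("".join(p for _, p in self.product_patterns))
        if lhs != rhs:
            raise ValidationError(
                f"{self.reaction_id}: carbon not conserved (reactant letters "
                f"{''.join(sorted(lhs.elements()))!r} vs product letters "
                f"{''.join(sorted(rhs.elements()))!r})"
            )
        for side in (self.reactant_patterns, self.product_patterns):
            for met, pat in side:
                if len(set(pat)) != len(pat):
                    raise ValidationError(
                        f"{self.reaction_id}: duplicate carbon letter within {met}({pat})"
                    )


@dataclass(frozen=True, order=True)
class EMU:
    """An elementary metabolite unit: a subset of a metabolite's carbons.

    Carbon positions are 1-based; the canonical name lists them ascending,
    e.g. ``cit_3_4_5`` for carbons 3-5 of citrate.
    """

    metabolite_id: str
    carbon_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(self.carbon_indices))
        if len(set(idx)) != len(idx) or not idx:
            raise ValidationError("EMU carbon indices must be distinct and nonempty")
        if idx[0] < 1:
            raise ValidationError("EMU carbon indices are 1-based")
        object.__setattr__(self, "carbon_indices", idx)

    @property
    def size(self) -> int:
        return len(self.carbon_indices)

    @property
    def name(self) -> str:
        return self.metabolite_id + "".join(f"_{i}" for i in self.carbon_indices)

    @classmethod
    def from_name(cls, name: str, known_metabolites: list[str] | None = None) -> "EMU":
        """Parse ``met_1_2_3``-style names.

        Metabolite ids may themselves contain underscores (``accoa_c``), so
        when ``known_metabolites`` is given the longest matching id wins;
        otherwise the trailing run of integer suffixes is taken as indices.
        """
        if known_metabolites:
            for met in sorted(known_metabolites, key=len, reverse=True):
                if name == met:
                    continue
                if name.startswith(met + "_"):
                    rest = name[len(met) + 1 :].split("_")
                    if all(tok.isdigit() for tok in rest):
                        return cls(met, tuple(int(t) for t in rest))
            raise ValidationError(f"cannot resolve EMU name {name!r} against network metabolites")
        parts = name.split("_")
        idx: list[int] = []
        while parts and parts[-1].isdigit():
            idx.append(int(parts.pop()))
        if not idx or not parts:
            raise ValidationError(f"not an EMU name: {name!r}")
        return cls("_".join(parts), tuple(reversed(idx)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class EMUTransition:
    """Flux-weighted rule mapping source EMU(s) onto a target EMU.

    One source is a simple transfer; two or more sources condense (their MDVs
    convolve). ``direction`` selects the forward or backward component of the
    reaction's flux; ``weight`` inherits the atom transition's symmetry weight.
    """

    reaction_id: str
    source_emus: tuple[EMU, ...]
    target_emu: EMU
    direction: str = "forward"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValidationError(f"direction must be forward/backward, got {self.direction!r}")
        if sum(e.size for e in self.source_emus) != self.target_emu.size:
            raise ValidationError(
                f"{self.reaction_id}: source EMU sizes "
                f"{[e.size for e in self.source_emus]} do not sum to target size "
                f"{self.target_emu.size}"
            )

    @property
    def is_condensation(self) -> bool:
        return len(self.source_emus) > 1


# ---------------------------------------------------------------------------
# mass distribution vectors
# ---------------------------------------------------------------------------


class MDV:
    """Mass distribution vector of an n-carbon fragment or EMU.

    ``fractions[m]`` is the fraction of molecules with ``m`` labeled carbons,
    for m = 0..n (the unlabeled fraction m0 is included so the vector sums
    to 1). Optional ``errors`` carry one standard deviation per component.
    """

    __slots__ = ("fractions", "errors")

    def __init__(self, fractions, errors=None, normalize: bool = True):
        frac = np.asarray(fractions, dtype=float)
        if frac.ndim != 1 or frac.size == 0:
            raise ValidationError("MDV fractions must be a nonempty 1-D vector")
        if np.any(frac < -1e-9):
            raise ValidationError("MDV fractions must be nonnegative")
        frac = np.clip(frac, 0.0, None)
        total = frac.sum()
        if normalize:
            if total <= 0:
                raise ValidationError("MDV fractions sum to zero; cannot normalize")
            frac = frac / total
        self.fractions = frac
        if errors is not None:
            errors = np.asarray(errors, dtype=float)
            if errors.shape != frac.shape:
                raise ValidationError("MDV errors must match fractions in length")
            if np.any(errors < 0):
                raise ValidationError("MDV errors must be nonnegative")
        self.errors = errors

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def __len__(self) -> int:
        return len(self.fractions)

    def __getitem__(self, m):
        return self.fractions[m]

    def __iter__(self):
        return iter(self.fractions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MDV):
            return NotImplemented
        return self.fractions.shape == other.fractions.shape and bool(
            np.allclose(self.fractions, other.fractions, atol=1e-12)
        )

    def __repr__(self) -> str:
        vals = ", ".join(f"{x:.4f}" for x in self.fractions)
        return f"MDV([{vals}])"

    def isclose(self, other: "MDV", atol: float = 1e-8) -> bool:
        return bool(np.allclose(self.fractions, other.fractions, atol=atol))


def convolve_mdv(a: MDV, b: MDV) -> MDV:
    """Cauchy product of two MDVs: the labeling of the condensed molecule.

    When two moieties with mass distributions *a* and *b* join, the number of
    labeled carbons adds, so the product's MDV is the discrete convolution.
    """
    return MDV(np.convolve(a.fractions, b.fractions), normalize=True)


# ---------------------------------------------------------------------------
# elemental formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: str) -> list[tuple[str, int]]:
    """Split an elemental composition string into (element, count) pairs.

    ``"H6NO2Si"`` -> ``[("H", 6), ("N", 1), ("O", 2), ("Si", 1)]``. An omitted
    count means 1; order of first appearance is preserved and repeated
    elements accumulate.
    """
    s = s.strip()
    if not s:
        return []
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(s):
        if match.start() != pos:
            raise ValidationError(f"unparseable formula {s!r} at position {pos}")
        elem, num = match.groups()
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(s):
        raise ValidationError(f"unparseable formula {s!r} at position {pos}")
    return list(counts.items())


def formula_to_string(composition: list[tuple[str, int]]) -> str:
    """Inverse of :func:`parse_formula` (counts of 1 are omitted)."""
    out = []
    for elem, count in composition:
        if count < 0:
            raise ValidationError(f"negative count for element {elem}")
        if count == 0:
            continue
        out.append(elem if count == 1 else f"{elem}{count}")
    return "".join(out)
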