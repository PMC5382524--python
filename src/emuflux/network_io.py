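"""Reaction networks and their file formats.

Three network flavors, mirroring the needs of the three flux techniques:

* :class:`ReactionNetwork` — plain stoichiometry with bounds and an
  objective; the substrate of FBA/FVA.
* :class:`C13ReactionNetwork` — adds per-reaction carbon (atom) transitions,
  a feed-labeling specification and measured fragment MDVs; the substrate of
  13C MFA.
* :class:`TwoScaleNetwork` — a genome-scale stoichiometric network whose
  carbon transitions cover only a defined core; the substrate of two-scale
  13C MFA.

File formats handled here: an SBML subset (Level 3 core; bounds and
objective read from fbc attributes or from reaction notes, written as
notes), a plain-text atom-transition dialect
(``CS<TAB>accoa(ab) + oac(cdef) --> cit(fedbac)``), CSV labeling
measurements and CSV feed-labeling specifications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    EMU,
    AtomTransition,
    MDV,
    Metabolite,
    Reaction,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionNetwork",
    "C13ReactionNetwork",
    "TwoScaleNetwork",
    "build_stoichiometric_matrix",
    "carbon_transitions_ok",
    "read_sbml",
    "write_sbml",
    "parse_atom_transitions",
    "parse_atom_transition_lines",
    "write_atom_transitions",
    "read_labeling_csv",
    "write_labeling_csv",
    "read_feed_csv",
    "write_feed_csv",
    "read_flux_csv",
    "write_flux_csv",
]

#: COBRA-convention default bounds used when an SBML file carries none.
DEFAULT_UB = 1000.0

#: Floor applied to reported measurement standard deviations; typical MS
#: precision, prevents zero-weight divisions in the fit.
SD_FLOOR = 0.003


# ---------------------------------------------------------------------------
# network containers
# ---------------------------------------------------------------------------


@dataclass
class ReactionNetwork:
    """A stoichiometric reaction network with bounds and an objective."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    id: str = "network"

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError("duplicate reaction ids")
        for rxn in self.reactions:
            missing = rxn.participants() - set(self._met_index)
            if missing:
                raise ValidationError(f"{rxn.id}: unknown metabolites {sorted(missing)}")
        for rid in self.objective:
            if rid not in self._rxn_index:
                raise ValidationError(f"objective references unknown reaction {rid}")

    # -- lookups ------------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        """Metabolites subject to steady-state mass balance (non-boundary)."""
        return [m for m in self.metabolites if not m.is_boundary]

    def stoichiometric_matrix(self) -> np.ndarray:
        return build_stoichiometric_matrix(self)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub


@dataclass
class C13ReactionNetwork(ReactionNetwork):
    """A reaction network annotated with carbon transitions and labeling data.

    ``transitions`` maps reaction id -> list of :class:`AtomTransition`
    (symmetric molecules contribute several fractional-weight entries whose
    weights sum to 1). ``feed`` maps each source-metabolite id to a mixture of
    positional isotopomers ``[(mask, fraction), ...]`` where the mask is a
    0/1 string over carbons (``"11"`` = [1,2-13C]) and fractions sum to 1.
    ``measured_fragments`` holds ``(fragment_name, MDV)`` pairs; fragment
    names are EMU names (``glu_1_2_3_4_5``).
    """

    transitions: dict[str, list[AtomTransition]] = field(default_factory=dict)
    feed: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    measured_fragments: list[tuple[str, MDV]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        for rid in self.transitions:
            if rid not in self._rxn_index:
                raise ValidationError(f"transition references unknown reaction {rid}")
        for met_id, mixture in self.feed.items():
            met = self._met_index.get(met_id)
            if met is None:
                raise ValidationError(f"feed references unknown metabolite {met_id}")
            total = sum(frac for _, frac in mixture)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValidationError(f"feed fractions for {met_id} sum to {total}, not 1")
            for mask, _ in mixture:
                if len(mask) != met.carbon_count or set(mask) - {"0", "1"}:
                    raise ValidationError(
                        f"feed mask {mask!r} invalid for {met_id} ({met.carbon_count} carbons)"
                    )

    def fragment_emu(self, fragment_name: str) -> EMU:
        return EMU.from_name(fragment_name, known_metabolites=self.metabolite_ids)

    def validate_carbon_transitions(self) -> None:
        reports = carbon_transitions_ok(self)
        if reports:
            raise ValidationError("carbon-transition inconsistencies:\n" + "\n".join(reports))


@dataclass
class TwoScaleNetwork:
    """Genome-scale stoichiometry with carbon transitions on a core subset.

    ``core`` is a :class:`C13ReactionNetwork` over the carbon-mapped core.
    ``mapping`` sends each core reaction id to the genome-scale reaction ids
    whose net fluxes sum to the (possibly lumped) core flux; core reactions
    absent from the mapping are taken to exist verbatim in the genome-scale
    network.
    """

    genome_scale: ReactionNetwork
    core: C13ReactionNetwork
    mapping: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gs_ids = set(self.genome_scale.reaction_ids)
        for rid in self.core.reaction_ids:
            mapped = self.mapping.get(rid, [rid])
            missing = [g for g in mapped if g not in gs_ids]
            if missing:
                raise ValidationError(
                    f"core reaction {rid} maps to unknown genome-scale reactions {missing}"
                )

    def core_reactions_of(self, rid: str) -> list[str]:
        return self.mapping.get(rid, [rid])


def build_stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Signed stoichiometric matrix over internal metabolites.

    Rows follow ``network.internal_metabolites``, columns follow
    ``network.reactions``; consumption is negative. ``S @ v = 0`` expresses
    steady state.
    """
    internal = network.internal_metabolites
    row = {m.id: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.reactants:
            if met in row:
                S[row[met], j] -= coeff
        for met, coeff in rxn.products:
            if met in row:
                S[row[met], j] += coeff
    return S


# ---------------------------------------------------------------------------
# carbon-transition consistency checks
# ---------------------------------------------------------------------------


def carbon_transitions_ok(network: C13ReactionNetwork) -> list[str]:
    """Cross-check carbon transitions against reaction stoichiometry.

    Returns a list of human-readable inconsistency reports (empty when the
    network is consistent). Checked per reaction: every transition names only
    actual reactants/products, pattern lengths match carbon counts, weights
    sum to 1, and carbon is conserved (enforced at construction). Checked
    globally: every internal carbon-bearing metabolite is produced by at
    least one transition, and every reaction with carbon-bearing products has
    a transition.
    """
    reports: list[str] = []
    produced: set[str] = set()

    for rid, trans_list in network.transitions.items():
        rxn = network.reaction(rid)
        reactant_ids = {m for m, _ in rxn.reactants}
        product_ids = {m for m, _ in rxn.products}
        total_weight = sum(t.weight for t in trans_list)
        if trans_list and not math.isclose(total_weight, 1.0, abs_tol=1e-9):
            reports.append(f"{rid}: transition weights sum to {total_weight:g}, expected 1")
        for trans in trans_list:
            for met, pat in trans.reactant_patterns:
                if met not in reactant_ids:
                    reports.append(f"{rid}: transition reactant {met} is not a reaction reactant")
                    continue
                if len(pat) != network.metabolite(met).carbon_count:
                    reports.append(
                        f"{rid}: pattern {met}({pat}) has {len(pat)} carbons, metabolite has "
                        f"{network.metabolite(met).carbon_count}"
                    )
            for met, pat in trans.product_patterns:
                if met not in product_ids:
                    reports.append(f"{rid}: transition product {met} is not a reaction product")
                    continue
                if len(pat) != network.metabolite(met).carbon_count:
                    reports.append(
                        f"{rid}: pattern {met}({pat}) has {len(pat)} carbons, metabolite has "
                        f"{network.metabolite(met).carbon_count}"
                    )
                produced.add(met)
            if rxn.reversible:
                # backward direction produces the transition's reactants
                produced.update(m for m, _ in trans.reactant_patterns)

    for rxn in network.reactions:
        has_carbon_product = any(
            network.metabolite(m).carbon_count > 0 for m, _ in rxn.products
        )
        if has_carbon_product and not network.transitions.get(rxn.id):
            reports.append(f"{rxn.id}: no atom transition for a carbon-producing reaction")

    for met in network.metabolites:
        if met.carbon_count == 0 or met.is_boundary:
            continue
        if met.id not in produced:
            reports.append(f"{met.id}: internal carbon-bearing metabolite never produced by a transition")
    return reports


# ---------------------------------------------------------------------------
# atom-transition text dialect
# ---------------------------------------------------------------------------


def _parse_side(text: str, rid: str) -> list[tuple[str, str]]:
    out = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ValidationError(f"{rid}: empty term in atom transition")
        if "(" in term:
            met, _, rest = term.partition("(")
            pat = rest.rstrip()
            if not pat.endswith(")"):
                raise ValidationError(f"{rid}: unbalanced parenthesis in {term!r}")
            out.append((met.strip(), pat[:-1]))
        else:
            out.append((term, ""))  # carbon-free participant
    return out


def parse_atom_transition_lines(lines) -> list[AtomTransition]:
    """Parse atom-transition lines of the form::

        CS<TAB>accoa(ab) + oac(cdef) --> cit(fedbac)

    Blank lines and ``#`` comments are ignored. Several lines may share one
    reaction id (symmetric molecules); their transitions receive equal
    fractional weights summing to 1.
    """
    raw: list[tuple[str, list, list]] = []
    per_reaction: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2 or "-->" not in parts[1]:
            raise ValidationError(f"line {lineno}: expected '<rxn>\\t<lhs> --> <rhs>', got {line!r}")
        rid, rule = parts
        lhs_text, _, rhs_text = rule.partition("-->")
        lhs = [(m, p) for m, p in _parse_side(lhs_text, rid) if p]
        rhs = [(m, p) for m, p in _parse_side(rhs_text, rid) if p]
        raw.append((rid, lhs, rhs))
        per_reaction[rid] = per_reaction.get(rid, 0) + 1
    return [
        AtomTransition(rid, tuple(lhs), tuple(rhs), weight=1.0 / per_reaction[rid])
        for rid, lhs, rhs in raw
    ]


def parse_atom_transitions(path) -> list[AtomTransition]:
    with open(path) as fh:
        return parse_atom_transition_lines(fh)


def write_atom_transitions(transitions: list[AtomTransition], path) -> None:
    with open(path, "w") as fh:
        for t in transitions:
            lhs = " + ".join(f"{m}({p})" for m, p in t.reactant_patterns)
            rhs = " + ".join(f"{m}({p})" for m, p in t.product_patterns)
            fh.write(f"{t.reaction_id}\t{lhs} --> {rhs}\n")


def group_transitions(transitions: list[AtomTransition]) -> dict[str, list[AtomTransition]]:
    grouped: dict[str, list[AtomTransition]] = {}
    for t in transitions:
        grouped.setdefault(t.reaction_id, []).append(t)
    return grouped


# ---------------------------------------------------------------------------
# CSV labeling / feed / flux files
# ---------------------------------------------------------------------------


def read_labeling_csv(path) -> list[tuple[str, MDV]]:
    """Read measured fragment MDVs.

    Columns: ``fragment, m0..mk, sd0..sdk`` (header optional). Rows whose
    fractions deviate from unit sum by more than 0.05 trigger a warning;
    all rows are renormalized. Standard deviations are floored at
    ``SD_FLOOR``.
    """
    import csv

    out: list[tuple[str, MDV]] = []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip() or row[0].startswith("#"):
                continue
            name = row[0].strip()
            if name.lower() == "fragment":
                continue
            try:
                values = [float(x) for x in row[1:] if x.strip() != ""]
            except ValueError as exc:
                raise ValidationError(f"nonnumeric labeling entry in row {row!r}") from exc
            if len(values) % 2 != 0:
                raise ValidationError(
                    f"{name}: expected equal-length fraction and sd columns, got {len(values)}"
                )
            half = len(values) // 2
            fractions = np.array(values[:half])
            sds = np.maximum(np.array(values[half:]), SD_FLOOR)
            total = fractions.sum()
            if abs(total - 1.0) > 0.05:
                logger.warning("%s: MDV fractions sum to %.4f; renormalizing", name, total)
            out.append((name, MDV(fractions, errors=sds)))
    return out


def write_labeling_csv(measurements: list[tuple[str, MDV]], path) -> None:
    with open(path, "w") as fh:
        for name, mdv in measurements:
            sds = mdv.errors if mdv.errors is not None else np.zeros(len(mdv))
            frac = ",".join(f"{x:.10g}" for x in mdv.fractions)
            sd = ",".join(f"{x:.10g}" for x in sds)
            fh.write(f"{name},{frac},{sd}\n")


def read_feed_csv(path) -> dict[str, list[tuple[str, float]]]:
    """Read a feed-labeling specification.

    Columns: ``metabolite, mask, fraction`` where the mask is a 0/1 string
    over the metabolite's carbons (``01`` = labeled at carbon 2).
    """
    import csv

    feed: dict[str, list[tuple[str, float]]] = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip() or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "metabolite":
                continue
            met, mask, frac = row[0].strip(), row[1].strip(), float(row[2])
            feed.setdefault(met, []).append((mask, frac))
    return feed


def write_feed_csv(feed: dict[str, list[tuple[str, float]]], path) -> None:
    with open(path, "w") as fh:
        for met, mixture in feed.items():
            for mask, frac in mixture:
                fh.write(f"{met},{mask},{frac:.10g}\n")


def read_flux_csv(path) -> dict[str, "Flux"]:
    """Read ``reaction, net[, exchange]`` rows into a flux map."""
    import csv

    from .core import Flux

    fluxes: dict[str, Flux] = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip() or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "reaction":
                continue
            net = float(row[1])
            exch = float(row[2]) if len(row) > 2 and row[2].strip() else 0.0
            fluxes[row[0].strip()] = Flux(net=net, exchange=exch)
    return fluxes


def write_flux_csv(fluxes, path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction,net,exchange\n")
        for rid, flux in fluxes.items():
            fh.write(f"{rid},{flux.net:.10g},{flux.exchange:.10g}\n")


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------


def _notes_dict(sbase) -> dict[str, str]:
    notes = sbase.getNotesString() if sbase.isSetNotes() else ""
    out: dict[str, str] = {}
    for line in notes.splitlines():
        line = line.strip()
        if line.startswith("<p>") and line.endswith("</p>") and ":" in line:
            body = line[3:-4]
            key, _, value = body.partition(":")
            out[key.strip().lower()] = value.strip()
    return out


def _set_notes(sbase, items: dict[str, str]) -> None:
    import libsbml

    body = "".join(f"<p>{k}: {v}</p>" for k, v in items.items())
    xml = f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    status = sbase.setNotes(xml)
    if status != libsbml.LIBSBML_OPERATION_SUCCESS:  # pragma: no cover
        raise IOError(f"libsbml refused notes: status {status}")


def _carbon_count_from_formula(formula: str) -> int:
    from .core import parse_formula

    for elem, count in parse_formula(formula):
        if elem == "C":
            return count
    return 0


def read_sbml(path) -> ReactionNetwork:
    """Read an SBML Level 2/3 core file into a :class:`ReactionNetwork`.

    Bounds are taken from fbc attributes when present, else from reaction
    notes (``lower_bound: x``), else defaulted to COBRA conventions
    ([0, 1000] irreversible, [-1000, 1000] reversible) with a warning.
    Carbon counts come from fbc chemical formulas or ``carbons:`` notes;
    source/excreted roles from ``role:`` notes or the SBML boundaryCondition
    attribute (boundary species with only consuming reactions are sources).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValidationError(f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}")
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"SBML file {path} contains no model")

    metabolites = []
    for sp in model.getListOfSpecies():
        notes = _notes_dict(sp)
        carbons = 0
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            carbons = _carbon_count_from_formula(fbc_sp.getChemicalFormula())
        if "carbons" in notes:
            carbons = int(notes["carbons"])
        role = notes.get("role", "")
        is_source = role == "source"
        is_excreted = role == "excreted"
        if sp.getBoundaryCondition() and not (is_source or is_excreted):
            is_excreted = True  # refined below once reactions are known
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                carbon_count=carbons,
                compartment=sp.getCompartment() or "",
                is_source=is_source,
                is_excreted=is_excreted,
            )
        )
    met_by_id = {m.id: m for m in metabolites}

    fbc_model = model.getPlugin("fbc")
    reactions = []
    objective: dict[str, float] = {}
    for rx in model.getListOfReactions():
        notes = _notes_dict(rx)
        reversible = rx.getReversible()
        lb = ub = None
        fbc_rx = rx.getPlugin("fbc")
        if fbc_rx is not None and fbc_rx.isSetLowerFluxBound():
            lb_param = model.getParameter(fbc_rx.getLowerFluxBound())
            ub_param = model.getParameter(fbc_rx.getUpperFluxBound())
            if lb_param is not None:
                lb = lb_param.getValue()
            if ub_param is not None:
                ub = ub_param.getValue()
        if "lower_bound" in notes:
            lb = float(notes["lower_bound"])
        if "upper_bound" in notes:
            ub = float(notes["upper_bound"])
        if lb is None or ub is None:
            logger.warning("%s: no bounds in SBML; applying defaults", rx.getId())
            lb = -DEFAULT_UB if reversible else 0.0 if lb is None else lb
            ub = DEFAULT_UB if ub is None else ub
        if "objective" in notes:
            objective[rx.getId()] = float(notes["objective"])
        reactions.append(
            Reaction(
                id=rx.getId(),
                reactants=[
                    (sr.getSpecies(), sr.getStoichiometry()) for sr in rx.getListOfReactants()
                ],
                products=[
                    (sr.getSpecies(), sr.getStoichiometry()) for sr in rx.getListOfProducts()
                ],
                reversible=reversible,
                lower_bound=lb,
                upper_bound=ub,
            )
        )

    if fbc_model is not None and fbc_model.getActiveObjective() is not None:
        active = fbc_model.getActiveObjective()
        for fo in active.getListOfFluxObjectives():
            objective[fo.getReaction()] = fo.getCoefficient()

    # boundary species defaulted to excreted above: flip to source when only consumed
    consumed = {m for r in reactions for m, _ in r.reactants}
    produced = {m for r in reactions for m, _ in r.products}
    for m in metabolites:
        if m.is_excreted and m.id in consumed and m.id not in produced:
            m.is_excreted, m.is_source = False, True

    return ReactionNetwork(
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        id=model.getId() or "network",
    )


def write_sbml(network: ReactionNetwork, path) -> None:
    """Write the supported SBML subset (Level 3 core, notes-encoded bounds).

    ``read_sbml(write_sbml(net))`` is the identity on that subset.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(network.id)

    compartments = {m.compartment or "default" for m in network.metabolites}
    for cid in sorted(compartments):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in network.metabolites:
        sp = model.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment or "default")
        sp.setBoundaryCondition(met.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        notes = {"carbons": str(met.carbon_count)}
        if met.is_source:
            notes["role"] = "source"
        elif met.is_excreted:
            notes["role"] = "excreted"
        _set_notes(sp, notes)

    for rxn in network.reactions:
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for met, coeff in rxn.reactants:
            sr = rx.createReactant()
            sr.setSpecies(met)
            sr.setStoichiometry(coeff)
            sr.setConstant(True)
        for met, coeff in rxn.products:
            sr = rx.createProduct()
            sr.setSpecies(met)
            sr.setStoichiometry(coeff)
            sr.setConstant(True)
        notes = {
            "lower_bound": f"{rxn.lower_bound:.10g}",
            "upper_bound": f"{rxn.upper_bound:.10g}",
        }
        if rxn.id in network.objective:
            notes["objective"] = f"{network.objective[rxn.id]:.10g}"
        _set_notes(rx, notes)

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")
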