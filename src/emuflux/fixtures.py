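"""Programmatic generators for every test input.

Nothing here is downloaded: the TCA-cycle toy network, the toy FBA and
two-scale networks, the soil-community model and all synthetic
measurements are built in code, deterministically per seed.

The TCA toy is the classic benchmark network for EMU-based 13C MFA
(a simplification of the tricarboxylic acid cycle): acetyl-CoA and
aspartate are the substrates, glutamate and CO2 the products, and the feed
is 50% unlabeled / 25% [2-13C] / 25% [1,2-13C] acetyl-CoA with unlabeled
aspartate. Flux values and carbon maps follow the standard published toy;
the in-repo brute-force isotopomer oracle — not any external figure — is
the ground truth the EMU solver is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Flux, MDV, Metabolite, Reaction, ValidationError
from .emu_engine import simulate_labeling
from .flux_models import FluxDistribution
from .network_io import (
    C13ReactionNetwork,
    ReactionNetwork,
    SD_FLOOR,
    TwoScaleNetwork,
    group_transitions,
    parse_atom_transition_lines,
)
from .pcap import OmicsMatrix

__all__ = [
    "FixtureSpec",
    "TCA_MEASURED_FRAGMENTS",
    "tca_toy",
    "TCA_REFERENCE_FLUXES",
    "TCA_REFERENCE_EXCHANGE",
    "chain_network",
    "parallel_paths_network",
    "branched_reference",
    "two_scale_toy",
    "soil_community_fixture",
    "synth_measurements",
    "synthetic_proteomics",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Identifies a fixture build: same name + seed + parameters, same bytes."""

    name: str
    seed: int = 0
    parameters: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# TCA toy network
# ---------------------------------------------------------------------------

#: reference net fluxes of the TCA toy (mmol/gDW/h, uptake-normalized scale)
TCA_REFERENCE_FLUXES: dict[str, float] = {
    "r1": 100.0,  # citrate synthase: accoa + oac -> cit
    "r2": 100.0,  # cit -> akg + co2
    "r3": 50.0,  # akg -> glu (product)
    "r4": 50.0,  # akg -> suc + co2
    "r5": 50.0,  # suc -> fum (symmetric scrambling)
    "r6": 50.0,  # fum <-> oac (net toward oac)
    "r7": 50.0,  # asp -> oac
    "r8": 150.0,  # co2 sink
    "r9": 50.0,  # glu sink
}

#: reference exchange flux of the one reversible reaction
TCA_REFERENCE_EXCHANGE: dict[str, float] = {"r6": 50.0}

_TCA_TRANSITIONS = """\
r1\toac(abcd) + accoa(ef) --> cit(dcbfea)
r2\tcit(abcdef) --> akg(abcde) + co2(f)
r3\takg(abcde) --> glu(abcde)
r4\takg(abcde) --> suc(bcde) + co2(a)
r4\takg(abcde) --> suc(edcb) + co2(a)
r5\tsuc(abcd) --> fum(abcd)
r5\tsuc(abcd) --> fum(dcba)
r6\tfum(abcd) --> oac(abcd)
r6\tfum(abcd) --> oac(dcba)
r7\tasp(abcd) --> oac(abcd)
"""

#: the feed printed on the toy's input files: AcCoA 50% unlabeled,
#: 25% labeled at carbon 2, 25% labeled at carbons 1+2; aspartate unlabeled
TCA_FEED = {
    "accoa": [("00", 0.50), ("01", 0.25), ("11", 0.25)],
    "asp": [("0000", 1.0)],
}


def tca_reference_flux_map() -> dict[str, Flux]:
    return {
        rid: Flux(net=v, exchange=TCA_REFERENCE_EXCHANGE.get(rid, 0.0))
        for rid, v in TCA_REFERENCE_FLUXES.items()
    }


def tca_toy(free=(), free_bound: float = 200.0) -> C13ReactionNetwork:
    """The TCA-cycle toy network with carbon transitions and feed labeling.

    All fluxes are pinned to their reference values (the forward-simulation
    scenario) except reactions named in ``free``, whose bounds open to
    ``[0, free_bound]`` (``[-free_bound, free_bound]`` for the reversible
    fumarate/oxaloacetate interconversion). Succinate and fumarate are
    symmetric molecules, represented by half-weight duplicate transitions.
    """
    mets = [
        Metabolite("accoa", "acetyl-CoA", 2, is_source=True),
        Metabolite("asp", "aspartate", 4, is_source=True),
        Metabolite("oac", "oxaloacetate", 4),
        Metabolite("cit", "citrate", 6),
        Metabolite("akg", "alpha-ketoglutarate", 5),
        Metabolite("suc", "succinate", 4),
        Metabolite("fum", "fumarate", 4),
        Metabolite("glu", "glutamate", 5),
        Metabolite("co2", "carbon dioxide", 1),
    ]
    stoich = {
        "r1": ([("accoa", 1), ("oac", 1)], [("cit", 1)]),
        "r2": ([("cit", 1)], [("akg", 1), ("co2", 1)]),
        "r3": ([("akg", 1)], [("glu", 1)]),
        "r4": ([("akg", 1)], [("suc", 1), ("co2", 1)]),
        "r5": ([("suc", 1)], [("fum", 1)]),
        "r6": ([("fum", 1)], [("oac", 1)]),
        "r7": ([("asp", 1)], [("oac", 1)]),
        "r8": ([("co2", 1)], []),
        "r9": ([("glu", 1)], []),
    }
    reactions = []
    for rid, (lhs, rhs) in stoich.items():
        reversible = rid == "r6"
        ref = TCA_REFERENCE_FLUXES[rid]
        if rid in free:
            lb, ub = (-free_bound if reversible else 0.0), free_bound
        else:
            lb = ub = ref
        reactions.append(
            Reaction(rid, reactants=lhs, products=rhs, reversible=reversible,
                     lower_bound=lb, upper_bound=ub)
        )
    transitions = group_transitions(
        parse_atom_transition_lines(_TCA_TRANSITIONS.splitlines())
    )
    net = C13ReactionNetwork(
        metabolites=mets,
        reactions=reactions,
        transitions=transitions,
        feed={k: list(v) for k, v in TCA_FEED.items()},
        id="tca_toy",
    )
    net.validate_carbon_transitions()
    return net


# ---------------------------------------------------------------------------
# toy FBA networks
# ---------------------------------------------------------------------------


def chain_network(uptake: float = 10.0) -> ReactionNetwork:
    """Linear chain source -> A -> B -> sink with bounded uptake."""
    mets = [
        Metabolite("s", is_source=True),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("p", is_excreted=True),
    ]
    reactions = [
        Reaction("upt", [("s", 1)], [("A", 1)], upper_bound=uptake),
        Reaction("conv", [("A", 1)], [("B", 1)]),
        Reaction("out", [("B", 1)], [("p", 1)]),
    ]
    return ReactionNetwork(mets, reactions, objective={"out": 1.0}, id="chain")


def parallel_paths_network(
    uptake: float = 10.0, branch_capacity: float = 1000.0
) -> ReactionNetwork:
    """Source -> A -> (two parallel branches) -> B -> sink."""
    mets = [
        Metabolite("s", is_source=True),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("p", is_excreted=True),
    ]
    reactions = [
        Reaction("upt", [("s", 1)], [("A", 1)], upper_bound=uptake),
        Reaction("b1", [("A", 1)], [("B", 1)], upper_bound=branch_capacity),
        Reaction("b2", [("A", 1)], [("B", 1)], upper_bound=branch_capacity),
        Reaction("out", [("B", 1)], [("p", 1)]),
    ]
    return ReactionNetwork(mets, reactions, objective={"out": 1.0}, id="parallel")


def branched_reference() -> tuple[ReactionNetwork, FluxDistribution]:
    """The two-branch toy with a 7/3 reference split (for MoMA/ROOM tests)."""
    net = parallel_paths_network(uptake=10.0)
    net.reaction("upt").lower_bound = 10.0  # fix uptake so rerouting is forced
    reference = FluxDistribution(
        fluxes={
            "upt": Flux(net=10.0),
            "b1": Flux(net=7.0),
            "b2": Flux(net=3.0),
            "out": Flux(net=10.0),
        }
    )
    return net, reference


# ---------------------------------------------------------------------------
# two-scale toy
# ---------------------------------------------------------------------------


def two_scale_toy(drain: float = 0.0, free=("r3", "r9")) -> TwoScaleNetwork:
    """TCA toy core inside a genome-scale network with a biomass drain.

    The genome-scale network is the core plus one alpha-ketoglutarate drain
    to biomass, pinned at ``drain``. Mass balance then forces the core
    glutamate-branch flux to shift by exactly the drain — the stoichiometric
    coupling two-scale MFA exists to capture. With ``drain=0`` the problem
    reduces to plain 13C MFA on the core.
    """
    core = tca_toy(free=free)
    gs_mets = [
        Metabolite(m.id, m.name, m.carbon_count, m.compartment, m.is_source, m.is_excreted)
        for m in core.metabolites
    ]
    gs_reactions = [
        Reaction(r.id, list(r.reactants), list(r.products), r.reversible,
                 r.lower_bound, r.upper_bound)
        for r in core.reactions
    ]
    gs_reactions.append(
        Reaction("akg_to_biomass", [("akg", 1)], [], lower_bound=drain, upper_bound=drain)
    )
    gs = ReactionNetwork(gs_mets, gs_reactions, id="tca_toy_gs")
    return TwoScaleNetwork(genome_scale=gs, core=core)


# ---------------------------------------------------------------------------
# soil-community fixture
# ---------------------------------------------------------------------------

_COMMUNITY_TRACERS = {
    "glucose": {"1-13C": "100000", "U-13C": "111111"},
    "pyruvate": {"1-13C": "100", "2,3-13C": "011"},
}


def _community_network(source: str, feed_mask: str, cue: float) -> tuple[C13ReactionNetwork, dict[str, Flux]]:
    uptake = 10.0
    if source == "glucose":
        mets = [
            Metabolite("glc", "glucose", 6, is_source=True),
            Metabolite("pyr", "pyruvate", 3),
            Metabolite("accoa", "acetyl-CoA", 2),
            Metabolite("co2", "carbon dioxide", 1),
        ]
        pyr_production = 2 * uptake
        lines = [
            "gly\tglc(abcdef) --> pyr(cba) + pyr(def)",
            "pdh\tpyr(abc) --> accoa(bc) + co2(a)",
            "tca\taccoa(ab) --> co2(a) + co2(b)",
        ]
        stoich = {
            "gly": ([("glc", 1)], [("pyr", 2)]),
            "pdh": ([("pyr", 1)], [("accoa", 1), ("co2", 1)]),
            "tca": ([("accoa", 1)], [("co2", 2)]),
            "bio_pyr": ([("pyr", 1)], []),
            "co2_out": ([("co2", 1)], []),
        }
        feed_met = "glc"
        base = {"gly": uptake}
    else:
        mets = [
            Metabolite("pyr", "pyruvate", 3, is_source=True),
            Metabolite("accoa", "acetyl-CoA", 2),
            Metabolite("co2", "carbon dioxide", 1),
        ]
        pyr_production = uptake
        lines = [
            "pdh\tpyr(abc) --> accoa(bc) + co2(a)",
            "tca\taccoa(ab) --> co2(a) + co2(b)",
        ]
        stoich = {
            "pdh": ([("pyr", 1)], [("accoa", 1), ("co2", 1)]),
            "tca": ([("accoa", 1)], [("co2", 2)]),
            "bio_pyr": ([("pyr", 1)], []),
            "co2_out": ([("co2", 1)], []),
        }
        feed_met = "pyr"
        base = {}

    # plant the carbon-use efficiency: CUE = biomass carbon / total carbon
    bio = cue * pyr_production
    pdh = pyr_production - bio
    fluxes = dict(base)
    fluxes.update({"bio_pyr": bio, "pdh": pdh, "tca": pdh, "co2_out": 3 * pdh})
    reactions = [
        Reaction(rid, reactants=lhs, products=rhs,
                 lower_bound=fluxes[rid], upper_bound=fluxes[rid])
        for rid, (lhs, rhs) in stoich.items()
    ]
    net = C13ReactionNetwork(
        metabolites=mets,
        reactions=reactions,
        transitions=group_transitions(parse_atom_transition_lines(lines)),
        feed={feed_met: [(feed_mask, 1.0)]},
        id=f"community_{source}",
    )
    net.validate_carbon_transitions()
    return net, {rid: Flux(net=v) for rid, v in fluxes.items()}


def soil_community_fixture(cue: float = 0.3) -> dict:
    """Two-substrate soil-community setup with a planted carbon-use efficiency.

    For each carbon source (glucose, pyruvate) a lumped central-metabolism
    network is built in two tracer variants that share identical fluxes and
    differ only in feed labeling. The planted CUE fixes the split between
    the pyruvate drain to biomass and respiration to CO2.
    """
    if not 0 <= cue < 1:
        raise ValidationError("planted CUE must lie in [0, 1)")
    out = {}
    for source, tracers in _COMMUNITY_TRACERS.items():
        variants = {}
        fluxes = None
        for label, mask in tracers.items():
            net, fluxes = _community_network(source, mask, cue)
            variants[label] = net
        out[source] = {
            "variants": variants,
            "fluxes": fluxes,
            "biomass_reactions": ["bio_pyr"],
            "co2_reactions": ["co2_out"],
            "planted_cue": cue,
        }
    return out


# ---------------------------------------------------------------------------
# synthetic measurements
# ---------------------------------------------------------------------------


#: default measured-fragment panel for fitting studies on the TCA toy.
#: Real 13C MFA fits many metabolite fragments at once (central-carbon MS
#: panels routinely cover ~9 metabolites); a single tiny-fraction fragment
#: is an unrealistically information-poor design.
TCA_MEASURED_FRAGMENTS = (
    "glu_1_2_3_4_5",
    "suc_1_2_3_4",
    "cit_1_2_3_4_5_6",
    "oac_1_2_3_4",
)


def synth_measurements(
    network: C13ReactionNetwork,
    true_fluxes,
    noise_sd: float = 0.0,
    seed: int = 0,
    fragments=TCA_MEASURED_FRAGMENTS,
) -> list[tuple[str, MDV]]:
    """Simulate fragment MDVs at known fluxes and add Gaussian noise.

    Noise is truncated to [0, 1] componentwise and the vector renormalized;
    the reported standard deviation is ``noise_sd`` floored at the package's
    measurement-error floor. Deterministic per seed.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    emus = [network.fragment_emu(f) for f in fragments]
    sim = simulate_labeling(network, true_fluxes, emus, check_balance=False)
    out = []
    for name, emu in zip(fragments, emus):
        vec = sim[emu].fractions.copy()
        if noise_sd > 0:
            vec = np.clip(vec + rng.normal(0.0, noise_sd, size=vec.shape), 0.0, 1.0)
        sd = np.full(vec.shape, max(noise_sd, SD_FLOOR))
        out.append((name, MDV(vec, errors=sd, normalize=True)))
    return out


# ---------------------------------------------------------------------------
# synthetic proteomics
# ---------------------------------------------------------------------------


def synthetic_proteomics(
    n_strains: int = 27,
    n_proteins: int = 20,
    n_informative: int = 3,
    effect: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, list[str]]:
    """Factorial pathway-engineering screen with a planted production signal.

    Mirrors a 3x3x3 combinatorial design (promoter strength x induction
    strength x induction time, 27 strains by default; other sizes take the
    leading combinations). The three factors jointly set one latent pathway
    expression level, which drives the ``n_informative`` planted pathway
    proteins (swing of ``effect`` abundance units, large against the
    ``noise_sd`` biological noise, as induction systems are) and the
    bioproduct titer. Returns the matrix and the planted protein names.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"prot{i + 1}" for i in range(n_proteins)]
    strains = [f"strain{i + 1}" for i in range(n_strains)]
    combos = np.array(
        [(i, j, k) for i in range(3) for j in range(3) for k in range(3)], dtype=float
    )
    levels = combos[np.arange(n_strains) % len(combos)]
    latent = levels.sum(axis=1) / 6.0  # pathway expression in [0, 1]
    X = rng.normal(10.0, noise_sd, size=(n_strains, n_proteins))
    informative = proteins[:n_informative]
    X[:, :n_informative] += effect * latent[:, None]
    production = 1.0 + 2.0 * latent + rng.normal(0.0, 0.1, size=n_strains)
    matrix = OmicsMatrix(
        data=pd.DataFrame(X, index=strains, columns=proteins),
        production=pd.Series(production, index=strains, name="titer"),
    )
    return matrix, informative
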