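import numpy as np
import pytest
from hypothesis import settings

from emuflux.core import Flux
from emuflux.fixtures import tca_reference_flux_map, tca_toy

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: unpinning everything except the acetyl-CoA uptake (r1) leaves the TCA toy
#: with one free net flux (the glutamate/TCA split, parametrized by r4) plus
#: the fumarate/oxaloacetate exchange — the standard 2-free-parameter fit.
TCA_FREE = ("r2", "r3", "r4", "r5", "r6", "r7", "r8", "r9")


def tca_truth_fluxes(r4: float, exchange: float = 0.0, scale: float = 1.0) -> dict[str, Flux]:
    """Balanced TCA-toy flux map with the split flux r4 and r6 exchange free."""
    nets = {
        "r1": 100.0,
        "r2": 100.0,
        "r3": 100.0 - r4,
        "r4": r4,
        "r5": r4,
        "r6": r4,
        "r7": 100.0 - r4,
        "r8": 100.0 + r4,
        "r9": 100.0 - r4,
    }
    return {
        rid: Flux(net=v * scale, exchange=(exchange * scale if rid == "r6" else 0.0))
        for rid, v in nets.items()
    }


def random_balanced_tca_fluxes(rng) -> dict[str, Flux]:
    return tca_truth_fluxes(
        r4=rng.uniform(10.0, 90.0), exchange=rng.uniform(0.0, 60.0),
        scale=rng.uniform(0.5, 2.0),
    )


@pytest.fixture()
def tca_network():
    return tca_toy()


@pytest.fixture()
def tca_fluxes():
    return tca_reference_flux_map()


@pytest.fixture()
def glu_emu(tca_network):
    return tca_network.fragment_emu("glu_1_2_3_4_5")
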