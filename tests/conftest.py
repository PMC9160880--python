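import numpy as np
import pytest

from emuflux.atom_network import FluxVector
from emuflux.emu import InputLabeling
from emuflux.synthetic import make_network, make_scenario


@pytest.fixture(scope="session")
def toy1():
    return make_network("TOY1")


@pytest.fixture(scope="session")
def toy_cmp():
    return make_network("TOY_CMP")


@pytest.fixture(scope="session")
def toy1_scenario():
    return make_scenario("TOY1")


@pytest.fixture(scope="session")
def cmp_scenario():
    return make_scenario("TOY_CMP")


@pytest.fixture
def toy1_labeled():
    """100% [1-13C] substrate for TOY1."""
    return InputLabeling({"Aex": [("10", 1.0)]})


def toy1_fluxes(v1: float, v3: float) -> FluxVector:
    u = v1 + v3
    return FluxVector({"upt": u, "v1": v1, "v3": v3, "v2": u,
                       "out_c": u, "out_d": u})


def random_cmp_fluxes(rng: np.random.Generator) -> FluxVector:
    """Random feasible flux vector for the TOY_CMP preset."""
    upt = rng.uniform(2.0, 10.0)
    ppp = rng.uniform(0.05, 0.9) * upt
    emp = upt - ppp
    bm = rng.uniform(0.0, 0.5) * emp
    ana = rng.uniform(0.0, 1.0)
    pdh = emp + ana - bm
    c_avail = ppp + pdh - ana
    ova = rng.uniform(0.05, 0.9) * c_avail
    cnd = (c_avail - ova) / 2.0
    exch = rng.uniform(0.0, 5.0)
    return FluxVector(
        {"upt": upt, "emp": emp, "ppp": ppp, "pdh": pdh, "ana": ana,
         "ova": ova, "cnd": cnd, "out_d": cnd, "bm_b": bm},
        {"emp": exch})


def random_toy1_fluxes(rng: np.random.Generator) -> FluxVector:
    return toy1_fluxes(rng.uniform(0.1, 10.0), rng.uniform(0.1, 10.0))


def random_labeling(rng: np.random.Generator, preset: str) -> InputLabeling:
    """Random substrate labeling mixture for a preset network."""
    if preset == "TOY1":
        patterns = ["00", "10", "01", "11"]
        fracs = rng.dirichlet(np.ones(len(patterns)))
        return InputLabeling({"Aex": list(zip(patterns, fracs))})
    patterns = ["000", "100", "110", "111", "101"]
    fracs = rng.dirichlet(np.ones(len(patterns)))
    co2 = rng.uniform(0.0, 0.1)
    return InputLabeling({
        "Aex": list(zip(patterns, fracs)),
        "CO2in": [("0", 1.0 - co2), ("1", co2)],
    })
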