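import numpy as np
import pytest

from biokin import fixtures as fx
from biokin.engine import SimulationContext


@pytest.fixture(scope="session")
def inert_context() -> SimulationContext:
    """Default well context: inert chemical, 24 h doubling cell line,
    96-well plate, 48 h exposure."""
    return fx.make_context()


@pytest.fixture(scope="session")
def cell_line():
    return fx.make_cell_line()


@pytest.fixture(scope="session")
def plate():
    return fx.make_plate()


@pytest.fixture(scope="session")
def default_tables():
    return fx.make_tables()


@pytest.fixture(scope="session")
def scenario_matrix():
    """The 8 volatile x sorbing x degrading toggle combinations as
    chemical records (sorption strength follows log Kow)."""
    chems = []
    for volatile in (False, True):
        for sorbing in (False, True):
            for degrading in (False, True):
                chem = fx.make_chemical("inert").model_copy(update={
                    "name": f"v{volatile:d}s{sorbing:d}d{degrading:d}",
                    "henry_kaw": 0.2 if volatile else 0.0,
                    "log_kow": 3.5 if sorbing else 0.0,
                    "k_deg_water": 0.05 if degrading else 0.0,
                    "k_deg_air": 0.02 if (degrading and volatile) else 0.0,
                })
                chems.append(chem)
    return chems


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
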