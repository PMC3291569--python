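import pytest

from oricycle import CellCycleParams, SimulationConfig

# Printed cell-cycle table for DnaA-overexpression strains: each row is
# (ori/ter, oriC/cell, C period min, D period min) for the minus- and
# plus-arabinose conditions of WT, pgm::kan and ftsA*.
TABLE2_ROWS = [
    ("WT -ara", 3.54, 7.0, 43.8, 23.7),
    ("pgm -ara", 2.59, 5.5, 34.3, 27.2),
    ("ftsA* -ara", 2.73, 5.76, 34.8, 25.9),
    ("WT +ara", 4.37, 8.4, 51.1, 22.6),
]

# Initiation age / size table: (generation time min, initiation age,
# cells per mL at matched OD) for the E. coli strains in rich medium.
TABLE1_ECOLI = {
    "wt": {"tau": 25.4, "age": 0.17, "cells_per_ml": 6.4e8},
    "pgm": {"tau": 26.2, "age": 0.47, "cells_per_ml": 8.3e8},
    "ftsA": {"tau": 25.7, "age": 0.38, "cells_per_ml": 7.8e8},
}


@pytest.fixture
def wt_params():
    """Fast-growth wild-type-like parameter set with overlapping rounds
    ((C+D)/tau ~ 2.81: run-out classes at 4 and 8 chromosomes)."""
    return CellCycleParams(tau=24.0, c_period=43.8, d_period=23.7)


@pytest.fixture
def wt_config(wt_params):
    return SimulationConfig(params=wt_params, n_cells=20_000, seed=1)
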