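import numpy as np
import pandas as pd
import pytest

from ovorisk import ElementTable, SyntheticConfig, generate


def make_table(values: dict, systems=None) -> ElementTable:
    """Hand-build a small table: values = {(sample_id, part): {el: val}}."""
    rows, nd_rows = [], []
    elements = sorted({e for cell in values.values() for e in cell})
    for (sid, part), cell in values.items():
        system = (systems or {}).get(sid, "home")
        row = {"sample_id": sid, "egg_part": part, "system": system}
        nd = {}
        for e in elements:
            v = cell.get(e, 0.0)
            if v == "ND":
                row[e] = np.nan
                nd[e] = True
            else:
                row[e] = float(v)
                nd[e] = False
        rows.append(row)
        nd_rows.append(nd)
    data = pd.DataFrame(rows)
    ndf = pd.DataFrame(nd_rows)[elements]
    return ElementTable(data, ndf)


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic dataset (70 eggs, 210 rows, 64 elements)."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture
def two_egg_table():
    return make_table({
        ("E1", "white"): {"Na": 10000.0, "K": 4000.0, "Ca": 400.0, "Pb": 1.0},
        ("E1", "yolk"): {"Na": 600.0, "K": 600.0, "Ca": 1200.0, "Pb": 1.4},
        ("E1", "shell"): {"Na": 650.0, "K": 150.0, "Ca": 75000.0, "Pb": 0.1},
        ("E2", "white"): {"Na": 9000.0, "K": 4500.0, "Ca": 500.0, "Pb": 0.8},
        ("E2", "yolk"): {"Na": 700.0, "K": 550.0, "Ca": 1100.0, "Pb": 1.2},
        ("E2", "shell"): {"Na": 600.0, "K": 160.0, "Ca": 70000.0, "Pb": 0.2},
    }, systems={"E1": "home", "E2": "commercial"})
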