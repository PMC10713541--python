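import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from painnet.graph import PainGraph
from painnet.io import BrainAreaCatalog, ProjectionTable


def make_catalog(acronyms, groups=None, coords=None):
    n = len(acronyms)
    groups = groups or ["CH"] * n
    if coords is None:  # deterministic, non-collinear spread
        coords = np.array([[i, (i * i) % 7, (3 * i) % 5] for i in range(n)], float)
    return BrainAreaCatalog(
        pd.DataFrame(
            {
                "acronym": list(acronyms),
                "name": [f"area {a}" for a in acronyms],
                "group": groups,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
            }
        )
    )


def make_table(rows, catalog=None):
    """rows: (source, target, hemisphere, experiment_id, volume) tuples."""
    frame = pd.DataFrame(
        rows, columns=["source", "target", "hemisphere", "experiment_id", "volume"]
    )
    if catalog is None:
        areas = sorted(set(frame["source"]) | set(frame["target"]))
        catalog = make_catalog(areas)
    return ProjectionTable(frame, catalog)


def mutual_clique(names):
    g = PainGraph()
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            g.add_edge(u, v)
            g.add_edge(v, u)
    return g


def directed_cycle(names):
    g = PainGraph()
    for i, u in enumerate(names):
        g.add_edge(u, names[(i + 1) % len(names)])
    return g


@pytest.fixture
def toy_catalog():
    return make_catalog(["A", "B", "C", "D"])


@pytest.fixture
def small_connectome():
    """One default-conditions synthetic connectome, shared across tests."""
    from painnet.synthetic import SyntheticConfig, generate_connectome

    return generate_connectome(SyntheticConfig(seed=0))
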