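import numpy as np
import pandas as pd
import pytest

from modconn.blocks import enumerate_blocks, summarize_blocks
from modconn.connectivity import (build_connectome, detrend_series,
                                  standardize_series)
from modconn.synthetic import (SimulationDesign, generate_group_timeseries,
                               generate_parcellation)

#: Scaled-down 9-module node system used by the Monte-Carlo suites: same
#: module set and block structure as the reference 209-node system, fewer
#: nodes per module so many-seed loops stay fast.
SMALL_SIZES = (4, 3, 4, 5, 6, 6, 8, 6, 5)


def make_design(seed, planted=(), couplings=(), n_timepoints=1000,
                sizes=SMALL_SIZES, **kwargs):
    return SimulationDesign(
        nodes_per_module=sizes, n_modules=len(sizes),
        n_timepoints=n_timepoints, planted_effects=list(planted),
        behavior_couplings=list(couplings), seed=seed, **kwargs)


def connectomes_from_series(series, parcellation, poly_order=2):
    node_ids = tuple(parcellation.nodes["node_id"])
    return [build_connectome(standardize_series(detrend_series(v, poly_order)),
                             sid, node_ids)
            for sid, v in series.items()]


def run_synthetic_study(design):
    """Generator -> connectomes -> block summaries, returned as a dict."""
    parc = generate_parcellation(design)
    series, groups, truth = generate_group_timeseries(design, parc)
    conns = connectomes_from_series(series, parc)
    block_index = enumerate_blocks(parc)
    summaries = summarize_blocks(conns, block_index)
    return {"parcellation": parc, "series": series, "groups": groups,
            "truth": truth, "connectomes": conns, "block_index": block_index,
            "summaries": summaries}


@pytest.fixture(scope="session")
def small_study():
    """One fixed planted-effect study shared by read-only tests."""
    design = make_design(seed=11, planted=[("EC", "FPR", 0.3, 1)])
    return run_synthetic_study(design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_parcellation():
    nodes = pd.DataFrame({
        "node_id": ["a", "b", "c", "d"],
        "x": [0.0, 10.0, 20.0, 30.0],
        "y": [0.0] * 4,
        "z": [0.0] * 4,
        "module": ["Med Vis", "Med Vis", "DMN", "DMN"],
    })
    from modconn.parcellation import Parcellation
    return Parcellation(nodes)
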