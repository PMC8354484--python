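"""Reference networks and parameter sets used throughout tests and docs.

The three-node worked examples are reconstructed from their defining
descriptions: the activating three-cycle (``network1``), the six-edge
all-activator design in which node 0 receives from every node, node 1 from
nodes 0 and 2, and node 2 from node 0 (``network12``), and the same design
minus the edge 2→1 (``network6``).  ``expected`` collects the reference
quantities each fixture is known to reproduce, used by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .networks import RegulatoryNetwork, parse_network

__all__ = ["Fixture", "make_fixture", "benchmark_hill_parameters", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class Fixture:
    name: str
    network: RegulatoryNetwork
    expected: dict = field(default_factory=dict)


_SPECS = {
    # activating 3-cycle 0 -> 1 -> 2 -> 0
    "network1": "x0 : (x2)\nx1 : (x0)\nx2 : (x1)",
    # network12 minus the edge 2 -> 1
    "network6": "x0 : (x0+x1+x2)\nx1 : (x0)\nx2 : (x0)",
    # six-edge all-activator switch design
    "network12": "x0 : (x0+x1+x2)\nx1 : (x0+x2)\nx2 : (x0)",
    # single node, no in-edge, one out-threshold (placeholder)
    "toy1d": "x0 :",
    # single self-repressing node (exercises the refined complex)
    "selfrepressor": "x0 : (~x0)",
}

_EXPECTED = {
    "network1": {
        "parameter_graph_size": 27,
        "hysteresis_score": 100.0,
        "perturbed_score": 20.0,
        "robustness": 0.2,
        "fragile": True,
        "n_cells": 8,
    },
    "network6": {
        "n_edges": 5,
        "n_cells": 16,
        "assured_fps": [(0, 0, 0), (3, 1, 1)],
    },
    "network12": {
        "n_edges": 6,
        "full_path_hysteresis_score": 100.0,
    },
    "toy1d": {"factor_graph_size": 2},
    "selfrepressor": {"n_cells": 3},
}

FIXTURE_NAMES = tuple(_SPECS)


def make_fixture(name: str) -> Fixture:
    if name not in _SPECS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    net = parse_network(_SPECS[name])
    return Fixture(name=name, network=net, expected=dict(_EXPECTED[name]))


def benchmark_hill_parameters() -> dict:
    """Published sample parameter point for the six-edge all-activator model.

    Decay rates are 1; the basal rates were published in lumped form
    (L_i = sum of the per-edge low rates of node i) and are split evenly
    across each node's in-edges, which leaves the Hill right-hand side
    unchanged.  With Hill exponent 4 this point yields a two-fold hysteretic
    continuation curve in the input signal.
    """
    L0 = 0.508736659464953
    L1 = 0.823149364604282
    L2 = 0.129562882298977
    return {
        ("g", 0): 1.0, ("g", 1): 1.0, ("g", 2): 1.0,
        ("t", 0, 0): 2.742699202456864,
        ("t", 1, 0): 3.176067131107269,
        ("t", 2, 0): 3.406985767928092,
        ("t", 0, 1): 1.753260803421655,
        ("t", 0, 2): 0.724695975751957,
        ("t", 1, 2): 1.566020932246446,
        ("d", 0, 0): 1.172412555847297,
        ("d", 1, 0): 2.862607698545040,
        ("d", 2, 0): 4.947150771599252,
        ("d", 0, 1): 0.946904335902318,
        ("d", 0, 2): 0.077108238106769,
        ("d", 1, 2): 1.624416688203425,
        ("l", 0, 0): L0 / 3, ("l", 0, 1): L0 / 3, ("l", 0, 2): L0 / 3,
        ("l", 1, 0): L1 / 2, ("l", 1, 2): L1 / 2,
        ("l", 2, 0): L2,
    }
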