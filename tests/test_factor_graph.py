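"""Factor-graph enumeration: up-sets, realizability, essentiality, order."""

import itertools
import math

import numpy as np
import pytest
import sympy

from switchgrade import (
    count_nested_chains,
    enumerate_factor_graph,
    enumerate_up_sets,
    is_realizable,
    parse_network,
    production_value_exprs,
    production_values,
)
from switchgrade.factor import DegenerateParameterError, input_states


@pytest.fixture(scope="module")
def net_11():
    """Both nodes have one in-edge and one out-edge."""
    return parse_network("x0:(x1)\nx1:(x0)")


@pytest.fixture(scope="module")
def net_2act():
    """Node 0 sums two activators and carries one out-edge."""
    return parse_network("x0:(x1+x2)\nx1:(x0)\nx2:(x1)")


class TestProductionValues:
    def test_summed_activators(self, net12):
        exprs = production_value_exprs(net12, 1)
        l10, d10, l12 = sympy.symbols("l_1_0 d_1_0 l_1_2", positive=True)
        assert sympy.simplify(exprs[(1, 0)] - (l10 + d10 + l12)) == 0

    def test_mixed_product(self):
        net = parse_network("x0:(x1)\nx1:(x0)(~x2)\nx2:(x0)")
        exprs = production_value_exprs(net, 1)
        l10, d10, l12 = sympy.symbols("l_1_0 d_1_0 l_1_2", positive=True)
        # both inputs high: activator at l+d, repressor factor at its low value
        assert sympy.simplify(exprs[(1, 1)] - (l10 + d10) * l12) == 0

    def test_no_in_edge_constant(self):
        net = parse_network("x0 :\nx1 : (x0)")
        exprs = production_value_exprs(net, 0)
        assert list(exprs) == [()]
        assert str(exprs[()]) == "beta_0"

    def test_numeric_matches_symbolic(self, net12):
        params = {("l", 1, 0): 0.3, ("d", 1, 0): 0.9,
                  ("l", 1, 2): 0.2, ("d", 1, 2): 0.5}
        vals = production_values(net12, 1, params)
        assert vals[(1, 0)] == pytest.approx(0.3 + 0.9 + 0.2)
        assert vals[(1, 1)] == pytest.approx(0.3 + 0.9 + 0.2 + 0.5)


class TestUpSetsAndChains:
    def test_up_set_counts(self):
        assert len(enumerate_up_sets(())) == 2
        assert len(enumerate_up_sets((1,))) == 3
        assert len(enumerate_up_sets((1, 1))) == 6
        assert len(enumerate_up_sets((1, -1))) == 6  # polarity flip, same count
        assert len(enumerate_up_sets((1, 1, 1))) == 20

    def test_nested_chain_counts(self):
        assert count_nested_chains(1, 1) == 3
        assert count_nested_chains(2, 2) == 20
        assert count_nested_chains(1, 2) == 6

    def test_up_set_invariant(self):
        # flipping an activator bit up never leaves an up-set
        for U in enumerate_up_sets((1, 1)):
            for s in U:
                for j in range(2):
                    if s[j] == 0:
                        up = s[:j] + (1,) + s[j + 1:]
                        assert up in U


class TestRealizability:
    def test_one_in_one_out_regions(self, net_11):
        fg = enumerate_factor_graph(net_11, 0)
        assert len(fg) == 3
        # a path: the middle (essential) region adjacent to both extremes
        assert fg.essential_indices() == [fg.minimal_vertex() + 1]
        assert len(fg.adjacency) == 2

    def test_monotonicity_violation_rejected(self, net_11):
        states = input_states(1)
        bad = (frozenset({states[0]}),)  # low state above, high below
        w, status = is_realizable(net_11, 0, (1,), bad)
        assert w is None and status == "invalid-chain"

    def test_two_summed_activators_all_up_sets(self, net_2act):
        fg = enumerate_factor_graph(net_2act, 0)
        assert len(fg) == 6
        ess = fg.essential_indices()
        chains = {fg.vertices[i].chain[0] for i in ess}
        and_like = frozenset({(1, 1)})
        or_like = frozenset({(1, 1), (1, 0), (0, 1)})
        assert chains == {and_like, or_like}

    def test_no_in_edge_node(self):
        net = parse_network("x0 :\nx1 : (x0)")
        fg = enumerate_factor_graph(net, 0)
        assert len(fg) == 2  # beta below / above the single threshold

    def test_witness_margin(self, net_2act):
        fg = enumerate_factor_graph(net_2act, 0)
        for v in fg.vertices:
            vals = production_values(net_2act, 0, v.witness)
            g = v.witness[("g", 0)]
            ts = [g * v.witness[("t", tgt, 0)] for tgt in v.order]
            for s, val in vals.items():
                k = v.k_of(s)
                if k >= 1:
                    assert val > ts[k - 1]
                if k < len(ts):
                    assert val < ts[k]


class TestGraphStructure:
    def test_signal_order_unique_extremes(self, pg12):
        fg = pg12.factors[0]
        lo, hi = fg.minimal_vertex(), fg.maximal_vertex()
        assert all(fg.signal_le(lo, i) for i in range(len(fg)))
        assert all(fg.signal_le(i, hi) for i in range(len(fg)))

    def test_adjacency_single_difference(self, net_2act):
        fg = enumerate_factor_graph(net_2act, 0)
        for a, b in fg.adjacency:
            u, w = fg.vertices[a], fg.vertices[b]
            assert u.order == w.order
            diffs = sum(len(x ^ y) for x, y in zip(u.chain, w.chain))
            assert diffs == 1

    def test_cross_class_adjacency(self, net12):
        # node 2 has two out-thresholds: order swap is an adjacency when the
        # two binarization sets coincide
        fg = enumerate_factor_graph(net12, 2, classes="all")
        cross = [
            (a, b) for a, b in fg.adjacency
            if fg.vertices[a].order != fg.vertices[b].order
        ]
        assert cross, "expected order-swap adjacencies"
        for a, b in cross:
            u = fg.vertices[a]
            assert u.chain[0] == u.chain[1]


class TestClassification:
    @pytest.mark.parametrize(
        "text, node",
        [
            ("x0:(x1)\nx1:(x0)", 0),                 # 1 activator, 1 out
            ("x0:(x1+x2)\nx1:(x0)\nx2:(x1)", 0),     # 2 activators, 1 out
            ("x0:(~x1)\nx1:(x0)", 0),                # 1 repressor, 1 out
            ("x0:(x1)\nx1:(x0)\nx2:(x0)", 0),        # 1 activator, 2 out
        ],
    )
    def test_partition_oracle_small(self, text, node):
        """Random positive parameter points always classify onto an
        enumerated vertex, and witnesses classify back to themselves."""
        net = parse_network(text)
        fg = enumerate_factor_graph(net, node, classes="all")
        rng = np.random.default_rng(5)
        edges = net.in_edges(node)
        for _ in range(800):
            params = {("g", node): 1.0}
            for src, _sign in edges:
                params[("l", node, src)] = math.exp(rng.uniform(-2, 2))
                params[("d", node, src)] = math.exp(rng.uniform(-2, 2))
            for tgt in net.out_edges(node):
                params[("t", tgt, node)] = math.exp(rng.uniform(-2, 2))
            try:
                idx = fg.classify_params(params)
            except DegenerateParameterError:
                continue
            assert 0 <= idx < len(fg)
        for i, v in enumerate(fg.vertices):
            assert fg.classify_params(v.witness) == i
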