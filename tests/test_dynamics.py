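"""Cubical complex, wall labels, STG and Morse graphs on the worked examples."""

import networkx as nx
import pytest

from switchgrade import (
    build_parameter_graph,
    build_stg,
    make_fixture,
    morse_graph,
    parse_network,
)
from switchgrade.dynamics import ABSORBING, REPELLING, build_complex, label_walls


def _fvs(pg, coords):
    return [pg.factors[n].vertices[coords[n]] for n in range(len(coords))]


@pytest.fixture(scope="module")
def selfrep_pg():
    return build_parameter_graph(make_fixture("selfrepressor").network)


class TestComplex:
    def test_three_cycle_eight_cells(self, pg1):
        cx = build_complex(pg1.net, _fvs(pg1, (0, 0, 0)))
        assert cx.n_cells() == 8

    def test_network6_sixteen_cells(self, pg6):
        cx = build_complex(pg6.net, _fvs(pg6, (0, 0, 0)))
        assert cx.n_cells() == 16  # 4 x 2 x 2

    def test_placeholder_threshold_for_no_out_node(self):
        net = parse_network("x0 :\nx1 : (x0)")
        pg = build_parameter_graph(net)
        cx = build_complex(net, _fvs(pg, (0, 0)))
        # both nodes carry one threshold: node 1's is the placeholder
        assert cx.n_cells() == 4

    def test_self_repressor_refinement(self, selfrep_pg):
        cx = build_complex(selfrep_pg.net, _fvs(selfrep_pg, (0,)))
        assert cx.n_cells() == 3
        # collapse consistency: forgetting the doubled coordinate recovers
        # the two-cell unrefined complex
        assert [cx.report_coords(c) for c in cx.cells()] == [(0,), (0,), (1,)]


class TestWallLabels:
    def test_every_wall_labeled(self, pg1):
        for coords in pg1.vertices():
            cx = build_complex(pg1.net, _fvs(pg1, coords))
            for w in label_walls(cx):
                assert w.label_lower in (ABSORBING, REPELLING)
                assert w.label_upper in (ABSORBING, REPELLING)

    def test_low_region_walls_absorb_from_above(self):
        # a (1,1) node whose production always lies below its threshold:
        # the variable decays through the wall from above everywhere
        net = parse_network("x0:(x1)\nx1:(x0)")
        pg = build_parameter_graph(net)
        hi = pg.factors[0].maximal_vertex()
        lo = pg.factors[0].minimal_vertex()
        cx = build_complex(net, _fvs(pg, (lo, 0)))
        for w in label_walls(cx):
            if w.axis == 0:
                assert w.label_upper == ABSORBING
                assert w.label_lower == REPELLING

    def test_self_threshold_copies_oppose(self, selfrep_pg):
        mid = 1  # essential region: threshold interleaves the two rates
        cx = build_complex(selfrep_pg.net, _fvs(selfrep_pg, (mid,)))
        walls = label_walls(cx)
        inner = {w.threshold_index: w for w in walls}
        # wall below the thin slab absorbs from outside, repels into the slab
        assert inner[1].label_lower == ABSORBING
        assert inner[1].label_upper == REPELLING
        assert inner[2].label_upper == ABSORBING
        assert inner[2].label_lower == REPELLING


class TestSTGAndMorse:
    def test_signal_sweep_of_three_cycle(self, pg1):
        """Low input is monostable low, medium input bistable, high input
        monostable high — the switching signature of the activating cycle."""
        f = pg1.factors
        v1 = f[1].essential_indices()[0]
        v2 = f[2].essential_indices()[0]
        expected = {0: [(0, 0, 0)], 1: [(0, 0, 0), (1, 1, 1)], 2: [(1, 1, 1)]}
        for v0, fps in expected.items():
            stg = build_stg(pg1.net, _fvs(pg1, (v0, v1, v2)))
            mg = morse_graph(stg)
            assert mg.minimal_fp_labels() == fps

    def test_self_edges_are_sinks(self, pg1):
        stg = build_stg(pg1.net, _fvs(pg1, (1, 1, 1)))
        assert stg.has_self_edge((0, 0, 0))
        assert stg.has_self_edge((1, 1, 1))
        for cell in stg.cells:
            if stg.has_self_edge(cell):
                outs = [e for e in stg.edges if e[0] == cell and e[1] != cell]
                assert not outs

    def test_morse_acyclic_with_minimal_node(self, pg1):
        for coords in pg1.vertices():
            mg = morse_graph(build_stg(pg1.net, _fvs(pg1, coords)))
            g = nx.DiGraph(mg.edges)
            g.add_nodes_from(range(len(mg.nodes)))
            assert nx.is_directed_acyclic_graph(g)
            assert mg.minimal

    def test_pure_cycle_stg_has_single_morse_node(self):
        # a repressilator-like loop oscillates: one recurrent component,
        # no FP label on it
        net = parse_network("x0:(~x2)\nx1:(~x0)\nx2:(~x1)")
        pg = build_parameter_graph(net)
        mids = [f.essential_indices()[0] for f in pg.factors]
        mg = morse_graph(build_stg(net, _fvs(pg, tuple(mids))))
        assert len(mg.nodes) == 1
        assert 0 not in mg.fp_labels
        big = max(len(ns) for ns in mg.nodes)
        assert big > 1

    def test_self_repressor_fp_at_thin_cell(self, selfrep_pg):
        for idx, fps in ((0, [(0,)]), (1, [(0,)]), (2, [(1,)])):
            mg = morse_graph(
                build_stg(selfrep_pg.net, _fvs(selfrep_pg, (idx,)))
            )
            assert mg.minimal_fp_labels() == fps

    def test_exports_are_wellformed(self, pg1):
        stg = build_stg(pg1.net, _fvs(pg1, (1, 1, 1)))
        mg = morse_graph(stg)
        dot = stg.to_dot()
        assert dot.startswith("digraph stg") and '"0,0,0" -> ' in dot
        mdot = mg.to_dot()
        assert "FP(0,0,0)" in mdot and "FP(1,1,1)" in mdot
        d = mg.to_dict()
        assert set(d) == {"nodes", "edges", "minimal", "fp"}

    def test_self_repression_with_downstream_node(self):
        """Doubled coordinate interacts correctly with a second axis."""
        net = parse_network("x0:(~x0)\nx1:(x0)")
        pg = build_parameter_graph(net)
        for coords in pg.vertices():
            mg = morse_graph(build_stg(net, _fvs(pg, coords)))
            g = nx.DiGraph(mg.edges)
            g.add_nodes_from(range(len(mg.nodes)))
            assert nx.is_directed_acyclic_graph(g)
            assert mg.minimal
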