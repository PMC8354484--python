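"""Combinatorial dynamics: cubical complex, wall labels, STG, Morse graph.

Phase space ``(0,∞)^N`` is cut by the threshold hyperplanes ``x_n = θ_{m,n}``
into rectangular *top cells*.  On each shared face (*wall*) the sign of
``-γ_n θ + Λ_n(x)`` is constant over a parameter region, labelling the wall
absorbing or repelling with respect to each of its two cells; those labels
induce the state transition graph (STG).  A cell all of whose walls repel
is an attracting equilibrium cell, annotated ``FP(α_0,...,α_{N-1})`` where
``α_n`` counts the true thresholds below the cell.

Two extensions widen the class of tractable networks: a node without
out-edges receives a placeholder threshold (used only to build the complex),
and a self-repressing node has its self-threshold doubled into a thin slab
so that walls on which the flow converges from both sides become a cell of
their own (labels on the two copies are set to opposite sides of the
classical label, and all other labels follow the classical rule).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .factor import FactorVertex
from .networks import RegulatoryNetwork

__all__ = [
    "CellComplex",
    "Wall",
    "StateTransitionGraph",
    "MorseGraph",
    "build_complex",
    "label_walls",
    "build_stg",
    "morse_graph",
]

ABSORBING = "absorbing"
REPELLING = "repelling"


@dataclass(frozen=True)
class Wall:
    lower_cell: tuple
    upper_cell: tuple
    axis: int
    threshold_index: int      # refined position, 1-based
    label_lower: str
    label_upper: str


class CellComplex:
    """Cubical decomposition of phase space at one parameter-graph vertex."""

    def __init__(self, net: RegulatoryNetwork, vertices: list[FactorVertex]):
        if len(vertices) != net.n_nodes:
            raise ValueError("need one factor vertex per node")
        self.net = net
        self.fvs = vertices
        self.orders = [v.order for v in vertices]
        self.E = [len(o) for o in self.orders]
        # refined self-repression bookkeeping: 1-based rank of the doubled
        # self-threshold in the node's threshold order, or None
        self.self_rank = []
        for n in range(net.n_nodes):
            if net.a(n, n) == -1:
                self.self_rank.append(self.orders[n].index(n) + 1)
            else:
                self.self_rank.append(None)
        self.extent = [
            self.E[n] + (1 if self.self_rank[n] is not None else 0)
            for n in range(net.n_nodes)
        ]

    # -- cells ------------------------------------------------------------
    def cells(self):
        return itertools.product(*(range(e + 1) for e in self.extent))

    def n_cells(self) -> int:
        out = 1
        for e in self.extent:
            out *= e + 1
        return out

    def report_coords(self, cell: tuple) -> tuple:
        """Collapse doubled self-threshold indices to true threshold counts."""
        out = []
        for n, j in enumerate(cell):
            k = self.self_rank[n]
            if k is None or j <= k - 1:
                out.append(j)
            elif j == k:       # thin slab sits at the true threshold
                out.append(k - 1)
            else:
                out.append(j - 1)
        return tuple(out)

    # -- threshold geometry -------------------------------------------------
    def refined_position(self, axis: int, target: int) -> int:
        """Refined 1-based position of threshold θ_{target,axis} on ``axis``.

        For the doubled self-threshold this returns the lower copy.
        """
        r = self.orders[axis].index(target) + 1
        k = self.self_rank[axis]
        if k is not None and r > k:
            return r + 1
        return r

    def true_rank(self, axis: int, position: int) -> int:
        """True (unrefined) threshold rank for a refined wall position."""
        k = self.self_rank[axis]
        if k is None or position < k:
            return position
        if position in (k, k + 1):
            return k
        return position - 1

    def _bit(self, source: int, j_source: int, target: int) -> int:
        """Is x_source above θ_{target,source} in a cell with coord j_source?"""
        r = self.orders[source].index(target) + 1
        k = self.self_rank[source]
        if k is not None:
            if target == source:
                if j_source <= k - 1:
                    return 0
                if j_source >= k + 1:
                    return 1
                raise AssertionError(
                    "self bit requested inside the thin self-threshold slab"
                )
            if r > k:
                r += 1
        return 1 if j_source >= r else 0

    def input_state(self, node: int, cell: tuple) -> tuple:
        """Switch state of ``node``'s inputs inside ``cell``."""
        return tuple(
            self._bit(src, cell[src], node)
            for src, _ in self.net.in_edges(node)
        )

    def above_threshold(self, node: int, state: tuple, rank: int) -> bool:
        """Does the production value at ``state`` exceed the rank-th threshold?"""
        return state in self.fvs[node].chain[rank - 1]


def build_complex(net: RegulatoryNetwork, vertices: list[FactorVertex]) -> CellComplex:
    return CellComplex(net, vertices)


def label_walls(cx: CellComplex) -> list[Wall]:
    """Label every interior wall absorbing/repelling w.r.t. both cells."""
    net = cx.net
    walls = []
    for axis in range(net.n_nodes):
        k = cx.self_rank[axis]
        for pos in range(1, cx.extent[axis] + 1):
            rank = cx.true_rank(axis, pos)
            ranges = [
                range(cx.extent[m] + 1) if m != axis else (pos - 1,)
                for m in range(net.n_nodes)
            ]
            for lower in itertools.product(*ranges):
                upper = lower[:axis] + (pos,) + lower[axis + 1:]

                def classical(side_cell):
                    s = cx.input_state(axis, side_cell)
                    above = cx.above_threshold(axis, s, rank)
                    # flow at the wall points up iff production exceeds γθ
                    if side_cell is lower:
                        return ABSORBING if above else REPELLING
                    return REPELLING if above else ABSORBING

                if k is not None and pos == k:
                    ll = classical(lower)
                    lu = ABSORBING if ll == REPELLING else REPELLING
                elif k is not None and pos == k + 1:
                    lu = classical(upper)
                    ll = ABSORBING if lu == REPELLING else REPELLING
                else:
                    ll = classical(lower)
                    lu = classical(upper)
                    assert not (ll == ABSORBING and lu == ABSORBING), (
                        "both-absorbing wall outside a doubled self-threshold"
                    )
                walls.append(Wall(lower, upper, axis, pos, ll, lu))
    return walls


@dataclass
class StateTransitionGraph:
    cells: list[tuple]
    edges: set[tuple]            # (from_cell, to_cell); self-loops included
    walls: list[Wall]
    complex: CellComplex

    def has_self_edge(self, cell: tuple) -> bool:
        return (cell, cell) in self.edges

    def to_dot(self) -> str:
        def name(c):
            return '"' + ",".join(map(str, c)) + '"'

        lines = ["digraph stg {"]
        lines += [f"  {name(c)};" for c in self.cells]
        lines += [f"  {name(a)} -> {name(b)};" for a, b in sorted(self.edges)]
        lines.append("}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cells": [list(c) for c in self.cells],
            "edges": sorted([list(a), list(b)] for a, b in self.edges),
        }


def build_stg(net: RegulatoryNetwork, vertices: list[FactorVertex]) -> StateTransitionGraph:
    """STG from wall labels: an edge crosses each wall in its absorbing
    direction; a cell with no outgoing wall gets a self-edge (an FP cell).

    Boundary faces at 0 and ∞ are repelling (positivity and decay dominate),
    so they never contribute outgoing edges.
    """
    cx = build_complex(net, vertices)
    walls = label_walls(cx)
    edges: set[tuple] = set()
    has_out: dict[tuple, bool] = {}
    for w in walls:
        if w.label_lower == ABSORBING:
            edges.add((w.lower_cell, w.upper_cell))
            has_out[w.lower_cell] = True
        if w.label_upper == ABSORBING:
            edges.add((w.upper_cell, w.lower_cell))
            has_out[w.upper_cell] = True
    cells = list(cx.cells())
    for c in cells:
        if not has_out.get(c):
            edges.add((c, c))
    return StateTransitionGraph(cells=cells, edges=edges, walls=walls, complex=cx)


@dataclass
class MorseGraph:
    """Acyclic condensation of the recurrent part of an STG.

    ``nodes`` are the recurrent strongly connected components (a singleton
    counts only if it carries a self-edge); ``edges (i, j)`` point in the
    direction of the dynamics (j reachable from i); ``minimal`` nodes have
    no successors and are the attractors; ``fp_labels`` annotates singleton
    attracting cells with their collapsed threshold coordinates.
    """

    nodes: list[frozenset]
    edges: set[tuple]
    minimal: list[int]
    fp_labels: dict[int, tuple]

    def minimal_fp_labels(self) -> list[tuple]:
        return sorted(self.fp_labels[i] for i in self.minimal if i in self.fp_labels)

    def to_dict(self) -> dict:
        return {
            "nodes": [sorted(map(list, ns)) for ns in self.nodes],
            "edges": sorted(map(list, self.edges)),
            "minimal": self.minimal,
            "fp": {str(i): list(v) for i, v in self.fp_labels.items()},
        }

    def to_dot(self) -> str:
        lines = ["digraph morse {"]
        for i in range(len(self.nodes)):
            label = (
                "FP(" + ",".join(map(str, self.fp_labels[i])) + ")"
                if i in self.fp_labels
                else f"rec{i}"
            )
            shape = ' peripheries=2' if i in self.minimal else ""
            lines.append(f'  n{i} [label="{label}"{shape}];')
        lines += [f"  n{a} -> n{b};" for a, b in sorted(self.edges)]
        lines.append("}")
        return "\n".join(lines)


def morse_graph(stg: StateTransitionGraph) -> MorseGraph:
    g = nx.DiGraph()
    g.add_nodes_from(stg.cells)
    g.add_edges_from(stg.edges)
    comps = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=comps)
    comp_of = cond.graph["mapping"]
    members = {i: frozenset(ns) for i, ns in enumerate(comps)}
    rec_ids = [
        i for i, ns in members.items()
        if len(ns) > 1 or stg.has_self_edge(next(iter(ns)))
    ]
    # reachability among recurrent components through the condensation DAG
    reach = {i: nx.descendants(cond, comp_of[next(iter(members[i]))]) for i in rec_ids}
    cid = {i: comp_of[next(iter(members[i]))] for i in rec_ids}
    order_edges = set()
    for a in rec_ids:
        for b in rec_ids:
            if a != b and cid[b] in reach[a]:
                order_edges.add((a, b))
    # transitive reduction for presentation
    h = nx.DiGraph(order_edges)
    h.add_nodes_from(rec_ids)
    h = nx.transitive_reduction(h)
    index = {comp_id: k for k, comp_id in enumerate(rec_ids)}
    nodes = [members[i] for i in rec_ids]
    edges = {(index[a], index[b]) for a, b in h.edges}
    has_succ = {index[a] for a, b in order_edges}
    minimal = [k for k in range(len(nodes)) if k not in has_succ]
    fp_labels = {}
    for k, ns in enumerate(nodes):
        if len(ns) == 1:
            (cell,) = ns
            if stg.has_self_edge(cell):
                fp_labels[k] = stg.complex.report_coords(cell)
    return MorseGraph(nodes=nodes, edges=edges, minimal=minimal, fp_labels=fp_labels)
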